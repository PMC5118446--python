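import warnings

import numpy as np
import pandas as pd
import pytest

from gsbench import markers as mk
from gsbench import synthetic as syn

warnings.filterwarnings("ignore", message="undefined correlation")


@pytest.fixture(scope="session")
def two_group_panel():
    """Structured two-group panel with mixed marker types (shared, read-only)."""
    cfg = syn.SimConfig(
        n_lines=120,
        group_sizes=(60, 60),
        fst=0.25,
        n_markers=400,
        frac_dominant=0.4,
        n_qtl=40,
        n_envs=2,
        n_reps=3,
        blocks_per_rep=5,
        seed=11,
    )
    geno, truth, pheno = syn.simulate_dataset(cfg)
    return cfg, geno, truth, pheno


def make_additive_panel(seed, h2, n=200, p=500, n_qtl=50, fst=0.0, groups=1):
    """Single-trait additive panel with noise injected at the entry-mean level."""
    sizes = tuple([n // groups] * groups)
    cfg = syn.SimConfig(
        n_lines=n,
        n_groups=groups,
        group_sizes=sizes,
        fst=fst,
        n_markers=p,
        frac_dominant=0.0,
        n_qtl=n_qtl,
        trait_names=("T",),
        target_H2=(h2,),
        n_envs=1,
        seed=seed,
    )
    geno, truth = syn.simulate_genotypes(cfg, np.random.default_rng(seed))
    truth = syn.simulate_qtl(geno, cfg, truth, np.random.default_rng(seed + 1))
    tbv = truth.true_breeding_values[:, 0]
    rng = np.random.default_rng(seed + 2)
    noise_sd = np.sqrt(tbv.var() * (1.0 / h2 - 1.0)) if h2 < 1 else 0.0
    y = tbv + rng.normal(0.0, noise_sd, n)
    blups = pd.DataFrame({"entry": geno.line_ids, "adjusted": y})
    return geno, truth, tbv, y, blups


@pytest.fixture(scope="session")
def additive_panel():
    return make_additive_panel(seed=1, h2=0.9, n=300, p=1000)


@pytest.fixture(scope="session")
def dose_matrix(two_group_panel):
    _, geno, _, _ = two_group_panel
    return mk.impute_missing(geno)
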