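"""Readers and writers for the pipeline's on-disk artifacts.

All other modules are format-agnostic: they consume :class:`GenotypeMatrix`
and phenotype record frames produced here.  Dialects are deliberately strict —
malformed input is rejected, never coerced.

Genotype dialect: comma-delimited, lines as rows, markers as columns, first
column ``line_id``, missing call ``NA`` (``-9`` accepted on read).  The marker
map is a separate 4-column CSV (marker_id, chrom, pos_bp, marker_type) with
1-based positions and free-form chromosome labels (e.g. ``CaLG04``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan
#: accepted missing tokens on read; the first is written
MISSING_TOKENS = ("NA", "-9")

CODOMINANT = "codominant"
DOMINANT = "dominant"


class FormatError(ValueError):
    """Malformed on-disk artifact."""


@dataclass
class GenotypeMatrix:
    """Lines x markers integer genotype calls plus a marker map.

    ``calls`` is float so missing can be ``NaN``; valid codes are {0,1,2} for
    codominant (SNP dose) markers and {0,1} for dominant (presence/absence)
    markers.  ``marker_map`` columns: marker_id, chrom, pos_bp (1-based),
    marker_type.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    marker_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise FormatError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise FormatError("duplicate marker ids")
        mm = self.marker_map
        required = {"marker_id", "chrom", "pos_bp", "marker_type"}
        if not required.issubset(mm.columns):
            raise FormatError(f"marker map needs columns {sorted(required)}")
        if list(mm["marker_id"]) != list(self.marker_ids):
            raise FormatError("marker map order must match marker_ids")
        if (mm["pos_bp"] <= 0).any():
            raise FormatError("marker positions must be strictly positive (1-based)")
        bad = set(mm["marker_type"]) - {CODOMINANT, DOMINANT}
        if bad:
            raise FormatError(f"unknown marker types: {sorted(bad)}")
        self._validate_calls()

    def _validate_calls(self) -> None:
        types = self.marker_map["marker_type"].to_numpy()
        dom = types == DOMINANT
        with np.errstate(invalid="ignore"):
            ok_codom = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
            ok_dom = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0))
        bad = np.where(dom[None, :], ~ok_dom, ~ok_codom)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid call {self.calls[i, j]!r} for {types[j]} marker "
                f"{self.marker_ids[j]!r} (line {self.line_ids[i]!r})"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def is_dominant(self) -> np.ndarray:
        return (self.marker_map["marker_type"] == DOMINANT).to_numpy()

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping markers at ``index`` (positions or bool mask)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[i] for i in index],
            calls=self.calls[:, index],
            marker_map=self.marker_map.iloc[index].reset_index(drop=True),
        )

    def subset_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in index],
            marker_ids=list(self.marker_ids),
            calls=self.calls[index, :],
            marker_map=self.marker_map.copy(),
        )


PHENO_COLUMNS = ["entry", "env", "rep", "block", "trait", "value"]


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format plot-record frame (entry/env/rep/block/trait/value)."""
    missing_cols = set(PHENO_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"phenotype records missing columns {sorted(missing_cols)}")
    df = df[PHENO_COLUMNS].copy()
    for c in ("entry", "env", "rep", "block", "trait"):
        df[c] = df[c].astype(str)
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric phenotype value: {exc}") from exc
    if not np.isfinite(df["value"]).all():
        raise FormatError("phenotype values must be finite")
    key = ["entry", "env", "rep", "trait"]
    dups = df.duplicated(subset=key)
    if dups.any():
        first = df.loc[dups.idxmax(), key].tolist()
        raise FormatError(f"duplicate (entry, env, rep, trait) row: {first}")
    return df


# ---------------------------------------------------------------------------
# genotype files


def _parse_call(token: str, row: str, col: str) -> float:
    if token in MISSING_TOKENS or token == "":
        return MISSING
    try:
        val = float(token)
    except ValueError:
        raise FormatError(f"unknown genotype code {token!r} at line {row!r}, marker {col!r}")
    if val not in (0.0, 1.0, 2.0):
        raise FormatError(f"unknown genotype code {token!r} at line {row!r}, marker {col!r}")
    return val


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Read the genotype CSV plus its marker-map CSV."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.columns[0] != "line_id":
        raise FormatError("first genotype column must be 'line_id'")
    marker_ids = list(raw.columns[1:])
    line_ids = list(raw["line_id"])
    calls = np.empty((len(line_ids), len(marker_ids)))
    for j, m in enumerate(marker_ids):
        col = raw[m].to_numpy()
        for i, tok in enumerate(col):
            calls[i, j] = _parse_call(tok, line_ids[i], m)
    mm = pd.read_csv(map_path, dtype={"marker_id": str, "chrom": str})
    return GenotypeMatrix(line_ids, marker_ids, calls, mm)


def write_genotypes(geno: GenotypeMatrix, path, map_path) -> None:
    df = pd.DataFrame(geno.calls, columns=geno.marker_ids)
    # integer codes on disk, NA for missing
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.insert(0, "line_id", geno.line_ids)
    out.to_csv(path, index=False)
    geno.marker_map.to_csv(map_path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(records: pd.DataFrame, path) -> None:
    validate_phenotypes(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF import (SNPs only; biallelic, GT field)


def read_vcf(path) -> GenotypeMatrix:
    """Import biallelic SNPs from a VCF as codominant dose markers.

    Only the GT field is used; unphased and phased calls are accepted.
    Multi-allelic records are skipped with a warning.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires cyvcf2 (install extra 'vcf')") from exc

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows = []
    map_rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_ids.append(mid)
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = MISSING
        rows.append(dose)
        map_rows.append((mid, var.CHROM, int(var.POS), CODOMINANT))
    calls = np.column_stack(rows) if rows else np.empty((len(line_ids), 0))
    mm = pd.DataFrame(map_rows, columns=["marker_id", "chrom", "pos_bp", "marker_type"])
    return GenotypeMatrix(line_ids, marker_ids, calls, mm)


# ---------------------------------------------------------------------------
# result tables

#: fixed column order and formats for the cross-validation summary table
CV_RESULT_COLUMNS = ["trait", "dataset", "model", "accuracy", "se", "slope"]
_CV_FORMATS = {"accuracy": "{:.3f}", "se": "{:.3f}", "slope": "{:.3f}"}


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write result tables as TSV with deterministic order and fixed decimals.

    Returns the mapping of table name to written path.  Re-running with the
    same inputs produces byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        df = df.copy()
        if set(CV_RESULT_COLUMNS).issubset(df.columns):
            df = df[CV_RESULT_COLUMNS + [c for c in df.columns if c not in CV_RESULT_COLUMNS]]
        for col, fmt in _CV_FORMATS.items():
            if col in df.columns:
                df[col] = df[col].map(
                    lambda v: "" if pd.isna(v) else fmt.format(v)
                )
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    return paths
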