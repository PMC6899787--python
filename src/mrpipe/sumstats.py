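"""Reading, validation, QC filtering and cross-cohort alignment of GWAS
summary statistics.

Summary statistics live in pandas DataFrames with a fixed canonical column
set; a :class:`CohortPanel` bundles one study's table with its label.  All
filters report per-reason removal counts through the module logger so a
pipeline run leaves an auditable QC trail.

Conventions
-----------
* Positions are 1-based on GRCh37; alleles are single-nucleotide, uppercase,
  forward strand.  No strand flipping is attempted during cohort alignment:
  inputs are expected to be pre-standardized, and allele-pair mismatches are
  dropped and counted rather than complement-rescued.
* Effect sizes are per effect-allele copy on a standardized (SD-unit)
  phenotype scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
CANONICAL_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "INFO",
]

_VALID_ALLELES = frozenset("ACGT")


class SumStatsError(ValueError):
    """Fatal configuration or data error in summary-statistics handling."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant: rsid preferred, (chrom, pos) fallback."""

    rsid: str = ""
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        if not self.rsid and not (self.chrom and self.pos >= 1):
            raise SumStatsError("variant needs an rsid or a (chrom, pos)")

    def __str__(self) -> str:
        return self.rsid if self.rsid else f"{self.chrom}:{self.pos}"


@dataclass
class QCThresholds:
    """Marginal QC filters applied per cohort before meta-analysis.

    Filters are strict inequalities: a variant at exactly the boundary is
    removed.  Records with missing imputation quality are retained only when
    ``info_min == 0`` (whole-genome-sequenced studies report no score).
    """

    maf_min: float = 0.01
    info_min: float = 0.8
    require_common_to_all: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min < 0.5):
            raise SumStatsError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if not (0 <= self.info_min <= 1):
            raise SumStatsError(f"info_min must be in [0, 1], got {self.info_min}")


@dataclass
class CohortPanel:
    """One study's validated summary statistics."""

    label: str
    df: pd.DataFrame
    n_default: int | None = None
    drop_counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def variant_keys(df: pd.DataFrame) -> pd.Series:
    """String key per row: rsid when present, else ``chrom:pos``."""
    rsid = df["SNP"].fillna("").astype(str)
    fallback = df["CHR"].astype(str) + ":" + df["POS"].astype("Int64").astype(str)
    return rsid.where(rsid.str.len() > 0, fallback)


def _normalise_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise SumStatsError(f"mapped columns absent from header: {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    else:
        upper = {c: c.upper() for c in df.columns}
        df = df.rename(columns=upper)
    mandatory = ["EA", "OA", "EAF", "BETA", "SE", "P"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SumStatsError(f"mandatory columns missing: {missing}")
    if "SNP" not in df.columns and not {"CHR", "POS"} <= set(df.columns):
        raise SumStatsError("need SNP or CHR+POS columns to key variants")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[CANONICAL_COLUMNS].copy()


def read_sumstats(
    path,
    column_map: dict | None = None,
    label: str = "",
    n_default: int | None = None,
) -> CohortPanel:
    """Read one cohort's summary statistics from delimited text.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited file with a header; gzip transparent.
    column_map
        Mapping from canonical name (``SNP``, ``CHR``, ``POS``, ``EA``,
        ``OA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``, ``INFO``) to the
        column name used in the file.  ``None`` matches canonical names
        case-insensitively.
    label
        Study label carried through to alignment and meta-analysis.
    n_default
        Fallback sample size for rows without an ``N`` entry.

    Malformed rows (invalid alleles, EAF outside [0,1], non-positive SE,
    p outside (0,1], missing effect) are dropped and counted; duplicate keys
    keep the smallest-SE record.  Raises :class:`SumStatsError` when a
    mandatory column is absent or no valid rows remain.
    """
    raw = pd.read_csv(path, sep=r"\s+", compression="infer", dtype={"SNP": str})
    df = _normalise_columns(raw, column_map)

    drops: dict[str, int] = {}
    df["EA"] = df["EA"].astype(str).str.upper()
    df["OA"] = df["OA"].astype(str).str.upper()
    for col in ("EAF", "BETA", "SE", "P", "N", "INFO"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["N"].isna().all() and n_default is not None:
        df["N"] = n_default

    checks = [
        ("invalid_allele", lambda d: ~d["EA"].isin(_VALID_ALLELES) | ~d["OA"].isin(_VALID_ALLELES)),
        ("identical_alleles", lambda d: d["EA"] == d["OA"]),
        ("eaf_out_of_range", lambda d: ~d["EAF"].between(0, 1)),
        ("nonpositive_se", lambda d: ~(d["SE"] > 0)),
        ("missing_beta", lambda d: ~np.isfinite(d["BETA"].to_numpy(dtype=float))),
        ("invalid_p", lambda d: ~((d["P"] > 0) & (d["P"] <= 1))),
        ("missing_n", lambda d: ~(d["N"] > 0)),
    ]
    for reason, bad_fn in checks:
        bad = bad_fn(df)
        n_bad = int(bad.sum())
        if n_bad:
            drops[reason] = n_bad
            logger.warning("%s: dropping %d rows (%s)", label or path, n_bad, reason)
            df = df.loc[~bad]

    if df.empty:
        raise SumStatsError(f"{label or path}: no valid rows after validation {drops}")

    key = variant_keys(df)
    if key.duplicated().any():
        n_dup = int(key.duplicated().sum())
        logger.warning("%s: %d duplicate keys, keeping smallest SE", label, n_dup)
        drops["duplicate_key"] = n_dup
        df = (
            df.assign(_key=key)
            .sort_values("SE", kind="stable")
            .drop_duplicates("_key", keep="first")
            .sort_index()
            .drop(columns="_key")
        )

    df = df.reset_index(drop=True)
    df["N"] = df["N"].astype(int)
    return CohortPanel(label=label, df=df, n_default=n_default, drop_counts=drops)


def apply_qc(panel: CohortPanel, thresholds: QCThresholds) -> CohortPanel:
    """Apply MAF and imputation-quality filters (strict inequalities).

    Raises :class:`SumStatsError` when every record is removed, reporting
    per-filter counts in the message.
    """
    if panel.df.empty:
        raise SumStatsError(f"{panel.label}: empty panel")
    df = panel.df
    maf = np.minimum(df["EAF"], 1 - df["EAF"])
    keep_maf = maf > thresholds.maf_min
    if thresholds.info_min == 0:
        keep_info = pd.Series(True, index=df.index)
    else:
        keep_info = df["INFO"] > thresholds.info_min  # NaN compares False
    counts = {
        "maf": int((~keep_maf).sum()),
        "info": int((keep_maf & ~keep_info).sum()),
    }
    kept = df.loc[keep_maf & keep_info].reset_index(drop=True)
    logger.info("%s QC: removed %s, kept %d", panel.label, counts, len(kept))
    if kept.empty:
        raise SumStatsError(f"{panel.label}: QC removed all records, counts {counts}")
    return CohortPanel(panel.label, kept, panel.n_default, {**panel.drop_counts, **counts})


def intersect_and_align(panels: list[CohortPanel], reference: int = 0) -> pd.DataFrame:
    """Restrict to variants present in every panel and orient all cohorts to
    the reference panel's effect allele.

    A cohort reporting the reference's other allele as its effect allele has
    its beta negated and EAF complemented.  Variants whose allele pair does
    not match the reference pair even after the swap are dropped and counted
    as mismatches (no strand-complement rescue is attempted).

    Returns a wide table with key columns ``SNP CHR POS EA OA`` and per-cohort
    columns ``BETA_<label> SE_<label> EAF_<label> N_<label>``.
    """
    if len(panels) < 2:
        raise SumStatsError("need at least 2 panels to intersect")
    labels = [p.label or f"cohort{i}" for i, p in enumerate(panels)]
    if len(set(labels)) != len(labels):
        raise SumStatsError(f"panel labels must be unique: {labels}")

    ref = panels[reference].df.assign(_key=variant_keys(panels[reference].df))
    out = ref[["_key", "SNP", "CHR", "POS", "EA", "OA"]].copy()
    mismatches = 0
    for panel, label in zip(panels, labels):
        df = panel.df.assign(_key=variant_keys(panel.df))
        sub = df[["_key", "EA", "OA", "EAF", "BETA", "SE", "N"]].rename(
            columns={c: f"{c}_{label}" for c in ("EA", "OA", "EAF", "BETA", "SE", "N")}
        )
        out = out.merge(sub, on="_key", how="inner")

    for label in labels:
        same = (out[f"EA_{label}"] == out["EA"]) & (out[f"OA_{label}"] == out["OA"])
        swap = (out[f"EA_{label}"] == out["OA"]) & (out[f"OA_{label}"] == out["EA"])
        out.loc[swap, f"BETA_{label}"] = -out.loc[swap, f"BETA_{label}"]
        out.loc[swap, f"EAF_{label}"] = 1 - out.loc[swap, f"EAF_{label}"]
        bad = ~(same | swap)
        mismatches += int(bad.sum())
        out = out.loc[~bad]
        out = out.drop(columns=[f"EA_{label}", f"OA_{label}"])

    if mismatches:
        logger.warning("alignment dropped %d variants with allele mismatches", mismatches)
    out = out.drop(columns="_key").reset_index(drop=True)
    if out.empty:
        raise SumStatsError("empty intersection across panels")
    out.attrs["cohorts"] = labels
    out.attrs["allele_mismatches"] = mismatches
    return out


def cohort_labels(aligned: pd.DataFrame) -> list[str]:
    """Cohort labels of an aligned table (from attrs or BETA_* columns)."""
    if "cohorts" in aligned.attrs:
        return list(aligned.attrs["cohorts"])
    return [c[len("BETA_"):] for c in aligned.columns if c.startswith("BETA_")]


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a canonical-column summary-statistics table as TSV."""
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA")
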