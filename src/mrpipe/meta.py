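"""Inverse-variance meta-analysis of aligned multi-cohort GWAS effects.

Implements fixed-effects and DerSimonian–Laird random-effects pooling,
Cochran's Q / I-squared heterogeneity, the genomic inflation factor, the
fraction of phenotypic variance explained by a single variant, greedy locus
clumping, and an approximate conditional scan that uses a regional LD
correlation matrix in place of individual-level genotypes.

Effects are per effect-allele copy on a standardized phenotype; two-sided
p-values come from the normal approximation to beta/SE and are additionally
reported as -log10(p) so genome-wide signals survive float underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import cohort_labels

_LN10 = np.log(10.0)
#: Median of the chi-square distribution with 1 df; calibrates lambda.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


def _norm_logsf(z: np.ndarray) -> np.ndarray:
    return stats.norm.logsf(z)


def two_sided_p(beta, se):
    """Two-sided normal p and -log10(p) from an effect and its SE."""
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    logp = _norm_logsf(z) + np.log(2.0)
    return np.exp(logp), -logp / _LN10


@dataclass
class MetaResult:
    """Pooled effect for one variant plus heterogeneity diagnostics."""

    beta: float
    se: float
    p: float
    k: int
    q: float = 0.0
    q_p: float = 1.0
    i2: float = 0.0
    tau2: float = 0.0
    n_total: int = 0
    eaf: float = float("nan")
    mlog10p: float = float("nan")


@dataclass
class Locus:
    """A clump of genome-wide-significant variants around a lead SNP."""

    lead: pd.Series
    members: pd.DataFrame
    window_bp: int
    label: str = ""

    @property
    def n_members(self) -> int:
        return len(self.members)


def i_squared(q: float, k: int) -> float:
    """I² from Cochran's Q over k studies: max(0, (Q-(k-1))/Q).

    Zero when Q is zero or below its (k-1) expectation.
    """
    if k < 2 or q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def heterogeneity(betas, ses, pooled_beta) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value (k-1 df) and I-squared.

    I² = max(0, (Q - (k-1))/Q); zero when Q is zero or below its expectation.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = betas.size
    if k < 2:
        return 0.0, 1.0, 0.0
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - pooled_beta) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    return q, q_p, i_squared(q, k)


def fixed_effects_meta(betas, ses, ns=None, eafs=None) -> MetaResult:
    """Fixed-effects inverse-variance pooling of per-cohort effects.

    Weights are 1/SE²; the pooled EAF, when frequencies are given, is the
    sample-size-weighted mean.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 1:
        raise ValueError("need at least one cohort")
    if not (np.all(np.isfinite(betas)) and np.all(ses > 0)):
        raise ValueError("non-finite effect or non-positive SE")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p, mlog10p = two_sided_p(beta, se)
    q, q_p, i2 = heterogeneity(betas, ses, beta)
    n_total = int(np.sum(ns)) if ns is not None else 0
    eaf = _pooled_eaf(eafs, ns)
    return MetaResult(beta, se, float(p), betas.size, q, q_p, i2, 0.0,
                      n_total, eaf, float(mlog10p))


def random_effects_meta(betas, ses, ns=None, eafs=None) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    tau² = max(0, (Q - (k-1)) / (Σw - Σw²/Σw)) with fixed-effects weights w;
    pooling then uses w* = 1/(SE² + tau²).  With homogeneous inputs tau²
    truncates to zero and the result equals the fixed-effects model.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 2:
        raise ValueError("random-effects model needs k >= 2; use fixed_effects_meta")
    w = 1.0 / ses**2
    beta_fe = np.sum(w * betas) / np.sum(w)
    q, q_p, i2 = heterogeneity(betas, ses, beta_fe)
    k = betas.size
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    p, mlog10p = two_sided_p(beta, se)
    n_total = int(np.sum(ns)) if ns is not None else 0
    eaf = _pooled_eaf(eafs, ns)
    return MetaResult(beta, se, float(p), k, q, q_p, i2, tau2,
                      n_total, eaf, float(mlog10p))


def _pooled_eaf(eafs, ns) -> float:
    if eafs is None:
        return float("nan")
    eafs = np.asarray(eafs, dtype=float)
    if ns is None:
        return float(np.mean(eafs))
    ns = np.asarray(ns, dtype=float)
    return float(np.sum(ns * eafs) / np.sum(ns))


def meta_analyze(aligned: pd.DataFrame, method: str = "fixed") -> pd.DataFrame:
    """Vectorized meta-analysis over an aligned multi-cohort table.

    Parameters
    ----------
    aligned
        Output of :func:`mrpipe.sumstats.intersect_and_align`.
    method
        ``"fixed"`` or ``"random"`` (DerSimonian–Laird).

    Returns one row per variant with pooled BETA/SE/P/MLOG10P, pooled EAF,
    heterogeneity columns Q, Q_P, I2, TAU2, plus K and N_TOTAL.
    """
    labels = cohort_labels(aligned)
    if method not in ("fixed", "random"):
        raise ValueError(f"unknown method {method!r}")
    b = aligned[[f"BETA_{l}" for l in labels]].to_numpy(dtype=float)
    s = aligned[[f"SE_{l}" for l in labels]].to_numpy(dtype=float)
    f = aligned[[f"EAF_{l}" for l in labels]].to_numpy(dtype=float)
    n = aligned[[f"N_{l}" for l in labels]].to_numpy(dtype=float)
    k = b.shape[1]

    w = 1.0 / s**2
    sw = w.sum(axis=1)
    beta_fe = (w * b).sum(axis=1) / sw
    q = (w * (b - beta_fe[:, None]) ** 2).sum(axis=1)
    q_p = stats.chi2.sf(q, k - 1) if k >= 2 else np.ones_like(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / q), 0.0)

    if method == "fixed":
        beta, se = beta_fe, sw**-0.5
        tau2 = np.zeros_like(q)
    else:
        denom = sw - (w**2).sum(axis=1) / sw
        with np.errstate(divide="ignore", invalid="ignore"):
            tau2 = np.where(denom > 0, np.maximum(0.0, (q - (k - 1)) / denom), 0.0)
        w_star = 1.0 / (s**2 + tau2[:, None])
        beta = (w_star * b).sum(axis=1) / w_star.sum(axis=1)
        se = w_star.sum(axis=1) ** -0.5
    p, mlog10p = two_sided_p(beta, se)

    out = aligned[["SNP", "CHR", "POS", "EA", "OA"]].copy()
    out["EAF"] = (n * f).sum(axis=1) / n.sum(axis=1)
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    out["MLOG10P"] = mlog10p
    out["N"] = n.sum(axis=1).astype(int)
    out["K"] = k
    out["Q"] = q
    out["Q_P"] = q_p
    out["I2"] = i2
    out["TAU2"] = tau2
    return out


def genomic_inflation(p=None, z=None, chisq=None) -> float:
    """Genomic inflation factor: median observed chi-square over the null
    median of chi-square(1).

    Accepts any one of p-values, z-scores, or 1-df chi-square statistics.
    """
    if chisq is None:
        if z is not None:
            chisq = np.asarray(z, dtype=float) ** 2
        elif p is not None:
            chisq = stats.chi2.isf(np.asarray(p, dtype=float), 1)
        else:
            raise ValueError("provide p, z, or chisq")
    chisq = np.asarray(chisq, dtype=float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(chisq) / CHI2_MEDIAN_1DF)


def variance_explained(beta, se, n) -> float:
    """Fraction of phenotypic variance explained by one variant.

    Uses r² = beta² / (beta² + N·SE²), the standard approximation from a
    variant's z-statistic and sample size on a standardized phenotype.
    """
    beta = float(beta)
    se = float(se)
    n = float(n)
    if se <= 0 or n <= 0:
        raise ValueError("se and n must be positive")
    return beta**2 / (beta**2 + n * se**2)


def define_loci(results: pd.DataFrame, p_threshold: float = 5e-8,
                window_bp: int = 500_000) -> list[Locus]:
    """Greedy clumping of significant variants into loci.

    Repeatedly takes the unassigned variant with the strongest evidence
    (largest -log10 p) below the significance threshold and assigns every
    significant variant within ``window_bp`` on the same chromosome to its
    locus.  Lead SNPs of distinct loci are therefore separated by more than
    ``window_bp``.
    """
    if "MLOG10P" in results.columns:
        strength = results["MLOG10P"].to_numpy(dtype=float)
        sig = strength > -np.log10(p_threshold)
    else:
        pvals = results["P"].to_numpy(dtype=float)
        sig = pvals < p_threshold
        with np.errstate(divide="ignore"):
            strength = -np.log10(pvals)
    cand = results.loc[sig].copy()
    cand["_strength"] = strength[sig]
    loci: list[Locus] = []
    while not cand.empty:
        lead = cand.loc[cand["_strength"].idxmax()]
        near = (cand["CHR"] == lead["CHR"]) & (
            (cand["POS"] - lead["POS"]).abs() <= window_bp
        )
        members = cand.loc[near].drop(columns="_strength").reset_index(drop=True)
        loci.append(Locus(lead=lead.drop("_strength"), members=members,
                          window_bp=window_bp, label=f"{lead['CHR']}:{lead['POS']}"))
        cand = cand.loc[~near]
    return loci


@dataclass
class LDMatrix:
    """Regional LD as a correlation matrix over an ordered SNP list."""

    snps: list
    r: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snps)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match SNP list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        evals = np.linalg.eigvalsh(self.r)
        if evals.min() < -1e-6:
            raise ValueError("LD matrix is not positive semi-definite")

    def index_of(self, snp) -> int:
        try:
            return self.snps.index(snp) if isinstance(self.snps, list) else int(
                np.where(np.asarray(self.snps) == snp)[0][0])
        except (ValueError, IndexError):
            raise KeyError(f"{snp} not in LD matrix") from None


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix file: first row SNP ids, then the matrix rows."""
    with open(path) as fh:
        snps = fh.readline().split()
        r = np.loadtxt(fh)
    return LDMatrix(snps=snps, r=np.atleast_2d(r))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, ld.snps)) + "\n")
        np.savetxt(fh, ld.r, fmt="%.8g")


def conditional_scan(
    locus_df: pd.DataFrame,
    ld: LDMatrix,
    lead: str,
    collinearity_r2: float = 0.9,
    independence_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Approximate association statistics conditional on the lead SNP.

    Works on the standardized-genotype, standardized-phenotype scale
    (beta_std = beta · sqrt(2·EAF·(1−EAF))), where for a SNP j with LD
    correlation r to the lead:

        beta_j|lead = (beta_j − r·beta_lead) / (1 − r²)
        se_j|lead   = se_j / sqrt(1 − r²)

    SNPs with r² above ``collinearity_r2`` are flagged ``ignored`` (no
    conditional estimate); SNPs farther than ``independence_bp`` from the
    lead are assumed in linkage equilibrium and returned unconditioned.
    Results are reported back on the per-allele scale.
    """
    df = locus_df.reset_index(drop=True)
    i_lead = ld.index_of(lead)
    snp_order = [ld.index_of(s) for s in df["SNP"]]
    r_lead = ld.r[i_lead, snp_order]

    scale = np.sqrt(2 * df["EAF"].to_numpy(float) * (1 - df["EAF"].to_numpy(float)))
    b_std = df["BETA"].to_numpy(float) * scale
    se_std = df["SE"].to_numpy(float) * scale
    lead_row = df.index[df["SNP"] == lead]
    if len(lead_row) == 0:
        raise ValueError(f"lead {lead} not present in locus table")
    b_lead = b_std[lead_row[0]]
    pos_lead = df.loc[lead_row[0], "POS"]

    beta_c = np.full(len(df), np.nan)
    se_c = np.full(len(df), np.nan)
    status = np.full(len(df), "conditioned", dtype=object)
    for j in range(len(df)):
        if df.loc[j, "SNP"] == lead:
            status[j] = "lead"
            continue
        r = r_lead[j]
        if abs(df.loc[j, "POS"] - pos_lead) > independence_bp:
            status[j] = "unconditioned"
            beta_c[j], se_c[j] = b_std[j], se_std[j]
            continue
        if r**2 > collinearity_r2 or 1 - r**2 < 1e-8:
            status[j] = "ignored"
            continue
        beta_c[j] = (b_std[j] - r * b_lead) / (1 - r**2)
        se_c[j] = se_std[j] / np.sqrt(1 - r**2)

    out = df[["SNP", "CHR", "POS", "EAF"]].copy() if "CHR" in df.columns else df[["SNP", "POS", "EAF"]].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["BETA_COND"] = beta_c / scale
        out["SE_COND"] = se_c / scale
        p, mlog10p = two_sided_p(beta_c, se_c)
    out["P_COND"] = p
    out["MLOG10P_COND"] = mlog10p
    out["STATUS"] = status
    return out
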