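"""Two-sample Mendelian randomization estimators and sensitivity analyses.

All estimators consume a harmonized instrument table (see
:mod:`mrpipe.harmonize`) whose outcome effects are oriented to the
exposure's effect allele.  Implemented methods:

* Wald ratio (single instrument), first- or second-order delta SE;
* inverse-variance-weighted (IVW), fixed or multiplicative-random effects;
* MR-Egger regression (slope + pleiotropy intercept);
* weighted median with parametric-bootstrap SE;
* Cochran Q instrument heterogeneity;
* radial-regression outlier detection (per-SNP Q contributions).

Causal estimates are in outcome units (SD, or log-odds for a binary
outcome) per SD of the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonize import harmonize_pair, kept_records, steiger_filter
from .meta import two_sided_p

Z95 = 1.96


class MRInputError(ValueError):
    """Instrument set does not meet an estimator's preconditions."""


@dataclass
class MREstimate:
    """One method's causal estimate with its uncertainty and heterogeneity."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    q: float | None = None
    q_p: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    def to_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
            "n_snps": self.n_snps, "q": self.q, "q_p": self.q_p,
        }


@dataclass
class RadialReport:
    """Per-instrument heterogeneity decomposition from the radial fit."""

    snps: list
    q_contributions: np.ndarray
    p_values: np.ndarray
    outliers: list
    alpha: float
    theta: float

    @property
    def total_q(self) -> float:
        return float(np.sum(self.q_contributions))


def _arrays(records: pd.DataFrame):
    bx = records["BETA_EXP"].to_numpy(dtype=float)
    sx = records["SE_EXP"].to_numpy(dtype=float)
    by = records["BETA_OUT"].to_numpy(dtype=float)
    sy = records["SE_OUT"].to_numpy(dtype=float)
    return bx, sx, by, sy


def wald_ratio(record, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta approximation se_out/|beta_exp|;
    ``second_order=True`` additionally propagates the exposure-side
    uncertainty, inflating by sqrt(1 + beta_out²·se_exp² / (beta_exp²·se_out²)).
    """
    bx, sx = float(record["BETA_EXP"]), float(record["SE_EXP"])
    by, sy = float(record["BETA_OUT"]), float(record["SE_OUT"])
    if bx == 0:
        raise MRInputError("Wald ratio undefined for a null exposure effect")
    beta = by / bx
    se = sy / abs(bx)
    if second_order:
        se *= np.sqrt(1 + (by**2 * sx**2) / (bx**2 * sy**2))
    p, _ = two_sided_p(beta, se)
    return MREstimate("wald", beta, se, float(p), 1)


def ratio_estimates(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order delta SEs."""
    bx, _, by, sy = _arrays(records)
    if np.any(bx == 0):
        raise MRInputError("zero exposure effect among instruments")
    return by / bx, sy / np.abs(bx)


def mr_heterogeneity(records: pd.DataFrame, theta: float, df_loss: int = 1) -> tuple[float, float]:
    """Cochran's Q of the per-SNP ratios around a fitted causal effect.

    Q = sum (ratio_j − theta)² / se_ratio_j², referred to chi-square with
    k − ``df_loss`` degrees of freedom (1 for IVW, 2 for Egger).
    """
    ratios, ses = ratio_estimates(records)
    q = float(np.sum((ratios - theta) ** 2 / ses**2))
    dof = ratios.size - df_loss
    q_p = float(stats.chi2.sf(q, dof)) if dof >= 1 else float("nan")
    return q, q_p


def ivw(records: pd.DataFrame, mode: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate: zero-intercept regression of
    outcome effects on exposure effects with weights 1/se_out².

    Identical to the 1/se_ratio²-weighted mean of per-SNP Wald ratios.
    ``mode="random"`` applies the multiplicative over-dispersion model,
    inflating the fixed-effects SE by max(1, sqrt(Q/(k−1))).
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    records = kept_records(records) if "ACTION" in records.columns else records
    k = len(records)
    if k < 1 or (mode == "random" and k < 2):
        raise MRInputError(f"IVW ({mode}) needs at least {1 if mode == 'fixed' else 2} instruments, got {k}")
    bx, _, by, sy = _arrays(records)
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(np.sum(w * bx**2) ** -0.5)
    if k >= 2:
        q, q_p = mr_heterogeneity(records, beta, df_loss=1)
    else:
        q, q_p = 0.0, float("nan")
    se = se_fixed
    if mode == "random" and k >= 2:
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    p, _ = two_sided_p(beta, se)
    return MREstimate(f"ivw_{mode}", beta, se, float(p), k, q, q_p)


def mr_egger(records: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted fit of outcome on exposure effects with
    a free intercept measuring directional pleiotropy.

    Exposure effects are re-oriented positive (outcome sign flipped in
    tandem) so the intercept is identified.  SEs use the multiplicative
    over-dispersion model with inflation floored at 1, on k−2 df.

    Returns (slope estimate, intercept estimate).
    """
    records = kept_records(records) if "ACTION" in records.columns else records
    k = len(records)
    if k < 3:
        raise MRInputError(f"MR-Egger needs at least 3 instruments, got {k}")
    bx, _, by, sy = _arrays(records)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    intercept, slope = fit.params
    # statsmodels scales bse by the estimated residual variance; undo, then
    # apply the floored multiplicative inflation
    q = float(fit.scale * (k - 2))
    inflation = max(1.0, np.sqrt(fit.scale))
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = se_unscaled * inflation
    q_p = float(stats.chi2.sf(q, k - 2))
    p_slope, _ = two_sided_p(slope, se_slope)
    p_int, _ = two_sided_p(intercept, se_int)
    return (
        MREstimate("egger_slope", float(slope), float(se_slope), float(p_slope), k, q, q_p),
        MREstimate("egger_intercept", float(intercept), float(se_int), float(p_int), k, q, q_p),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2
    return float(np.interp(0.5, cum, v))


def weighted_median(records: pd.DataFrame, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Instruments are ordered by ratio; the estimate interpolates the ratio at
    cumulative (midpoint-adjusted) inverse-variance weight 0.5.  Consistent
    when instruments carrying >=50% of the weight are valid.  The SE is the
    standard deviation of the estimate over ``n_boot`` parametric bootstrap
    draws of (beta_exp, beta_out) from their sampling distributions.
    """
    records = kept_records(records) if "ACTION" in records.columns else records
    k = len(records)
    if k < 3:
        raise MRInputError(f"weighted median needs at least 3 instruments, got {k}")
    bx, sx, by, sy = _arrays(records)
    ratios, ses = ratio_estimates(records)
    weights = 1.0 / ses**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        r_b = by_b[ok] / bx_b[ok]
        w_b = (np.abs(bx_b[ok]) / sy[ok]) ** 2
        boot[b] = _weighted_median(r_b, w_b)
    se = float(np.std(boot, ddof=1))
    p, _ = two_sided_p(beta, se)
    return MREstimate("weighted_median", float(beta), se, float(p), k)


def radial_outliers(records: pd.DataFrame, alpha: float = 0.05) -> RadialReport:
    """Radial (modified second-order-free) IVW outlier detection.

    Fits the regression through the origin of beta_ratio_j·sqrt(w_j) on
    sqrt(w_j) with w_j = beta_exp_j²/se_out_j² (algebraically the IVW fit),
    decomposes Cochran's Q into per-SNP contributions
    q_j = w_j (ratio_j − theta)², and flags SNPs whose upper-tail
    chi-square(1) p-value falls below ``alpha``.
    """
    records = kept_records(records) if "ACTION" in records.columns else records
    k = len(records)
    if k < 3:
        raise MRInputError(f"radial outlier scan needs at least 3 instruments, got {k}")
    bx, _, by, sy = _arrays(records)
    ratios, ses = ratio_estimates(records)
    w = bx**2 / sy**2
    theta = float(np.sum(w * ratios) / np.sum(w))
    q_j = w * (ratios - theta) ** 2
    p_j = stats.chi2.sf(q_j, 1)
    snps = list(records["SNP"]) if "SNP" in records.columns else list(range(k))
    outliers = [s for s, p in zip(snps, p_j) if p < alpha]
    return RadialReport(snps, q_j, p_j, outliers, alpha, theta)


@dataclass
class MRReport:
    """Structured output of one MR analysis direction."""

    direction: str
    estimates: list[MREstimate] = field(default_factory=list)
    not_applicable: dict = field(default_factory=dict)
    per_snp_wald: list[dict] = field(default_factory=list)
    radial: RadialReport | None = None
    steiger: list = field(default_factory=list)
    harmonized: pd.DataFrame | None = None
    binary_outcome: bool = False

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "binary_outcome": self.binary_outcome,
            "estimates": [e.to_dict() for e in self.estimates],
            "not_applicable": self.not_applicable,
            "per_snp_wald": self.per_snp_wald,
        }
        if self.radial is not None:
            d["radial"] = {
                "snps": [str(s) for s in self.radial.snps],
                "q_contributions": self.radial.q_contributions.tolist(),
                "p_values": self.radial.p_values.tolist(),
                "outliers": [str(s) for s in self.radial.outliers],
                "alpha": self.radial.alpha,
                "total_q": self.radial.total_q,
            }
        if self.steiger:
            d["steiger"] = [vars(s) for s in self.steiger]
        return d


def run_mr_suite(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    direction: str = "exposure->outcome",
    palindrome_policy: str = "infer",
    steiger: bool = False,
    steiger_alpha: float | None = None,
    radial_alpha: float = 0.05,
    remove_outliers: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
    binary_outcome: bool = False,
) -> MRReport:
    """Harmonize, optionally Steiger-filter, and run every estimator whose
    instrument-count precondition holds.

    Estimators that cannot run are recorded under ``not_applicable`` with the
    reason rather than raised.  With ``remove_outliers`` the radial scan's
    flagged SNPs are dropped and IVW is re-fitted on the remainder
    (``ivw_random_outliers_removed``).  A bidirectional analysis is two calls
    with the roles swapped and the reverse-direction instrument set.
    """
    if exposure.empty:
        raise MRInputError("empty instrument set for the exposure")
    harmonized = harmonize_pair(exposure, outcome, palindrome_policy=palindrome_policy)
    report = MRReport(direction=direction, harmonized=harmonized, binary_outcome=binary_outcome)

    records = kept_records(harmonized)
    if records.empty:
        raise MRInputError("harmonization left no usable instruments")
    if steiger:
        records, steiger_results = steiger_filter(records, alpha=steiger_alpha)
        report.steiger = steiger_results
        if records.empty:
            raise MRInputError("Steiger filtering left no instruments")

    for _, rec in records.iterrows():
        est = wald_ratio(rec)
        report.per_snp_wald.append({"snp": rec["SNP"], **est.to_dict()})

    report.estimates.append(ivw(records, mode="fixed"))
    if len(records) >= 2:
        report.estimates.append(ivw(records, mode="random"))
    else:
        report.not_applicable["ivw_random"] = "not applicable (<2 SNPs)"
    if len(records) >= 3:
        slope, intercept = mr_egger(records)
        report.estimates += [slope, intercept]
        report.estimates.append(weighted_median(records, n_boot=n_boot, seed=seed))
        report.radial = radial_outliers(records, alpha=radial_alpha)
        if remove_outliers and report.radial.outliers:
            kept = records.loc[~records["SNP"].isin(report.radial.outliers)]
            if len(kept) >= 2:
                refit = ivw(kept, mode="random")
                refit.method = "ivw_random_outliers_removed"
                report.estimates.append(refit)
    else:
        for m in ("egger_slope", "egger_intercept", "weighted_median", "radial"):
            report.not_applicable[m] = "not applicable (<3 SNPs)"
    return report
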