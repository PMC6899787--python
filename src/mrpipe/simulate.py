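"""Synthetic GWAS generator with known ground truth.

Emulates, at a scale a laptop handles in seconds, the study design the
pipeline targets: four cohorts measuring a standardized protein exposure
(sample sizes 7292, 1041, 1316, 935 — roughly 10.6k in total), a much
larger outcome GWAS, LD-blocked regions with one or two causal variants,
and an exposure→outcome causal effect theta with optional directional
pleiotropy.

Summary statistics are simulated directly on the standardized-genotype /
standardized-phenotype scale: a variant with joint (causal) effects b has
marginal effects R·b within its LD block, and the sampling error of the
marginal estimate is MVN(0, R) scaled by the analytic SE
1/sqrt(2·maf·(1−maf)·n) after conversion to the per-allele scale.  A
small-n individual-level mode (continuous standardized dosages) exists
purely as an oracle for the conditional scan.

All generators are pure functions of (config, seed); per-cohort streams are
split by hashing the cohort label into the seed sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import RegionalTrait
from .meta import LDMatrix, two_sided_p
from .sumstats import CANONICAL_COLUMNS, CohortPanel

#: Cohort sample sizes of the emulated exposure GWAS meta-analysis.
DEFAULT_COHORT_NS = (7292, 1041, 1316, 935)


@dataclass
class SimConfig:
    """Ground-truth configuration for one simulated dataset.

    Defaults mirror the emulated study: ~10.6k exposure samples split over
    four cohorts, two causal variants jointly explaining ~2.4% of the
    exposure variance, a causal effect of −0.12 outcome SD per exposure SD,
    no pleiotropy, and an outcome GWAS of 426,824 individuals.
    """

    m_variants: int = 200
    n_blocks: int = 10
    rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    cohort_ns: tuple[int, ...] = DEFAULT_COHORT_NS
    n_causal: int = 2
    h2_exp: float = 0.024
    #: fraction of h2_exp carried by each causal variant (None = equal);
    #: the default mirrors one strong (~2%) and one modest (~0.4%) signal
    h2_shares: tuple[float, ...] | None = (5 / 6, 1 / 6)
    theta: float = -0.12
    alpha_pleio: float = 0.0
    pleio_sd: float = 0.0
    n_out: int = 426_824
    seed: int = 0
    #: spacing keeps distinct LD blocks outside a +/-500 kb clumping window
    bp_spacing: int = 100_000
    #: index of the cohort emulating a sequenced study (no imputation INFO)
    sequenced_cohort: int | None = 2

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1 for a valid AR(1) block")
        if self.h2_exp < 0 or self.pleio_sd < 0:
            raise ValueError("variances must be non-negative")
        if any(n <= 0 for n in self.cohort_ns):
            raise ValueError("cohort sizes must be positive")
        if self.n_causal > self.n_blocks:
            raise ValueError("at most one causal variant per block")
        if self.h2_shares is not None and len(self.h2_shares) != self.n_causal:
            # shares are a per-causal-variant split; fall back to equal
            self.h2_shares = None


@dataclass
class TruthRecord:
    """Ground truth of one simulated region."""

    joint: np.ndarray          # true joint effects on the exposure, std scale
    marginal: np.ndarray       # LD-convolved marginal effects, R @ joint
    causal_idx: np.ndarray     # indices of causal variants
    theta: float
    pleio: np.ndarray = field(default=None)  # direct effects on the outcome


@dataclass
class Region:
    """A simulated LD region: correlation structure plus ground truth."""

    ld: LDMatrix
    positions: np.ndarray
    mafs: np.ndarray
    truth: TruthRecord
    block_bounds: np.ndarray  # block i spans indices [bounds[i], bounds[i+1])

    @property
    def m(self) -> int:
        return len(self.positions)


def _rng_for(seed, label: str = "") -> np.random.Generator:
    parts = [int(seed)]
    if label:
        parts.append(zlib.crc32(label.encode()))
    return np.random.default_rng(parts)


def _block_chol(ld: LDMatrix, bounds: np.ndarray) -> list[np.ndarray]:
    return [np.linalg.cholesky(ld.r[a:b, a:b])
            for a, b in zip(bounds[:-1], bounds[1:])]


def _correlated_noise(rng, ld: LDMatrix, bounds: np.ndarray) -> np.ndarray:
    out = np.empty(ld.r.shape[0])
    for chol, (a, b) in zip(_block_chol(ld, bounds), zip(bounds[:-1], bounds[1:])):
        out[a:b] = chol @ rng.standard_normal(b - a)
    return out


def simulate_region(config: SimConfig, seed: int | None = None) -> Region:
    """Build a block-diagonal AR(1) LD region with planted causal effects.

    Within a block, r_jk = rho^|j−k|; across blocks, zero.  MAFs are uniform
    on ``maf_range``; positions are evenly spaced at ``bp_spacing``.  Joint
    causal effects (one SNP in each of ``n_causal`` distinct blocks) are
    drawn standard-normal and rescaled so they jointly explain ``h2_exp`` of
    the exposure variance (bᵀRb = h2_exp).
    """
    rng = _rng_for(config.seed if seed is None else seed, "region")
    m, k = config.m_variants, config.n_blocks
    bounds = np.linspace(0, m, k + 1).astype(int)

    r = np.zeros((m, m))
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = np.arange(b - a)
        r[a:b, a:b] = config.rho ** np.abs(idx[:, None] - idx[None, :])
    positions = np.arange(m) * config.bp_spacing + 1
    mafs = rng.uniform(*config.maf_range, size=m)
    snps = [f"rs{j + 1}" for j in range(m)]
    ld = LDMatrix(snps=snps, r=r, positions=positions)

    joint = np.zeros(m)
    causal_blocks = rng.choice(k, size=config.n_causal, replace=False)
    causal_idx = np.array(sorted(
        int(rng.integers(bounds[cb], bounds[cb + 1])) for cb in causal_blocks
    ))
    if config.n_causal and config.h2_exp > 0:
        shares = (np.asarray(config.h2_shares, dtype=float)
                  if config.h2_shares is not None
                  else np.full(config.n_causal, 1.0))
        shares = shares / shares.sum()
        signs = rng.choice([-1.0, 1.0], size=config.n_causal)
        # causal variants sit in distinct blocks, so their variance
        # contributions are independent: b_j = sqrt(share_j * h2_exp)
        joint[causal_idx] = signs * np.sqrt(shares * config.h2_exp)
    marginal = r @ joint
    truth = TruthRecord(joint=joint, marginal=marginal, causal_idx=causal_idx,
                        theta=config.theta)
    return Region(ld=ld, positions=positions, mafs=mafs, truth=truth,
                  block_bounds=bounds)


def _panel_from_effects(
    region: Region,
    marginal_std: np.ndarray,
    n: int,
    rng: np.random.Generator,
    label: str,
    chrom: str = "1",
    info: np.ndarray | None = None,
    trait_var: float = 1.0,
) -> CohortPanel:
    """Sample one study's summary statistics around true marginal effects."""
    mafs = region.mafs
    allele_scale = np.sqrt(2 * mafs * (1 - mafs))
    beta_true = marginal_std / allele_scale
    se = 1.0 / np.sqrt(2 * mafs * (1 - mafs) * n * trait_var)
    noise = _correlated_noise(rng, region.ld, region.block_bounds)
    beta_hat = beta_true + se * noise
    eaf_hat = rng.binomial(2 * n, mafs) / (2 * n)
    p, _ = two_sided_p(beta_hat, se)

    df = pd.DataFrame({
        "SNP": region.ld.snps,
        "CHR": chrom,
        "POS": region.positions,
        "EA": "A",
        "OA": "G",
        "EAF": eaf_hat,
        "BETA": beta_hat,
        "SE": se,
        "P": p,
        "N": n,
        "INFO": info if info is not None else np.nan,
    })[CANONICAL_COLUMNS]
    return CohortPanel(label=label, df=df, n_default=n)


def simulate_exposure_gwas(
    region: Region,
    cohort_ns=None,
    seed: int = 0,
    labels=None,
    sequenced_cohort: int | None = 2,
) -> list[CohortPanel]:
    """Per-cohort exposure summary statistics around the region's truth.

    Every cohort measures the same standardized phenotype, so cohorts share
    true marginal effects and differ only in sampling noise (scaled by
    1/sqrt(n)) and estimated allele frequencies (binomial resampling at 2n
    draws).  Imputed cohorts get INFO scores uniform on (0.85, 1); the
    cohort at index ``sequenced_cohort`` reports none.
    """
    if cohort_ns is None:
        cohort_ns = DEFAULT_COHORT_NS
    if labels is None:
        labels = [f"cohort{i + 1}" for i in range(len(cohort_ns))]
    panels = []
    for i, (n, label) in enumerate(zip(cohort_ns, labels)):
        rng = _rng_for(seed, f"exposure/{label}")
        info = None if i == sequenced_cohort else rng.uniform(0.85, 1.0, region.m)
        panels.append(_panel_from_effects(region, region.truth.marginal, int(n),
                                          rng, label, info=info))
    return panels


def simulate_outcome_gwas(
    region: Region,
    theta: float | None = None,
    alpha_pleio: float = 0.0,
    pleio_sd: float = 0.0,
    n_out: int = 426_824,
    seed: int = 0,
    label: str = "outcome",
    binary: bool = False,
    case_fraction: float = 0.5,
) -> CohortPanel:
    """Outcome GWAS with a planted causal effect of the exposure.

    True outcome marginal effects are theta·(exposure marginals) plus the
    LD-convolution of per-variant direct (pleiotropic) effects drawn
    N(alpha_pleio, pleio_sd²) at the causal indices.  ``binary=True`` keeps
    the same linear mechanics on the log-odds scale, with the SE reflecting
    the Bernoulli variance at ``case_fraction``.  The drawn pleiotropic
    effects are stored on ``region.truth.pleio``.
    """
    rng = _rng_for(seed, f"outcome/{label}")
    if theta is None:
        theta = region.truth.theta
    pleio = np.zeros(region.m)
    if (alpha_pleio != 0.0 or pleio_sd > 0.0) and region.truth.causal_idx.size:
        ci = region.truth.causal_idx
        # mean pleiotropy is directional with respect to the
        # exposure-increasing allele of each causal variant
        orient = np.where(region.truth.joint[ci] < 0, -1.0, 1.0)
        pleio[ci] = orient * rng.normal(alpha_pleio, pleio_sd, ci.size)
    region.truth.pleio = pleio
    marginal_out = theta * region.truth.marginal + region.ld.r @ pleio
    trait_var = case_fraction * (1 - case_fraction) if binary else 1.0
    return _panel_from_effects(region, marginal_out, int(n_out), rng, label,
                               trait_var=trait_var)


def simulate_coloc_pair(
    region: Region,
    shared: bool,
    z1: float,
    z2: float,
    seed: int = 0,
    n1: int = 10_000,
    n2: int = 10_000,
) -> tuple[RegionalTrait, RegionalTrait]:
    """Two traits' regional statistics with shared or distinct causal SNPs.

    ``z1``/``z2`` set the causal variant's expected association z-score in
    each trait (0 for a null trait).  ``shared=True`` plants one SNP for
    both traits; otherwise the two causal SNPs land in distinct LD blocks.
    """
    rng = _rng_for(seed, "coloc")
    bounds = region.block_bounds
    k = len(bounds) - 1
    if not shared and k < 2:
        raise ValueError("distinct causal variants need at least 2 blocks")
    b1 = int(rng.integers(k))
    c1 = int(rng.integers(bounds[b1], bounds[b1 + 1]))
    if shared:
        c2 = c1
    else:
        b2 = int(rng.integers(k - 1))
        b2 = b2 + 1 if b2 >= b1 else b2
        c2 = int(rng.integers(bounds[b2], bounds[b2 + 1]))

    traits = []
    for c, z, n in ((c1, z1, n1), (c2, z2, n2)):
        se = 1.0 / np.sqrt(2 * region.mafs * (1 - region.mafs) * n)
        z_marginal = z * region.ld.r[:, c]
        noise = _correlated_noise(rng, region.ld, bounds)
        beta = (z_marginal + noise) * se
        traits.append(RegionalTrait(snps=list(region.ld.snps), beta=beta, se=se))
    return traits[0], traits[1]


def simulate_instruments(
    k: int,
    theta: float,
    n_exp: int = 50_000,
    n_out: int = 50_000,
    h2_per_snp: float = 0.005,
    alpha_pleio: float = 0.0,
    pleio_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Harmonized table of k independent instruments on the standardized scale.

    Per SNP the true exposure effect magnitude is uniform on
    [0.5, 1.5]·sqrt(h2_per_snp) with a random sign; the outcome effect is
    theta·bx plus a pleiotropic effect N(alpha_pleio, pleio_sd²) acting on
    the exposure-increasing allele; sampling SEs are 1/sqrt(n).  The default
    per-SNP strength (mean F ≈ 250) keeps exposure-effect measurement error
    negligible, as the Egger model assumes.
    """
    rng = _rng_for(seed, "instruments")
    sign = rng.choice([-1.0, 1.0], k)
    bx = rng.uniform(0.5, 1.5, k) * np.sqrt(h2_per_snp) * sign
    pleio = (sign * rng.normal(alpha_pleio, pleio_sd, k)
             if (alpha_pleio or pleio_sd) else np.zeros(k))
    by = theta * bx + pleio
    sx = np.full(k, 1 / np.sqrt(n_exp))
    sy = np.full(k, 1 / np.sqrt(n_out))
    return pd.DataFrame({
        "SNP": [f"rs{j}" for j in range(k)],
        "EA": "A", "OA": "G",
        "BETA_EXP": rng.normal(bx, sx), "SE_EXP": sx, "EAF_EXP": 0.5, "N_EXP": n_exp,
        "BETA_OUT": rng.normal(by, sy), "SE_OUT": sy, "EAF_OUT": 0.5, "N_OUT": n_out,
        "ACTION": "kept",
    })


def simulate_individual(
    region: Region,
    joint_std: np.ndarray,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level oracle data: standardized dosages X ~ MVN(0, R) and
    phenotype y = X·joint + e with residual variance topped up to 1.

    Continuous dosages carry exactly the LD correlation structure the
    summary-level formulas assume, which is what makes this the reference
    for the conditional scan; it does not emulate hard genotype calls.
    """
    rng = _rng_for(seed, "individual")
    x = np.empty((n, region.m))
    for chol, (a, b) in zip(_block_chol(region.ld, region.block_bounds),
                            zip(region.block_bounds[:-1], region.block_bounds[1:])):
        x[:, a:b] = rng.standard_normal((n, b - a)) @ chol.T
    g = x @ joint_std
    resid_var = max(1e-12, 1.0 - float(joint_std @ region.ld.r @ joint_std))
    y = g + rng.normal(0, np.sqrt(resid_var), n)
    return x, y
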