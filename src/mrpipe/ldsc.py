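"""Simplified LD-score regression.

The regression model is E[chi²_j] = intercept + (N·h²/M)·l_j, where l_j is
SNP j's LD score (sum of squared correlations with SNPs in a physical
window, self included), N the GWAS sample size and M the number of SNPs.
The intercept captures confounding inflation; the slope rescales to the
SNP heritability h².  Standard errors come from a delete-one-block
jackknife over contiguous SNP blocks.

This is the single-trait, non-partitioned core of the method: no annotation
categories, no cross-trait genetic covariance, no reference SNP-list
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meta import LDMatrix


@dataclass
class LdscFit:
    """LD-score regression fit: intercept, heritability, jackknife SEs."""

    intercept: float
    h2: float
    se_intercept: float
    se_h2: float
    m: int
    n: float
    n_blocks: int

    @property
    def h2_out_of_range(self) -> bool:
        """Heritability outside [0, 1]; reported unconstrained but flagged."""
        return not (0.0 <= self.h2 <= 1.0)


def ld_scores(ld: LDMatrix, window_bp: float = np.inf, positions=None) -> np.ndarray:
    """LD score per SNP: sum of r² with every SNP within ``window_bp``.

    The self term r²=1 is always included, so scores are >= 1.  With no
    positions (or an infinite window) all pairs count.
    """
    r2 = ld.r**2
    if positions is None and ld.positions is not None:
        positions = ld.positions
    if positions is not None and np.isfinite(window_bp):
        pos = np.asarray(positions, dtype=float)
        within = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        r2 = r2 * within
    return r2.sum(axis=1)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    det = sw * sxx - sx**2
    if det <= 0:
        raise ValueError("degenerate design: LD scores are constant")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / sw
    return float(intercept), float(slope)


def ldsc_fit(
    chisq,
    ell,
    n: float,
    m: int | None = None,
    n_blocks: int = 200,
    weighted: bool = True,
) -> LdscFit:
    """Fit the LD-score regression and jackknife its standard errors.

    Parameters
    ----------
    chisq, ell
        Per-SNP association chi-square statistics and LD scores, aligned.
    n
        GWAS sample size.
    m
        Number of SNPs the heritability is summed over; defaults to
        ``len(chisq)``.
    n_blocks
        Delete-one jackknife blocks (contiguous index ranges).
    weighted
        Two-pass heteroskedasticity weighting 1/(2·E[chi²]²) with first-pass
        OLS estimates, as in standard practice.  ``False`` keeps plain OLS,
        which recovers a noise-free line exactly.
    """
    chisq = np.asarray(chisq, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if chisq.shape != ell.shape or chisq.ndim != 1:
        raise ValueError("chisq and ell must be equal-length 1-D arrays")
    if m is None:
        m = chisq.size
    if not (chisq.size >= n_blocks >= 2):
        raise ValueError("need m >= n_blocks >= 2")
    if np.ptp(ell) == 0:
        raise ValueError("degenerate design: LD scores are constant")

    w = np.ones_like(chisq)
    a, slope = _wls(ell, chisq, w)
    if weighted:
        pred = np.clip(a + slope * ell, 0.1, None)
        w = 1.0 / (2.0 * pred**2)
        a, slope = _wls(ell, chisq, w)

    bounds = np.linspace(0, chisq.size, n_blocks + 1).astype(int)
    # accumulate the five WLS sufficient statistics per block, then delete-one
    stats_full = np.array([w.sum(), (w * ell).sum(), (w * chisq).sum(),
                           (w * ell**2).sum(), (w * ell * chisq).sum()])
    jack_int = np.empty(n_blocks)
    jack_slope = np.empty(n_blocks)
    for i in range(n_blocks):
        s = slice(bounds[i], bounds[i + 1])
        wi, xi, yi = w[s], ell[s], chisq[s]
        sb = stats_full - np.array([wi.sum(), (wi * xi).sum(), (wi * yi).sum(),
                                    (wi * xi**2).sum(), (wi * xi * yi).sum()])
        sw, sx, sy, sxx, sxy = sb
        det = sw * sxx - sx**2
        jack_slope[i] = (sw * sxy - sx * sy) / det
        jack_int[i] = (sy - jack_slope[i] * sx) / sw

    g = n_blocks
    se_int = float(np.sqrt((g - 1) / g * np.sum((jack_int - jack_int.mean()) ** 2)))
    se_slope = float(np.sqrt((g - 1) / g * np.sum((jack_slope - jack_slope.mean()) ** 2)))

    return LdscFit(
        intercept=a,
        h2=slope * m / n,
        se_intercept=se_int,
        se_h2=se_slope * m / n,
        m=int(m),
        n=float(n),
        n_blocks=n_blocks,
    )
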