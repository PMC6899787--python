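"""Exposure/outcome harmonization for two-sample Mendelian randomization.

Aligns an outcome study's effects onto the exposure study's effect-allele
orientation, resolves strand-complement reporting for non-palindromic
variants, infers or drops palindromic (A/T, C/G) variants using allele
frequencies, locates LD proxies for instruments missing from the outcome,
and applies the Steiger directionality filter (keep instruments that
explain more variance in the exposure than in the outcome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import LDMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Actions that leave a usable harmonized record.
KEPT_ACTIONS = ("kept", "flipped", "palindrome_inferred", "proxy_substituted")

HARMONIZED_COLUMNS = [
    "SNP", "EA", "OA",
    "BETA_EXP", "SE_EXP", "EAF_EXP", "N_EXP",
    "BETA_OUT", "SE_OUT", "EAF_OUT", "N_OUT",
    "ACTION",
]


class HarmonizationError(ValueError):
    pass


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer",
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Merge exposure and outcome summary statistics on variant id and align
    the outcome to the exposure's effect allele.

    Both inputs need canonical columns SNP, EA, OA, EAF, BETA, SE and
    (optionally) N.  Decision order per shared variant:

    1. allele pairs match directly -> ``kept``;
    2. pairs match with EA/OA swapped -> ``flipped`` (beta negated, EAF
       complemented);
    3. non-palindromic pairs are re-tested after strand-complementing the
       outcome alleles (same two cases); still no match -> ``dropped_mismatch``;
    4. palindromic pairs (A/T, C/G) cannot be resolved by letters: under
       ``palindrome_policy="infer"`` the orientation is chosen so both EAFs
       fall on the same side of 0.5, unless either EAF lies inside
       ``eaf_ambiguity_band`` (then ``dropped_palindrome``); under ``"drop"``
       every palindrome is dropped.

    Returns one row per shared variant including dropped rows, with the
    ACTION column recording the outcome; filter with :func:`kept_records`.
    """
    if palindrome_policy not in ("infer", "drop"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    lo, hi = eaf_ambiguity_band

    exp = exposure.rename(columns={c: f"{c}_EXP" for c in ("EAF", "BETA", "SE", "N", "P")})
    out = outcome.rename(columns={c: f"{c}_OUT" for c in ("EAF", "BETA", "SE", "N", "P")})
    out = out.rename(columns={"EA": "EA_OUT", "OA": "OA_OUT"})
    keep_exp = [c for c in ("SNP", "EA", "OA", "BETA_EXP", "SE_EXP", "EAF_EXP", "N_EXP") if c in exp.columns]
    keep_out = [c for c in ("SNP", "EA_OUT", "OA_OUT", "BETA_OUT", "SE_OUT", "EAF_OUT", "N_OUT") if c in out.columns]
    merged = exp[keep_exp].merge(out[keep_out], on="SNP", how="inner")
    if merged.empty:
        raise HarmonizationError("no shared variants between exposure and outcome")

    actions = []
    for row in merged.itertuples(index=False):
        ea, oa = row.EA, row.OA
        ea_o, oa_o = row.EA_OUT, row.OA_OUT
        if _is_palindromic(ea, oa):
            if palindrome_policy == "drop":
                actions.append(("dropped_palindrome", False))
                continue
            if {ea_o, oa_o} != {ea, oa}:
                actions.append(("dropped_mismatch", False))
                continue
            eaf_exp, eaf_out = row.EAF_EXP, row.EAF_OUT
            letter_flip = ea_o != ea  # letters reported swapped
            eaf_out_letters = 1 - eaf_out if letter_flip else eaf_out
            if lo < eaf_exp < hi or lo < eaf_out_letters < hi:
                actions.append(("dropped_palindrome", False))
                continue
            same_side = (eaf_exp < 0.5) == (eaf_out_letters < 0.5)
            # opposite EAF sides => the outcome reported the other strand,
            # which for a palindrome swaps effect and other allele
            actions.append(("palindrome_inferred", letter_flip ^ (not same_side)))
        else:
            pairs = [((ea_o, oa_o), False), ((oa_o, ea_o), True)]
            comp = (_COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?"))
            pairs += [(comp, False), (comp[::-1], True)]
            for (a1, a2), flip in pairs:
                if (a1, a2) == (ea, oa):
                    actions.append(("flipped" if flip else "kept", flip))
                    break
            else:
                actions.append(("dropped_mismatch", False))

    merged["ACTION"] = [a for a, _ in actions]
    flip_mask = np.array([f for _, f in actions], dtype=bool)
    merged.loc[flip_mask, "BETA_OUT"] = -merged.loc[flip_mask, "BETA_OUT"]
    merged.loc[flip_mask, "EAF_OUT"] = 1 - merged.loc[flip_mask, "EAF_OUT"]
    merged = merged.drop(columns=["EA_OUT", "OA_OUT"])
    for col in HARMONIZED_COLUMNS:
        if col not in merged.columns:
            merged[col] = np.nan
    n_dropped = int((~merged["ACTION"].isin(KEPT_ACTIONS)).sum())
    if n_dropped:
        logger.info("harmonization dropped %d of %d shared variants", n_dropped, len(merged))
    return merged[HARMONIZED_COLUMNS]


def kept_records(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized table usable for estimation."""
    return harmonized.loc[harmonized["ACTION"].isin(KEPT_ACTIONS)].reset_index(drop=True)


def find_proxies(
    target,
    ld: LDMatrix,
    r2_min: float = 0.8,
    available=None,
):
    """Best LD proxy for ``target`` among ``available`` SNPs.

    Returns the target itself when it is available, else the available SNP
    with maximal r² to the target subject to r² >= ``r2_min``; ties break by
    smaller base-pair distance (when the matrix carries positions) then by
    lexicographic id.  Returns ``None`` when no candidate qualifies.
    """
    idx = ld.index_of(target)  # KeyError when absent
    snps = list(ld.snps)
    if available is None:
        available = set(snps)
    else:
        available = set(available)
    if target in available:
        return target
    best = None
    for j, snp in enumerate(snps):
        if snp == target or snp not in available:
            continue
        r2 = ld.r[idx, j] ** 2
        if r2 < r2_min:
            continue
        dist = abs(ld.positions[j] - ld.positions[idx]) if ld.positions is not None else 0.0
        cand = (-r2, dist, str(snp))
        if best is None or cand < best[0]:
            best = (cand, snp)
    return None if best is None else best[1]


def steiger_r2(z, n):
    """Variance in a standardized trait explained by one SNP, from its
    association z-statistic: r² = z² / (z² + n)."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    return z**2 / (z**2 + n)


@dataclass
class SteigerResult:
    """Directionality evidence for one instrument."""

    snp: str
    r2_exp: float
    r2_out: float
    z: float
    p: float
    correct_direction: bool


def steiger_filter(
    harmonized: pd.DataFrame,
    n_exp=None,
    n_out=None,
    alpha: float | None = None,
) -> tuple[pd.DataFrame, list[SteigerResult]]:
    """Retain instruments whose primary effect is on the exposure.

    Per SNP, the variance explained in each trait is r² = z²/(z²+n); the
    difference of Fisher-transformed correlations gives

        z_steiger = (atanh r_exp − atanh r_out) / sqrt(1/(n_exp−3) + 1/(n_out−3))

    Retention requires strictly r²_exp > r²_out; passing ``alpha`` adds a
    one-sided significance gate p < alpha on z_steiger.
    """
    df = kept_records(harmonized)
    ne = df["N_EXP"].to_numpy(float) if n_exp is None else np.full(len(df), float(n_exp))
    no = df["N_OUT"].to_numpy(float) if n_out is None else np.full(len(df), float(n_out))
    if np.any(ne <= 3) or np.any(no <= 3):
        raise ValueError("sample sizes must exceed 3 for the Steiger test")

    z_exp = df["BETA_EXP"].to_numpy(float) / df["SE_EXP"].to_numpy(float)
    z_out = df["BETA_OUT"].to_numpy(float) / df["SE_OUT"].to_numpy(float)
    r2_exp = steiger_r2(z_exp, ne)
    r2_out = steiger_r2(z_out, no)
    r_exp, r_out = np.sqrt(r2_exp), np.sqrt(r2_out)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(1 / (ne - 3) + 1 / (no - 3))
    p = 2 * stats.norm.sf(np.abs(z))
    correct = r2_exp > r2_out

    results = [
        SteigerResult(snp=s, r2_exp=float(a), r2_out=float(b), z=float(zz),
                      p=float(pp), correct_direction=bool(c))
        for s, a, b, zz, pp, c in zip(df["SNP"], r2_exp, r2_out, z, p, correct)
    ]
    keep = correct
    if alpha is not None:
        keep = keep & (stats.norm.sf(z) < alpha)
    return df.loc[keep].reset_index(drop=True), results
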