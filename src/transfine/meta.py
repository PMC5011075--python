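"""Combining per-study summary statistics across ancestries.

Fixed-effects inverse-variance meta-analysis (the primary engine), a
sample-size-weighted z alternative for case/control traits, Cochran's Q
heterogeneity, the 50%-of-total-sample-size coverage filter, greedy locus
definition around lead variants, distinct-signal calling from conditional
statistics, and a two-sample z comparison of allelic effects between
cohorts.

Effect alleles are harmonized across studies before combining, and combined
records are oriented so the effect allele is the trait-decreasing allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Locus",
    "inverse_variance_meta",
    "sample_size_meta",
    "cochran_q",
    "coverage_filter",
    "define_loci",
    "distinct_signal_test",
    "effect_difference_z",
    "harmonize_studies",
    "meta_analyze",
]

GENOME_WIDE_P = 5e-8
DEFAULT_HALF_WINDOW = 500_000
DISTINCT_SIGNAL_P = 1e-5  # Bonferroni for ~5,000 variants per locus

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Locus:
    """A lead variant and its flanking window (1-based inclusive)."""

    chrom: str
    lead_pos: int
    lead_p: float
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def inverse_variance_meta(betas, ses) -> tuple[float, float, float, float]:
    """Fixed-effects inverse-variance combination.

    beta = sum(w_i b_i)/sum(w_i) with w = 1/se², se = 1/sqrt(sum w);
    two-sided normal p. Returns (beta, se, z, p).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("inverse_variance_meta requires at least one study")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    return beta, se, z, 2.0 * float(stats.norm.sf(abs(z)))


def sample_size_meta(zs, ns, signs=None) -> tuple[float, float]:
    """Sample-size-weighted z combination: z = sum(z_i sign_i sqrt(n_i)) / sqrt(sum n_i)."""
    z = np.asarray(zs, dtype=float)
    n = np.asarray(ns, dtype=float)
    if z.size == 0:
        raise ValueError("sample_size_meta requires at least one study")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    sign = np.ones_like(z) if signs is None else np.sign(np.asarray(signs, dtype=float))
    zc = float(np.sum(z * sign * np.sqrt(n)) / np.sqrt(np.sum(n)))
    return zc, 2.0 * float(stats.norm.sf(abs(zc)))


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic: Q = sum w_i (b_i - b̂)², chi²(k-1) p."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("Cochran's Q requires at least two studies")
    w = 1.0 / s**2
    bhat = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bhat) ** 2))
    df = int(b.size - 1)
    return q, df, float(stats.chi2.sf(q, df))


def coverage_filter(contributing_n: float, total_n: float) -> bool:
    """Keep a variant iff it passed QC in at least 50% of the total sample size."""
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    return contributing_n >= 0.5 * total_n


def effect_difference_z(beta1, se1, beta2, se2) -> tuple[float, float]:
    """Two-sample z-test for a difference in allelic effect between cohorts."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta1 - beta2) / np.sqrt(se1**2 + se2**2)
    return float(z), 2.0 * float(stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_studies(
    studies: list[pd.DataFrame], freq_cap: float = 0.2
) -> list[pd.DataFrame]:
    """Align effect alleles across studies to the first study's orientation.

    Matching order per variant (keyed by chrom:pos): same allele pair;
    swapped pair (flip beta, eaf); strand-complemented pair (relabel);
    complemented-and-swapped (relabel and flip). Palindromic A/T and C/G
    pairs are orientation-ambiguous and resolved by effect-allele-frequency
    proximity to the reference; if neither orientation brings the frequency
    difference under ``freq_cap`` the variant is dropped from that study.
    """
    if not studies:
        return []
    ref = studies[0].set_index(_variant_key(studies[0]))
    out = [studies[0].reset_index(drop=True)]
    for df in studies[1:]:
        df = df.copy()
        keys = _variant_key(df)
        keep = np.ones(len(df), dtype=bool)
        ea = df["effect_allele"].to_numpy(dtype=object)
        oa = df["other_allele"].to_numpy(dtype=object)
        beta = df["beta"].to_numpy(dtype=float)
        eaf = df["eaf"].to_numpy(dtype=float)
        for i, key in enumerate(keys):
            if key not in ref.index:
                continue
            r = ref.loc[key]
            r_ea, r_oa = r["effect_allele"], r["other_allele"]
            a1, a2 = str(ea[i]).upper(), str(oa[i]).upper()
            if _is_palindromic(a1, a2) and {a1, a2} == {str(r_ea), str(r_oa)}:
                # ambiguous: orient by frequency proximity
                d_keep = abs(eaf[i] - r["eaf"])
                d_flip = abs((1.0 - eaf[i]) - r["eaf"])
                if min(d_keep, d_flip) > freq_cap:
                    keep[i] = False
                elif d_flip < d_keep:
                    ea[i], oa[i] = r_ea, r_oa
                    beta[i] = -beta[i]
                    eaf[i] = 1.0 - eaf[i]
                continue
            if (a1, a2) == (r_ea, r_oa):
                continue
            if (a1, a2) == (r_oa, r_ea):
                ea[i], oa[i] = r_ea, r_oa
                beta[i] = -beta[i]
                eaf[i] = 1.0 - eaf[i]
                continue
            c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if (c1, c2) == (r_ea, r_oa):
                ea[i], oa[i] = r_ea, r_oa
            elif (c1, c2) == (r_oa, r_ea):
                ea[i], oa[i] = r_ea, r_oa
                beta[i] = -beta[i]
                eaf[i] = 1.0 - eaf[i]
            else:
                keep[i] = False  # allele pair irreconcilable with reference
        df["effect_allele"], df["other_allele"] = ea, oa
        df["beta"], df["eaf"] = beta, eaf
        out.append(df.loc[keep].reset_index(drop=True))
    return out


def _variant_key(df: pd.DataFrame) -> pd.Index:
    return pd.Index(df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str))


# ---------------------------------------------------------------------------
# Whole-table meta-analysis
# ---------------------------------------------------------------------------

def meta_analyze(
    studies: list[pd.DataFrame],
    harmonize: bool = True,
    apply_coverage_filter: bool = True,
    orient_decreasing: bool = True,
) -> pd.DataFrame:
    """Variant-by-variant fixed-effects meta-analysis of per-study tables.

    Returns one row per variant with combined ``beta, se, z, p``, Cochran's
    ``q, q_df, q_p``, total ``n`` and ``n_studies``. Variants contributing
    less than half the total sample size are excluded (inclusive at exactly
    50%). When ``orient_decreasing`` the effect allele of each combined
    record is switched, where needed, to the trait-decreasing allele.
    """
    if not studies:
        raise ValueError("meta_analyze requires at least one study table")
    if harmonize:
        studies = harmonize_studies(studies)
    total_n = sum(float(df["n"].max()) for df in studies)

    stacked = pd.concat(
        [df.assign(_study=i, _key=_variant_key(df)) for i, df in enumerate(studies)],
        ignore_index=True,
    )
    rows = []
    for key, grp in stacked.groupby("_key", sort=False):
        contributing = float(grp["n"].sum())
        if apply_coverage_filter and not coverage_filter(contributing, total_n):
            continue
        beta, se, z, p = inverse_variance_meta(grp["beta"], grp["se"])
        k = len(grp)
        if k >= 2:
            q, q_df, q_p = cochran_q(grp["beta"], grp["se"])
        else:
            q, q_df, q_p = 0.0, 0, np.nan
        first = grp.iloc[0]
        ea, oa = first["effect_allele"], first["other_allele"]
        eaf = float(np.average(grp["eaf"], weights=grp["n"]))
        if orient_decreasing and beta > 0:
            beta, ea, oa, eaf = -beta, oa, ea, 1.0 - eaf
            z = -z
        rows.append(
            (
                first["chrom"], int(first["pos"]), ea, oa, eaf,
                beta, se, z, p, q, q_df, q_p, contributing, k,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "effect_allele", "other_allele", "eaf",
            "beta", "se", "z", "p", "q", "q_df", "q_p", "n", "n_studies",
        ],
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Loci and distinct signals
# ---------------------------------------------------------------------------

def define_loci(
    meta_records: pd.DataFrame,
    threshold: float = GENOME_WIDE_P,
    half_window: int = DEFAULT_HALF_WINDOW,
) -> list[Locus]:
    """Greedy locus definition around successive minimum-p lead variants.

    Repeatedly take the smallest-p unclaimed variant with p below the
    threshold as a lead and claim everything within ``half_window`` bp of
    it on the same chromosome; repeat until no significant variant remains
    unclaimed.
    """
    df = meta_records[["chrom", "pos", "p"]].copy()
    claimed = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    p = df["p"].to_numpy(dtype=float)
    loci: list[Locus] = []
    while True:
        candidates = np.flatnonzero(~claimed & (p < threshold))
        if candidates.size == 0:
            break
        lead = candidates[np.argmin(p[candidates])]
        window = (chrom == chrom[lead]) & (np.abs(pos - pos[lead]) <= half_window)
        claimed |= window
        loci.append(
            Locus(
                chrom=str(chrom[lead]),
                lead_pos=int(pos[lead]),
                lead_p=float(p[lead]),
                start=int(pos[lead] - half_window),
                end=int(pos[lead] + half_window),
            )
        )
    return loci


def distinct_signal_test(
    conditional_records: pd.DataFrame, threshold: float = DISTINCT_SIGNAL_P
) -> pd.Series:
    """Flag variants whose conditional meta p is below the distinct-signal cut."""
    p = conditional_records["p"].to_numpy(dtype=float)
    flags = np.zeros(len(p), dtype=bool)
    ok = np.isfinite(p)
    flags[ok] = p[ok] < threshold
    return pd.Series(flags, index=conditional_records.index, name="distinct_signal")
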