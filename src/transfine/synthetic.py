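"""Multi-ancestry synthetic GWAS data with known ground truth.

Generates the inputs the analysis pipeline expects — per-ancestry dosage
matrices with ancestry-specific allele frequencies and LD, quantitative
kidney-function phenotypes under an additive dosage model, imputation-quality
scores, annotation tracks enriched for causal variants — together with a
truth record so that recovery (fine-mapping coverage, enrichment parameter
recovery, conditional-analysis behaviour) can be tested.

Model choices, deliberately the simplest with the right structure:

* Allele-frequency divergence between ancestry groups follows the
  Balding-Nichols model: given an ancestral frequency p and divergence F
  (an Fst-like parameter), each group's frequency is drawn from
  Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F·p(1-p).
* Linkage disequilibrium follows a latent Gaussian AR(1) copula: haplotype
  alleles are thresholded correlated normals, so marginal frequencies are
  exact and adjacent-pair LD rises monotonically with the copula parameter.
* Exactly one causal variant per region by default; the phenotype is
  beta * causal_dosage + covariate effects + Gaussian noise.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AncestryModel",
    "RegionTruth",
    "StudyDataset",
    "DEFAULT_ANCESTRIES",
    "balding_nichols_freqs",
    "diverge_frequencies",
    "simulate_haplotypes",
    "simulate_region_truth",
    "simulate_study",
    "simulate_annotation_tracks",
    "simulate_ckd_status",
    "egfr_to_creatinine",
]

# Defaults are stated-world values: four ancestry groups as in the consortium
# design, Fst in the range typical of continental human divergence, causal
# effect in the observed per-allele eGFR range (|beta| 0.6-2.0), residual SD
# 24 eGFR units (the value implied by reported SEs at the full sample size).
DEFAULT_CAUSAL_BETA = -0.9
DEFAULT_RESIDUAL_SD = 24.0


@dataclass(frozen=True)
class AncestryModel:
    """One ancestry group's population-genetic parameters."""

    label: str
    fst: float
    ld_rho: float
    n_individuals: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst <= 0.5:
            raise ValueError(f"fst must lie in [0, 0.5], got {self.fst}")
        if not 0.0 <= self.ld_rho <= 0.99:
            raise ValueError(f"ld_rho must lie in [0, 0.99], got {self.ld_rho}")
        if self.n_individuals < 10:
            raise ValueError(f"n_individuals must be >= 10, got {self.n_individuals}")


DEFAULT_ANCESTRIES = (
    AncestryModel("AFR", fst=0.15, ld_rho=0.80, n_individuals=500),
    AncestryModel("HIS", fst=0.08, ld_rho=0.88, n_individuals=500),
    AncestryModel("EUR", fst=0.05, ld_rho=0.92, n_individuals=500),
    AncestryModel("EAS", fst=0.11, ld_rho=0.90, n_individuals=500),
)


@dataclass
class RegionTruth:
    """Ground truth for one simulated association region."""

    positions: np.ndarray            # 1-based bp, strictly increasing
    ancestral_freqs: np.ndarray      # in (0,1)
    ancestry_freqs: dict[str, np.ndarray]
    causal_index: int
    causal_beta: float               # phenotype units per effect allele
    residual_sd: float
    chrom: str = "1"
    extra_causal: dict[int, float] = field(default_factory=dict)
    annotation_log_odds: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if np.any(self.ancestral_freqs <= 0) or np.any(self.ancestral_freqs >= 1):
            raise ValueError("ancestral frequencies must lie in (0,1)")
        if not 0 <= self.causal_index < len(self.positions):
            raise ValueError("causal_index out of range")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def causal_indices(self) -> list[int]:
        return [self.causal_index, *sorted(self.extra_causal)]


@dataclass
class StudyDataset:
    """One study's individual-level data."""

    dosages: np.ndarray       # individuals x variants, values in [0,2]
    phenotype: np.ndarray
    covariates: np.ndarray    # individuals x k (no intercept column)
    ancestry: str
    info_scores: np.ndarray   # in [0,1]
    software: str             # imputation dialect tag
    study_id: str = "study"

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length inconsistent with dosage rows")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows inconsistent with dosage rows")
        if self.info_scores.shape != (m,):
            raise ValueError("one info score per variant required")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0,2]")
        if self.info_scores.min() < 0 or self.info_scores.max() > 1:
            raise ValueError("info scores must lie in [0,1]")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def balding_nichols_freqs(
    p_ancestral: float, fst: float, k: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``k`` descendant-population frequencies for one variant.

    Under Balding-Nichols the draws are Beta(p(1-F)/F, (1-p)(1-F)/F), with
    mean ``p_ancestral`` and variance ``F p (1-p)``. ``fst = 0`` is the
    degenerate no-divergence case and returns the ancestral frequency
    exactly. Draws are clipped to [0.001, 0.999] so downstream code never
    sees a monomorphic variant.
    """
    if not 0 < p_ancestral < 1:
        raise ValueError(f"p_ancestral must lie in (0,1), got {p_ancestral}")
    if not 0 <= fst < 1:
        raise ValueError(f"fst must lie in [0,1), got {fst}")
    if fst == 0:
        return np.full(k, p_ancestral)
    rng = np.random.default_rng(seed)
    a = p_ancestral * (1 - fst) / fst
    b = (1 - p_ancestral) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, size=k), 0.001, 0.999)


def diverge_frequencies(
    p_ancestral: np.ndarray,
    ancestries: tuple[AncestryModel, ...],
    seed: int | np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-ancestry frequency vectors for a whole region (one Fst per group)."""
    rng = np.random.default_rng(seed)
    p = np.asarray(p_ancestral, dtype=float)
    out: dict[str, np.ndarray] = {}
    for anc in ancestries:
        if anc.fst == 0:
            out[anc.label] = p.copy()
        else:
            a = p * (1 - anc.fst) / anc.fst
            b = (1 - p) * (1 - anc.fst) / anc.fst
            out[anc.label] = np.clip(rng.beta(a, b), 0.001, 0.999)
    return out


# ---------------------------------------------------------------------------
# Haplotypes and dosages
# ---------------------------------------------------------------------------

def simulate_haplotypes(
    freqs: np.ndarray,
    ld_rho: float,
    n_haplotypes: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Binary haplotype matrix (n_haplotypes x m) with AR(1)-copula LD.

    A latent Gaussian AR(1) chain with parameter ``ld_rho`` is thresholded
    at each variant's normal quantile, so marginals match ``freqs`` exactly
    in expectation while adjacent variants are correlated.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise ValueError("freqs must lie in (0,1)")
    if n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even (haplotypes pair into genotypes)")
    rng = np.random.default_rng(seed)
    m = len(freqs)
    eps = rng.standard_normal((n_haplotypes, m))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - ld_rho**2)
    for j in range(1, m):
        z[:, j] = ld_rho * z[:, j - 1] + scale * eps[:, j]
    thresholds = stats.norm.ppf(freqs)
    return (z < thresholds).astype(np.int8)


def _dosages_from_haplotypes(haps: np.ndarray) -> np.ndarray:
    return (haps[0::2] + haps[1::2]).astype(float)


# ---------------------------------------------------------------------------
# Regions and studies
# ---------------------------------------------------------------------------

def simulate_region_truth(
    n_variants: int,
    ancestries: tuple[AncestryModel, ...] = DEFAULT_ANCESTRIES,
    seed: int | np.random.Generator = 0,
    causal_beta: float = DEFAULT_CAUSAL_BETA,
    residual_sd: float = DEFAULT_RESIDUAL_SD,
    chrom: str = "1",
    start_bp: int = 1_000_000,
    n_causal: int = 1,
    min_causal_freq: float = 0.15,
) -> RegionTruth:
    """Lay out one region: positions, diverged frequencies, causal variant(s).

    ``n_causal > 1`` adds extra independent causal variants (same effect
    size) for negative/distinct-signal tests; the default single-causal
    region mirrors what conditional analysis found at every reported locus.
    """
    rng = np.random.default_rng(seed)
    positions = start_bp + np.cumsum(rng.integers(200, 5000, size=n_variants))
    p_anc = rng.uniform(0.05, 0.95, size=n_variants)
    freqs = diverge_frequencies(p_anc, ancestries, rng)
    # keep the causal variant common in every group so power is ancestry-shared
    common = np.flatnonzero(
        np.all(
            [(f > min_causal_freq) & (f < 1 - min_causal_freq) for f in freqs.values()],
            axis=0,
        )
    )
    if len(common) < n_causal:
        common = np.arange(n_variants)
    chosen = rng.choice(common, size=n_causal, replace=False)
    extra = {int(i): causal_beta for i in chosen[1:]}
    return RegionTruth(
        positions=positions,
        ancestral_freqs=p_anc,
        ancestry_freqs=freqs,
        causal_index=int(chosen[0]),
        causal_beta=causal_beta,
        residual_sd=residual_sd,
        chrom=chrom,
        extra_causal=extra,
    )


def simulate_study(
    truth: RegionTruth,
    ancestry: AncestryModel,
    seed: int | np.random.Generator,
    n_covariates: int = 2,
    covariate_betas: tuple[float, ...] = (-0.15, -2.0),
    intercept: float = 90.0,
    software: str = "IMPUTE2",
    study_id: str | None = None,
) -> StudyDataset:
    """Individual-level data for one study drawn from one ancestry group.

    Phenotype model: ``intercept + beta * causal_dosage + covariates @ b +
    N(0, residual_sd)``. Covariates default to an age-like N(55, 8) column
    and a binary sex column. Imputation-quality scores are drawn U[0.3, 1]
    so the QC filter has something to remove.
    """
    if ancestry.label not in truth.ancestry_freqs:
        raise ValueError(f"truth has no frequencies for ancestry {ancestry.label!r}")
    freqs = truth.ancestry_freqs[ancestry.label]
    if len(freqs) != truth.n_variants:
        raise ValueError("truth and ancestry disagree on variant count")
    rng = np.random.default_rng(seed)
    haps = simulate_haplotypes(freqs, ancestry.ld_rho, 2 * ancestry.n_individuals, rng)
    dosages = _dosages_from_haplotypes(haps)
    n = ancestry.n_individuals

    cov_cols = []
    if n_covariates >= 1:
        cov_cols.append(rng.normal(55.0, 8.0, size=n))
    if n_covariates >= 2:
        cov_cols.append(rng.integers(0, 2, size=n).astype(float))
    for _ in range(max(0, n_covariates - 2)):
        cov_cols.append(rng.standard_normal(n))
    covariates = np.column_stack(cov_cols) if cov_cols else np.empty((n, 0))
    betas = np.asarray(covariate_betas[: covariates.shape[1]], dtype=float)
    if betas.size < covariates.shape[1]:
        betas = np.concatenate([betas, np.ones(covariates.shape[1] - betas.size)])

    genetic = truth.causal_beta * dosages[:, truth.causal_index]
    for idx, beta in truth.extra_causal.items():
        genetic = genetic + beta * dosages[:, idx]
    noise = rng.normal(0.0, truth.residual_sd, size=n) if truth.residual_sd > 0 else 0.0
    phenotype = intercept + genetic + covariates @ betas + noise

    info = rng.uniform(0.3, 1.0, size=truth.n_variants)
    return StudyDataset(
        dosages=dosages,
        phenotype=phenotype,
        covariates=covariates,
        ancestry=ancestry.label,
        info_scores=info,
        software=software,
        study_id=study_id or f"{ancestry.label}_1",
    )


# ---------------------------------------------------------------------------
# Annotations and CKD
# ---------------------------------------------------------------------------

def simulate_annotation_tracks(
    truth: RegionTruth,
    n_tracks: int,
    enrichment_log_odds: float,
    background_coverage: float,
    seed: int | np.random.Generator,
) -> list[list[tuple[str, int, int]]]:
    """BED-style tracks (0-based half-open) enriched at causal variants.

    Each variant lands in each track independently with probability
    ``logit^-1(logit(background) + log_odds * causal_indicator)``; the
    log-odds shift is capped at 20 so +inf saturates instead of overflowing.
    Overlapping intervals are 1 bp wide, anchored on the variant position.
    """
    if not 0 < background_coverage < 1:
        raise ValueError("background_coverage must lie in (0,1)")
    rng = np.random.default_rng(seed)
    lo = min(enrichment_log_odds, 20.0)
    causal = np.zeros(truth.n_variants)
    for idx in truth.causal_indices():
        causal[idx] = 1.0
    logit_bg = np.log(background_coverage / (1 - background_coverage))
    prob = 1.0 / (1.0 + np.exp(-(logit_bg + lo * causal)))
    tracks = []
    for _ in range(n_tracks):
        hit = rng.random(truth.n_variants) < prob
        intervals = [
            (truth.chrom, int(pos) - 1, int(pos))
            for pos in truth.positions[hit]
        ]
        tracks.append(intervals)
    return tracks


def simulate_ckd_status(egfr_values: np.ndarray) -> np.ndarray:
    """Chronic kidney disease case status: 1 iff eGFR < 60 mL/min/1.73m² (strict)."""
    egfr = np.asarray(egfr_values, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR values must be positive")
    return (egfr < 60.0).astype(int)


def egfr_to_creatinine(
    egfr: np.ndarray, age: np.ndarray, female: np.ndarray, black: np.ndarray
) -> np.ndarray:
    """Invert the 4-variable MDRD equation to recover serum creatinine (mg/dL).

    Lets a latent eGFR-scale phenotype be expressed as creatinine and run
    back through ``association.mdrd_egfr`` end to end.
    """
    egfr = np.asarray(egfr, dtype=float)
    demog = (
        175.0
        * np.asarray(age, dtype=float) ** -0.203
        * np.where(np.asarray(female, dtype=bool), 0.742, 1.0)
        * np.where(np.asarray(black, dtype=bool), 1.212, 1.0)
    )
    return (egfr / demog) ** (-1.0 / 1.154)
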