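"""Annotation enrichment of fine-mapping posterior probabilities.

Two complementary models quantify whether variants in an annotation carry
more of the posterior probability of driving association signals:

1. A fractional (quasi-binomial) logistic regression of the posterior
   π_Cj on a per-locus intercept, one tested annotation indicator, and
   four genic covariates (3' UTR, 5' UTR, coding exon, 1 kb upstream of a
   TSS), with heteroskedasticity-robust sandwich standard errors. One
   annotation is tested at a time; over a battery of annotations
   significance is Bonferroni-corrected.

2. A hierarchical Bayes-factor model: each locus contains exactly one
   driver variant, whose prior of being variant j is proportional to
   exp(γᵀ x_j); the per-locus marginal likelihood is the prior-weighted
   sum of the variants' Bayes factors, and γ is estimated by Newton ascent
   of the summed log marginal likelihood, with a 95% CI from observed
   information. An annotation is called enriched when the CI excludes 0.

Also: interval-overlap indicators (1-based variant positions against
0-based half-open BED intervals), aggregation of posterior mass by most
severe variant consequence, rank-agreement between enrichment analyses,
and Bonferroni thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "EnrichmentEstimate",
    "CONSEQUENCE_SEVERITY",
    "CODING_CONSEQUENCES",
    "overlap_indicators",
    "severity_aggregate",
    "enrichment_logistic",
    "hierarchical_bf_enrichment",
    "compare_rankings",
    "bonferroni_threshold",
]

LN10 = float(np.log(10.0))

# Variant consequences from most to least severe (standard VEP ordering).
CONSEQUENCE_SEVERITY: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "feature_elongation",
    "regulatory_region_variant",
    "feature_truncation",
    "intergenic_variant",
)
_SEVERITY_RANK = {name: i for i, name in enumerate(CONSEQUENCE_SEVERITY)}

CODING_CONSEQUENCES = frozenset(CONSEQUENCE_SEVERITY[:18]) - {"mature_miRNA_variant"}


@dataclass
class EnrichmentEstimate:
    """One annotation's enrichment effect under one model."""

    annotation: str
    model: str                  # "logistic" or "hierarchical-BF"
    effect: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    significant: bool | None = None
    converged: bool = True


def overlap_indicators(positions: np.ndarray, intervals) -> np.ndarray:
    """Binary overlap of 1-based variant positions with 0-based half-open intervals.

    ``intervals`` is an iterable of (chrom, start, end) or (start, end);
    when chromosomes are present all intervals must be on the variants'
    chromosome already (filter upstream). A 1-based position p occupies
    0-based coordinate p-1, so p overlaps [start, end) iff start < p <= end.
    """
    pos = np.asarray(positions, dtype=np.int64)
    out = np.zeros(pos.size, dtype=np.int8)
    for iv in intervals:
        start, end = (iv[-2], iv[-1]) if len(iv) >= 3 else iv
        out |= ((pos - 1 >= start) & (pos - 1 < end)).astype(np.int8)
    return out


def severity_aggregate(
    posterior_table: pd.DataFrame, consequence_labels: pd.DataFrame
) -> pd.DataFrame:
    """Total posterior probability per most-severe consequence class.

    ``posterior_table`` needs ``variant`` and ``pi`` columns (across all
    loci); ``consequence_labels`` maps ``variant`` to one or more
    ``consequence`` labels, of which the most severe is kept per variant.
    Returns one row per represented class with summed ``pi`` and its
    ``share`` of the grand total.
    """
    labels = consequence_labels.copy()
    unknown = sorted(set(labels["consequence"]) - set(_SEVERITY_RANK))
    if unknown:
        raise ValueError(f"unknown consequence label(s): {unknown}")
    labels["rank"] = labels["consequence"].map(_SEVERITY_RANK)
    worst = labels.loc[labels.groupby("variant")["rank"].idxmin(), ["variant", "consequence"]]
    merged = posterior_table.merge(worst, on="variant", how="inner")
    agg = merged.groupby("consequence", as_index=False)["pi"].sum()
    agg["share"] = agg["pi"] / agg["pi"].sum()
    agg["coding"] = agg["consequence"].isin(CODING_CONSEQUENCES)
    return agg.sort_values("pi", ascending=False).reset_index(drop=True)


def _build_design(
    annotation: np.ndarray,
    locus_labels: np.ndarray,
    genic: np.ndarray | None,
    annotation_name: str,
) -> tuple[np.ndarray, list[str]]:
    x_k = np.asarray(annotation, dtype=float)
    if np.all(x_k == x_k[0]):
        raise ValueError(
            f"annotation {annotation_name!r} has no overlap variation (constant indicator)"
        )
    loci = pd.Categorical(locus_labels)
    # one intercept per locus; no global intercept (locus indicators span it)
    locus_mat = np.asarray(pd.get_dummies(loci), dtype=float)
    cols = [locus_mat, x_k[:, None]]
    names = [f"locus[{c}]" for c in loci.categories] + [annotation_name]
    if genic is not None and genic.size:
        genic = np.atleast_2d(np.asarray(genic, dtype=float))
        if genic.shape[0] != x_k.size:
            genic = genic.T
        for j in range(genic.shape[1]):
            if np.array_equal(genic[:, j], x_k):
                raise ValueError(
                    f"annotation {annotation_name!r} identical to genic covariate {j}"
                )
        cols.append(genic)
        names += [f"genic_{j}" for j in range(genic.shape[1])]
    return np.column_stack(cols), names


def enrichment_logistic(
    posteriors: np.ndarray,
    annotation: np.ndarray,
    locus_labels: np.ndarray,
    genic: np.ndarray | None = None,
    annotation_name: str = "annotation",
    battery_size: int | None = None,
    family_alpha: float = 0.05,
) -> EnrichmentEstimate:
    """Fractional logistic regression of posterior probability on annotation overlap.

    Quasi-binomial fit by IRLS (statsmodels GLM, binomial family) of π on
    {locus indicators, annotation, genic covariates}; the annotation
    coefficient's SE uses the HC1 robust sandwich estimator and the flag
    applies the Bonferroni threshold for ``battery_size`` tests (nominal
    0.05 when no battery is given).
    """
    pi = np.asarray(posteriors, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("posteriors must lie in [0,1]")
    design, names = _build_design(np.asarray(annotation), np.asarray(locus_labels), genic, annotation_name)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(f"collinear design; columns: {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fractional y triggers a binomial-domain warning
        fit = sm.GLM(pi, design, family=sm.families.Binomial()).fit(cov_type="HC1")
    k = names.index(annotation_name)
    effect = float(fit.params[k])
    se = float(fit.bse[k])
    z = effect / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    cut = bonferroni_threshold(battery_size, family_alpha) if battery_size else family_alpha
    return EnrichmentEstimate(
        annotation=annotation_name,
        model="logistic",
        effect=effect,
        se=se,
        ci_low=effect - 1.959963984540054 * se,
        ci_high=effect + 1.959963984540054 * se,
        p=p,
        significant=bool(p < cut),
    )


def hierarchical_bf_enrichment(
    log10_bfs: np.ndarray,
    annotation: np.ndarray,
    locus_labels: np.ndarray,
    genic: np.ndarray | None = None,
    annotation_name: str = "annotation",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> EnrichmentEstimate:
    """One-driver-per-locus hierarchical Bayes-factor enrichment model.

    Each locus holds exactly one driver; the prior that variant j is the
    driver is softmax(γᵀ x_j) within its locus, so the locus marginal
    likelihood is Σ_j softmax_j(γᵀx) · BF_j and the log-likelihood is

        Σ_loci [ logsumexp(γᵀx_j + λ_j ln10) − logsumexp(γᵀx_j) ].

    Newton ascent with analytic gradient (posterior minus prior mean of x
    per locus) and Hessian (posterior minus prior covariance). The first
    coefficient is the tested annotation; genic covariates, when given,
    are estimated jointly. 95% CI from the observed information.
    """
    lam = np.asarray(log10_bfs, dtype=float)
    x_k = np.asarray(annotation, dtype=float)
    cols = [x_k[:, None]]
    if genic is not None and np.asarray(genic).size:
        g = np.atleast_2d(np.asarray(genic, dtype=float))
        if g.shape[0] != x_k.size:
            g = g.T
        cols.append(g)
    x = np.column_stack(cols)
    labels = np.asarray(locus_labels)
    groups = [np.flatnonzero(labels == lab) for lab in pd.unique(labels)]
    for g_idx in groups:
        if g_idx.size < 2:
            raise ValueError("every locus needs at least two variants")
    # identifiability: the annotation must vary within at least one locus
    if all(np.all(x_k[g] == x_k[g][0]) for g in groups):
        raise ValueError(
            f"annotation {annotation_name!r} constant within every locus; effect unidentifiable"
        )

    ln_bf = lam * LN10
    p_dim = x.shape[1]
    gamma = np.zeros(p_dim)

    def _moments(gam):
        ll = 0.0
        grad = np.zeros(p_dim)
        hess = np.zeros((p_dim, p_dim))
        for g in groups:
            eta = x[g] @ gam
            prior_ln = eta - logsumexp(eta)
            post_ln = eta + ln_bf[g]
            norm = logsumexp(post_ln)
            post_ln = post_ln - norm
            ll += norm - logsumexp(eta)
            wp = np.exp(post_ln)
            wq = np.exp(prior_ln)
            mp = wp @ x[g]
            mq = wq @ x[g]
            grad += mp - mq
            cp = (x[g] * wp[:, None]).T @ x[g] - np.outer(mp, mp)
            cq = (x[g] * wq[:, None]).T @ x[g] - np.outer(mq, mq)
            hess += cp - cq
        return ll, grad, hess

    converged = False
    ll, grad, hess = _moments(gamma)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # flat likelihoods (weak BF contrast) invite runaway steps; cap them
        norm = np.linalg.norm(step)
        if norm > 2.0:
            step = step * (2.0 / norm)
        new = gamma - step  # ascent: hess is the ll Hessian (negative definite near optimum)
        ll_new, grad_new, hess_new = _moments(new)
        # fall back to damped steps if the full Newton step decreases the objective
        shrink = 1.0
        while ll_new < ll - 1e-12 and shrink > 1e-4:
            shrink /= 2.0
            new = gamma - shrink * step
            ll_new, grad_new, hess_new = _moments(new)
        if not np.all(np.isfinite(new)):
            break
        delta = np.max(np.abs(new - gamma))
        gamma, ll, grad, hess = new, ll_new, grad_new, hess_new
        if np.max(np.abs(gamma)) > 20.0:
            break  # likelihood flat in the tail: effect unbounded (separation-like)
        if delta < tol:
            converged = True
            break

    info = -hess  # observed information
    try:
        cov = np.linalg.inv(info)
        se = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
        converged = False
    effect = float(gamma[0])
    ci_low = effect - 1.959963984540054 * se
    ci_high = effect + 1.959963984540054 * se
    return EnrichmentEstimate(
        annotation=annotation_name,
        model="hierarchical-BF",
        effect=effect,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=bool(converged and (ci_low > 0 or ci_high < 0)),
        converged=converged,
    )


def compare_rankings(effects_a, effects_b) -> float:
    """Squared Spearman rank correlation between two sets of effect estimates."""
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.size != b.size:
        raise ValueError("effect vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three annotations to compare rankings")
    rho = stats.spearmanr(a, b).statistic
    return float(rho**2)


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests
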