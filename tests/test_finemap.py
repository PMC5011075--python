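"""Partition-averaged Bayes factors, posteriors, and credible sets."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp

from transfine.finemap import (
    finemap_locus,
    PartitionModel,
    build_credible_set,
    enumerate_partitions,
    freq_distance_matrix,
    partition_log10_bf,
    posterior_probs,
    transethnic_log10_bf,
    wakefield_log10_abf,
)


def abf_quadrature_oracle(beta, se, prior_sd):
    """Numerically integrate the Gaussian marginal likelihood ratio.

    ABF = ∫ N(beta_hat; b, se²) N(b; 0, W) db / N(beta_hat; 0, se²),
    evaluated by quadrature, independent of the closed form.
    """
    num, _ = integrate.quad(
        lambda b: stats.norm.pdf(beta, loc=b, scale=se)
        * stats.norm.pdf(b, loc=0, scale=prior_sd),
        -10 * prior_sd,
        10 * prior_sd,
        limit=200,
    )
    den = stats.norm.pdf(beta, loc=0, scale=se)
    return np.log10(num / den)


class TestFreqDistance:
    def test_identical_vectors(self):
        f = np.array([[0.2, 0.4], [0.2, 0.4]])
        np.testing.assert_allclose(freq_distance_matrix(f), 0.0)

    def test_hand_mean(self):
        f = np.array([[0.1, 0.1], [0.3, 0.5]])
        d = freq_distance_matrix(f)
        assert d[0, 1] == pytest.approx(0.3)
        assert d[1, 0] == pytest.approx(0.3)

    def test_matches_double_loop(self, rng):
        f = rng.uniform(0.01, 0.99, size=(5, 40))
        d = freq_distance_matrix(f)
        for a in range(5):
            for b in range(5):
                manual = np.mean([abs(f[a, j] - f[b, j]) for j in range(40)])
                assert d[a, b] == pytest.approx(manual, abs=1e-12)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            freq_distance_matrix(np.empty((3, 0)))


class TestPartitions:
    def test_single_study(self):
        model = enumerate_partitions(np.zeros((1, 1)))
        assert model.partitions == (((0,),),)
        assert model.prior == (1.0,)

    def test_two_studies_complete(self):
        model = enumerate_partitions(np.array([[0, 0.2], [0.2, 0]]))
        assert set(model.partitions) == {((0, 1),), ((0,), (1,))}
        assert model.prior == (0.5, 0.5)

    def test_two_pools_separate_at_k2(self):
        # studies 0,1 share low frequencies; 2,3 share high: average linkage
        # cuts between the pools at K=2
        f = np.array([[0.1] * 50, [0.12] * 50, [0.8] * 50, [0.82] * 50])
        model = enumerate_partitions(freq_distance_matrix(f))
        two_cluster = [p for p in model.partitions if len(p) == 2]
        assert two_cluster == [((0, 1), (2, 3))]

    def test_full_enumeration_bell_number(self):
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        model = enumerate_partitions(d, mode="full")
        assert len(model.partitions) == 15  # Bell(4)

    def test_invalid_partition_model_rejected(self):
        with pytest.raises(ValueError):
            PartitionModel(partitions=(((0,),),), prior=(0.5,))


class TestWakefieldABF:
    def test_null_beta_negative_evidence(self):
        assert wakefield_log10_abf(0.0, 0.1, 0.2) == pytest.approx(
            0.5 * np.log10(0.01 / (0.01 + 0.04))
        )

    def test_point_null_prior_limit(self):
        assert wakefield_log10_abf(0.5, 0.1, 1e-8) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quadrature_oracle(self):
        # includes the strong-signal reference case log10 ABF ~ 4.373
        cases = [(0.1, 0.02, 0.2), (0.3, 0.1, 0.2), (-0.2, 0.15, 0.5), (0.0, 0.05, 0.2)]
        for beta, se, w_sd in cases:
            got = wakefield_log10_abf(beta, se, w_sd)
            assert got == pytest.approx(abf_quadrature_oracle(beta, se, w_sd), abs=1e-6)
        assert wakefield_log10_abf(0.1, 0.02, 0.2) == pytest.approx(4.373, abs=0.001)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wakefield_log10_abf(0.1, 0.0, 0.2)
        with pytest.raises(ValueError):
            wakefield_log10_abf(0.1, 0.1, -1.0)


class TestPartitionBF:
    def test_single_cluster_equals_combined_abf(self, rng):
        betas, ses = rng.standard_normal(4) * 0.2, rng.uniform(0.05, 0.3, 4)
        w = 1 / ses**2
        bc = np.sum(w * betas) / np.sum(w)
        sc = 1 / np.sqrt(np.sum(w))
        got = partition_log10_bf(((0, 1, 2, 3),), betas, ses)
        assert got == pytest.approx(wakefield_log10_abf(bc, sc), abs=1e-12)

    def test_singletons_sum_of_abfs(self, rng):
        betas, ses = rng.standard_normal(3) * 0.2, rng.uniform(0.05, 0.3, 3)
        got = partition_log10_bf(((0,), (1,), (2,)), betas, ses)
        expected = sum(wakefield_log10_abf(b, s) for b, s in zip(betas, ses))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError):
            partition_log10_bf(((0,),), np.array([0.1, 0.2]), np.array([0.1, 0.1]))


class TestTransethnicBF:
    def test_one_study_reduces_to_wakefield(self):
        model = enumerate_partitions(np.zeros((1, 1)))
        got = transethnic_log10_bf(np.array([0.2]), np.array([0.05]), model)
        assert got == pytest.approx(wakefield_log10_abf(0.2, 0.05), abs=1e-12)

    def test_homogeneous_close_to_single_cluster(self, rng):
        # nine studies with identical effects: the fixed-effects partition
        # dominates and carries half the prior mass, so the averaged BF
        # stays within 0.5 log10 units (~log10 2 + dilution) of it
        betas = np.full(9, 0.25) + rng.normal(0, 0.01, 9)
        ses = np.full(9, 0.05)
        freqs = rng.uniform(0.2, 0.8, size=(9, 100))
        model = enumerate_partitions(freq_distance_matrix(freqs))
        lam = transethnic_log10_bf(betas, ses, model)
        single = partition_log10_bf((tuple(range(9)),), betas, ses)
        assert abs(lam - single) < 0.5

    def test_heterogeneity_beats_single_cluster(self):
        # two ancestry blocks with opposite effects: clustering wins
        betas = np.array([0.4, 0.4, -0.4, -0.4])
        ses = np.full(4, 0.05)
        f = np.array([[0.1] * 50, [0.12] * 50, [0.8] * 50, [0.82] * 50])
        model = enumerate_partitions(freq_distance_matrix(f))
        lam = transethnic_log10_bf(betas, ses, model)
        single = partition_log10_bf((tuple(range(4)),), betas, ses)
        assert lam > single

    def test_natural_log_internal_equivalence(self, rng):
        # same prior-weighted average computed wholly in natural logs
        betas, ses = rng.standard_normal(4) * 0.3, rng.uniform(0.04, 0.2, 4)
        freqs = rng.uniform(0.1, 0.9, size=(4, 30))
        model = enumerate_partitions(freq_distance_matrix(freqs))
        lam = transethnic_log10_bf(betas, ses, model)
        ln10 = np.log(10)
        ln_bfs = [partition_log10_bf(p, betas, ses) * ln10 for p in model.partitions]
        manual = logsumexp(np.array(ln_bfs) + np.log(model.prior)) / ln10
        assert lam == pytest.approx(manual, abs=1e-9)


class TestPosteriors:
    def test_equal_bfs_uniform(self):
        pi = posterior_probs(np.full(8, 2.5))
        np.testing.assert_allclose(pi, 1 / 8)

    def test_dominant_bf(self):
        lam = np.zeros(100)
        lam[0] = 3.0  # 3 log10 units above the rest
        pi = posterior_probs(lam)
        assert pi[0] > 0.9

    def test_sums_to_one(self, rng):
        for _ in range(20):
            pi = posterior_probs(rng.uniform(-5, 10, size=rng.integers(1, 200)))
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_z(self):
        # raising |z| at one variant (fixed SE) never lowers its posterior
        model = enumerate_partitions(np.zeros((1, 1)))
        ses = np.full(20, 0.1)
        base = np.linspace(0, 0.3, 20)
        prev = -1.0
        for bump in (0.0, 0.1, 0.2, 0.4):
            betas = base.copy()
            betas[7] += bump
            lam = np.array(
                [transethnic_log10_bf(np.array([b]), np.array([0.1]), model) for b in betas]
            )
            pi7 = posterior_probs(lam)[7]
            assert pi7 >= prev
            prev = pi7


def test_transethnic_median_set_size_no_larger_than_single_ancestry():
    """At matched total sample size and adequate power, combining four
    ancestries with differing LD never yields larger median credible sets
    than any single ancestry alone."""
    import pandas as pd

    from transfine import association
    from transfine.synthetic import AncestryModel, simulate_region_truth, simulate_study

    four = tuple(
        AncestryModel(lab, fst, rho, 500)
        for lab, fst, rho in (
            ("AFR", 0.15, 0.80), ("HIS", 0.08, 0.88),
            ("EUR", 0.05, 0.92), ("EAS", 0.11, 0.90),
        )
    )

    def median_set_size(config, seed):
        rng = np.random.default_rng(seed)
        sizes = []
        for _ in range(60):
            truth = simulate_region_truth(
                60, ancestries=four, seed=int(rng.integers(2**31)),
                causal_beta=-1.0, residual_sd=4.0,
            )
            tables = []
            for anc in config:
                ds = simulate_study(truth, anc, seed=int(rng.integers(2**31)), n_covariates=0)
                res = association.linear_assoc(ds.dosages, ds.phenotype)
                tab = pd.DataFrame(
                    {"chrom": truth.chrom, "pos": truth.positions,
                     "eaf": ds.dosages.mean(axis=0) / 2,
                     "beta": res["beta"], "se": res["se"]}
                ).dropna()
                tables.append(tab.reset_index(drop=True))
            shared = set(tables[0]["pos"])
            for t in tables[1:]:
                shared &= set(t["pos"])
            tables = [t[t["pos"].isin(shared)].reset_index(drop=True) for t in tables]
            _, cs = finemap_locus(tables)
            sizes.append(cs.size)
        return float(np.median(sizes))

    trans = median_set_size(four, seed=91)
    for anc in four:
        single = (AncestryModel(anc.label, anc.fst, anc.ld_rho, 2000),)
        assert trans <= median_set_size(single, seed=91)


class TestCredibleSet:
    def test_single_dominant_variant(self):
        pi = np.array([0.995, 0.004, 0.001])
        cs = build_credible_set(pi)
        assert cs.size == 1
        assert cs.cumulative == pytest.approx(0.995)

    def test_uniform_hundred_needs_all(self):
        # 99 variants reach exactly 0.99 which does not *exceed* it
        pi = np.full(100, 0.01)
        cs = build_credible_set(pi)
        assert cs.size == 100

    def test_two_variant_set(self):
        cs = build_credible_set(np.array([0.6, 0.4]))
        assert cs.size == 2

    def test_strict_exceedance_and_minimality(self, rng):
        for _ in range(50):
            lam = rng.uniform(-2, 6, size=rng.integers(3, 120))
            pi = posterior_probs(lam)
            cs = build_credible_set(pi, log10_bfs=lam)
            assert cs.cumulative > 0.99
            if cs.size > 1:
                without_last = cs.cumulative - pi[cs.indices[-1]]
                assert without_last <= 0.99 + 1e-9

    def test_tie_break_by_position(self):
        pi = np.array([0.5, 0.5])
        cs = build_credible_set(
            pi, positions=np.array([200, 100]), level=0.4
        )
        assert cs.indices[0] == 1  # equal posterior: earlier position first

    def test_span(self):
        pi = np.array([0.7, 0.25, 0.05])
        cs = build_credible_set(pi, positions=np.array([100, 500, 900]), level=0.9)
        assert cs.size == 2
        assert cs.span_bp == 400

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            build_credible_set(np.array([0.5, 0.2]))
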