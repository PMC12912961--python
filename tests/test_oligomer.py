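"""Dual Poisson mixture: prediction, fitting, V/O scoring, K selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligocount import (
    FitError,
    build_distribution,
    fit_monomer_mean,
    oligomer_mean_from_totals,
    predict_dual_poisson,
    score_O,
    score_V,
    select_oligomer_size,
    simulate_cluster_compositions,
)
from oligocount.oligomer import CopyNumberDistribution

from conftest import (
    MUT_K,
    MUT_KMER_MEAN,
    MUT_M,
    MUT_N,
    WT_K,
    WT_KMER_MEAN,
    WT_M,
    exact_distribution,
    wt_config,
)
from conftest import SyntheticConfig


def _pois(n: int, mu: float) -> float:
    """Poisson pmf from first principles (oracle helper, no scipy)."""
    if mu == 0:
        return 1.0 if n == 0 else 0.0
    return math.exp(-mu + n * math.log(mu) - math.lgamma(n + 1))


def convolution_oracle(K: int, m: float, k: float, n_max: int) -> np.ndarray:
    """Brute-force convolution of the monomer pmf with the K-spaced K-mer pmf."""
    mono = [_pois(n, m) for n in range(n_max + 1)]
    olig = [0.0] * (n_max + 1)
    j = 0
    while K * j <= n_max:
        olig[K * j] = _pois(j, k)
        j += 1
    return np.array(
        [sum(mono[i] * olig[n - i] for i in range(n + 1)) for n in range(n_max + 1)]
    )


class TestPredictDualPoisson:
    @settings(max_examples=60, deadline=None)
    @given(
        K=st.integers(1, 6),
        m=st.floats(0.0, 6.0),
        k=st.floats(0.0, 3.0),
    )
    def test_matches_convolution_oracle(self, K, m, k):
        pred = predict_dual_poisson(K, m, k, n_pred_max=30)
        assert np.allclose(pred, convolution_oracle(K, m, k, 30), atol=1e-12)

    def test_wild_type_peaks_at_four_and_seven(self):
        pred = predict_dual_poisson(3, 2.2, 1.5)
        maxima = [
            n for n in range(2, 11) if pred[n] > pred[n - 1] and pred[n] > pred[n + 1]
        ]
        assert maxima == [4, 7]

    def test_k1_is_sum_of_independent_poissons(self):
        pred = predict_dual_poisson(1, 1.0, 1.0, n_pred_max=20)
        assert pred[0] == pytest.approx(math.exp(-2.0), abs=1e-12)
        assert np.allclose(pred, [_pois(n, 2.0) for n in range(21)], atol=1e-12)

    def test_degenerate_all_mass_at_zero(self):
        pred = predict_dual_poisson(3, 0.0, 0.0, n_pred_max=5)
        assert pred[0] == 1.0 and pred[1:].sum() == 0.0

    def test_normalization_within_1e9(self):
        for K, m, k in [(3, 2.2, 1.5), (6, 2.0, 1.0), (2, 0.5, 0.1)]:
            assert predict_dual_poisson(K, m, k).sum() == pytest.approx(1.0, abs=1e-9)

    def test_sub_k_bins_carry_zero_oligomer_factor(self):
        K, m, k = 4, 1.5, 0.8
        pred = predict_dual_poisson(K, m, k, n_pred_max=10)
        for n in range(K):
            assert pred[n] == pytest.approx(math.exp(-k) * _pois(n, m), abs=1e-12)


class TestBuildDistribution:
    def test_small_example(self):
        dist = build_distribution([4, 4, 7])
        assert dist.p_obs(4) == pytest.approx(2 / 3)
        assert dist.p_obs(7) == pytest.approx(1 / 3)
        assert dist.mean_N == pytest.approx(5.0)

    def test_single_cluster(self):
        dist = build_distribution([1])
        assert dist.p_obs(1) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            build_distribution([])

    def test_wild_type_sample_mean_near_paper_value(self, wt_distribution):
        """878 clusters: observed mean within the 3-sigma sampling band of 6.6."""
        sd = math.sqrt(WT_M + WT_K**2 * WT_KMER_MEAN)
        assert abs(wt_distribution.mean_N - 6.6) < 3 * sd / math.sqrt(878)


class TestMonomerFit:
    def test_self_consistency_on_exact_histogram(self):
        dist = exact_distribution(predict_dual_poisson(3, 2.2, 1.5, n_pred_max=60))
        m_hat, resid = fit_monomer_mean(dist, 3)
        assert m_hat == pytest.approx(2.2, abs=1e-3)
        assert resid < 1e-10

    def test_pure_poisson_histogram_with_k2(self):
        m0 = 1.3
        dist = exact_distribution(np.array([_pois(n, m0) for n in range(40)]))
        m_hat, _ = fit_monomer_mean(dist, 2)
        assert m_hat == pytest.approx(m0, abs=1e-3)

    def test_k1_returns_observed_mean(self):
        dist = build_distribution([4, 4, 7])
        assert fit_monomer_mean(dist, 1)[0] == dist.mean_N

    def test_empty_sub_k_bins_rejected(self):
        dist = build_distribution([10, 12, 14])
        with pytest.raises(FitError):
            fit_monomer_mean(dist, 3)


class TestOligomerMeanFromTotals:
    def test_paper_values_round_to_published_k(self):
        assert round(oligomer_mean_from_totals(6.6, 2.2, 3), 1) == 1.5

    def test_zero_when_mean_equals_monomers(self):
        assert oligomer_mean_from_totals(2.2, 2.2, 3) == 0.0

    def test_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            assert oligomer_mean_from_totals(1.0, 2.0, 3) == 0.0


class TestScores:
    def _dist(self, probs):
        counts = {n + 1: p for n, p in enumerate(probs) if p > 0}
        mean = sum(n * p for n, p in counts.items())
        return CopyNumberDistribution(counts=counts, n_total=1, mean_N=mean)

    def test_perfect_agreement_is_infinite(self):
        dist = self._dist([0.5, 0.5])
        pred = np.array([0.0, 0.5, 0.5])
        assert score_V(dist, pred) == math.inf
        assert score_O(dist, pred) == math.inf

    def test_v_uniform_vs_zero_prediction(self):
        dist = self._dist([0.1] * 10)
        assert score_V(dist, np.zeros(11)) == pytest.approx(10.0)

    def test_v_disjoint_deltas(self):
        dist = self._dist([1.0])  # all mass at N=1
        pred = np.array([0.0, 0.0, 1.0])  # all mass at N=2
        assert score_V(dist, pred) == pytest.approx(0.5)

    def test_o_weighted_relative_error(self):
        dist = self._dist([0.5, 0.5])
        pred = np.array([0.0, 0.25, 0.75])
        assert score_O(dist, pred) == pytest.approx(4.0)

    def test_o_excludes_empty_bins(self):
        dist = self._dist([1.0])  # support {1} only
        pred = np.array([0.0, 0.8, 0.2])  # mass at N=2 must not contribute
        assert score_O(dist, pred) == pytest.approx(1 / (0.2**2 / 1.0))

    def test_o_undefined_when_all_bins_empty(self):
        dist = CopyNumberDistribution(counts={20: 5}, n_total=5, mean_N=20.0)
        with pytest.raises(FitError):
            score_O(dist, np.zeros(11))

    @pytest.mark.parametrize("eps", [1e-3, 1e-2, 0.1])
    def test_scores_strictly_decrease_under_perturbation(self, eps):
        dist = self._dist([0.3, 0.3, 0.4])
        pred = np.array([0.0, 0.3, 0.3, 0.4])
        bumped = pred.copy()
        bumped[2] += eps
        assert score_V(dist, bumped) < score_V(dist, pred)
        assert score_O(dist, bumped) < score_O(dist, pred)
        smaller = pred.copy()
        smaller[2] += eps / 2
        assert score_V(dist, bumped) < score_V(dist, smaller)


class TestModelSelection:
    def test_exact_trimer_histogram_selects_k3(self):
        dist = exact_distribution(predict_dual_poisson(3, 2.2, 1.5, n_pred_max=60))
        sel = select_oligomer_size(dist)
        assert sel.best_K_by_V == 3
        assert sel.best_K_by_O == 3

    def test_pure_poisson_selects_k1_by_parsimony(self):
        dist = exact_distribution(np.array([_pois(n, 2.0) for n in range(40)]))
        sel = select_oligomer_size(dist)
        assert sel.best_K_by_V == 1
        assert sel.best_K_by_O == 1

    def test_hexamer_mixture_selects_k6(self):
        cfg = SyntheticConfig(
            seed=21, oligomer_size=MUT_K, monomer_mean=MUT_M,
            oligomer_mean=MUT_KMER_MEAN, n_clusters=MUT_N,
        )
        dist = build_distribution(
            [c.copy_number for c in simulate_cluster_compositions(cfg)]
        )
        sel = select_oligomer_size(dist)
        assert sel.best_K_by_O == 6

    def test_limit_k_to_zero_recovers_single_poisson(self):
        # k -> 0: the mixture collapses onto Poisson(m)
        pred = predict_dual_poisson(3, 2.0, 0.0, n_pred_max=25)
        assert np.allclose(pred, [_pois(n, 2.0) for n in range(26)], atol=1e-12)

    def test_parameter_recovery_over_replicates(self):
        """The selected K is 3 in >= 90% of 100 replicates at n=878, the two
        statistics agree in a clear majority, and m is nearly unbiased."""
        o_wins = 0
        agree = 0
        m_hats = []
        for rep in range(100):
            clusters = simulate_cluster_compositions(wt_config(seed=5000 + rep))
            dist = build_distribution([c.copy_number for c in clusters])
            sel = select_oligomer_size(dist)
            o_wins += sel.best_K_by_O == 3
            agree += sel.best_K_by_V == sel.best_K_by_O == 3
            if 3 in sel.fits:
                m_hats.append(sel.fits[3].m)
        assert o_wins >= 90
        assert agree > 50
        assert abs(np.mean(m_hats) - WT_M) < 0.2
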