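"""Closed-form block size distributions: values, identities, diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from syndecay import (
    CombinedParams,
    DegenerateModelError,
    HotspotParams,
    OneCutParams,
    TwoCutParams,
    hotspot_condition_vector,
    hotspot_matrices,
    hotspot_stationary,
    multicut_error,
    overlap_error,
    pmf_combined,
    pmf_hotspot,
    pmf_one_cut,
    pmf_two_cut,
    truncated_pmf,
    two_cut_span_pmf,
)
from syndecay.models import hotspot_spectrum


def enumerate_hotspot_pmf(n: int, params: HotspotParams, t: float) -> float:
    """Exhaustive oracle: sum over all 2**(n+1) hotspot/coldspot sequences.

    A spot sequence covers the reference region plus the next n regions;
    its weight is the conditioning probability of the first state, the
    Markov transition at each step, no-cut factors at the n - 1 interior
    regions and an at-least-one-cut factor at the last.
    """
    mats = hotspot_matrices(params, t)
    transition = mats.transition
    no_cut = mats.no_cut[0]  # per-destination-state no-cut probabilities
    cut = 1.0 - no_cut
    sigma = mats.condition_vector
    states = (np.arange(2 ** (n + 1))[:, None] >> np.arange(n + 1)) & 1
    weights = sigma[states[:, 0]]
    for i in range(1, n + 1):
        weights = weights * transition[states[:, i - 1], states[:, i]]
        weights = weights * (no_cut[states[:, i]] if i < n else cut[states[:, i]])
    return float(weights.sum())


class TestOneCut:
    @pytest.mark.parametrize(
        "n, kappa, t, expected",
        [
            (1, math.log(2), 1.0, 0.5),
            (2, math.log(2), 1.0, 0.25),
            (1, 0.1, 0.25, 0.024690087971667385),
        ],
    )
    def test_values(self, n, kappa, t, expected):
        assert pmf_one_cut(n, OneCutParams(kappa), t) == pytest.approx(expected, rel=1e-12)

    def test_normalizes(self):
        ns = np.arange(1, 2001)
        total = pmf_one_cut(ns, OneCutParams(0.1), 0.25).sum()
        tail = math.exp(-0.025 * 2000)  # mass beyond the truncation
        assert total + tail == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateModelError):
            pmf_one_cut(1, OneCutParams(0.0), 1.0)
        with pytest.raises(DegenerateModelError):
            pmf_one_cut(1, OneCutParams(0.5), 0.0)


class TestTwoCut:
    def test_span_collapses_for_large_theta(self):
        assert two_cut_span_pmf(1, theta=700.0) == pytest.approx(1.0)

    def test_span_mean(self):
        ns = np.arange(1, 5001)
        mean = float((ns * two_cut_span_pmf(ns, 0.5)).sum())
        assert mean == pytest.approx(2.5414940825367984, rel=1e-9)
        mean262 = float((ns * two_cut_span_pmf(ns, 0.4808)).sum())
        assert mean262 == pytest.approx(2.62, abs=5e-3)

    def test_pmf_value(self):
        value = pmf_two_cut(1, TwoCutParams(gamma=0.1, theta=0.5), 0.25)
        assert value == pytest.approx(0.21656736180242617, rel=1e-12)

    def test_large_theta_limit(self):
        value = pmf_two_cut(1, TwoCutParams(gamma=0.1, theta=700.0), 0.25)
        expected = 0.5 + 0.5 * (1 - math.exp(-0.025))
        assert value == pytest.approx(expected, rel=1e-12)

    def test_normalizes(self):
        ns = np.arange(1, 5001)
        total = pmf_two_cut(ns, TwoCutParams(0.1, 0.5), 0.25).sum()
        tail = 0.5 * math.exp(-0.525 * 5000) + 0.5 * math.exp(-0.025 * 5000)
        assert total + tail == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateModelError):
            pmf_two_cut(1, TwoCutParams(0.0, 0.5), 1.0)
        with pytest.raises(DegenerateModelError):
            two_cut_span_pmf(1, 0.0)


class TestCombined:
    def test_reduces_to_one_cut(self):
        ns = np.arange(1, 2001)
        combined = pmf_combined(ns, CombinedParams(kappa=0.2, gamma=0.0, theta=0.7), 0.25)
        pure = pmf_one_cut(ns, OneCutParams(0.2), 0.25)
        np.testing.assert_allclose(combined, pure, rtol=0, atol=1e-12)

    def test_reduces_to_two_cut(self):
        ns = np.arange(1, 2001)
        combined = pmf_combined(ns, CombinedParams(kappa=0.0, gamma=0.15, theta=0.4), 0.25)
        pure = pmf_two_cut(ns, TwoCutParams(0.15, 0.4), 0.25)
        np.testing.assert_allclose(combined, pure, rtol=0, atol=1e-12)

    def test_mixture_weights(self):
        # kappa = gamma gives weight 1/3 on the theta-shifted component
        params = CombinedParams(kappa=0.1, gamma=0.1, theta=0.5)
        t = 0.25
        n = np.arange(1, 100)
        a, b = 0.05 + 0.5, 0.05  # (kappa+gamma)t + theta, (kappa+gamma)t
        expected = (1 / 3) * np.exp(-a * (n - 1)) * (1 - np.exp(-a)) + (
            2 / 3
        ) * np.exp(-b * (n - 1)) * (1 - np.exp(-b))
        np.testing.assert_allclose(pmf_combined(n, params, t), expected, rtol=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateModelError):
            pmf_combined(1, CombinedParams(0.0, 0.0, 0.5), 1.0)


class TestHotspot:
    def test_stationary_example(self):
        pi_h, pi_c = hotspot_stationary(HotspotParams(0.5, 0.01, r_hc=0.05, r_ch=0.01))
        assert pi_h == pytest.approx(1 / 6)
        assert pi_c == pytest.approx(5 / 6)

    def test_stationary_symmetry_and_eigenvector(self):
        params = HotspotParams(0.5, 0.01, r_hc=0.3, r_ch=0.3)
        assert hotspot_stationary(params) == pytest.approx((0.5, 0.5))
        params = HotspotParams(0.5, 0.01, r_hc=0.07, r_ch=0.4)
        pi = np.array(hotspot_stationary(params))
        mats = hotspot_matrices(params, 0.25)
        np.testing.assert_allclose(pi @ mats.transition, pi, atol=1e-14)

    def test_condition_vector_example(self):
        sigma = hotspot_condition_vector(HotspotParams(0.5, 0.01, 0.05, 0.01), 0.25)
        assert sigma[0] == pytest.approx(0.9039570003867436, rel=1e-10)
        assert sigma.sum() == pytest.approx(1.0)

    def test_condition_vector_limits(self):
        equal = HotspotParams(0.3, 0.3, 0.05, 0.01)
        sigma = hotspot_condition_vector(equal, 0.25)
        assert sigma[0] == pytest.approx(hotspot_stationary(equal)[0])
        all_hot = HotspotParams(0.3, 0.0, 0.05, 0.01)
        assert hotspot_condition_vector(all_hot, 0.25)[0] == pytest.approx(1.0)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateModelError):
            hotspot_condition_vector(HotspotParams(0.0, 0.0, 0.05, 0.01), 0.25)

    def test_reduces_to_one_cut(self):
        ns = np.arange(1, 1001)
        params = HotspotParams(0.2, 0.2, r_hc=0.3, r_ch=0.6)
        np.testing.assert_allclose(
            pmf_hotspot(ns, params, 0.25),
            pmf_one_cut(ns, OneCutParams(0.2), 0.25),
            rtol=0,
            atol=1e-12,
        )

    def test_label_swap_symmetry(self):
        # constructor canonicalizes, so a swapped specification gives the
        # same object and hence the same distribution
        a = HotspotParams(0.5, 0.01, r_hc=0.05, r_ch=0.2)
        b = HotspotParams(0.01, 0.5, r_hc=0.2, r_ch=0.05)
        assert a == b
        np.testing.assert_allclose(
            pmf_hotspot(np.arange(1, 50), a, 0.3), pmf_hotspot(np.arange(1, 50), b, 0.3)
        )

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 10])
    def test_matches_enumeration(self, n, fig2_params):
        params = fig2_params["hotspot"]
        assert pmf_hotspot(n, params, 0.25) == pytest.approx(
            enumerate_hotspot_pmf(n, params, 0.25), abs=1e-12
        )

    def test_spectrum_reconstructs_pmf(self, fig2_params):
        params = fig2_params["hotspot"]
        lam1, lam2, weight = hotspot_spectrum(params, 0.25)
        other = (1 - weight / (1 - lam1)) * (1 - lam2)  # normalization fixes it
        ns = np.arange(1, 500)
        mixture = weight * lam1 ** (ns - 1) + other * lam2 ** (ns - 1)
        np.testing.assert_allclose(mixture, pmf_hotspot(ns, params, 0.25), atol=1e-13)


class TestDiagnostics:
    def test_values(self):
        params = TwoCutParams(gamma=0.1, theta=0.5)
        assert overlap_error(params, 0.25) == pytest.approx(0.014975295345818374, rel=1e-10)
        assert multicut_error(params, 0.25) == pytest.approx(3.0734017095901747e-4, rel=1e-8)

    def test_zero_rate(self):
        assert overlap_error(TwoCutParams(0.0, 0.5), 1.0) == 0.0
        assert multicut_error(TwoCutParams(0.0, 0.5), 1.0) == 0.0

    def test_monotonicity_and_limits(self):
        gammas = np.linspace(0.01, 3.0, 40)
        overlaps = [overlap_error(TwoCutParams(g, 0.5), 1.0) for g in gammas]
        multis = [multicut_error(TwoCutParams(g, 0.5), 1.0) for g in gammas]
        assert np.all(np.diff(overlaps) > 0)
        assert np.all(np.diff(multis) > 0)
        assert all(0 <= v < 1 for v in overlaps + multis)
        # gamma -> infinity: overlap error approaches exp(-theta)
        assert overlap_error(TwoCutParams(1e6, 0.5), 1.0) == pytest.approx(math.exp(-0.5))
        thetas = np.linspace(0.1, 3.0, 30)
        by_theta = [overlap_error(TwoCutParams(0.2, th), 1.0) for th in thetas]
        assert np.all(np.diff(by_theta) < 0)


class TestTruncation:
    def test_single_atom(self):
        pmf = truncated_pmf("two_cut", TwoCutParams(0.1, 0.5), 0.25, 7, 7)
        assert pmf.support.tolist() == [7]
        assert pmf.probabilities[0] == pytest.approx(1.0)

    def test_memoryless_geometric(self):
        # truncating a geometric from below leaves the ratio unchanged
        pmf = truncated_pmf("one_cut", OneCutParams(0.4), 0.25, 3, 60)
        ratios = pmf.probabilities[1:] / pmf.probabilities[:-1]
        np.testing.assert_allclose(ratios, math.exp(-0.1), rtol=1e-10)

    def test_hotspot_window_sums_to_one(self, fig2_params):
        pmf = truncated_pmf("hotspot", fig2_params["hotspot"], 0.25, 3, 1000)
        assert pmf.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            truncated_pmf("one_cut", OneCutParams(0.1), 0.25, 5, 4)


@given(
    kappa=st.floats(0.01, 5.0),
    gamma=st.floats(0.01, 5.0),
    theta=st.floats(0.01, 5.0),
    t=st.floats(0.05, 1.0),
)
def test_combined_is_normalized_probability(kappa, gamma, theta, t):
    """Mixture PMFs are non-negative and sum to one up to a bounded tail."""
    ns = np.arange(1, 3001)
    values = pmf_combined(ns, CombinedParams(kappa, gamma, theta), t)
    assert np.all(values >= 0)
    both = (kappa + gamma) * t
    tail = math.exp(-both * 3000)  # dominated by the slower component
    assert values.sum() == pytest.approx(1.0, abs=tail + 1e-12)


@given(
    kappa_h=st.floats(0.05, 3.0),
    kappa_c=st.floats(0.001, 3.0),
    r_hc=st.floats(0.01, 1.0),
    r_ch=st.floats(0.01, 1.0),
)
def test_hotspot_matches_enumeration_fuzz(kappa_h, kappa_c, r_hc, r_ch):
    """Matrix-product law equals the exhaustive spot-sequence sum."""
    params = HotspotParams(kappa_h, kappa_c, r_hc, r_ch)
    for n in (1, 2, 4, 7):
        assert pmf_hotspot(n, params, 0.25) == pytest.approx(
            enumerate_hotspot_pmf(n, params, 0.25), abs=1e-12
        )
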