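import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from wilsonplan import (WilsonIntensityModel, assign_sigmas, count_overlaps,
                        max_overlap_probability, probability_surface,
                        recommend_ratio, sample_intensities, sigma_param,
                        simulate_overlap_experiment, sum_f_squared)

TAURINE_COMP = {"C": 8, "H": 28, "N": 4, "O": 12, "S": 4}


# ---------------------------------------------------------------------------
# Sigma and the Wilson distributions
# ---------------------------------------------------------------------------

def test_sigma_param_reduces_to_sum_f_squared_at_B0():
    assert sigma_param({"C": 3}, 0.0, 0.3) == pytest.approx(
        sum_f_squared({"C": 3}, 0.3), rel=1e-14)


def test_sigma_param_debye_waller_factor():
    # exp(-2 * 1.53 * 0.495^2) evaluated independently
    ratio = sigma_param(TAURINE_COMP, 1.53, 0.495) \
        / sum_f_squared(TAURINE_COMP, 0.495)
    assert ratio == pytest.approx(0.4725, abs=2e-4)
    assert ratio == pytest.approx(math.exp(-2 * 1.53 * 0.495 ** 2), rel=1e-12)


def test_sigma_param_strictly_decreasing_in_s():
    s = np.linspace(0.01, 0.65, 50)
    vals = [sigma_param(TAURINE_COMP, 1.0, x) for x in s]
    assert all(a > b for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("sig", [1e-2, 1.0, 1e4])
@pytest.mark.parametrize("centric", [False, True])
def test_pdf_normalization_and_mean_equal_sigma(sig, centric):
    model = WilsonIntensityModel(sig, centric)
    # integrate in units of Sigma for stable quadrature at any scale
    norm, _ = integrate.quad(lambda u: sig * model.pdf(u * sig), 0, np.inf,
                             limit=200)
    mean, _ = integrate.quad(lambda u: u * sig * sig * model.pdf(u * sig),
                             0, np.inf, limit=200)
    assert norm == pytest.approx(1.0, abs=1e-6)
    assert mean == pytest.approx(sig, rel=1e-6)


def test_acentric_cdf_at_sigma():
    model = WilsonIntensityModel(7.0, centric=False)
    assert model.cdf(7.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)


def test_centric_cdf_is_erf_and_median():
    model = WilsonIntensityModel(2.0, centric=True)
    for i in (0.1, 1.0, 5.0):
        assert model.cdf(i) == pytest.approx(
            math.erf(math.sqrt(i / (2 * 2.0))), rel=1e-10)
    # median of the chi^2_1 law in units of Sigma
    assert model.cdf(0.454936 * 2.0) == pytest.approx(0.5, abs=1e-5)


def test_negative_intensity_rejected():
    model = WilsonIntensityModel(1.0, centric=False)
    with pytest.raises(ValueError):
        model.pdf(-1.0)
    with pytest.raises(ValueError):
        WilsonIntensityModel(0.0, False)


# ---------------------------------------------------------------------------
# Probability surface and the weakest-bin overlap probability
# ---------------------------------------------------------------------------

def test_surface_cells_are_cdf_differences():
    surf = probability_surface(TAURINE_COMP, 1.53, (0.4, 0.5), 0.01,
                               (0.0, 50.0), 5.0, centric=True)
    model = WilsonIntensityModel(
        sigma_param(TAURINE_COMP, 1.53, surf.s_mid[3]), True)
    expected = model.cdf(surf.i_edges[3]) - model.cdf(surf.i_edges[2])
    assert surf.probabilities[3, 2] == pytest.approx(expected, rel=1e-12)


def test_surface_rows_normalize_over_wide_intensity_range():
    sig_max = sigma_param(TAURINE_COMP, 1.53, 0.405)
    surf = probability_surface(TAURINE_COMP, 1.53, (0.4, 0.5), 0.01,
                               (0.0, 50 * sig_max), sig_max, centric=True)
    assert np.all(surf.probabilities.sum(axis=1) >= 0.999999)


def test_surface_maximum_at_weakest_bin_of_highest_shell():
    surf = probability_surface(TAURINE_COMP, 1.53, (0.1, 0.5), 0.01,
                               (0.0, 1.0), 0.01, centric=True)
    m, b = np.unravel_index(np.argmax(surf.probabilities),
                            surf.probabilities.shape)
    assert b == 0
    assert m == len(surf.s_mid) - 1


def test_max_overlap_probability_equals_squared_surface_entry():
    surf = probability_surface(TAURINE_COMP, 1.53, (0.49, 0.50), 0.01,
                               (0.0, 1.0), 0.01, centric=True)
    p2 = max_overlap_probability(TAURINE_COMP, 1.53, (0.49, 0.50), 0.01,
                                 centric=True)
    assert p2 == surf.probabilities[-1, 0] ** 2


def test_max_overlap_probability_monotone_in_bin_width():
    args = (TAURINE_COMP, 1.53, (0.49, 0.50))
    small = max_overlap_probability(*args, 1e-6, centric=True)
    mid = max_overlap_probability(*args, 0.01, centric=True)
    big = max_overlap_probability(*args, 0.02, centric=True)
    assert small < 1e-8
    assert small < mid < big
    with pytest.raises(ValueError):
        max_overlap_probability(*args, 0.0, centric=True)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def test_exact_acentric_mean_near_sigma():
    model = WilsonIntensityModel(3.0, centric=False)
    draws = sample_intensities(model, 100_000, "exact", seed=1)
    assert draws.mean() == pytest.approx(3.0, rel=0.02)


def test_exact_centric_matches_scaled_chi2_cdf():
    model = WilsonIntensityModel(5.0, centric=True)
    draws = sample_intensities(model, 10_000, "exact", seed=2)
    ks = stats.kstest(draws, stats.chi2(df=1, scale=5.0).cdf).statistic
    assert ks < 0.02


@pytest.mark.parametrize("sampler", ["exact", "slice"])
@pytest.mark.parametrize("centric", [False, True])
def test_sampler_seed_reproducibility(sampler, centric):
    model = WilsonIntensityModel(2.5, centric)
    a = sample_intensities(model, 200, sampler, seed=7)
    b = sample_intensities(model, 200, sampler, seed=7)
    np.testing.assert_array_equal(a, b)
    c = sample_intensities(model, 200, sampler, seed=8)
    assert not np.array_equal(a, c)


def test_slice_sampler_tracks_exact_distribution():
    model = WilsonIntensityModel(144.0, centric=True)
    a = sample_intensities(model, 3000, "slice", seed=11)
    b = sample_intensities(model, 3000, "exact", seed=12)
    assert stats.ks_2samp(a, b).pvalue > 0.01
    assert a.min() > 0


def test_sampler_input_validation():
    model = WilsonIntensityModel(1.0, False)
    with pytest.raises(ValueError):
        sample_intensities(model, 0, "exact", seed=1)
    with pytest.raises(ValueError):
        sample_intensities(model, 5, "exact")
    with pytest.raises(ValueError):
        sample_intensities(model, 5, "metropolis", seed=1)


# ---------------------------------------------------------------------------
# Sigma assignment and overlap counting
# ---------------------------------------------------------------------------

def test_assign_sigmas_elementwise():
    np.testing.assert_allclose(assign_sigmas([100.0, 50.0], 20), [5.0, 2.5])
    np.testing.assert_allclose(assign_sigmas([100.0], 1e9), [1e-7])
    with pytest.raises(ValueError):
        assign_sigmas([1.0], 0.0)


def brute_force_overlaps(I, sig):
    """Independent re-implementation of the adjacent-pair overlap rule."""
    order = sorted(range(len(I)), key=lambda i: -I[i])
    Is = [I[i] for i in order]
    ss = [sig[i] for i in order]
    pairs, involved = 0, set()
    for a in range(len(Is) - 1):
        if Is[a] - Is[a + 1] < ss[a] + ss[a + 1]:
            pairs += 1
            involved |= {a, a + 1}
    return pairs, len(involved)


def test_count_overlaps_hand_example():
    I = [100.0, 99.0, 50.0]
    sig = assign_sigmas(I, 20)
    rpt = count_overlaps(I, sig)
    assert (rpt.overlapping_pairs, rpt.intensities_involved) == (1, 2)
    assert brute_force_overlaps(I, list(sig)) == (1, 2)
    assert rpt.intensities[0] >= rpt.intensities[-1]


def test_count_overlaps_degenerate_cases():
    equal = count_overlaps([5.0] * 6, [0.1] * 6)
    assert equal.overlapping_pairs == 5
    assert equal.intensities_involved == 6
    none = count_overlaps([3.0, 2.0, 1.0], [0.0, 0.0, 0.0])
    assert none.overlapping_pairs == 0
    zero = count_overlaps([1.0, 0.0], [0.1, 0.0])
    assert zero.zero_intensities == 1
    with pytest.raises(ValueError):
        count_overlaps([1.0], [0.1, 0.2])


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=30),
       st.floats(1.0, 200.0), st.sampled_from([1e-3, 1.0, 1e3]))
def test_overlap_counts_match_brute_force_and_scale_invariance(I, ratio, k):
    sig = assign_sigmas(I, ratio)
    rpt = count_overlaps(I, sig)
    assert (rpt.overlapping_pairs, rpt.intensities_involved) == \
        brute_force_overlaps(I, list(sig))
    scaled = count_overlaps([k * x for x in I],
                            assign_sigmas([k * x for x in I], ratio))
    assert scaled.overlapping_pairs == rpt.overlapping_pairs
    assert scaled.intensities_involved == rpt.intensities_involved


# ---------------------------------------------------------------------------
# Overlap experiment and ratio recommendation
# ---------------------------------------------------------------------------

def test_simulate_overlap_experiment_deterministic(taurine_cell, p21c):
    kw = dict(shell=(0.490, 0.500), ratio=20.0, replicates=10,
              sampler="exact", seed=5)
    a = simulate_overlap_experiment(TAURINE_COMP, 1.53, taurine_cell, p21c,
                                    **kw)
    b = simulate_overlap_experiment(TAURINE_COMP, 1.53, taurine_cell, p21c,
                                    **kw)
    assert a.n == 28
    np.testing.assert_array_equal(a.pair_counts, b.pair_counts)
    np.testing.assert_array_equal(a.reports[0].intensities,
                                  b.reports[0].intensities)


def test_huge_ratio_eliminates_overlaps(taurine_cell, p21c):
    sim = simulate_overlap_experiment(
        TAURINE_COMP, 1.53, taurine_cell, p21c, (0.490, 0.500),
        ratio=1e9, replicates=20, sampler="exact", seed=1)
    assert sim.pair_counts.sum() == 0
    assert sim.involved_counts.sum() == 0


def test_empty_shell_errors(taurine_cell, p21c):
    with pytest.raises(ValueError, match="no reflections"):
        simulate_overlap_experiment(TAURINE_COMP, 1.53, taurine_cell, p21c,
                                    (0.0001, 0.0002), 20.0, seed=0)


def test_recommend_ratio_contract(taurine_cell, p21c):
    kw = dict(shell=(0.490, 0.500), replicates=50, sampler="exact", seed=3)
    # permissive target: smallest candidate wins
    assert recommend_ratio(TAURINE_COMP, 1.53, taurine_cell, p21c,
                           target_involved=28, ratios=[10, 20, 65],
                           **kw) == 10
    # achievable only by the largest candidate
    big = recommend_ratio(TAURINE_COMP, 1.53, taurine_cell, p21c,
                          target_involved=0.5, ratios=[10, 1e6], **kw)
    assert big == 1e6
    with pytest.raises(ValueError, match="best mean"):
        recommend_ratio(TAURINE_COMP, 1.53, taurine_cell, p21c,
                        target_involved=0.0, ratios=[1.0, 2.0], **kw)
    with pytest.raises(ValueError, match="ascending"):
        recommend_ratio(TAURINE_COMP, 1.53, taurine_cell, p21c,
                        target_involved=5, ratios=[20, 10], **kw)
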