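"""Disproportionality engines against independent from-definition oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from faersig.dispro import (
    DEFAULT_MGPS_PRIOR,
    MGPSHyperparams,
    ScreeningCriteria,
    Z_95,
    bcpnn_ic,
    compare_methods,
    ebgm_estimate,
    fit_mgps_prior,
    mgps_marginal_loglik,
    prr_estimate,
    ror_estimate,
    screen_signals,
)


def random_tables(n, seed, a_min=0):
    rng = np.random.default_rng(seed)
    a = rng.integers(a_min, 200, n)
    b = rng.integers(1, 5000, n)
    c = rng.integers(1, 5000, n)
    d = rng.integers(1000, 200_000, n)
    return a, b, c, d


# ---------------------------------------------------------------------------
# ROR / PRR
# ---------------------------------------------------------------------------

def test_ror_and_prr_hand_examples():
    ror, lo, hi = ror_estimate(10, 90, 100, 9900)
    assert ror == pytest.approx(11.0)
    assert lo < ror < hi
    prr, _ = prr_estimate(10, 90, 100, 9900)
    assert prr == pytest.approx(10.0)


def test_homogeneous_table_is_null():
    ror, lo, hi = ror_estimate(25, 25, 25, 25)
    assert ror == pytest.approx(1.0)
    assert lo < 1.0 < hi
    assert lo == pytest.approx(math.exp(-Z_95 * math.sqrt(4 / 25)))
    prr, chi2 = prr_estimate(25, 25, 25, 25)
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)


def test_ror_prr_match_from_definition_on_random_tables():
    a, b, c, d = random_tables(50, seed=5, a_min=1)
    ror, lo, hi = ror_estimate(a, b, c, d)
    prr, chi2 = prr_estimate(a, b, c, d)
    for i in range(50):
        ai, bi, ci, di = (float(x[i]) for x in (a, b, c, d))
        ror_def = (ai * di) / (bi * ci)
        se = math.sqrt(1 / ai + 1 / bi + 1 / ci + 1 / di)
        assert ror[i] == pytest.approx(ror_def, rel=1e-10)
        assert lo[i] == pytest.approx(ror_def * math.exp(-Z_95 * se), rel=1e-10)
        assert hi[i] == pytest.approx(ror_def * math.exp(Z_95 * se), rel=1e-10)
        prr_def = (ai / (ai + bi)) / (ci / (ci + di))
        assert prr[i] == pytest.approx(prr_def, rel=1e-10)
        # independent chi-square route
        chi2_ref = stats.chi2_contingency(
            [[ai, bi], [ci, di]], correction=True
        ).statistic
        assert chi2[i] == pytest.approx(chi2_ref, rel=1e-9)


def test_zero_cell_haldane_correction():
    ror, lo, hi = ror_estimate(5, 0, 10, 1000)
    assert np.isfinite([ror, lo, hi]).all()
    assert ror == pytest.approx((5.5 * 1000.5) / (0.5 * 10.5))
    # correction applies only when a cell is zero
    ror2, _, _ = ror_estimate(5, 1, 10, 1000)
    assert ror2 == pytest.approx((5 * 1000) / (1 * 10))


def test_ror_interval_matches_parametric_bootstrap():
    """Wald 2.5% bound vs a multinomial parametric bootstrap (1e5 draws)."""
    rng = np.random.default_rng(2024)
    n = 100
    draws = rng.multinomial(n, [0.25] * 4, size=100_000).astype(float)
    zero = (draws == 0).any(axis=1)
    draws[zero] += 0.5
    rors = (draws[:, 0] * draws[:, 3]) / (draws[:, 1] * draws[:, 2])
    boot_lo = np.quantile(rors, 0.025)
    _, lo, _ = ror_estimate(25, 25, 25, 25)
    assert lo == pytest.approx(boot_lo, rel=0.1)


@settings(max_examples=200, derandomize=True)
@given(
    a=st.integers(1, 500),
    b=st.integers(1, 5000),
    c=st.integers(1, 5000),
    d=st.integers(1, 100_000),
)
def test_sign_equivalence_ror_prr(a, b, c, d):
    """ror > 1 iff prr > 1 iff ad > bc, for all-positive cells."""
    ror, _, _ = ror_estimate(a, b, c, d)
    prr, _ = prr_estimate(a, b, c, d)
    assert (ror > 1) == (a * d > b * c)
    assert (prr > 1) == (a * d > b * c)


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def test_ic_zero_when_observed_equals_expected():
    ic, _ = bcpnn_ic(1000, 1000.0)
    assert ic == pytest.approx(0.0, abs=1e-12)


def test_ic_negative_for_zero_count():
    ic, ic_lo = bcpnn_ic(0, 10.0)
    assert ic == pytest.approx(math.log2(0.5 / 10.5))
    assert ic_lo < ic < 0


def test_gamma_quantile_matches_monte_carlo():
    # the credible bound is a Gamma(a + 0.5, rate 1) quantile on the log2
    # ratio scale: check against simulation
    a, e = 12, 4.0
    rng = np.random.default_rng(7)
    sims = np.log2(rng.gamma(a + 0.5, 1.0, size=400_000) / (e + 0.5))
    _, ic_lo = bcpnn_ic(a, e)
    assert ic_lo == pytest.approx(np.quantile(sims, 0.025), abs=0.01)


def test_closed_form_ic025_close_to_gamma_quantile_for_a_ge_10():
    rng = np.random.default_rng(11)
    a = rng.integers(10, 2000, 1000)
    e = rng.uniform(0.5, 500.0, 1000)
    _, lo_gamma = bcpnn_ic(a, e, variant="gamma")
    _, lo_approx = bcpnn_ic(a, e, variant="approx")
    assert np.max(np.abs(lo_gamma - lo_approx)) <= 0.1


def test_unknown_variant_errors():
    with pytest.raises(ValueError):
        bcpnn_ic(1, 1.0, variant="dirichlet")


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

def simulate_pairs(h: MGPSHyperparams, n, seed):
    rng = np.random.default_rng(seed)
    e = rng.lognormal(0.5, 1.0, n) + 0.05
    comp = rng.random(n) < h.p_mix
    lam = np.where(
        comp,
        rng.gamma(h.alpha1, 1.0 / h.beta1, n),
        rng.gamma(h.alpha2, 1.0 / h.beta2, n),
    )
    a = rng.poisson(lam * e)
    return a, e


def test_fit_improves_on_starting_point():
    truth = MGPSHyperparams(0.5, 0.5, 3.0, 3.0, 0.5)
    a, e = simulate_pairs(truth, 3000, seed=3)
    start = DEFAULT_MGPS_PRIOR
    fitted = fit_mgps_prior(a, e, start=start)
    assert fitted.loglik >= mgps_marginal_loglik(a, e, start)


def test_single_component_data_hits_boundary_without_crashing():
    rng = np.random.default_rng(9)
    e = rng.uniform(1, 20, 2000)
    a = rng.poisson(2.0 * e)  # pure Gamma-free point mass-ish single regime
    fitted = fit_mgps_prior(a, e)
    assert fitted.loglik is not None and np.isfinite(fitted.loglik)


def test_ebgm_degenerate_prior_matches_quadrature():
    """Single-gamma prior: EBGM and EB05 vs numerical integration."""
    h = MGPSHyperparams(2.0, 4.0, 2.0, 4.0, 0.5)  # both components equal
    a, e = 50, 10.0
    ebgm, lo = ebgm_estimate(a, e, h)
    shape, rate = h.alpha1 + a, h.beta1 + e
    # closed form through the digamma function
    assert ebgm == pytest.approx(math.exp(special.digamma(shape) - math.log(rate)), rel=1e-10)
    # quadrature oracle for the posterior mean log
    dens = lambda x: stats.gamma.pdf(x, shape, scale=1 / rate)
    mean_log, _ = integrate.quad(lambda x: math.log(x) * dens(x), 0, 50)
    assert ebgm == pytest.approx(math.exp(mean_log), rel=1e-6)
    assert lo == pytest.approx(stats.gamma.ppf(0.05, shape, scale=1 / rate), abs=1e-5)


def test_eb05_matches_grid_inversion_of_mixture_cdf():
    rng = np.random.default_rng(13)
    a = rng.integers(0, 300, 100)
    e = rng.uniform(0.2, 100.0, 100)
    h = DEFAULT_MGPS_PRIOR
    _, lo = ebgm_estimate(a, e, h)
    from faersig.dispro import _posterior_mixture

    q, (s1, r1), (s2, r2) = _posterior_mixture(a, e, h)
    for i in range(100):
        grid = np.linspace(max(lo[i] - 0.5, 1e-9), lo[i] + 0.5, 20001)
        cdf = q[i] * stats.gamma.cdf(grid, s1[i], scale=1 / r1[i]) + (
            1 - q[i]
        ) * stats.gamma.cdf(grid, s2[i], scale=1 / r2[i])
        grid_lo = grid[np.searchsorted(cdf, 0.05)]
        assert abs(lo[i] - grid_lo) <= 1e-4 + (grid[1] - grid[0])


def test_shrinkage_vanishes_for_large_counts():
    ebgm, _ = ebgm_estimate(50_000, 10_000.0, DEFAULT_MGPS_PRIOR)
    assert ebgm == pytest.approx(5.0, rel=0.01)


def test_eb05_below_ebgm_and_shrinkage_toward_one():
    rng = np.random.default_rng(17)
    a = rng.integers(1, 200, 200)
    e = rng.uniform(0.5, 50.0, 200)
    ebgm, lo = ebgm_estimate(a, e, DEFAULT_MGPS_PRIOR)
    assert (lo < ebgm).all()
    ratio = a / e
    high = ratio > 1
    assert (ebgm[high] < ratio[high]).all()
    assert (ebgm[high] > 1.0 - 1e-9).any()  # shrunk but not collapsed


def test_monotonic_in_a_with_other_cells_fixed():
    b, c, d = 500.0, 400.0, 100_000.0
    a = np.arange(1, 60)
    e = (a + b) * (a + c) / (a + b + c + d)
    ror, _, _ = ror_estimate(a, np.full_like(a, b), np.full_like(a, c), np.full_like(a, d))
    ic, _ = bcpnn_ic(a, e)
    ebgm, _ = ebgm_estimate(a.astype(float), e, DEFAULT_MGPS_PRIOR)
    assert (np.diff(ror) > 0).all()
    assert (np.diff(ic) > 0).all()
    assert (np.diff(ebgm) > 0).all()


# ---------------------------------------------------------------------------
# screening and method comparison
# ---------------------------------------------------------------------------

def _results_frame(rows):
    base = {
        "drug": "d",
        "term": "t",
        "level": "PT",
        "a": 10,
        "ror": 2.0,
        "ror_lo": 1.5,
        "ror_hi": 3.0,
        "prr": 2.0,
        "chi2": 5.0,
        "ic": 1.0,
        "ic_lo": 0.5,
        "ebgm": 2.0,
        "ebgm_lo": 1.0,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


@pytest.mark.parametrize(
    "row,expected_band",
    [
        ({"ic_lo": 3.2}, "strong"),
        ({"ic_lo": 3.0}, "moderate"),  # closed upper bound of the moderate band
        ({"ic_lo": 1.5}, "weak"),  # closed upper bound of the weak band
        ({"ic_lo": 1.5000001}, "moderate"),
        ({"ic_lo": 0.0}, "negative"),  # positivity requires ic_lo > 0
        ({"ic_lo": 5.0, "a": 2}, "negative"),  # below the 3-report minimum
    ],
)
def test_band_boundaries(row, expected_band):
    out = screen_signals(_results_frame([row]))
    assert out["band"].iloc[0] == expected_band


def test_screening_thresholds_at_boundaries():
    rows = [
        {"a": 2, "ror_lo": 50.0, "ic_lo": 5.0, "ebgm_lo": 50.0, "chi2": 100.0, "prr": 9.0},
        {"a": 3, "ror_lo": 1.0},  # ROR requires strictly > 1
        {"a": 3, "ror_lo": 1.0001},
        {"a": 3, "ebgm_lo": 2.0},  # MGPS requires strictly > 2
        {"a": 3, "ebgm_lo": 2.0001},
        {"a": 3, "prr": 2.0, "chi2": 4.0},  # MHRA thresholds are inclusive
        {"a": 3, "prr": 1.9999, "chi2": 4.0},
    ]
    out = screen_signals(_results_frame(rows))
    assert not out.loc[0, ["ror_pos", "mhra_pos", "bcpnn_pos", "mgps_pos"]].any()
    assert not out.loc[1, "ror_pos"] and out.loc[2, "ror_pos"]
    assert not out.loc[3, "mgps_pos"] and out.loc[4, "mgps_pos"]
    assert out.loc[5, "mhra_pos"] and not out.loc[6, "mhra_pos"]


def test_compare_methods_counts_and_empty():
    rows = [
        {"drug": "x", "ror_lo": 2.0, "ic_lo": 1.0, "ebgm_lo": 3.0, "prr": 3.0, "chi2": 10.0},
        {"drug": "y", "ror_lo": 2.0, "ic_lo": 1.0, "ebgm_lo": 3.0, "prr": 3.0, "chi2": 10.0},
    ]
    out = compare_methods(screen_signals(_results_frame(rows)))
    assert (out["counts"].loc["ROR"] == 1).all()
    assert out["counts"].values.sum() == 8  # every method positive everywhere
    assert out["overlap"].loc["ROR", "MGPS"] == 2
    empty = compare_methods(_results_frame([]).assign(
        eligible=False, ror_pos=False, mhra_pos=False, bcpnn_pos=False, mgps_pos=False
    ))
    assert empty["counts"].values.sum() == 0
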