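"""Disproportionality engines: ROR, PRR/MHRA, BCPNN information component,
and the multi-item gamma-Poisson shrinker (MGPS / EBGM).

All engines consume the a/b/c/d counts of a 2x2 report-level contingency
table (see :mod:`faersig.contingency`).  Positive-signal screening follows
the conventional criteria: at least three target reports for any method,
ROR025 > 1, IC025 > 0, EBGM05 > 2, and PRR >= 2 with chi-square >= 4 for the
MHRA rule.  Signal intensity bands are derived from IC025:
0 < IC025 <= 1.5 weak (+), 1.5 < IC025 <= 3.0 moderate (++), > 3.0 strong
(+++), with the upper bound closed on each band.

The BCPNN variant implemented here is the gamma-posterior ("shrunk
observed count") formulation: IC = log2((a + 0.5)/(E + 0.5)) with the 2.5%
credible bound taken from the Gamma(a + 0.5, rate 1) posterior of the shrunk
count; the widely used closed-form approximation is available behind
``variant="approx"``.

MGPS places a two-component gamma mixture prior on the relative reporting
rate lambda (a ~ Poisson(lambda * E)); the hyperparameters are fitted by
maximising the marginal likelihood, under which each count is a mixture of
negative binomials.  EBGM is the posterior geometric mean 2^{E[log2 lambda]}
and EBGM05 the 5th posterior percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "Z_95",
    "MGPSHyperparams",
    "DEFAULT_MGPS_PRIOR",
    "ScreeningCriteria",
    "ror_estimate",
    "prr_estimate",
    "bcpnn_ic",
    "fit_mgps_prior",
    "ebgm_estimate",
    "score_tables",
    "screen_signals",
    "compare_methods",
]

#: two-sided 95% normal quantile used for the ROR confidence interval
Z_95 = 1.959964


# ---------------------------------------------------------------------------
# frequentist engines
# ---------------------------------------------------------------------------

def _asarray(*xs):
    return [np.asarray(x, dtype=float) for x in xs]


def ror_estimate(a, b, c, d, z: float = Z_95):
    """Reporting odds ratio with Wald 95% CI on the log scale.

    ROR = ad/bc; CI = exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    When any cell is zero the Haldane–Anscombe correction adds 0.5 to all
    four cells of that table (only then).  Returns (ror, ror_lo, ror_hi).
    """
    a, b, c, d = _asarray(a, b, c, d)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    corr = np.where(zero, 0.5, 0.0)
    a_, b_, c_, d_ = a + corr, b + corr, c + corr, d + corr
    ror = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
    lo = np.exp(np.log(ror) - z * se)
    hi = np.exp(np.log(ror) + z * se)
    return ror, lo, hi


def prr_estimate(a, b, c, d):
    """Proportional reporting ratio and Yates-corrected chi-square.

    PRR = (a/(a+b)) / (c/(c+d)) on the uncorrected counts; c = 0 yields +inf.
    The chi-square is the Yates-corrected Pearson statistic of the 2x2 table:
    chi2 = n (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d)), clamped at 0 when
    the continuity correction exceeds |ad - bc|.
    """
    a, b, c, d = _asarray(a, b, c, d)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / (a + b)) / np.where(c + d > 0, c / (c + d), np.nan)
        prr = np.where((c == 0) & (a > 0), np.inf, prr)
        diff = np.abs(a * d - b * c) - n / 2.0
        diff = np.maximum(diff, 0.0)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(denom > 0, n * diff**2 / np.where(denom > 0, denom, 1.0), 0.0)
    return prr, chi2


def bcpnn_ic(a, e, alpha: float = 0.05, variant: str = "gamma"):
    """Information component and its lower credible bound.

    ``gamma`` (default): IC = log2((a+0.5)/(E+0.5)); IC025 = log2(q/(E+0.5))
    with q the alpha/2 quantile of Gamma(shape=a+0.5, rate=1) — the posterior
    of the shrunk observed count whose mean is a+0.5.

    ``approx``: the closed-form IC025 ≈ IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2).
    """
    a, e = _asarray(a, e)
    shrunk = a + 0.5
    ic = np.log2(shrunk / (e + 0.5))
    if variant == "gamma":
        q = stats.gamma.ppf(alpha / 2.0, shrunk)  # rate 1 -> mean a+0.5
        ic_lo = np.log2(q / (e + 0.5))
    elif variant == "approx":
        ic_lo = ic - 3.3 * shrunk ** (-0.5) - 2.0 * shrunk ** (-1.5)
    else:
        raise ValueError(f"unknown BCPNN variant {variant!r}")
    return ic, ic_lo


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

@dataclass
class MGPSHyperparams:
    """Two-component gamma mixture prior on the relative reporting rate.

    lambda ~ p_mix * Gamma(alpha1, rate beta1) + (1 - p_mix) * Gamma(alpha2,
    rate beta2).  The conventional starting point (0.2, 0.1, 2.0, 4.0, 1/3)
    mixes a diffuse component with one concentrated below 1.
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    p_mix: float = 1.0 / 3.0
    converged: bool | None = None
    at_boundary: bool = False
    loglik: float | None = None

    def __post_init__(self):
        vals = (self.alpha1, self.beta1, self.alpha2, self.beta2, self.p_mix)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all MGPS hyperparameters must be finite and positive")
        if not self.p_mix < 1:
            raise ValueError("p_mix must be in (0, 1)")


DEFAULT_MGPS_PRIOR = MGPSHyperparams()


def _nb_logpmf(a, alpha, beta, e):
    # marginal of a ~ Poisson(lambda e), lambda ~ Gamma(alpha, rate beta):
    # negative binomial with size alpha and success prob beta/(beta+e)
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def mgps_marginal_loglik(a, e, h: MGPSHyperparams) -> float:
    """Summed log marginal likelihood of (a, E) pairs under the mixture prior."""
    a, e = _asarray(a, e)
    l1 = _nb_logpmf(a, h.alpha1, h.beta1, e) + np.log(h.p_mix)
    l2 = _nb_logpmf(a, h.alpha2, h.beta2, e) + np.log1p(-h.p_mix)
    return float(np.sum(special.logsumexp(np.stack([l1, l2]), axis=0)))


def fit_mgps_prior(
    a,
    e,
    start: MGPSHyperparams | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MGPSHyperparams:
    """Fit the mixture prior by maximum marginal likelihood.

    Optimised with L-BFGS-B over log-transformed shape/rate parameters and a
    logit-transformed mixture weight, starting from the conventional
    defaults.  The returned object records convergence, whether the mixture
    weight ended at a boundary (single-component data), and the final
    log-likelihood; non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("a and e must be 1-D arrays of equal length")
    h0 = start or DEFAULT_MGPS_PRIOR
    x0 = np.array(
        [
            np.log(h0.alpha1),
            np.log(h0.beta1),
            np.log(h0.alpha2),
            np.log(h0.beta2),
            special.logit(h0.p_mix),
        ]
    )

    def unpack(x):
        return MGPSHyperparams(
            alpha1=float(np.exp(x[0])),
            beta1=float(np.exp(x[1])),
            alpha2=float(np.exp(x[2])),
            beta2=float(np.exp(x[3])),
            p_mix=float(special.expit(np.clip(x[4], -30, 30))),
        )

    def nll(x):
        try:
            return -mgps_marginal_loglik(a, e, unpack(x))
        except (ValueError, FloatingPointError):
            return np.inf

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
        bounds=[(-20, 20)] * 4 + [(-30, 30)],
    )
    best = res.x if res.fun <= nll(x0) else x0
    h = unpack(best)
    h.converged = bool(res.success)
    h.at_boundary = bool(abs(best[4]) >= 29.5)
    h.loglik = -float(nll(best))
    if not h.converged:
        warnings.warn("MGPS prior fit did not converge; returning best iterate")
    return h


def _posterior_mixture(a, e, h: MGPSHyperparams):
    """Posterior component weights and gamma parameters for each (a, E)."""
    a, e = _asarray(a, e)
    l1 = _nb_logpmf(a, h.alpha1, h.beta1, e) + np.log(h.p_mix)
    l2 = _nb_logpmf(a, h.alpha2, h.beta2, e) + np.log1p(-h.p_mix)
    q = np.exp(l1 - special.logsumexp(np.stack([l1, l2]), axis=0))
    return q, (h.alpha1 + a, h.beta1 + e), (h.alpha2 + a, h.beta2 + e)


def ebgm_estimate(a, e, h: MGPSHyperparams = DEFAULT_MGPS_PRIOR, q_level: float = 0.05):
    """Empirical-Bayes geometric mean and 5th posterior percentile.

    The posterior of lambda is Q * Gamma(alpha1+a, beta1+E) + (1-Q) *
    Gamma(alpha2+a, beta2+E) with Q the posterior component weight.
    EBGM = 2^{E[log2 lambda]} evaluated through the digamma function;
    EBGM05 solves the mixture CDF = ``q_level`` by monotone root-finding to
    absolute tolerance 1e-6.
    """
    a, e = _asarray(a, e)
    scalar = a.ndim == 0
    a, e = np.atleast_1d(a), np.atleast_1d(e)
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")
    q, (s1, r1), (s2, r2) = _posterior_mixture(a, e, h)
    mean_log = q * (special.digamma(s1) - np.log(r1)) + (1 - q) * (
        special.digamma(s2) - np.log(r2)
    )
    ebgm = np.exp(mean_log)

    lo = np.empty_like(ebgm)
    for i in range(len(ebgm)):
        cdf = lambda x: (
            q[i] * stats.gamma.cdf(x, s1[i], scale=1.0 / r1[i])
            + (1 - q[i]) * stats.gamma.cdf(x, s2[i], scale=1.0 / r2[i])
        ) - q_level
        lo_b = min(
            stats.gamma.ppf(q_level / 2, s1[i], scale=1.0 / r1[i]),
            stats.gamma.ppf(q_level / 2, s2[i], scale=1.0 / r2[i]),
        )
        hi_b = max(
            stats.gamma.ppf(q_level, s1[i], scale=1.0 / r1[i]),
            stats.gamma.ppf(q_level, s2[i], scale=1.0 / r2[i]),
        )
        lo_b = max(lo_b, 1e-12)
        lo[i] = optimize.brentq(cdf, lo_b * 0.5, hi_b * 2.0 + 1e-9, xtol=1e-6)
    if scalar:
        return float(ebgm[0]), float(lo[0])
    return ebgm, lo


# ---------------------------------------------------------------------------
# scoring, screening, method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningCriteria:
    """Positive-signal thresholds; the defaults are the conventional ones."""

    min_reports: int = 3
    ror_lo_gt: float = 1.0
    ic_lo_gt: float = 0.0
    ebgm_lo_gt: float = 2.0
    mhra_prr_ge: float = 2.0
    mhra_chi2_ge: float = 4.0
    band_weak_le: float = 1.5
    band_moderate_le: float = 3.0


def score_tables(
    tables: pd.DataFrame,
    prior: MGPSHyperparams | None = None,
    fit_prior: bool = False,
    bcpnn_variant: str = "gamma",
) -> pd.DataFrame:
    """Run every engine over a long-format contingency table frame.

    ``tables`` needs columns drug, level, term, a, b, c, d, n, e (as produced
    by :func:`faersig.contingency.build_tables`).  With ``fit_prior=True``
    the MGPS prior is fitted to this frame's (a, e) pairs; otherwise
    ``prior`` (default: the conventional starting values) is used as-is.
    Returns the frame with ror/prr/ic/ebgm estimate and bound columns added.
    """
    out = tables.copy()
    a, b, c, d = (out[k].to_numpy(float) for k in "abcd")
    e = out["e"].to_numpy(float)
    if fit_prior and len(out) >= 100:
        # below ~100 (a, e) pairs the marginal likelihood is too flat to
        # support a five-parameter fit; fall back to the conventional prior
        prior = fit_mgps_prior(a, e, start=prior)
    if prior is None:
        prior = DEFAULT_MGPS_PRIOR
    out["ror"], out["ror_lo"], out["ror_hi"] = ror_estimate(a, b, c, d)
    out["prr"], out["chi2"] = prr_estimate(a, b, c, d)
    out["ic"], out["ic_lo"] = bcpnn_ic(a, e, variant=bcpnn_variant)
    out["ebgm"], out["ebgm_lo"] = ebgm_estimate(a, e, prior)
    out.attrs["mgps_prior"] = prior
    return out


def screen_signals(
    results: pd.DataFrame, criteria: ScreeningCriteria = ScreeningCriteria()
) -> pd.DataFrame:
    """Apply the positive-signal rules and the IC025 intensity bands.

    Adds ``eligible`` (a >= min_reports) and boolean flags ``ror_pos``,
    ``mhra_pos``, ``bcpnn_pos``, ``mgps_pos`` (all False when ineligible),
    plus ``band`` in {negative, weak, moderate, strong} driven by IC025 for
    BCPNN-positive rows.
    """
    out = results.copy()
    a = out["a"].to_numpy(float)
    eligible = a >= criteria.min_reports
    out["eligible"] = eligible
    out["ror_pos"] = eligible & (out["ror_lo"].to_numpy(float) > criteria.ror_lo_gt)
    out["mhra_pos"] = (
        eligible
        & (out["prr"].to_numpy(float) >= criteria.mhra_prr_ge)
        & (out["chi2"].to_numpy(float) >= criteria.mhra_chi2_ge)
    )
    out["bcpnn_pos"] = eligible & (out["ic_lo"].to_numpy(float) > criteria.ic_lo_gt)
    out["mgps_pos"] = eligible & (out["ebgm_lo"].to_numpy(float) > criteria.ebgm_lo_gt)

    ic_lo = out["ic_lo"].to_numpy(float)
    band = np.full(len(out), "negative", dtype=object)
    pos = out["bcpnn_pos"].to_numpy(bool)
    band[pos & (ic_lo <= criteria.band_weak_le)] = "weak"
    band[pos & (ic_lo > criteria.band_weak_le) & (ic_lo <= criteria.band_moderate_le)] = (
        "moderate"
    )
    band[pos & (ic_lo > criteria.band_moderate_le)] = "strong"
    out["band"] = band
    return out


METHOD_FLAGS = {"ROR": "ror_pos", "MHRA": "mhra_pos", "BCPNN": "bcpnn_pos", "MGPS": "mgps_pos"}


def compare_methods(results: pd.DataFrame) -> dict:
    """Per-drug positive counts per method, plus pairwise overlap counts.

    Returns ``{"counts": DataFrame (method x drug), "overlap": DataFrame
    (method x method, number of (drug, term) pairs positive under both)}``.
    An empty input yields zero matrices.
    """
    methods = list(METHOD_FLAGS)
    drugs = sorted(results["drug"].unique()) if len(results) else []
    counts = pd.DataFrame(0, index=methods, columns=drugs, dtype=int)
    overlap = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    if len(results):
        for m, col in METHOD_FLAGS.items():
            sub = results[results[col].astype(bool)]
            per_drug = sub.groupby("drug").size()
            for drg, k in per_drug.items():
                counts.loc[m, drg] = int(k)
        for m1, c1 in METHOD_FLAGS.items():
            for m2, c2 in METHOD_FLAGS.items():
                overlap.loc[m1, m2] = int(
                    (results[c1].astype(bool) & results[c2].astype(bool)).sum()
                )
    return {"counts": counts, "overlap": overlap}
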