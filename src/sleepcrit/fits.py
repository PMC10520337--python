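"""Power-law inference and criticality statistics.

Avalanche size and duration distributions are fitted with a *bounded*
continuous power law p(x) = C x^-gamma on [xmin, xmax] by exact maximum
likelihood (1-D numerical optimization of the truncated log-likelihood; the
Hill closed form is recovered as xmax -> infinity).  Goodness of fit is the
Kolmogorov-Smirnov distance D = sup_x |F_data - F_fit| on the fitted range;
model preference is the log-likelihood ratio R against a truncated
exponential fitted on the same support, with a Vuong-type normal
approximation for its significance.  The systematic error of an exponent is
the SD of the MLE over a grid of (xmin, xmax) fit ranges.

At criticality the three avalanche exponents — tau (size), alpha (duration)
and k (the slope of <s> ~ T^k) — obey the crackling-noise scaling relation
k = (alpha - 1) / (tau - 1); mean-field directed percolation predicts
tau = 3/2, alpha = 2, k = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerLawFit",
    "FitComparison",
    "SystematicErrorGrid",
    "ScalingFit",
    "fit_power_law_mle",
    "ks_distance",
    "compare_power_law_exponential",
    "systematic_error_grid",
    "size_duration_scaling",
    "check_scaling_relation",
    "threshold_robustness_sweep",
]

_GAMMA_MAX = 25.0


@dataclass
class PowerLawFit:
    exponent: float
    xmin: float
    xmax: float
    n_tail: int
    ks_D: float
    loglik: float

    def cdf(self, x) -> np.ndarray:
        """Fitted CDF on [xmin, xmax]."""
        x = np.asarray(x, dtype=float)
        g = 1.0 - self.exponent
        if np.isinf(self.xmax):
            return np.clip(1.0 - (x / self.xmin) ** g, 0.0, 1.0)
        return np.clip(
            (x**g - self.xmin**g) / (self.xmax**g - self.xmin**g), 0.0, 1.0
        )

    def logpdf(self, x) -> np.ndarray:
        return _pl_loglik_terms(np.asarray(x, dtype=float), self.exponent,
                                self.xmin, self.xmax)


@dataclass(frozen=True)
class FitComparison:
    R: float  # sum of pointwise log-likelihood differences (PL minus exp)
    p: float  # two-sided Vuong normal approximation
    lambda_exp: float
    n: int


@dataclass
class SystematicErrorGrid:
    xmin_values: np.ndarray
    xmax_values: np.ndarray
    exponent_matrix: np.ndarray  # |xmin| x |xmax|, NaN where a fit failed
    mean_exponent: float
    sd_exponent: float


@dataclass
class ScalingFit:
    k_low: float
    k_high: float
    crossover_T: float
    binned_curve: pd.DataFrame  # columns T_bin, mean_size, n


def _pl_logC(gamma: float, xmin: float, xmax: float) -> float:
    if np.isclose(gamma, 1.0):
        return -np.log(np.log(xmax / xmin))
    g = 1.0 - gamma
    if np.isinf(xmax):
        return np.log(gamma - 1.0) - g * np.log(xmin)
    return np.log((gamma - 1.0) / (xmin**g - xmax**g))


def _pl_loglik_terms(x, gamma, xmin, xmax):
    return _pl_logC(gamma, xmin, xmax) - gamma * np.log(x)


def fit_power_law_mle(
    sample: np.ndarray, xmin: float, xmax: float = np.inf
) -> PowerLawFit:
    """MLE of a bounded continuous power law on [xmin, xmax].

    Samples outside the range are excluded; at least 10 must remain.  With
    xmax = inf the estimate equals the Hill closed form
    1 + n / sum(log(x_i / xmin)).
    """
    if xmax <= xmin:
        raise ValueError("xmax must exceed xmin")
    x = np.asarray(sample, dtype=float)
    tail = x[(x >= xmin) & (x <= xmax)]
    n = tail.size
    if n < 10:
        raise ValueError(f"only {n} samples in [{xmin}, {xmax}]; need >= 10")
    slog = float(np.log(tail).sum())
    if np.isinf(xmax):
        gamma = 1.0 + n / (slog - n * np.log(xmin))
    else:
        def nll(g):
            return -(n * _pl_logC(g, xmin, xmax) - g * slog)

        res = optimize.minimize_scalar(
            nll, bounds=(1.0 + 1e-9, _GAMMA_MAX), method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = float(res.x)
    ll = n * _pl_logC(gamma, xmin, xmax) - gamma * slog
    fit = PowerLawFit(gamma, xmin, xmax, n, np.nan, float(ll))
    fit.ks_D = ks_distance(tail, fit)
    return fit


def ks_distance(sample: np.ndarray, fit: PowerLawFit) -> float:
    """sup_x |F_data(x) - F_fit(x)| over [xmin, xmax], evaluated at the
    empirical jump points with both left and right limits."""
    x = np.sort(np.asarray(sample, dtype=float))
    x = x[(x >= fit.xmin) & (x <= fit.xmax)]
    n = x.size
    if n == 0:
        raise ValueError("no samples in the fitted range")
    F = fit.cdf(x)
    upper = np.arange(1, n + 1) / n
    lower = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(upper - F), np.abs(F - lower))))


def _fit_truncated_exponential(x: np.ndarray, a: float, b: float) -> float:
    """MLE rate of p(x) ~ exp(-lam*x) on [a, b]; lam may be negative."""
    y = x - a
    L = b - a
    ybar = float(y.mean())
    if not 0 < ybar < L:
        raise ValueError("degenerate sample for exponential fit")

    def mean_resid(lam):
        if abs(lam) < 1e-12:
            return L / 2 - ybar
        # E[y] = 1/lam - L / (exp(lam*L) - 1)
        return 1.0 / lam - L / np.expm1(lam * L) - ybar

    hi = 1.0 / max(ybar, 1e-300) + 1.0 / L
    lo = -hi
    while mean_resid(hi) > 0:
        hi *= 2
    while mean_resid(lo) < 0:
        lo *= 2
    return float(optimize.brentq(mean_resid, lo, hi, xtol=1e-14, rtol=1e-12))


def _exp_loglik_terms(x, lam, a, b):
    if abs(lam) < 1e-12:
        return np.full_like(x, -np.log(b - a))
    # log C = log(lam) - log(1 - exp(-lam*(b-a))) , valid for either sign
    logC = np.log(abs(lam)) - np.log(abs(-np.expm1(-lam * (b - a))))
    return logC - lam * (x - a)


def compare_power_law_exponential(
    sample: np.ndarray, xmin: float, xmax: float
) -> FitComparison:
    """Log-likelihood ratio R of the truncated power law against a truncated
    exponential fitted on the same support.

    R > 0 favors the power law.  The two-sided p value uses the Vuong
    normal approximation R / (sd(d_i) * sqrt(n)) ~ N(0, 1), where d_i are the
    pointwise log-likelihood differences.
    """
    x = np.asarray(sample, dtype=float)
    x = x[(x >= xmin) & (x <= xmax)]
    if x.size < 10:
        raise ValueError("too few samples in range")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values equal")
    pl = fit_power_law_mle(x, xmin, xmax)
    lam = _fit_truncated_exponential(x, xmin, xmax)
    d = pl.logpdf(x) - _exp_loglik_terms(x, lam, xmin, xmax)
    R = float(d.sum())
    sd = float(d.std())
    if sd == 0:
        raise ValueError("identical likelihoods; comparison undefined")
    z = R / (sd * np.sqrt(x.size))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return FitComparison(R, p, lam, int(x.size))


def systematic_error_grid(
    sample: np.ndarray,
    xmin_list: Sequence[float],
    xmax_low: float,
    xmax_high: float,
    n_xmax: int = 10,
    seed: int = 0,
) -> SystematicErrorGrid:
    """Fit every (xmin, xmax) combination with xmax values uniformly sampled
    in [xmax_low, xmax_high]; the SD of the exponents is the systematic
    error.  Failing cells are recorded as NaN with a warning."""
    rng = np.random.default_rng(seed)
    xmaxs = np.sort(rng.uniform(xmax_low, xmax_high, n_xmax))
    xmins = np.asarray(list(xmin_list), dtype=float)
    mat = np.full((xmins.size, xmaxs.size), np.nan)
    for i, a in enumerate(xmins):
        for j, b in enumerate(xmaxs):
            try:
                mat[i, j] = fit_power_law_mle(sample, a, b).exponent
            except ValueError as e:
                warnings.warn(f"grid cell (xmin={a}, xmax={b:.3g}) failed: {e}")
    vals = mat[np.isfinite(mat)]
    return SystematicErrorGrid(
        xmins, xmaxs, mat, float(vals.mean()), float(vals.std())
    )


def size_duration_scaling(
    durations: np.ndarray,
    sizes: np.ndarray,
    n_bins: int = 40,
    regime_split_T: float = 0.4,
    t_range: Optional[tuple] = None,
) -> ScalingFit:
    """<s>(T) ~ T^k with a two-regime fit.

    Durations are log-binned over ``t_range`` (default: observed range); the
    arithmetic mean size per bin is regressed (least squares, log-log)
    separately below and above ``regime_split_T``.  A regime with fewer than
    3 populated bins yields NaN for its exponent.
    """
    T = np.asarray(durations, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if T.size == 0:
        raise ValueError("empty catalog")
    lo, hi = t_range if t_range is not None else (T.min(), T.max())
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    which = np.digitize(T, edges) - 1
    ok = (which >= 0) & (which < n_bins)
    mean_size = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = ok & (which == b)
        counts[b] = sel.sum()
        if counts[b]:
            mean_size[b] = s[sel].mean()
    centers = np.sqrt(edges[:-1] * edges[1:])
    curve = pd.DataFrame({"T_bin": centers, "mean_size": mean_size, "n": counts})

    def slope(sel):
        sel = sel & np.isfinite(mean_size)
        if sel.sum() < 3:
            return np.nan
        return float(
            np.polyfit(np.log(centers[sel]), np.log(mean_size[sel]), 1)[0]
        )

    k_low = slope(centers <= regime_split_T)
    k_high = slope(centers > regime_split_T)
    return ScalingFit(k_low, k_high, regime_split_T, curve)


def check_scaling_relation(
    tau: float,
    alpha: float,
    k: float,
    tau_err: float = 0.0,
    alpha_err: float = 0.0,
    k_err: float = 0.0,
) -> dict:
    """Crackling-noise consistency check k = (alpha - 1) / (tau - 1).

    Uncertainty on the prediction is propagated to first order (delta
    method); the relation is 'consistent' when |k - predicted| is within the
    combined (quadrature) uncertainty.
    """
    if tau <= 1.0:
        raise ValueError("tau must exceed 1")
    predicted = (alpha - 1.0) / (tau - 1.0)
    pred_err = np.hypot(
        alpha_err / (tau - 1.0), (alpha - 1.0) / (tau - 1.0) ** 2 * tau_err
    )
    combined = float(np.hypot(pred_err, k_err))
    return {
        "predicted_k": float(predicted),
        "predicted_k_err": float(pred_err),
        "measured_k": float(k),
        "difference": float(k - predicted),
        "combined_err": combined,
        "consistent": bool(abs(k - predicted) <= combined),
    }


def threshold_robustness_sweep(
    rec,
    theta_list: Sequence[float],
    size_range: tuple = (1.0, 800.0),
    duration_range: tuple = (0.03, 1.0),
    scaling_split: float = 0.4,
    size_mode: str = "integrated",
) -> pd.DataFrame:
    """Re-run detection and all fits for each threshold theta.

    Returns one row per theta with tau, alpha, k (low regime), sigma, the
    avalanche count and total avalanche time; fit failures yield NaN.
    """
    from .detect import estimate_branching_parameter, extract_avalanches
    from .ingest import DetectionConfig, detect_excursions, zscore_normalize

    if any(t <= 0 for t in theta_list):
        raise ValueError("thresholds must be positive")
    z = rec if rec.is_zscored else zscore_normalize(rec)
    rows = []
    for theta in theta_list:
        cfg = DetectionConfig(theta=theta, size_mode=size_mode)
        raster = detect_excursions(z, cfg)
        catalog = extract_avalanches(raster, z, cfg)
        row = {
            "theta": theta,
            "n_avalanches": len(catalog),
            "total_avalanche_time": catalog.total_avalanche_time,
            "tau": np.nan,
            "alpha": np.nan,
            "k": np.nan,
            "sigma": np.nan,
        }
        try:
            row["tau"] = fit_power_law_mle(catalog.sizes, *size_range).exponent
        except ValueError:
            pass
        try:
            row["alpha"] = fit_power_law_mle(
                catalog.durations, *duration_range
            ).exponent
        except ValueError:
            pass
        try:
            row["k"] = size_duration_scaling(
                catalog.durations, catalog.sizes, regime_split_T=scaling_split
            ).k_low
        except ValueError:
            pass
        try:
            row["sigma"] = estimate_branching_parameter(catalog, raster).sigma_hat
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)
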