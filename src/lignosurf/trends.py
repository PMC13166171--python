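"""Small-sample trend and association statistics.

The study design has only four timepoints (days 0, 3, 6, 9), which rules
out asymptotic trend tests: the Mann–Kendall statistic is therefore tested
against its exact permutation null, obtained by full enumeration of all n!
orderings of the observed values (ties handled naturally, since the actual
data are permuted). For n = 4 the maximum attainable |S| is 6 and a strictly
monotone series reaches one-sided p = 1/24 ≈ 0.042.

Decay trajectories are summarised by a least-squares fit of either an
exponential ``y0·exp(−rate·t)`` or a straight line ``y0 + slope·t``, with a
seeded residual bootstrap confidence interval on the rate/slope (pairwise
resampling degenerates at n = 4).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .core_io import TimeSeries
from .errors import FitError

DecayModel = Literal["exponential", "linear"]


@dataclass(frozen=True)
class MKResult:
    """Exact Mann–Kendall test result."""

    s: int
    n: int
    p_one_sided: float
    p_two_sided: float
    direction: Literal["increasing", "decreasing", "none"]


@dataclass(frozen=True)
class DecayFit:
    """Least-squares decay fit with a bootstrap CI on the rate/slope.

    For the exponential model ``rate`` is the decay constant k in
    ``y0·exp(−k·t)`` (positive for decay); for the linear model it is the
    signed slope in value units per day.
    """

    model: DecayModel
    y0: float
    rate: float
    r_squared: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def mann_kendall_s(values: np.ndarray) -> int:
    """S = Σ_{i<j} sign(v_j − v_i)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(values[i + 1:] - values[i])))
    return s


def mann_kendall_null(values: np.ndarray) -> dict[int, int]:
    """Exact null distribution of S: counts over all n! orderings of ``values``."""
    values = tuple(np.asarray(values, dtype=float))
    counts: dict[int, int] = {}
    for perm in itertools.permutations(values):
        s = mann_kendall_s(np.array(perm))
        counts[s] = counts.get(s, 0) + 1
    return counts


def mann_kendall_exact(ts: TimeSeries) -> MKResult:
    """Exact Mann–Kendall trend test by full permutation enumeration.

    Valid for 3 ≤ n ≤ 8 (the exact-enumeration regime; n! ≤ 40320).
    One-sided p is the probability, under random ordering of the observed
    values, of an S at least as extreme as observed in the observed
    direction; two-sided p uses |S|.
    """
    n = len(ts)
    if not 3 <= n <= 8:
        raise ValueError(f"exact enumeration requires 3 ≤ n ≤ 8, got {n}")
    if not np.all(np.isfinite(ts.values)):
        raise ValueError("series contains missing/non-finite values")

    s_obs = mann_kendall_s(ts.values)
    counts = mann_kendall_null(ts.values)
    total = math.factorial(n)

    if s_obs < 0:
        one = sum(c for s, c in counts.items() if s <= s_obs) / total
        direction: Literal["increasing", "decreasing", "none"] = "decreasing"
    elif s_obs > 0:
        one = sum(c for s, c in counts.items() if s >= s_obs) / total
        direction = "increasing"
    else:
        one = sum(c for s, c in counts.items() if s >= 0) / total
        direction = "none"
    two = sum(c for s, c in counts.items() if abs(s) >= abs(s_obs)) / total
    return MKResult(s=s_obs, n=n, p_one_sided=one, p_two_sided=min(two, 1.0),
                    direction=direction)


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.any(y <= 0):
        raise FitError("exponential model requires strictly positive values")
    # log-linear start, then nonlinear refinement on the raw scale
    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, y0, k: y0 * np.exp(-k * tt), t, y, p0=p0, maxfev=2000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])


def fit_decay(
    ts: TimeSeries,
    model: DecayModel = "exponential",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DecayFit:
    """First-order decay fit with a seeded residual-bootstrap CI.

    The CI on the rate/slope is a bootstrap-t interval built from
    leverage-adjusted residuals: raw least-squares residuals at very small
    n underestimate the error scale (two parameters are fitted from as few
    as four points), so residuals are rescaled before resampling and each
    resample's rate is studentised by its own standard error. A noiseless
    series yields a degenerate CI at the fitted rate. Same seed →
    identical CI.
    """
    if len(ts) < 3:
        raise ValueError("decay fit requires at least 3 points")
    n = len(ts)
    n_params = 2
    t = ts.days
    y = ts.values.astype(float)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0

    if model == "linear":
        X = np.column_stack([np.ones_like(t), t])
        pinv = np.linalg.pinv(X)
        beta = pinv @ y
        intercept, slope = float(beta[0]), float(beta[1])
        y_hat = X @ beta
        resid = y - y_hat
        r2 = _r_squared(y, y_hat)
        c_slope = float((pinv @ pinv.T)[1, 1])  # slope variance factor
        s2_hat = float(np.sum(resid**2)) / (n - n_params)
        se_hat = math.sqrt(s2_hat * c_slope)
        if se_hat <= 1e-12 * max(float(np.abs(y).max()), 1.0):
            return DecayFit(model="linear", y0=intercept, rate=slope,
                            r_squared=r2, ci_low=slope, ci_high=slope,
                            n_boot=n_boot, seed=seed)
        leverage = np.diag(X @ pinv)
        r_adj = resid / np.sqrt(np.clip(1.0 - leverage, 1e-12, None))
        r_adj = r_adj - r_adj.mean()
        idx = rng.integers(0, n, size=(n_boot, n))
        y_b = y_hat[None, :] + r_adj[idx]
        beta_b = pinv @ y_b.T  # (2, n_boot)
        resid_b = y_b - (X @ beta_b).T
        s2_b = (resid_b**2).sum(axis=1) / (n - n_params)
        se_b = np.sqrt(s2_b * c_slope)
        ok = se_b > 1e-14 * max(abs(slope), 1.0)
        t_b = (beta_b[1][ok] - slope) / se_b[ok]
        if t_b.size < n_boot // 2:
            raise FitError("bootstrap studentisation degenerate for most resamples")
        q_lo, q_hi = np.quantile(t_b, [alpha, 1.0 - alpha])
        return DecayFit(model="linear", y0=intercept, rate=slope,
                        r_squared=r2,
                        ci_low=float(slope - q_hi * se_hat),
                        ci_high=float(slope - q_lo * se_hat),
                        n_boot=n_boot, seed=seed)

    if model == "exponential":
        y0, rate = _fit_exponential(t, y)
        y_hat = y0 * np.exp(-rate * t)
        resid = y - y_hat
        r2 = _r_squared(y, y_hat)

        def _fit_with_se(yy: np.ndarray) -> tuple[float, float]:
            popt, pcov = optimize.curve_fit(
                lambda tt, a, k: a * np.exp(-k * tt), t, yy,
                p0=(y0, rate), maxfev=500,
            )
            return float(popt[1]), float(math.sqrt(max(pcov[1, 1], 0.0)))

        s_resid = float(np.sqrt(np.sum(resid**2) / (n - n_params)))
        if s_resid < 1e-12 * max(abs(y).max(), 1.0):
            return DecayFit(model="exponential", y0=y0, rate=rate,
                            r_squared=r2, ci_low=rate, ci_high=rate,
                            n_boot=n_boot, seed=seed)
        _, se_hat = _fit_with_se(y)
        # degrees-of-freedom rescaling analogous to the linear leverage fix
        r_adj = resid * math.sqrt(n / (n - n_params))
        r_adj = r_adj - r_adj.mean()
        t_stats = np.empty(n_boot)
        t_stats.fill(np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            y_b = np.clip(y_hat + r_adj[idx], 1e-12, None)
            try:
                rate_b, se_b = _fit_with_se(y_b)
            except RuntimeError:
                continue
            if se_b > 1e-14 * max(abs(rate), 1.0):
                t_stats[b] = (rate_b - rate) / se_b
        t_stats = t_stats[np.isfinite(t_stats)]
        if t_stats.size < n_boot // 2:
            raise FitError("bootstrap refits failed for most resamples")
        q_lo, q_hi = np.quantile(t_stats, [alpha, 1.0 - alpha])
        return DecayFit(model="exponential", y0=y0, rate=rate,
                        r_squared=r2,
                        ci_low=float(rate - q_hi * se_hat),
                        ci_high=float(rate - q_lo * se_hat),
                        n_boot=n_boot, seed=seed)

    raise ValueError(f"unknown model {model!r}")


def correlations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and Spearman ρ of two equal-length series (n ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length ≥ 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series have undefined correlation")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho
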