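"""Vectorized batch evaluation of the rank statistics.

Operates on arrays of B independent datasets at once (shape (B, n1) and
(B, n2)); used by the permutation test and the Monte-Carlo harnesses, where
recomputing ranks dataset-by-dataset in Python would dominate the runtime.
The scalar public API in :mod:`npbf.effect` is the readable reference
implementation; the two are asserted equal in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, rankdata
from scipy.stats import t as t_dist

_NEG_TOL = 1e-14


def batch_core(x1: np.ndarray, x2: np.ndarray) -> dict[str, np.ndarray]:
    """theta_hat, placement sums of squares, both variance estimators and
    the tie probability for each of B paired rows."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    B, n1 = x1.shape
    n2 = x2.shape[1]
    N = n1 + n2
    pooled = np.concatenate([x1, x2], axis=1)

    r_mid = rankdata(pooled, method="average", axis=1)
    p1 = r_mid[:, :n1] - rankdata(x1, method="average", axis=1)
    p2 = r_mid[:, n1:] - rankdata(x2, method="average", axis=1)

    theta = (r_mid[:, n1:].mean(axis=1) - (n2 + 1) / 2.0) / n1
    np.clip(theta, 0.0, 1.0, out=theta)

    ss1 = np.sum((p1 - p1.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ss2 = np.sum((p2 - p2.mean(axis=1, keepdims=True)) ** 2, axis=1)
    sigma1 = ss1 / ((N - n1) ** 2 * (n1 - 1))
    sigma2 = ss2 / ((N - n2) ** 2 * (n2 - 1))
    v_dl = N * (sigma1 / n1 + sigma2 / n2)

    r_max2 = rankdata(pooled, method="max", axis=1)[:, n1:].mean(axis=1)
    r_min2 = rankdata(pooled, method="min", axis=1)[:, n1:].mean(axis=1)
    ri_max2 = rankdata(x2, method="max", axis=1).mean(axis=1)
    ri_min2 = rankdata(x2, method="min", axis=1).mean(axis=1)
    tau = ((r_max2 - r_min2) - (ri_max2 - ri_min2)) / n1

    d_n = n1 * (n1 - 1) * n2 * (n2 - 1)
    sigma_n = (ss1 + ss2 - n1 * n2 * (theta * (1 - theta) - tau / 4.0)) / d_n
    sigma_n[(sigma_n < 0) & (sigma_n > -_NEG_TOL * np.maximum(1.0, ss1 + ss2))] = 0.0

    return {
        "n1": n1,
        "n2": n2,
        "theta": theta,
        "sigma1": sigma1,
        "sigma2": sigma2,
        "v_dl": v_dl,
        "tau": tau,
        "sigma_n": sigma_n,
    }


def bm_statistic(core: dict[str, np.ndarray]) -> np.ndarray:
    """Studentized statistic sqrt(N)(theta_hat - 1/2)/v_dl.

    Degenerate rows (v_dl = 0) map to signed infinity, 0 when theta_hat
    is exactly 1/2, so the permutation distribution stays well defined.
    """
    n1, n2 = core["n1"], core["n2"]
    N = n1 + n2
    theta, v_dl = core["theta"], core["v_dl"]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.sqrt(N) * (theta - 0.5) / np.sqrt(v_dl)
    bad = v_dl == 0
    if np.any(bad):
        with np.errstate(invalid="ignore"):
            t = np.where(bad, np.sign(theta - 0.5) * np.inf, t)
        t = np.where(bad & (theta == 0.5), 0.0, t)
    return t


def bm_df(core: dict[str, np.ndarray]) -> np.ndarray:
    """Satterthwaite degrees of freedom with placement-variance weights
    w_i = (N - n_i) * sigma_i^2. Rows with both weights zero give nan."""
    n1, n2 = core["n1"], core["n2"]
    N = n1 + n2
    w1 = (N - n1) * core["sigma1"]
    w2 = (N - n2) * core["sigma2"]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (w1 + w2) ** 2 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1))
    return f


def bm_pvalue(core: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(statistic, df, two-sided p) of the t-approximated test per row."""
    t = bm_statistic(core)
    f = bm_df(core)
    with np.errstate(invalid="ignore"):
        p = 2.0 * t_dist.sf(np.abs(t), np.where(np.isnan(f), 1.0, f))
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(t == 0.0, 1.0, p)
    return t, f, np.minimum(p, 1.0)


def c2_statistic(core: dict[str, np.ndarray], theta0: float = 0.5) -> np.ndarray:
    """Chi-square statistic (theta_hat - theta0)^2 / [q_hat theta0(1-theta0)]
    per row; degenerate rows (sigma_N^2 = 0, incl. separated samples) use the
    Birnbaum-Klose maximum variance: m (theta_hat - theta0)^2 / [theta0(1-theta0)]."""
    n1, n2 = core["n1"], core["n2"]
    m = min(n1, n2)
    theta, sigma_n = core["theta"], core["sigma_n"]
    tp0 = theta0 * (1.0 - theta0)
    dev = (theta - theta0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = dev * theta * (1.0 - theta) / (sigma_n * tp0)
    degen = sigma_n == 0.0
    if np.any(degen):
        stat = np.where(degen, m * dev / tp0, stat)
    return stat


def c2_pvalue(core: dict[str, np.ndarray], theta0: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    stat = c2_statistic(core, theta0)
    return stat, chi2.sf(stat, 1)


def c2_interval_bounds(
    core: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson-type bounds per row; degenerate rows fall back to the
    Birnbaum-Klose inversion with sigma_max^2 = theta(1-theta)/m."""
    n1, n2 = core["n1"], core["n2"]
    m = min(n1, n2)
    c = chi2.ppf(1.0 - alpha, 1)
    theta, sigma_n = core["theta"], core["sigma_n"]
    tp = theta * (1.0 - theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = sigma_n / tp
        disc = np.sqrt(q * q * c * c + 4.0 * q * tp * c)
        lo = (2.0 * theta + q * c - disc) / (2.0 * (1.0 + q * c))
        hi = (2.0 * theta + q * c + disc) / (2.0 * (1.0 + q * c))
    degen = (sigma_n == 0.0) | (tp == 0.0)
    if np.any(degen):
        disc_bk = np.sqrt(4.0 * m * tp * c + c * c)
        lo_bk = (2.0 * m * theta + c - disc_bk) / (2.0 * (m + c))
        hi_bk = (2.0 * m * theta + c + disc_bk) / (2.0 * (m + c))
        lo = np.where(degen, lo_bk, lo)
        hi = np.where(degen, hi_bk, hi)
    return lo, hi


def bm_interval_bounds(
    core: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """t-inversion bounds per row (unclipped); degenerate rows give nan."""
    n1, n2 = core["n1"], core["n2"]
    N = n1 + n2
    f = bm_df(core)
    with np.errstate(invalid="ignore"):
        tq = t_dist.ppf(1.0 - alpha / 2.0, np.where(np.isnan(f), 1.0, f))
    half = tq * np.sqrt(core["v_dl"] / N)
    half = np.where(core["v_dl"] == 0.0, np.nan, half)
    return core["theta"] - half, core["theta"] + half
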