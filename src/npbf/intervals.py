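"""Confidence intervals for the Mann-Whitney effect.

Each interval inverts one of the tests in :mod:`npbf.hypotheses` and is
therefore *compatible* with it: the interval excludes 1/2 exactly when the
test rejects H0: theta = 1/2 at the same level. The t-inversion interval is
symmetric about theta_hat and not range-preserving (its bounds may leave
[0, 1]); the Wilson-type inversion of the chi-square test and its
Birnbaum-Klose fallback are range-preserving by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from scipy.stats import t as t_dist

from .effect import estimate_all
from .hypotheses import permutation_distribution, satterthwaite_df
from .ranks import TwoSampleData

__all__ = [
    "ConfidenceInterval",
    "bm_interval",
    "permutation_interval",
    "c2_interval",
    "bk_interval",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    method: str
    range_preserving: bool
    compatible_test: str

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def round(self, ndigits: int) -> tuple[float, float]:
        return round(self.lower, ndigits), round(self.upper, ndigits)


def bm_interval(data: TwoSampleData, alpha: float = 0.05, clip: bool = False) -> ConfidenceInterval:
    """t-inversion interval theta_hat -/+ t_{f,1-alpha/2} v_dl / sqrt(N).

    Reported unclipped by default — the bounds can exceed [0, 1], which is
    the method's documented weakness. Undefined when v_dl = 0.
    """
    effect, variances = estimate_all(data)
    if variances.v_dl_sq == 0.0:
        raise ValueError("v_dl^2 = 0 (separated or fully tied samples): "
                         "the t-inversion interval is undefined")
    df = satterthwaite_df(variances.sigma1_sq, variances.sigma2_sq, data.n1, data.n2)
    half = t_dist.ppf(1.0 - alpha / 2.0, df) * math.sqrt(variances.v_dl_sq / data.N)
    lo, hi = effect.theta_hat - half, effect.theta_hat + half
    if clip:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return ConfidenceInterval(lo, hi, 1.0 - alpha, "bm", clip, "brunner-munzel")


def permutation_interval(
    data: TwoSampleData,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: np.random.Generator | int | None = None,
    exact: bool = False,
) -> ConfidenceInterval:
    """Interval from the empirical permutation quantiles of the studentized
    statistic: [theta_hat - c1 v_dl/sqrt(N), theta_hat - c2 v_dl/sqrt(N)]
    with c1, c2 the 1-alpha/2 and alpha/2 permutation quantiles."""
    effect, variances = estimate_all(data)
    if variances.v_dl_sq == 0.0:
        raise ValueError("v_dl^2 = 0: the permutation interval is undefined")
    t_perm = permutation_distribution(data, n_permutations, seed, exact=exact)
    t_perm = t_perm[np.isfinite(t_perm)]
    c1, c2 = np.quantile(t_perm, [1.0 - alpha / 2.0, alpha / 2.0])
    scale = math.sqrt(variances.v_dl_sq / data.N)
    return ConfidenceInterval(
        effect.theta_hat - c1 * scale,
        effect.theta_hat - c2 * scale,
        1.0 - alpha,
        "permutation",
        False,
        "permutation",
    )


def c2_interval(data: TwoSampleData, alpha: float = 0.05) -> ConfidenceInterval:
    """Wilson-type interval inverting the chi-square test.

    Solves (theta_hat - theta)^2 < q_hat c theta(1-theta) for theta with
    c the (1-alpha) quantile of chi2(1):

        theta_{L,U} = [2 theta_hat + q c -/+ sqrt(q^2 c^2 + 4 q theta_hat
                       (1-theta_hat) c)] / [2 (1 + q c)].

    Bounds always lie in [0, 1] and are asymmetric about theta_hat in
    general. Degenerate samples (sigma_N^2 = 0 or theta_hat in {0, 1})
    delegate to :func:`bk_interval`.
    """
    effect, variances = estimate_all(data)
    theta = effect.theta_hat
    if variances.sigma_n_sq == 0.0 or effect.separated:
        inner = bk_interval(theta, data.m, alpha)
        return ConfidenceInterval(
            inner.lower, inner.upper, inner.level, "c2->bk", True, "c2"
        )
    c = chi2.ppf(1.0 - alpha, 1)
    q = variances.q_hat
    tp = theta * (1.0 - theta)
    disc = math.sqrt(q * q * c * c + 4.0 * q * tp * c)
    lo = (2.0 * theta + q * c - disc) / (2.0 * (1.0 + q * c))
    hi = (2.0 * theta + q * c + disc) / (2.0 * (1.0 + q * c))
    return ConfidenceInterval(lo, hi, 1.0 - alpha, "c2", True, "c2")


def bk_interval(theta_hat: float, m: int, alpha: float = 0.05) -> ConfidenceInterval:
    """Interval from the Birnbaum-Klose maximum variance theta(1-theta)/m.

    Solves (theta_hat - theta)^2 <= c theta(1-theta)/m for theta:

        theta_{L,U} = [2 m theta_hat + c -/+ sqrt(4 m theta_hat
                       (1-theta_hat) c + c^2)] / [2 (m + c)].

    At theta_hat = 1 this is [m/(m+c), 1]; at theta_hat = 0 it is
    [0, c/(m+c)] — one-sided intervals for the extreme estimates. Needs no
    variance estimation, hence it serves as the fallback for degenerate
    samples; conservative whenever the normal approximation is adequate.
    """
    if m < 2:
        raise ValueError("m >= 2 required")
    if not 0.0 <= theta_hat <= 1.0:
        raise ValueError("theta_hat must lie in [0, 1]")
    c = chi2.ppf(1.0 - alpha, 1)
    tp = theta_hat * (1.0 - theta_hat)
    disc = math.sqrt(4.0 * m * tp * c + c * c)
    lo = (2.0 * m * theta_hat + c - disc) / (2.0 * (m + c))
    hi = (2.0 * m * theta_hat + c + disc) / (2.0 * (m + c))
    if theta_hat == 1.0:
        lo, hi = m / (m + c), 1.0
    elif theta_hat == 0.0:
        lo, hi = 0.0, c / (m + c)
    return ConfidenceInterval(lo, hi, 1.0 - alpha, "bk", True, "c2-sigma-max")
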