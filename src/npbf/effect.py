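"""Point estimation of the Mann-Whitney effect and its variance.

Two variance estimators are provided: the classical plug-in estimator of
DeLong et al. (used by the Brunner-Munzel test; positively biased for
continuous data) and the unbiased rank-based estimator of Brunner &
Konietschke, which incorporates a tie-probability correction and obeys the
sharp empirical Birnbaum-Klose bound

    sigma_N^2 <= theta_hat * (1 - theta_hat) / (m - 1),  m = min(n1, n2).

The ratio quantities q_hat = sigma_N^2 / [theta_hat (1 - theta_hat)] and
r_hat = 1 / (m * q_hat) drive the chi-square test in :mod:`npbf.hypotheses`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranks import RankDecomposition, TwoSampleData, decompose

__all__ = [
    "EffectEstimate",
    "VarianceEstimates",
    "estimate_effect",
    "delong_variance",
    "tie_probability",
    "unbiased_variance",
    "variance_ratio",
    "estimate_all",
]

# negatives of this size in sigma_N^2 can only be float round-off;
# the estimator is provably non-negative
_NEG_TOL = 1e-14


class DegenerateSampleError(ValueError):
    """Raised when an operation needs a non-degenerate variance estimate."""


@dataclass(frozen=True)
class EffectEstimate:
    """theta_hat = (Rbar_2. - (n2+1)/2) / n1, a multiple of 1/(2 n1 n2)."""

    theta_hat: float
    rank_mean_2: float
    n1: int
    n2: int

    @property
    def separated(self) -> bool:
        return self.theta_hat in (0.0, 1.0)


@dataclass(frozen=True)
class VarianceEstimates:
    sigma1_sq: float
    sigma2_sq: float
    v_dl_sq: float
    tau_hat: float
    sigma_n_sq: float
    q_hat: float | None
    r_hat: float | None
    separated: bool
    degenerate_variance: bool


def estimate_effect(data: TwoSampleData, ranks: RankDecomposition | None = None) -> EffectEstimate:
    """Rank estimator of theta = P(X1 < X2) + 0.5 P(X1 = X2).

    Equals the pairwise count (1/(n1 n2)) sum_k sum_j [1{x1k < x2j}
    + 0.5 * 1{x1k = x2j}] exactly.
    """
    if ranks is None:
        ranks = decompose(data)
    rbar2 = ranks.rank_mean(1)
    theta = (rbar2 - (data.n2 + 1) / 2.0) / data.n1
    # theta lives on the grid j/(2 n1 n2); snap off float noise at the ends
    theta = min(max(theta, 0.0), 1.0)
    return EffectEstimate(theta_hat=theta, rank_mean_2=rbar2, n1=data.n1, n2=data.n2)


def delong_variance(ranks: RankDecomposition) -> tuple[float, float, float]:
    """Plug-in variance estimators (sigma1_sq, sigma2_sq, v_dl_sq).

    sigma_i^2 is the empirical variance of the placements of sample i,
    scaled by 1/(N - n_i)^2; v_dl_sq = N * (sigma1_sq/n1 + sigma2_sq/n2)
    estimates Var(sqrt(N) * theta_hat).
    """
    data = ranks.data
    N = data.N
    sigmas = []
    for i, ni in ((0, data.n1), (1, data.n2)):
        p = ranks.placements[i]
        ss = float(np.sum((p - p.mean()) ** 2))
        sigmas.append(ss / ((N - ni) ** 2 * (ni - 1)))
    v_dl = N * (sigmas[0] / data.n1 + sigmas[1] / data.n2)
    return sigmas[0], sigmas[1], v_dl


def tie_probability(ranks: RankDecomposition) -> float:
    """Estimator of tau = P(X1 = X2), the cross-sample tie probability.

    tau_hat = [(Rbar2+ - Rbar2-) - (Rbar2(2)+ - Rbar2(2)-)] / n1 using the
    means of max/min overall and internal ranks of the second sample; it
    equals the proportion of tied pairs among the n1*n2 cross pairs.
    """
    data = ranks.data
    spread_overall = ranks.overall_max[1].mean() - ranks.overall_min[1].mean()
    spread_internal = ranks.internal_max[1].mean() - ranks.internal_min[1].mean()
    return float((spread_overall - spread_internal) / data.n1)


def unbiased_variance(
    ranks: RankDecomposition,
    effect: EffectEstimate,
    tau_hat: float,
) -> float:
    """Unbiased rank-based estimator of Var(theta_hat).

    sigma_N^2 = [SS_placements - n1 n2 (theta_hat(1-theta_hat) - tau_hat/4)]
    / [n1(n1-1) n2(n2-1)]. Non-negative for n_i >= 2; tiny float negatives
    are clamped to zero.
    """
    data = ranks.data
    n1, n2 = data.n1, data.n2
    ss = 0.0
    for i in (0, 1):
        p = ranks.placements[i]
        ss += float(np.sum((p - p.mean()) ** 2))
    theta = effect.theta_hat
    d_n = n1 * (n1 - 1) * n2 * (n2 - 1)
    sigma = (ss - n1 * n2 * (theta * (1.0 - theta) - tau_hat / 4.0)) / d_n
    if sigma < 0:
        if sigma < -_NEG_TOL * max(1.0, abs(ss)):
            raise AssertionError(f"sigma_N^2 = {sigma} is negative beyond round-off")
        sigma = 0.0
    return sigma


def variance_ratio(
    effect: EffectEstimate,
    sigma_n_sq: float,
    m: int,
    small_sample_factor: bool = False,
) -> tuple[float, float]:
    """(q_hat, r_hat): variance relative to the Birnbaum-Klose maximum.

    q_hat = sigma_N^2 / [theta_hat (1 - theta_hat)];
    r_hat = theta_hat (1 - theta_hat) / (m sigma_N^2) estimates
    sigma_N,max^2 / sigma_N^2. With ``small_sample_factor`` the bound-aware
    variant r* using (m-1) instead of m is returned (off by default).
    """
    theta = effect.theta_hat
    tp = theta * (1.0 - theta)
    if tp == 0.0:
        raise DegenerateSampleError("theta_hat in {0,1}: variance ratio undefined")
    if sigma_n_sq <= 0.0:
        raise DegenerateSampleError("sigma_N^2 = 0: variance ratio undefined")
    denom = (m - 1) if small_sample_factor else m
    q_hat = sigma_n_sq / tp
    r_hat = tp / (denom * sigma_n_sq)
    return q_hat, r_hat


def estimate_all(
    data: TwoSampleData, ranks: RankDecomposition | None = None
) -> tuple[EffectEstimate, VarianceEstimates]:
    """Convenience bundle: effect plus every variance quantity with flags."""
    if ranks is None:
        ranks = decompose(data)
    effect = estimate_effect(data, ranks)
    s1, s2, v_dl = delong_variance(ranks)
    tau = tie_probability(ranks)
    sigma_n = unbiased_variance(ranks, effect, tau)
    separated = effect.separated
    degenerate = sigma_n == 0.0 or v_dl == 0.0
    if separated or sigma_n == 0.0:
        q_hat = r_hat = None
    else:
        q_hat, r_hat = variance_ratio(effect, sigma_n, data.m)
    variances = VarianceEstimates(
        sigma1_sq=s1,
        sigma2_sq=s2,
        v_dl_sq=v_dl,
        tau_hat=tau,
        sigma_n_sq=sigma_n,
        q_hat=q_hat,
        r_hat=r_hat,
        separated=separated,
        degenerate_variance=degenerate,
    )
    return effect, variances
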