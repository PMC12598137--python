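"""Hypothesis tests for H0: theta = 1/2 (and H0: theta = theta0).

Three tests are provided:

* :func:`brunner_munzel_test` — the studentized rank statistic with a
  Satterthwaite t-approximation;
* :func:`permutation_test` — the studentized permutation version, which
  re-ranks the pooled data for every permutation;
* :func:`c2_test` — the chi-square test built on the unbiased variance
  estimator and the Birnbaum-Klose variance bound, with a closed-form
  degenerate branch for completely separated samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2
from scipy.stats import t as t_dist

from . import _kernel
from .effect import EffectEstimate, VarianceEstimates, estimate_all
from .ranks import TwoSampleData, decompose

__all__ = [
    "TestResult",
    "satterthwaite_df",
    "brunner_munzel_test",
    "c2_test",
    "c2_degenerate_test",
    "permutation_test",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    theta_hat: float
    reference: str
    df: float | None = None
    degenerate: bool = False
    n_permutations: int | None = None
    effect: EffectEstimate | None = None
    variances: VarianceEstimates | None = None

    def __str__(self):  # pragma: no cover - convenience only
        return (
            f"{self.method}: statistic={self.statistic:.4f}, "
            f"p={self.p_value:.4f}, theta_hat={self.theta_hat:.4f}, "
            f"{'reject' if self.reject else 'do not reject'} at alpha={self.alpha}"
        )


def satterthwaite_df(sigma1_sq: float, sigma2_sq: float, n1: int, n2: int) -> float:
    """Estimated degrees of freedom of the t-approximation.

    Weights are the placement variances w_i = (N - n_i) * sigma_i^2
    (sigma_i^2 on the scale of :func:`npbf.effect.delong_variance`):

        f = (w1 + w2)^2 / [w1^2/(n1-1) + w2^2/(n2-1)].

    For n1 = n2 = n and equal variances this reduces to 2(n-1); if one
    variance vanishes, to n_i - 1 of the other sample.
    """
    N = n1 + n2
    w1 = (N - n1) * sigma1_sq
    w2 = (N - n2) * sigma2_sq
    denom = w1**2 / (n1 - 1) + w2**2 / (n2 - 1)
    if denom == 0.0:
        raise ValueError("both variance estimates are zero: df undefined")
    return (w1 + w2) ** 2 / denom


def brunner_munzel_test(data: TwoSampleData, alpha: float = 0.05) -> TestResult:
    """Two-sided Brunner-Munzel test of H0: theta = 1/2.

    T = sqrt(N) (theta_hat - 1/2) / v_dl compared against a central t
    distribution with Satterthwaite degrees of freedom. When v_dl = 0
    (separated or fully tied samples) the statistic is reported as signed
    infinity with p = 0, or p = 1 when theta_hat = 1/2, and flagged.
    """
    ranks = decompose(data)
    effect, variances = estimate_all(data, ranks)
    theta = effect.theta_hat
    if variances.v_dl_sq == 0.0:
        if theta == 0.5:
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, theta - 0.5), 0.0
        return TestResult(
            method="brunner-munzel",
            statistic=stat,
            p_value=p,
            alpha=alpha,
            reject=p < alpha,
            theta_hat=theta,
            reference="t (degenerate)",
            df=None,
            degenerate=True,
            effect=effect,
            variances=variances,
        )
    stat = math.sqrt(data.N) * (theta - 0.5) / math.sqrt(variances.v_dl_sq)
    df = satterthwaite_df(variances.sigma1_sq, variances.sigma2_sq, data.n1, data.n2)
    p = float(2.0 * t_dist.sf(abs(stat), df))
    p = min(p, 1.0)
    return TestResult(
        method="brunner-munzel",
        statistic=stat,
        p_value=p,
        alpha=alpha,
        reject=p < alpha,
        theta_hat=theta,
        reference=f"t({df:.2f})",
        df=df,
        effect=effect,
        variances=variances,
    )


def c2_test(data: TwoSampleData, alpha: float = 0.05, theta0: float = 0.5) -> TestResult:
    """Chi-square test of H0: theta = theta0 based on the variance ratio.

    Regular branch: C2 = (theta_hat - theta0)^2 / [q_hat theta0(1-theta0)]
    with q_hat = sigma_N^2 / [theta_hat(1-theta_hat)], referred to a
    chi-square distribution with one degree of freedom; for theta0 = 1/2
    this is 4 (theta_hat - 1/2)^2 / q_hat. Degenerate samples
    (sigma_N^2 = 0, including complete separation) are routed to
    :func:`c2_degenerate_test`.
    """
    if not 0.0 < theta0 < 1.0:
        raise ValueError("theta0 must lie strictly between 0 and 1")
    ranks = decompose(data)
    effect, variances = estimate_all(data, ranks)
    if variances.sigma_n_sq == 0.0 or effect.separated:
        return c2_degenerate_test(data, alpha=alpha, theta0=theta0,
                                  effect=effect, variances=variances)
    theta = effect.theta_hat
    stat = (theta - theta0) ** 2 / (variances.q_hat * theta0 * (1.0 - theta0))
    p = float(chi2.sf(stat, 1))
    return TestResult(
        method="c2",
        statistic=stat,
        p_value=p,
        alpha=alpha,
        reject=bool(stat > chi2.ppf(1.0 - alpha, 1)),
        theta_hat=theta,
        reference="chi2(1)",
        df=1.0,
        effect=effect,
        variances=variances,
    )


def c2_degenerate_test(
    data: TwoSampleData,
    alpha: float = 0.05,
    theta0: float = 0.5,
    effect: EffectEstimate | None = None,
    variances: VarianceEstimates | None = None,
) -> TestResult:
    """Degenerate-sample branch of the chi-square test.

    With sigma_N^2 = 0 the unknown variance is replaced by its sharp
    Birnbaum-Klose maximum theta(1-theta)/m, giving
    C2 = m (theta_hat - theta0)^2 / [theta0(1-theta0)]; for theta0 = 1/2
    and theta_hat in {0, 1} this is simply m, so the test rejects at
    alpha = 0.05 whenever m >= 4 and at alpha = 0.01 whenever m >= 7.
    """
    if effect is None or variances is None:
        effect, variances = estimate_all(data)
    theta = effect.theta_hat
    stat = data.m * (theta - theta0) ** 2 / (theta0 * (1.0 - theta0))
    p = float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    return TestResult(
        method="c2-sigma-max",
        statistic=stat,
        p_value=p,
        alpha=alpha,
        reject=bool(stat > chi2.ppf(1.0 - alpha, 1)),
        theta_hat=theta,
        reference="chi2(1)",
        df=1.0,
        degenerate=True,
        effect=effect,
        variances=variances,
    )


def _enumerate_assignments(N: int, n1: int):
    for idx in combinations(range(N), n1):
        yield np.asarray(idx, dtype=np.intp)


def permutation_distribution(
    data: TwoSampleData,
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
    exact: bool = False,
    max_exact: int = 200_000,
) -> np.ndarray:
    """Brunner-Munzel statistics of permuted datasets.

    Random mode shuffles the pooled vector ``n_permutations`` times (draws
    with replacement from the permutation space). ``exact=True`` enumerates
    every distinct assignment of pooled positions to the first sample
    (C(N, n1) of them), which includes the identity.
    """
    pooled = data.pooled
    N, n1 = data.N, data.n1
    if exact:
        n_total = math.comb(N, n1)
        if n_total > max_exact:
            raise ValueError(f"exact enumeration would need {n_total} assignments")
        x1 = np.empty((n_total, n1))
        x2 = np.empty((n_total, N - n1))
        mask = np.zeros(N, dtype=bool)
        for row, idx in enumerate(_enumerate_assignments(N, n1)):
            mask[:] = False
            mask[idx] = True
            x1[row] = pooled[mask]
            x2[row] = pooled[~mask]
    else:
        rng = np.random.default_rng(rng)
        perms = rng.permuted(np.tile(pooled, (n_permutations, 1)), axis=1)
        x1, x2 = perms[:, :n1], perms[:, n1:]
    return _kernel.bm_statistic(_kernel.batch_core(x1, x2))


def permutation_test(
    data: TwoSampleData,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: np.random.Generator | int | None = None,
    p_rule: str = "plain",
    exact: bool = False,
) -> TestResult:
    """Studentized permutation test of H0: theta = 1/2.

    The observed statistic is compared to the permutation distribution of
    the fully re-ranked Brunner-Munzel statistic. ``p_rule="plain"`` doubles
    the smaller tail proportion (capped at 1); ``p_rule="add-one"`` uses the
    (U+1)/(n_permutations+1) convention per tail, which cannot return 0.
    """
    if p_rule not in ("plain", "add-one"):
        raise ValueError("p_rule must be 'plain' or 'add-one'")
    ranks = decompose(data)
    effect, variances = estimate_all(data, ranks)
    theta = effect.theta_hat
    if variances.v_dl_sq == 0.0:
        t_obs = 0.0 if theta == 0.5 else math.copysign(math.inf, theta - 0.5)
        degenerate = True
    else:
        t_obs = math.sqrt(data.N) * (theta - 0.5) / math.sqrt(variances.v_dl_sq)
        degenerate = False
    t_perm = permutation_distribution(data, n_permutations, seed, exact=exact)
    n_used = t_perm.size
    lower = int(np.sum(t_perm <= t_obs))
    upper = int(np.sum(t_perm >= t_obs))
    if p_rule == "add-one" and not exact:
        # count the identity permutation once: cannot return 0, and gives
        # 1/(n_permutations+1) when no permuted statistic is as extreme
        p = (2 * min(lower, upper) + 1) / (n_used + 1)
    else:
        p = 2.0 * min(lower / n_used, upper / n_used)
    p = min(p, 1.0)
    return TestResult(
        method="permutation",
        statistic=t_obs,
        p_value=p,
        alpha=alpha,
        reject=p < alpha,
        theta_hat=theta,
        reference="permutation",
        degenerate=degenerate,
        n_permutations=n_used,
        effect=effect,
        variances=variances,
    )
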