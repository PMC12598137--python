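"""Monte-Carlo study harnesses: type-I error, power and interval coverage.

The data-generating mechanisms cover metric (continuous and discrete) and
ordinal data: normal, beta, 5-point ordered-categorical scales obtained by
discretizing beta draws, Poisson, exponential and Laplace distributions,
in homoscedastic and heteroscedastic pairings. Null scenarios are chosen so
that theta = 1/2 holds (for Poisson and exponential families theta = 1/2
forces F1 = F2); alternatives are parameterized by a target effect
theta, with the free distribution parameter found by root finding on the
exact effect functional theta = int F1 dF2 + tie mass / 2.

All harnesses run on the vectorized kernel, evaluating every replicate of a
scenario in one batched rank computation, and draw their randomness from
per-scenario child streams of one master seed so results do not depend on
evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from . import _kernel

__all__ = [
    "DistSpec",
    "ScenarioSpec",
    "SimulationResult",
    "generate_sample",
    "true_effect",
    "solve_effect_parameter",
    "simulate_type1",
    "simulate_power",
    "simulate_coverage",
    "NULL_SETTINGS",
    "POWER_SETTINGS",
    "SIZE_GRID_BALANCED",
    "SIZE_GRID_N2_LARGER",
    "SIZE_GRID_N1_LARGER",
]

# 5-point Likert discretization: beta draws on (0,1) cut into equal-width
# categories coded 1..5
_LIKERT_CUTS = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class DistSpec:
    """One arm's data-generating distribution.

    Families: ``normal(mu, sd)``, ``beta(a, b)``, ``ordcat(a, b)`` (beta
    discretized to a 5-point scale), ``poisson(lam)``, ``exponential(rate)``
    and ``laplace(mu, scale)`` (variance 2*scale^2).
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        _FAMILIES[self.family](*self.params)  # validates arity/ranges

    def frozen(self):
        return _FAMILIES[self.family](*self.params)

    @property
    def discrete(self) -> bool:
        return self.family in ("ordcat", "poisson")

    def __str__(self):
        args = ",".join(f"{p:g}" for p in self.params)
        return f"{self.family}({args})"


def _normal(mu, sd):
    if sd <= 0:
        raise ValueError("sd must be positive")
    return stats.norm(mu, sd)


def _beta(a, b):
    if a <= 0 or b <= 0:
        raise ValueError("beta shapes must be positive")
    return stats.beta(a, b)


def _poisson(lam):
    if lam <= 0:
        raise ValueError("rate must be positive")
    return stats.poisson(lam)


def _exponential(rate):
    if rate <= 0:
        raise ValueError("rate must be positive")
    return stats.expon(scale=1.0 / rate)


def _laplace(mu, scale):
    if scale <= 0:
        raise ValueError("scale must be positive")
    return stats.laplace(mu, scale)


_FAMILIES = {
    "normal": _normal,
    "beta": _beta,
    "ordcat": _beta,  # latent beta, discretized on draw
    "poisson": _poisson,
    "exponential": _exponential,
    "laplace": _laplace,
}


def generate_sample(spec: DistSpec, size, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` observations (scalar or shape tuple) from ``spec``."""
    draws = spec.frozen().rvs(size=size, random_state=rng)
    if spec.family == "ordcat":
        draws = np.digitize(draws, _LIKERT_CUTS) + 1.0
    return np.asarray(draws, dtype=float)


def _category_probs(spec: DistSpec) -> np.ndarray:
    cdf = spec.frozen().cdf
    edges = np.concatenate([[0.0], _LIKERT_CUTS, [1.0]])
    return np.diff(cdf(edges))


def _discrete_probs(spec: DistSpec, tail_tol: float = 1e-12):
    if spec.family == "ordcat":
        return np.arange(1, 6, dtype=float), _category_probs(spec)
    # Poisson: truncate where the tail is negligible
    dist = spec.frozen()
    hi = int(dist.ppf(1.0 - tail_tol)) + 10
    ks = np.arange(0, hi + 1)
    return ks.astype(float), dist.pmf(ks)


def true_effect(spec1: DistSpec, spec2: DistSpec) -> float:
    """Exact Mann-Whitney effect theta = P(X1 < X2) + 0.5 P(X1 = X2).

    Closed forms for normal/normal (Phi(dmu / sqrt(s1^2 + s2^2))) and
    exponential/exponential (rate1 / (rate1 + rate2)); exact finite sums
    for discrete pairs; deterministic numerical integration otherwise.
    """
    if spec1.family == "normal" and spec2.family == "normal":
        mu1, s1 = spec1.params
        mu2, s2 = spec2.params
        return float(stats.norm.cdf((mu2 - mu1) / math.hypot(s1, s2)))
    if spec1.family == "exponential" and spec2.family == "exponential":
        r1, r2 = spec1.params[0], spec2.params[0]
        return r1 / (r1 + r2)
    if spec1.discrete and spec2.discrete:
        x1, p1 = _discrete_probs(spec1)
        x2, p2 = _discrete_probs(spec2)
        less = (x1[:, None] < x2[None, :]).astype(float)
        equal = (x1[:, None] == x2[None, :]).astype(float)
        return float(p1 @ (less + 0.5 * equal) @ p2)
    if spec1.discrete or spec2.discrete:
        raise NotImplementedError("mixed discrete/continuous pairs are not supported")
    d1, d2 = spec1.frozen(), spec2.frozen()
    lo = min(d1.ppf(1e-12), d2.ppf(1e-12))
    hi = max(d1.ppf(1.0 - 1e-12), d2.ppf(1.0 - 1e-12))
    val, _ = integrate.quad(lambda x: d1.cdf(x) * d2.pdf(x), lo, hi, limit=200)
    return float(min(max(val, 0.0), 1.0))


def solve_effect_parameter(
    make_pair,
    target: float,
    bracket: tuple[float, float],
    tol: float = 1e-10,
) -> float:
    """Find the parameter value at which ``true_effect(*make_pair(p))``
    equals ``target`` (monotone root finding on the exact effect).

    ``make_pair`` maps the free parameter to a (spec1, spec2) pair;
    ``bracket`` must enclose the root.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target effect must lie in (0, 1)")

    def gap(p):
        return true_effect(*make_pair(p)) - target

    lo, hi = bracket
    f_lo, f_hi = gap(lo), gap(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target {target} not attainable in bracket {bracket} "
            f"(effect range [{f_lo + target:.4f}, {f_hi + target:.4f}])"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=tol))


# -- study-design registries -------------------------------------------------

#: Null scenarios (theta = 1/2). Keys are the setting numbers of the study
#: design; values are (F1, F2) pairs.
NULL_SETTINGS: dict[int, tuple[DistSpec, DistSpec]] = {
    1: (DistSpec("normal", (0.0, 1.0)), DistSpec("normal", (0.0, 1.0))),
    2: (DistSpec("normal", (0.0, 1.0)), DistSpec("normal", (0.0, 3.0))),
    3: (DistSpec("beta", (1.0, 1.0)), DistSpec("beta", (1.0, 1.0))),
    4: (DistSpec("beta", (2.0, 5.0)), DistSpec("beta", (2.0, 5.0))),
    5: (DistSpec("beta", (5.0, 5.0)), DistSpec("beta", (1.0, 1.0))),
    6: (DistSpec("beta", (5.0, 5.0)), DistSpec("beta", (2.0, 2.0))),
    7: (DistSpec("ordcat", (1.0, 1.0)), DistSpec("ordcat", (1.0, 1.0))),
    8: (DistSpec("ordcat", (2.0, 5.0)), DistSpec("ordcat", (2.0, 5.0))),
    9: (DistSpec("ordcat", (5.0, 5.0)), DistSpec("ordcat", (1.0, 1.0))),
    10: (DistSpec("ordcat", (5.0, 5.0)), DistSpec("ordcat", (2.0, 2.0))),
    11: (DistSpec("poisson", (1.0,)), DistSpec("poisson", (1.0,))),
    12: (DistSpec("exponential", (1.0,)), DistSpec("exponential", (1.0,))),
    13: (DistSpec("laplace", (0.0, 1.0)), DistSpec("laplace", (0.0, 1.0))),
    14: (DistSpec("laplace", (0.0, 1.0)), DistSpec("laplace", (0.0, 3.0))),
}

#: Alternative scenarios: parameter -> (control F1, treatment F2) maps with
#: root-finding brackets, one per power-study setting.
POWER_SETTINGS: dict[int, dict] = {
    1: {
        "make_pair": lambda mu: (DistSpec("normal", (0.0, 1.0)), DistSpec("normal", (mu, 1.0))),
        "bracket": (0.0, 6.0),
        "label": "normal shift, equal variances",
    },
    2: {
        "make_pair": lambda mu: (DistSpec("normal", (0.0, 1.0)), DistSpec("normal", (mu, 3.0))),
        "bracket": (0.0, 15.0),
        "label": "normal shift, var ratio 9",
    },
    3: {
        "make_pair": lambda a: (DistSpec("ordcat", (1.0, 1.0)), DistSpec("ordcat", (a, 1.0))),
        "bracket": (1.0, 60.0),
        "label": "5-point scales from B(1,1) vs B(a,1)",
    },
    4: {
        "make_pair": lambda lam: (DistSpec("exponential", (lam,)), DistSpec("exponential", (1.0,))),
        "bracket": (1.0, 100.0),
        "label": "exponential rates",
    },
}

SIZE_GRID_BALANCED = [(15, 15), (30, 30), (45, 45), (60, 60), (75, 75)]
SIZE_GRID_N2_LARGER = [(15, 30), (20, 40), (30, 60), (40, 80), (50, 100)]
SIZE_GRID_N1_LARGER = [(30, 15), (40, 20), (60, 30), (80, 40), (100, 50)]


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: a distribution pair and a sample-size pair."""

    name: str
    spec1: DistSpec
    spec2: DistSpec
    n1: int
    n2: int
    theta: float | None = None  # exact effect, if known

    def with_sizes(self, n1: int, n2: int) -> "ScenarioSpec":
        return replace(self, n1=n1, n2=n2)


@dataclass
class SimulationResult:
    """Tidy per-(scenario, method, alpha) rates with Monte-Carlo SEs."""

    table: pd.DataFrame
    niter: int
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def rate(self, **filters) -> float:
        sub = self.table
        for col, val in filters.items():
            sub = sub[sub[col] == val]
        if len(sub) != 1:
            raise KeyError(f"filters {filters} match {len(sub)} rows")
        return float(sub["rate"].iloc[0])


def _child_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _mc_se(rate: float, niter: int) -> float:
    return math.sqrt(rate * (1.0 - rate) / niter)


def _batch_draws(scn: ScenarioSpec, niter: int, rng: np.random.Generator):
    x1 = generate_sample(scn.spec1, (niter, scn.n1), rng)
    x2 = generate_sample(scn.spec2, (niter, scn.n2), rng)
    return x1, x2


def _test_rejections(core, test: str, alphas, data_x=None) -> dict[float, np.ndarray]:
    if test == "bm":
        _, _, p = _kernel.bm_pvalue(core)
        return {a: p < a for a in alphas}
    if test == "c2":
        stat, _ = _kernel.c2_pvalue(core)
        return {a: stat > stats.chi2.ppf(1.0 - a, 1) for a in alphas}
    raise ValueError(f"unknown test {test!r} (batch harness supports 'bm' and 'c2')")


def simulate_type1(
    scenarios: list[ScenarioSpec],
    tests: tuple[str, ...] = ("bm", "c2"),
    niter: int = 10_000,
    seed: int = 0,
    alphas: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001),
) -> SimulationResult:
    """Empirical type-I error rates under null scenarios (theta = 1/2).

    Degenerate replicates (separated samples) are analyzed with each test's
    degenerate branch — never dropped — and counted in ``n_degenerate``.
    """
    rows = []
    for idx, scn in enumerate(scenarios):
        rng = _child_rng(seed, idx)
        core = _kernel.batch_core(*_batch_draws(scn, niter, rng))
        n_degen = int(np.sum(core["sigma_n"] == 0.0))
        for test in tests:
            rej = _test_rejections(core, test, alphas)
            for a in alphas:
                rate = float(np.mean(rej[a]))
                rows.append(
                    {
                        "scenario": scn.name,
                        "distribution": f"{scn.spec1} vs {scn.spec2}",
                        "test": test,
                        "alpha": a,
                        "n1": scn.n1,
                        "n2": scn.n2,
                        "rate": rate,
                        "mc_se": _mc_se(rate, niter),
                        "n_degenerate": n_degen,
                    }
                )
    return SimulationResult(pd.DataFrame(rows), niter, seed)


def simulate_power(
    setting: int,
    theta_grid,
    sizes=((15, 15), (15, 30), (30, 15)),
    tests: tuple[str, ...] = ("bm", "c2"),
    niter: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SimulationResult:
    """Empirical power over a grid of target effects for one power setting.

    The free distribution parameter is solved from each target effect
    before any data are drawn.
    """
    cfg = POWER_SETTINGS[setting]
    rows = []
    idx = 0
    for theta_target in theta_grid:
        param = solve_effect_parameter(cfg["make_pair"], theta_target, cfg["bracket"])
        spec1, spec2 = cfg["make_pair"](param)
        for n1, n2 in sizes:
            scn = ScenarioSpec(
                f"power-{setting}-theta{theta_target:g}", spec1, spec2, n1, n2, theta_target
            )
            rng = _child_rng(seed, idx)
            idx += 1
            core = _kernel.batch_core(*_batch_draws(scn, niter, rng))
            n_degen = int(np.sum(core["sigma_n"] == 0.0))
            for test in tests:
                rej = _test_rejections(core, test, (alpha,))
                rate = float(np.mean(rej[alpha]))
                rows.append(
                    {
                        "scenario": scn.name,
                        "setting": setting,
                        "theta": theta_target,
                        "param": param,
                        "test": test,
                        "alpha": alpha,
                        "n1": n1,
                        "n2": n2,
                        "rate": rate,
                        "mc_se": _mc_se(rate, niter),
                        "n_degenerate": n_degen,
                    }
                )
    return SimulationResult(pd.DataFrame(rows), niter, seed)


def simulate_coverage(
    setting: int,
    theta_grid,
    sizes=((15, 15), (15, 30), (30, 15)),
    methods: tuple[str, ...] = ("bm", "c2"),
    niter: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SimulationResult:
    """Empirical coverage of the true effect by the confidence intervals.

    The coverage denominator is always ``niter``: replicates where the
    t-inversion interval is undefined (v_dl = 0) count as non-covering for
    that method, while the chi-square interval falls back to its
    Birnbaum-Klose branch and is always defined.
    """
    cfg = POWER_SETTINGS[setting]
    rows = []
    idx = 0
    for theta_target in theta_grid:
        if theta_target == 0.5:
            spec1, spec2 = cfg["make_pair"](cfg["bracket"][0])
            if abs(true_effect(spec1, spec2) - 0.5) > 1e-12:
                param = solve_effect_parameter(cfg["make_pair"], 0.5, cfg["bracket"])
                spec1, spec2 = cfg["make_pair"](param)
        else:
            param = solve_effect_parameter(cfg["make_pair"], theta_target, cfg["bracket"])
            spec1, spec2 = cfg["make_pair"](param)
        for n1, n2 in sizes:
            scn = ScenarioSpec(
                f"coverage-{setting}-theta{theta_target:g}", spec1, spec2, n1, n2, theta_target
            )
            rng = _child_rng(seed, idx)
            idx += 1
            core = _kernel.batch_core(*_batch_draws(scn, niter, rng))
            n_degen = int(np.sum(core["sigma_n"] == 0.0))
            for method in methods:
                if method == "bm":
                    lo, hi = _kernel.bm_interval_bounds(core, alpha)
                    covered = (lo <= theta_target) & (theta_target <= hi)
                    covered = np.where(np.isnan(lo), False, covered)
                elif method == "c2":
                    lo, hi = _kernel.c2_interval_bounds(core, alpha)
                    covered = (lo <= theta_target) & (theta_target <= hi)
                else:
                    raise ValueError(f"unknown method {method!r}")
                rate = float(np.mean(covered))
                rows.append(
                    {
                        "scenario": scn.name,
                        "setting": setting,
                        "theta": theta_target,
                        "method": method,
                        "level": 1.0 - alpha,
                        "n1": n1,
                        "n2": n2,
                        "rate": rate,
                        "mc_se": _mc_se(rate, niter),
                        "n_degenerate": n_degen,
                    }
                )
    return SimulationResult(pd.DataFrame(rows), niter, seed)
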