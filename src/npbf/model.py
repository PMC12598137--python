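"""Model/results interface for two-sample relative-effect inference.

Follows the fit-then-inspect idiom of statistical modelling packages: a
:class:`MannWhitneyEffectModel` is built from the two samples (or from a
dataframe / frequency table), ``fit()`` runs the requested tests and their
compatible confidence intervals, and the returned
:class:`MannWhitneyEffectResults` carries the estimates, variance
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as ci
from .effect import EffectEstimate, VarianceEstimates, estimate_all
from .hypotheses import TestResult, brunner_munzel_test, c2_test, permutation_test
from .intervals import ConfidenceInterval
from .io import expand_frequency_table, two_sample_from_frame
from .ranks import TwoSampleData

__all__ = ["MannWhitneyEffectModel", "MannWhitneyEffectResults"]

_ALL_TESTS = ("bm", "perm", "c2")


class MannWhitneyEffectModel:
    """Nonparametric Behrens-Fisher model for two independent samples.

    The estimand is the Mann-Whitney effect
    theta = P(X1 < X2) + 0.5 P(X1 = X2), the probability that a draw from
    the second sample's distribution exceeds a draw from the first, ties
    counted half. ``fit`` tests H0: theta = 1/2 with any subset of the
    Brunner-Munzel, studentized permutation and chi-square procedures.
    """

    def __init__(self, sample1, sample2, labels: tuple[str, str] | None = None):
        if isinstance(sample1, TwoSampleData):
            self.data = sample1
        else:
            self.data = TwoSampleData(
                np.asarray(sample1, dtype=float),
                np.asarray(sample2, dtype=float),
                labels or ("sample1", "sample2"),
            )

    @classmethod
    def from_data(cls, data: TwoSampleData) -> "MannWhitneyEffectModel":
        return cls(data, None)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str = "value",
        group_col: str = "group",
        direction: str = "g1-first",
        decimals: int | None = None,
    ) -> "MannWhitneyEffectModel":
        return cls(two_sample_from_frame(df, value_col, group_col, direction, decimals), None)

    @classmethod
    def from_frequency_table(
        cls, table: pd.DataFrame, direction: str = "g1-first"
    ) -> "MannWhitneyEffectModel":
        return cls(expand_frequency_table(table, direction), None)

    def fit(
        self,
        tests: tuple[str, ...] | str = "all",
        alpha: float = 0.05,
        n_permutations: int = 10_000,
        seed: int | None = 20_000,
        p_rule: str = "plain",
    ) -> "MannWhitneyEffectResults":
        if tests == "all":
            tests = _ALL_TESTS
        elif isinstance(tests, str):
            tests = (tests,)
        unknown = set(tests) - set(_ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}; choose from {_ALL_TESTS}")
        data = self.data
        effect, variances = estimate_all(data)
        test_results: dict[str, TestResult] = {}
        interval_results: dict[str, ConfidenceInterval] = {}
        degenerate_notes: list[str] = []
        if "bm" in tests:
            test_results["bm"] = brunner_munzel_test(data, alpha)
            if variances.v_dl_sq > 0:
                interval_results["bm"] = ci.bm_interval(data, alpha)
            else:
                degenerate_notes.append("bm interval undefined (v_dl^2 = 0)")
        if "perm" in tests:
            test_results["perm"] = permutation_test(
                data, alpha, n_permutations, seed, p_rule
            )
            if variances.v_dl_sq > 0:
                interval_results["perm"] = ci.permutation_interval(
                    data, alpha, n_permutations, seed
                )
            else:
                degenerate_notes.append("permutation interval undefined (v_dl^2 = 0)")
        if "c2" in tests:
            test_results["c2"] = c2_test(data, alpha)
            interval_results["c2"] = ci.c2_interval(data, alpha)
        return MannWhitneyEffectResults(
            model=self,
            effect=effect,
            variances=variances,
            tests=test_results,
            intervals=interval_results,
            alpha=alpha,
            n_permutations=n_permutations,
            seed=seed,
            p_rule=p_rule,
            notes=degenerate_notes,
        )


@dataclass
class MannWhitneyEffectResults:
    """Fitted results: effect estimate, variances, tests and intervals."""

    model: MannWhitneyEffectModel
    effect: EffectEstimate
    variances: VarianceEstimates
    tests: dict[str, TestResult]
    intervals: dict[str, ConfidenceInterval]
    alpha: float
    n_permutations: int
    seed: int | None
    p_rule: str
    notes: list[str] = field(default_factory=list)

    @property
    def theta_hat(self) -> float:
        return self.effect.theta_hat

    @property
    def tie_fraction(self) -> float:
        return self.variances.tau_hat

    def conf_int(self, method: str = "c2") -> tuple[float, float]:
        interval = self.intervals[method]
        return interval.lower, interval.upper

    def to_dict(self) -> dict:
        """Losslessly JSON-serializable report of every quantity."""
        data = self.model.data
        return {
            "data": {
                "labels": list(data.labels),
                "n1": data.n1,
                "n2": data.n2,
                "N": data.N,
                "tie_fraction": self.variances.tau_hat,
            },
            "theta_hat": self.effect.theta_hat,
            "variances": {
                "sigma1_sq": self.variances.sigma1_sq,
                "sigma2_sq": self.variances.sigma2_sq,
                "v_dl_sq": self.variances.v_dl_sq,
                "sigma_n_sq": self.variances.sigma_n_sq,
                "N_sigma_n_sq": data.N * self.variances.sigma_n_sq,
                "tau_hat": self.variances.tau_hat,
                "q_hat": self.variances.q_hat,
                "r_hat": self.variances.r_hat,
                "separated": self.variances.separated,
                "degenerate": self.variances.degenerate_variance,
            },
            "tests": {
                name: {
                    "method": t.method,
                    "statistic": t.statistic,
                    "df": t.df,
                    "p_value": t.p_value,
                    "reject": t.reject,
                    "reference": t.reference,
                    "degenerate": t.degenerate,
                }
                for name, t in self.tests.items()
            },
            "intervals": {
                name: {
                    "method": iv.method,
                    "lower": iv.lower,
                    "upper": iv.upper,
                    "level": iv.level,
                    "range_preserving": iv.range_preserving,
                    "compatible_test": iv.compatible_test,
                }
                for name, iv in self.intervals.items()
            },
            "settings": {
                "alpha": self.alpha,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "p_rule": self.p_rule,
            },
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=kwargs.pop("indent", 2), **kwargs)

    _NAMES = {"bm": "Brunner-Munzel", "perm": "Permutation", "c2": "C2"}

    def summary(self) -> str:
        """Human-readable report: variances to 3 d.p., p-values to 4 d.p.,
        interval bounds to 2 d.p. (full precision via ``to_dict``)."""
        data = self.model.data
        v = self.variances
        lines = [
            "Two-sample Mann-Whitney effect analysis",
            "=" * 55,
            f"Samples: {data.labels[0]} (n1={data.n1}) vs {data.labels[1]} (n2={data.n2})",
            f"theta = P({data.labels[0]} < {data.labels[1]}) + 0.5 P(equal)",
            f"theta_hat = {self.effect.theta_hat:.4f}   tie fraction = {v.tau_hat:.4f}",
            "",
            f"Variance estimates:  v_DL^2 = {v.v_dl_sq:.3f}   "
            f"N*sigma_N^2 = {data.N * v.sigma_n_sq:.3f}",
            "",
            f"{'Test':<16}{'statistic':>10}{'p-value':>9}  "
            f"{'reject':<7}{int(round((1-self.alpha)*100))}% CI",
        ]
        for name, t in self.tests.items():
            interval = self.intervals.get(name)
            ci_txt = f"[{interval.lower:.2f}, {interval.upper:.2f}]" if interval else "undefined"
            lines.append(
                f"{self._NAMES[name]:<16}{t.statistic:>10.4f}{t.p_value:>9.4f}  "
                f"{'yes' if t.reject else 'no':<7}{ci_txt}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)
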