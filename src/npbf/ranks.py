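"""Rank decompositions for two independent samples.

Every estimator and test in this package is a function of mid-, min- and
max-ranks taken over the pooled sample and within each sample separately.
The *placement* of an observation — its overall rank minus its within-sample
rank — counts, with ties weighted one half, how many observations of the
other sample it exceeds; placements are the building block of both the
Mann-Whitney effect estimator and the variance estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "TwoSampleData",
    "RankDecomposition",
    "midranks",
    "min_max_ranks",
    "decompose",
]


def _validate_values(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-d vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class TwoSampleData:
    """Two independent samples X_1k ~ F1 (k=1..n1) and X_2k ~ F2 (k=1..n2).

    The Mann-Whitney effect theta = P(X1 < X2) + 0.5*P(X1 = X2) is read as
    the tendency of ``sample2`` toward larger values than ``sample1``.
    Callers that need the opposite orientation swap the samples (see the
    ``direction`` argument of the readers in :mod:`npbf.io`).
    """

    sample1: np.ndarray
    sample2: np.ndarray
    labels: tuple[str, str] = ("sample1", "sample2")

    def __post_init__(self):
        object.__setattr__(self, "sample1", _validate_values(self.sample1, "sample1"))
        object.__setattr__(self, "sample2", _validate_values(self.sample2, "sample2"))
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                "each sample needs at least two observations "
                f"(got n1={self.n1}, n2={self.n2})"
            )

    @property
    def n1(self) -> int:
        return self.sample1.size

    @property
    def n2(self) -> int:
        return self.sample2.size

    @property
    def N(self) -> int:
        return self.n1 + self.n2

    @property
    def m(self) -> int:
        """Smaller of the two sample sizes (enters the variance bound)."""
        return min(self.n1, self.n2)

    def swapped(self) -> "TwoSampleData":
        """Same data with the roles of the samples exchanged."""
        return TwoSampleData(self.sample2, self.sample1, (self.labels[1], self.labels[0]))

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.sample1, self.sample2])


def midranks(values) -> np.ndarray:
    """Midranks of ``values``: tied observations share the average of the
    positions they occupy. Sums to n(n+1)/2."""
    return rankdata(_validate_values(values), method="average")


def min_max_ranks(values) -> tuple[np.ndarray, np.ndarray]:
    """Minimum and maximum ranks.

    min-rank(x) = 1 + #{values strictly below x}; max-rank(x) = #{values <= x};
    the midrank is their average.
    """
    arr = _validate_values(values)
    return rankdata(arr, method="min").astype(float), rankdata(arr, method="max").astype(float)


@dataclass(frozen=True)
class RankDecomposition:
    """All rank quantities for a two-sample dataset.

    ``overall_*`` ranks are taken among all N pooled observations,
    ``internal_*`` ranks within the own sample only; ``placements`` are
    overall midrank minus internal midrank, one vector per sample.
    """

    data: TwoSampleData
    overall_mid: tuple[np.ndarray, np.ndarray]
    internal_mid: tuple[np.ndarray, np.ndarray]
    overall_min: tuple[np.ndarray, np.ndarray]
    overall_max: tuple[np.ndarray, np.ndarray]
    internal_min: tuple[np.ndarray, np.ndarray]
    internal_max: tuple[np.ndarray, np.ndarray]
    placements: tuple[np.ndarray, np.ndarray] = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "placements",
            tuple(self.overall_mid[i] - self.internal_mid[i] for i in (0, 1)),
        )

    # per-sample means used throughout the formulas
    def rank_mean(self, i: int) -> float:
        return float(self.overall_mid[i].mean())

    def placement_mean(self, i: int) -> float:
        return float(self.placements[i].mean())


def decompose(data: TwoSampleData) -> RankDecomposition:
    """Compute every rank quantity the estimators consume, in one pass."""
    pooled = data.pooled
    n1 = data.n1

    def split(v):
        return v[:n1], v[n1:]

    r_mid = rankdata(pooled, method="average")
    r_min = rankdata(pooled, method="min").astype(float)
    r_max = rankdata(pooled, method="max").astype(float)

    return RankDecomposition(
        data=data,
        overall_mid=split(r_mid),
        internal_mid=(midranks(data.sample1), midranks(data.sample2)),
        overall_min=split(r_min),
        overall_max=split(r_max),
        internal_min=(
            rankdata(data.sample1, method="min").astype(float),
            rankdata(data.sample2, method="min").astype(float),
        ),
        internal_max=(
            rankdata(data.sample1, method="max").astype(float),
            rankdata(data.sample2, method="max").astype(float),
        ),
    )
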