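"""Reading two-sample data from delimited text files.

Two layouts are supported: *long format* (one row per observation, a value
column and a group column) and a *frequency table* (rows = groups, columns =
ordered categories, cells = counts). The ``direction`` flag controls which
group becomes the first sample: theta always measures the tendency of the
second sample toward larger values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ranks import TwoSampleData

__all__ = ["read_long_format", "read_frequency_table", "two_sample_from_frame"]


def _order_groups(groups: list, direction: str) -> list:
    if direction not in ("g1-first", "g2-first"):
        raise ValueError("direction must be 'g1-first' or 'g2-first'")
    return groups if direction == "g1-first" else groups[::-1]


def two_sample_from_frame(
    df: pd.DataFrame,
    value_col: str,
    group_col: str,
    direction: str = "g1-first",
    decimals: int | None = None,
) -> TwoSampleData:
    """Build :class:`TwoSampleData` from a long-format dataframe.

    Groups are ordered by first appearance; ``direction='g2-first'`` swaps
    them. ``decimals`` optionally rounds values before ranking, for data
    where ties are meaningful only to a stated precision (ordinal codes are
    exact integers, so the default is no rounding).
    """
    for col in (value_col, group_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found")
    groups = list(pd.unique(df[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(groups)}: {groups}")
    values = pd.to_numeric(df[value_col], errors="raise").to_numpy(dtype=float)
    if decimals is not None:
        values = np.round(values, decimals)
    g_first, g_second = _order_groups(groups, direction)
    s1 = values[(df[group_col] == g_first).to_numpy()]
    s2 = values[(df[group_col] == g_second).to_numpy()]
    return TwoSampleData(s1, s2, (str(g_first), str(g_second)))


def read_long_format(
    path: str | Path,
    value_col: str = "value",
    group_col: str = "group",
    direction: str = "g1-first",
    decimals: int | None = None,
    sep: str | None = None,
) -> TwoSampleData:
    """Read a delimited long-format file (CSV or TSV, sniffed by default)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return two_sample_from_frame(df, value_col, group_col, direction, decimals)


def read_frequency_table(
    path: str | Path,
    direction: str = "g1-first",
    sep: str | None = None,
) -> TwoSampleData:
    """Read a group-by-category count table.

    First column: group label; remaining columns: ordered categories whose
    headers are used as the ordinal codes (must be numeric). Counts are
    expanded into observation vectors.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    return expand_frequency_table(df, direction)


def expand_frequency_table(df: pd.DataFrame, direction: str = "g1-first") -> TwoSampleData:
    if df.shape[0] != 2:
        raise ValueError(f"expected exactly 2 group rows, found {df.shape[0]}")
    try:
        codes = np.asarray([float(c) for c in df.columns])
    except (TypeError, ValueError) as exc:
        raise ValueError("category headers must be numeric ordinal codes") from exc
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("cell counts must be non-negative integers")
    rows = list(df.index)
    order = _order_groups([0, 1], direction)
    samples = []
    for i in order:
        sample = np.repeat(codes, counts[i].astype(int))
        if sample.size < 2:
            raise ValueError(f"group {rows[i]!r} has fewer than 2 observations")
        samples.append(sample)
    return TwoSampleData(samples[0], samples[1], (str(rows[order[0]]), str(rows[order[1]])))
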