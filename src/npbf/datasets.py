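"""Built-in example datasets.

``shoulder_pain`` is the shoulder-tip-pain trial of Jorgensen et al. (1995),
as reported by Lumley (1996): 41 laparoscopic-surgery patients randomized to
a specific air-suction procedure (n=22) or standard care (n=19), pain scored
on a 5-point ordinal scale (1 = no pain ... 5 = severe pain) on the evening
of post-operative day 2. A standard benchmark for rank methods with heavy
ties.

``illustrative_outcomes`` is a small 17-observation metric dataset (10 + 7)
whose effect estimate of 0.8 makes the non-range-preserving behaviour of the
t-inversion interval visible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ranks import TwoSampleData

__all__ = ["shoulder_pain", "shoulder_pain_frequencies", "illustrative_outcomes"]

# category counts per pain score 1..5
_SUCTION = {1: 16, 2: 5, 3: 0, 4: 1, 5: 0}
_CONTROL = {1: 4, 2: 1, 3: 5, 4: 7, 5: 2}

_GROUP1_OUTCOMES = (1956, 3828, 2051, 3721, 3233, 2000, 4000, 4428, 2603, 2370)
_GROUP2_OUTCOMES = (820, 3364, 1957, 1851, 2984, 744, 2044)


def _expand(counts: dict[int, int]) -> np.ndarray:
    return np.repeat(list(counts.keys()), list(counts.values())).astype(float)


def shoulder_pain_frequencies() -> pd.DataFrame:
    """Score-by-group frequency table (rows: treatment arms, columns 1..5)."""
    return pd.DataFrame(
        [list(_SUCTION.values()), list(_CONTROL.values())],
        index=["suction", "control"],
        columns=[1, 2, 3, 4, 5],
    )


def shoulder_pain(treatment_first: bool = True) -> TwoSampleData:
    """Shoulder-tip-pain scores as a two-sample dataset.

    With ``treatment_first`` (default) the suction arm is the first sample,
    so theta measures the tendency of control scores to exceed treatment
    scores — i.e. theta > 1/2 means the suction procedure reduces pain.
    """
    suction, control = _expand(_SUCTION), _expand(_CONTROL)
    if treatment_first:
        return TwoSampleData(suction, control, ("suction", "control"))
    return TwoSampleData(control, suction, ("control", "suction"))


def illustrative_outcomes(group1_second: bool = True) -> TwoSampleData:
    """17-value metric dataset in two groups of 10 and 7.

    With ``group1_second`` (default) the 7-value group is the first sample,
    so theta measures the tendency of the 10-value group toward larger
    outcomes (theta_hat = 0.8).
    """
    g1 = np.asarray(_GROUP1_OUTCOMES, dtype=float)
    g2 = np.asarray(_GROUP2_OUTCOMES, dtype=float)
    if group1_second:
        return TwoSampleData(g2, g1, ("group2", "group1"))
    return TwoSampleData(g1, g2, ("group1", "group2"))
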