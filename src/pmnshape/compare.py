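"""Two-group and before/after statistical comparison of measure batteries.

Each measure is compared between groups with a pooled-variance two-sample
t statistic on the per-cell values, df = n1 + n2 - 2 (adjusted downward when
a measure is missing for some cells: the comparison then runs on the
available subsets, flagged in the output).  The default p-value is
one-tailed in the direction of the observed difference, p = sf(|t|, df)
(t = 0 gives p = 0.5); two-tailed and fixed-direction tails are available.
No multiple-testing correction is applied across the measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientGroupError
from .measures import MEASURE_ORDER, MeasureSet, measure_battery
from .series import RSeries

#: directions of the significant measure contrasts for an
#: idling -> treadmilling change: SD up, Skew up, Lambda1 down, alpha down
SIGNIFICANT_DIRECTIONS = {"sd": +1, "skew": +1, "lambda1": -1, "alpha": -1}


@dataclass
class MeasureComparison:
    measure: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: int
    p: float
    adjusted: bool   # True when missing values reduced the df


@dataclass
class GroupComparison:
    """Per-measure pooled-variance t comparison of two groups of cells."""

    rows: list
    n1: int
    n2: int
    tail: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def row(self, measure: str) -> MeasureComparison:
        for r in self.rows:
            if r.measure == measure:
                return r
        raise KeyError(measure)


def pooled_t(a: np.ndarray, b: np.ndarray):
    """Pooled-variance two-sample t statistic (b - a) and its df."""
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = (b.mean() - a.mean()) / se if se > 0 else 0.0
    return float(t), int(df)


def _pvalue(t: float, df: int, tail: str) -> float:
    if tail == "observed":
        return float(stats.t.sf(abs(t), df))
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    if tail == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    raise ValueError(f"unknown tail {tail!r}")


def compare_groups(a: Sequence[MeasureSet], b: Sequence[MeasureSet],
                   tail: str = "observed",
                   measures: Sequence[str] = MEASURE_ORDER) -> GroupComparison:
    """Compare two groups of measure batteries measure by measure.

    ``a`` and ``b`` are sequences of :class:`MeasureSet` (e.g., 10 idling
    and 10 treadmilling cells, giving df = 18 per fully-present measure).
    Missing measures are compared on the available subsets with adjusted df.
    The reported t is signed as (mean of b) - (mean of a).
    """
    if len(a) < 2 or len(b) < 2:
        raise InsufficientGroupError("need at least 2 cells per group")
    rows = []
    for m in measures:
        va = np.array([s.get(m) for s in a if s.get(m) is not None], float)
        vb = np.array([s.get(m) for s in b if s.get(m) is not None], float)
        if len(va) < 2 or len(vb) < 2:
            raise InsufficientGroupError(
                f"measure {m!r} present in fewer than 2 cells per group")
        t, df = pooled_t(va, vb)
        rows.append(MeasureComparison(
            measure=m, mean_a=float(va.mean()), sd_a=float(va.std(ddof=1)),
            n_a=len(va), mean_b=float(vb.mean()), sd_b=float(vb.std(ddof=1)),
            n_b=len(vb), t=t, df=df, p=_pvalue(t, df, tail),
            adjusted=(len(va) < len(a) or len(vb) < len(b))))
    return GroupComparison(rows=rows, n1=len(a), n2=len(b), tail=tail)


@dataclass
class BeforeAfter:
    """Single-cell pre/post state-change comparison."""

    before: MeasureSet
    after: MeasureSet
    deltas: dict = field(default_factory=dict)
    direction_match: dict = field(default_factory=dict)


def before_after(series: RSeries, split_index: int,
                 min_segment: int = 100) -> BeforeAfter:
    """Measure battery before and after a split point of one series.

    Reports signed per-measure deltas (after - before) and whether each
    delta's direction matches the significant idling -> treadmilling
    contrasts (SD up, Skew up, Lambda1 down, alpha down).
    """
    n = series.n
    if split_index < min_segment or n - split_index < min_segment:
        raise ValueError(
            f"both segments must have at least {min_segment} samples")
    pre = measure_battery(series.segment(0, split_index))
    post = measure_battery(series.segment(split_index, n))
    deltas = {}
    match = {}
    for m in MEASURE_ORDER:
        va, vb = pre.get(m), post.get(m)
        if va is None or vb is None:
            continue
        deltas[m] = vb - va
        if m in SIGNIFICANT_DIRECTIONS:
            match[m] = (deltas[m] * SIGNIFICANT_DIRECTIONS[m]) > 0
    return BeforeAfter(before=pre, after=post, deltas=deltas,
                       direction_match=match)
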