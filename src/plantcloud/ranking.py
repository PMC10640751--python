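"""Rank-based comparison of down-sampling strategies.

Given a strategies × metrics table (values in %), two summaries are
computed per strategy:

* **Score** — per metric column the strategies are ranked descending and
  the top three receive points: 3/2/1 for the non-comprehensive metrics
  (Precision, Recall, mPrec, mRec) and 6/4/2 for the comprehensive ones
  (F1, IoU, Cov, WCov). A strategy's Score is the sum over columns; the
  maximum is 18 in semantic mode (4 metrics) and 36 in dual mode
  (8 metrics).
* **AveDiff** — the mean, over metric columns, of the column best minus
  the strategy's value, in percentage points; 0 for a strategy that is
  best everywhere. Lower is better.

Values tied at the table's printed precision share the arithmetic mean of
the points of the positions they span ("average" policy); a "first" policy
(earlier row wins) is available for tables whose ties were resolved on
unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "SEMANTIC_METRICS",
    "DUAL_METRICS",
    "MINOR_POINTS",
    "MAJOR_POINTS",
    "StrategyMetricsTable",
    "ScoreCard",
    "rank_points",
    "score_table",
    "avediff",
    "scorecard",
    "read_metrics_csv",
    "write_scorecard_csv",
]

SEMANTIC_METRICS = ("Precision", "Recall", "F1", "IoU")
DUAL_METRICS = SEMANTIC_METRICS + ("Cov", "WCov", "mPrec", "mRec")

_MINOR = {"Precision", "Recall", "mPrec", "mRec"}
_MAJOR = {"F1", "IoU", "Cov", "WCov"}
MINOR_POINTS = (3.0, 2.0, 1.0)
MAJOR_POINTS = (6.0, 4.0, 2.0)


def metric_weight_class(metric: str) -> str:
    if metric in _MINOR:
        return "minor"
    if metric in _MAJOR:
        return "major"
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class StrategyMetricsTable:
    """Strategies × metrics matrix of percentages.

    ``values`` is a DataFrame indexed by strategy name with metric columns
    that must be exactly the semantic four or the dual eight, in order.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = tuple(self.values.columns)
        if cols not in (SEMANTIC_METRICS, DUAL_METRICS):
            raise ValueError(
                f"metric columns must be {SEMANTIC_METRICS} or "
                f"{DUAL_METRICS}, got {cols}"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("metric values must be finite")

    @classmethod
    def from_dict(cls, rows: dict, metrics=None) -> "StrategyMetricsTable":
        """Build from ``{strategy: [values...]}`` (dual mode inferred from
        row length when ``metrics`` is not given)."""
        if metrics is None:
            width = len(next(iter(rows.values())))
            metrics = SEMANTIC_METRICS if width == 4 else DUAL_METRICS
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=list(metrics)
        ).astype(float)
        return cls(values=df)

    @property
    def mode(self) -> str:
        return "semantic" if len(self.values.columns) == 4 else "dual"

    @property
    def strategies(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ScoreCard:
    """Per-strategy Score and AveDiff (percentage points)."""

    score: pd.Series
    avediff: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Score": self.score, "AveDiff": self.avediff})


def rank_points(
    column, weight_class: str, tie: str = "average"
) -> np.ndarray:
    """Points for one metric column (higher value is better).

    Positions 1–3 in descending order receive (3, 2, 1) for ``"minor"``
    columns or (6, 4, 2) for ``"major"``; later positions 0. With
    ``tie="average"``, equal values share the mean of the points of the
    positions they span; ``tie="first"`` gives earlier rows the higher
    points.
    """
    values = np.asarray(column, dtype=float)
    base = MINOR_POINTS if weight_class == "minor" else MAJOR_POINTS
    if weight_class not in ("minor", "major"):
        raise ValueError("weight_class must be 'minor' or 'major'")
    slots = np.zeros(len(values))
    slots[: min(3, len(values))] = base[: min(3, len(values))]
    order = np.argsort(-values, kind="stable")
    points = np.zeros(len(values))
    if tie == "first":
        points[order] = slots
        return points
    if tie != "average":
        raise ValueError("tie must be 'average' or 'first'")
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        points[order[i:j + 1]] = slots[i:j + 1].mean()
        i = j + 1
    return points


def score_table(
    table: StrategyMetricsTable, tie: str = "average"
) -> pd.Series:
    """Total Score per strategy: rank points summed over metric columns."""
    total = np.zeros(len(table.strategies))
    for metric in table.values.columns:
        total += rank_points(
            table.values[metric].to_numpy(),
            metric_weight_class(metric),
            tie=tie,
        )
    return pd.Series(total, index=table.values.index, name="Score")


def avediff(table: StrategyMetricsTable, decimals: int | None = 2):
    """Mean shortfall from the per-metric best, in percentage points.

    Rounded half-to-even to ``decimals`` places (None disables rounding).
    """
    vals = table.values
    diffs = vals.max(axis=0) - vals
    out = diffs.mean(axis=1)
    if decimals is not None:
        out = out.round(decimals)
    return out.rename("AveDiff")


def scorecard(table: StrategyMetricsTable, tie: str = "average") -> ScoreCard:
    return ScoreCard(score=score_table(table, tie=tie), avediff=avediff(table))


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_metrics_csv(path: str | Path) -> StrategyMetricsTable:
    """Read ``strategy,Precision,Recall,F1,IoU[,Cov,WCov,mPrec,mRec]``."""
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "strategy":
        raise FormatError(f"{path}: first column must be 'strategy', got "
                          f"{df.columns[0]!r}")
    cols = tuple(df.columns[1:])
    if cols not in (SEMANTIC_METRICS, DUAL_METRICS):
        raise FormatError(
            f"{path}: metric columns must be {list(SEMANTIC_METRICS)} or "
            f"{list(DUAL_METRICS)}, got {list(cols)}"
        )
    df = df.set_index("strategy")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric metric cell ({exc})") from exc
    return StrategyMetricsTable(values=df)


def write_scorecard_csv(card: ScoreCard, path: str | Path) -> None:
    frame = card.to_frame()
    frame.index.name = "strategy"
    frame.to_csv(path, float_format="%.2f")
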