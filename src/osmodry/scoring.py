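"""Multi-criteria standard-score ranking of experimental runs.

Each response column is a criterion with a direction: for a *benefit*
criterion larger is better and the min-max normalized score is
``(x - min) / (max - min)``; for a *cost* criterion smaller is better and
the score is ``(max - x) / (max - min)``.  A run's standard score ``SS`` is
the arithmetic mean of its normalized criterion scores, so ``SS`` lies in
[0, 1] and approaches 1 as the run approaches the per-criterion optima
simultaneously.  Runs are ranked by descending ``SS``.

By default the antioxidant IC50s (``DPPH``, ``ABTS``) and ``acidity`` are
cost criteria -- a lower IC50 means a stronger antioxidant -- and every
other response is a benefit criterion.  Directions are user-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import RESPONSES, DesignTable

__all__ = [
    "Direction",
    "CriterionSpec",
    "ScoreTable",
    "DEFAULT_DIRECTIONS",
    "default_criteria",
    "normalize_criterion",
    "standard_scores",
]

Direction = Literal["benefit", "cost"]

#: Default direction per response of the reference experiment.
DEFAULT_DIRECTIONS: dict[str, Direction] = {
    name: ("cost" if name in ("DPPH", "ABTS", "acidity") else "benefit")
    for name in RESPONSES
}


@dataclass(frozen=True)
class CriterionSpec:
    """One ranking criterion: a response column and its direction."""

    name: str
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost"):
            raise ValueError(f"direction must be 'benefit' or 'cost', got {self.direction!r}")


def default_criteria(overrides: dict[str, Direction] | None = None) -> list[CriterionSpec]:
    """The 13 default criteria, optionally with per-column direction overrides."""
    directions = dict(DEFAULT_DIRECTIONS)
    for name, direction in (overrides or {}).items():
        if name not in directions:
            raise KeyError(f"unknown criterion column {name!r}")
        directions[name] = direction
    return [CriterionSpec(name, directions[name]) for name in RESPONSES]


@dataclass(frozen=True)
class ScoreTable:
    """Normalized criterion scores, per-run standard scores and the ranking."""

    scores: pd.DataFrame   # runs x criteria, each column min-max normalized
    ss: pd.Series          # per-run standard score (mean of the row's scores)
    ranking: list[int]     # run ids, best first

    @property
    def best_run(self) -> int:
        return self.ranking[0]


def normalize_criterion(values: Sequence[float] | np.ndarray,
                        direction: Direction) -> np.ndarray:
    """Min-max normalize one criterion column to [0, 1].

    A constant column carries no ranking information; it is scored 0.5
    everywhere with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("a criterion needs at least 2 values")
    if direction not in ("benefit", "cost"):
        raise ValueError(f"direction must be 'benefit' or 'cost', got {direction!r}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant criterion column; scoring all runs 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    score = (x - lo) / (hi - lo)
    return 1.0 - score if direction == "cost" else score


def standard_scores(table: DesignTable,
                    criteria: Iterable[CriterionSpec] | None = None) -> ScoreTable:
    """Score and rank all runs of a design table.

    Ties in ``SS`` are broken by ascending run id, with a warning.
    """
    criteria = list(criteria) if criteria is not None else default_criteria()
    responses = table.responses()
    unknown = [c.name for c in criteria if c.name not in responses.columns]
    if unknown:
        raise KeyError(f"unknown criterion column(s): {unknown}")

    scores = pd.DataFrame(
        {c.name: normalize_criterion(responses[c.name].to_numpy(), c.direction)
         for c in criteria},
        index=responses.index,
    )
    ss = scores.mean(axis=1)
    ss.name = "SS"

    order = np.lexsort((ss.index.to_numpy(), -ss.to_numpy()))
    ranked_ss = ss.to_numpy()[order]
    if np.any(np.isclose(ranked_ss[:-1], ranked_ss[1:], rtol=0, atol=1e-12)):
        warnings.warn("tied standard scores; ties broken by ascending run id", stacklevel=2)
    ranking = [int(ss.index[i]) for i in order]
    return ScoreTable(scores=scores, ss=ss, ranking=ranking)
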