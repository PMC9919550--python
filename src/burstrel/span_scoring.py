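"""Partial-credit scoring of complex-span trials and session-level scores.

Complex span tasks interleave to-be-remembered items (letters, locations,
oriented arrows) with a processing judgment; recall is in serial order.
Partial-credit ("partial-trial", or load) scoring credits each item recalled
regardless of whether the whole trial was recalled, which preserves
measurement precision when only 2-3 trials are administered per session.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import BurstDataset
from .exceptions import DegenerateScaleError, RowValidationError

logger = logging.getLogger(__name__)

SESSION_KEY = ["person_id", "session_index", "day_index", "task"]


@dataclass
class SessionScore:
    """Sum of trial scores within one (person, session, task) block."""

    person_id: str
    session_index: int
    day_index: int
    task: str
    span_score: float
    max_possible: int


@dataclass
class CompositeScore:
    """Mean of per-task z-scores within one (person, session)."""

    person_id: str
    session_index: int
    composite: float
    tasks_included: tuple


def score_trial(
    presented: Sequence[str], recalled: Sequence[str], credit: str = "position"
) -> int:
    """Partial-credit score of one trial.

    credit="position" (default): an item is credited only when recalled in its
    correct serial position.  credit="free": items are credited wherever they
    appear in the response (multiset intersection), ignoring order.
    """
    presented = list(presented)
    recalled = list(recalled)
    if len(recalled) > len(presented):
        raise RowValidationError(
            f"recalled ({len(recalled)} items) longer than presented ({len(presented)})"
        )
    if credit == "position":
        return sum(p == r for p, r in zip(presented, recalled))
    if credit == "free":
        return sum((Counter(presented) & Counter(recalled)).values())
    raise ValueError(f"unknown credit rule: {credit!r}")


def score_sessions(data: BurstDataset) -> pd.DataFrame:
    """Sum trial scores within each (person, session, task) block.

    Returns a frame with columns
    ``person_id, session_index, day_index, task, span_score, max_possible``.
    """
    f = data.frame
    g = f.groupby(SESSION_KEY, as_index=False).agg(
        span_score=("trial_score", "sum"), max_possible=("set_size", "sum")
    )
    return g.sort_values(SESSION_KEY).reset_index(drop=True)


def drop_lowest_set_size(data: BurstDataset) -> BurstDataset:
    """Remove each session x task block's minimum set-size trials.

    Blocks with a single distinct set size are passed through unchanged (with
    a logged warning): there is nothing meaningful to drop.
    """
    f = data.frame
    grp = f.groupby(["person_id", "session_index", "task"])["set_size"]
    lo = grp.transform("min")
    n_distinct = grp.transform("nunique")
    degenerate = int((n_distinct == 1).groupby(
        [f["person_id"], f["session_index"], f["task"]]).first().sum()) \
        if len(f) else 0
    if degenerate:
        logger.warning(
            "drop_lowest_set_size: %d block(s) have a single set size; left unchanged",
            degenerate,
        )
    keep = (f["set_size"] > lo) | (n_distinct == 1)
    return data.subset(keep)


def composite_wmc(
    scores: pd.DataFrame,
    tasks: Sequence[str] | None = None,
    z_reference: str = "pooled",
    require_all_tasks: bool = True,
) -> pd.DataFrame:
    """Composite working-memory score: mean of per-task z-scores per session.

    Parameters
    ----------
    scores
        Session-score frame from :func:`score_sessions`.
    tasks
        Tasks entering the composite (default: all tasks present).
    z_reference
        Standardization pool per task: ``"pooled"`` standardizes against all
        person-sessions; ``"person_mean"`` against the distribution of person
        means.
    require_all_tasks
        If True (default) a session yields a composite only when every
        configured task is present in that session; otherwise the available
        tasks are averaged.

    Returns a frame ``person_id, session_index, day_index, composite, n_tasks``.
    """
    tasks = list(tasks) if tasks is not None else sorted(scores["task"].unique())
    sub = scores[scores["task"].isin(tasks)].copy()

    zparts = []
    for task, g in sub.groupby("task"):
        if z_reference == "pooled":
            mu, sd = g["span_score"].mean(), g["span_score"].std(ddof=1)
        elif z_reference == "person_mean":
            pm = g.groupby("person_id")["span_score"].mean()
            mu, sd = pm.mean(), pm.std(ddof=1)
        else:
            raise ValueError(f"unknown z_reference: {z_reference!r}")
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateScaleError(f"task {task!r} has zero score variance")
        g = g.copy()
        g["z"] = (g["span_score"] - mu) / sd
        zparts.append(g)
    z = pd.concat(zparts, ignore_index=True)

    comp = z.groupby(["person_id", "session_index", "day_index"], as_index=False).agg(
        composite=("z", "mean"), n_tasks=("z", "size")
    )
    if require_all_tasks:
        comp = comp[comp["n_tasks"] == len(tasks)]
    return comp.sort_values(["person_id", "session_index"]).reset_index(drop=True)
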