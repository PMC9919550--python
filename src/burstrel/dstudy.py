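"""Decision-study reliability coefficients for measurement-burst designs.

Given G-study variance components, a Decision study projects the reliability
of scores aggregated over a design with ``m`` item administrations per
occasion and ``k`` occasions:

* between-person reliability (consistency of persons' burst means),

    R_BP = (s2_p + s2_pi/m) / (s2_p + s2_pi/m + s2_po/k + s2_e/(m k))

* within-person reliability of change (ability to detect systematic
  occasion-to-occasion change within a person),

    R_WP = s2_po / (s2_po + s2_e/m).

At the momentary timescale an occasion is a session and m counts the items
(tasks or trials) per session; at the daily timescale an occasion is a day
and m counts all item administrations across the day's sessions.
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import BurstDataset, first_k_sessions
from .exceptions import DesignError, UndefinedReliabilityError
from .gstudy import VarianceComponents, build_cells, estimate_components
from .span_scoring import composite_wmc, score_sessions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DStudyDesign:
    """Facet counts for a Decision study.

    m: item administrations per occasion (tasks or trials per session, or
    items x sessions per day at the daily level); k: number of occasions.
    """

    m: int
    k: int
    occasion_level: str = "session"

    def __post_init__(self):
        if self.m < 1 or self.k < 1:
            raise ValueError(f"m and k must be >= 1, got m={self.m}, k={self.k}")


@dataclass
class ReliabilityResult:
    r_bp: float
    r_wp: float
    design: DStudyDesign
    components_used: VarianceComponents


def r_within(vc: VarianceComponents, m: int) -> float:
    """Within-person reliability of change for m items per occasion."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    num = vc.sigma2_po
    den = num + vc.sigma2_e / m
    if den == 0:
        raise UndefinedReliabilityError(
            "sigma2_po + sigma2_e/m = 0: within-person reliability undefined"
        )
    return num / den


def r_between(vc: VarianceComponents, design: DStudyDesign | None = None,
              m: int | None = None, k: int | None = None) -> float:
    """Between-person reliability for m items per occasion over k occasions."""
    if design is None:
        design = DStudyDesign(m=m, k=k)
    m, k = design.m, design.k
    num = vc.sigma2_p + vc.sigma2_pi / m
    den = num + vc.sigma2_po / k + vc.sigma2_e / (m * k)
    if den == 0:
        raise UndefinedReliabilityError("zero denominator: between-person reliability undefined")
    return num / den


def reliability(vc: VarianceComponents, design: DStudyDesign) -> ReliabilityResult:
    return ReliabilityResult(
        r_bp=r_between(vc, design),
        r_wp=r_within(vc, design.m),
        design=design,
        components_used=vc,
    )


def projection(
    vc: VarianceComponents,
    m_grid: Sequence[int],
    k_grid: Sequence[int],
) -> pd.DataFrame:
    """Pure D-study projection of both coefficients over a design grid.

    Components are not re-estimated; rows are (m, k, r_bp, r_wp), with r_wp
    depending on m only.
    """
    m_grid = list(m_grid)
    k_grid = list(k_grid)
    if not m_grid or not k_grid:
        raise ValueError("m_grid and k_grid must be non-empty")
    rows = []
    for m in m_grid:
        rwp = r_within(vc, m)
        for k in k_grid:
            rows.append({"m": m, "k": k,
                         "r_bp": r_between(vc, m=m, k=k), "r_wp": rwp})
    return pd.DataFrame(rows)


def incremental_r_bp(
    data: BurstDataset,
    k_range: Iterable[int],
    *,
    occasion_level: str = "session",
    item_meaning: str = "task",
    task: str | None = None,
    estimator: str = "ems",
    require_balanced: bool = True,
    fixed_components: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Between-person reliability of the first k sessions, for each k.

    For every k the data are restricted to each person's first k sessions,
    the variance components are re-estimated on that subset and R_BP is
    evaluated at (m = items per occasion, k).  With ``require_balanced`` the
    estimation uses only persons who completed all first k sessions
    (complete-case restriction, needed by the balanced EMS estimator).
    ``fixed_components`` skips re-estimation and projects the supplied
    components over k (the cheap variant).
    """
    rows = []
    for k in k_range:
        if fixed_components is not None:
            vc = fixed_components
            m = (vc.n_i or 0) * vc.n_rep
            rows.append({"k": k, "r_bp": r_between(vc, m=m, k=k), "n_persons": vc.n_p})
            continue
        sub = first_k_sessions(data, k)
        if require_balanced:
            counts = sub.frame.groupby("person_id")["session_index"].nunique()
            complete = counts[counts == k].index
            sub = sub.subset(sub.frame["person_id"].isin(complete))
        try:
            cells = build_cells(sub, occasion_level=occasion_level,
                                item_meaning=item_meaning, task=task)
            vc = estimate_components(cells, estimator=estimator)
        except DesignError as e:
            logger.warning("incremental_r_bp: skipping k=%d (%s)", k, e)
            continue
        m = cells.n_i * cells.n_rep
        rows.append({"k": k, "r_bp": r_between(vc, m=m, k=k),
                     "n_persons": cells.n_p})
    return pd.DataFrame(rows, columns=["k", "r_bp", "n_persons"])


def incremental_criterion_correlation(
    data: BurstDataset,
    criterion: pd.Series,
    k_range: Iterable[int],
    *,
    tasks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlation of first-k-session burst means with a per-person criterion.

    For each k, each person's composite score (mean of per-task z-scores) is
    averaged over their first k sessions and Pearson-correlated with the
    criterion (e.g. a laboratory composite).  ``criterion`` is indexed by
    person_id.
    """
    rows = []
    for k in k_range:
        sub = first_k_sessions(data, k)
        scores = score_sessions(sub)
        comp = composite_wmc(scores, tasks=tasks)
        means = comp.groupby("person_id")["composite"].mean()
        joined = pd.concat([means, criterion], axis=1, join="inner")
        joined.columns = ["burst_mean", "criterion"]
        if len(joined) < 3:
            raise DesignError(f"k={k}: fewer than 3 persons with both scores")
        r = float(np.corrcoef(joined["burst_mean"], joined["criterion"])[0, 1])
        rows.append({"k": k, "r": r, "n_persons": len(joined)})
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching conventional reporting."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
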