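"""Synthetic measurement-burst generators.

Two generation modes cover the two jobs a synthetic burst has to do:

* ``gaussian`` draws cell scores directly from the crossed random-effects
  ANOVA model that the G-study estimates (exact generative match; used for
  estimator validation and parameter recovery).
* ``mechanistic`` simulates trial-level recall: each memorandum is recalled
  with a probability driven by a person trait, an occasion state, day-level
  drift and a set-size penalty on the log-odds scale, and emits
  presented/recalled token sequences consistent with partial-credit scoring
  (used for end-to-end pipeline tests).

Presets mirror the two burst designs the package targets: a 4-day,
4-sessions/day burst with a 3-task battery of 2 trials each, and a 7-day,
5-sessions/day burst with a single task of 3 set-size-5 trials.  Notification
schedules anchor the first session within 2 h of wake time and space later
sessions 3.75 h apart with up to 30 min of jitter; sessions are completed
with a compliance probability (missing completely at random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .data_model import COLUMNS, BurstDataset
from .exceptions import ConfigError
from .gstudy import VarianceComponents

logger = logging.getLogger(__name__)

_ALPHABET = list("ABCDEFGHJKLMNPQRSTUVWXYZ")  # I and O dropped: too confusable


class TaskSpec(BaseModel):
    name: Literal["ospan", "sspan", "rspan"]
    set_sizes: list[int] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self):
        if any(s < 2 for s in self.set_sizes):
            raise ValueError("set sizes must be >= 2")
        return self

    @property
    def n_trials(self) -> int:
        return len(self.set_sizes)


class GaussianComponents(BaseModel):
    """True variance components of the gaussian generative model."""

    mu: float = 0.0
    p: float = Field(ge=0)
    o: float = Field(ge=0)
    i: float = Field(ge=0)
    po: float = Field(ge=0)
    pi: float = Field(ge=0)
    oi: float = Field(ge=0)
    e: float = Field(ge=0)

    def to_variance_components(self, **kw) -> VarianceComponents:
        d = self.model_dump()
        d.pop("mu")
        return VarianceComponents.from_mapping(d, **kw)


class MechanisticParams(BaseModel):
    """Trial-level recall model parameters (log-odds scale unless noted)."""

    ability_sd: float = Field(default=0.9, ge=0)
    occasion_sd: float = Field(default=0.55, ge=0)
    day_sd: float = Field(default=0.25, ge=0)
    intercept: float = 1.2
    setsize_slope: float = Field(default=0.35, ge=0)  # penalty per item above reference
    reference_set_size: int = 5
    guess_floor: float = Field(default=0.02, ge=0, le=0.5)


class CriterionModel(BaseModel):
    """Latent correlations of laboratory criteria with the burst trait."""

    r_lab: float = Field(default=0.7, ge=-1, le=1)
    r_gf: float = Field(default=0.6, ge=-1, le=1)


class SimConfig(BaseModel):
    """Full generative specification of a synthetic measurement burst."""

    n_persons: int = Field(ge=1)
    n_days: int = Field(ge=1)
    sessions_per_day: int = Field(ge=1)
    tasks: list[TaskSpec] = Field(min_length=1)
    mode: Literal["gaussian", "mechanistic"] = "gaussian"
    components: Optional[GaussianComponents] = None
    mechanistic: MechanisticParams = MechanisticParams()
    compliance: float = Field(default=1.0, gt=0, le=1)
    criteria: CriterionModel = CriterionModel()
    exact_marginals: bool = False
    wake_minutes: tuple[int, int] = (360, 540)  # 06:00-09:00
    session_gap_minutes: float = 225.0          # 3.75 h
    jitter_minutes: float = 30.0
    discretize: bool = False
    start_date: str = "2024-01-01"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "gaussian" and self.components is None:
            raise ValueError("gaussian mode requires true components")
        return self

    @property
    def n_occasions(self) -> int:
        return self.n_days * self.sessions_per_day


@dataclass
class SimResult:
    """A simulated burst plus the latent quantities that generated it."""

    data: BurstDataset
    traits: pd.Series            # per-person latent trait (score or logit scale)
    trait_sd: float
    criteria: pd.DataFrame       # person_id, lab_wmc, gf
    schedule: pd.DataFrame       # ScheduleEvent rows
    config: SimConfig


# -- presets -----------------------------------------------------------

#: G-study components reported for the composite score of the 3-task,
#: 4-day x 4-session burst (momentary timescale, item = task).
STUDY2_COMPONENTS = GaussianComponents(
    mu=8.0, p=0.871, o=0.008, i=4.639, po=0.094, pi=0.381, oi=0.000, e=1.409
)

#: G-study components reported for the single-task, 7-day x 5-session burst
#: (momentary timescale, item = trial of the rotation-span task).
STUDY3_COMPONENTS = GaussianComponents(
    mu=3.9, p=0.488, o=0.007, i=0.008, po=0.177, pi=0.005, oi=0.000, e=0.914
)


def study2_config(**overrides) -> SimConfig:
    """3-task battery burst: 39 persons, 4 days x 4 sessions, 2 trials/task.

    Compliance 15/16 reproduces the reported mean of 15 completed sessions
    out of 16 scheduled.
    """
    base = dict(
        n_persons=39,
        n_days=4,
        sessions_per_day=4,
        tasks=[
            TaskSpec(name="ospan", set_sizes=[5, 6]),
            TaskSpec(name="sspan", set_sizes=[4, 5]),
            TaskSpec(name="rspan", set_sizes=[4, 5]),
        ],
        mode="gaussian",
        components=STUDY2_COMPONENTS,
        compliance=15 / 16,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


def study3_config(**overrides) -> SimConfig:
    """Single-task burst: 102 persons, 7 days x 5 sessions, 3 trials of set-size 5.

    Compliance 29/35 reproduces the reported mean of 29 completed sessions
    out of 35 scheduled.
    """
    base = dict(
        n_persons=102,
        n_days=7,
        sessions_per_day=5,
        tasks=[TaskSpec(name="rspan", set_sizes=[5, 5, 5])],
        mode="gaussian",
        components=STUDY3_COMPONENTS,
        compliance=29 / 35,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


PRESETS = {"study2": study2_config, "study3": study3_config}


# -- schedule ----------------------------------------------------------


def simulate_schedule_and_compliance(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-person daily notification schedules with completion flags.

    The first slot of each day falls within 2 hours after the person's wake
    time; consecutive slots are separated by the configured mean gap
    (3.75 h) jittered uniformly by up to the configured amount (30 min).
    Each slot is completed independently with probability ``compliance``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    last = (cfg.wake_minutes[1] + 120
            + (cfg.sessions_per_day - 1) * (cfg.session_gap_minutes + cfg.jitter_minutes))
    if last > 24 * 60:
        logger.warning(
            "schedule may overflow the waking day: last slot up to %.0f min", last
        )
    rows = []
    for p in range(cfg.n_persons):
        wake = rng.uniform(*cfg.wake_minutes)
        for d in range(1, cfg.n_days + 1):
            t = wake + rng.uniform(0, 120)
            for slot in range(1, cfg.sessions_per_day + 1):
                rows.append(
                    {
                        "person_id": f"P{p + 1:04d}",
                        "day_index": d,
                        "slot": slot,
                        "scheduled_minutes": float(t),
                        "completed": bool(rng.random() < cfg.compliance),
                    }
                )
                t += cfg.session_gap_minutes + rng.uniform(
                    -cfg.jitter_minutes, cfg.jitter_minutes
                )
    return pd.DataFrame(rows)


def _timestamps(schedule: pd.DataFrame, start_date: str) -> pd.Series:
    base = pd.Timestamp(start_date)
    ts = (
        base
        + pd.to_timedelta(schedule["day_index"] - 1, unit="D")
        + pd.to_timedelta(schedule["scheduled_minutes"].round().astype(int), unit="m")
    )
    return ts.dt.strftime("%Y-%m-%dT%H:%M:%S")


# -- gaussian mode -----------------------------------------------------


def simulate_gaussian(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Draw cell scores from the crossed random-effects ANOVA model.

    With a multi-task battery the item facet is the *task* and each emitted
    row is a session-level task score (one pseudo-trial per task); with a
    single task the item facet is the *trial*.  Scores are continuous unless
    ``discretize`` is set, in which case they are rounded and clipped into
    [0, set-size sum].
    """
    if cfg.mode != "gaussian":
        raise ConfigError("simulate_gaussian requires mode='gaussian'")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    comp = cfg.components
    a, b = cfg.n_persons, cfg.n_occasions
    item_is_task = len(cfg.tasks) > 1
    if item_is_task:
        items = [t.name for t in cfg.tasks]
        set_sizes = {t.name: sum(t.set_sizes) for t in cfg.tasks}
    else:
        task = cfg.tasks[0]
        items = list(range(1, task.n_trials + 1))
        set_sizes = {j: task.set_sizes[j - 1] for j in items}
    c = len(items)

    sd = {k: float(np.sqrt(getattr(comp, k))) for k in ("p", "o", "i", "po", "pi", "oi", "e")}

    def draw(scale, shape):
        x = rng.normal(0, 1.0, shape)
        if cfg.exact_marginals and x.size > 1:
            # pin the realized first two moments of the effect vector to the
            # nominal component, so finite facets (e.g. 3 items) do not make
            # parameter recovery a coin flip on a handful of draws
            x = x - x.mean()
            s = x.std(ddof=1)
            if s > 0:
                x = x / s
        return scale * x

    ap = draw(sd["p"], a)
    bo = draw(sd["o"], b)
    ci = draw(sd["i"], c)
    ab = draw(sd["po"], (a, b))
    ac = draw(sd["pi"], (a, c))
    bc = draw(sd["oi"], (b, c))
    e = draw(sd["e"], (a, b, c))
    y = (
        comp.mu
        + ap[:, None, None] + bo[None, :, None] + ci[None, None, :]
        + ab[:, :, None] + ac[:, None, :] + bc[None, :, :]
        + e
    )

    schedule = simulate_schedule_and_compliance(cfg, rng)
    frame = _cells_to_frame(cfg, y, items, set_sizes, item_is_task, schedule)
    if cfg.discretize:
        mx = frame["set_size"].to_numpy(float)
        frame["trial_score"] = np.clip(np.round(frame["trial_score"]), 0, mx)

    data = BurstDataset(
        frame,
        continuous=not cfg.discretize,
        provenance=f"gaussian simulation, seed={cfg.seed}",
        validate=False,
    )
    traits = pd.Series(ap, index=[f"P{j + 1:04d}" for j in range(a)], name="trait")
    crit = simulate_criteria(cfg, traits, trait_sd=sd["p"], rng=rng)
    return SimResult(data=data, traits=traits, trait_sd=sd["p"],
                     criteria=crit, schedule=schedule, config=cfg)


def _cells_to_frame(
    cfg: SimConfig,
    y: np.ndarray,
    items: list,
    set_sizes: dict,
    item_is_task: bool,
    schedule: pd.DataFrame,
) -> pd.DataFrame:
    """Expand the (p, occasion, item) score array into completed long rows."""
    a, b, c = y.shape
    spd = cfg.sessions_per_day
    occ = np.arange(b)
    day_of_occ = occ // spd + 1
    sid_of_occ = occ % spd + 1

    done = schedule[schedule["completed"]].copy()
    done["ts"] = _timestamps(done, cfg.start_date)
    # completion order defines the global session index
    done = done.sort_values(["person_id", "day_index", "slot"])
    done["session_index"] = done.groupby("person_id").cumcount() + 1
    key = {(r.person_id, r.day_index, r.slot): (r.session_index, r.ts)
           for r in done.itertuples()}

    rows = []
    for pj in range(a):
        pid = f"P{pj + 1:04d}"
        for oj in range(b):
            d, s = int(day_of_occ[oj]), int(sid_of_occ[oj])
            hit = key.get((pid, d, s))
            if hit is None:
                continue
            sess_idx, ts = hit
            for ij, item in enumerate(items):
                rows.append(
                    {
                        "person_id": pid,
                        "day_index": d,
                        "session_in_day": s,
                        "session_index": int(sess_idx),
                        "task": item if item_is_task else cfg.tasks[0].name,
                        "trial_index": 1 if item_is_task else int(item),
                        "set_size": int(set_sizes[item]),
                        "presented": "",
                        "recalled": "",
                        "trial_score": float(y[pj, oj, ij]),
                        "timestamp": ts,
                    }
                )
    return pd.DataFrame(rows, columns=COLUMNS)


# -- mechanistic mode --------------------------------------------------


def simulate_mechanistic(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Trial-level recall simulation emitting presented/recalled sequences.

    Each position of each trial is recalled with probability

        guess_floor + (1 - guess_floor) *
            logistic(intercept + theta_p + drift_pd + state_po
                     - slope * (set_size - reference))

    Failed positions appear as intruder tokens (drawn outside the presented
    set) or are truncated from the end of the response, so position-strict
    partial-credit scoring of the emitted sequences reproduces the trial
    score exactly.
    """
    if cfg.mode != "mechanistic":
        raise ConfigError("simulate_mechanistic requires mode='mechanistic'")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mp = cfg.mechanistic
    a, b = cfg.n_persons, cfg.n_occasions
    spd = cfg.sessions_per_day

    theta = rng.normal(0, mp.ability_sd, a)
    drift = rng.normal(0, mp.day_sd, (a, cfg.n_days))
    state = rng.normal(0, mp.occasion_sd, (a, b))

    schedule = simulate_schedule_and_compliance(cfg, rng)
    done = schedule[schedule["completed"]].copy()
    done["ts"] = _timestamps(done, cfg.start_date)
    done = done.sort_values(["person_id", "day_index", "slot"])
    done["session_index"] = done.groupby("person_id").cumcount() + 1
    key = {(r.person_id, r.day_index, r.slot): (r.session_index, r.ts)
           for r in done.itertuples()}

    rows = []
    for pj in range(a):
        pid = f"P{pj + 1:04d}"
        for oj in range(b):
            d = oj // spd + 1
            s = oj % spd + 1
            hit = key.get((pid, d, s))
            if hit is None:
                continue
            sess_idx, ts = hit
            for task in cfg.tasks:
                for tj, set_size in enumerate(task.set_sizes, start=1):
                    logit = (
                        mp.intercept + theta[pj] + drift[pj, d - 1] + state[pj, oj]
                        - mp.setsize_slope * (set_size - mp.reference_set_size)
                    )
                    prob = mp.guess_floor + (1 - mp.guess_floor) * expit(logit)
                    success = rng.random(set_size) < prob
                    presented = list(rng.choice(_ALPHABET, size=set_size, replace=False))
                    recalled = _emit_recall(presented, success, rng)
                    rows.append(
                        {
                            "person_id": pid,
                            "day_index": d,
                            "session_in_day": s,
                            "session_index": int(sess_idx),
                            "task": task.name,
                            "trial_index": tj,
                            "set_size": set_size,
                            "presented": "|".join(presented),
                            "recalled": "|".join(recalled),
                            "trial_score": float(success.sum()),
                            "timestamp": ts,
                        }
                    )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    data = BurstDataset(
        frame,
        continuous=False,
        provenance=f"mechanistic simulation, seed={cfg.seed}",
        validate=False,
    )
    traits = pd.Series(theta, index=[f"P{j + 1:04d}" for j in range(a)], name="trait")
    crit = simulate_criteria(cfg, traits, trait_sd=mp.ability_sd, rng=rng)
    return SimResult(data=data, traits=traits, trait_sd=mp.ability_sd,
                     criteria=crit, schedule=schedule, config=cfg)


def _emit_recall(presented: list, success: np.ndarray, rng: np.random.Generator) -> list:
    """Build a response sequence whose position-strict score equals success.sum().

    Trailing failures are truncated (participants may submit fewer items);
    interior failures become intruder tokens from outside the presented set.
    """
    last_hit = int(np.max(np.nonzero(success)[0])) if success.any() else -1
    # beyond the last success, truncate with probability 1/2 per trailing item
    n_out = last_hit + 1
    for j in range(last_hit + 1, len(presented)):
        if rng.random() < 0.5:
            n_out = j + 1
        else:
            break
    pool = [t for t in _ALPHABET if t not in presented]
    out = []
    for j in range(n_out):
        if success[j]:
            out.append(presented[j])
        else:
            out.append(str(rng.choice(pool)))
    return out


# -- criteria ----------------------------------------------------------


def simulate_criteria(
    cfg: SimConfig,
    traits: pd.Series,
    trait_sd: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-person laboratory criterion scores correlated with the burst trait.

    Each criterion is r * z(trait) + sqrt(1 - r^2) * noise on the standard
    scale, achieving the configured population correlation exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    z = traits.to_numpy(float) / trait_sd if trait_sd > 0 else np.zeros(len(traits))
    out = {"person_id": traits.index}
    for name, r in (("lab_wmc", cfg.criteria.r_lab), ("gf", cfg.criteria.r_gf)):
        noise = rng.normal(size=len(traits))
        out[name] = r * z + np.sqrt(1 - r * r) * noise
    return pd.DataFrame(out).set_index("person_id").reset_index()


# -- dispatch ----------------------------------------------------------


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a burst according to ``cfg.mode``; deterministic given seed."""
    if cfg.mode == "gaussian":
        return simulate_gaussian(cfg)
    return simulate_mechanistic(cfg)
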