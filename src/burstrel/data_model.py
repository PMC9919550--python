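"""Long-format data model for measurement-burst complex-span data.

A *burst dataset* holds one row per complex-span trial collected in an
ecological momentary assessment (EMA) study: several ultra-brief sessions
per day over several days, each session containing a small number of trials
per task.  The canonical on-disk form is a UTF-8 CSV with header

    person_id,day_index,session_in_day,session_index,task,trial_index,
    set_size,presented,recalled,trial_score,timestamp

where ``presented``/``recalled`` are pipe-delimited token lists (``F|K|R|Q|J``)
and the empty string means "not recorded".  All indices are 1-based.
``session_index`` is the global completion order of sessions within a person;
when absent it is derived from timestamps, falling back to
(day_index, session_in_day).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateKeyError,
    RowValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

TASKS = ("ospan", "sspan", "rspan")

#: canonical column order of the long format
COLUMNS = [
    "person_id",
    "day_index",
    "session_in_day",
    "session_index",
    "task",
    "trial_index",
    "set_size",
    "presented",
    "recalled",
    "trial_score",
    "timestamp",
]

_REQUIRED = [
    "person_id",
    "day_index",
    "session_in_day",
    "task",
    "trial_index",
    "set_size",
]

_KEY = ["person_id", "session_index", "task", "trial_index"]


def parse_tokens(s: str) -> list[str]:
    """Parse a pipe-delimited token list; '' -> []."""
    if s is None or s == "" or (isinstance(s, float) and np.isnan(s)):
        return []
    return str(s).split("|")


def format_tokens(tokens: Sequence[str]) -> str:
    return "|".join(str(t) for t in tokens)


@dataclass
class TrialRecord:
    """One span-task trial.

    ``trial_score`` is the partial-credit score: the number of memoranda
    credited at recall, in [0, set_size].  ``presented``/``recalled`` are the
    ordered stimulus tokens; recall may legitimately be shorter than the set
    size because participants may submit fewer items than were presented.
    """

    person_id: str
    day_index: int
    session_in_day: int
    session_index: int
    task: str
    trial_index: int
    set_size: int
    trial_score: float
    presented: list[str] = field(default_factory=list)
    recalled: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self):
        if self.set_size < 2:
            raise RowValidationError(f"set_size must be >= 2, got {self.set_size}")
        if self.presented and len(self.presented) != self.set_size:
            raise RowValidationError(
                f"presented has {len(self.presented)} tokens, set_size={self.set_size}"
            )
        if self.recalled and len(self.recalled) > self.set_size:
            raise RowValidationError(
                f"recalled has {len(self.recalled)} tokens > set_size={self.set_size}"
            )

    def to_row(self) -> dict:
        return {
            "person_id": self.person_id,
            "day_index": self.day_index,
            "session_in_day": self.session_in_day,
            "session_index": self.session_index,
            "task": self.task,
            "trial_index": self.trial_index,
            "set_size": self.set_size,
            "presented": format_tokens(self.presented),
            "recalled": format_tokens(self.recalled),
            "trial_score": self.trial_score,
            "timestamp": self.timestamp,
        }


class BurstDataset:
    """Validated collection of trial records from a measurement burst.

    Parameters
    ----------
    frame
        Long-format DataFrame with the canonical columns.  ``session_index``
        is derived if absent.
    continuous
        If True, trial scores are continuous synthetic values and the
        integer range invariant ``0 <= score <= set_size`` is not enforced
        (used by the non-discretized gaussian generator, whose scores live
        on an unbounded latent scale).
    credit_rule
        Credit rule used to check score/sequence consistency
        (``"position"`` or ``"free"``).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        *,
        continuous: bool = False,
        provenance: str = "",
        credit_rule: str = "position",
        validate: bool = True,
    ):
        self.continuous = bool(continuous)
        self.provenance = provenance
        self.credit_rule = credit_rule
        self._frame = _normalize_frame(frame)
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[TrialRecord], **kw) -> "BurstDataset":
        rows = [r.to_row() for r in records]
        if not rows:
            frame = pd.DataFrame(columns=COLUMNS)
        else:
            frame = pd.DataFrame(rows)
        return cls(frame, **kw)

    # -- accessors ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format frame (do not mutate)."""
        return self._frame

    @property
    def persons(self) -> list[str]:
        return sorted(self._frame["person_id"].unique())

    @property
    def tasks(self) -> list[str]:
        return sorted(self._frame["task"].unique())

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[TrialRecord]:
        for _, row in self._frame.iterrows():
            yield TrialRecord(
                person_id=row.person_id,
                day_index=int(row.day_index),
                session_in_day=int(row.session_in_day),
                session_index=int(row.session_index),
                task=row.task,
                trial_index=int(row.trial_index),
                set_size=int(row.set_size),
                trial_score=float(row.trial_score),
                presented=parse_tokens(row.presented),
                recalled=parse_tokens(row.recalled),
                timestamp=row.timestamp,
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BurstDataset):
            return NotImplemented
        a = self._frame.sort_values(_KEY).reset_index(drop=True)
        b = other._frame.sort_values(_KEY).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if col == "trial_score":
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float),
                                   rtol=0, atol=1e-12):
                    return False
            elif not a[col].astype(str).equals(b[col].astype(str)):
                return False
        return True

    def design_summary(self) -> dict:
        f = self._frame
        sessions_per_person = f.groupby("person_id")["session_index"].nunique()
        return {
            "n_persons": int(f["person_id"].nunique()),
            "n_tasks": int(f["task"].nunique()),
            "n_days": int(f["day_index"].max()) if len(f) else 0,
            "sessions_per_day": int(f["session_in_day"].max()) if len(f) else 0,
            "mean_sessions_completed": float(sessions_per_person.mean()) if len(f) else 0.0,
            "trials_per_task": (
                int(f.groupby(["person_id", "session_index", "task"]).size().max())
                if len(f)
                else 0
            ),
            "n_trials": int(len(f)),
        }

    def subset(self, mask: pd.Series) -> "BurstDataset":
        """Row-subset sharing this dataset's options; skips re-validation."""
        out = BurstDataset(
            self._frame.loc[mask],
            continuous=self.continuous,
            provenance=self.provenance,
            credit_rule=self.credit_rule,
            validate=False,
        )
        return out

    # -- validation ---------------------------------------------------

    def _validate(self):
        from .span_scoring import score_trial  # deferred: avoids import cycle

        f = self._frame
        bad: list[str] = []
        for idx, row in f.iterrows():
            if row.set_size < 2:
                bad.append(f"row {idx}: set_size={row.set_size} < 2")
                continue
            if not self.continuous:
                if not (0 <= row.trial_score <= row.set_size):
                    bad.append(
                        f"row {idx}: trial_score={row.trial_score} outside "
                        f"[0, {row.set_size}]"
                    )
            pres = parse_tokens(row.presented)
            rec = parse_tokens(row.recalled)
            if pres and len(pres) != row.set_size:
                bad.append(f"row {idx}: presented length {len(pres)} != set_size")
            if rec and len(rec) > row.set_size:
                bad.append(f"row {idx}: recalled length {len(rec)} > set_size")
            if pres and row.recalled != "" and not np.isnan(row.trial_score):
                # both sequences recorded: score must agree with the credit rule
                expected = score_trial(pres, rec, credit=self.credit_rule)
                if expected != row.trial_score:
                    bad.append(
                        f"row {idx}: trial_score={row.trial_score} but "
                        f"{self.credit_rule}-credit scoring of sequences gives {expected}"
                    )
        if bad:
            shown = "; ".join(bad[:10])
            more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
            raise RowValidationError(f"invalid rows: {shown}{more}")

        dup = f.duplicated(subset=_KEY)
        if dup.any():
            keys = f.loc[dup, _KEY].head(5).to_dict("records")
            raise DuplicateKeyError(f"duplicate (person, session, task, trial) keys: {keys}")

        # session_index must respect timestamp order within person
        if len(f) and (f["timestamp"] != "").all():
            sess = f.drop_duplicates(["person_id", "session_index"])
            for pid, g in sess.groupby("person_id"):
                g = g.sort_values("session_index")
                ts = g["timestamp"].tolist()
                if ts != sorted(ts):
                    raise RowValidationError(
                        f"person {pid}: session_index order disagrees with timestamps"
                    )


def _normalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    f = frame.copy()
    for col in ("presented", "recalled", "timestamp"):
        if col not in f.columns:
            f[col] = ""
        f[col] = f[col].fillna("").astype(str)
        f.loc[f[col].isin(("nan", "None")), col] = ""
    if "trial_score" not in f.columns:
        f["trial_score"] = np.nan
    f["trial_score"] = pd.to_numeric(f["trial_score"], errors="coerce")

    # compute scores from sequences where absent
    need = f["trial_score"].isna()
    if need.any():
        from .span_scoring import score_trial

        for idx in f.index[need]:
            pres = parse_tokens(f.at[idx, "presented"])
            if not pres:
                raise RowValidationError(
                    f"row {idx}: trial_score missing and no presented sequence to score"
                )
            f.at[idx, "trial_score"] = score_trial(pres, parse_tokens(f.at[idx, "recalled"]))

    for col in ("day_index", "session_in_day", "trial_index", "set_size"):
        try:
            f[col] = pd.to_numeric(f[col]).astype(np.int64)
        except (ValueError, TypeError) as e:
            raise SchemaError(f"column {col} is not integer-valued: {e}") from e
    f["person_id"] = f["person_id"].astype(str)
    f["task"] = f["task"].astype(str)

    if "session_index" not in f.columns or f["session_index"].isna().all():
        f["session_index"] = _derive_session_index(f)
    f["session_index"] = pd.to_numeric(f["session_index"]).astype(np.int64)

    f = f[COLUMNS].sort_values(_KEY, kind="mergesort").reset_index(drop=True)
    return f


def _derive_session_index(f: pd.DataFrame) -> pd.Series:
    """Rank each person's sessions by completion order.

    Ordered by timestamp when every row has one, else by
    (day_index, session_in_day).
    """
    if len(f) == 0:
        return pd.Series([], dtype=np.int64)
    if (f["timestamp"] != "").all():
        order_cols = ["timestamp"]
    else:
        order_cols = ["day_index", "session_in_day"]
    key = f[["person_id", "day_index", "session_in_day"]].copy()
    sess = (
        f[["person_id", "day_index", "session_in_day"] + order_cols]
        .drop_duplicates(["person_id", "day_index", "session_in_day"])
        .sort_values(["person_id"] + order_cols, kind="mergesort")
    )
    sess["session_index"] = sess.groupby("person_id").cumcount() + 1
    merged = key.merge(
        sess[["person_id", "day_index", "session_in_day", "session_index"]],
        on=["person_id", "day_index", "session_in_day"],
        how="left",
    )
    return merged["session_index"].to_numpy()


# -- I/O ---------------------------------------------------------------


def load_burst_csv(path, schema_options: dict | None = None) -> BurstDataset:
    """Read a long-format burst CSV into a validated :class:`BurstDataset`.

    ``schema_options`` keys: ``continuous`` (bool, default False),
    ``credit_rule`` ("position"|"free").
    """
    opts = dict(schema_options or {})
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as e:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {e}") from e
    raw = raw.replace({"": None})
    raw = raw.where(raw.notna(), "")
    if "trial_score" in raw.columns:
        raw["trial_score"] = raw["trial_score"].replace({"": np.nan})
    if "session_index" in raw.columns and (raw["session_index"] == "").all():
        raw = raw.drop(columns=["session_index"])
    return BurstDataset(
        raw,
        continuous=opts.get("continuous", False),
        credit_rule=opts.get("credit_rule", "position"),
        provenance=f"loaded from {path}",
    )


def write_burst_csv(data: BurstDataset, path) -> None:
    """Write a burst dataset to the canonical long-format CSV."""
    f = data.to_frame()
    if not data.continuous:
        # integer scores round-trip without a decimal point
        if np.allclose(f["trial_score"], np.round(f["trial_score"])):
            f["trial_score"] = f["trial_score"].astype(np.int64)
    f.to_csv(path, index=False)


def first_k_sessions(data: BurstDataset, k: int) -> BurstDataset:
    """Restrict each person to their first ``k`` completed sessions.

    Persons with fewer than ``k`` sessions keep everything they have.  A
    session counts if it contains at least one completed trial of any task.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out = data.subset(data.frame["session_index"] <= k)
    counts = out.frame.groupby("person_id")["session_index"].nunique()
    logger.info(
        "first_k_sessions(k=%d): %d persons, mean %.2f sessions retained",
        k, len(counts), counts.mean() if len(counts) else float("nan"),
    )
    return out
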