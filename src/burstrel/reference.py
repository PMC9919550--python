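"""Published G-study variance components shipped as a text fixture.

These are the reported variance decompositions of two smartphone
measurement-burst working-memory studies: a 3-task composite score from a
4-day, 4-sessions/day burst (``study2_composite``) and the rotation-span
task from a 7-day, 5-sessions/day burst (``study3_rspan``), each at the
momentary (occasion = session) and daily (occasion = day) timescales.
Shipping them lets the decision-study reproduction run without any raw data.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .exceptions import SchemaError
from .gstudy import VarianceComponents

_NAME_MAP = {
    "person": "p",
    "occasion": "o",
    "item": "i",
    "person_x_occasion": "po",
    "person_x_item": "pi",
    "occasion_x_item": "oi",
    "error": "e",
}

#: number of occasions in the full burst (mean sessions completed)
BURST_SESSIONS = {"study2_composite": 15, "study3_rspan": 29}

#: scheduled sessions per day, i.e. daily-level replicates
SESSIONS_PER_DAY = {"study2_composite": 4, "study3_rspan": 5}

#: what the item facet indexes in each study
ITEM_MEANING = {"study2_composite": "task", "study3_rspan": "trial"}


def reference_components_path():
    return importlib.resources.files("burstrel.data") / "reference_components.csv"


def load_reference_table() -> pd.DataFrame:
    return pd.read_csv(reference_components_path())


def load_reference_components(
    study: str, timescale: str
) -> tuple[VarianceComponents, int]:
    """Return (components, m) for one study and timescale.

    ``m`` is the number of item administrations per occasion: items per
    session at the momentary level, items x sessions per day at the daily
    level.
    """
    table = load_reference_table()
    sub = table[(table["study"] == study) & (table["timescale"] == timescale)]
    if sub.empty:
        raise KeyError(f"no reference components for ({study!r}, {timescale!r})")
    return components_from_table(sub, study=study, timescale=timescale)


def components_from_table(
    sub: pd.DataFrame, study: str | None = None, timescale: str = "momentary"
) -> tuple[VarianceComponents, int]:
    """Parse a component table (``component,value`` rows incl. an ``m`` row)."""
    d = dict(zip(sub["component"], sub["value"]))
    missing = [k for k in _NAME_MAP if k not in d]
    if missing or "m" not in d:
        raise SchemaError(f"component table missing rows: {missing + ['m'] * ('m' not in d)}")
    m = int(d.pop("m"))
    comps = {_NAME_MAP[k]: float(v) for k, v in d.items() if k in _NAME_MAP}
    n_rep = 1
    n_i = m
    if timescale == "daily" and study in SESSIONS_PER_DAY:
        n_rep = SESSIONS_PER_DAY[study]
        n_i = m // n_rep
    vc = VarianceComponents.from_mapping(
        comps,
        occasion_level="session" if timescale == "momentary" else "day",
        item_meaning=ITEM_MEANING.get(study, "task"),
        n_i=n_i,
        n_rep=n_rep,
    )
    return vc, m
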