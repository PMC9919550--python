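"""End-to-end pipeline: simulate/load -> score -> G-study -> D-study -> report.

``run_pipeline`` executes the full analysis and writes CSV tables plus a JSON
manifest (config snapshot, seed, version, SHA-256 digest of every output) to
a report directory.  Given the same config and seed the output files are
byte-identical across runs; only the manifest's ``created`` timestamp varies.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import BurstDataset, first_k_sessions, load_burst_csv, write_burst_csv
from .dstudy import incremental_r_bp, projection, r_between, r_within, round_half_up
from .exceptions import BurstrelError, DesignError, PipelineError
from .gstudy import build_cells, estimate_components
from .reference import BURST_SESSIONS, components_from_table
from .span_scoring import composite_wmc, score_sessions
from .synthetic_data import PRESETS, SimConfig, simulate

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    """Decorator-free stage guard: re-raise with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, BurstrelError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the full pipeline described by ``config`` and write a report directory.

    Config keys (all optional unless noted):

    - ``preset``: "study2" | "study3" (simulation geometry), or
    - ``input_csv``: path to an existing burst CSV, or
    - ``components_csv``: a component table; skips simulation/estimation and
      only evaluates the decision-study coefficients.
    - ``mode``: "gaussian" | "mechanistic"; ``simulate``: SimConfig overrides.
    - ``seed``: simulation seed (the ``seed`` argument overrides it).
    - ``first_k``: restrict to each person's first k sessions.
    - ``k_range``: [k_min, k_max] for the incremental reliability curve.
    - ``projection``: {"m_grid": [...], "k_grid": [...]}.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = {**config, "seed": seed}

    outputs: dict[str, Path] = {}

    if "components_csv" in config:
        with _stage("dstudy-from-components"):
            table = pd.read_csv(config["components_csv"])
            rel = _reliability_from_components(table, config)
            path = out / "reliability.csv"
            rel.to_csv(path, index=False)
            outputs["reliability"] = path
    else:
        with _stage("acquire"):
            data = _acquire(config)
            if len(data) == 0:
                raise DesignError("empty dataset")
            path = out / "dataset.csv"
            write_burst_csv(data, path)
            outputs["dataset"] = path
            if config.get("first_k"):
                data = first_k_sessions(data, int(config["first_k"]))

        with _stage("score"):
            scores = score_sessions(data)
            path = out / "session_scores.csv"
            scores.to_csv(path, index=False)
            outputs["session_scores"] = path
            if data.frame["task"].nunique() > 1 and not data.continuous:
                comp = composite_wmc(scores)
                path = out / "composite_scores.csv"
                comp.to_csv(path, index=False)
                outputs["composite_scores"] = path

        item_meaning = "task" if data.frame["task"].nunique() > 1 else "trial"
        estimator = config.get("estimator", "auto")
        vcs = {}
        with _stage("gstudy"):
            rows = []
            for level in ("session", "day"):
                cells = build_cells(data, occasion_level=level, item_meaning=item_meaning)
                if not cells.is_balanced and estimator == "ems":
                    raise DesignError("unbalanced data; use estimator='iterative' or 'auto'")
                vc = estimate_components(cells, estimator=estimator)
                vcs[level] = vc
                f = vc.to_frame()
                f.insert(0, "timescale", "momentary" if level == "session" else "daily")
                rows.append(f)
            comp_table = pd.concat(rows, ignore_index=True)
            path = out / "components.csv"
            comp_table.to_csv(path, index=False)
            outputs["components"] = path

        with _stage("dstudy"):
            k_full = int(data.frame.groupby("person_id")["session_index"].nunique().median())
            rel_rows = []
            for level, vc in vcs.items():
                m = vc.n_i * vc.n_rep
                tag = "momentary" if level == "session" else "daily"
                rel_rows.append({"timescale": tag, "coefficient": "R_WP",
                                 "m": m, "k": "", "value": round_half_up(r_within(vc, m), 2)})
            m_mom = vcs["session"].n_i
            rel_rows.append({
                "timescale": "momentary", "coefficient": "R_BP_burst",
                "m": m_mom, "k": k_full,
                "value": round_half_up(r_between(vcs["session"], m=m_mom, k=k_full), 2),
            })
            rel = pd.DataFrame(rel_rows)
            path = out / "reliability.csv"
            rel.to_csv(path, index=False)
            outputs["reliability"] = path

            k_range = config.get("k_range") or [2, k_full]
            curve = incremental_r_bp(
                data, range(int(k_range[0]), int(k_range[1]) + 1),
                item_meaning=item_meaning, estimator=estimator,
            )
            path = out / "incremental_r_bp.csv"
            curve.to_csv(path, index=False)
            outputs["incremental_r_bp"] = path

            proj_cfg = config.get("projection") or {}
            m_grid = proj_cfg.get("m_grid", [m_mom, 2 * m_mom, 4 * m_mom])
            k_grid = proj_cfg.get("k_grid", [1, 2, 5, 10, k_full])
            surf = projection(vcs["session"], m_grid, k_grid)
            path = out / "projection.csv"
            surf.to_csv(path, index=False)
            outputs["projection"] = path

    manifest = {
        "version": __version__,
        "seed": config.get("seed"),
        "config": {k: v for k, v in config.items()},
        "outputs": {k: {"file": p.name, "sha256": _digest(p)} for k, p in outputs.items()},
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline wrote %d output(s) to %s", len(outputs), out)
    return out


def _acquire(config: dict) -> BurstDataset:
    if "input_csv" in config:
        return load_burst_csv(config["input_csv"], config.get("schema_options"))
    preset = config.get("preset")
    overrides = dict(config.get("simulate") or {})
    if "mode" in config:
        overrides["mode"] = config["mode"]
    if "seed" in config:
        overrides["seed"] = int(config["seed"])
    if preset:
        cfg = PRESETS[preset](**overrides)
    else:
        cfg = SimConfig(**overrides)
    return simulate(cfg).data


def _reliability_from_components(table: pd.DataFrame, config: dict) -> pd.DataFrame:
    """Decision-study table straight from a printed component table."""
    if "study" not in table.columns:
        table = table.assign(study="components", timescale=table.get("timescale", "momentary"))
    rows = []
    for (study, timescale), sub in table.groupby(["study", "timescale"]):
        vc, m = components_from_table(sub, study=study, timescale=timescale)
        label = "R_WPM" if timescale == "momentary" else "R_WPD"
        rows.append({"study": study, "timescale": timescale, "coefficient": label,
                     "m": m, "k": "", "value": round_half_up(r_within(vc, m), 2)})
        if timescale == "momentary":
            k = int(config.get("burst_k", {}).get(study, BURST_SESSIONS.get(study, 0)))
            if k:
                rows.append({"study": study, "timescale": timescale,
                             "coefficient": "R_BP_burst", "m": m, "k": k,
                             "value": round_half_up(r_between(vc, m=m, k=k), 2)})
    return pd.DataFrame(rows).sort_values(["study", "timescale", "coefficient"]).reset_index(drop=True)
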