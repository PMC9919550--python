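"""Generalizability-study variance decomposition for p x o x i burst designs.

Observed scores from a measurement burst are modeled as a fully crossed
random-effects ANOVA,

    y_poi = mu + a_p + b_o + c_i + (ab)_po + (ac)_pi + (bc)_oi + e_poi,

with persons (p), occasions (o = sessions or days) and items (i = trials or
tasks) all random.  The seven variance components (sigma^2_p, sigma^2_o,
sigma^2_i, sigma^2_po, sigma^2_pi, sigma^2_oi, sigma^2_e) are estimated by
equating observed mean squares to their Cornfield-Tukey expectations (the
classical balanced G-study estimator) or, for unbalanced data, by EM-REML on
the equivalent crossed mixed model.  At the daily timescale, sessions within
a day enter as unlabeled replicates of the (person, day, item) cell and the
session-within-day variance is pooled into the residual together with the
three-way interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import BurstDataset
from .exceptions import ConvergenceError, DesignError
from .span_scoring import score_sessions

logger = logging.getLogger(__name__)

COMPONENT_NAMES = ("p", "o", "i", "po", "pi", "oi", "e")

#: labels used in component tables, mirroring the usual G-study row layout
COMPONENT_LABELS = {
    "p": "Person",
    "o": "Occasion",
    "i": "Item",
    "po": "Person x occasion",
    "pi": "Person x item",
    "oi": "Occasion x item",
    "e": "Error",
}


@dataclass
class VarianceComponents:
    """The seven G-study variance components plus design sizes.

    Components are reported on the score scale squared; negative
    method-of-moments solutions are truncated to 0 (``raw`` keeps the
    untruncated solutions, whose expectation equals the truth on balanced
    data).
    """

    sigma2_p: float
    sigma2_o: float
    sigma2_i: float
    sigma2_po: float
    sigma2_pi: float
    sigma2_oi: float
    sigma2_e: float
    occasion_level: str = "session"
    item_meaning: str = "task"
    n_p: int | None = None
    n_o: int | None = None
    n_i: int | None = None
    n_rep: int = 1
    raw: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        for name in COMPONENT_NAMES:
            v = getattr(self, f"sigma2_{name}")
            if v < 0:
                raise ValueError(f"sigma2_{name} must be >= 0, got {v}")

    def to_dict(self) -> dict:
        return {name: getattr(self, f"sigma2_{name}") for name in COMPONENT_NAMES}

    def total(self) -> float:
        return float(sum(self.to_dict().values()))

    def scaled(self, c: float) -> "VarianceComponents":
        """Components after multiplying all scores by ``c``."""
        kw = {f"sigma2_{k}": v * c * c for k, v in self.to_dict().items()}
        return replace(self, raw=None, **kw)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": COMPONENT_LABELS[k], "value": v}
            for k, v in self.to_dict().items()
        ]
        rows.append({"component": "m", "value": (self.n_i or 0) * self.n_rep})
        return pd.DataFrame(rows)

    @classmethod
    def from_mapping(cls, d: dict, **kw) -> "VarianceComponents":
        return cls(**{f"sigma2_{k}": float(d[k]) for k in COMPONENT_NAMES}, **kw)


@dataclass
class IccResult:
    """One-way random-effects intraclass correlation."""

    icc: float
    sigma2_between: float
    sigma2_within: float
    unit: str = ""


@dataclass
class CellArray:
    """Fully indexed p x o x i x replicate score array; NaN marks missing cells."""

    values: np.ndarray  # shape (n_p, n_o, n_i, n_rep)
    person_ids: list
    occasion_ids: list
    item_ids: list
    occasion_level: str
    item_meaning: str

    @property
    def n_p(self) -> int:
        return self.values.shape[0]

    @property
    def n_o(self) -> int:
        return self.values.shape[1]

    @property
    def n_i(self) -> int:
        return self.values.shape[2]

    @property
    def n_rep(self) -> int:
        return self.values.shape[3]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a cell value is observed."""
        return ~np.isnan(self.values)

    @property
    def is_balanced(self) -> bool:
        return bool(self.mask.all())


def build_cells(
    data,
    occasion_level: str = "session",
    item_meaning: str = "task",
    task: str | None = None,
) -> CellArray:
    """Arrange scores into the p x o x i (x replicate) array of a G-study.

    ``data`` may be a :class:`BurstDataset` or a session-score frame from
    :func:`burstrel.span_scoring.score_sessions`.

    item_meaning="task": the item facet indexes tasks and the cell value is
    the session-level span score of that task (trials already summed).
    item_meaning="trial": the item facet indexes trial positions within a
    session of a single task (pass ``task`` when several are present).

    occasion_level="session": one cell per session, n_rep=1.
    occasion_level="day": occasions are days and the sessions within a day
    become unlabeled replicates of the (person, day, item) cell.
    """
    if occasion_level not in ("session", "day"):
        raise ValueError(f"occasion_level must be 'session' or 'day': {occasion_level!r}")
    if item_meaning not in ("task", "trial"):
        raise ValueError(f"item_meaning must be 'task' or 'trial': {item_meaning!r}")

    if isinstance(data, BurstDataset):
        frame = data.frame
    else:
        frame = data

    if item_meaning == "task":
        if isinstance(data, BurstDataset):
            scores = score_sessions(data)
        else:
            scores = frame
        tidy = scores.rename(columns={"task": "item", "span_score": "value"})[
            ["person_id", "day_index", "session_index", "item", "value"]
        ]
    else:
        f = frame
        if task is not None:
            f = f[f["task"] == task]
        if f["task"].nunique() > 1:
            raise DesignError(
                "item_meaning='trial' needs a single task; pass task=..."
            )
        tidy = f.rename(columns={"trial_index": "item", "trial_score": "value"})[
            ["person_id", "day_index", "session_index", "item", "value"]
        ]

    if occasion_level == "session":
        tidy = tidy.assign(occasion=tidy["session_index"], rep=1)
    else:
        tidy = tidy.assign(occasion=tidy["day_index"])
        # sessions within a day become replicate slots 1..r
        rep = (
            tidy[["person_id", "occasion", "session_index"]]
            .drop_duplicates()
            .sort_values(["person_id", "occasion", "session_index"])
        )
        rep["rep"] = rep.groupby(["person_id", "occasion"]).cumcount() + 1
        tidy = tidy.merge(rep, on=["person_id", "occasion", "session_index"])

    persons = sorted(tidy["person_id"].unique())
    occasions = sorted(tidy["occasion"].unique())
    items = sorted(tidy["item"].unique())
    n_rep = int(tidy["rep"].max()) if len(tidy) else 0
    if len(persons) < 2 or len(occasions) < 2 or len(items) < 2:
        raise DesignError(
            f"need >= 2 levels per facet, got p={len(persons)}, "
            f"o={len(occasions)}, i={len(items)}"
        )

    values = np.full((len(persons), len(occasions), len(items), n_rep), np.nan)
    pidx = {v: j for j, v in enumerate(persons)}
    oidx = {v: j for j, v in enumerate(occasions)}
    iidx = {v: j for j, v in enumerate(items)}
    values[
        tidy["person_id"].map(pidx).to_numpy(),
        tidy["occasion"].map(oidx).to_numpy(),
        tidy["item"].map(iidx).to_numpy(),
        tidy["rep"].to_numpy() - 1,
    ] = tidy["value"].to_numpy(float)

    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("build_cells: %d of %d cells missing", n_missing, values.size)
    return CellArray(values, persons, occasions, items, occasion_level, item_meaning)


# -- balanced estimator (expected mean squares) ------------------------


def _mean_squares(y: np.ndarray) -> tuple[dict, dict]:
    """Sums of squares and mean squares of the crossed three-way layout.

    ``y`` has shape (a, b, c, r).  The three-way interaction and the
    within-cell replicate variation are pooled into the residual.
    """
    a, b, c, r = y.shape
    g = y.mean()
    mp = y.mean(axis=(1, 2, 3))
    mo = y.mean(axis=(0, 2, 3))
    mi = y.mean(axis=(0, 1, 3))
    mpo = y.mean(axis=(2, 3))
    mpi = y.mean(axis=(1, 3))
    moi = y.mean(axis=(0, 3))

    ss = {
        "p": b * c * r * float(((mp - g) ** 2).sum()),
        "o": a * c * r * float(((mo - g) ** 2).sum()),
        "i": a * b * r * float(((mi - g) ** 2).sum()),
        "po": c * r * float(((mpo - mp[:, None] - mo[None, :] + g) ** 2).sum()),
        "pi": b * r * float(((mpi - mp[:, None] - mi[None, :] + g) ** 2).sum()),
        "oi": a * r * float(((moi - mo[:, None] - mi[None, :] + g) ** 2).sum()),
    }
    ss_total = float(((y - g) ** 2).sum())
    ss["e"] = ss_total - sum(ss.values())

    df = {
        "p": a - 1,
        "o": b - 1,
        "i": c - 1,
        "po": (a - 1) * (b - 1),
        "pi": (a - 1) * (c - 1),
        "oi": (b - 1) * (c - 1),
        "e": (a - 1) * (b - 1) * (c - 1) + a * b * c * (r - 1),
    }
    ms = {k: ss[k] / df[k] for k in ss}
    return ss, ms


def estimate_components_ems(cells: CellArray) -> VarianceComponents:
    """Method-of-moments G-study estimator for balanced data.

    Solves the expected-mean-square equations of the fully crossed random
    model with ``n_rep`` replicates pooled into the residual.  Negative
    solutions are truncated to 0; the untruncated values are kept in
    ``.raw``.
    """
    if not cells.is_balanced:
        raise DesignError(
            "cell array has missing cells; use estimate_components_iterative"
        )
    y = cells.values
    a, b, c, r = y.shape
    if a < 2 or b < 2 or c < 2:
        raise DesignError("need >= 2 levels per facet")
    _, ms = _mean_squares(y)

    if np.allclose(y, y.flat[0]):
        logger.warning("estimate_components_ems: zero total variance; all components 0")
        raw = {k: 0.0 for k in COMPONENT_NAMES}
    else:
        raw = {
            "e": ms["e"],
            "po": (ms["po"] - ms["e"]) / (c * r),
            "pi": (ms["pi"] - ms["e"]) / (b * r),
            "oi": (ms["oi"] - ms["e"]) / (a * r),
            "p": (ms["p"] - ms["po"] - ms["pi"] + ms["e"]) / (b * c * r),
            "o": (ms["o"] - ms["po"] - ms["oi"] + ms["e"]) / (a * c * r),
            "i": (ms["i"] - ms["pi"] - ms["oi"] + ms["e"]) / (a * b * r),
        }
    trunc = {k: max(0.0, raw[k]) for k in COMPONENT_NAMES}
    return VarianceComponents(
        **{f"sigma2_{k}": trunc[k] for k in COMPONENT_NAMES},
        occasion_level=cells.occasion_level,
        item_meaning=cells.item_meaning,
        n_p=a, n_o=b, n_i=c, n_rep=r,
        raw=raw,
    )


# -- iterative estimator (EM-REML) -------------------------------------

_FACTORS = ("p", "o", "i", "po", "pi", "oi")


def estimate_components_iterative(
    cells: CellArray,
    max_iter: int = 500,
    tol: float = 1e-14,
) -> VarianceComponents:
    """REML estimator of the crossed random model, tolerant of missing cells.

    Builds Henderson's mixed-model equations (MME) for the six random factors
    plus residual, warm-starts with a few EM steps

        sigma^2_f <- (u_f' u_f + sigma^2_e tr(C_ff)) / q_f

    (C the inverse MME coefficient matrix), then minimizes the restricted
    log-likelihood deviance directly with analytic gradients on the
    log-variance scale, which handles boundary components that make plain EM
    crawl.  On balanced data the REML solution coincides with the EMS
    estimator whenever that solution is interior.  Missing cells are assumed
    missing completely at random; facet levels with no observed cells are
    dropped with a log message.
    """
    from scipy.linalg import cho_factor, cho_solve
    from scipy.optimize import minimize

    y4 = cells.values
    obs = ~np.isnan(y4)
    # drop empty levels along each facet
    keep_p = obs.any(axis=(1, 2, 3))
    keep_o = obs.any(axis=(0, 2, 3))
    keep_i = obs.any(axis=(0, 1, 3))
    if not keep_p.all():
        logger.info("dropping %d person(s) with no observed cells", int((~keep_p).sum()))
    y4 = y4[keep_p][:, keep_o][:, :, keep_i]
    obs = ~np.isnan(y4)
    a, b, c, r = y4.shape
    if a < 2 or b < 2 or c < 2:
        raise DesignError("need >= 2 observed levels per facet")

    pi_, oi_, ii_, _ = np.indices(y4.shape)
    p_code = pi_[obs]
    o_code = oi_[obs]
    i_code = ii_[obs]
    y = y4[obs].astype(float)
    n = y.size

    codes = {
        "p": p_code,
        "o": o_code,
        "i": i_code,
        "po": p_code * b + o_code,
        "pi": p_code * c + i_code,
        "oi": o_code * c + i_code,
    }
    q = {}
    col0 = {}
    cols_all = []
    offset = 1  # column 0 is the intercept
    for f in _FACTORS:
        uniq, comp = np.unique(codes[f], return_inverse=True)
        codes[f] = comp
        q[f] = uniq.size
        col0[f] = offset
        cols_all.append(comp + offset)
        offset += uniq.size
    dim = offset
    q_tot = dim - 1

    # W = [1 | Z]; G0 = W'W and rhs = W'y are fixed across iterations
    W_cols = np.concatenate(
        [np.zeros(n, dtype=np.int64)[None, :], np.array(cols_all)], axis=0
    )  # (7, n)
    G0 = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    for jrow in range(7):
        np.add.at(rhs, W_cols[jrow], y)
        for jcol in range(7):
            np.add.at(G0, (W_cols[jrow], W_cols[jcol]), 1.0)
    yty = float(y @ y)

    var_y = float(np.var(y, ddof=1))
    meta = dict(
        occasion_level=cells.occasion_level, item_meaning=cells.item_meaning,
        n_p=a, n_o=b, n_i=c, n_rep=r,
    )
    if var_y == 0:
        logger.warning("estimate_components_iterative: zero total variance")
        zero = {k: 0.0 for k in COMPONENT_NAMES}
        return VarianceComponents(
            **{f"sigma2_{k}": 0.0 for k in COMPONENT_NAMES}, raw=zero, **meta
        )

    floor = 1e-10 * var_y
    lam_vec = np.zeros(dim)
    blocks = {f: slice(col0[f], col0[f] + q[f]) for f in _FACTORS}

    def mme(v, ve):
        """Solve the MME; return solution, block traces of C, and logdet."""
        for f in _FACTORS:
            lam_vec[blocks[f]] = ve / max(v[f], floor)
        M = G0.copy()
        M[np.diag_indices(dim)] += lam_vec
        M[0, 0] -= lam_vec[0]  # intercept carries no shrinkage
        cf = cho_factor(M, lower=True, check_finite=False)
        sol = cho_solve(cf, rhs, check_finite=False)
        C = cho_solve(cf, np.eye(dim), check_finite=False)
        logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
        tr = {f: float(np.trace(C[blocks[f], blocks[f]])) for f in _FACTORS}
        return sol, tr, logdet

    def deviance_grad(theta):
        """-2 restricted log-likelihood and gradient w.r.t. log-variances."""
        vv = np.exp(theta)
        v = dict(zip(_FACTORS, vv[:-1]))
        ve = vv[-1]
        sol, tr, logdet = mme(v, ve)
        ypy_num = yty - float(rhs @ sol)          # sigma2_e * y'Py
        dev = (
            (n - 1 - q_tot) * np.log(ve)
            + sum(q[f] * np.log(max(v[f], floor)) for f in _FACTORS)
            + logdet
            + ypy_num / ve
        )
        grad = np.empty(7)
        lam_u2 = 0.0
        lam_tr = 0.0
        for j, f in enumerate(_FACTORS):
            u = sol[blocks[f]]
            uu = float(u @ u)
            lam = ve / max(v[f], floor)
            lam_u2 += lam * uu
            lam_tr += lam * tr[f]
            g = (q[f] - lam * tr[f]) / v[f] - uu / v[f] ** 2
            grad[j] = g * v[f]                    # chain rule: d/d log v
        rss = ypy_num - lam_u2                    # ||y - W sol||^2
        g_e = (n - 1 - q_tot + lam_tr) / ve - rss / ve ** 2
        grad[6] = g_e * ve
        return dev, grad

    # EM warm start from an equal split of the total variance
    v = {f: var_y / 7.0 for f in _FACTORS}
    ve = var_y / 7.0
    for _ in range(8):
        sol, tr, _ = mme(v, ve)
        for f in _FACTORS:
            u = sol[blocks[f]]
            v[f] = max(floor, (float(u @ u) + ve * tr[f]) / q[f])
        ve = max(floor, (yty - float(rhs @ sol)) / (n - 1))

    theta0 = np.log(np.array([v[f] for f in _FACTORS] + [ve]))
    lb = np.log(floor)
    ub = np.log(1e3 * var_y)

    def solve(x0):
        return minimize(
            deviance_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(lb, ub)] * 7,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-11, "maxcor": 20},
        )

    # On the log scale the gradient vanishes as a component approaches the
    # lower bound, so the optimizer can stall there even when the REML
    # optimum is interior.  Restart any floored component from a clearly
    # interior value and keep the lower-deviance solution.
    best = solve(theta0)
    near_zero = np.log(2e-4 * var_y)
    for _ in range(3):
        floored = best.x[:-1] <= near_zero
        if not floored.any():
            break
        x0 = best.x.copy()
        x0[:-1][floored] = np.log(1e-3 * var_y)
        retry = solve(x0)
        if retry.fun < best.fun - 1e-12:
            best = retry
        else:
            break
    res = best
    if not res.success and res.status != 0:
        # L-BFGS-B reports "abnormal" only for line-search failure; a tiny
        # projected gradient still means convergence
        if np.max(np.abs(res.jac)) > 1e-4 * (1 + var_y):
            raise ConvergenceError(
                f"REML optimization failed: {res.message} "
                f"(|grad|={np.max(np.abs(res.jac)):.3e})",
                trace=res,
            )
    vv = np.exp(res.x)
    raw = {**{f: float(vv[j]) for j, f in enumerate(_FACTORS)}, "e": float(vv[6])}
    trunc = {k: (0.0 if raw[k] <= 10 * floor else raw[k]) for k in raw}
    return VarianceComponents(
        **{f"sigma2_{k}": trunc[k] for k in COMPONENT_NAMES}, raw=raw, **meta
    )


def estimate_components(cells: CellArray, estimator: str = "auto", **kw) -> VarianceComponents:
    """Dispatch to the EMS (balanced) or EM-REML (unbalanced) estimator."""
    if estimator == "ems":
        return estimate_components_ems(cells)
    if estimator == "iterative":
        return estimate_components_iterative(cells, **kw)
    if estimator == "auto":
        if cells.is_balanced:
            return estimate_components_ems(cells)
        return estimate_components_iterative(cells, **kw)
    raise ValueError(f"unknown estimator: {estimator!r}")


# -- intraclass correlation --------------------------------------------


def icc_oneway(scores: pd.DataFrame, value_col: str = "value", unit: str = "") -> IccResult:
    """One-way random-effects ICC by unbalanced ANOVA method of moments.

    ``scores`` needs columns ``person_id`` and ``value_col``.  The ICC is the
    share of total variance attributable to stable between-person
    differences; the complement is within-person variation over repeated
    sessions plus measurement error.
    """
    g = scores.groupby("person_id")[value_col]
    sizes = g.size().to_numpy(float)
    a = sizes.size
    N = sizes.sum()
    if a < 2:
        raise DesignError("icc_oneway needs >= 2 persons")
    if N - a < 1:
        raise DesignError("icc_oneway needs repeated scores within persons")
    means = g.mean().to_numpy(float)
    grand = float(scores[value_col].mean())
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((scores[value_col] - g.transform("mean")) ** 2).sum())
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - (sizes ** 2).sum() / N) / (a - 1)
    s2b = max(0.0, (msb - msw) / n0)
    s2w = msw
    denom = s2b + s2w
    icc = s2b / denom if denom > 0 else 0.0
    return IccResult(icc=icc, sigma2_between=s2b, sigma2_within=s2w, unit=unit)
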