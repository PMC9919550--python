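"""Independent brute-force variance-component oracle for the test suite.

Computes the crossed three-way random-model ANOVA decomposition directly from
definitions with explicit Python loops, and solves for the components by
building the expected-mean-square coefficient matrix from first principles
(E[MS] of each line = sum over the components it contains, with the usual
multipliers).  Deliberately shares no code with burstrel.gstudy.
"""

import numpy as np


def brute_force_components(y: np.ndarray) -> dict:
    """y: (a, b, c) or (a, b, c, r) array, fully observed."""
    if y.ndim == 3:
        y = y[..., None]
    a, b, c, r = y.shape
    grand = y.mean()

    def mean_p(p):
        return y[p].mean()

    def mean_o(o):
        return y[:, o].mean()

    def mean_i(i):
        return y[:, :, i].mean()

    ss = dict.fromkeys(["p", "o", "i", "po", "pi", "oi", "e"], 0.0)
    for p in range(a):
        ss["p"] += b * c * r * (mean_p(p) - grand) ** 2
    for o in range(b):
        ss["o"] += a * c * r * (mean_o(o) - grand) ** 2
    for i in range(c):
        ss["i"] += a * b * r * (mean_i(i) - grand) ** 2
    for p in range(a):
        for o in range(b):
            ss["po"] += c * r * (y[p, o].mean() - mean_p(p) - mean_o(o) + grand) ** 2
    for p in range(a):
        for i in range(c):
            ss["pi"] += b * r * (y[p, :, i].mean() - mean_p(p) - mean_i(i) + grand) ** 2
    for o in range(b):
        for i in range(c):
            ss["oi"] += a * r * (y[:, o, i].mean() - mean_o(o) - mean_i(i) + grand) ** 2
    ss_total = float(((y - grand) ** 2).sum())
    ss["e"] = ss_total - sum(v for k, v in ss.items() if k != "e")

    df = {
        "p": a - 1,
        "o": b - 1,
        "i": c - 1,
        "po": (a - 1) * (b - 1),
        "pi": (a - 1) * (c - 1),
        "oi": (b - 1) * (c - 1),
        "e": (a - 1) * (b - 1) * (c - 1) + a * b * c * (r - 1),
    }
    names = ["p", "o", "i", "po", "pi", "oi", "e"]
    ms = np.array([ss[k] / df[k] for k in names])

    # E[MS_line] rows: which components appear, with multiplier
    # (number of observations averaged per level combination of that component)
    mult = {"p": b * c * r, "o": a * c * r, "i": a * b * r,
            "po": c * r, "pi": b * r, "oi": a * r, "e": 1}
    contains = {
        "p": ["p", "po", "pi", "e"],
        "o": ["o", "po", "oi", "e"],
        "i": ["i", "pi", "oi", "e"],
        "po": ["po", "e"],
        "pi": ["pi", "e"],
        "oi": ["oi", "e"],
        "e": ["e"],
    }
    A = np.zeros((7, 7))
    for row, line in enumerate(names):
        for comp in contains[line]:
            A[row, names.index(comp)] = mult[comp]
    sol = np.linalg.solve(A, ms)
    return dict(zip(names, sol))
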