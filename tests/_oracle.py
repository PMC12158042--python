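"""Independent brute-force Mamdani oracle.

A deliberately naive reference implementation — explicit loops over every
rule, membership degrees recomputed from the raw MF parameters, aggregation
on a dense output grid — kept free of any code from the package's inference
engine so the two can disagree.
"""

from __future__ import annotations

import math

import numpy as np


def _gauss(x: float, c: float, s: float) -> float:
    return math.exp(-((x - c) ** 2) / (2.0 * s * s))


def _pi(x: float, a: float, b: float, c: float, d: float) -> float:
    def s_up(x, lo, hi):
        if hi <= lo:
            return 1.0 if x >= lo else 0.0
        if x <= lo:
            return 0.0
        if x >= hi:
            return 1.0
        t = (x - lo) / (hi - lo)
        return 2 * t * t if t <= 0.5 else 1 - 2 * (1 - t) ** 2

    return min(s_up(x, a, b), 1.0 - s_up(x, c, d))


def _degree(mf, x: float) -> float:
    if mf.shape == "gaussian":
        return _gauss(x, *mf.params)
    return _pi(x, *mf.params)


def brute_force_mamdani(cfg, x, grid_n: int = 4001) -> float:
    """Reference Mamdani min/min/max + centroid for one crisp input vector."""
    x = [min(max(float(v), var.domain[0]), var.domain[1])
         for v, var in zip(x, cfg.inputs)]
    grid = [i / (grid_n - 1) for i in range(grid_n)]
    agg = [0.0] * grid_n
    for combo, out_level in cfg.rules.table.items():
        strength = 1.0
        for i_var, level in enumerate(combo):
            strength = min(strength, _degree(cfg.inputs[i_var].mfs[level], x[i_var]))
        if strength <= 0.0:
            continue
        out_mf = cfg.output.mfs[out_level]
        for i, g in enumerate(grid):
            agg[i] = max(agg[i], min(strength, _degree(out_mf, g)))
    num = sum(g * m for g, m in zip(grid, agg))
    den = sum(agg)
    if den == 0.0:
        raise ValueError("no rule fired")
    return num / den


def oracle_centroid(mu: np.ndarray) -> float:
    """Reference grid centroid for a membership profile on [0, 1]."""
    grid = np.linspace(0.0, 1.0, len(mu))
    return float(np.sum(grid * mu) / np.sum(mu))
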