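"""Mamdani fuzzy inference: membership functions, rule bases, defuzzification.

Every fusion node in the cognitive-load hierarchy is a small Mamdani system:
crisp inputs are fuzzified through Gaussian or Pi-shaped membership functions,
rules fire with min (t-norm), implication is min, aggregation is max, and the
aggregated output set is collapsed by its centroid on a uniform grid of the
[0, 1] load domain.  The anchor semantics are fixed throughout the hierarchy:
0 = low cognitive load, 0.5 = medium, 1 = high.

Rule bases are not hand-enumerated.  Each input level carries a *load score*
in [0, 1] (by default ``i / (n_levels - 1)``, but a variable may reinterpret
its levels — e.g. heart rate deviating from baseline in either direction
scores high).  A rule maps a combination of input levels to the output level
whose anchor (0, 0.5, 1) is nearest the mean of the load scores, ties
resolved upward (toward higher load).  This yields a total rule base that is
monotone in load by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "FWHM_FACTOR",
    "MembershipFunction",
    "FuzzyVariable",
    "RuleBase",
    "FISConfig",
    "gaussmf",
    "pimf",
    "mf_degree",
    "auto_sigma",
    "build_monotone_rulebase",
    "evaluate_fis",
    "evaluate_fis_batch",
    "defuzz_centroid",
    "output_load_variable",
]

#: 2 * sqrt(2 * ln 2) — converts a full width at half maximum to a Gaussian sigma.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class MembershipFunction:
    """A labelled fuzzy set over the reals.

    ``shape`` is ``"gaussian"`` with params ``(center, sigma)`` or ``"pi"``
    with params ``(a, b, c, d)`` (feet at a/d, unit plateau on [b, c]).
    """

    label: str
    shape: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape == "gaussian":
            c, sigma = self.params
            if not (sigma > 0):
                raise ValueError(f"gaussian MF {self.label!r}: sigma must be > 0")
        elif self.shape == "pi":
            a, b, c, d = self.params
            if not (a <= b <= c <= d):
                raise ValueError(f"pi MF {self.label!r}: need a <= b <= c <= d")
        else:
            raise ValueError(f"unknown MF shape {self.shape!r}")

    @property
    def center(self) -> float:
        """Representative point: Gaussian center or Pi plateau midpoint."""
        if self.shape == "gaussian":
            return self.params[0]
        a, b, c, d = self.params
        return 0.5 * (b + c)

    def degree(self, x) -> np.ndarray:
        """Membership degree(s) in [0, 1] for crisp value(s) ``x``."""
        x = np.asarray(x, dtype=float)
        if self.shape == "gaussian":
            c, sigma = self.params
            return np.exp(-0.5 * ((x - c) / sigma) ** 2)
        return _pi_degree(x, *self.params)


def _s_curve(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Quadratic S-spline rising 0 -> 1 on [a, b] (step when a == b)."""
    if b <= a:
        return (x >= a).astype(float)
    t = np.clip((x - a) / (b - a), 0.0, 1.0)
    return np.where(t <= 0.5, 2.0 * t**2, 1.0 - 2.0 * (1.0 - t) ** 2)


def _pi_degree(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    rise = _s_curve(x, a, b)
    fall = 1.0 - _s_curve(x, c, d)
    return np.minimum(rise, fall)


def gaussmf(label: str, center: float, sigma: float) -> MembershipFunction:
    return MembershipFunction(label, "gaussian", (float(center), float(sigma)))


def pimf(label: str, a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction(label, "pi", (float(a), float(b), float(c), float(d)))


def mf_degree(mf: MembershipFunction, x) -> np.ndarray | float:
    """Functional form of :meth:`MembershipFunction.degree`."""
    out = mf.degree(x)
    return float(out) if np.ndim(x) == 0 else out


def auto_sigma(centers: Sequence[float]) -> np.ndarray:
    """Sigma per center so adjacent Gaussians cross at degree 0.5.

    ``sigma_i = d_i / (2 * sqrt(2 ln 2))`` where ``d_i`` is the distance to
    the nearest neighbouring center (the gap equals a full width at half
    maximum, so two neighbours meet at their mutual midpoint with degree 0.5).
    """
    c = np.asarray(centers, dtype=float)
    if c.size < 2:
        raise ValueError("auto_sigma needs at least 2 centers")
    gaps = np.diff(np.sort(c))
    if np.any(gaps == 0):
        raise ValueError("auto_sigma: duplicate centers")
    nearest = np.minimum(
        np.concatenate([[gaps[0]], gaps]), np.concatenate([gaps, [gaps[-1]]])
    )
    return nearest / FWHM_FACTOR


@dataclass(frozen=True)
class FuzzyVariable:
    """A named variable on a closed domain with an ordered bank of MFs.

    ``load_scores`` reinterprets each level as a cognitive-load score in
    [0, 1]; default is the monotone ramp ``i / (n - 1)``.  A U-shaped
    variable (e.g. temperature with a comfort center) scores its middle
    level 0 and both extremes 1.
    """

    name: str
    domain: tuple[float, float]
    mfs: tuple[MembershipFunction, ...]
    load_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"variable {self.name!r}: empty domain")
        centers = [mf.center for mf in self.mfs]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError(f"variable {self.name!r}: MF centers must be strictly increasing")
        if not self.load_scores:
            n = len(self.mfs)
            scores = (0.5,) if n == 1 else tuple(i / (n - 1) for i in range(n))
            object.__setattr__(self, "load_scores", scores)
        if len(self.load_scores) != len(self.mfs):
            raise ValueError(f"variable {self.name!r}: one load score per MF required")
        grid = np.linspace(lo, hi, 501)
        total = np.sum([mf.degree(grid) for mf in self.mfs], axis=0)
        if np.any(total <= 0):
            raise ValueError(f"variable {self.name!r}: MFs do not cover the domain")

    @property
    def n_levels(self) -> int:
        return len(self.mfs)

    def fuzzify(self, x) -> np.ndarray:
        """Degrees for all levels; shape (..., n_levels). Clips to the domain."""
        x = np.clip(np.asarray(x, dtype=float), *self.domain)
        return np.stack([mf.degree(x) for mf in self.mfs], axis=-1)


@dataclass(frozen=True)
class RuleBase:
    """Total mapping from input-level combinations to one output level."""

    n_levels_per_input: tuple[int, ...]
    n_out: int
    table: Mapping[tuple[int, ...], int]
    policy: str = "monotone-mean"

    def __post_init__(self) -> None:
        expected = 1
        for n in self.n_levels_per_input:
            expected *= n
        if len(self.table) != expected:
            raise ValueError("rule base is not total")
        for combo, out in self.table.items():
            if not 0 <= out < self.n_out:
                raise ValueError(f"rule {combo}: output level {out} out of range")

    def check_monotone(self, load_scores_per_input: Sequence[Sequence[float]]) -> None:
        """Raise unless raising any input's load score never lowers the output."""
        for combo, out in self.table.items():
            for i, li in enumerate(combo):
                for lj in range(self.n_levels_per_input[i]):
                    if load_scores_per_input[i][lj] > load_scores_per_input[i][li]:
                        other = self.table[combo[:i] + (lj,) + combo[i + 1 :]]
                        if other < out:
                            raise ValueError("rule base is not monotone in load")


def build_monotone_rulebase(
    levels_per_input: Sequence[int | Sequence[float]],
    n_out: int = 3,
) -> RuleBase:
    """Build the total monotone rule base from per-input load scores.

    Each entry of ``levels_per_input`` is either a level count (scores default
    to the ramp ``i/(n-1)``) or an explicit score sequence.  Output level =
    anchor in {0, 1/(n_out-1), ..., 1} nearest the mean score, ties upward.
    """
    scores: list[tuple[float, ...]] = []
    for spec in levels_per_input:
        if isinstance(spec, int):
            if spec < 2:
                raise ValueError("each input needs at least 2 levels")
            scores.append(tuple(i / (spec - 1) for i in range(spec)))
        else:
            scores.append(tuple(float(s) for s in spec))
    table: dict[tuple[int, ...], int] = {}
    for combo in product(*(range(len(s)) for s in scores)):
        mean = sum(s[li] for s, li in zip(scores, combo)) / len(combo)
        out = min(int(math.floor(mean * (n_out - 1) + 0.5)), n_out - 1)
        table[combo] = out
    rb = RuleBase(tuple(len(s) for s in scores), n_out, table)
    rb.check_monotone(scores)
    return rb


def output_load_variable(grid_hint: str = "load") -> FuzzyVariable:
    """Standard [0, 1] output: three Gaussians at 0.1 / 0.5 / 0.9, auto sigma."""
    centers = [0.1, 0.5, 0.9]
    sigmas = auto_sigma(centers)
    return FuzzyVariable(
        grid_hint,
        (0.0, 1.0),
        tuple(
            gaussmf(lbl, c, s)
            for lbl, c, s in zip(("low", "medium", "high"), centers, sigmas)
        ),
    )


@dataclass(frozen=True)
class FISConfig:
    """One Mamdani inference node: inputs, output variable, rules, defuzz."""

    name: str
    inputs: tuple[FuzzyVariable, ...]
    output: FuzzyVariable
    rules: RuleBase
    defuzz: str = "centroid"
    grid_n: int = 2001

    def __post_init__(self) -> None:
        if self.output.domain != (0.0, 1.0):
            raise ValueError("output domain must be [0, 1]")
        if self.defuzz != "centroid":
            raise ValueError("only centroid defuzzification is supported")
        if tuple(v.n_levels for v in self.inputs) != self.rules.n_levels_per_input:
            raise ValueError("rule base shape does not match inputs")
        if self.output.n_levels != self.rules.n_out:
            raise ValueError("rule base output levels do not match output variable")

    def to_dict(self) -> dict:
        def mf_d(mf: MembershipFunction) -> dict:
            return {"label": mf.label, "shape": mf.shape, "params": list(mf.params)}

        def var_d(v: FuzzyVariable) -> dict:
            return {
                "name": v.name,
                "domain": list(v.domain),
                "mfs": [mf_d(m) for m in v.mfs],
                "load_scores": list(v.load_scores),
            }

        return {
            "name": self.name,
            "inputs": [var_d(v) for v in self.inputs],
            "output": var_d(self.output),
            "rules": {
                "policy": self.rules.policy,
                "n_out": self.rules.n_out,
                "table": {",".join(map(str, k)): v for k, v in self.rules.table.items()},
            },
            "defuzz": self.defuzz,
            "grid_n": self.grid_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FISConfig":
        def var_f(vd: dict) -> FuzzyVariable:
            mfs = tuple(
                MembershipFunction(m["label"], m["shape"], tuple(m["params"]))
                for m in vd["mfs"]
            )
            return FuzzyVariable(
                vd["name"], tuple(vd["domain"]), mfs, tuple(vd.get("load_scores", ()))
            )

        inputs = tuple(var_f(v) for v in d["inputs"])
        table = {
            tuple(int(i) for i in k.split(",")): int(v)
            for k, v in d["rules"]["table"].items()
        }
        rules = RuleBase(
            tuple(v.n_levels for v in inputs),
            int(d["rules"]["n_out"]),
            table,
            d["rules"].get("policy", "monotone-mean"),
        )
        return cls(d["name"], inputs, var_f(d["output"]), rules, d["defuzz"], int(d["grid_n"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FISConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def defuzz_centroid(membership: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Centroid of a membership profile over a uniform grid of [0, 1]."""
    mu = np.asarray(membership, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, mu.size)
    den = mu.sum()
    if den <= 0:
        raise ValueError("empty aggregate: no positive membership to defuzzify")
    return float((grid * mu).sum() / den)


# Cache of output-MF samples keyed by (output variable identity, grid_n).
_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _output_grid(cfg: FISConfig) -> tuple[np.ndarray, np.ndarray]:
    key = (id(cfg.output), cfg.grid_n)
    hit = _GRID_CACHE.get(key)
    if hit is None:
        grid = np.linspace(0.0, 1.0, cfg.grid_n)
        mfs = np.stack([mf.degree(grid) for mf in cfg.output.mfs])
        hit = (grid, mfs)
        _GRID_CACHE[key] = hit
    return hit


def evaluate_fis_batch(cfg: FISConfig, X: np.ndarray) -> np.ndarray:
    """Evaluate the FIS on an (n, d) array of crisp input vectors.

    Mamdani min/min/max with centroid defuzzification; inputs are clipped to
    their variable domains before fuzzification.  Returns shape (n,).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(cfg.inputs):
        raise ValueError(f"{cfg.name}: expected {len(cfg.inputs)} inputs, got {X.shape[1]}")
    n = X.shape[0]
    degrees = [v.fuzzify(X[:, i]) for i, v in enumerate(cfg.inputs)]

    # Firing strength per output level = max over rules mapping to that level
    # of the min of antecedent degrees.
    strength = np.zeros((n, cfg.rules.n_out))
    for combo, out in cfg.rules.table.items():
        s = degrees[0][:, combo[0]]
        for i, li in enumerate(combo[1:], start=1):
            s = np.minimum(s, degrees[i][:, li])
        np.maximum(strength[:, out], s, out=strength[:, out])

    grid, out_mfs = _output_grid(cfg)
    result = np.empty(n)
    chunk = max(1, 4_000_000 // (cfg.rules.n_out * cfg.grid_n))
    for lo in range(0, n, chunk):
        s = strength[lo : lo + chunk]
        # aggregate: max over levels of min(strength, clipped output MF)
        agg = np.minimum(s[:, :, None], out_mfs[None, :, :]).max(axis=1)
        den = agg.sum(axis=1)
        if np.any(den <= 0):
            raise ValueError("empty aggregate: no rule fired")
        result[lo : lo + chunk] = (agg @ grid) / den
    return result


def evaluate_fis(cfg: FISConfig, x: Sequence[float]) -> float:
    """Single-vector convenience wrapper around :func:`evaluate_fis_batch`."""
    return float(evaluate_fis_batch(cfg, np.asarray(x, dtype=float)[None, :])[0])
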