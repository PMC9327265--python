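"""The composite productivity index and its four-class rating.

A tree's productivity score is the weighted sum of three submodels,

    y = 0.24 y1 + 0.71 y2 + 0.05 y3,

where y1 is environmental suitability (contribution-weighted quadratic
suitability of seven variables), y2 is tree growth
(0.54 GD/71.5 + 0.46 CW/11.5 with GD the ground diameter in cm and CW the
crown width in m, the denominators being the observed study maxima), and
y3 is management (0.57 harvest + 0.43 protection on their ordinal score
grids).  The top-level weights come from normalizing the standardized
path coefficients of the fitted covariance-structure model (0.325, 0.982,
0.075 -> 0.24, 0.71, 0.05), and the submodel weights likewise (0.826,
0.693 -> 0.54, 0.46; 0.866, 0.651 -> 0.57, 0.43).

Scores are classified as unproductive (< 0.3), poorly productive
([0.3, 0.5)), productive ([0.5, 0.8]) and highly productive (> 0.8).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import TOP_SEVEN, TOP_SEVEN_CONTRIBUTIONS, TOP_SEVEN_OPTIMA, \
    VARIABLE_RANGES

__all__ = [
    "QuadraticSuitability", "IndexWeights", "ProductivityIndex",
    "normalize_weights", "report_weights", "quadratic_suitability",
    "suitable_range", "y1", "y2", "y3", "productivity", "classify",
    "summarize", "default_quadratics", "CLASS_LABELS",
]

CLASS_LABELS = ["unproductive", "poorly productive", "productive",
                "highly productive"]

HARVEST_GRID = (0.0, 0.5, 1.0)
PROTECTION_GRID = (0.0, 0.1, 0.5, 1.0)


def normalize_weights(raw) -> np.ndarray:
    """Divide nonnegative coefficients by their sum (exact, unrounded)."""
    w = np.asarray(raw, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return w / total


def report_weights(raw, decimals: int = 2) -> list[float]:
    """Normalized weights rounded for reporting (2 decimals by default)."""
    return [float(round(v, decimals)) for v in normalize_weights(raw)]


@dataclass
class QuadraticSuitability:
    """Single-variable suitability: a quadratic bump or plateau.

    A point optimum ``mu`` gives s(x) = max(0, 1 - ((x - mu)/rho)^2); a
    plateau ``(a, b)`` gives s = 1 inside and the same quadratic decay of
    half-width ``rho`` outside.  ``weight`` is the variable's normalized
    contribution share in y1.
    """

    name: str
    optimum: float | tuple[float, float]
    rho: float
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"{self.name}: rho must be positive")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"{self.name}: weight must be in [0, 1]")
        if isinstance(self.optimum, (tuple, list)):
            a, b = self.optimum
            if a > b:
                raise ValueError(f"{self.name}: plateau must have a <= b")
            self.optimum = (float(a), float(b))

    def suitability(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if isinstance(self.optimum, tuple):
            a, b = self.optimum
            d = np.where(x < a, a - x, np.where(x > b, x - b, 0.0))
        else:
            d = np.abs(x - self.optimum)
        u = d / self.rho
        return np.clip(1.0 - u * u, 0.0, 1.0)

    def suitable_range(self) -> tuple[float, float]:
        """Interval where suitability >= 0.5 (the suitability threshold)."""
        half = self.rho / np.sqrt(2.0)
        if isinstance(self.optimum, tuple):
            a, b = self.optimum
            return (a - half, b + half)
        return (self.optimum - half, self.optimum + half)

    def to_dict(self) -> dict:
        opt = list(self.optimum) if isinstance(self.optimum, tuple) else self.optimum
        return {"name": self.name, "optimum": opt, "rho": self.rho,
                "weight": self.weight}


def quadratic_suitability(x, q: QuadraticSuitability) -> np.ndarray:
    return q.suitability(x)


def suitable_range(q: QuadraticSuitability) -> tuple[float, float]:
    return q.suitable_range()


def default_quadratics() -> list[QuadraticSuitability]:
    """The frozen seven-variable environmental submodel.

    Optima are the published most-suitable values; half-widths default to
    the distance from the optimum (or plateau edge) to the nearer end of
    the observed value range, so suitability reaches zero exactly at the
    edge of the observed conditions; weights are the relative
    contributions normalized over the seven variables.
    """
    total = sum(TOP_SEVEN_CONTRIBUTIONS.values())
    out = []
    for name in TOP_SEVEN:
        lo, hi = VARIABLE_RANGES[name]
        opt = TOP_SEVEN_OPTIMA[name]
        if isinstance(opt, tuple):
            rho = min(opt[0] - lo, hi - opt[1])
        else:
            rho = min(opt - lo, hi - opt)
        out.append(QuadraticSuitability(name, opt, rho,
                                        TOP_SEVEN_CONTRIBUTIONS[name] / total))
    return out


@dataclass
class IndexWeights:
    """Frozen coefficients of the composite index."""

    top: tuple[float, float, float] = (0.24, 0.71, 0.05)
    growth: tuple[float, float] = (0.54, 0.46)
    growth_denominators: tuple[float, float] = (71.5, 11.5)  # GD cm, CW m
    management: tuple[float, float] = (0.57, 0.43)
    thresholds: tuple[float, float, float] = (0.3, 0.5, 0.8)

    def __post_init__(self) -> None:
        for name, w in (("top", self.top), ("growth", self.growth),
                        ("management", self.management)):
            if abs(sum(w) - 1.0) > 1e-6:
                raise ValueError(f"{name} weights must sum to 1, got {sum(w)}")
        t = self.thresholds
        if not (0 < t[0] < t[1] < t[2] < 1):
            raise ValueError("thresholds must be strictly increasing in (0, 1)")
        if min(self.growth_denominators) <= 0:
            raise ValueError("denominators must be positive")


def y1(env_values: dict | pd.DataFrame,
       quadratics: list[QuadraticSuitability]) -> np.ndarray | float:
    """Environmental suitability: contribution-weighted quadratic scores."""
    w = np.array([q.weight for q in quadratics])
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("quadratic weights must sum to 1")
    scalar = isinstance(env_values, dict)
    table = pd.DataFrame([env_values]) if scalar else env_values
    missing = [q.name for q in quadratics if q.name not in table.columns]
    if missing:
        raise ValueError(f"missing environmental variable(s): {missing}")
    s = np.zeros(len(table))
    for q in quadratics:
        s += q.weight * q.suitability(table[q.name].to_numpy(dtype=float))
    return float(s[0]) if scalar else s


def y2(ground_diameter, crown_width, weights: IndexWeights | None = None):
    """Tree-growth submodel: weighted, max-standardized GD and CW.

    Values above the study maxima (71.5 cm, 11.5 m) are clipped to a
    per-term score of 1 with a warning.
    """
    w = weights or IndexWeights()
    gd = np.asarray(ground_diameter, dtype=float)
    cw = np.asarray(crown_width, dtype=float)
    if np.any(gd < 0) or np.any(cw < 0):
        raise ValueError("measurements must be nonnegative")
    d_gd, d_cw = w.growth_denominators
    if np.any(gd > d_gd) or np.any(cw > d_cw):
        warnings.warn("measurement above the study maximum; per-term score "
                      "clipped to 1", stacklevel=2)
    out = (w.growth[0] * np.minimum(gd / d_gd, 1.0)
           + w.growth[1] * np.minimum(cw / d_cw, 1.0))
    return float(out) if out.ndim == 0 else out


def y3(harvest, protection, weights: IndexWeights | None = None):
    """Management submodel: weighted ordinal harvest and protection scores."""
    w = weights or IndexWeights()
    h = np.asarray(harvest, dtype=float)
    p = np.asarray(protection, dtype=float)
    if np.any((h < 0) | (h > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("management scores must be within [0, 1]")
    if (not np.all(np.isin(np.round(h, 6), HARVEST_GRID))
            or not np.all(np.isin(np.round(p, 6), PROTECTION_GRID))):
        warnings.warn("management score off the ordinal grid; accepted as-is",
                      stacklevel=2)
    out = w.management[0] * h + w.management[1] * p
    return float(out) if out.ndim == 0 else out


def productivity(y1_, y2_, y3_, weights: IndexWeights | None = None):
    """Top-level score y = w1 y1 + w2 y2 + w3 y3 (components in [0, 1])."""
    w = weights or IndexWeights()
    comps = [np.asarray(c, dtype=float) for c in (y1_, y2_, y3_)]
    for c in comps:
        if np.any((c < -1e-9) | (c > 1 + 1e-9)):
            raise ValueError("index components must be within [0, 1]")
    out = w.top[0] * comps[0] + w.top[1] * comps[1] + w.top[2] * comps[2]
    return float(out) if out.ndim == 0 else out


def classify(y, weights: IndexWeights | None = None):
    """Four-class rating of a score in [0, 1].

    Boundaries resolve as [0, 0.3) unproductive, [0.3, 0.5) poorly
    productive, [0.5, 0.8] productive, (0.8, 1] highly productive.
    """
    w = weights or IndexWeights()
    t1, t2, t3 = w.thresholds
    arr = np.asarray(y, dtype=float)
    if np.any((arr < -1e-9) | (arr > 1 + 1e-9)):
        raise ValueError("score outside [0, 1]")
    idx = np.select([arr < t1, arr < t2, arr <= t3], [0, 1, 2], default=3)
    labels = np.asarray(CLASS_LABELS, dtype=object)[idx]
    return str(labels) if arr.ndim == 0 else labels


def summarize(labels) -> dict:
    """Per-class counts and shares, plus the low-productivity share.

    The low-productivity share pools the poorly-productive and
    unproductive classes; ``low_share_pct`` is rounded to a whole percent.
    """
    arr = np.asarray(labels, dtype=object)
    if arr.size == 0:
        raise ValueError("no classified trees to summarize")
    counts = {c: int(np.sum(arr == c)) for c in CLASS_LABELS}
    total = int(arr.size)
    low = counts["unproductive"] + counts["poorly productive"]
    return {
        "counts": counts,
        "total": total,
        "shares": {c: counts[c] / total for c in CLASS_LABELS},
        "low_share": low / total,
        "low_share_pct": int(round(100.0 * low / total)),
    }


@dataclass
class ProductivityIndex:
    """Bundle of the frozen scoring constants; scores whole tree tables."""

    quadratics: list[QuadraticSuitability] = field(default_factory=default_quadratics)
    weights: IndexWeights = field(default_factory=IndexWeights)

    def score_table(self, trees: pd.DataFrame) -> pd.DataFrame:
        """Append y1, y2, y3, y and the class label to a tree table."""
        out = trees.copy()
        out["y1"] = y1(trees, self.quadratics)
        out["y2"] = y2(trees["ground_diameter"], trees["crown_width"],
                       self.weights)
        out["y3"] = y3(trees["harvest_intensity"], trees["protection"],
                       self.weights)
        out["y"] = productivity(out["y1"], out["y2"], out["y3"], self.weights)
        out["productivity_class"] = classify(out["y"].to_numpy(), self.weights)
        return out

    def to_dict(self) -> dict:
        return {
            "quadratics": [q.to_dict() for q in self.quadratics],
            "weights": {
                "top": list(self.weights.top),
                "growth": list(self.weights.growth),
                "growth_denominators": list(self.weights.growth_denominators),
                "management": list(self.weights.management),
                "thresholds": list(self.weights.thresholds),
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ProductivityIndex":
        quads = [QuadraticSuitability(
            q["name"],
            tuple(q["optimum"]) if isinstance(q["optimum"], list) else q["optimum"],
            q["rho"], q.get("weight", 0.0)) for q in d["quadratics"]]
        w = d["weights"]
        weights = IndexWeights(tuple(w["top"]), tuple(w["growth"]),
                               tuple(w["growth_denominators"]),
                               tuple(w["management"]), tuple(w["thresholds"]))
        return cls(quads, weights)

    @classmethod
    def from_json(cls, path: str) -> "ProductivityIndex":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
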