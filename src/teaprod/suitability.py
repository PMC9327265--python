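"""Presence/background maximum-entropy suitability modelling.

The model is the Gibbs density over background cells

    P_w(x) = exp(f(x) . w) / Z(w),   Z(w) = sum_bg exp(f(x) . w)

with features f(x) = (z_1, z_1^2, ..., z_K, z_K^2) built from variables
standardized over the background.  Fitting maximizes the regularized
training gain

    G(w) = mean_presence f(x).w - log Z(w) + log N_bg - (reg/2) |w|^2

by cyclic coordinate ascent with exact one-dimensional Newton steps; the
gain increase of every accepted update is attributed to the variable whose
feature moved, which yields the percent-contribution accounting.  The
effective ridge strength is reg / sqrt(n_presence) (the usual sample-size
scaling of maxent regularization).  The ridge keeps the objective smooth,
so the same optimum is reachable by any generic optimizer (a property the
test-suite exploits).

Suitability is reported on two scales: the raw scale (the Gibbs density,
nonnegative) and the logistic scale r e^H / (1 + r e^H) with H the entropy
of the fitted background distribution, which maps a typical cell to 0.5
and lives in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

__all__ = [
    "EvaluationProtocol", "SuitabilityFit", "transform_aspect", "fit_maxent",
    "percent_contribution", "permutation_importance", "jackknife_gains",
    "evaluate", "response_curve",
]


def transform_aspect(aspect_degrees):
    """Decompose terrain aspect into east-west and north-south components.

    Returns ``(sin, cos)`` of the compass angle: +1 east-west means due
    east, +1 north-south means due north.  Values outside [0, 360) are
    reduced modulo 360.
    """
    a = np.asarray(aspect_degrees, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("aspect must be finite")
    rad = np.deg2rad(np.mod(a, 360.0))
    return np.sin(rad), np.cos(rad)


@dataclass
class EvaluationProtocol:
    """How held-out discrimination (AUC) is estimated.

    ``kind='cross-validation'`` runs k-fold CV over presences (the default,
    10 folds); ``kind='subsample'`` draws ``replicates`` random
    train/test splits with the given test fraction.
    """

    kind: str = "cross-validation"
    folds: int = 10
    replicates: int = 10
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"cross-validation", "subsample"}:
            raise ValueError(f"unknown protocol kind: {self.kind}")
        if self.kind == "cross-validation" and self.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test fraction must be in (0, 1)")


@dataclass
class SuitabilityFit:
    """A fitted maxent model plus its importance diagnostics."""

    variables: list[str]
    weights: np.ndarray            # (2K,) linear+quadratic per variable
    regularization: float
    bg_means: np.ndarray
    bg_sds: np.ndarray
    log_z: float                   # log-partition over the training background
    entropy: float                 # entropy of the fitted background distribution
    gain: float                    # regularized training gain at the optimum
    gain_trace: list[float] = field(default_factory=list)
    gain_by_variable: dict[str, float] = field(default_factory=dict)
    contributions: dict[str, float] = field(default_factory=dict)
    permutation: dict[str, float] = field(default_factory=dict)
    jackknife: dict[str, dict[str, float]] = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    variable_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    presence_means: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)

    def features(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for i, v in enumerate(self.variables):
            z = (table[v].to_numpy(dtype=float) - self.bg_means[i]) / self.bg_sds[i]
            cols.append(z)
            cols.append(z * z)
        return np.column_stack(cols)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        return self.features(table) @ self.weights

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        """Gibbs density relative to the training background (nonnegative)."""
        return np.exp(self.linear_predictor(table) - self.log_z)

    def logistic(self, table: pd.DataFrame) -> np.ndarray:
        """Logistic-scale suitability in [0, 1]."""
        eta = self.linear_predictor(table) - self.log_z + self.entropy
        out = np.empty_like(eta)
        pos = eta >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
        e = np.exp(eta[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "weights": self.weights.tolist(),
            "regularization": self.regularization,
            "bg_means": self.bg_means.tolist(),
            "bg_sds": self.bg_sds.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "contributions": self.contributions,
            "permutation": self.permutation,
            "jackknife": self.jackknife,
            "auc": self.auc,
            "variable_ranges": {k: list(v) for k, v in self.variable_ranges.items()},
            "presence_means": self.presence_means,
            "dropped": self.dropped,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _prepare(presences: pd.DataFrame, background: pd.DataFrame,
             variables: list[str] | None):
    if variables is None:
        skip = {"lon", "lat", "outside_extent"}
        variables = [c for c in background.columns
                     if c not in skip and np.issubdtype(background[c].dtype, np.number)]
    keep, dropped = [], []
    for v in variables:
        if background[v].std() <= 1e-12:
            dropped.append(v)
        else:
            keep.append(v)
    if dropped:
        warnings.warn(f"constant variable(s) dropped: {dropped}", stacklevel=3)
    return keep, dropped


def fit_maxent(presences: pd.DataFrame, background: pd.DataFrame,
               regularization: float = 1.0,
               variables: list[str] | None = None,
               max_epochs: int = 200, tol: float = 1e-8) -> SuitabilityFit:
    """Fit the penalized maxent model by coordinate ascent.

    ``presences`` and ``background`` are per-point variable tables (as
    produced by raster extraction).  Constant variables are dropped with a
    warning; the ridge strength ``regularization`` applies per feature.
    """
    if len(presences) < 2:
        raise ValueError("need at least 2 presence rows")
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    variables, dropped = _prepare(presences, background, variables)
    if not variables:
        raise ValueError("no usable (non-constant) variables")
    # per-observation scaling of the ridge; floor guards singular designs
    reg = max(regularization, 1e-8) / np.sqrt(len(presences))

    bg_means = background[variables].mean().to_numpy(dtype=float)
    bg_sds = background[variables].std(ddof=0).to_numpy(dtype=float)

    def feats(table: pd.DataFrame) -> np.ndarray:
        cols = []
        for i, v in enumerate(variables):
            z = (table[v].to_numpy(dtype=float) - bg_means[i]) / bg_sds[i]
            cols.append(z)
            cols.append(z * z)
        return np.column_stack(cols)

    f_pr = feats(presences)
    f_bg = feats(background)
    n_bg = len(background)
    k = f_bg.shape[1]
    w = np.zeros(k)
    mean_pr = f_pr.mean(axis=0)

    eta_bg = np.zeros(n_bg)

    def gain_of(eta: np.ndarray, wvec: np.ndarray) -> float:
        lz = logsumexp(eta)
        return (float(mean_pr @ wvec) - lz + np.log(n_bg)
                - 0.5 * reg * float(wvec @ wvec))

    gain = gain_of(eta_bg, w)  # == 0 at w = 0
    trace = [gain]
    gain_by_feature = np.zeros(k)

    for _epoch in range(max_epochs):
        epoch_start = gain
        for j in range(k):
            lz = logsumexp(eta_bg)
            p_bg = np.exp(eta_bg - lz)
            ef = float(p_bg @ f_bg[:, j])
            ef2 = float(p_bg @ (f_bg[:, j] ** 2))
            grad = mean_pr[j] - ef - reg * w[j]
            hess = (ef2 - ef * ef) + reg
            step = grad / hess
            # damped Newton: backtrack until the gain does not decrease
            for _ in range(30):
                w_new = w[j] + step
                eta_new = eta_bg + f_bg[:, j] * step
                w_try = w.copy()
                w_try[j] = w_new
                g_new = gain_of(eta_new, w_try)
                if g_new >= gain - 1e-14:
                    break
                step *= 0.5
            else:
                continue
            if g_new > gain:
                gain_by_feature[j] += g_new - gain
            gain = g_new
            w[j] = w_new
            eta_bg = eta_new
        trace.append(gain)
        if gain - epoch_start < tol:
            break

    lz = logsumexp(eta_bg)
    p_bg = np.exp(eta_bg - lz)
    entropy = float(-np.sum(p_bg * (eta_bg - lz)))

    gain_by_var = {}
    for i, v in enumerate(variables):
        gain_by_var[v] = float(gain_by_feature[2 * i] + gain_by_feature[2 * i + 1])

    fit = SuitabilityFit(
        variables=variables, weights=w, regularization=regularization,
        bg_means=bg_means, bg_sds=bg_sds, log_z=float(lz), entropy=entropy,
        gain=float(gain), gain_trace=trace, gain_by_variable=gain_by_var,
        dropped=dropped,
        variable_ranges={
            v: (float(min(presences[v].min(), background[v].min())),
                float(max(presences[v].max(), background[v].max())))
            for v in variables},
        presence_means={v: float(presences[v].mean()) for v in variables},
    )
    fit.contributions = percent_contribution(fit)
    return fit


def percent_contribution(fit: SuitabilityFit) -> dict[str, float]:
    """Share of the training-gain increase attributed to each variable.

    Each accepted coordinate update's gain increase is credited to the
    variable whose feature moved; shares are normalized to sum to 100.
    A fit with zero total gain gets a uniform attribution with a warning.
    """
    raw = np.array([fit.gain_by_variable.get(v, 0.0) for v in fit.variables])
    total = raw.sum()
    if total <= 0:
        warnings.warn("zero total gain: uniform contribution attribution",
                      stacklevel=2)
        raw = np.ones_like(raw)
        total = raw.sum()
    return {v: float(100.0 * r / total) for v, r in zip(fit.variables, raw)}


def _training_auc(fit: SuitabilityFit, presences: pd.DataFrame,
                  background: pd.DataFrame) -> float:
    scores = np.concatenate([fit.linear_predictor(presences),
                             fit.linear_predictor(background)])
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(background))])
    return float(roc_auc_score(y, scores))


def permutation_importance(fit: SuitabilityFit, presences: pd.DataFrame,
                           background: pd.DataFrame, seed: int = 0,
                           ) -> dict[str, float]:
    """Normalized drop in training AUC when one variable is shuffled.

    Each variable's values are permuted jointly across presences and
    background; drops (floored at 0) are normalized to sum to 100.
    """
    n_pr, n_bg = len(presences), len(background)
    if n_pr + n_bg < 5:
        raise ValueError("too few rows to permute (< 5)")
    rng = np.random.default_rng(seed)
    base = _training_auc(fit, presences, background)
    drops = {}
    for v in fit.variables:
        combined = np.concatenate([presences[v].to_numpy(dtype=float),
                                   background[v].to_numpy(dtype=float)])
        perm = rng.permutation(combined)
        pr = presences.copy()
        bg = background.copy()
        pr[v] = perm[:n_pr]
        bg[v] = perm[n_pr:]
        drops[v] = max(0.0, base - _training_auc(fit, pr, bg))
    total = sum(drops.values())
    if total <= 0:
        warnings.warn("no AUC drop under any permutation: uniform importance",
                      stacklevel=2)
        return {v: 100.0 / len(drops) for v in drops}
    out = {v: float(100.0 * d / total) for v, d in drops.items()}
    fit.permutation = out
    return out


def jackknife_gains(presences: pd.DataFrame, background: pd.DataFrame,
                    variables: list[str], regularization: float = 1.0,
                    ) -> dict[str, dict[str, float]]:
    """Regularized training gain with each variable alone and excluded.

    Returns ``{variable: {"with_only": g, "without": g}, "_full": {...}}``;
    a failed refit records NaN for that entry and the run continues.
    """
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full = fit_maxent(presences, background, regularization, variables)
    out: dict[str, dict[str, float]] = {"_full": {"gain": full.gain}}
    for v in variables:
        entry = {}
        for key, subset in (("with_only", [v]),
                            ("without", [u for u in variables if u != v])):
            try:
                entry[key] = fit_maxent(presences, background, regularization,
                                        subset).gain
            except Exception:  # refit failure: record and continue
                entry[key] = float("nan")
        out[v] = entry
    return out


def evaluate(protocol: EvaluationProtocol, presences: pd.DataFrame,
             background: pd.DataFrame, regularization: float = 1.0,
             variables: list[str] | None = None) -> dict:
    """Replicated held-out AUC (presence vs background).

    Cross-validation folds partition the presences; each replicate trains
    on the remaining presences (full background) and scores the held-out
    presences against the background.  Returns per-replicate AUCs with
    their mean and standard deviation.
    """
    aucs = []
    rng = np.random.default_rng(protocol.seed)
    if protocol.kind == "cross-validation":
        kf = KFold(n_splits=protocol.folds, shuffle=True,
                   random_state=protocol.seed)
        splits = kf.split(presences)
    else:
        n = len(presences)
        n_test = max(1, int(round(protocol.test_fraction * n)))
        splits = []
        for _ in range(protocol.replicates):
            perm = rng.permutation(n)
            splits.append((perm[n_test:], perm[:n_test]))
    for train_idx, test_idx in splits:
        if len(test_idx) == 0 or len(train_idx) < 2:
            warnings.warn("fold skipped: not enough presences", stacklevel=2)
            continue
        fit = fit_maxent(presences.iloc[train_idx], background,
                         regularization, variables)
        scores = np.concatenate([fit.linear_predictor(presences.iloc[test_idx]),
                                 fit.linear_predictor(background)])
        y = np.concatenate([np.ones(len(test_idx)), np.zeros(len(background))])
        aucs.append(float(roc_auc_score(y, scores)))
    if not aucs:
        raise ValueError("no evaluable folds")
    return {"replicates": aucs, "mean": float(np.mean(aucs)),
            "sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0}


def response_curve(fit: SuitabilityFit, variable: str, n_points: int = 100,
                   ) -> pd.DataFrame:
    """Logistic output along one variable, others held at presence means.

    The variable sweeps its observed range (presences plus background);
    the result has columns ``x`` and ``logistic``.
    """
    if variable not in fit.variables:
        raise ValueError(f"variable {variable!r} not in model")
    lo, hi = fit.variable_ranges[variable]
    xs = np.linspace(lo, hi, n_points)
    frame = pd.DataFrame({v: np.full(n_points, fit.presence_means[v])
                          for v in fit.variables})
    frame[variable] = xs
    return pd.DataFrame({"x": xs, "logistic": fit.logistic(frame)})
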