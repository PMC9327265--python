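"""Latent-variable path models fitted by maximum-likelihood covariance discrepancy.

The model is the standard LISREL-type structure

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

with Lambda the indicator loadings, B the (recursive) latent-to-latent
paths, Psi the exogenous-latent and disturbance (co)variances, and Theta
the indicator residual (co)variances.  Estimation minimizes

    F_ML(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

over the free parameters, with S the unbiased (n-1 denominator) sample
covariance; chi^2 = (n - 1) F_ML at the optimum.  Fit indices (GFI, AGFI,
CFI, AIC) follow the conventional definitions with the independence model
as baseline.

Two ready-made specifications mirror the study design: a 17-indicator
initial model (seven environmental, seven tree-growth, two management
indicators and the total tree value) and a reduced 7-indicator final model
(annual precipitation, coldest-month minimum temperature, ground diameter,
crown width, harvest intensity, protection, total value), both with the
latent structure environment -> {growth, management, productivity},
management -> {growth, productivity}, growth -> productivity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SampleMoments", "PathModelSpec", "FittedPathModel",
    "sample_covariance", "implied_covariance", "fit_ml", "standardize",
    "fit_indices", "model_dof", "final_model_spec", "initial_model_spec",
    "load_spec", "FINAL_MODEL_VARIABLES", "INITIAL_MODEL_VARIABLES",
]

FINAL_MODEL_VARIABLES = [
    "bio12", "bio6", "ground_diameter", "crown_width",
    "harvest_intensity", "protection", "total_value_rmb",
]
INITIAL_MODEL_VARIABLES = [
    "bio12", "bio6", "bio17", "bio3", "bio15", "bio4", "srad",
    "tree_age", "dbh", "ground_diameter", "tree_height", "crown_width",
    "height_under_branch", "growth_vigor",
    "harvest_intensity", "protection", "total_value_rmb",
]


@dataclass
class SampleMoments:
    """Unbiased sample covariance matrix with means and sample size."""

    cov: np.ndarray
    means: np.ndarray
    n: int
    variables: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.variables)
        if self.cov.shape != (p, p):
            raise ValueError("covariance shape inconsistent with variables")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    def reorder(self, variables: list[str]) -> "SampleMoments":
        idx = [self.variables.index(v) for v in variables]
        return SampleMoments(self.cov[np.ix_(idx, idx)],
                             np.asarray(self.means)[idx], self.n,
                             list(variables), self.n_dropped)


def sample_covariance(table: pd.DataFrame, variables: list[str]) -> SampleMoments:
    """Unbiased (n-1 denominator) covariance of the selected columns.

    Rows with any missing value are dropped listwise; the count is recorded
    on the result.  A zero-variance column is an error (it cannot enter a
    covariance-structure fit).
    """
    missing_cols = [v for v in variables if v not in table.columns]
    if missing_cols:
        raise ValueError(f"columns absent from table: {missing_cols}")
    sub = table[variables].astype(float)
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    n = len(complete)
    if n < 3:
        raise ValueError(f"need at least 3 complete rows, got {n}")
    x = complete.to_numpy()
    s = np.cov(x, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    zero = [v for v, var in zip(variables, np.diag(s)) if var <= 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return SampleMoments(s, x.mean(axis=0), n, list(variables), n_dropped)


@dataclass
class PathModelSpec:
    """Declarative path-model specification.

    ``loadings`` entries are ``(indicator, latent, fixed)`` with ``fixed``
    a number or None (free); likewise ``paths`` = ``(source, target, fixed)``,
    ``latent_variances`` = ``(latent, fixed)`` (exogenous variance or
    disturbance variance), ``residual_variances`` = ``(indicator, fixed)``
    and ``residual_covariances`` = ``(indicator, indicator, fixed)``.
    Latents must be listed in causal order (recursive model).
    """

    observed: list[str]
    latents: list[str]
    loadings: list[tuple[str, str, float | None]]
    paths: list[tuple[str, str, float | None]]
    latent_variances: list[tuple[str, float | None]]
    residual_variances: list[tuple[str, float | None]]
    residual_covariances: list[tuple[str, str, float | None]] = field(
        default_factory=list)
    name: str = "path model"

    def __post_init__(self) -> None:
        obs, lat = set(self.observed), set(self.latents)
        lat_order = {l: i for i, l in enumerate(self.latents)}
        for o, l, _ in self.loadings:
            if o not in obs or l not in lat:
                raise ValueError(f"loading refers to unknown name: {o} -> {l}")
        for s, t, _ in self.paths:
            if s not in lat or t not in lat:
                raise ValueError(f"path refers to unknown latent: {s} -> {t}")
            if lat_order[s] >= lat_order[t]:
                raise ValueError(
                    f"path {s} -> {t} violates the causal latent order")
        with_ind = {l for _, l, _ in self.loadings}
        if with_ind != lat:
            raise ValueError(f"latents without indicators: {sorted(lat - with_ind)}")
        scaled = {l for _, l, v in self.loadings if v is not None}
        if scaled != lat:
            raise ValueError(
                f"latents lack a fixed scale-setting loading: {sorted(lat - scaled)}")

    # -- free-parameter bookkeeping -------------------------------------
    def free_parameters(self) -> list[tuple[str, str]]:
        """(kind, label) for each free parameter, in canonical order."""
        out = []
        for o, l, v in self.loadings:
            if v is None:
                out.append(("loading", f"{l}=~{o}"))
        for s, t, v in self.paths:
            if v is None:
                out.append(("path", f"{s}->{t}"))
        for l, v in self.latent_variances:
            if v is None:
                out.append(("variance", f"psi[{l}]"))
        for o, v in self.residual_variances:
            if v is None:
                out.append(("variance", f"theta[{o}]"))
        for a, b, v in self.residual_covariances:
            if v is None:
                out.append(("covariance", f"theta[{a},{b}]"))
        return out

    def matrices(self, values: np.ndarray) -> tuple[np.ndarray, ...]:
        """Assemble (Lambda, B, Psi, Theta) from a free-parameter vector."""
        p, m = len(self.observed), len(self.latents)
        oi = {o: i for i, o in enumerate(self.observed)}
        li = {l: i for i, l in enumerate(self.latents)}
        lam = np.zeros((p, m))
        b = np.zeros((m, m))
        psi = np.zeros((m, m))
        theta = np.zeros((p, p))
        it = iter(values)
        for o, l, v in self.loadings:
            lam[oi[o], li[l]] = next(it) if v is None else v
        for s, t, v in self.paths:
            b[li[t], li[s]] = next(it) if v is None else v
        for l, v in self.latent_variances:
            psi[li[l], li[l]] = next(it) if v is None else v
        for o, v in self.residual_variances:
            theta[oi[o], oi[o]] = next(it) if v is None else v
        for a, c, v in self.residual_covariances:
            val = next(it) if v is None else v
            theta[oi[a], oi[c]] = theta[oi[c], oi[a]] = val
        return lam, b, psi, theta

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "observed": self.observed,
            "latents": self.latents,
            "loadings": [list(t) for t in self.loadings],
            "paths": [list(t) for t in self.paths],
            "latent_variances": [list(t) for t in self.latent_variances],
            "residual_variances": [list(t) for t in self.residual_variances],
            "residual_covariances": [list(t) for t in self.residual_covariances],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathModelSpec":
        return cls(
            observed=list(d["observed"]),
            latents=list(d["latents"]),
            loadings=[tuple(t) for t in d["loadings"]],
            paths=[tuple(t) for t in d["paths"]],
            latent_variances=[tuple(t) for t in d["latent_variances"]],
            residual_variances=[tuple(t) for t in d["residual_variances"]],
            residual_covariances=[tuple(t) for t in d.get("residual_covariances", [])],
            name=d.get("name", "path model"),
        )


def load_spec(path: str) -> PathModelSpec:
    """Read a declarative model spec from a JSON or YAML file."""
    with open(path) as fh:
        text = fh.read()
    if path.endswith((".yaml", ".yml")):
        import yaml
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return PathModelSpec.from_dict(d)


def model_dof(spec: PathModelSpec) -> tuple[int, int, int]:
    """(p, q, df): observed count, free-parameter count, degrees of freedom."""
    p = len(spec.observed)
    q = len(spec.free_parameters())
    df = p * (p + 1) // 2 - q
    if df < 0:
        raise ValueError(f"model not identified: df = {df} < 0")
    return p, q, df


def implied_covariance(spec: PathModelSpec, values: np.ndarray) -> np.ndarray:
    """Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta."""
    lam, b, psi, theta = spec.matrices(np.asarray(values, dtype=float))
    m = len(spec.latents)
    i_b = np.eye(m) - b
    if abs(np.linalg.det(i_b)) < 1e-12:
        raise ValueError("(I - B) is singular: non-recursive or degenerate paths")
    a = np.linalg.inv(i_b)
    v = a @ psi @ a.T
    return lam @ v @ lam.T + theta


def _f_ml(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        solve = np.linalg.solve(sigma, s)
    except np.linalg.LinAlgError:
        return np.inf
    return logdet - logdet_s + np.trace(solve) - s.shape[0]


@dataclass
class FittedPathModel:
    """Converged ML estimates plus fit statistics for one specification."""

    spec: PathModelSpec
    estimates: dict[str, float]
    values: np.ndarray
    f_ml: float
    chi2: float
    df: int
    n: int
    converged: bool
    n_restarts: int
    sample: SampleMoments

    def implied_covariance(self) -> np.ndarray:
        return implied_covariance(self.spec, self.values)

    def latent_covariance(self) -> np.ndarray:
        lam, b, psi, theta = self.spec.matrices(self.values)
        a = np.linalg.inv(np.eye(len(self.spec.latents)) - b)
        return a @ psi @ a.T

    def to_dict(self) -> dict:
        std = standardize(self)
        chi2, dff, gfi, agfi, cfi, aic = fit_indices(self, self.sample, self.n)
        return {
            "model": self.spec.name,
            "n": self.n,
            "converged": bool(self.converged),
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "standardized": {k: float(v) for k, v in std.items()},
            "fit": {"f_ml": float(self.f_ml), "chi2": float(chi2), "df": int(dff),
                    "gfi": float(gfi), "agfi": float(agfi) if agfi is not None else None,
                    "cfi": float(cfi), "aic": float(aic)},
        }


def _initial_vector(spec: PathModelSpec, s: np.ndarray) -> np.ndarray:
    """Deterministic, scale-aware starting values."""
    oi = {o: i for i, o in enumerate(spec.observed)}
    var_obs = np.diag(s)
    # reference indicator per latent (the one with a fixed loading)
    ref_var = {}
    for o, l, v in spec.loadings:
        if v is not None and l not in ref_var:
            ref_var[l] = var_obs[oi[o]] / (v * v if v else 1.0)
    x0 = []
    for kind, label in spec.free_parameters():
        if kind == "loading":
            x0.append(1.0)
        elif kind == "path":
            x0.append(0.1)
        elif kind == "covariance":
            x0.append(0.0)
        else:  # variance
            if label.startswith("psi["):
                latent = label[4:-1]
                x0.append(0.5 * ref_var.get(latent, 1.0))
            else:
                obs = label[6:-1]
                x0.append(0.5 * var_obs[oi[obs]])
    return np.array(x0, dtype=float)


def fit_ml(moments: SampleMoments, spec: PathModelSpec, *,
           restarts: int = 10, seed: int = 0, tol: float = 1e-8,
           canonicalize: bool = True) -> FittedPathModel:
    """Minimize F_ML over the free parameters.

    Variance parameters are optimized on a log scale (with a floor of
    1e-6 times the matching sample variance, which also bounds Heywood
    cases); loadings, paths and residual covariances are unconstrained.
    The optimizer is quasi-Newton (L-BFGS-B) from one deterministic start
    plus ``restarts`` randomly perturbed starts; the best optimum wins.
    """
    s_mom = moments.reorder(spec.observed)
    s = s_mom.cov
    p, q, df = model_dof(spec)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")
    free = spec.free_parameters()
    kinds = [k for k, _ in free]
    labels = [l for _, l in free]
    oi = {o: i for i, o in enumerate(spec.observed)}
    var_obs = np.diag(s)

    floors = np.zeros(len(free))
    for i, (kind, label) in enumerate(free):
        if kind == "variance":
            if label.startswith("theta["):
                floors[i] = 1e-6 * var_obs[oi[label[6:-1]]]
            else:
                floors[i] = 1e-8 * float(np.mean(var_obs))

    def to_free(x: np.ndarray) -> np.ndarray:
        out = x.copy()
        for i, kind in enumerate(kinds):
            if kind == "variance":
                out[i] = floors[i] + np.exp(x[i])
        return out

    def to_opt(v: np.ndarray) -> np.ndarray:
        out = v.copy()
        for i, kind in enumerate(kinds):
            if kind == "variance":
                out[i] = np.log(max(v[i] - floors[i], 1e-10))
        return out

    def objective(x: np.ndarray) -> float:
        vals = to_free(x)
        try:
            sigma = implied_covariance(spec, vals)
        except ValueError:
            return 1e10
        f = _f_ml(sigma, s, logdet_s)
        return f if np.isfinite(f) else 1e10

    x0 = to_opt(_initial_vector(spec, s))
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(restarts + 1):
        start = x0 if trial == 0 else x0 + rng.normal(0, 0.3, size=x0.shape)
        res = optimize.minimize(objective, start, method="L-BFGS-B",
                                options={"maxiter": 3000, "ftol": tol,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError(f"ML fit failed to converge; best F_ML = "
                           f"{None if best is None else best.fun}")
    values = to_free(best.x)
    # Heywood reporting: any variance pinned at its floor
    for i, kind in enumerate(kinds):
        if kind == "variance" and values[i] <= floors[i] + 1e-8 * max(floors[i], 1e-12):
            warnings.warn(f"variance {labels[i]} bounded at its admissibility "
                          "floor (Heywood case)", stacklevel=2)
    if canonicalize:
        values = _canonicalize_single_indicator(spec, values, floors, kinds, labels)
    f_val = objective(to_opt(values))
    chi2 = (moments.n - 1) * max(f_val, 0.0)
    estimates = dict(zip(labels, values))
    return FittedPathModel(spec, estimates, values, max(f_val, 0.0), chi2, df,
                           moments.n, bool(best.success or f_val < 1e9),
                           restarts, s_mom)


def _canonicalize_single_indicator(spec, values, floors, kinds, labels):
    """Resolve the disturbance/residual ridge of single-indicator latents.

    For a terminal latent measured by exactly one indicator with a fixed
    loading, only psi + theta_indicator is identified.  Moving the whole
    sum into the disturbance (theta -> its floor) leaves Sigma unchanged
    and makes standardized coefficients deterministic.
    """
    by_latent: dict[str, list[tuple[str, float | None]]] = {}
    for o, l, v in spec.loadings:
        by_latent.setdefault(l, []).append((o, v))
    outgoing = {s for s, _, _ in spec.paths}
    label_idx = {lab: i for i, lab in enumerate(labels)}
    out = values.copy()
    for latent, inds in by_latent.items():
        if latent in outgoing or len(inds) != 1:
            continue
        obs, loading = inds[0]
        if loading is None:
            continue
        t_lab, p_lab = f"theta[{obs}]", f"psi[{latent}]"
        if t_lab in label_idx and p_lab in label_idx:
            ti, pi = label_idx[t_lab], label_idx[p_lab]
            excess = out[ti] - floors[ti]
            out[pi] += excess / (loading * loading)
            out[ti] = floors[ti]
    return out


def standardize(fit: FittedPathModel) -> dict[str, float]:
    """Standardized loadings and path coefficients.

    Each raw coefficient is scaled by sd(source)/sd(target) using the
    model-implied standard deviations of latents and indicators.
    """
    spec = fit.spec
    lam, b, psi, theta = spec.matrices(fit.values)
    m = len(spec.latents)
    a = np.linalg.inv(np.eye(m) - b)
    v = a @ psi @ a.T
    sigma = lam @ v @ lam.T + theta
    sd_lat = np.sqrt(np.diag(v))
    sd_obs = np.sqrt(np.diag(sigma))
    if np.any(sd_lat <= 0) or np.any(sd_obs <= 0):
        raise ValueError("zero implied variance; cannot standardize")
    li = {l: i for i, l in enumerate(spec.latents)}
    oi = {o: i for i, o in enumerate(spec.observed)}
    out: dict[str, float] = {}
    for o, l, _v in spec.loadings:
        out[f"{l}=~{o}"] = lam[oi[o], li[l]] * sd_lat[li[l]] / sd_obs[oi[o]]
    for s_, t, _v in spec.paths:
        out[f"{s_}->{t}"] = b[li[t], li[s_]] * sd_lat[li[s_]] / sd_lat[li[t]]
    return out


def fit_indices(fit: FittedPathModel, moments: SampleMoments, n: int | None = None,
                ) -> tuple[float, int, float, float | None, float, float]:
    """(chi2, df, GFI, AGFI, CFI, AIC) for a converged fit.

    The baseline for CFI is the independence model (free variances, zero
    covariances), whose ML solution is diag(S) in closed form.  AGFI is
    None when df = 0.
    """
    n = fit.n if n is None else n
    s = moments.reorder(fit.spec.observed).cov
    p = s.shape[0]
    sigma = fit.implied_covariance()
    chi2 = (n - 1) * fit.f_ml
    df = fit.df
    q = len(fit.spec.free_parameters())
    # GFI / AGFI
    sinv_s = np.linalg.solve(sigma, s)
    resid = sinv_s - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(sinv_s @ sinv_s)
    agfi = None if df == 0 else 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
    # baseline (independence) model
    sign, logdet_s = np.linalg.slogdet(s)
    f_base = float(np.sum(np.log(np.diag(s))) - logdet_s)
    chi2_b = (n - 1) * f_base
    df_b = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    aic = chi2 + 2 * q
    return chi2, df, gfi, agfi, cfi, aic


# ---------------------------------------------------------------------------
# Pinned study specifications


def final_model_spec(residual_correlations: bool = False) -> PathModelSpec:
    """The reduced 7-indicator model (p=7, q=20, df=8).

    ``residual_correlations=True`` additionally frees the covariances of
    the harvest and protection residuals with the total-value residual
    (df drops to 6); the default omits them.
    """
    observed = list(FINAL_MODEL_VARIABLES)
    latents = ["environment", "management", "growth", "productivity"]
    loadings = [
        ("bio12", "environment", 1.0),
        ("bio6", "environment", None),
        ("ground_diameter", "growth", 1.0),
        ("crown_width", "growth", None),
        ("harvest_intensity", "management", 1.0),
        ("protection", "management", None),
        ("total_value_rmb", "productivity", 1.0),
    ]
    paths = [
        ("environment", "management", None),
        ("environment", "growth", None),
        ("management", "growth", None),
        ("environment", "productivity", None),
        ("management", "productivity", None),
        ("growth", "productivity", None),
    ]
    latent_variances = [(l, None) for l in latents]
    residual_variances = [(o, None) for o in observed]
    residual_covariances = []
    if residual_correlations:
        residual_covariances = [
            ("harvest_intensity", "total_value_rmb", None),
            ("protection", "total_value_rmb", None),
        ]
    return PathModelSpec(observed, latents, loadings, paths, latent_variances,
                         residual_variances, residual_covariances,
                         name="final (7-indicator)")


def initial_model_spec() -> PathModelSpec:
    """The full 17-indicator model (p=17, q=39, df=114).

    Productivity is equated with the total value (loading fixed at 1,
    residual fixed at 0).
    """
    observed = list(INITIAL_MODEL_VARIABLES)
    latents = ["environment", "management", "growth", "productivity"]
    env = ["bio12", "bio6", "bio17", "bio3", "bio15", "bio4", "srad"]
    tree = ["ground_diameter", "tree_age", "dbh", "tree_height", "crown_width",
            "height_under_branch", "growth_vigor"]
    loadings = [(o, "environment", 1.0 if o == env[0] else None) for o in env]
    loadings += [(o, "growth", 1.0 if o == tree[0] else None) for o in tree]
    loadings += [("harvest_intensity", "management", 1.0),
                 ("protection", "management", None)]
    loadings += [("total_value_rmb", "productivity", 1.0)]
    paths = [
        ("environment", "management", None),
        ("environment", "growth", None),
        ("management", "growth", None),
        ("environment", "productivity", None),
        ("management", "productivity", None),
        ("growth", "productivity", None),
    ]
    latent_variances = [(l, None) for l in latents]
    residual_variances = [(o, 0.0 if o == "total_value_rmb" else None)
                          for o in observed]
    return PathModelSpec(observed, latents, loadings, paths, latent_variances,
                         residual_variances, name="initial (17-indicator)")
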