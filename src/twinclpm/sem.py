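"""Covariance-structure estimation in RAM form.

A structural model over ``m`` variables (observed + latent) is written as

    v = A v + m + e,    e ~ N(0, S)

with ``A`` the directed-path matrix (regressions and loadings), ``S`` the
symmetric covariance matrix of exogenous parts/residuals, and ``m`` the
intercept vector.  With ``B = (I - A)^{-1}`` the implied moments of the
observed subvector (selected by the filter ``F``) are

    mu    = F B m
    Sigma = F B S B' F'

Estimation is full-information maximum likelihood: rows are grouped by
missingness pattern and each pattern contributes the marginal Gaussian
log-density of its observed coordinates.  Gradients of the deviance with
respect to every free entry of (A, S, m) are computed analytically from
the RAM algebra, which is what makes repeated fitting of the pair-level
twin models cheap enough for simulation studies.

Free parameters are declared by string labels; entries sharing a label are
constrained equal.  Free variances are optimised on the log scale so the
search is unconstrained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "ObservedMatrix",
    "implied_moments",
    "fiml_loglik",
    "fit_model",
    "robust_se",
    "standardize",
    "saturated_loglik",
    "baseline_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1.0e10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ObservedMatrix:
    """Rectangular data for the engine: one row per independent unit.

    ``values`` uses NaN as the missing marker; ``columns`` is the manifest
    tying columns to model variable names; ``ids`` carries the unit (pair or
    individual) identifiers.
    """

    values: np.ndarray
    columns: list[str]
    ids: np.ndarray | None = None
    unit: str = "pair"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"column manifest length {len(self.columns)} does not match "
                f"data width {self.values.shape[1]}"
            )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


class ModelSpec:
    """RAM-form model specification with labelled free parameters.

    Parameters
    ----------
    variables
        Ordered names of all model variables, observed and latent.
    observed
        Names of the observed variables (the filter ``F`` selects these rows
        in this order; it must match the data column manifest).
    """

    def __init__(self, variables: list[str], observed: list[str]):
        self.variables = list(variables)
        self.observed = list(observed)
        idx = {v: i for i, v in enumerate(self.variables)}
        if len(idx) != len(self.variables):
            raise ValueError("duplicate variable names")
        missing = [v for v in self.observed if v not in idx]
        if missing:
            raise ValueError(f"observed variables not in roster: {missing}")
        self._idx = idx
        m = len(self.variables)
        self.A_fixed = np.zeros((m, m))
        self.S_fixed = np.zeros((m, m))
        self.m_fixed = np.zeros(m)
        self.A_labels: dict[tuple[int, int], str] = {}
        self.S_labels: dict[tuple[int, int], str] = {}  # i <= j stored once
        self.m_labels: dict[int, str] = {}
        self.start: dict[str, float] = {}
        self.start_frac: dict[str, float] = {}  # start as fraction of mean obs variance
        self.meta: dict = {}                    # builder-provided context (traits, ...)

    # -- construction -----------------------------------------------------
    def ix(self, name: str) -> int:
        return self._idx[name]

    def add_path(self, src: str, dst: str, *, label: str | None = None,
                 value: float = 0.0, start: float | None = None) -> None:
        """Directed path src -> dst (entry A[dst, src])."""
        i, j = self.ix(dst), self.ix(src)
        if label is None:
            self.A_fixed[i, j] = value
        else:
            self.A_labels[(i, j)] = label
            if start is not None:
                self.start[label] = start

    def add_cov(self, a: str, b: str, *, label: str | None = None,
                value: float = 0.0, start: float | None = None,
                start_frac: float | None = None) -> None:
        """(Co)variance entry S[a, b] (symmetric; a == b for a variance)."""
        i, j = sorted((self.ix(a), self.ix(b)))
        if label is None:
            self.S_fixed[i, j] = self.S_fixed[j, i] = value
        else:
            self.S_labels[(i, j)] = label
            if start is not None:
                self.start[label] = start
            if start_frac is not None:
                self.start_frac[label] = start_frac

    def add_mean(self, v: str, *, label: str | None = None,
                 value: float = 0.0, start: float | None = None) -> None:
        i = self.ix(v)
        if label is None:
            self.m_fixed[i] = value
        else:
            self.m_labels[i] = label
            if start is not None:
                self.start[label] = start

    # -- derived structure -------------------------------------------------
    @property
    def free_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in (self.A_labels, self.S_labels, self.m_labels):
            for lab in d.values():
                seen.setdefault(lab, None)
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def variance_labels(self) -> set[str]:
        return {lab for (i, j), lab in self.S_labels.items() if i == j}

    def n_moments(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 + p

    def degrees_of_freedom(self) -> int:
        df = self.n_moments() - self.n_free
        if df < 0:
            raise ValueError(
                f"over-parameterised model: {self.n_free} free parameters for "
                f"{self.n_moments()} observed moments"
            )
        return df

    def parameter_table(self) -> pd.DataFrame:
        """Human-readable listing of every entry, status and label."""
        rows = []
        names = self.variables
        for (i, j), lab in sorted(self.A_labels.items()):
            rows.append(("path", f"{names[j]} -> {names[i]}", "free", lab))
        nz = np.argwhere(self.A_fixed != 0)
        for i, j in nz:
            rows.append(("path", f"{names[j]} -> {names[i]}", "fixed",
                         f"{self.A_fixed[i, j]:g}"))
        for (i, j), lab in sorted(self.S_labels.items()):
            kind = "variance" if i == j else "covariance"
            rows.append((kind, f"{names[i]} <-> {names[j]}", "free", lab))
        for i in np.argwhere(np.triu(self.S_fixed) != 0)[:, 0:0].tolist():
            pass
        iu = np.triu_indices(len(names))
        for i, j in zip(*iu):
            if self.S_fixed[i, j] != 0 and (min(i, j), max(i, j)) not in self.S_labels:
                kind = "variance" if i == j else "covariance"
                rows.append((kind, f"{names[i]} <-> {names[j]}", "fixed",
                             f"{self.S_fixed[i, j]:g}"))
        for i, lab in sorted(self.m_labels.items()):
            rows.append(("mean", names[i], "free", lab))
        return pd.DataFrame(rows, columns=["kind", "entry", "status", "label"])

    # -- compiled form -----------------------------------------------------
    def _compile(self) -> "_Compiled":
        return _Compiled(self)


class _Compiled:
    """Index arrays mapping the free-parameter vector into (A, S, m)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.labels = spec.free_labels
        self.lab_index = {lab: k for k, lab in enumerate(self.labels)}
        self.k = len(self.labels)
        m = len(spec.variables)
        self.m = m
        self.obs_idx = np.array([spec.ix(v) for v in spec.observed], dtype=int)
        self.p = len(self.obs_idx)
        # A entries
        self.A_e = np.array([(self.lab_index[lab], i, j)
                             for (i, j), lab in spec.A_labels.items()],
                            dtype=int).reshape(-1, 3)
        # S entries stored once with i <= j, diag flag
        se = [(self.lab_index[lab], i, j) for (i, j), lab in spec.S_labels.items()]
        self.S_e = np.array(se, dtype=int).reshape(-1, 3)
        self.S_diag = self.S_e[:, 1] == self.S_e[:, 2] if len(se) else np.zeros(0, bool)
        self.m_e = np.array([(self.lab_index[lab], i)
                             for i, lab in spec.m_labels.items()],
                            dtype=int).reshape(-1, 2)
        var_labs = spec.variance_labels()
        self.is_var = np.array([lab in var_labs for lab in self.labels], dtype=bool)

    def matrices(self, theta: np.ndarray):
        """Natural-scale parameter vector -> (A, S, mvec)."""
        spec = self.spec
        A = spec.A_fixed.copy()
        S = spec.S_fixed.copy()
        mv = spec.m_fixed.copy()
        if len(self.A_e):
            A[self.A_e[:, 1], self.A_e[:, 2]] = theta[self.A_e[:, 0]]
        if len(self.S_e):
            S[self.S_e[:, 1], self.S_e[:, 2]] = theta[self.S_e[:, 0]]
            S[self.S_e[:, 2], self.S_e[:, 1]] = theta[self.S_e[:, 0]]
        if len(self.m_e):
            mv[self.m_e[:, 1]] = theta[self.m_e[:, 0]]
        return A, S, mv

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        x = np.array(theta, dtype=float)
        x[self.is_var] = np.log(np.maximum(x[self.is_var], 1e-10))
        return x

    def from_unconstrained(self, x: np.ndarray) -> np.ndarray:
        theta = np.array(x, dtype=float)
        theta[self.is_var] = np.exp(np.clip(theta[self.is_var], -40.0, 40.0))
        return theta


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def _implied_from_matrices(comp: _Compiled, A, S, mv):
    m = comp.m
    ImA = np.eye(m) - A
    try:
        B = np.linalg.inv(ImA)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "singular (I - A): the directed paths contain a cyclic block"
        ) from exc
    W = B @ S @ B.T           # covariance of all model variables
    nu = B @ mv               # means of all model variables
    Sigma = W[np.ix_(comp.obs_idx, comp.obs_idx)]
    mu = nu[comp.obs_idx]
    return mu, Sigma, B, W, nu


def implied_moments(spec: ModelSpec, theta: dict[str, float] | np.ndarray):
    """Model-implied mean vector and covariance of the observed variables.

    ``theta`` maps labels to natural-scale values (or is a vector in
    ``spec.free_labels`` order).
    """
    comp = spec._compile()
    vec = _theta_vector(comp, theta)
    A, S, mv = comp.matrices(vec)
    mu, Sigma, *_ = _implied_from_matrices(comp, A, S, mv)
    Sigma = 0.5 * (Sigma + Sigma.T)
    return mu, Sigma


def _theta_vector(comp: _Compiled, theta) -> np.ndarray:
    if isinstance(theta, dict):
        missing = [lab for lab in comp.labels if lab not in theta]
        if missing:
            raise ValueError(f"missing parameter values for labels: {missing}")
        return np.array([theta[lab] for lab in comp.labels], dtype=float)
    vec = np.asarray(theta, dtype=float)
    if vec.shape != (comp.k,):
        raise ValueError(f"theta must have length {comp.k}")
    return vec


# ---------------------------------------------------------------------------
# missing-data patterns and FIML deviance
# ---------------------------------------------------------------------------

class _Patterns:
    """Sufficient statistics per missingness pattern.

    For pattern r with observed coordinate set o_r, n_r units, pattern mean
    ybar_r and ML scatter S_r the deviance contribution is

        n_r [ p_r log 2pi + log|Sigma_oo| + tr(Sigma_oo^{-1} S_r)
              + d' Sigma_oo^{-1} d ],   d = ybar_r - mu_o.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        mask = ~np.isnan(values)
        keep = mask.any(axis=1)          # all-missing rows contribute nothing
        self.n_dropped = int((~keep).sum())
        values, mask = values[keep], mask[keep]
        self.n_units = values.shape[0]
        self.p = values.shape[1]
        self.groups = []
        if self.n_units == 0:
            return
        # group rows by pattern
        codes = np.packbits(mask, axis=1).view()
        order = np.lexsort(codes.T[::-1])
        sm = mask[order]
        sv = values[order]
        boundaries = np.any(sm[1:] != sm[:-1], axis=1).nonzero()[0] + 1
        starts = np.concatenate([[0], boundaries, [len(sv)]])
        for a, b in zip(starts[:-1], starts[1:]):
            obs = np.flatnonzero(sm[a])
            block = sv[a:b][:, obs]
            n_r = b - a
            ybar = block.mean(axis=0)
            resid = block - ybar
            scatter = resid.T @ resid / n_r
            self.groups.append({
                "obs": obs, "n": int(n_r), "ybar": ybar, "S": scatter,
                "rows": sv[a:b], "rowblock": block,
            })
        self.complete = len(self.groups) == 1 and len(self.groups[0]["obs"]) == self.p


def _deviance_and_moment_grads(patterns: _Patterns, mu, Sigma):
    """Deviance (-2 loglik) plus gradients wrt Sigma (full p x p) and mu.

    Returns (dev, G, gmu, ok): if a pattern sub-block is not positive
    definite, returns a finite penalised value with a pushback gradient and
    ok=False.
    """
    p = patterns.p
    G = np.zeros((p, p))
    gmu = np.zeros(p)
    dev = 0.0
    ok = True
    for grp in patterns.groups:
        o = grp["obs"]
        n_r = grp["n"]
        sub = Sigma[np.ix_(o, o)]
        try:
            L = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            ok = False
            w, V = np.linalg.eigh(sub)
            bad = w < 1e-8
            dev += _PENALTY + 1e6 * float(np.sum((1e-8 - w[bad]) ** 2))
            push = (V[:, bad] * (-2e6 * (1e-8 - w[bad]))) @ V[:, bad].T
            G[np.ix_(o, o)] += push
            continue
        inv = np.linalg.inv(sub)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        d = grp["ybar"] - mu[o]
        Md = grp["S"] + np.outer(d, d)
        dev += n_r * (len(o) * _LOG2PI + logdet + float(np.sum(inv * Md)))
        G[np.ix_(o, o)] += n_r * (inv - inv @ Md @ inv)
        gmu[o] += -2.0 * n_r * (inv @ d)
    return dev, G, gmu, ok


def fiml_loglik(data: ObservedMatrix | np.ndarray, mu, Sigma) -> float:
    """Full-information Gaussian log-likelihood of ``data`` at (mu, Sigma).

    Each unit contributes the log-density of its observed coordinates under
    the corresponding marginal of N(mu, Sigma); all-missing rows contribute 0.
    """
    values = data.values if isinstance(data, ObservedMatrix) else np.asarray(data, float)
    patterns = _Patterns(values)
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    dev, _, _, ok = _deviance_and_moment_grads(patterns, mu, Sigma)
    if not ok:
        raise np.linalg.LinAlgError(
            "Sigma not positive definite on an observed sub-block"
        )
    return -0.5 * dev


# ---------------------------------------------------------------------------
# objective with analytic gradient
# ---------------------------------------------------------------------------

def _objective(comp: _Compiled, patterns: _Patterns, theta: np.ndarray):
    """Deviance and its gradient wrt natural-scale free parameters."""
    A, S, mv = comp.matrices(theta)
    mu, Sigma, B, W, nu = _implied_from_matrices(comp, A, S, mv)
    dev, G, gmu, ok = _deviance_and_moment_grads(patterns, mu, Sigma)
    # chain rule through the RAM algebra; see module docstring
    oi = comp.obs_idx
    C = B[oi, :]                     # F B            (p x m)
    V = W[oi, :]                     # F B S B'       (p x m)
    GC = G @ C
    M_A = C.T @ (G @ V)              # m x m
    M_S = C.T @ GC                   # m x m
    cg = C.T @ gmu                   # m
    Bm = B @ mv                      # m
    grad = np.zeros(comp.k)
    if len(comp.A_e):
        vals = 2.0 * M_A[comp.A_e[:, 1], comp.A_e[:, 2]] \
            + cg[comp.A_e[:, 1]] * Bm[comp.A_e[:, 2]]
        np.add.at(grad, comp.A_e[:, 0], vals)
    if len(comp.S_e):
        vals = np.where(comp.S_diag,
                        M_S[comp.S_e[:, 1], comp.S_e[:, 2]],
                        2.0 * M_S[comp.S_e[:, 1], comp.S_e[:, 2]])
        np.add.at(grad, comp.S_e[:, 0], vals)
    if len(comp.m_e):
        np.add.at(grad, comp.m_e[:, 0], cg[comp.m_e[:, 1]])
    return dev, grad, ok


def _make_unconstrained_objective(comp: _Compiled, patterns: _Patterns):
    def f(x):
        theta = comp.from_unconstrained(x)
        dev, grad, _ = _objective(comp, patterns, theta)
        grad = grad.copy()
        grad[comp.is_var] *= theta[comp.is_var]   # d value / d log value
        return dev, grad
    return f


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates and inference for a fitted model.

    ``params`` has one row per free label: estimate, naive SE, robust SE,
    z and two-sided p (robust), standardized estimate with delta-method CI.
    """

    spec: ModelSpec
    params: pd.DataFrame
    loglik: float
    loglik_sat: float | None
    loglik_base: float | None
    n_units: int
    n_params: int
    df: int
    chi2: float | None
    indices: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    grad_norm: float = np.nan
    n_iter: int = 0
    vcov_naive: np.ndarray | None = None
    vcov_robust: np.ndarray | None = None
    implied_mu: np.ndarray | None = None
    implied_Sigma: np.ndarray | None = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.params.index, self.params["estimate"]))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_units)

    def to_frame(self) -> pd.DataFrame:
        return self.params.copy()

    def to_tsv(self, path) -> None:
        """Parameter table: parameter, estimate, SE, p, std beta and 95% CI."""
        out = self.params.reset_index().rename(columns={"index": "parameter"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self) -> str:
        payload = {
            "estimates": {k: _jsonable(v) for k, v in self.estimates.items()},
            "robust_se": {k: _jsonable(v) for k, v in
                          zip(self.params.index, self.params["robust_se"])},
            "loglik": self.loglik,
            "n_units": self.n_units,
            "n_params": self.n_params,
            "df": self.df,
            "chi2": _jsonable(self.chi2),
            "aic": self.aic,
            "bic": self.bic,
            "indices": {k: _jsonable(v) for k, v in self.indices.items()},
            "converged": self.converged,
        }
        return json.dumps(payload, indent=2)


def _jsonable(v):
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v


# ---------------------------------------------------------------------------
# saturated / baseline helpers
# ---------------------------------------------------------------------------

def _sample_moments(values: np.ndarray):
    """Available-case means and ML covariance (pairwise, PD-repaired)."""
    df = pd.DataFrame(values)
    means = df.mean().to_numpy()
    cov = df.cov(ddof=0).to_numpy()
    bad = ~np.isfinite(cov)
    if bad.any():
        cov[bad] = 0.0
    # ensure positive definite starting point
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if w.min() < 1e-8:
        cov = cov + (1e-6 + abs(min(w.min(), 0.0))) * np.eye(cov.shape[0])
    return means, 0.5 * (cov + cov.T)


def _saturated_spec(columns: list[str]) -> ModelSpec:
    spec = ModelSpec(list(columns), list(columns))
    for i, a in enumerate(columns):
        spec.add_mean(a, label=f"_mu_{a}")
        for j in range(i, len(columns)):
            b = columns[j]
            spec.add_cov(a, b, label=f"_s_{a}_{b}")
    return spec


def _baseline_spec(columns: list[str]) -> ModelSpec:
    spec = ModelSpec(list(columns), list(columns))
    for a in columns:
        spec.add_mean(a, label=f"_mu_{a}")
        spec.add_cov(a, a, label=f"_v_{a}")
    return spec


def saturated_loglik(data: ObservedMatrix) -> float:
    """Log-likelihood of the unstructured (saturated) Gaussian model.

    Closed form (sample moments) with complete data; otherwise maximised by
    the same FIML machinery over all means and covariances.
    """
    patterns = _Patterns(data.values)
    if patterns.complete:
        grp = patterns.groups[0]
        mu, S = grp["ybar"], grp["S"]
        return fiml_loglik(data, mu, S)
    fit = fit_model(_saturated_spec(data.columns), data,
                    compute_se=False, compute_indices=False, _allow_sat=True)
    return fit.loglik


def baseline_loglik(data: ObservedMatrix) -> float:
    """Log-likelihood of the independence model (free means and variances)."""
    fit = fit_model(_baseline_spec(data.columns), data,
                    compute_se=False, compute_indices=False, _allow_sat=True)
    return fit.loglik


# ---------------------------------------------------------------------------
# start values
# ---------------------------------------------------------------------------

def _start_vector(comp: _Compiled, patterns: _Patterns, spec: ModelSpec) -> np.ndarray:
    p = patterns.p
    col_mean = np.zeros(p)
    col_var = np.ones(p)
    tot_n = np.zeros(p)
    for grp in patterns.groups:
        o = grp["obs"]
        col_mean[o] += grp["n"] * grp["ybar"]
        col_var[o] += grp["n"] * np.diag(grp["S"])
        tot_n[o] += grp["n"]
    nz = tot_n > 0
    col_mean[nz] /= tot_n[nz]
    col_var[nz] = np.maximum(col_var[nz] / tot_n[nz], 1e-6)
    vbar = float(np.mean(col_var[nz])) if nz.any() else 1.0

    obs_pos = {int(i): k for k, i in enumerate(comp.obs_idx)}
    # mean labels on observed variables start at the column mean
    mean_starts: dict[str, list[float]] = {}
    for i, lab in spec.m_labels.items():
        if i in obs_pos:
            mean_starts.setdefault(lab, []).append(col_mean[obs_pos[i]])
    var_labs = spec.variance_labels()
    # observed-diagonal variance labels start at a share of the column variance
    var_starts: dict[str, list[float]] = {}
    for (i, j), lab in spec.S_labels.items():
        if i == j and i in obs_pos:
            var_starts.setdefault(lab, []).append(col_var[obs_pos[i]])

    theta = np.zeros(comp.k)
    for k, lab in enumerate(comp.labels):
        if lab in spec.start:
            theta[k] = spec.start[lab]
        elif lab in spec.start_frac:
            theta[k] = spec.start_frac[lab] * vbar
        elif lab in mean_starts:
            theta[k] = float(np.mean(mean_starts[lab]))
        elif lab in var_starts:
            theta[k] = 0.9 * float(np.mean(var_starts[lab]))
        elif lab in var_labs:
            theta[k] = 0.5 * vbar
        else:
            theta[k] = 0.0
    return theta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_model(spec: ModelSpec, data: ObservedMatrix, *,
              compute_se: bool = True, compute_indices: bool = True,
              saturated_ll: float | None = None,
              baseline_ll: float | None = None,
              max_iter: int = 5000, gtol: float = 1e-5,
              theta0: dict[str, float] | None = None,
              _allow_sat: bool = False) -> FitResult:
    """Fit ``spec`` to ``data`` by FIML; optionally SEs and fit indices.

    With zero free parameters the log-likelihood is evaluated directly.
    Saturated and baseline models are fitted internally when indices are
    requested and their log-likelihoods are not supplied.
    """
    if list(data.columns) != list(spec.observed):
        raise ValueError(
            "data column manifest does not match the model's observed "
            f"variables; expected {spec.observed}, got {list(data.columns)}"
        )
    comp = spec._compile()
    patterns = _Patterns(data.values)
    n_units = patterns.n_units
    if n_units == 0:
        raise ValueError("no units with observed data")
    df = spec.degrees_of_freedom()
    warns: list[str] = []
    if comp.k >= n_units and comp.k > 0:
        warns.append(f"fewer units ({n_units}) than free parameters ({comp.k})")
        warnings.warn(warns[-1], stacklevel=2)
    for grp in patterns.groups:
        if grp["n"] > len(grp["obs"]):
            ew = np.linalg.eigvalsh(grp["S"])
            if ew[0] < 1e-10 * max(ew[-1], 1e-12):
                warns.append(
                    "observed covariance is singular within a missingness "
                    "pattern; some parameters may be unidentified")
                break

    if comp.k == 0:
        A, S, mv = comp.matrices(np.zeros(0))
        mu, Sigma, B, W, nu = _implied_from_matrices(comp, A, S, mv)
        dev, *_ = _deviance_and_moment_grads(patterns, mu, Sigma)
        ll = -0.5 * dev
        theta_hat = np.zeros(0)
        converged, grad_norm, n_iter = True, 0.0, 0
    else:
        theta0_vec = (_theta_vector(comp, theta0) if theta0 is not None
                      else _start_vector(comp, patterns, spec))
        x0 = comp.to_unconstrained(theta0_vec)
        fun = _make_unconstrained_objective(comp, patterns)
        res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                                         "ftol": 1e-12, "gtol": gtol, "maxcor": 25})
        theta_hat = comp.from_unconstrained(res.x)
        dev, grad, ok = _objective(comp, patterns, theta_hat)
        ll = -0.5 * dev
        grad_norm = float(np.linalg.norm(res.jac, ord=np.inf))
        n_iter = int(res.nit)
        converged = bool(ok) and (res.success or grad_norm < 1e-3 * max(1.0, n_units))
        if not converged:
            warns.append(f"optimizer did not converge: {res.message}")
        A, S, mv = comp.matrices(theta_hat)
        mu, Sigma, B, W, nu = _implied_from_matrices(comp, A, S, mv)

    params = pd.DataFrame(index=pd.Index(comp.labels, name="parameter"))
    params["estimate"] = theta_hat
    for col in ("naive_se", "robust_se", "z", "p"):
        params[col] = np.nan
    for col in ("std", "std_lo", "std_hi"):
        params[col] = np.nan

    result = FitResult(
        spec=spec, params=params, loglik=ll,
        loglik_sat=saturated_ll, loglik_base=baseline_ll,
        n_units=n_units, n_params=comp.k, df=df, chi2=None,
        converged=converged, grad_norm=grad_norm, n_iter=n_iter,
        implied_mu=mu, implied_Sigma=0.5 * (Sigma + Sigma.T),
        warnings_=warns,
    )
    result._comp = comp
    result._patterns = patterns
    result._theta = theta_hat
    result._W = W

    if compute_se and comp.k > 0 and converged:
        robust_se(result, data)
        standardize(result)

    if compute_indices and not _allow_sat:
        from . import fit_indices as fi
        if converged:
            if result.loglik_sat is None:
                result.loglik_sat = saturated_loglik(data)
            if result.loglik_base is None:
                result.loglik_base = baseline_loglik(data)
            fi.attach_indices(result)
        else:
            warns.append("fit indices withheld: model did not converge")
    return result


# ---------------------------------------------------------------------------
# inference: sandwich SEs, standardisation
# ---------------------------------------------------------------------------

def _numeric_hessian(comp: _Compiled, patterns: _Patterns, theta: np.ndarray):
    """Hessian of the deviance wrt natural parameters (central differences
    of the analytic gradient)."""
    k = comp.k
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for j in range(k):
        tp = theta.copy(); tp[j] += h[j]
        tm = theta.copy(); tm[j] -= h[j]
        _, gp, _ = _objective(comp, patterns, tp)
        _, gm, _ = _objective(comp, patterns, tm)
        H[:, j] = (gp - gm) / (2.0 * h[j])
    return 0.5 * (H + H.T)


def _unit_scores(comp: _Compiled, patterns: _Patterns, theta: np.ndarray):
    """Per-unit score vectors s_i = d loglik_i / d theta (natural scale)."""
    A, S, mv = comp.matrices(theta)
    mu, Sigma, B, W, nu = _implied_from_matrices(comp, A, S, mv)
    oi = comp.obs_idx
    C = B[oi, :]
    V = W[oi, :]
    Bm = B @ mv
    scores = np.zeros((patterns.n_units, comp.k))
    row0 = 0
    for grp in patterns.groups:
        o = grp["obs"]
        n_r = grp["n"]
        sub = Sigma[np.ix_(o, o)]
        inv = np.linalg.inv(sub)
        Cr = C[o, :]                       # p_r x m
        Vr = V[o, :]
        R = grp["rowblock"] - mu[o]        # n_r x p_r residuals
        Q = R @ inv                        # n_r x p_r  (rows are q_u')
        Au = Q @ Cr                        # n_r x m    a_u = Cr' q_u
        Bu = Q @ Vr                        # n_r x m    b_u = Vr' q_u
        constA = Cr.T @ inv @ Vr           # m x m
        constS = Cr.T @ inv @ Cr
        sl = slice(row0, row0 + n_r)
        if len(comp.A_e):
            i_e, j_e = comp.A_e[:, 1], comp.A_e[:, 2]
            vals = (-constA[i_e, j_e][None, :]
                    + Au[:, i_e] * Bu[:, j_e]
                    + Au[:, i_e] * Bm[j_e][None, :])
            for col in range(vals.shape[1]):
                scores[sl, comp.A_e[col, 0]] += vals[:, col]
        if len(comp.S_e):
            i_e, j_e = comp.S_e[:, 1], comp.S_e[:, 2]
            base = -constS[i_e, j_e][None, :] + Au[:, i_e] * Au[:, j_e]
            base = np.where(comp.S_diag[None, :], 0.5 * base, base)
            for col in range(base.shape[1]):
                scores[sl, comp.S_e[col, 0]] += base[:, col]
        if len(comp.m_e):
            i_e = comp.m_e[:, 1]
            vals = Au[:, i_e]
            for col in range(vals.shape[1]):
                scores[sl, comp.m_e[col, 0]] += vals[:, col]
        row0 += n_r
    return scores


def robust_se(fit: FitResult, data: ObservedMatrix | None = None) -> pd.DataFrame:
    """Naive and sandwich standard errors; updates ``fit.params`` in place.

    The sandwich is H^{-1} (sum_i s_i s_i') H^{-1} with H the observed
    information and s_i per-unit scores; with pairs as units, clustering by
    pair is automatic.
    """
    comp = fit._comp
    if data is not None and list(data.columns) != list(fit.spec.observed):
        raise ValueError("data does not match the fitted model")
    patterns = fit._patterns if data is None else _Patterns(data.values)
    theta = fit._theta
    if comp.k == 0:
        return fit.params
    H_dev = _numeric_hessian(comp, patterns, theta)
    H = 0.5 * H_dev                    # observed information of -loglik
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; using pseudo-inverse",
                      stacklevel=2)
        fit.warnings_.append("singular information matrix; pseudo-inverse used")
        Hinv = np.linalg.pinv(H)
    scores = _unit_scores(comp, patterns, theta)
    Bmat = scores.T @ scores
    vcov_naive = Hinv
    vcov_robust = Hinv @ Bmat @ Hinv
    fit.vcov_naive = vcov_naive
    fit.vcov_robust = vcov_robust
    with np.errstate(invalid="ignore"):
        fit.params["naive_se"] = np.sqrt(np.clip(np.diag(vcov_naive), 0, None))
        fit.params["robust_se"] = np.sqrt(np.clip(np.diag(vcov_robust), 0, None))
    se = fit.params["robust_se"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.params["estimate"].to_numpy() / se
    fit.params["z"] = z
    fit.params["p"] = 2.0 * stats.norm.sf(np.abs(z))
    return fit.params


def _standardized_vector(comp: _Compiled, theta: np.ndarray) -> np.ndarray:
    """Standardized value per free label (paths and covariances; variances
    and means pass through unscaled)."""
    A, S, mv = comp.matrices(theta)
    _, _, B, W, _ = _implied_from_matrices(comp, A, S, mv)
    sd = np.sqrt(np.clip(np.diag(W), 0.0, None))
    out = np.full(comp.k, np.nan)
    counts = np.zeros(comp.k)
    vals = np.zeros(comp.k)
    if len(comp.A_e):
        i_e, j_e = comp.A_e[:, 1], comp.A_e[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            sv = A[i_e, j_e] * sd[j_e] / sd[i_e]
        np.add.at(vals, comp.A_e[:, 0], sv)
        np.add.at(counts, comp.A_e[:, 0], 1.0)
    if len(comp.S_e):
        i_e, j_e = comp.S_e[:, 1], comp.S_e[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            sv = np.where(comp.S_diag, S[i_e, j_e],
                          S[i_e, j_e] / (sd[i_e] * sd[j_e]))
        np.add.at(vals, comp.S_e[:, 0], sv)
        np.add.at(counts, comp.S_e[:, 0], 1.0)
    if len(comp.m_e):
        np.add.at(vals, comp.m_e[:, 0], theta[comp.m_e[:, 0]])
        np.add.at(counts, comp.m_e[:, 0], 1.0)
    nz = counts > 0
    out[nz] = vals[nz] / counts[nz]
    return out


def standardize(fit: FitResult) -> pd.DataFrame:
    """Standardized estimates with delta-method 95% CIs (robust vcov).

    Paths are rescaled by SD(source)/SD(target) under the model-implied
    covariance of all variables (latents included); covariances become
    correlations.
    """
    comp = fit._comp
    theta = fit._theta
    if comp.k == 0:
        return fit.params
    std = _standardized_vector(comp, theta)
    fit.params["std"] = std
    vcov = fit.vcov_robust if fit.vcov_robust is not None else fit.vcov_naive
    if vcov is not None:
        J = np.zeros((comp.k, comp.k))
        h = 1e-5 * np.maximum(np.abs(theta), 1.0)
        for j in range(comp.k):
            tp = theta.copy(); tp[j] += h[j]
            tm = theta.copy(); tm[j] -= h[j]
            J[:, j] = (_standardized_vector(comp, tp)
                       - _standardized_vector(comp, tm)) / (2 * h[j])
        var_std = np.einsum("ij,jk,ik->i", J, vcov, J)
        se_std = np.sqrt(np.clip(var_std, 0.0, None))
        fit.params["std_lo"] = std - 1.96 * se_std
        fit.params["std_hi"] = std + 1.96 * se_std
    if np.isnan(std).any():
        bad = [lab for lab, v in zip(comp.labels, std) if np.isnan(v)]
        fit.warnings_.append(
            f"standardized value undefined (zero implied variance): {bad}")
    return fit.params
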