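"""Synthetic MZ twin panel generator with switchable confounding regimes.

Each trait score is assembled from components chosen to mirror what the
three panel models condition on:

* a **stable shared** component (genetic + shared environment as one block,
  identical within a pair, constant over time);
* a **stable nonshared** component (twin-unique, constant over time);
* a **within-person process** ``w`` following a lag-1 recursion
  ``w_t = B_t w_{t-1} + eta_t`` whose innovations split into a shared part
  (identical within the pair) and a nonshared part;
* optionally an unobserved **confounder** ``U`` loading on an exposure and
  an outcome trait, in one of three regimes:

  - ``shared_stable``      — one draw per pair, constant over occasions;
  - ``shared_timevarying`` — an independent draw per occasion, still
    identical within the pair;
  - ``nonshared_stable``   — one draw per twin, constant over occasions.

The regimes operationalise the models' control claims: twin differencing
removes anything shared (stable or not), random intercepts remove anything
stable (shared or not), and the plain CLPM removes neither.

All components are Gaussian.  The real instruments are short ordinal sum
scores; the normal approximation matches the normal-theory estimator used
downstream and is documented as a deliberate simplification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import OCCASIONS, TRAITS, Schema, TwinPanelTable

__all__ = ["SimulationConfig", "simulate_twin_panel", "regime_presets",
           "attach_covariates", "PRESET_NAMES", "FOCAL_PATH"]

REGIMES = ("none", "shared_stable", "shared_timevarying", "nonshared_stable")

#: focal cross-lagged path of the simulation studies: behavioural problems
#: driving later maladaptive parenting (target trait index 0, source 2)
FOCAL_PATH = ("bp", "mp")


def _arr(x, n, name):
    a = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


@dataclass
class SimulationConfig:
    """Variance components, true lagged effects and confounding regime."""

    n_pairs: int = 2000
    traits: tuple[str, ...] = TRAITS
    occasions: tuple[int, ...] = OCCASIONS
    mu: tuple[float, ...] | float = 0.0
    var_shared_stable: tuple[float, ...] | float = 0.4
    var_nonshared_stable: tuple[float, ...] | float = 0.0
    var_shared_innov: tuple[float, ...] | float = 0.2
    var_nonshared_innov: tuple[float, ...] | float = 0.3
    stable_cross_corr: float = 0.0      # corr of stable shared parts across traits
    innov_cross_corr: float = 0.0       # contemporaneous corr of innovations
    lagged_effects: object = 0.0        # (K,K) matrix [target, source] or (T-1,K,K)
    regime: str = "none"
    conf_load: tuple[float, ...] | float = 0.0
    conf_var: float = 1.0
    age_effect: tuple[float, ...] | float = 0.0
    sex_effect: tuple[float, ...] | float = 0.0
    missing_rate: tuple[float, ...] | float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        K, T = self.K, self.T
        for name in ("var_shared_stable", "var_nonshared_stable",
                     "var_shared_innov", "var_nonshared_innov"):
            v = _arr(getattr(self, name), K, name)
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.conf_var < 0:
            raise ValueError("conf_var must be nonnegative")
        if self.regime == "none" and np.any(_arr(self.conf_load, K, "conf_load") != 0):
            raise ValueError("conf_load must be zero when regime='none'")
        B = self.B_matrices()
        if B.shape != (T - 1, K, K):
            raise ValueError(f"lagged_effects must broadcast to ({T-1},{K},{K})")

    @property
    def K(self) -> int:
        return len(self.traits)

    @property
    def T(self) -> int:
        return len(self.occasions)

    def B_matrices(self) -> np.ndarray:
        B = np.asarray(self.lagged_effects, dtype=float)
        if B.ndim == 0:
            B = float(B) * np.eye(self.K)   # scalar = common autoregression
        if B.ndim == 2:
            B = np.repeat(B[None, :, :], self.T - 1, axis=0)
        return B

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lagged_effects"] = np.asarray(self.B_matrices()).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("traits", "occasions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("mu", "var_shared_stable", "var_nonshared_stable",
                    "var_shared_innov", "var_nonshared_innov",
                    "conf_load", "age_effect", "sex_effect", "missing_rate"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _corr_cov(var: np.ndarray, rho: float) -> np.ndarray:
    sd = np.sqrt(var)
    R = np.full((len(var), len(var)), rho) + (1 - rho) * np.eye(len(var))
    return R * np.outer(sd, sd)


def simulate_twin_panel(config: SimulationConfig,
                        seed: int | None = None) -> TwinPanelTable:
    """Draw an MZ twin panel from the generative model; reproducible from
    ``seed`` (falls back to ``config.seed``)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K, T = config.n_pairs, config.K, config.T
    mu = _arr(config.mu, K, "mu")
    lam = _arr(config.conf_load, K, "conf_load")
    B = config.B_matrices()

    cov_sh = _corr_cov(_arr(config.var_shared_stable, K, "v"), config.stable_cross_corr)
    t_shared = _mvn(rng, cov_sh, n)
    sd_ns = np.sqrt(_arr(config.var_nonshared_stable, K, "v"))
    t_ns = [rng.standard_normal((n, K)) * sd_ns for _ in range(2)]

    cov_si = _corr_cov(_arr(config.var_shared_innov, K, "v"), config.innov_cross_corr)
    cov_ni = _corr_cov(_arr(config.var_nonshared_innov, K, "v"), config.innov_cross_corr)

    # confounder draws
    sd_u = np.sqrt(config.conf_var)
    if config.regime == "shared_stable":
        U = [np.repeat(rng.standard_normal((n, 1)) * sd_u, T, axis=1)] * 2
    elif config.regime == "shared_timevarying":
        u = rng.standard_normal((n, T)) * sd_u
        U = [u, u]
    elif config.regime == "nonshared_stable":
        U = [np.repeat(rng.standard_normal((n, 1)) * sd_u, T, axis=1)
             for _ in range(2)]
    else:
        U = [np.zeros((n, T)), np.zeros((n, T))]

    # within-person recursion, shared + nonshared innovations
    w = [np.zeros((n, T, K)), np.zeros((n, T, K))]
    for t in range(T):
        eta_s = _mvn(rng, cov_si, n)
        for j in range(2):
            eta = eta_s + _mvn(rng, cov_ni, n)
            if t == 0:
                w[j][:, 0, :] = eta
            else:
                w[j][:, t, :] = w[j][:, t - 1, :] @ B[t - 1].T + eta

    y = [np.zeros((n, T, K)), np.zeros((n, T, K))]
    for j in range(2):
        for t in range(T):
            y[j][:, t, :] = (mu + t_shared + t_ns[j] + w[j][:, t, :]
                             + U[j][:, t][:, None] * lam)

    # missingness: MCAR per twin-wave (a skipped questionnaire wave)
    miss = _arr(config.missing_rate, T, "missing_rate")
    if np.any((miss < 0) | (miss >= 1)):
        raise ValueError("missing_rate must be in [0, 1)")
    for j in range(2):
        for t in range(T):
            if miss[t] > 0:
                drop = rng.random(n) < miss[t]
                y[j][drop, t, :] = np.nan

    schema = Schema(traits=config.traits, occasions=config.occasions,
                    age={t: f"age{t}" for t in config.occasions})
    width = len(str(n))
    frame = pd.DataFrame({"pair_id": [f"p{i:0{width}d}" for i in range(n)]})
    frame["sex"] = rng.integers(0, 2, size=n).astype(float)
    for t, occ in enumerate(config.occasions):
        frame[f"age{occ}"] = occ + rng.uniform(-0.5, 0.5, size=n)
    for j in (1, 2):
        for t, occ in enumerate(config.occasions):
            for a, v in enumerate(config.traits):
                frame[f"{v}{occ}_t{j}"] = y[j - 1][:, t, a]
    return TwinPanelTable(frame, schema)


def _pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        return True
    except np.linalg.LinAlgError:
        return False


def _mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    if np.allclose(cov, np.diag(np.diag(cov))):
        return rng.standard_normal((n, cov.shape[0])) * np.sqrt(np.diag(cov))
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n,
                                   method="cholesky" if _pd(cov) else "eigh")


def attach_covariates(table: TwinPanelTable, config: SimulationConfig) -> TwinPanelTable:
    """Add the configured linear age and sex effects to the trait scores.

    Ages enter wave-centred (age minus the nominal wave age), so zero
    effects leave the table unchanged and the sex effect equals the group
    mean difference in expectation.
    """
    K = config.K
    age_eff = _arr(config.age_effect, K, "age_effect")
    sex_eff = _arr(config.sex_effect, K, "sex_effect")
    out = table.frame.copy()
    schema = table.schema
    sexcol = schema.sex if isinstance(schema.sex, str) else schema.sex[0]
    for occ in schema.occasions:
        dage = out[schema.age[occ]] - occ
        for a, v in enumerate(schema.traits):
            shift = age_eff[a] * dage + sex_eff[a] * out[sexcol]
            for j in (1, 2):
                col = schema.value_column(v, occ, j)
                out[col] = out[col] + shift
    return TwinPanelTable(out, schema, table.residualized)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("null_effects", "true_crosslag", "shared_stable_confounder",
                "shared_timevarying_confounder", "nonshared_stable_confounder",
                "teds_like")


def regime_presets(name: str, n_pairs: int = 2000,
                   seed: int | None = None) -> SimulationConfig:
    """Documented study conditions for the simulation experiments.

    The confounder presets share one base: stable shared variance 0.4,
    innovation variances 0.2 (shared) + 0.3 (nonshared), autoregressions
    0.3, traits otherwise uncoupled, so that any cross-lagged estimate on
    the focal path (behavioural problems -> later maladaptive parenting)
    reflects only the injected confounder.  ``true_crosslag`` instead sets
    that path to 0.30 with only a small stable component, so all three
    models can recover it.  ``teds_like`` is the realistic default used for
    end-to-end runs: correlated traits, moderate stabilities, wave
    missingness and covariate effects.
    """
    K = 3
    auto = 0.3 * np.eye(K)
    base = dict(n_pairs=n_pairs, seed=seed)
    if name == "null_effects":
        return SimulationConfig(lagged_effects=0.0, regime="none", **base)
    if name == "true_crosslag":
        B = auto.copy()
        B[0, 2] = 0.3          # bp -> mp, the headline direction
        return SimulationConfig(var_shared_stable=0.05,
                                lagged_effects=B, regime="none", **base)
    if name in ("shared_stable_confounder", "shared_timevarying_confounder",
                "nonshared_stable_confounder"):
        regime = name.removesuffix("_confounder")
        return SimulationConfig(lagged_effects=auto, regime=regime,
                                conf_load=(0.5, 0.0, 0.5), conf_var=1.0, **base)
    if name == "teds_like":
        B = 0.25 * np.eye(K)
        B[0, 2] = 0.08         # mild true bp -> mp effect
        return SimulationConfig(
            mu=(3.2, 3.2, 2.2),
            var_shared_stable=0.35, var_nonshared_stable=0.10,
            var_shared_innov=0.15, var_nonshared_innov=0.40,
            stable_cross_corr=0.45, innov_cross_corr=0.25,
            lagged_effects=B, regime="none",
            age_effect=(0.0, 0.05, -0.05), sex_effect=(0.05, 0.3, -0.2),
            missing_rate=(0.05, 0.12, 0.25), **base)
    raise ValueError(f"unknown preset {name!r}; one of {PRESET_NAMES}")
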