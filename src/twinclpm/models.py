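"""Builders for the cross-lagged panel model variants.

Three designs are compared on the same MZ-twin panel:

* **CLPM** — individual-level lag-1 panel model on the K*T observed
  variables.  No lag-2 paths; those omissions are its only restrictions.
* **RI-CLPM (pair form)** — each twin's trajectory is split into a trait
  random intercept and a within-person process; lagged paths among the
  within components are equated across twins, and non-independence of
  co-twins is absorbed by freely correlating twin 1 and twin 2 random
  intercepts and occasion-specific residuals.
* **MZD-CLPM (pair form)** — a latent familial factor per trait-occasion
  carries everything co-twins share; the twin-specific remainders carry the
  autoregressive/cross-lagged structure (paths equated across twins) and
  are uncorrelated between twins, which is what confines the lagged paths
  to the nonshared environment.

The constraint patterns are pinned by their degrees of freedom: with three
traits and three occasions the builders yield df = 9 (CLPM), 102 (RI-CLPM)
and 99 (MZD-CLPM).  Any change that moves these fingerprints changes the
model being fitted.
"""

from __future__ import annotations

from .data import TRAITS, individual_manifest, pair_manifest
from .sem import ModelSpec

__all__ = [
    "build_clpm", "build_riclpm_pair", "build_mzd_clpm_pair",
    "build_clpm_on_differences", "count_df", "default_occasions",
]


def default_occasions(T: int):
    return (9, 12, 16)[:T] if T <= 3 else tuple(range(1, T + 1))


def _names(K: int, T: int, traits, occasions):
    traits = tuple(traits) if traits is not None else (
        TRAITS if K == 3 else tuple(f"v{k+1}" for k in range(K)))
    occasions = tuple(occasions) if occasions is not None else default_occasions(T)
    if len(traits) != K or len(occasions) != T:
        raise ValueError("trait/occasion label counts must match K and T")
    return traits, occasions


def _check_dims(K: int, T: int) -> None:
    if K < 2 or T < 2:
        raise ValueError("need at least two traits and two occasions")


# ---------------------------------------------------------------------------
# CLPM (individual level)
# ---------------------------------------------------------------------------

def build_clpm(K: int = 3, T: int = 3, *, traits=None, occasions=None) -> ModelSpec:
    """Individual-level cross-lagged panel model on K*T observed variables.

    Free parameters: all means; the full first-occasion covariance block;
    every lag-1 autoregressive and cross-lagged path, separately per
    transition; occasion-specific residual variances and within-occasion
    residual covariances.  For (3, 3): 45 free parameters, df = 9.
    """
    _check_dims(K, T)
    traits, occasions = _names(K, T, traits, occasions)
    obs = individual_manifest(traits, occasions)
    spec = ModelSpec(obs, obs)
    spec.meta = {"traits": traits, "occasions": occasions, "kind": "clpm"}
    name = lambda v, t: f"{v}{occasions[t]}"

    for t in range(T):
        for a in range(K):
            va = name(traits[a], t)
            spec.add_mean(va, label=f"mu_{va}")
            for b in range(a, K):
                vb = name(traits[b], t)
                if t == 0:
                    lab = (f"v_{va}" if a == b else f"c_{va}_{vb}")
                else:
                    lab = (f"rv_{va}" if a == b else f"rc_{va}_{vb}")
                spec.add_cov(va, vb, label=lab,
                             start_frac=0.9 if t == 0 and a == b else
                             (0.6 if a == b else None))
    for t in range(1, T):
        for a in range(K):        # target
            for b in range(K):    # source at t-1
                src = name(traits[b], t - 1)
                dst = name(traits[a], t)
                spec.add_path(src, dst, label=f"b_{src}_to_{dst}")
    return spec


def build_clpm_on_differences(K: int = 3, T: int = 3, *, traits=None,
                              occasions=None) -> ModelSpec:
    """CLPM over the K*T twin-difference scores (twin 1 - twin 2).

    Structurally identical to :func:`build_clpm`; the familial half of each
    score cancels in the differencing, so its lagged paths are the
    difference-score analogue of the latent MZD-CLPM's twin-specific paths.
    """
    return build_clpm(K, T, traits=traits, occasions=occasions)


# ---------------------------------------------------------------------------
# RI-CLPM, twin-pair form
# ---------------------------------------------------------------------------

def build_riclpm_pair(K: int = 3, T: int = 3, *, traits=None,
                      occasions=None) -> ModelSpec:
    """Twin-pair random-intercept CLPM on 2*K*T observed variables.

    Per twin j and trait v:  y[v,t,j] = mu[v,t] + RI[v,j] + w[v,t,j] with
    unit loadings.  Means and all within-twin (co)variance parameters are
    equated across twins; lagged paths among the within components are
    equated across twins; the cross-twin random-intercept and residual
    covariance blocks are fully free (K*K entries each), which is where
    co-twin resemblance lives.  For (3, 3): 87 free parameters, df = 102.
    """
    _check_dims(K, T)
    traits, occasions = _names(K, T, traits, occasions)
    obs = pair_manifest(traits, occasions)
    ri = [f"ri_{v}_t{j}" for j in (1, 2) for v in traits]
    w = [f"w_{v}{t}_t{j}" for j in (1, 2) for t in occasions for v in traits]
    spec = ModelSpec(obs + ri + w, obs)
    spec.meta = {"traits": traits, "occasions": occasions, "kind": "riclpm"}
    yname = lambda v, t, j: f"{v}{occasions[t]}_t{j}"
    wname = lambda v, t, j: f"w_{v}{occasions[t]}_t{j}"

    for j in (1, 2):
        for t in range(T):
            for a, v in enumerate(traits):
                y = yname(v, t, j)
                spec.add_path(f"ri_{v}_t{j}", y, value=1.0)
                spec.add_path(wname(v, t, j), y, value=1.0)
                spec.add_mean(y, label=f"mu_{v}{occasions[t]}")
        # random-intercept block, within twin (labels shared across twins)
        for a in range(K):
            spec.add_cov(f"ri_{traits[a]}_t{j}", f"ri_{traits[a]}_t{j}",
                         label=f"ri_v_{traits[a]}", start_frac=0.25)
            for b in range(a + 1, K):
                spec.add_cov(f"ri_{traits[a]}_t{j}", f"ri_{traits[b]}_t{j}",
                             label=f"ri_c_{traits[a]}_{traits[b]}")
        # within-process blocks
        for t in range(T):
            pre = "w1" if t == 0 else f"e{occasions[t]}"
            frac = 0.55 if t == 0 else 0.45
            for a in range(K):
                spec.add_cov(wname(traits[a], t, j), wname(traits[a], t, j),
                             label=f"{pre}_v_{traits[a]}", start_frac=frac)
                for b in range(a + 1, K):
                    spec.add_cov(wname(traits[a], t, j), wname(traits[b], t, j),
                                 label=f"{pre}_c_{traits[a]}_{traits[b]}")
        # lagged paths among within components, equated across twins
        for t in range(1, T):
            for a in range(K):
                for b in range(K):
                    src = wname(traits[b], t - 1, j)
                    dst = wname(traits[a], t, j)
                    lab = f"b_{traits[b]}{occasions[t-1]}_to_{traits[a]}{occasions[t]}"
                    spec.add_path(src, dst, label=lab)

    # cross-twin covariance blocks: fully free (K*K each)
    for a in range(K):
        for b in range(K):
            spec.add_cov(f"ri_{traits[a]}_t1", f"ri_{traits[b]}_t2",
                         label=f"ri_x_{traits[a]}_{traits[b]}",
                         start_frac=0.12 if a == b else None)
    for t in range(T):
        pre = "w1" if t == 0 else f"e{occasions[t]}"
        for a in range(K):
            for b in range(K):
                spec.add_cov(wname(traits[a], t, 1), wname(traits[b], t, 2),
                             label=f"{pre}_x_{traits[a]}_{traits[b]}",
                             start_frac=0.1 if a == b else None)
    return spec


# ---------------------------------------------------------------------------
# MZD-CLPM, twin-pair latent form
# ---------------------------------------------------------------------------

def build_mzd_clpm_pair(K: int = 3, T: int = 3, *, traits=None,
                        occasions=None) -> ModelSpec:
    """Latent MZ twin-difference CLPM on 2*K*T observed variables.

    One familial factor per trait-occasion loads (fixed 1) on both twins'
    scores and the K*T familial factors covary freely, absorbing everything
    co-twins share, time-stable or not.  The twin-specific remainders carry
    the lag-1 structure with paths equated across twins, have equated
    within-twin (co)variances, and are fixed uncorrelated between twins.
    For (3, 3): 90 free parameters, df = 99.
    """
    _check_dims(K, T)
    traits, occasions = _names(K, T, traits, occasions)
    obs = pair_manifest(traits, occasions)
    fam = [f"f_{v}{t}" for t in occasions for v in traits]
    u = [f"u_{v}{t}_t{j}" for j in (1, 2) for t in occasions for v in traits]
    spec = ModelSpec(obs + fam + u, obs)
    spec.meta = {"traits": traits, "occasions": occasions, "kind": "mzd"}
    yname = lambda v, t, j: f"{v}{occasions[t]}_t{j}"
    uname = lambda v, t, j: f"u_{v}{occasions[t]}_t{j}"
    fname = lambda v, t: f"f_{v}{occasions[t]}"

    for j in (1, 2):
        for t in range(T):
            for v in traits:
                y = yname(v, t, j)
                spec.add_path(fname(v, t), y, value=1.0)
                spec.add_path(uname(v, t, j), y, value=1.0)
                spec.add_mean(y, label=f"mu_{v}{occasions[t]}")
        for t in range(T):
            pre = "u1" if t == 0 else f"e{occasions[t]}"
            frac = 0.5 if t == 0 else 0.4
            for a in range(K):
                spec.add_cov(uname(traits[a], t, j), uname(traits[a], t, j),
                             label=f"{pre}_v_{traits[a]}", start_frac=frac)
                for b in range(a + 1, K):
                    spec.add_cov(uname(traits[a], t, j), uname(traits[b], t, j),
                                 label=f"{pre}_c_{traits[a]}_{traits[b]}")
        for t in range(1, T):
            for a in range(K):
                for b in range(K):
                    src = uname(traits[b], t - 1, j)
                    dst = uname(traits[a], t, j)
                    lab = f"b_{traits[b]}{occasions[t-1]}_to_{traits[a]}{occasions[t]}"
                    spec.add_path(src, dst, label=lab)

    # familial covariance block: fully free K*T x K*T symmetric
    for i, fa in enumerate(fam):
        for jj in range(i, len(fam)):
            fb = fam[jj]
            lab = f"fam_v_{fa[2:]}" if fa == fb else f"fam_c_{fa[2:]}_{fb[2:]}"
            spec.add_cov(fa, fb, label=lab,
                         start_frac=0.45 if fa == fb else None)
    # cross-twin twin-specific covariances are structurally zero (S defaults)
    return spec


def count_df(spec: ModelSpec) -> int:
    """SEM degrees of freedom: nonredundant observed moments (covariances,
    variances and means) minus the number of distinct free labels."""
    return spec.degrees_of_freedom()
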