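"""Fit statistics for covariance-structure models.

All indices derive from three log-likelihoods fitted by the same engine:
the target model, the saturated model (unrestricted means and covariances)
and the independence baseline (free means and variances only).  The
likelihood-ratio statistic is the plain chi-square 2(l_sat - l_model); no
scaling correction is applied.  ``n`` is the number of independent units
contributing likelihood terms — pairs for the pair-level models,
individuals for the individual-level CLPM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["lr_chi_square", "cfi_tli", "rmsea", "srmr",
           "information_criteria", "attach_indices", "fit_table"]

_TOL = 1e-6


def lr_chi_square(ll_model: float, ll_sat: float, df: int,
                  tol: float = 1e-4) -> tuple[float, int]:
    """Likelihood-ratio chi-square 2(l_sat - l_model), clipped at zero.

    A model likelihood exceeding the saturated one beyond ``tol`` (scaled
    by the likelihood magnitude) means the saturated fit failed.
    """
    gap = ll_model - ll_sat
    if gap > tol * max(1.0, abs(ll_sat)):
        raise ValueError(
            f"model log-likelihood {ll_model:.6f} exceeds saturated "
            f"{ll_sat:.6f}: saturated fit failed")
    return max(2.0 * (ll_sat - ll_model), 0.0), df


def cfi_tli(chi2_m: float, df_m: int, chi2_b: float, df_b: int):
    """Comparative fit index and Tucker-Lewis index against the
    independence baseline; CFI clipped to [0, 1], TLI missing if df_m=0."""
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den <= 0 else float(np.clip(1.0 - num / den, 0.0, 1.0))
    if df_m == 0 or df_b == 0:
        return cfi, np.nan
    rb = chi2_b / df_b
    rm = chi2_m / df_m
    tli = np.nan if abs(rb - 1.0) < 1e-12 else (rb - rm) / (rb - 1.0)
    return cfi, float(tli)


def rmsea(chi2: float, df: int, n_units: int) -> float:
    """Root mean square error of approximation,
    sqrt(max(chi2 - df, 0) / (df (n - 1)))."""
    if df <= 0 or n_units <= 1:
        return np.nan
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n_units - 1))))


def srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Standardised root mean square residual over the lower triangle
    (diagonal included) of the correlation-metric residual matrix.

    Covariances are standardised by the *sample* standard deviations; the
    mean structure is excluded.
    """
    S = np.asarray(sample_cov, dtype=float)
    C = np.asarray(implied_cov, dtype=float)
    if S.shape != C.shape:
        raise ValueError("dimension mismatch")
    sd = np.sqrt(np.diag(S))
    if np.any(sd <= 0):
        raise ValueError("zero sample variance")
    D = (S - C) / np.outer(sd, sd)
    il = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(D[il] ** 2)))


def information_criteria(ll: float, k: int, n_units: int) -> tuple[float, float]:
    """AIC = -2l + 2k and BIC = -2l + k log(n)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return -2.0 * ll + 2.0 * k, -2.0 * ll + k * np.log(n_units)


# ---------------------------------------------------------------------------
# integration with FitResult
# ---------------------------------------------------------------------------

def attach_indices(fit) -> None:
    """Populate chi-square and fit indices on a converged FitResult that
    carries saturated and baseline log-likelihoods."""
    chi2, df = lr_chi_square(fit.loglik, fit.loglik_sat, fit.df)
    fit.chi2 = chi2
    p = len(fit.spec.observed)
    df_base = fit.spec.n_moments() - 2 * p
    chi2_b, _ = lr_chi_square(fit.loglik_base, fit.loglik_sat, df_base)
    cfi, tli = cfi_tli(chi2, df, chi2_b, df_base)
    patterns = fit._patterns
    # SRMR needs a sample covariance: available only under complete data
    srmr_val = np.nan
    if patterns.complete:
        grp = patterns.groups[0]
        try:
            srmr_val = srmr(grp["S"], fit.implied_Sigma)
        except ValueError:
            pass
    aic, bic = information_criteria(fit.loglik, fit.n_params, fit.n_units)
    fit.indices = {
        "chi2": chi2, "df": df,
        "cfi": cfi, "tli": tli,
        "rmsea": rmsea(chi2, df, fit.n_units),
        "srmr": srmr_val,
        "aic": aic, "bic": bic,
    }


def fit_table(fits: dict[str, object]) -> pd.DataFrame:
    """Fit-index table across models, one row per model."""
    rows = []
    for name, fit in fits.items():
        idx = fit.indices or {}
        rows.append({
            "model": name,
            "chi_square": idx.get("chi2", np.nan),
            "df": fit.df,
            "AIC": idx.get("aic", fit.aic),
            "BIC": idx.get("bic", fit.bic),
            "RMSEA": idx.get("rmsea", np.nan),
            "CFI": idx.get("cfi", np.nan),
            "TLI": idx.get("tli", np.nan),
        })
    return pd.DataFrame(rows)
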