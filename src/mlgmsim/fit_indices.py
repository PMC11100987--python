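"""Level-specific and target-specific fit indices for two-level growth models.

Each comparison pits a partially saturated model against the fully saturated
reference: the deviance chi-square isolates misfit to the non-saturated part,
and RMSEA / CFI / TLI / SRMR are derived from it with the conventional
formulas. The comparative indices use independence-style baselines per level
(covariance diagonal at the target level, everything else saturated) and an
equal-means baseline for the mean-structure comparison; RMSEA uses the total
individual count N throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimator import FitResult, OptimOptions, fit_catalog
from .model_spec import GrowthBasis, SpecError, is_nested
from .simulator import ClusteredDataset, SufficientStats, sufficient_stats

__all__ = [
    "FitIndexSet",
    "INDEX_COLUMNS",
    "chi_square",
    "rmsea",
    "cfi",
    "tli",
    "srmr_level",
    "compute_all",
    "IndexError_",
]


class IndexError_(ValueError):
    """Raised when a fit index is undefined for the given inputs."""


# The 20 per-replication output columns, in canonical order.
INDEX_COLUMNS = [
    "chi2_ps_b", "chi2_ps_w", "chi2_ts_cov", "chi2_ts_mean",
    "rmsea_ps_b", "rmsea_ps_w", "rmsea_ts_cov", "rmsea_ts_mean",
    "cfi_ps_b", "cfi_ps_w", "cfi_ts_cov", "cfi_ts_mean",
    "tli_ps_b", "tli_ps_w", "tli_ts_cov", "tli_ts_mean",
    "srmr_b", "srmr_w", "srmr_ts_cov", "srmr_ts_mean",
]


def chi_square(fit_h0: FitResult, fit_h1: FitResult) -> tuple[float, int, float]:
    """Deviance test of a restricted model against a more general one.

    chi2 = 2 (loglik_h1 - loglik_h0), floored at zero; df is the difference
    in free-parameter counts; p is the upper chi-square tail.
    """
    if not is_nested(fit_h0.template, fit_h1.template):
        raise SpecError(
            f"{fit_h0.template.name} is not nested in {fit_h1.template.name}"
        )
    chi2 = max(0.0, 2.0 * (fit_h1.loglik - fit_h0.loglik))
    df = fit_h1.n_free - fit_h0.n_free
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 == 0 else 0.0)
    return chi2, df, p


def rmsea(chi2: float, df: int, n_total: int) -> float:
    """sqrt(max(chi2 - df, 0) / (df * N)); zero whenever chi2 <= df."""
    if df <= 0 or n_total <= 0:
        raise IndexError_("RMSEA undefined for df <= 0 or N <= 0")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * n_total)))


def cfi(chi2: float, df: int, chi2_base: float, df_base: int) -> float:
    """Comparative fit index against a baseline model, clamped to [0, 1]."""
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, num, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def tli(chi2: float, df: int, chi2_base: float, df_base: int) -> float:
    """Tucker-Lewis index; stored unclamped (values above 1 occur by design)."""
    if df <= 0 or df_base <= 0:
        raise IndexError_("TLI undefined for zero df")
    base_ratio = chi2_base / df_base
    if base_ratio == 1.0:
        raise IndexError_("TLI undefined: baseline chi2/df equals 1")
    return (base_ratio - chi2 / df) / (base_ratio - 1.0)


def srmr_level(sat_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Standardized root mean square residual over one level's covariances.

    Averages squared standardized residuals over the T(T+1)/2 unique
    elements, standardizing by the saturated estimate's variances.
    """
    d = np.diag(sat_cov)
    if np.any(d <= 0):
        raise IndexError_("SRMR undefined: nonpositive saturated variance")
    scale = np.sqrt(np.outer(d, d))
    resid = (sat_cov - implied_cov) / scale
    iu = np.triu_indices(sat_cov.shape[0])
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


@dataclass(frozen=True)
class FitIndexSet:
    """The 20 fit indices of one replication plus bookkeeping."""

    values: dict
    n_total: int
    converged_all: bool

    def as_row(self) -> dict:
        row = {k: self.values.get(k, np.nan) for k in INDEX_COLUMNS}
        row["n_total"] = self.n_total
        row["converged"] = self.converged_all
        return row


# comparison name -> (model template, baseline template)
_COMPARISONS = {
    "ps_b": ("PS_B", "BASE_B"),
    "ps_w": ("PS_W", "BASE_W"),
    "ts_cov": ("TS_COV", "BASE_B"),
    "ts_mean": ("TS_MEAN", "BASE_MEAN"),
}


def compute_all(
    data: ClusteredDataset | SufficientStats,
    basis: GrowthBasis,
    opts: OptimOptions | None = None,
    ts_variant: str = "literal",
    fits: dict[str, FitResult] | None = None,
) -> FitIndexSet:
    """Fit the template catalog and derive all 20 indices for one dataset."""
    stats = data if isinstance(data, SufficientStats) else sufficient_stats(data)
    if fits is None:
        fits = fit_catalog(stats, basis, opts, ts_variant=ts_variant)
    h1 = fits["H1"]
    n = stats.n_total
    values: dict[str, float] = {}
    converged = all(f.converged for f in fits.values())

    for key, (model_name, base_name) in _COMPARISONS.items():
        m, b = fits[model_name], fits[base_name]
        chi2, df, _ = chi_square(m, h1)
        chi2_b, df_b, _ = chi_square(b, h1)
        values[f"chi2_{key}"] = chi2
        values[f"rmsea_{key}"] = rmsea(chi2, df, n)
        values[f"cfi_{key}"] = cfi(chi2, df, chi2_b, df_b)
        values[f"tli_{key}"] = tli(chi2, df, chi2_b, df_b)

    # SRMR: saturated (H1) estimate of each level against the hypothesized
    # model's implied matrix at that level. The between side standardizes by
    # the saturated between variances; means are saturated in PS_B so mean
    # residuals are identically zero and excluded.
    sat_b, sat_w = h1.params["sigma_b"], h1.params["sigma_w"]
    values["srmr_b"] = srmr_level(sat_b, fits["PS_B"].params["sigma_b"])
    values["srmr_w"] = srmr_level(sat_w, fits["PS_W"].params["sigma_w"])
    values["srmr_ts_cov"] = srmr_level(sat_b, fits["TS_COV"].params["sigma_b"])
    values["srmr_ts_mean"] = srmr_level(sat_b, fits["TS_MEAN"].params["sigma_b"])

    return FitIndexSet(values=values, n_total=n, converged_all=converged)
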