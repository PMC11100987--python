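"""Two-level latent growth model: structure, implied moments, and df accounting.

A multilevel latent growth model (MLGM) decomposes repeated measures on
individuals nested in groups as

    y_gi = (Lambda @ eta_B_g + eps_B_g) + (Lambda @ eta_W_gi + eps_W_gi),

with a shared polynomial growth-factor loading matrix ``Lambda`` at both
levels, latent growth factors ``eta`` (intercept / linear / quadratic, ...)
and wave-specific residuals ``eps``. All observed-mean structure is carried
at the between (group) level; within-level latent means are zero.

This module holds the model description (:class:`MLGMSpec`), its implied
mean/covariance moments, the catalog of analysis-model templates
(saturated, partially saturated, baselines) and the free-parameter / degree
of freedom bookkeeping they share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GrowthBasis",
    "LevelParams",
    "MLGMSpec",
    "ImpliedMoments",
    "ModelTemplate",
    "InvalidDesignError",
    "SpecError",
    "build_growth_basis",
    "default_spec",
    "implied_moments",
    "icc_profile",
    "model_df",
    "block_param_count",
    "template_catalog",
    "get_template",
]


class InvalidDesignError(ValueError):
    """Raised for structurally invalid study designs (e.g. bad time codes)."""


class SpecError(ValueError):
    """Raised when model matrices are inconsistent or inadmissible."""


# ---------------------------------------------------------------------------
# Growth basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthBasis:
    """Polynomial growth basis: wave timings and the T x q loading matrix."""

    time_codes: np.ndarray
    degree: int
    loading_matrix: np.ndarray

    @property
    def n_waves(self) -> int:
        return self.loading_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loading_matrix.shape[1]


def build_growth_basis(time_codes, degree: int) -> GrowthBasis:
    """Build a polynomial growth basis.

    Column ``k`` (1-based) of the loading matrix is the time codes raised to
    the power ``k - 1``; the first column is all ones (intercept factor).

    Parameters
    ----------
    time_codes
        Strictly increasing wave timings, length T.
    degree
        Polynomial degree; the basis has ``q = degree + 1`` growth factors.
        Requires ``T > degree + 1`` so a saturated model is richer than the
        growth structure.
    """
    t = np.asarray(time_codes, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidDesignError("time_codes must be a 1-d vector of length >= 2")
    if not np.all(np.diff(t) > 0):
        raise InvalidDesignError("time_codes must be strictly increasing")
    if degree < 1:
        raise InvalidDesignError("polynomial degree must be >= 1")
    if t.size < degree + 1:
        raise InvalidDesignError(
            f"need at least as many waves ({t.size}) as growth factors ({degree + 1})"
        )
    lam = np.vander(t, N=degree + 1, increasing=True)
    return GrowthBasis(time_codes=t, degree=degree, loading_matrix=lam)


# ---------------------------------------------------------------------------
# Level parameters and full spec
# ---------------------------------------------------------------------------


def _check_symmetric_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise SpecError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise SpecError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    if eig.min() < -tol * max(1.0, abs(eig.max())):
        raise SpecError(f"{name} must be positive semidefinite (min eig {eig.min():.3g})")


@dataclass(frozen=True)
class LevelParams:
    """Latent growth-factor mean/covariance and wave residual variances at one level."""

    latent_mean: np.ndarray  # alpha, length q
    latent_cov: np.ndarray  # Phi, q x q symmetric PSD
    residual_var: np.ndarray  # theta, length T, elementwise >= 0

    def __post_init__(self):
        object.__setattr__(self, "latent_mean", np.asarray(self.latent_mean, float))
        object.__setattr__(self, "latent_cov", np.asarray(self.latent_cov, float))
        object.__setattr__(self, "residual_var", np.asarray(self.residual_var, float))
        _check_symmetric_psd(self.latent_cov, "latent_cov")
        if np.any(self.residual_var < 0):
            raise SpecError("residual variances must be nonnegative")
        if self.latent_mean.shape[0] != self.latent_cov.shape[0]:
            raise SpecError("latent_mean and latent_cov dimensions disagree")


@dataclass(frozen=True)
class MLGMSpec:
    """Full two-level latent growth population/analysis model."""

    basis: GrowthBasis
    within: LevelParams
    between: LevelParams

    def __post_init__(self):
        q = self.basis.n_factors
        T = self.basis.n_waves
        for lev, name in ((self.within, "within"), (self.between, "between")):
            if lev.latent_mean.shape[0] != q or lev.residual_var.shape[0] != T:
                raise SpecError(f"{name} level parameters do not match the growth basis")
        if not np.allclose(self.within.latent_mean, 0.0):
            raise SpecError("within-level latent means must be zero (means live at the between level)")


# Default population: a five-wave quadratic growth model calibrated to a
# longitudinal study of adolescent achievement (students nested in schools).
_ALPHA_B = (49.96, 4.32, -0.13)
_PHI_B = ((16.2, 2.82, 0.0), (2.82, 0.61, 0.0), (0.0, 0.0, 0.02))
_PHI_W = ((71.45, 6.76, 0.0), (6.76, 14.76, 0.0), (0.0, 0.0, 0.07))
_THETA_B = (11.91, 15.25, 10.32, 12.59, 1.93)
_THETA_W = (1.80, 1.28, 0.06, 0.54, 0.31)


def default_spec(time_codes=(0.0, 1.0, 2.0, 3.0, 4.0), degree: int = 2) -> MLGMSpec:
    """The study's population model: 5 waves, quadratic growth at both levels."""
    basis = build_growth_basis(time_codes, degree)
    within = LevelParams(np.zeros(degree + 1), np.array(_PHI_W), np.array(_THETA_W))
    between = LevelParams(np.array(_ALPHA_B), np.array(_PHI_B), np.array(_THETA_B))
    return MLGMSpec(basis=basis, within=within, between=between)


# ---------------------------------------------------------------------------
# Implied moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied observed mean and level-specific covariance matrices."""

    mean: np.ndarray  # mu, length T
    within_cov: np.ndarray  # Sigma_W, T x T
    between_cov: np.ndarray  # Sigma_B, T x T


def implied_moments(spec: MLGMSpec) -> ImpliedMoments:
    """Compute mu = Lambda a_B, Sigma_W = L Phi_W L' + diag(theta_W), likewise between."""
    lam = spec.basis.loading_matrix
    mu = lam @ spec.between.latent_mean
    sw = lam @ spec.within.latent_cov @ lam.T + np.diag(spec.within.residual_var)
    sb = lam @ spec.between.latent_cov @ lam.T + np.diag(spec.between.residual_var)
    return ImpliedMoments(mean=mu, within_cov=0.5 * (sw + sw.T), between_cov=0.5 * (sb + sb.T))


def icc_profile(moments: ImpliedMoments) -> np.ndarray:
    """Intraclass correlation per wave: between-variance share of total variance."""
    vb = np.diag(moments.between_cov)
    vw = np.diag(moments.within_cov)
    total = vb + vw
    if np.any(total <= 0):
        raise SpecError("ICC undefined: zero total variance at some wave")
    return vb / total


# ---------------------------------------------------------------------------
# Analysis-model templates and degree-of-freedom accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelTemplate:
    """A saturation pattern for the two-level analysis model.

    Covariance modes
      ``saturated``       free T(T+1)/2 covariance block
      ``structured``      growth structure L Phi L' + diag(theta), all
                          q(q+1)/2 elements of Phi free
      ``structured_diag`` growth structure with Phi restricted to diagonal
                          (q + T free parameters); probe variant only
      ``diagonal``        independence baseline, T free variances
    Mean modes
      ``saturated`` (T free), ``structured`` (mu = Lambda alpha, q free),
      ``equal`` (single common mean, 1 free).
    """

    name: str
    within_cov_mode: str
    between_cov_mode: str
    mean_mode: str


_COV_MODES = ("saturated", "structured", "structured_diag", "diagonal")
_MEAN_MODES = ("saturated", "structured", "equal")

# Nesting rank: a block with lower rank is a restriction of any higher rank.
_COV_RANK = {"saturated": 3, "structured": 2, "structured_diag": 1, "diagonal": 0}
_MEAN_RANK = {"saturated": 2, "structured": 1, "equal": 0}


def block_param_count(kind: str, mode: str, T: int, q: int) -> int:
    """Free-parameter count of one covariance or mean block."""
    if kind == "cov":
        if mode == "saturated":
            return T * (T + 1) // 2
        if mode == "structured":
            return q * (q + 1) // 2 + T
        if mode == "structured_diag":
            return q + T
        if mode == "diagonal":
            return T
    elif kind == "mean":
        if mode == "saturated":
            return T
        if mode == "structured":
            return q
        if mode == "equal":
            return 1
    raise SpecError(f"unknown {kind} block mode {mode!r}")


def model_df(template: ModelTemplate, T: int, q: int) -> tuple[int, int]:
    """Free-parameter count of a template and its df against the saturated model.

    df = params(H1) - params(template) with params(H1) = 2 * T(T+1)/2 + T.
    """
    if template.within_cov_mode not in _COV_MODES or template.between_cov_mode not in _COV_MODES:
        raise SpecError("invalid covariance mode")
    if template.mean_mode not in _MEAN_MODES:
        raise SpecError("invalid mean mode")
    params = (
        block_param_count("cov", template.within_cov_mode, T, q)
        + block_param_count("cov", template.between_cov_mode, T, q)
        + block_param_count("mean", template.mean_mode, T, q)
    )
    h1 = T * (T + 1) + T
    return params, h1 - params


def is_nested(restricted: ModelTemplate, general: ModelTemplate) -> bool:
    """True when every block of ``restricted`` is a restriction of ``general``."""
    return (
        _COV_RANK[restricted.within_cov_mode] <= _COV_RANK[general.within_cov_mode]
        and _COV_RANK[restricted.between_cov_mode] <= _COV_RANK[general.between_cov_mode]
        and _MEAN_RANK[restricted.mean_mode] <= _MEAN_RANK[general.mean_mode]
    )


# Template registry. H1 is the fully saturated reference; PS_* are the
# partially saturated models isolating one level; BASE_* are the
# independence-style baselines used by CFI/TLI; TS_* are the target-specific
# between-side models.
_LITERAL_TEMPLATES = {
    "H1": ModelTemplate("H1", "saturated", "saturated", "saturated"),
    "PS_B": ModelTemplate("PS_B", "saturated", "structured", "saturated"),
    "PS_W": ModelTemplate("PS_W", "structured", "saturated", "saturated"),
    "TS_COV": ModelTemplate("TS_COV", "saturated", "structured", "saturated"),
    "TS_MEAN": ModelTemplate("TS_MEAN", "saturated", "saturated", "structured"),
    "BASE_B": ModelTemplate("BASE_B", "saturated", "diagonal", "saturated"),
    "BASE_W": ModelTemplate("BASE_W", "diagonal", "saturated", "saturated"),
    "BASE_MEAN": ModelTemplate("BASE_MEAN", "saturated", "saturated", "equal"),
}

# Probe reconstruction of the target-specific models: the hypothesized
# within-level growth structure is retained and growth-factor covariances are
# fixed to zero in every structured block. Against the default population
# (which has nonzero intercept-linear covariances) these templates are
# deliberately misspecified; they reproduce the qualitative behaviour of
# target-specific statistics whose misfit grows with total sample size.
_DIAG_PROBE_TEMPLATES = {
    **_LITERAL_TEMPLATES,
    "TS_COV": ModelTemplate("TS_COV", "structured_diag", "structured_diag", "saturated"),
    "TS_MEAN": ModelTemplate("TS_MEAN", "structured_diag", "saturated", "structured"),
}

TS_VARIANTS = ("literal", "diagonal_growth")


def template_catalog(ts_variant: str = "literal") -> dict[str, ModelTemplate]:
    """The named analysis-model templates, under the chosen target-specific variant."""
    if ts_variant == "literal":
        return dict(_LITERAL_TEMPLATES)
    if ts_variant == "diagonal_growth":
        return dict(_DIAG_PROBE_TEMPLATES)
    raise SpecError(f"unknown ts_variant {ts_variant!r}; expected one of {TS_VARIANTS}")


def get_template(name: str, ts_variant: str = "literal") -> ModelTemplate:
    catalog = template_catalog(ts_variant)
    try:
        return catalog[name]
    except KeyError:
        raise SpecError(f"unknown template {name!r}; known: {sorted(catalog)}") from None
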