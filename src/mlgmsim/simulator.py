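"""Simulate unbalanced clustered growth data and compute moment statistics.

The study design crosses the number of groups (NG) with an unbalanced
group-size (GS) condition: exactly half the groups take a small size and
half a large size, with large = 3 x small, which fixes the coefficient of
variation of cluster sizes at 0.5.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_spec import InvalidDesignError, MLGMSpec, SpecError, default_spec

__all__ = [
    "DesignCondition",
    "ClusteredDataset",
    "SizeClassStats",
    "SufficientStats",
    "study_conditions",
    "draw_cluster_sizes",
    "simulate_dataset",
    "pooled_within_cov",
    "between_cov",
    "sufficient_stats",
    "read_dataset_csv",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class DesignCondition:
    """One cell of the design grid: NG groups, half small_size and half large_size."""

    n_groups: int
    small_size: int
    large_size: int
    label: str = ""

    def __post_init__(self):
        if self.n_groups < 2 or self.n_groups % 2:
            raise InvalidDesignError("n_groups must be even and >= 2")
        if not (0 < self.small_size <= self.large_size):
            raise InvalidDesignError("need 0 < small_size <= large_size")
        if not self.label:
            object.__setattr__(
                self, "label", f"NG{self.n_groups}_GS{self.small_size}_{self.large_size}"
            )

    @property
    def n_total(self) -> int:
        return self.n_groups * (self.small_size + self.large_size) // 2

    @property
    def size_cv(self) -> float:
        """Coefficient of variation of cluster sizes; 0.5 whenever large = 3 x small."""
        m = 0.5 * (self.small_size + self.large_size)
        var = 0.5 * ((self.small_size - m) ** 2 + (self.large_size - m) ** 2)
        return float(np.sqrt(var) / m)


def study_conditions() -> list[DesignCondition]:
    """The 3 x 3 study grid: NG in {50,100,200} x GS in {5/15, 10/30, 25/75}."""
    return [
        DesignCondition(ng, s, 3 * s)
        for ng in (50, 100, 200)
        for s in (5, 10, 25)
    ]


def draw_cluster_sizes(condition: DesignCondition) -> np.ndarray:
    """Deterministic size vector: first half small, second half large.

    Assignment order is irrelevant downstream — clusters are exchangeable and
    every statistic depends only on the multiset of sizes.
    """
    g = condition.n_groups
    return np.repeat([condition.small_size, condition.large_size], g // 2)


@dataclass(frozen=True)
class ClusteredDataset:
    """Simulated individuals nested in clusters, T outcomes per individual."""

    cluster_ids: np.ndarray  # length N, int
    member_ids: np.ndarray  # length N, int, 1-based within cluster
    y: np.ndarray  # N x T
    condition: DesignCondition | None = None
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return self.y.shape[0]

    @property
    def n_waves(self) -> int:
        return self.y.shape[1]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self._codes())[: len(np.unique(self.cluster_ids))]

    def _codes(self) -> np.ndarray:
        _, codes = np.unique(self.cluster_ids, return_inverse=True)
        return codes

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"V{t + 1}": self.y[:, t] for t in range(self.n_waves)}
        return pd.DataFrame(
            {"cluster_id": self.cluster_ids, "member_id": self.member_ids, **cols}
        )


def simulate_dataset(
    spec: MLGMSpec | None,
    condition: DesignCondition,
    seed,
) -> ClusteredDataset:
    """Draw one dataset from the two-level growth model.

    Per cluster g: growth factors eta_B ~ N(alpha_B, Phi_B) and residuals
    eps_B ~ N(0, diag theta_B) give the cluster component
    b_g = Lambda eta_B + eps_B; each member adds Lambda eta_W + eps_W with
    eta_W ~ N(0, Phi_W), eps_W ~ N(0, diag theta_W). The same seed always
    reproduces the same dataset.
    """
    spec = spec if spec is not None else default_spec()
    rng = np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None

    lam = spec.basis.loading_matrix
    T, q = lam.shape
    sizes = draw_cluster_sizes(condition)
    G = sizes.size
    N = int(sizes.sum())

    def _factor(mat, name):
        try:
            return np.linalg.cholesky(mat + 1e-12 * np.trace(mat) / mat.shape[0] * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(0.5 * (mat + mat.T))
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise SpecError(f"{name} is not positive semidefinite") from None
            return v * np.sqrt(np.clip(w, 0.0, None))

    lb = _factor(spec.between.latent_cov, "phi_between")
    lw = _factor(spec.within.latent_cov, "phi_within")

    eta_b = spec.between.latent_mean + rng.standard_normal((G, q)) @ lb.T
    eps_b = rng.standard_normal((G, T)) * np.sqrt(spec.between.residual_var)
    b = eta_b @ lam.T + eps_b  # G x T cluster components

    eta_w = rng.standard_normal((N, q)) @ lw.T
    eps_w = rng.standard_normal((N, T)) * np.sqrt(spec.within.residual_var)
    codes = np.repeat(np.arange(G), sizes)
    y = b[codes] + eta_w @ lam.T + eps_w

    member_ids = np.concatenate([np.arange(1, n + 1) for n in sizes])
    return ClusteredDataset(
        cluster_ids=codes + 1,
        member_ids=member_ids,
        y=y,
        condition=condition,
        seed=seed_int,
    )


# ---------------------------------------------------------------------------
# Moment matrices and sufficient statistics
# ---------------------------------------------------------------------------


def _cluster_means_and_scatter(dataset: ClusteredDataset):
    """Per-cluster sizes/means and the pooled within-cluster scatter matrix."""
    codes = dataset._codes()
    G = codes.max() + 1
    sizes = np.bincount(codes, minlength=G)
    if np.any(sizes == 0):
        raise InvalidDesignError("dataset contains an empty cluster")
    means = np.zeros((G, dataset.n_waves))
    np.add.at(means, codes, dataset.y)
    means /= sizes[:, None]
    resid = dataset.y - means[codes]
    scatter = resid.T @ resid
    return sizes, means, 0.5 * (scatter + scatter.T)


def pooled_within_cov(dataset: ClusteredDataset) -> np.ndarray:
    """S_PW: within-cluster deviations pooled over all clusters, divisor N - G."""
    sizes, _, scatter = _cluster_means_and_scatter(dataset)
    n, g = int(sizes.sum()), sizes.size
    if n <= g:
        raise InvalidDesignError("pooled within covariance needs N > G")
    return scatter / (n - g)


def between_cov(dataset: ClusteredDataset) -> np.ndarray:
    """S*_B: size-weighted scatter of cluster means about the grand mean, divisor G - 1.

    Descriptive only — with unequal cluster sizes this aggregate is not a
    sufficient statistic for any single between-cluster covariance.
    """
    sizes, means, _ = _cluster_means_and_scatter(dataset)
    if sizes.size < 2:
        raise InvalidDesignError("between covariance needs at least 2 clusters")
    grand = dataset.y.mean(axis=0)
    dev = means - grand
    sb = (dev * sizes[:, None]).T @ dev / (sizes.size - 1)
    return 0.5 * (sb + sb.T)


@dataclass(frozen=True)
class SizeClassStats:
    """Cluster-mean statistics for all clusters sharing one size."""

    size: int
    count: int
    mean: np.ndarray  # mean of cluster means, length T
    scatter: np.ndarray  # scatter of cluster means about that mean, T x T


@dataclass(frozen=True)
class SufficientStats:
    """Exact compression of the two-level normal likelihood's data dependence.

    The likelihood depends on the data only through the pooled within-cluster
    scatter and, per distinct cluster size d, the count, mean and scatter of
    the cluster means — O(#size classes) matrices regardless of N.
    """

    n_total: int
    n_groups: int
    pooled_within_scatter: np.ndarray  # T x T
    size_classes: tuple[SizeClassStats, ...]

    @property
    def n_waves(self) -> int:
        return self.pooled_within_scatter.shape[0]

    def grand_mean(self) -> np.ndarray:
        """Individual-weighted grand mean reconstructed from the size classes."""
        tot = sum(c.size * c.count * c.mean for c in self.size_classes)
        return tot / self.n_total


def sufficient_stats(dataset: ClusteredDataset) -> SufficientStats:
    sizes, means, scatter = _cluster_means_and_scatter(dataset)
    classes = []
    for d in np.unique(sizes):
        sel = sizes == d
        m = means[sel]
        center = m.mean(axis=0)
        dev = m - center
        s = dev.T @ dev
        classes.append(
            SizeClassStats(size=int(d), count=int(sel.sum()), mean=center, scatter=0.5 * (s + s.T))
        )
    return SufficientStats(
        n_total=int(sizes.sum()),
        n_groups=int(sizes.size),
        pooled_within_scatter=scatter,
        size_classes=tuple(classes),
    )


# ---------------------------------------------------------------------------
# CSV exchange
# ---------------------------------------------------------------------------


def write_dataset_csv(dataset: ClusteredDataset, path_or_buf) -> None:
    """Wide CSV, one row per individual: cluster_id, member_id, V1..VT."""
    df = dataset.to_dataframe()
    df.to_csv(path_or_buf, index=False)


def read_dataset_csv(path_or_buf) -> ClusteredDataset:
    df = pd.read_csv(path_or_buf)
    required = ["cluster_id", "member_id"]
    waves = [c for c in df.columns if c.startswith("V") and c[1:].isdigit()]
    waves.sort(key=lambda c: int(c[1:]))
    if list(df.columns[:2]) != required or not waves:
        raise InvalidDesignError(
            "dataset CSV must have header cluster_id,member_id,V1..VT"
        )
    if df[waves].isna().any().any():
        raise InvalidDesignError("dataset CSV is not rectangular (missing values)")
    return ClusteredDataset(
        cluster_ids=df["cluster_id"].to_numpy(),
        member_ids=df["member_id"].to_numpy(),
        y=df[waves].to_numpy(dtype=float),
    )


def dataset_csv_bytes(dataset: ClusteredDataset) -> bytes:
    buf = io.StringIO()
    write_dataset_csv(dataset, buf)
    return buf.getvalue().encode()
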