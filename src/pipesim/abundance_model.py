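"""Ground-truth protein concentration model for two sample classes.

Control-class mean concentrations are Gamma(t, θ) distributed (dynamic range
of roughly four orders of magnitude). A designated set of marker proteins
carries a multiplicative fold change between classes, with the direction
(over-/under-expression) chosen by fair coin. Sample-to-sample variation is
multivariate Gaussian with a block-diagonal correlation structure: proteins
within a block of size D (a pathway surrogate) are correlated at ρ, proteins
in different blocks are independent. The per-protein standard deviation is
φ·η, i.e. φ is a coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import stage_rng

__all__ = [
    "AbundanceConfig",
    "GroundTruthSamples",
    "draw_control_means",
    "draw_fold_changes",
    "build_covariance",
    "draw_samples",
]


@dataclass
class AbundanceConfig:
    """Parameters of the two-class protein mixture model."""

    t: float = 2.0           # Gamma shape
    theta: float = 1000.0    # Gamma scale
    M: int = 50              # samples per class
    n_markers: int = 20
    n_background: int = 500
    a_range: tuple[float, float] = (1.5, 2.0)  # fold-change magnitude bounds
    rho: float = 0.6         # within-block correlation
    D: int = 2               # block size
    phi: float = 0.1         # coefficient of variation, sd = phi * eta
    marker_quantile_cap: float | None = None  # e.g. 0.25 for low-abundance markers

    def __post_init__(self) -> None:
        if self.t <= 0 or self.theta <= 0:
            raise ValueError("Gamma parameters must be positive")
        if self.M < 2:
            raise ValueError("need at least 2 samples per class")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.D < 1:
            raise ValueError("block size D must be >= 1")
        if self.a_range[0] <= 1 or self.a_range[1] < self.a_range[0]:
            raise ValueError("fold-change bounds must satisfy 1 < a_lo <= a_hi")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.marker_quantile_cap is not None and not (
            0 < self.marker_quantile_cap <= 1
        ):
            raise ValueError("marker_quantile_cap must be in (0, 1]")


@dataclass
class GroundTruthSamples:
    """True protein concentrations for 2M samples plus marker bookkeeping.

    ``concentrations`` has one row per protein and 2M columns: the first M
    are class 0 (control), the last M class 1 (treatment).
    """

    concentrations: np.ndarray          # (n_pro, 2M), >= 0
    class_labels: np.ndarray            # (2M,), values {0, 1}
    eta: np.ndarray                     # (n_pro,) control means
    fold: np.ndarray                    # (n_pro,) fold changes, 1 for non-markers
    marker_ids: list[str]
    protein_ids: list[str] = field(default_factory=list)

    @property
    def n_pro(self) -> int:
        return self.concentrations.shape[0]

    @property
    def M(self) -> int:
        return self.concentrations.shape[1] // 2

    def marker_indices(self) -> np.ndarray:
        idx = {pid: i for i, pid in enumerate(self.protein_ids)}
        return np.array([idx[m] for m in self.marker_ids], dtype=int)

    def to_tsv(self, conc_path, manifest_path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.concentrations,
            index=self.protein_ids,
            columns=[f"s{j}_c{int(l)}" for j, l in enumerate(self.class_labels)],
        ).to_csv(conc_path, sep="\t")
        pd.DataFrame(
            {"protein_id": self.protein_ids, "eta": self.eta, "fold": self.fold}
        ).to_csv(manifest_path, sep="\t", index=False)


def draw_control_means(
    config: AbundanceConfig,
    n_proteins: int,
    seed: int,
    marker_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Draw per-protein control-class mean concentrations η ~ Gamma(t, θ).

    If ``config.marker_quantile_cap`` is set, marker means are drawn from the
    Gamma truncated to its lower-q quantile instead — the low-abundance-marker
    scenario where every marker hides in the bottom q of the concentration
    distribution.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = stage_rng(seed, "control_means")
    eta = rng.gamma(shape=config.t, scale=config.theta, size=n_proteins)
    if config.marker_quantile_cap is not None and marker_indices is not None:
        q = config.marker_quantile_cap
        u = rng.uniform(0.0, q, size=len(marker_indices))
        eta[marker_indices] = stats.gamma.ppf(u, a=config.t, scale=config.theta)
    return eta


def draw_fold_changes(
    config: AbundanceConfig, n_proteins: int, marker_indices: np.ndarray, seed: int
) -> np.ndarray:
    """Fold changes: a ~ Unif(a_lo, a_hi) per marker, direction by fair coin.

    Over-expressed markers get f = a, under-expressed f = 1/a; all other
    proteins have f = 1.
    """
    if np.any(marker_indices >= n_proteins) or np.any(marker_indices < 0):
        raise ValueError("marker indices out of range")
    rng = stage_rng(seed, "fold_changes")
    fold = np.ones(n_proteins)
    a = rng.uniform(config.a_range[0], config.a_range[1], size=len(marker_indices))
    over = rng.random(len(marker_indices)) < 0.5
    fold[marker_indices] = np.where(over, a, 1.0 / a)
    return fold


def _correlation_blocks(n_proteins: int, D: int) -> list[tuple[int, int]]:
    """Row-order block extents [(start, stop), ...]; trailing block may be short."""
    return [(s, min(s + D, n_proteins)) for s in range(0, n_proteins, D)]


def build_covariance(config: AbundanceConfig, eta: np.ndarray) -> np.ndarray:
    """Dense covariance Σ with σ_l = φ η_l and block-equicorrelation ρ.

    Intended for validation and small problems; the sampler exploits the block
    structure directly and never forms Σ for large proteomes.
    """
    n = len(eta)
    if config.D > 1 and config.rho <= -1.0 / (config.D - 1):
        raise ValueError("rho makes the block correlation matrix non-PSD")
    sd = config.phi * eta
    R = np.zeros((n, n))
    for s, e in _correlation_blocks(n, config.D):
        R[s:e, s:e] = config.rho
    np.fill_diagonal(R, 1.0)
    return R * np.outer(sd, sd)


def draw_samples(
    config: AbundanceConfig,
    eta: np.ndarray,
    fold: np.ndarray,
    marker_ids: list[str],
    protein_ids: list[str],
    seed: int,
    M: int | None = None,
) -> GroundTruthSamples:
    """Draw 2M concentration columns from the block-MVG model.

    Class-0 columns have mean η, class-1 columns mean η∘f; both share the
    block covariance implied by (φ, ρ, D). Sampling is done block-by-block via
    the Cholesky factor of the D×D equicorrelation matrix, so cost is
    O(n_pro · 2M) rather than O(n_pro²). Negative draws are clamped to zero
    (concentrations cannot be negative); at the default φ = 0.1 clamping is
    vanishingly rare.
    """
    n = len(eta)
    if len(fold) != n or len(protein_ids) != n:
        raise ValueError("eta, fold and protein_ids must agree in length")
    M = config.M if M is None else M
    rng = stage_rng(seed, "sample_draws")

    n_cols = 2 * M
    z = rng.standard_normal((n, n_cols))
    D = config.D
    if D > 1 and config.rho != 0.0:
        if config.rho <= -1.0 / (D - 1):
            raise ValueError("rho makes the block correlation matrix non-PSD")
        L = np.linalg.cholesky(
            np.full((D, D), config.rho) + (1 - config.rho) * np.eye(D)
        )
        n_full = n // D
        if n_full:
            body = z[: n_full * D].reshape(n_full, D, n_cols)
            z[: n_full * D] = np.einsum("de,ben->bdn", L, body).reshape(-1, n_cols)
        rem = n - n_full * D
        if rem > 1:
            Lr = np.linalg.cholesky(
                np.full((rem, rem), config.rho) + (1 - config.rho) * np.eye(rem)
            )
            z[n_full * D:] = Lr @ z[n_full * D:]

    sd = (config.phi * eta)[:, None]
    means = np.concatenate(
        [np.repeat(eta[:, None], M, axis=1), np.repeat((eta * fold)[:, None], M, axis=1)],
        axis=1,
    )
    conc = np.maximum(means + sd * z, 0.0)
    labels = np.concatenate([np.zeros(M, dtype=int), np.ones(M, dtype=int)])
    return GroundTruthSamples(
        concentrations=conc,
        class_labels=labels,
        eta=eta,
        fold=fold,
        marker_ids=list(marker_ids),
        protein_ids=list(protein_ids),
    )
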