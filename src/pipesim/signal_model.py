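"""From true protein concentrations to noisy peptide ion abundances.

Peptide concentration is the sum of its parent proteins' concentrations.
The expected ion abundance is μ = c · e · κ, where e is a per-peptide
efficiency factor (LC transmission × ionization efficiency, drawn uniform and
fixed per species) and κ the instrument response factor; detector saturation
caps μ at a ceiling ``sat``. The measured abundance adds zero-mean Gaussian
noise with variance αμ² + βμ — a multiplicative term dominating at high
signal plus a shot-noise-like term dominating at low signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import stage_rng
from .abundance_model import GroundTruthSamples
from .proteome import ProteomeCatalog

__all__ = [
    "SignalConfig",
    "PeptideSignalMatrix",
    "rollup_protein_to_peptide",
    "draw_efficiencies",
    "expected_abundance",
    "add_noise",
]


@dataclass
class SignalConfig:
    e_range: tuple[float, float] = (0.1, 1.0)
    kappa: float = 5.0
    sat: float = np.inf
    alpha: float = 0.03
    beta: float = 3.6

    def __post_init__(self) -> None:
        e_lo, e_hi = self.e_range
        if not (0 < e_lo <= e_hi <= 1):
            raise ValueError("efficiency bounds must satisfy 0 < e_lo <= e_hi <= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.sat <= 0:
            raise ValueError("sat must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("noise coefficients must be non-negative")


@dataclass
class PeptideSignalMatrix:
    """Peptide-level ground truth and measurements for all 2M samples."""

    c_pep: np.ndarray       # (n_pep, 2M) peptide concentrations
    mu: np.ndarray          # (n_pep, 2M) expected abundances (<= sat)
    v: np.ndarray           # (n_pep, 2M) noisy abundances (>= 0)
    efficiency: np.ndarray  # (n_pep,)

    def to_tsv(self, path, catalog: ProteomeCatalog) -> None:
        import pandas as pd

        pd.DataFrame(
            self.v,
            index=[p.id for p in catalog.peptides],
            columns=[f"s{j}" for j in range(self.v.shape[1])],
        ).to_csv(path, sep="\t")


def rollup_protein_to_peptide(
    catalog: ProteomeCatalog, truth: GroundTruthSamples
) -> np.ndarray:
    """Peptide concentrations: sum of parent-protein concentrations.

    Requires the catalog protein order to match the truth's row order.
    """
    if [p.id for p in catalog.proteins] != list(truth.protein_ids):
        raise ValueError("catalog protein order does not match ground truth")
    A = catalog.membership_matrix()
    return np.asarray(A @ truth.concentrations)


def draw_efficiencies(
    catalog: ProteomeCatalog, e_range: tuple[float, float], seed: int
) -> np.ndarray:
    """Per-peptide efficiency e ~ Unif(e_lo, e_hi), fixed across samples."""
    if not catalog.peptides:
        raise ValueError("catalog has no peptides; digest first")
    rng = stage_rng(seed, "efficiencies")
    return rng.uniform(e_range[0], e_range[1], size=catalog.n_pep)


def expected_abundance(
    c_pep: np.ndarray, efficiency: np.ndarray, kappa: float, sat: float = np.inf
) -> np.ndarray:
    """μ = min(c · e · κ, sat), elementwise."""
    mu = c_pep * efficiency[:, None] * kappa
    return np.minimum(mu, sat)


def add_noise(mu: np.ndarray, alpha: float, beta: float, seed: int) -> np.ndarray:
    """Measured abundance v = max(0, μ + ε), ε ~ N(0, αμ² + βμ).

    Cells with μ = 0 stay exactly zero (no signal, no noise). Negative draws
    are clamped at zero: ion counts cannot be negative.
    """
    if np.any(mu < 0):
        raise ValueError("expected abundances must be non-negative")
    rng = stage_rng(seed, "abundance_noise")
    var = alpha * mu**2 + beta * mu
    v = mu + np.sqrt(var) * rng.standard_normal(mu.shape)
    v[mu == 0] = 0.0
    return np.maximum(v, 0.0)
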