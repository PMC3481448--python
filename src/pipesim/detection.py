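"""MS1 peptide detection, MS2 identification and their AND-linking.

MS1 detection is a per-cell Bernoulli trial whose success probability (the
true positive rate) grows polynomially with the signal-to-noise ratio,
TPR = clamp(k·SNR^p + b, 0, 1), and is attenuated for algorithms that cannot
resolve overlapping peptide signals: if a peptide co-occurs with others in a
mass/retention-time window, the overlap-sensitive TPR is divided by the size
of that clash group. MS2 identification is a per-cell Bernoulli with a
per-species identifiability p_i (the chance the peptide is selected,
fragmented and matched in one assay); r replicate MS2 runs succeed with
probability 1 − (1 − p_i)^r. A peptide cell is *observed* only when reported
by both routes — the AND-link that suppresses single-route false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._rng import stage_rng
from .proteome import KYTE_DOOLITTLE, ProteomeCatalog

__all__ = [
    "DetectionConfig",
    "ObservedPeptideTable",
    "snr",
    "overlap_counts",
    "tpr",
    "detect_ms1",
    "assign_identifiability",
    "identify_ms2",
    "link",
]


@dataclass
class DetectionConfig:
    k: float = 0.0016            # TPR curve gain
    p: float = 2.0               # TPR curve exponent
    b: float = 0.0               # TPR floor at SNR -> 0
    overlap_aware: bool = True   # True: NITPICK/BPDA-class algorithms (o = 1)
    mass_resolution: float = 50000.0
    n_scans: int = 1000
    rt_tol_frac: float = 0.005
    n_ms2_replicates: int = 1
    identifiability_model: str = "beta"  # "beta" | "logistic"
    identifiability_params: tuple[float, float] = (2.0, 8.0)
    perfect_detection: bool = False      # TPR = 1 wherever SNR > 0

    def __post_init__(self) -> None:
        if self.k < 0 or self.p <= 0 or not (0 <= self.b <= 1):
            raise ValueError("require k >= 0, p > 0, 0 <= b <= 1")
        if self.mass_resolution <= 0:
            raise ValueError("mass_resolution must be positive")
        if self.n_ms2_replicates < 1:
            raise ValueError("n_ms2_replicates must be >= 1")


@dataclass
class ObservedPeptideTable:
    """Boolean detection/identification masks and the observed abundances."""

    detected: np.ndarray         # (n_pep, 2M) MS1 mask
    identified: np.ndarray       # (n_pep, 2M) MS2 mask
    observed: np.ndarray         # detected AND identified
    abundance: np.ndarray        # v where observed, NaN elsewhere
    identifiability: np.ndarray  # (n_pep,) per-species p_i
    overlap_count: np.ndarray    # (n_pep,) clash-group sizes (self included)

    def to_tsv(self, path, catalog: ProteomeCatalog) -> None:
        import pandas as pd

        n_pep, n_s = self.observed.shape
        ii, jj = np.meshgrid(np.arange(n_pep), np.arange(n_s), indexing="ij")
        pd.DataFrame(
            {
                "peptide_id": [catalog.peptides[i].id for i in ii.ravel()],
                "sample_id": jj.ravel(),
                "abundance": self.abundance.ravel(),
                "detected": self.detected.ravel(),
                "identified": self.identified.ravel(),
                "observed": self.observed.ravel(),
            }
        ).to_csv(path, sep="\t", index=False)


def snr(mu: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Signal-to-noise ratio E[v]²/Var(v) = μ/(αμ + β); zero where μ = 0.

    Monotone increasing in μ and saturating at 1/α. With α = β = 0 the signal
    is noiseless and the SNR is infinite wherever μ > 0.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    out = np.zeros_like(mu)
    pos = mu > 0
    denom = alpha * mu[pos] + beta
    if alpha == 0 and beta == 0:
        out[pos] = np.inf
    else:
        with np.errstate(divide="ignore"):
            out[pos] = mu[pos] / denom
    return out


def overlap_counts(
    catalog: ProteomeCatalog,
    mass_resolution: float,
    n_scans: int,
    rt_tol_frac: float = 0.005,
) -> np.ndarray:
    """Size of each peptide's mass/RT clash group (counting itself).

    Two peptides overlap when their relative mass gap (denominator: the
    smaller mass, making the test symmetric) is below 1/mass_resolution *and*
    their RT gap is below rt_tol_frac of the gradient. Computed with a sort
    and sliding mass window, O(n log n + n·w).
    """
    masses = np.array([p.mono_mass for p in catalog.peptides])
    rts = np.array([p.rt for p in catalog.peptides])
    n = len(masses)
    counts = np.ones(n, dtype=int)
    order = np.argsort(masses, kind="stable")
    ms, rs = masses[order], rts[order]
    mass_tol = 1.0 / mass_resolution
    rt_tol = rt_tol_frac * n_scans
    for a in range(n):
        m_a = ms[a]
        b = a + 1
        while b < n and (ms[b] - m_a) < mass_tol * m_a:  # min(mass) = m_a (sorted)
            if abs(rs[a] - rs[b]) < rt_tol:
                counts[order[a]] += 1
                counts[order[b]] += 1
            b += 1
    return counts


def tpr(
    snr_matrix: np.ndarray, overlap: np.ndarray, config: DetectionConfig
) -> np.ndarray:
    """Per-cell true positive rate of the MS1 detection algorithm."""
    if config.perfect_detection:
        return (snr_matrix > 0).astype(float)
    with np.errstate(over="ignore"):
        base = config.k * snr_matrix**config.p + config.b
    base = np.clip(np.nan_to_num(base, nan=0.0, posinf=np.inf), 0.0, 1.0)
    if config.overlap_aware:
        return base
    return base / overlap[:, None]


def detect_ms1(tpr_matrix: np.ndarray, seed: int) -> np.ndarray:
    """Realise per-cell Bernoulli(TPR) detection trials."""
    if np.any(tpr_matrix < 0) or np.any(tpr_matrix > 1):
        raise ValueError("TPR values must lie in [0, 1]")
    rng = stage_rng(seed, "ms1_detection")
    return rng.random(tpr_matrix.shape) < tpr_matrix


def assign_identifiability(
    catalog: ProteomeCatalog, config: DetectionConfig, seed: int
) -> np.ndarray:
    """Per-species MS2 identifiability p_i.

    ``beta`` (default): p_i ~ Beta(a, b), seeded; the default Beta(2, 8) has
    mean 0.2, in the ballpark of typical single-run identification rates.
    ``logistic``: a deterministic sequence-based score — a logistic in peptide
    length and mean hydropathy — for studies that need p_i reproducible from
    the sequence alone. ``perfect``: p_i = 1 everywhere, the idealised MS2
    used by noiseless end-to-end checks.
    """
    if not catalog.peptides:
        raise ValueError("catalog has no peptides; digest first")
    if config.identifiability_model == "perfect":
        return np.ones(catalog.n_pep)
    if config.identifiability_model == "beta":
        a, b = config.identifiability_params
        rng = stage_rng(seed, "identifiability")
        return rng.beta(a, b, size=catalog.n_pep)
    if config.identifiability_model == "logistic":
        p = np.empty(catalog.n_pep)
        for i, pep in enumerate(catalog.peptides):
            kd = sum(KYTE_DOOLITTLE[r] for r in pep.sequence) / len(pep.sequence)
            p[i] = expit(-1.6 + 0.25 * kd - 0.04 * (len(pep.sequence) - 15))
        return p
    raise ValueError(
        f"unknown identifiability model {config.identifiability_model!r}"
    )


def identify_ms2(
    p_i: np.ndarray, n_samples: int, n_replicates: int, seed: int
) -> np.ndarray:
    """MS2 identification mask over r replicate assays per sample.

    Cell (i, j) is identified when at least one of r independent
    Bernoulli(p_i) trials succeeds, i.e. with probability 1 − (1 − p_i)^r.
    Identification is re-drawn per sample: under-sampling makes precursor
    selection poorly reproducible across runs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if np.any(p_i < 0) or np.any(p_i > 1):
        raise ValueError("identifiabilities must lie in [0, 1]")
    rng = stage_rng(seed, "ms2_identification")
    p_cell = 1.0 - (1.0 - np.asarray(p_i)) ** n_replicates
    return rng.random((len(p_i), n_samples)) < p_cell[:, None]


def link(
    detected: np.ndarray,
    identified: np.ndarray,
    v: np.ndarray,
    identifiability: np.ndarray,
    overlap: np.ndarray,
) -> ObservedPeptideTable:
    """AND-link MS1 and MS2: a cell is observed only if reported by both."""
    if not (detected.shape == identified.shape == v.shape):
        raise ValueError("mask and abundance shapes must agree")
    observed = detected & identified
    abundance = np.where(observed, v, np.nan)
    return ObservedPeptideTable(
        detected=detected,
        identified=identified,
        observed=observed,
        abundance=abundance,
        identifiability=np.asarray(identifiability),
        overlap_count=np.asarray(overlap),
    )
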