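"""Peptide-to-protein abundance roll-up with quality filtering.

Protein abundance is estimated by averaging the observed abundances of its
peptides that survive three filters: (1) only unique peptides (a single
parent protein) enter; (2) peptides missing in more than a threshold fraction
of samples are dropped (poor reproducibility flags dubious identifications);
(3) a peptide must correlate with at least one sibling peptide of the same
protein above a threshold, over their commonly observed samples. A protein
with fewer than two surviving peptides is not quantified (all-zero row).
Estimated concentration is estimated abundance divided by the instrument
response factor κ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .abundance_model import GroundTruthSamples
from .detection import ObservedPeptideTable
from .proteome import ProteomeCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "RollupConfig",
    "ProteinEstimate",
    "filter_peptides",
    "estimate_protein",
    "quantification_error",
    "missing_value_rates",
]

# Filter-audit stage labels.
STAGE_NON_UNIQUE = "non_unique"
STAGE_MISSING_RATE = "missing_rate"
STAGE_CORRELATION = "correlation"
STAGE_PASSED = "passed"


@dataclass
class RollupConfig:
    max_missing_rate: float = 0.7
    min_corr: float = 0.6
    min_peptides: int = 2
    unique_only: bool = True
    min_common_samples: int = 3  # pairwise-complete obs needed for a correlation

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing_rate <= 1) or not (-1 <= self.min_corr <= 1):
            raise ValueError("thresholds out of range")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")


@dataclass
class ProteinEstimate:
    """Estimated protein abundances/concentrations with a filter audit trail."""

    abundance_hat: np.ndarray      # (n_pro, 2M), >= 0; unquantified rows all-zero
    conc_hat: np.ndarray           # abundance_hat / kappa
    quantified: np.ndarray         # (n_pro,) bool
    filter_audit: dict[str, str]   # peptide_id -> stage that removed it / "passed"
    protein_ids: list[str] = field(default_factory=list)
    survivors: dict[str, list[int]] = field(default_factory=dict)

    def to_tsv(self, est_path, audit_path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.abundance_hat,
            index=self.protein_ids,
            columns=[f"s{j}" for j in range(self.abundance_hat.shape[1])],
        ).to_csv(est_path, sep="\t")
        pd.DataFrame(
            sorted(self.filter_audit.items()),
            columns=["peptide_id", "removed_at_stage"],
        ).to_csv(audit_path, sep="\t", index=False)


def _pairwise_complete_corr(
    x: np.ndarray, y: np.ndarray, ox: np.ndarray, oy: np.ndarray, min_common: int
) -> float:
    """Pearson r over samples where both peptides are observed; NaN if undefined."""
    both = ox & oy
    if both.sum() < min_common:
        return np.nan
    a, b = x[both], y[both]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def filter_peptides(
    table: ObservedPeptideTable,
    catalog: ProteomeCatalog,
    config: RollupConfig = RollupConfig(),
) -> tuple[dict[str, list[int]], dict[str, str]]:
    """Apply the three roll-up filters.

    Returns ``(survivors, audit)`` where ``survivors`` maps protein id to the
    catalog indices of its peptides passing all filters, and ``audit`` maps
    every peptide id to the first stage that removed it (or "passed").

    Stage 3 keeps a peptide when its best Pearson correlation with a sibling
    (same parent protein, pairwise-complete over commonly observed samples)
    exceeds ``min_corr``; a protein left with a single peptide after stage 2
    has no sibling, so that peptide cannot qualify.
    """
    n_samples = table.observed.shape[1]
    audit: dict[str, str] = {}
    # protein id -> peptide indices that survived stages 1-2
    stage2: dict[str, list[int]] = {}

    missing_rate = 1.0 - table.observed.sum(axis=1) / n_samples
    for i, pep in enumerate(catalog.peptides):
        if config.unique_only and not pep.is_unique:
            audit[pep.id] = STAGE_NON_UNIQUE
            continue
        if missing_rate[i] > config.max_missing_rate:
            audit[pep.id] = STAGE_MISSING_RATE
            continue
        for pid in pep.parents:
            stage2.setdefault(pid, []).append(i)

    survivors: dict[str, list[int]] = {}
    for pid, idxs in stage2.items():
        if len(idxs) < 2:
            for i in idxs:
                audit[catalog.peptides[i].id] = STAGE_CORRELATION
            continue
        sub_v = table.abundance[idxs]
        sub_o = table.observed[idxs]
        k = len(idxs)
        best = np.full(k, -np.inf)
        for a in range(k):
            for b in range(a + 1, k):
                r = _pairwise_complete_corr(
                    sub_v[a], sub_v[b], sub_o[a], sub_o[b],
                    config.min_common_samples,
                )
                if not np.isnan(r):
                    best[a] = max(best[a], r)
                    best[b] = max(best[b], r)
        keep = [idxs[a] for a in range(k) if best[a] > config.min_corr]
        for a in range(k):
            audit[catalog.peptides[idxs[a]].id] = (
                STAGE_PASSED if best[a] > config.min_corr else STAGE_CORRELATION
            )
        if keep:
            survivors[pid] = keep
    return survivors, audit


def estimate_protein(
    table: ObservedPeptideTable,
    survivors: dict[str, list[int]],
    catalog: ProteomeCatalog,
    kappa: float,
    min_peptides: int = 2,
) -> ProteinEstimate:
    """Average surviving peptides into protein abundance estimates.

    Proteins with fewer than ``min_peptides`` survivors get an all-zero row.
    Within a quantified protein, sample j's estimate averages the survivors
    observed in j; if none is observed there the entry is zero (a
    protein-level missing value). The mean is computed in shifted form
    (first observed value + mean of deviations), which avoids cancellation
    and is exact when all contributing values coincide.
    """
    protein_ids = [p.id for p in catalog.proteins]
    n_samples = table.observed.shape[1]
    abundance = np.zeros((len(protein_ids), n_samples))
    for li, pid in enumerate(protein_ids):
        idxs = survivors.get(pid, [])
        if len(idxs) < min_peptides:
            continue
        obs = table.observed[idxs]
        cnt = obs.sum(axis=0)
        first = np.argmax(obs, axis=0)  # first observed survivor per sample
        shift = np.nan_to_num(
            table.abundance[idxs][first, np.arange(n_samples)], nan=0.0
        )
        diffs = np.where(obs, table.abundance[idxs] - shift[None, :], 0.0)
        abundance[li] = np.where(
            cnt > 0, shift + diffs.sum(axis=0) / np.maximum(cnt, 1), 0.0
        )
    quantified = abundance.any(axis=1)
    return ProteinEstimate(
        abundance_hat=abundance,
        conc_hat=abundance / kappa,
        quantified=quantified,
        filter_audit={},
        protein_ids=protein_ids,
        survivors=survivors,
    )


def quantification_error(
    truth: GroundTruthSamples, estimate: ProteinEstimate
) -> float:
    """Mean relative quantification error over all proteins and samples.

    qerr = mean over (l, j) of |c_lj − ĉ_lj| / c_lj, including unquantified
    proteins (whose per-entry error is 1). Entries with true concentration
    zero are excluded with a warning (the relative error is undefined there).
    """
    c = truth.concentrations
    chat = estimate.conc_hat
    if c.shape != chat.shape:
        raise ValueError("truth and estimate shapes differ")
    ok = c > 0
    n_bad = c.size - ok.sum()
    if n_bad:
        logger.warning(
            "quantification_error: excluded %d cell(s) with zero true concentration",
            n_bad,
        )
    return float((np.abs(c[ok] - chat[ok]) / c[ok]).mean())


def missing_value_rates(
    table: ObservedPeptideTable, estimate: ProteinEstimate
) -> tuple[float, float]:
    """(peptide-level, protein-level) missing-value rates.

    Peptide level: fraction of (peptide, sample) cells not observed after
    AND-linking. Protein level: fraction of (protein, sample) cells with a
    zero abundance estimate.
    """
    pep_rate = 1.0 - float(table.observed.mean())
    pro_rate = float((estimate.abundance_hat == 0).mean())
    return pep_rate, pro_rate
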