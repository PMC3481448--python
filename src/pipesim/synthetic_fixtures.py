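"""Deterministic miniature fixtures for hand-checkable testing.

The toy proteome's tryptic products are known by construction: every protein
is a concatenation of K/R-terminated segments with no internal cleavage
sites, so digestion at zero missed cleavages returns exactly those segments
(length-filtered). It includes one peptide shared between two proteins and
one protein with a single length-passing peptide, exercising the uniqueness
filter and the "fewer than two peptides → unquantified" rule.
"""

from __future__ import annotations

from .analysis import RunResult
from .experiments import PipelineConfig, run_once, with_overrides
from .proteome import Protein, ProteomeCatalog

__all__ = [
    "TOY_SEQUENCES",
    "TOY_EXPECTED_PEPTIDES",
    "make_toy_proteome",
    "make_pipeline_golden",
    "GOLDEN_SEED",
]

# Segments are the expected tryptic products (0 missed cleavages, default
# length bounds 6-40). "SSSEEEGGGK" is shared between T1 and T2; T5's "LM"
# tail falls below the length filter, leaving T5 a single unique peptide.
TOY_SEQUENCES: dict[str, str] = {
    "T1": "AAAGGGK" + "CCCDDDK" + "SSSEEEGGGK" + "TTTVVVK",
    "T2": "MMMNNNK" + "SSSEEEGGGK" + "QQQWWWK" + "YYYFFFK",
    "T3": "DDDEEEK" + "GGGHHHK" + "IIILLLK",
    "T4": "NNNQQQR" + "TTTWWWR" + "VVVYYYR",
    "T5": "ACDEFGHIK" + "LM",
}

#: Expected peptide -> parent-id set under default digestion, derived by hand.
TOY_EXPECTED_PEPTIDES: dict[str, frozenset[str]] = {
    "AAAGGGK": frozenset({"T1"}),
    "CCCDDDK": frozenset({"T1"}),
    "SSSEEEGGGK": frozenset({"T1", "T2"}),
    "TTTVVVK": frozenset({"T1"}),
    "MMMNNNK": frozenset({"T2"}),
    "QQQWWWK": frozenset({"T2"}),
    "YYYFFFK": frozenset({"T2"}),
    "DDDEEEK": frozenset({"T3"}),
    "GGGHHHK": frozenset({"T3"}),
    "IIILLLK": frozenset({"T3"}),
    "NNNQQQR": frozenset({"T4"}),
    "TTTWWWR": frozenset({"T4"}),
    "VVVYYYR": frozenset({"T4"}),
    "ACDEFGHIK": frozenset({"T5"}),
}

GOLDEN_SEED = 20120
GOLDEN_CONFIG_OVERRIDES = dict(
    n_markers=5,
    n_background=25,
    M=20,
    n_test_per_class=100,
    n_features=10,
)


def make_toy_proteome(ids: list[str] | None = None) -> ProteomeCatalog:
    """The 5-protein toy catalog (proteins only; digest separately).

    ``ids`` restricts to a subset, e.g. T1-T4 for scenarios that need every
    protein to carry at least two exclusive unique peptides.
    """
    keys = ids if ids is not None else list(TOY_SEQUENCES)
    return ProteomeCatalog(
        proteins=[Protein(id=k, sequence=TOY_SEQUENCES[k]) for k in keys]
    )


def golden_config() -> PipelineConfig:
    """The small fixed configuration behind the golden regression snapshot."""
    cfg = with_overrides(PipelineConfig(), **GOLDEN_CONFIG_OVERRIDES)
    cfg.n_proteome = 60
    return cfg


def make_pipeline_golden(seed: int = GOLDEN_SEED) -> RunResult:
    """End-to-end RunResult at a pinned seed and small scale.

    The committed snapshot of this result guards against silent numeric
    drift anywhere in the pipeline; an intentional change requires an
    explicit golden refresh.
    """
    return run_once(golden_config(), seed)
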