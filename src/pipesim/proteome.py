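"""Proteome handling: FASTA input, synthetic proteomes, in-silico digestion.

A :class:`ProteomeCatalog` holds the proteins under study and, after
:func:`digest`, their tryptic peptides. Each peptide is annotated with its
monoisotopic mass, a predicted retention time (in LC scan units) and the set
of parent proteins that contain it — the inverse peptide-to-protein map that
drives the shared-peptide roll-up downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from pyteomics import mass as pmass
from pyteomics import parser as pparser
from scipy.special import expit

from ._rng import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "Protein",
    "Peptide",
    "ProteomeCatalog",
    "read_fasta",
    "generate_synthetic_proteome",
    "digest",
    "predict_rt",
    "mono_mass",
    "WATER_MONO",
    "CANONICAL_RESIDUES",
]

#: Monoisotopic mass of water, added once per peptide chain.
WATER_MONO = 18.0105646863

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)
_NONCANONICAL_RE = re.compile(f"[^{CANONICAL_RESIDUES}]")

# Trypsin: cleave C-terminal to K or R unless followed by P.
TRYPSIN_RULE = r"[KR](?!P)"

# Swiss-Prot background amino-acid frequencies (release-stable values,
# normalised to sum to 1), used by the synthetic proteome generator.
SWISSPROT_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}

# Kyte-Doolittle hydropathy index, used by the retention-time predictor.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class Protein:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-canonical residues {sorted(bad)}"
            )


@dataclass
class Peptide:
    """A digested peptide species, deduplicated by sequence within a catalog.

    ``parents`` is the set of catalog proteins whose digestion produced this
    sequence; a peptide is *unique* when it has exactly one parent, which is
    the condition for entering the protein roll-up.
    """

    id: str
    sequence: str
    mono_mass: float
    rt: float
    parents: frozenset[str]

    @property
    def is_unique(self) -> bool:
        return len(self.parents) == 1


@dataclass
class ProteomeCatalog:
    """Proteins plus (after digestion) their peptide species."""

    proteins: list[Protein]
    peptides: list[Peptide] = field(default_factory=list)

    @property
    def n_pro(self) -> int:
        return len(self.proteins)

    @property
    def n_pep(self) -> int:
        return len(self.peptides)

    def protein_index(self) -> dict[str, int]:
        return {p.id: i for i, p in enumerate(self.proteins)}

    def peptide_by_sequence(self) -> dict[str, Peptide]:
        return {p.sequence: p for p in self.peptides}

    def membership_matrix(self):
        """Sparse (n_pep, n_pro) 0/1 matrix mapping peptides to their parents."""
        from scipy import sparse

        pidx = self.protein_index()
        rows, cols = [], []
        for i, pep in enumerate(self.peptides):
            for pid in pep.parents:
                if pid not in pidx:
                    raise ValueError(
                        f"peptide {pep.id!r} references unknown protein {pid!r}"
                    )
                rows.append(i)
                cols.append(pidx[pid])
        data = np.ones(len(rows))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_pep, self.n_pro)
        )

    def subset(self, protein_ids: list[str]) -> "ProteomeCatalog":
        """New catalog (proteins only) restricted to ``protein_ids`` in order."""
        by_id = {p.id: p for p in self.proteins}
        return ProteomeCatalog(proteins=[by_id[i] for i in protein_ids])

    def to_tsv(self, path) -> None:
        """Write the digested catalog as a peptide table."""
        import pandas as pd

        pd.DataFrame(
            {
                "peptide_id": [p.id for p in self.peptides],
                "sequence": [p.sequence for p in self.peptides],
                "mono_mass": [p.mono_mass for p in self.peptides],
                "rt": [p.rt for p in self.peptides],
                "parent_ids": [";".join(sorted(p.parents)) for p in self.peptides],
                "is_unique": [p.is_unique for p in self.peptides],
            }
        ).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> ProteomeCatalog:
    """Load proteins from a FASTA file.

    Record ids are taken from the header up to the first whitespace and
    sequences are uppercased. Non-canonical residues (B, J, O, U, X, Z, gaps)
    are dropped with a warning rather than raising, for robustness to real
    database files.
    """
    proteins: list[Protein] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = _NONCANONICAL_RE.sub("", seq)
        if cleaned != seq:
            logger.warning(
                "protein %s: dropped %d non-canonical residue(s)",
                rec.id, len(seq) - len(cleaned),
            )
        if not cleaned:
            logger.warning("protein %s: empty after cleaning, skipped", rec.id)
            continue
        proteins.append(Protein(id=rec.id, sequence=cleaned))
    if not proteins:
        raise ValueError(f"no usable FASTA records in {path!s}")
    return ProteomeCatalog(proteins=proteins)


def generate_synthetic_proteome(
    n_proteins: int,
    length_law: tuple[float, float] = (350.0, 100.0),
    seed: int = 0,
    min_length: int = 50,
) -> ProteomeCatalog:
    """Random proteome with realistic composition and length distribution.

    Sequences are i.i.d. over the 20 canonical residues at Swiss-Prot
    background frequencies; lengths follow a normal law truncated below at
    ``min_length``. The default mean/sd yield roughly 20 length-filtered
    tryptic peptides per protein, the typical ratio for human proteins.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    mean, sd = length_law
    rng = stage_rng(seed, "synthetic_proteome")
    residues = np.array(list(SWISSPROT_FREQS))
    freqs = np.array(list(SWISSPROT_FREQS.values()))
    freqs = freqs / freqs.sum()

    if sd == 0:
        lengths = np.full(n_proteins, max(int(round(mean)), min_length))
    else:
        lengths = np.empty(n_proteins, dtype=int)
        filled = 0
        while filled < n_proteins:  # rejection sampling of the truncation
            draw = rng.normal(mean, sd, size=2 * (n_proteins - filled))
            draw = draw[draw >= min_length]
            take = min(len(draw), n_proteins - filled)
            lengths[filled:filled + take] = np.round(draw[:take]).astype(int)
            filled += take

    width = len(str(n_proteins))
    proteins = [
        Protein(
            id=f"SYN{i:0{width}d}",
            sequence="".join(rng.choice(residues, size=lengths[i], p=freqs)),
        )
        for i in range(n_proteins)
    ]
    return ProteomeCatalog(proteins=proteins)


def mono_mass(sequence: str) -> float:
    """Monoisotopic peptide mass: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence has no mass")
    bad = set(sequence) - _CANONICAL_SET
    if bad:
        raise ValueError(f"non-canonical residue(s) {sorted(bad)} in {sequence!r}")
    return float(pmass.fast_mass(sequence))


def predict_rt(sequence: str, n_scans: int = 1000) -> float:
    """Predicted LC retention time in scan units.

    A deterministic residue-additive hydrophobicity stand-in: the mean
    Kyte-Doolittle hydropathy of the peptide is mapped through a logistic onto
    (0, n_scans), so more hydrophobic peptides elute later. Only relative RT
    proximity matters downstream (the overlap criterion), so any monotone
    deterministic predictor serves.
    """
    if not sequence:
        raise ValueError("empty sequence has no retention time")
    score = sum(KYTE_DOOLITTLE[a] for a in sequence) / len(sequence)
    return float(n_scans * expit(score))


def digest(
    catalog: ProteomeCatalog,
    missed_cleavages: int = 0,
    min_length: int = 6,
    max_length: int = 40,
    n_scans: int = 1000,
) -> ProteomeCatalog:
    """In-silico tryptic digestion of every protein in the catalog.

    Cleavage is C-terminal to K/R except before P. Peptides shorter than
    ``min_length`` or longer than ``max_length`` are discarded. Identical
    sequences arising from multiple proteins are merged into a single
    :class:`Peptide` whose ``parents`` is the union — this realises the
    peptide-to-protein ambiguity set used by the concentration roll-up.
    Returns a new catalog; the input is not modified.
    """
    if not catalog.proteins:
        raise ValueError("catalog has no proteins to digest")

    parents: dict[str, set[str]] = {}
    order: list[str] = []  # first-seen order, for stable peptide ids
    for prot in catalog.proteins:
        pieces = pparser.cleave(
            prot.sequence,
            TRYPSIN_RULE,
            missed_cleavages=missed_cleavages,
            min_length=min_length,
            max_length=max_length,
        )
        for seq in sorted(pieces):
            if seq not in parents:
                parents[seq] = set()
                order.append(seq)
            parents[seq].add(prot.id)

    width = max(len(str(len(order))), 5)
    peptides = [
        Peptide(
            id=f"pep{i:0{width}d}",
            sequence=seq,
            mono_mass=mono_mass(seq),
            rt=predict_rt(seq, n_scans=n_scans),
            parents=frozenset(parents[seq]),
        )
        for i, seq in enumerate(order)
    ]
    return ProteomeCatalog(proteins=list(catalog.proteins), peptides=peptides)
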