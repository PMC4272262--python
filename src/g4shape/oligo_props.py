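"""Sequence-derived physical properties of DNA oligonucleotides.

Molecular weight (free-acid convention), nearest-neighbor molar absorption
coefficient at 260 nm, and Beer-Lambert strand concentration — the three
numbers needed to put spectroscopic and hydrodynamic data on a molar basis.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "OligoSequence",
    "molecular_weight",
    "extinction_260",
    "concentration_from_absorbance",
    "read_fasta",
    "HTERT_SEQ",
    "XAV_SEQ",
]

_VALID_BASES = frozenset("ACGT")

# Average monomer masses (Da) for the 5'-OH free-acid convention; the
# terminal correction removes one HPO3 + adds H2O across the strand.
MONOMER_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2}
TERMINAL_CORRECTION = -61.96

# The two strands studied throughout this package: the 68-nt hTERT core
# promoter G-rich strand and the c-myc promoter variant whose parallel
# quadruplex NMR structure is PDB 1XAV.
HTERT_SEQ = (
    "GGGGAGGGGCTGGGAGGGCCCGGAGGGGGCTGGGCC"
    "GGGGACCCGGGAGGGGTCGGGACGGGGCGGGG"
)
XAV_SEQ = "TGAGGGTGGGTAGGGTGGGTAA"


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or characters outside {A, C, G, T}."""


def _clean(bases: str) -> str:
    seq = "".join(bases.split()).upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise InvalidSequenceError(f"non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass
class OligoSequence:
    """A DNA strand with its derived physical properties.

    Properties are computed once at construction; ``mw`` is the average
    molecular weight in Da (free acid), ``eps260`` the nearest-neighbor
    molar absorption coefficient in mM^-1 cm^-1 (None for mononucleotides,
    where the method does not apply).
    """

    name: str
    bases: str
    counts: Counter = field(init=False)
    mw: float = field(init=False)
    eps260: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.bases = _clean(self.bases)
        self.counts = Counter(self.bases)
        self.mw = molecular_weight(self.bases)
        self.eps260 = extinction_260(self.bases) if len(self.bases) >= 2 else None

    def __len__(self) -> int:
        return len(self.bases)


def molecular_weight(seq: str | OligoSequence) -> float:
    """Average molecular weight in Da of a single-stranded DNA (free acid).

    Sum of average monomer residue masses minus one terminal correction
    (61.96 Da), reported to 0.1 Da.
    """
    bases = seq.bases if isinstance(seq, OligoSequence) else _clean(seq)
    mass = sum(MONOMER_MASS[b] for b in bases) + TERMINAL_CORRECTION
    return round(mass, 1)


def _load_nn_table(path: str | Path | None = None) -> dict:
    if path is None:
        ref = importlib.resources.files("g4shape.data") / "nn_extinction_cantor.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    for key in ("pairs", "monomers"):
        if key not in table:
            raise ValueError(f"NN extinction table missing '{key}' section")
    return table


def extinction_260(seq: str | OligoSequence, table: str | Path | dict | None = None) -> float:
    """Nearest-neighbor molar absorption coefficient at 260 nm (mM^-1 cm^-1).

    eps = sum over dinucleotide steps of eps_NN  -  sum over internal bases
    of eps_mono.  Requires length >= 2.  ``table`` may be a parameter-set
    dict or a path to an alternate YAML table (the default is bundled).
    """
    bases = seq.bases if isinstance(seq, OligoSequence) else _clean(seq)
    if len(bases) < 2:
        raise InvalidSequenceError(
            "nearest-neighbor method needs at least one dinucleotide step"
        )
    if not isinstance(table, dict):
        table = _load_nn_table(table)
    pairs, mono = table["pairs"], table["monomers"]
    eps = sum(pairs[bases[i : i + 2]] for i in range(len(bases) - 1))
    eps -= sum(mono[b] for b in bases[1:-1])
    return round(eps, 1)


def concentration_from_absorbance(A: float, eps: float, path: float = 1.0) -> float:
    """Strand concentration in uM from A260 via Beer-Lambert.

    ``eps`` in mM^-1 cm^-1, ``path`` in cm; c = 1000 * A / (eps * path).
    """
    if eps <= 0 or path <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    if A < 0:
        raise ValueError("absorbance must be non-negative")
    return 1000.0 * A / (eps * path)


def read_fasta(path: str | Path) -> list[OligoSequence]:
    """Read DNA sequences from FASTA into :class:`OligoSequence` records."""
    from Bio import SeqIO

    return [
        OligoSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
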