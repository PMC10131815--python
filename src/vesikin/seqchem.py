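"""Sequence parsing, composition and molecular-weight arithmetic.

Molecular weights follow the additive residue-mass convention used for
synthetic mRNA constructs: each ribonucleotide contributes its average
monophosphate residue mass and the 5' triphosphate of an uncapped in vitro
transcript adds a flat 159 g/mol.  Protein masses are sums of standard
average amino-acid residue masses plus one water.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_rna_table
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "RnaSequence",
    "ProteinSequence",
    "Composition",
    "FastaError",
    "AlphabetError",
    "parse_fasta",
    "composition",
    "rna_molecular_weight",
    "translate",
    "protein_molecular_weight",
    "RNA_RESIDUE_MASS",
    "PROTEIN_RESIDUE_MASS",
    "TRIPHOSPHATE_MASS",
    "WATER_MASS",
]

RNA_ALPHABET = frozenset("AUGC")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average residue masses of the four ribonucleotide monophosphates, g/mol.
RNA_RESIDUE_MASS = {"A": 329.2, "U": 306.2, "C": 305.2, "G": 345.2}

#: Flat mass added for a 5' triphosphate on an uncapped transcript, g/mol.
TRIPHOSPHATE_MASS = 159.0

#: Standard average amino-acid residue masses (protein minus water), g/mol.
PROTEIN_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Mass of one water molecule, g/mol, added once per peptide chain.
WATER_MASS = 18.0153


class FastaError(ValueError):
    """Malformed FASTA input (no records, or an empty record)."""


class AlphabetError(ValueError):
    """A residue outside the declared alphabet."""


def _validate_residues(residues: str, alphabet: frozenset[str], name: str) -> None:
    if len(residues) == 0:
        raise FastaError(f"sequence {name!r} is empty")
    for pos, ch in enumerate(residues):
        if ch not in alphabet:
            raise AlphabetError(
                f"sequence {name!r}: invalid residue {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, U, G, C}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        _validate_residues(self.residues, RNA_ALPHABET, self.name)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard one-letter codes."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        _validate_residues(self.residues, PROTEIN_ALPHABET, self.name)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Composition:
    """Residue counts and fractions of a sequence."""

    counts: dict[str, int]
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return sum(self.counts.values())


def _normalize(raw: str, alphabet: str) -> str:
    seq = "".join(raw.split()).upper().replace(".", "")
    if alphabet == "rna":
        seq = seq.replace("T", "U")
    return seq


def parse_fasta(text: str, alphabet: str = "rna") -> list[RnaSequence | ProteinSequence]:
    """Parse FASTA text into validated sequences.

    Whitespace inside sequence lines is stripped (sequences printed as
    space-separated 5-mers are accepted), case is normalized to upper and,
    for RNA, ``T`` is transliterated to ``U``.  Any other character outside
    the alphabet raises :class:`AlphabetError` naming the offending position.
    """
    if alphabet not in ("rna", "protein"):
        raise ValueError(f"alphabet must be 'rna' or 'protein', got {alphabet!r}")
    records = list(SimpleFastaParser(io.StringIO(text)))
    if not records:
        raise FastaError("no FASTA records found")
    cls = RnaSequence if alphabet == "rna" else ProteinSequence
    out: list[RnaSequence | ProteinSequence] = []
    for title, raw in records:
        name = title.split()[0] if title.split() else title
        out.append(cls(name=name, residues=_normalize(raw, alphabet)))
    return out


def composition(seq: RnaSequence | ProteinSequence) -> Composition:
    """Residue counts and fractions; counts always cover the full alphabet."""
    alphabet = RNA_ALPHABET if isinstance(seq, RnaSequence) else PROTEIN_ALPHABET
    tally = Counter(seq.residues)
    counts = {r: tally.get(r, 0) for r in sorted(alphabet)}
    n = len(seq)
    fractions = {r: c / n for r, c in counts.items()}
    return Composition(counts=counts, fractions=fractions)


def rna_molecular_weight(seq: RnaSequence, triphosphate: bool = True) -> float:
    """Average molecular weight of an RNA in g/mol.

    Sum of per-base residue masses (A 329.2, U 306.2, C 305.2, G 345.2) plus
    159.0 for the 5' triphosphate when ``triphosphate`` is set.  Depends only
    on base composition, so it is invariant under residue permutation.
    """
    comp = composition(seq)
    mw = sum(RNA_RESIDUE_MASS[r] * n for r, n in comp.counts.items())
    if triphosphate:
        mw += TRIPHOSPHATE_MASS
    return mw


def translate(seq: RnaSequence) -> ProteinSequence:
    """Translate an in-frame coding sequence with the standard genetic code.

    The sequence must start with AUG and have length divisible by 3.
    Translation stops at the first stop codon (excluded from the product);
    a stop before the final codon, or a missing terminal stop, raises a
    warning rather than an error so fragments remain analyzable.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    if seq.residues[:3] != "AUG":
        raise ValueError(f"sequence does not begin with AUG (got {seq.residues[:3]!r})")
    table = standard_rna_table
    residues = []
    stop_at: int | None = None
    for i in range(0, len(seq), 3):
        codon = seq.residues[i : i + 3]
        if codon in table.stop_codons:
            stop_at = i
            break
        residues.append(table.forward_table[codon])
    if stop_at is None:
        warnings.warn(f"sequence {seq.name!r} has no stop codon", stacklevel=2)
    elif stop_at < len(seq) - 3:
        warnings.warn(
            f"sequence {seq.name!r}: stop codon at nucleotide {stop_at}, "
            f"before the final codon",
            stacklevel=2,
        )
    return ProteinSequence(name=seq.name, residues="".join(residues))


def protein_molecular_weight(seq: ProteinSequence) -> float:
    """Average molecular weight of a protein in g/mol.

    Sum of standard average residue masses plus one water (18.0153 g/mol).
    """
    return sum(PROTEIN_RESIDUE_MASS[r] for r in seq.residues) + WATER_MASS
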