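"""Amino-acid and nucleobase alphabets and the standard genetic code.

Central definitions shared by every stage: the 20 canonical amino acids,
the 4 RNA bases, the purine/pyrimidine partition, and codon lookups built
from Biopython's standard RNA codon table.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_rna_by_id

#: Canonical amino acids, one-letter codes, fixed alphabetical order.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: RNA bases in fixed order.
BASES: tuple[str, ...] = ("A", "C", "G", "U")

PURINES: frozenset[str] = frozenset({"A", "G"})
PYRIMIDINES: frozenset[str] = frozenset({"C", "U"})

#: Base classes: the four single bases plus the merged purine/pyrimidine classes.
BASE_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset({"A"}),
    "C": frozenset({"C"}),
    "G": frozenset({"G"}),
    "U": frozenset({"U"}),
    "PUR": PURINES,
    "PYR": PYRIMIDINES,
}

#: Which partition of the 4 bases a class belongs to. Merged classes use a
#: fresh two-class partition when computing mole fractions, never an average
#: of single-base quantities.
SINGLE_PARTITION: tuple[str, ...] = ("G", "A", "C", "U")
MERGED_PARTITION: tuple[str, ...] = ("PUR", "PYR")

#: Three-letter to one-letter amino-acid codes; MSE (selenomethionine) is
#: treated as methionine.
AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

AA1_TO_3: dict[str, str] = {
    one: three for three, one in AA3_TO_1.items() if three != "MSE"
}

#: PDB residue names of ribonucleotides / deoxyribonucleotides.
RNA_RESNAMES: frozenset[str] = frozenset({"A", "C", "G", "U"})
DNA_RESNAMES: frozenset[str] = frozenset({"DA", "DC", "DG", "DT"})

_table = unambiguous_rna_by_id[1]

#: codon -> one-letter amino acid (standard code, RNA alphabet).
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(_table.stop_codons)

#: one-letter amino acid -> tuple of its codons, in a fixed sorted order.
CODONS_BY_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AA_ORDER
}


def class_count(codon: str, base_class: str) -> int:
    """Number of positions in ``codon`` occupied by bases of ``base_class``."""
    members = BASE_CLASSES[base_class]
    return sum(1 for b in codon if b in members)


def validate_base_class(base_class: str) -> str:
    if base_class not in BASE_CLASSES:
        raise ValueError(
            f"unknown base class {base_class!r}; expected one of {sorted(BASE_CLASSES)}"
        )
    return base_class
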