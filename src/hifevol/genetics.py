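"""Genetic code and codon alphabet.

The selection machinery works on the 61 sense codons of the standard
nuclear code; stop codons are excluded from the state space and their
appearance inside a coding sequence is treated as a data error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
GAP_CODON = "---"
UNKNOWN_AA = "X"
STOP_AA = "*"


def _standard_tables() -> tuple[dict[str, str], tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping: dict[str, str] = {}
    for codon in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)):
        if codon in table.stop_codons:
            mapping[codon] = STOP_AA
        else:
            mapping[codon] = table.forward_table[codon]
    sense = tuple(c for c in sorted(mapping) if mapping[c] != STOP_AA)
    return mapping, sense


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid map plus the ordered sense-codon alphabet."""

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {c: i for i, c in enumerate(self.sense_codons)}
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        mapping, sense = _standard_tables()
        code = cls(codon_to_aa=mapping, sense_codons=sense)
        if len(sense) != 61:
            raise AssertionError("standard code must have 61 sense codons")
        return code

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP_AA

    def translate(self, codon: str) -> str:
        """Translate one triplet; any non-ACGT character yields ``X``."""
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"codon must be a triplet, got {codon!r}")
        if codon == GAP_CODON:
            return "-"
        aa = self.codon_to_aa.get(codon)
        return aa if aa is not None else UNKNOWN_AA


STANDARD_CODE = GeneticCode.standard()


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a<->b is a transition."""
    return (a in PURINES) == (b in PURINES)


def codon_diffs(c1: str, c2: str) -> list[int]:
    """Positions (0-based) at which two codons differ."""
    return [k for k in range(3) if c1[k] != c2[k]]
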