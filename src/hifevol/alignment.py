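"""In-frame codon alignments.

Alignment columns are "MSA codons", indexed 1-based throughout the
package. A codon containing any gap or ambiguous character is treated
as fully missing at that site (whole-codon granularity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GAP_CODON, STANDARD_CODE, GeneticCode

MISSING = -1  # integer state for gap/ambiguous codons


class FrameError(ValueError):
    """Sequence length not divisible by three."""


class ContentError(ValueError):
    """Internal stop codon in a coding sequence."""


class IdentityError(ValueError):
    """Duplicate or mismatched taxon names."""


@dataclass
class CodonAlignment:
    """Codon alignment over the 61 sense codons.

    ``codes`` holds one integer row per taxon: the index of the sense
    codon in ``code.sense_codons``, or ``MISSING`` for gap/ambiguous
    codons.
    """

    taxa: list[str]
    codons: list[list[str]]  # taxa x sites, raw triplets
    code: GeneticCode

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise IdentityError("duplicate taxon names in alignment")
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise FrameError("rows of unequal codon length")
        self.codes = np.array(
            [
                [self.code.index.get(c, MISSING) for c in row]
                for row in self.codons
            ],
            dtype=np.int64,
        ).reshape(len(self.taxa), -1)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length_codons(self) -> int:
        return self.codes.shape[1]

    def column(self, site: int) -> list[str]:
        """Raw codons at a 1-based MSA codon position."""
        if not 1 <= site <= self.length_codons:
            raise IndexError(f"site {site} outside 1..{self.length_codons}")
        return [row[site - 1] for row in self.codons]

    def site_codes(self, site: int) -> np.ndarray:
        """Integer states at a 1-based site."""
        if not 1 <= site <= self.length_codons:
            raise IndexError(f"site {site} outside 1..{self.length_codons}")
        return self.codes[:, site - 1]

    def to_protein(self) -> dict[str, str]:
        """Translate every row (gap codons to '-')."""
        return {
            t: "".join(self.code.translate(c) for c in row)
            for t, row in zip(self.taxa, self.codons)
        }


def _split_codons(name: str, seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise FrameError(
            f"record {name!r}: length {len(seq)} not divisible by 3"
        )
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _normalize_codon(codon: str) -> str:
    """Whole-codon gap policy: any gap/ambiguity makes the codon a gap."""
    if any(ch not in "ACGT" for ch in codon):
        return GAP_CODON
    return codon


def read_codon_fasta(
    path: str | Path,
    code: GeneticCode = STANDARD_CODE,
    allow_stops: bool = False,
) -> CodonAlignment:
    """Read an in-frame FASTA alignment into a :class:`CodonAlignment`.

    Raises :class:`FrameError` when a record's length is not a multiple
    of three, :class:`ContentError` on an internal stop codon (unless
    ``allow_stops``), and :class:`IdentityError` on duplicate names.
    """
    taxa: list[str] = []
    rows: list[list[str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        codons = [_normalize_codon(c) for c in _split_codons(rec.id, str(rec.seq))]
        if not allow_stops:
            for j, c in enumerate(codons):
                if c != GAP_CODON and code.is_stop(c):
                    raise ContentError(
                        f"record {rec.id!r}: stop codon {c} at codon {j + 1}"
                    )
        if rec.id in taxa:
            raise IdentityError(f"duplicate taxon {rec.id!r}")
        taxa.append(rec.id)
        rows.append(codons)
    if not taxa:
        raise ValueError(f"no FASTA records in {path}")
    return CodonAlignment(taxa=taxa, codons=rows, code=code)


def write_codon_fasta(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=t, description="")
        for t, row in zip(aln.taxa, aln.codons)
    ]
    SeqIO.write(records, str(path), "fasta")
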