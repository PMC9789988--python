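"""Degradation-motif scanning, column-to-reference mapping, domain tallies.

HIFα proteins carry two prolyl-hydroxylation targets with the canonical
LxxLAP consensus (in the N- and C-terminal oxygen-dependent degradation
domains) and a C-terminal asparaginyl-hydroxylation motif (CEVN) whose
asparagine can be substituted in some lineages; a near-match report
names such substitutions. Selected alignment columns are mapped onto a
reference sequence (e.g. human, to compare against known PTM sites) and
tallied by structural domain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path


@dataclass
class MotifHit:
    sequence_id: str
    start: int  # 1-based
    matched: str
    motif: str  # "LxxLAP" or "CEVN"
    substitution: str | None = None  # e.g. "N->T" for a degraded motif


@dataclass
class DomainAnnotation:
    """Named 1-based inclusive residue intervals on a reference protein."""

    reference: str
    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (a, b) in self.intervals.items():
            if a < 1 or b < a:
                raise ValueError(f"bad interval {name}: [{a}, {b}]")
        items = sorted(self.intervals.items(), key=lambda kv: kv[1])
        for (n1, (_, e1)), (n2, (s2, _)) in zip(items, items[1:]):
            if s2 <= e1:
                raise ValueError(f"domains {n1} and {n2} overlap")


_LXXLAP = re.compile(r"(?=(L..LAP))")


def scan_lxxlap(sequence: str, sequence_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) LxxLAP occurrences, 1-based starts."""
    seq = sequence.upper()
    return [
        MotifHit(
            sequence_id=sequence_id, start=m.start() + 1,
            matched=m.group(1), motif="LxxLAP",
        )
        for m in _LXXLAP.finditer(seq)
    ]


def scan_cterm_asn_motif(
    sequence: str, sequence_id: str = "", window: int = 50
) -> MotifHit | None:
    """Exact CEVN in the C-terminal window, else a 1-mismatch report.

    A near-match (exactly one substituted residue) is returned with the
    substitution named (e.g. "N->T" when the hydroxyl-acceptor
    asparagine is replaced); it is a degraded-motif report, not a hit.
    Sequences shorter than the window are scanned in full.
    """
    seq = sequence.upper().rstrip("*")
    tail_start = max(0, len(seq) - window)
    tail = seq[tail_start:]
    exact = tail.rfind("CEVN")
    if exact >= 0:
        return MotifHit(
            sequence_id=sequence_id, start=tail_start + exact + 1,
            matched="CEVN", motif="CEVN",
        )
    best = None
    for i in range(len(tail) - 3):
        sub = tail[i : i + 4]
        mismatches = [k for k in range(4) if sub[k] != "CEVN"[k]]
        if len(mismatches) == 1:
            k = mismatches[0]
            best = MotifHit(
                sequence_id=sequence_id, start=tail_start + i + 1,
                matched=sub, motif="CEVN",
                substitution=f"{'CEVN'[k]}->{sub[k]}",
            )
    return best


def map_column_to_reference(
    msa: dict[str, str], column: int, reference: str
) -> int | None:
    """Map a 1-based alignment column to a reference residue number.

    Returns the count of non-gap reference characters up to and
    including the column, or None when the reference is gapped there.
    """
    if reference not in msa:
        raise KeyError(f"reference taxon {reference!r} not in alignment")
    row = msa[reference]
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} outside 1..{len(row)}")
    if row[column - 1] == "-":
        return None
    return sum(1 for ch in row[:column] if ch != "-")


def tally_sites_by_domain(
    sites: list[int], annotation: DomainAnnotation
) -> dict[str, int]:
    """Count reference-coordinate sites per domain; the remainder is
    reported under "linker"."""
    counts = {name: 0 for name in annotation.intervals}
    counts["linker"] = 0
    for s in sites:
        for name, (a, b) in annotation.intervals.items():
            if a <= s <= b:
                counts[name] += 1
                break
        else:
            counts["linker"] += 1
    return counts


def read_domain_config(path: str | Path) -> DomainAnnotation:
    """Plain-text config: ``reference <taxon>`` then ``<name> <start> <end>``."""
    reference = ""
    intervals: dict[str, tuple[int, int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0].lower() == "reference":
            reference = parts[1]
        elif len(parts) == 3:
            intervals[parts[0]] = (int(parts[1]), int(parts[2]))
        else:
            raise ValueError(f"cannot parse domain config line: {raw!r}")
    if not reference:
        raise ValueError("domain config must name a reference taxon")
    return DomainAnnotation(reference=reference, intervals=intervals)
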