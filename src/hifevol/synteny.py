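"""Flanking-gene neighborhoods and phylogenetically informed ohnolog naming.

After a whole-genome duplication the two copies of a gene sit in two
copies of the ancestral neighborhood, which then erode independently.
Comparing the genes flanking each copy against a pre-duplication
outgroup (or the sister lineage, for a later duplication) identifies
which copy retains the ancestral neighborhood better, and that drives
the naming rules:

* TGD (teleost) paralog pairs: the copy sharing more flanking genes
  with the ancestral (gar) neighborhood is "a", the other "b"; the
  suffix is only applied when at least one lineage retains both copies.
* SGD (salmonid) pairs: the copy sharing more flanks with the sister
  group (Esociformes) is "s1", the other "s2".

Matching is by normalized gene symbol; "unknown" never matches, and
duplicate symbols inside one window count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

UNKNOWN = "UNKNOWN"


@dataclass
class GeneNeighborhood:
    """Up to 10 upstream (+offset -10..-1) and 10 downstream (+1..+10)
    flanking genes around a focal gene."""

    species: str
    focal_gene: str
    flanks: list[tuple[int, str, str]]  # (offset, symbol, strand)

    def __post_init__(self) -> None:
        offsets = [o for o, _, _ in self.flanks]
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate flank offsets")
        for o, _, s in self.flanks:
            if o == 0 or not -10 <= o <= 10:
                raise ValueError(f"offset {o} outside -10..10 (excluding 0)")
            if s not in "+-":
                raise ValueError(f"strand must be + or -, got {s!r}")
        self.flanks = [
            (o, sym.strip().upper(), s) for o, sym, s in self.flanks
        ]

    def known_symbols(self) -> set[str]:
        return {sym for _, sym, _ in self.flanks if sym != UNKNOWN}

    def side(self, which: str) -> list[tuple[int, str, str]]:
        """Flanks on one side, ordered walking outward from the focal gene."""
        if which == "up":
            entries = [f for f in self.flanks if f[0] < 0]
            return sorted(entries, key=lambda f: -f[0])  # -1, -2, ...
        if which == "down":
            entries = [f for f in self.flanks if f[0] > 0]
            return sorted(entries, key=lambda f: f[0])
        raise ValueError("side must be 'up' or 'down'")


@dataclass
class SyntenyScore:
    shared_count: int
    conserved_run_up: int
    conserved_run_down: int
    strand_agreement_up: int = 0
    strand_agreement_down: int = 0


@dataclass
class ParalogAssignment:
    labels: dict[str, str]  # paralog id -> a|b|s1|s2|unsuffixed|unresolved
    scores: dict[str, int]
    reference: str  # "ancestral" or "sister_group"
    rule: str = ""


def shared_flank_count(n1: GeneNeighborhood, n2: GeneNeighborhood) -> int:
    """Number of distinct known gene symbols shared by the two windows."""
    return len(n1.known_symbols() & n2.known_symbols())


def conserved_run(
    n1: GeneNeighborhood, n2: GeneNeighborhood, side: str
) -> int:
    """Longest in-order matching run walking outward from the focal gene.

    Unknowns break the run; strand differences do not (strand agreement
    is reported separately by :func:`synteny_score`).
    """
    s1, s2 = n1.side(side), n2.side(side)
    run = 0
    for (_, a, _), (_, b, _) in zip(s1, s2):
        if a == b and a != UNKNOWN:
            run += 1
        else:
            break
    return run


def synteny_score(n1: GeneNeighborhood, n2: GeneNeighborhood) -> SyntenyScore:
    agree = {"up": 0, "down": 0}
    for side in ("up", "down"):
        for (_, a, sa), (_, b, sb) in zip(n1.side(side), n2.side(side)):
            if a == b and a != UNKNOWN and sa == sb:
                agree[side] += 1
    return SyntenyScore(
        shared_count=shared_flank_count(n1, n2),
        conserved_run_up=conserved_run(n1, n2, "up"),
        conserved_run_down=conserved_run(n1, n2, "down"),
        strand_agreement_up=agree["up"],
        strand_agreement_down=agree["down"],
    )


def assign_tgd_labels(
    p1: GeneNeighborhood,
    p2: GeneNeighborhood,
    ancestral: GeneNeighborhood | None,
    retained_in_any_lineage_both: bool = True,
) -> ParalogAssignment:
    """Name a TGD paralog pair "a"/"b" by shared flanks with the ancestor.

    When no lineage retains both copies the suffix is withheld
    ("unsuffixed"); ties leave both copies "unresolved".
    """
    if ancestral is None:
        raise ValueError("ancestral (pre-duplication) neighborhood required")
    s1 = shared_flank_count(p1, ancestral)
    s2 = shared_flank_count(p2, ancestral)
    scores = {p1.focal_gene: s1, p2.focal_gene: s2}
    if not retained_in_any_lineage_both:
        labels = {p1.focal_gene: "unsuffixed", p2.focal_gene: "unsuffixed"}
        rule = "single surviving paralog lineage-wide: a/b suffix withheld"
    elif s1 == s2:
        labels = {p1.focal_gene: "unresolved", p2.focal_gene: "unresolved"}
        rule = "tie on shared flank counts"
    else:
        first_is_a = s1 > s2
        labels = {
            p1.focal_gene: "a" if first_is_a else "b",
            p2.focal_gene: "b" if first_is_a else "a",
        }
        rule = "'a' shares more flanking genes with the ancestral form"
    return ParalogAssignment(
        labels=labels, scores=scores, reference="ancestral", rule=rule
    )


def assign_sgd_labels(
    p1: GeneNeighborhood,
    p2: GeneNeighborhood,
    sister_group_ref: GeneNeighborhood | None,
) -> ParalogAssignment:
    """Name an SGD paralog pair "s1"/"s2" by shared flanks with the sister
    group; ties leave both unresolved."""
    if sister_group_ref is None:
        raise ValueError("sister-group neighborhood required")
    s1 = shared_flank_count(p1, sister_group_ref)
    s2 = shared_flank_count(p2, sister_group_ref)
    scores = {p1.focal_gene: s1, p2.focal_gene: s2}
    if s1 == s2:
        labels = {p1.focal_gene: "unresolved", p2.focal_gene: "unresolved"}
        rule = "tie on shared flank counts"
    else:
        first_is_s1 = s1 > s2
        labels = {
            p1.focal_gene: "s1" if first_is_s1 else "s2",
            p2.focal_gene: "s2" if first_is_s1 else "s1",
        }
        rule = "'s1' shares more flanking genes with the sister group"
    return ParalogAssignment(
        labels=labels, scores=scores, reference="sister_group", rule=rule
    )


# ---------------------------------------------------------------------------
# TSV interface: species, focal_gene, offset, symbol, strand


def read_neighborhood_tsv(path: str | Path) -> dict[str, GeneNeighborhood]:
    """Read neighborhoods keyed by ``species:focal_gene``."""
    df = pd.read_csv(path, sep="\t", dtype={"offset": int})
    required = {"species", "focal_gene", "offset", "symbol", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"neighborhood TSV missing columns: {sorted(missing)}")
    out: dict[str, GeneNeighborhood] = {}
    for (sp, gene), grp in df.groupby(["species", "focal_gene"], sort=False):
        flanks = [
            (int(r.offset), str(r.symbol), str(r.strand))
            for r in grp.itertuples()
        ]
        out[f"{sp}:{gene}"] = GeneNeighborhood(
            species=sp, focal_gene=gene, flanks=flanks
        )
    return out


def write_neighborhood_tsv(
    neighborhoods: dict[str, GeneNeighborhood], path: str | Path
) -> None:
    rows = []
    for nb in neighborhoods.values():
        for off, sym, strand in sorted(nb.flanks):
            rows.append(
                {
                    "species": nb.species,
                    "focal_gene": nb.focal_gene,
                    "offset": off,
                    "symbol": sym,
                    "strand": strand,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
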