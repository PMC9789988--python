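"""Rooted phylogenies with branch lengths and foreground-branch flags.

Branch models need to single out "foreground" branches whose dN/dS is
allowed to differ from the rest of the tree. We follow the codeml label
dialect: a ``#1`` suffix on a leaf or internal-node label marks that
branch (and only that branch) as foreground; the extension ``#1*`` marks
the branch and every branch of the subtree below it.

Newick parsing itself is delegated to dendropy; the ``#1`` tags (not
standard Newick) are lifted out before parsing and re-applied after.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

_FG_SENTINEL = "@@FG@@"
_FG_CLADE_SENTINEL = "@@FGC@@"
_TAG_RE = re.compile(r"\s*#1(\*?)")


@dataclass
class Phylogeny:
    """Array-backed rooted tree.

    Node 0 is the root; ``parent[i]`` is -1 for the root. ``labels[i]``
    is the taxon name for leaves and an (optional) internal label
    otherwise. ``lengths[i]`` is the length of the branch above node
    ``i`` (0 for the root). ``foreground[i]`` flags that branch.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list[str]
    foreground: np.ndarray
    children: list[list[int]] = field(init=False)
    postorder: list[int] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if (self.lengths < 0).any():
            raise ValueError("negative branch length")
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = order[::-1]  # children before parents

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def branch_nodes(self) -> list[int]:
        """Nodes carrying a branch above them (all but the root)."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def with_foreground(self, node_labels: set[str]) -> "Phylogeny":
        """Copy with foreground set on branches above the named nodes."""
        fg = np.array([lab in node_labels for lab in self.labels])
        fg[0] = False
        return Phylogeny(
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            labels=list(self.labels),
            foreground=fg,
        )

    def scaled(self, factor: float) -> "Phylogeny":
        return Phylogeny(
            parent=self.parent.copy(),
            lengths=self.lengths * factor,
            labels=list(self.labels),
            foreground=self.foreground.copy(),
        )


def _extract_tags(text: str) -> str:
    def repl(m: re.Match) -> str:
        return _FG_CLADE_SENTINEL if m.group(1) else _FG_SENTINEL

    return _TAG_RE.sub(repl, text)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (with optional ``#1``/``#1*`` tags)."""
    clean = _extract_tags(text)
    try:
        tree = dendropy.Tree.get(
            data=clean,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc

    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    labels: list[str] = []
    fg = np.zeros(len(nodes), dtype=bool)
    clade_tagged: list[int] = []
    for i, nd in enumerate(nodes):
        raw = nd.taxon.label if nd.taxon else (nd.label or "")
        tag = _FG_CLADE_SENTINEL in raw or _FG_SENTINEL in raw
        clade = _FG_CLADE_SENTINEL in raw
        label = raw.replace(_FG_CLADE_SENTINEL, "").replace(_FG_SENTINEL, "")
        labels.append(label)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is not None:
                if nd.edge.length < 0:
                    raise ValueError(
                        f"negative branch length on {label or 'internal node'}"
                    )
                lengths[i] = nd.edge.length
            fg[i] = tag
        if clade:
            clade_tagged.append(i)
    phy = Phylogeny(parent=parent, lengths=lengths, labels=labels, foreground=fg)
    for i in clade_tagged:  # propagate clade tags to all descendants
        stack = list(phy.children[i])
        while stack:
            v = stack.pop()
            phy.foreground[v] = True
            stack.extend(phy.children[v])
    if clade_tagged:
        return Phylogeny(
            parent=phy.parent, lengths=phy.lengths,
            labels=phy.labels, foreground=phy.foreground,
        )
    return phy


def _write_node(phy: Phylogeny, i: int) -> str:
    lab = phy.labels[i]
    tag = "#1" if phy.foreground[i] else ""
    if phy.children[i]:
        inner = ",".join(_write_node(phy, c) for c in phy.children[i])
        body = f"({inner}){lab}{tag}"
    else:
        body = f"{lab}{tag}"
    if phy.parent[i] >= 0:
        body += f":{phy.lengths[i]:g}"
    return body


def write_newick(phy: Phylogeny) -> str:
    """Render to Newick, re-emitting ``#1`` branch tags."""
    return _write_node(phy, 0) + ";"


def check_taxa_match(phy: Phylogeny, taxa: list[str]) -> None:
    tree_set = set(phy.leaf_labels)
    aln_set = set(taxa)
    if tree_set != aln_set:
        missing = sorted(aln_set - tree_set)
        extra = sorted(tree_set - aln_set)
        raise ValueError(
            f"tree/alignment taxa mismatch (alignment-only: {missing}, "
            f"tree-only: {extra})"
        )
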