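"""Seeded generators emulating the statistical structure of the analysis.

Three generators cover the three data domains the pipeline consumes:

* codon alignments evolving on a tree under a GY94 model with constant,
  site-class, branch (foreground), or episodic branch-site omega;
* post-WGD gene neighborhoods with per-branch flank turnover and strand
  inversion, with true copy identities recorded;
* negative-binomial expression counts with paralog-by-tissue means and
  background genes filling out the normalization universe.

Every generator takes a mandatory seed and returns a machine-readable
truth record alongside the data. Default sizes are desk scale: 16 taxa
and 300-500 codons, windows of 10+10 flanking genes, and a PhyloFish-like
tissue panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .codon_model import SpectralQ, _rate_matrix, site_rate_matrix
from .genetics import STANDARD_CODE, GeneticCode
from .phylo import Phylogeny

# ---------------------------------------------------------------------------
# trees


def random_tree(
    n_taxa: int = 16,
    seed: int = 0,
    branch_length_range: tuple[float, float] = (0.02, 0.15),
) -> Phylogeny:
    """Random bifurcating rooted tree by successive pair joining.

    Branch lengths (expected substitutions per codon) are uniform over
    ``branch_length_range``; the default total tree length (~2.5 for 16
    taxa) matches a moderately diverged gene family.
    """
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    # build children lists bottom-up, then flatten to preorder arrays
    nodes: list[dict] = [{"label": lab, "children": []} for lab in labels]
    active = list(range(n_taxa))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        nodes.append({"label": "", "children": [a, b]})
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append(len(nodes) - 1)
    root = active[0]
    parent_map: dict[int, int] = {}
    order: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for c in nodes[v]["children"]:
            parent_map[c] = v
            stack.append(c)
    new_index = {old: new for new, old in enumerate(order)}
    parent = np.full(len(order), -1, dtype=np.int64)
    lengths = np.zeros(len(order))
    labels_out = []
    lo, hi = branch_length_range
    for old in order:
        new = new_index[old]
        labels_out.append(nodes[old]["label"])
        if old in parent_map:
            parent[new] = new_index[parent_map[old]]
            lengths[new] = rng.uniform(lo, hi)
    return Phylogeny(
        parent=parent, lengths=lengths, labels=labels_out,
        foreground=np.zeros(len(order), dtype=bool),
    )


# ---------------------------------------------------------------------------
# codon alignments


@dataclass
class SimulationScenario:
    """Codon-evolution scenario.

    ``omega_regime`` is one of::

        {"type": "constant", "omega": w}
        {"type": "site_classes", "classes": [(omega, weight), ...]}
        {"type": "branch", "omega_background": w0, "omega_foreground": w1}
        {"type": "episodic", "omega_background": w0, "omega_plus": w1,
         "branch_fraction": f, "site_fraction": g}

    In the episodic regime a fraction ``site_fraction`` of sites is
    affected; at each affected site an independent ``branch_fraction``
    of branches evolves at ``omega_plus`` (the MEME data-generating
    picture). The branch regime uses the tree's foreground flags.
    """

    tree: Phylogeny
    n_codons: int = 300
    kappa: float = 2.0
    omega_regime: dict[str, Any] = field(
        default_factory=lambda: {"type": "constant", "omega": 0.2}
    )
    pi: np.ndarray | str = "equal"
    seed: int = 0


def _resolve_pi(spec, code: GeneticCode) -> np.ndarray:
    n = len(code.sense_codons)
    if isinstance(spec, str):
        if spec != "equal":
            raise ValueError("pi spec must be 'equal' or an explicit vector")
        return np.full(n, 1.0 / n)
    pi = np.asarray(spec, dtype=float)
    return pi / pi.sum()


def _sample_children(
    P: np.ndarray, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(parents))
    return (u[:, None] > cum[parents]).sum(axis=1)


def simulate_codon_alignment(
    scenario: SimulationScenario, code: GeneticCode = STANDARD_CODE
) -> tuple[CodonAlignment, dict]:
    """Evolve codon sequences down the tree; returns (alignment, truth)."""
    rng = np.random.default_rng(scenario.seed)
    phy = scenario.tree
    pi = _resolve_pi(scenario.pi, code)
    n_sites = scenario.n_codons
    regime = scenario.omega_regime
    kind = regime["type"]

    # per-(site, branch) omega values, encoded via site classes per branch
    if kind == "constant":
        omegas = [regime["omega"]]
        site_class = np.zeros(n_sites, dtype=int)  # same class on all branches
        branch_dependent = False
    elif kind == "site_classes":
        ws = [w for w, _ in regime["classes"]]
        probs = np.array([p for _, p in regime["classes"]])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("site-class weights must sum to 1")
        omegas = ws
        site_class = rng.choice(len(ws), size=n_sites, p=probs)
        branch_dependent = False
    elif kind == "branch":
        omegas = [regime["omega_background"], regime["omega_foreground"]]
        site_class = np.zeros(n_sites, dtype=int)
        branch_dependent = True
    elif kind == "episodic":
        omegas = [regime["omega_background"], regime["omega_plus"]]
        site_fraction = regime.get("site_fraction", 1.0)
        branch_fraction = regime["branch_fraction"]
        affected_sites = rng.random(n_sites) < site_fraction
        branch_dependent = True
    else:
        raise ValueError(f"unknown omega regime {kind!r}")

    # Single-model regimes use the codeml convention (each matrix scaled
    # to mean rate 1, branch lengths = expected substitutions under that
    # model). Mixture regimes must share one time scale, so their class
    # matrices are normalized by the neutral mean rate instead.
    if kind in ("constant", "branch"):
        specs = [SpectralQ(_rate_matrix(scenario.kappa, w, pi, code), pi)
                 for w in omegas]
    else:
        specs = [
            SpectralQ(site_rate_matrix(scenario.kappa, 1.0, w, pi, code), pi)
            for w in omegas
        ]

    # root states
    states = np.empty((phy.n_nodes, n_sites), dtype=np.int64)
    cum_pi = np.cumsum(pi)
    states[0] = np.searchsorted(cum_pi, rng.random(n_sites), side="right")

    episodic_truth = np.zeros((n_sites, phy.n_nodes), dtype=bool)
    for v in phy.postorder[::-1]:  # preorder: parents before children
        if phy.parent[v] < 0:
            continue
        t = phy.lengths[v]
        parents = states[phy.parent[v]]
        if kind == "episodic":
            on = affected_sites & (rng.random(n_sites) < branch_fraction)
            episodic_truth[:, v] = on
            cls = on.astype(int)
        elif kind == "branch":
            cls = np.full(n_sites, int(phy.foreground[v]))
        else:
            cls = site_class
        child = np.empty(n_sites, dtype=np.int64)
        for k in set(cls.tolist()):
            mask = cls == k
            P = specs[k].probs(t)
            child[mask] = _sample_children(P, parents[mask], rng)
        states[v] = child

    sense = code.sense_codons
    taxa, rows = [], []
    for node in phy.leaves:
        taxa.append(phy.labels[node])
        rows.append([sense[s] for s in states[node]])
    aln = CodonAlignment(taxa=taxa, codons=rows, code=code)
    truth: dict[str, Any] = {
        "kappa": scenario.kappa,
        "omega_regime": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                         for k, v in regime.items()},
        "seed": scenario.seed,
        "n_codons": n_sites,
    }
    if kind == "site_classes":
        truth["site_class"] = site_class.tolist()
        truth["class_omegas"] = omegas
    if kind == "episodic":
        truth["affected_sites"] = np.flatnonzero(affected_sites).tolist()
        truth["episodic_branch_sets"] = episodic_truth
    return aln, truth


# ---------------------------------------------------------------------------
# gene neighborhoods


@dataclass
class NeighborhoodScenario:
    """Post-WGD neighborhood history.

    Each descendant branch independently replaces each flank slot with a
    novel gene with probability ``loss_prob`` (gene loss plus locus
    turnover), flips strand with ``inversion_prob``, and blanks the
    identification to "unknown" with ``unknown_prob``.
    """

    window: int = 10
    loss_prob: float = 0.2
    inversion_prob: float = 0.05
    unknown_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.loss_prob, self.inversion_prob, self.unknown_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def _ancestral_window(window: int) -> list[tuple[int, str, str]]:
    flanks = []
    for off in range(-window, window + 1):
        if off == 0:
            continue
        side = "U" if off < 0 else "D"
        flanks.append((off, f"ANC{side}{abs(off):02d}", "+"))
    return flanks


def _mutate_window(flanks, scenario, rng, novel_counter):
    out = []
    for off, sym, strand in flanks:
        if rng.random() < scenario.loss_prob:
            sym = f"NOV{next(novel_counter):04d}"
        if rng.random() < scenario.unknown_prob:
            sym = "unknown"
        if rng.random() < scenario.inversion_prob:
            strand = "-" if strand == "+" else "+"
        out.append((off, sym, strand))
    return out


def simulate_neighborhoods(
    scenario: NeighborhoodScenario,
    loss_prob_copy2: float | None = None,
) -> tuple[dict[str, list[tuple[int, str, str]]], dict]:
    """Simulate ancestor, two WGD copies, and a sister-group ortholog.

    ``loss_prob_copy2`` lets the second copy erode faster (asymmetric
    ohnolog resolution); default is the shared ``loss_prob``. Returns a
    dict of neighborhoods keyed by role and a truth record naming which
    copy is the slowly-eroding one.
    """
    rng = np.random.default_rng(scenario.seed)
    counter = iter(range(10**6))
    anc = _ancestral_window(scenario.window)
    p2 = scenario.loss_prob if loss_prob_copy2 is None else loss_prob_copy2
    sc2 = NeighborhoodScenario(
        window=scenario.window, loss_prob=p2,
        inversion_prob=scenario.inversion_prob,
        unknown_prob=scenario.unknown_prob, seed=scenario.seed,
    )
    sister = _mutate_window(anc, scenario, rng, counter)
    copy1 = _mutate_window(anc, scenario, rng, counter)
    copy2 = _mutate_window(anc, sc2, rng, counter)
    truth = {
        "seed": scenario.seed,
        "loss_prob_copy1": scenario.loss_prob,
        "loss_prob_copy2": p2,
        "slow_copy": "copy1" if scenario.loss_prob <= p2 else "copy2",
    }
    return (
        {"ancestor": anc, "sister": sister, "copy1": copy1, "copy2": copy2},
        truth,
    )


# ---------------------------------------------------------------------------
# expression counts

PHYLOFISH_TISSUES = [
    "brain", "liver", "gill", "heart", "muscle", "kidney",
    "bone", "intestine", "ovary", "testis", "embryo",
]

# Mean TPM-scale expression emulating the qualitative pattern of the
# survey: HIF1A broad with a heart maximum, HIF2A gill-restricted,
# HIF3A broad/low with an embryo maximum, HIF4A low and sparse.
DEFAULT_PARALOG_MEANS = pd.DataFrame(
    {
        "brain":     [60.0, 5.0, 18.0, 1.0],
        "liver":     [45.0, 4.0, 12.0, 0.0],
        "gill":      [55.0, 80.0, 10.0, 2.0],
        "heart":     [90.0, 8.0, 14.0, 3.0],
        "muscle":    [40.0, 3.0, 8.0, 0.0],
        "kidney":    [50.0, 10.0, 12.0, 2.0],
        "bone":      [35.0, 4.0, 9.0, 1.0],
        "intestine": [42.0, 5.0, 11.0, 0.0],
        "ovary":     [30.0, 2.0, 10.0, 0.0],
        "testis":    [28.0, 2.0, 9.0, 0.0],
        "embryo":    [38.0, 3.0, 30.0, 1.0],
    },
    index=["HIF1A", "HIF2A", "HIF3A", "HIF4A"],
)


@dataclass
class ExpressionScenario:
    species: list[str] = field(
        default_factory=lambda: [f"sp{i + 1}" for i in range(6)]
    )
    paralog_tissue_means: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_PARALOG_MEANS.copy()
    )
    dispersion: float = 5.0  # NB size parameter; np.inf = Poisson
    n_background_genes: int = 200
    background_mean_log2: tuple[float, float] = (5.0, 2.0)
    length_kb_log_mean_sd: tuple[float, float] = (0.6, 0.5)
    library_scale: float = 2e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if (self.paralog_tissue_means.values < 0).any():
            raise ValueError("means must be >= 0")


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = dispersion / (dispersion + mean[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_expression(
    scenario: ExpressionScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate counts, lengths, and the paralog map for several species.

    Returns ``(counts, lengths, paralog_map, truth)``: counts is tidy
    (species, gene, tissue, count); lengths maps (species, gene) to kb;
    paralog_map maps focal genes to paralog labels. Background genes
    fill out the per-tissue normalization universe.
    """
    rng = np.random.default_rng(scenario.seed)
    means = scenario.paralog_tissue_means
    tissues = list(means.columns)
    rows, len_rows, map_rows = [], [], []
    for sp in scenario.species:
        genes = [f"{sp}_{par}" for par in means.index]
        bg = [f"{sp}_bg{i + 1}" for i in range(scenario.n_background_genes)]
        mu_bg = 2.0 ** rng.normal(*scenario.background_mean_log2,
                                  size=scenario.n_background_genes)
        lens = np.exp(rng.normal(*scenario.length_kb_log_mean_sd,
                                 size=len(genes) + len(bg)))
        for g, L in zip(genes + bg, lens):
            len_rows.append({"species": sp, "gene": g, "length_kb": float(L)})
        for par, g in zip(means.index, genes):
            map_rows.append({"species": sp, "gene": g, "paralog": par})
        for tis in tissues:
            depth = scenario.library_scale * rng.uniform(0.5, 2.0)
            mu_focal = means[tis].values * lens[: len(genes)]
            mu_all = np.concatenate([mu_focal, mu_bg * lens[len(genes):]])
            mu_all = mu_all * depth / max(mu_all.sum(), 1.0)
            counts = _nb_draw(rng, mu_all, scenario.dispersion)
            for g, c in zip(genes + bg, counts):
                rows.append(
                    {"species": sp, "gene": g, "tissue": tis, "count": int(c)}
                )
    counts = pd.DataFrame(rows)
    lengths = pd.DataFrame(len_rows)
    paralog_map = pd.DataFrame(map_rows)
    truth = {
        "seed": scenario.seed,
        "tissues": tissues,
        "paralogs": list(means.index),
        "means": means.to_dict(),
    }
    return counts, lengths, paralog_map, truth
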