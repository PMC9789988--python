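"""Calibration, power and recovery experiments on synthetic data.

These are the package's standard self-checks: simulate data under a
known regime with the generators in :mod:`hifevol.simulate`, run the
inference machinery, and summarize how well truth is recovered. Sizes
default to desk scale (16 taxa, 300-500 codons, a few hundred
replicates), chosen so the full battery runs on one CPU in minutes.

Two tree-depth regimes are used deliberately: branch-model calibration
and estimator recovery run on moderately diverged trees (branch lengths
U(0.02, 0.15)); single-site tests need deeply diverged trees to carry
information, so site-level experiments use U(0.05, 0.35) — comparable
to a gene family spanning a whole vertebrate class plus an outgroup.
"""

from __future__ import annotations

import numpy as np

from .codon_model import fit_m0, fit_two_ratio, likelihood_ratio_test
from .phylo import Phylogeny
from .simulate import (
    SimulationScenario,
    random_tree,
    simulate_codon_alignment,
)
from .site_tests import fel_site_test, meme_site_test

SHALLOW = (0.02, 0.15)
DEEP = (0.05, 0.35)


def _flag_clade(tree: Phylogeny, min_leaves: int = 3) -> Phylogeny:
    """Flag the first internal clade with >= min_leaves leaves as foreground."""
    for v in range(1, tree.n_nodes):
        if not tree.children[v]:
            continue
        stack, leaves = [v], 0
        nodes = []
        while stack:
            u = stack.pop()
            nodes.append(u)
            if not tree.children[u]:
                leaves += 1
            stack.extend(tree.children[u])
        if leaves >= min_leaves and leaves <= len(tree.leaves) - 2:
            for u in nodes:
                tree.foreground[u] = True
            return tree
    tree.foreground[1] = True
    return tree


def branch_lrt_calibration(
    n_replicates: int = 200,
    n_taxa: int = 16,
    n_codons: int = 300,
    omega: float = 0.2,
    kappa: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Null rejection rate of the two-ratio vs Model 0 LRT.

    Data are simulated with one constant omega; a clade is flagged
    foreground and both models are fit. Under a correct test the
    rejection rate at level alpha is close to alpha.
    """
    rng = np.random.default_rng(seed)
    p_values = []
    for _ in range(n_replicates):
        tree_seed, sim_seed = rng.integers(0, 2**31 - 1, size=2)
        tree = _flag_clade(
            random_tree(n_taxa, seed=int(tree_seed),
                        branch_length_range=SHALLOW)
        )
        aln, _ = simulate_codon_alignment(
            SimulationScenario(
                tree=tree, n_codons=n_codons, kappa=kappa,
                omega_regime={"type": "constant", "omega": omega},
                seed=int(sim_seed),
            )
        )
        m0 = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
        two = fit_two_ratio(aln, tree, freq_model="equal", seed=0, n_starts=1)
        lrt = likelihood_ratio_test(m0, two, df=1)
        p_values.append(lrt.p_value)
    p = np.array(p_values)
    return {
        "rejection_rate": float((p <= alpha).mean()),
        "n_replicates": n_replicates,
        "p_values": p,
    }


def m0_recovery(
    n_replicates: int = 20,
    n_taxa: int = 16,
    n_codons: int = 500,
    omega: float = 0.3,
    kappa: float = 2.0,
    seed: int = 0,
) -> dict:
    """Median absolute error of the Model 0 omega estimate."""
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_replicates):
        tree_seed, sim_seed = rng.integers(0, 2**31 - 1, size=2)
        tree = random_tree(n_taxa, seed=int(tree_seed),
                           branch_length_range=SHALLOW)
        aln, _ = simulate_codon_alignment(
            SimulationScenario(
                tree=tree, n_codons=n_codons, kappa=kappa,
                omega_regime={"type": "constant", "omega": omega},
                seed=int(sim_seed),
            )
        )
        fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
        estimates.append(fit.params.omega_map["all"])
    est = np.array(estimates)
    return {
        "omega_true": omega,
        "estimates": est,
        "median_abs_error": float(np.median(np.abs(est - omega))),
    }


def site_test_calibration(
    n_sites: int = 300,
    n_taxa: int = 16,
    kappa: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """FEL and MEME type-I error on neutral (omega = 1) sites."""
    tree = random_tree(n_taxa, seed=seed, branch_length_range=DEEP)
    aln, _ = simulate_codon_alignment(
        SimulationScenario(
            tree=tree, n_codons=n_sites, kappa=kappa,
            omega_regime={"type": "constant", "omega": 1.0}, seed=seed + 1,
        )
    )
    fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
    fel_p, meme_p = [], []
    for s in range(1, n_sites + 1):
        fel_p.append(fel_site_test(aln, tree, s, fit).p_value)
        meme_p.append(meme_site_test(aln, tree, s, fit).p_value)
    fel_p, meme_p = np.array(fel_p), np.array(meme_p)
    return {
        "fel_type1": float((fel_p <= alpha).mean()),
        "meme_type1": float((meme_p <= alpha).mean()),
        "fel_p": fel_p,
        "meme_p": meme_p,
        "n_sites": n_sites,
    }


def episodic_power(
    n_sites: int = 50,
    n_taxa: int = 16,
    omega_background: float = 0.2,
    omega_plus: float = 6.0,
    branch_fraction: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Paired FEL vs MEME detection under episodic selection.

    Every site evolves at ``omega_plus`` on an independent random
    ``branch_fraction`` of branches and ``omega_background`` elsewhere —
    the regime MEME models and FEL does not.
    """
    tree = random_tree(n_taxa, seed=seed, branch_length_range=DEEP)
    aln, _ = simulate_codon_alignment(
        SimulationScenario(
            tree=tree, n_codons=n_sites,
            omega_regime={
                "type": "episodic",
                "omega_background": omega_background,
                "omega_plus": omega_plus,
                "branch_fraction": branch_fraction,
                "site_fraction": 1.0,
            },
            seed=seed + 1,
        )
    )
    fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
    fel_hits = meme_hits = 0
    for s in range(1, n_sites + 1):
        if fel_site_test(aln, tree, s, fit, alpha).classification == "positive":
            fel_hits += 1
        if meme_site_test(aln, tree, s, fit, alpha).classification == "positive":
            meme_hits += 1
    return {
        "fel_power": fel_hits / n_sites,
        "meme_power": meme_hits / n_sites,
        "fel_hits": fel_hits,
        "meme_hits": meme_hits,
        "n_sites": n_sites,
    }


def pervasive_power(
    n_test_sites: int = 40,
    n_taxa: int = 32,
    omega_positive: float = 5.0,
    omega_background: float = 0.2,
    background_fraction: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """FEL detection rate on sites under pervasive positive selection.

    Positive sites (beta/alpha = omega_positive) are embedded in a
    purifying background so the gene-wide fit reflects typical usage.
    """
    n_codons = int(np.ceil(n_test_sites / (1 - background_fraction)))
    tree = random_tree(n_taxa, seed=seed, branch_length_range=DEEP)
    aln, truth = simulate_codon_alignment(
        SimulationScenario(
            tree=tree, n_codons=n_codons,
            omega_regime={
                "type": "site_classes",
                "classes": [
                    (omega_background, background_fraction),
                    (omega_positive, 1 - background_fraction),
                ],
            },
            seed=seed + 1,
        )
    )
    fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
    hot = (np.flatnonzero(np.array(truth["site_class"]) == 1) + 1)[
        :n_test_sites
    ]
    hits = sum(
        fel_site_test(aln, tree, int(s), fit, alpha).classification
        == "positive"
        for s in hot
    )
    return {"fel_power": hits / len(hot), "n_sites": int(len(hot))}
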