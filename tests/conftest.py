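from pathlib import Path

import numpy as np
import pytest

from hifevol.alignment import CodonAlignment
from hifevol.codon_model import fit_m0
from hifevol.genetics import STANDARD_CODE
from hifevol.phylo import read_newick
from hifevol.simulate import (
    SimulationScenario,
    random_tree,
    simulate_codon_alignment,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def tiny_tree():
    """4-taxon rooted tree used by the enumeration oracles."""
    return read_newick("((A:0.12,B:0.23):0.1,(C:0.3,D:0.18):0.07);")


@pytest.fixture(scope="session")
def tiny_alignment():
    """4 taxa x 3 codons, including one gap codon."""
    return CodonAlignment(
        taxa=["A", "B", "C", "D"],
        codons=[
            ["ATG", "TTT", "GGA"],
            ["ATA", "TTC", "GGA"],
            ["ACG", "CTT", "---"],
            ["ATG", "TTT", "GGC"],
        ],
        code=STANDARD_CODE,
    )


@pytest.fixture(scope="session")
def sim16():
    """16-taxon constant-omega alignment and its generating tree."""
    tree = random_tree(16, seed=11)
    sc = SimulationScenario(
        tree=tree, n_codons=300, kappa=2.0,
        omega_regime={"type": "constant", "omega": 0.2}, seed=12,
    )
    aln, truth = simulate_codon_alignment(sc)
    return aln, tree, truth


@pytest.fixture(scope="session")
def sim16_fit(sim16):
    aln, tree, _ = sim16
    return fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)


def enumeration_loglik(aln, phy, params):
    """Exhaustive-state likelihood oracle for small trees.

    Sums the joint probability over every assignment of sense codons to
    the internal nodes; gap codons marginalize over all states.
    """
    from itertools import product

    from hifevol.codon_model import SpectralQ, _rate_matrix
    from hifevol.alignment import MISSING

    pi = params.pi
    spec = SpectralQ(
        _rate_matrix(params.kappa, params.omega_map["all"], pi, aln.code), pi
    )
    P = {i: spec.probs(phy.lengths[i]) for i in range(1, phy.n_nodes)}
    internal = [i for i in range(phy.n_nodes) if phy.children[i]]
    leaves = {i: aln.codes[aln.taxa.index(phy.labels[i])] for i in phy.leaves}
    n_states = len(pi)
    total = 0.0
    for site in range(aln.length_codons):
        site_like = 0.0
        for assign in product(range(n_states), repeat=len(internal)):
            state = dict(zip(internal, assign))
            p = pi[state[0]]
            for v in range(1, phy.n_nodes):
                parent_state = state[phy.parent[v]]
                if v in leaves:
                    obs = leaves[v][site]
                    if obs == MISSING:
                        continue  # marginalized: sum over states = 1
                    p *= P[v][parent_state, obs]
                else:
                    p *= P[v][parent_state, state[v]]
            site_like += p
        total += np.log(site_like)
    return total
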