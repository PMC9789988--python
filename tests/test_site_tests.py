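"""SLAC counting, FEL/MEME site tests, and the gene-wide episodic test."""

from itertools import permutations, product

import numpy as np
import pytest

from hifevol.alignment import MISSING, CodonAlignment
from hifevol.codon_model import SpectralQ, TreeData, fit_m0, site_rate_matrix
from hifevol.genetics import STANDARD_CODE
from hifevol.phylo import read_newick
from hifevol.simulate import (
    SimulationScenario,
    random_tree,
    simulate_codon_alignment,
)
from hifevol.site_tests import (
    GeneSiteSummary,
    SiteEngine,
    busted_gene_test,
    fel_site_test,
    marginal_ancestral_states,
    meme_loglik,
    meme_site_test,
    shortest_path_syn_fraction,
    slac_site_counts,
    summarize_selected_sites,
)


def _fit(aln, tree):
    return fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)


class TestSlac:
    def test_synonymous_pair_counts_one_syn(self):
        phy = read_newick("(A:0.1,B:0.1);")
        aln = CodonAlignment(
            taxa=["A", "B"], codons=[["ATT", "AAA"], ["ATC", "AAA"]],
            code=STANDARD_CODE,
        )
        counts = slac_site_counts(aln, phy, _fit(aln, phy))
        assert counts[0].observed_syn == pytest.approx(1.0)
        assert counts[0].observed_nonsyn == pytest.approx(0.0)

    def test_invariant_column_counts_nothing(self):
        phy = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment(
            taxa=["A", "B", "C"], codons=[["ATG"], ["ATG"], ["ATG"]],
            code=STANDARD_CODE,
        )
        c = slac_site_counts(aln, phy, _fit(aln, phy))[0]
        assert c.observed_syn == 0 and c.observed_nonsyn == 0
        assert c.p_positive == 1.0 and c.p_negative == 1.0

    def test_path_averaging_avoids_stops(self):
        # TTA <-> TCG: via TCA (S: T->S nonsyn, then syn) or via TTG
        # (syn then nonsyn); neither passes a stop codon
        syn, nonsyn = shortest_path_syn_fraction("TTA", "TCG", STANDARD_CODE)
        assert syn + nonsyn == pytest.approx(2.0)
        assert 0 < syn < 2

    def test_counts_match_exhaustive_oracle(self, tiny_tree, tiny_alignment):
        fit = _fit(tiny_alignment, tiny_tree)
        ours = slac_site_counts(tiny_alignment, tiny_tree, fit)
        oracle = _slac_oracle(tiny_alignment, tiny_tree, fit)
        for a, b in zip(ours, oracle):
            assert a.observed_syn == pytest.approx(b[0], abs=1e-9)
            assert a.observed_nonsyn == pytest.approx(b[1], abs=1e-9)


def _slac_oracle(aln, phy, fit):
    """Brute-force reconstruction + path counting for <=4-taxon trees.

    Marginal posteriors computed by exhaustive enumeration over internal
    states; substitutions classified by enumerating all shortest
    stop-free mutational paths, independently of the package's counting
    helpers.
    """
    params = fit.params
    spec = SpectralQ(
        site_rate_matrix(
            params.kappa, 1.0, next(iter(params.omega_map.values())),
            params.pi, aln.code,
        ),
        params.pi,
    )
    tree = fit.tree
    P = {i: spec.probs(tree.lengths[i]) for i in range(1, tree.n_nodes)}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    leaves = {i: aln.codes[aln.taxa.index(tree.labels[i])]
              for i in tree.leaves}
    sense = aln.code.sense_codons

    def classify(c1, c2):
        diffs = [k for k in range(3) if c1[k] != c2[k]]
        if not diffs:
            return 0.0, 0.0
        path_counts = []
        for order in permutations(diffs):
            cur, syn, ok = c1, 0.0, True
            for k in order:
                nxt = cur[:k] + c2[k] + cur[k + 1:]
                if aln.code.is_stop(nxt):
                    ok = False
                    break
                if aln.code.translate(cur) == aln.code.translate(nxt):
                    syn += 1
                cur = nxt
            if ok:
                path_counts.append(syn)
        s = float(np.mean(path_counts))
        return s, len(diffs) - s

    out = []
    for site in range(aln.length_codons):
        post = {v: np.zeros(61) for v in internal}
        for assign in product(range(61), repeat=len(internal)):
            state = dict(zip(internal, assign))
            p = params.pi[state[0]]
            for v in range(1, tree.n_nodes):
                sp = state[tree.parent[v]]
                if v in leaves:
                    obs = leaves[v][site]
                    if obs != MISSING:
                        p *= P[v][sp, obs]
                else:
                    p *= P[v][sp, state[v]]
            for v in internal:
                post[v][state[v]] += p
        anc = {v: int(np.argmax(post[v])) for v in internal}
        syn = nonsyn = 0.0
        for v in range(1, tree.n_nodes):
            sp = anc[tree.parent[v]]
            sc = leaves[v][site] if v in leaves else anc[v]
            if sc == MISSING:
                continue
            s, ns = classify(sense[sp], sense[sc])
            syn += s
            nonsyn += ns
        out.append((syn, nonsyn))
    return out


class TestMarginalReconstruction:
    def test_identical_leaves_reconstruct_observed_state(self):
        phy = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = CodonAlignment(
            taxa=list("ABCD"), codons=[["ATG"]] * 4, code=STANDARD_CODE
        )
        fit = _fit(aln, phy)
        td = TreeData(aln, fit.tree)
        spec = SpectralQ(
            site_rate_matrix(fit.params.kappa, 1.0, 0.5, fit.params.pi,
                             aln.code),
            fit.params.pi,
        )
        P = np.empty((phy.n_nodes, 61, 61))
        P[1:] = spec.probs_many(fit.tree.lengths[1:])
        states = marginal_ancestral_states(td, P, fit.params.pi)
        atg = STANDARD_CODE.index["ATG"]
        assert (states == atg).all()


@pytest.fixture(scope="module")
def deep_sim():
    """Deep 12-taxon neutral alignment for site-test behaviour checks."""
    tree = random_tree(12, seed=31, branch_length_range=(0.05, 0.35))
    sc = SimulationScenario(
        tree=tree, n_codons=40, kappa=2.0,
        omega_regime={"type": "constant", "omega": 1.0}, seed=32,
    )
    aln, _ = simulate_codon_alignment(sc)
    fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
    return aln, tree, fit


class TestFel:
    def test_invariant_site_untestable(self):
        phy = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment(
            taxa=["A", "B", "C"],
            codons=[["ATG", "TTT"], ["ATG", "TTC"], ["ATG", "CTT"]],
            code=STANDARD_CODE,
        )
        r = fel_site_test(aln, phy, 1, _fit(aln, phy))
        assert r.classification == "untestable"
        assert r.p_value == 1.0 and r.lrt_statistic == 0.0

    def test_null_rejection_rate_moderate(self, deep_sim):
        aln, tree, fit = deep_sim
        rejections = sum(
            fel_site_test(aln, tree, s, fit).p_value <= 0.05
            for s in range(1, 41)
        )
        assert rejections <= 6  # ~1.6x nominal on 40 neutral sites

    def test_alpha_beta_nonnegative_and_p_valid(self, deep_sim):
        aln, tree, fit = deep_sim
        r = fel_site_test(aln, tree, 1, fit)
        assert r.alpha >= 0 and r.beta >= 0
        assert 0 <= r.p_value <= 1


class TestMeme:
    def test_invariant_site_untestable(self):
        phy = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment(
            taxa=["A", "B", "C"],
            codons=[["ATG", "TTT"], ["ATG", "TTC"], ["ATG", "CTT"]],
            code=STANDARD_CODE,
        )
        r = meme_site_test(aln, phy, 1, _fit(aln, phy))
        assert r.classification == "untestable"

    def test_full_weight_plus_class_equals_fel_alternative(self, deep_sim):
        aln, tree, fit = deep_sim
        fel = fel_site_test(aln, tree, 3, fit)
        engine = SiteEngine(aln, fit)
        l_meme = meme_loglik(
            engine, 3, fel.alpha, fel.alpha, fel.beta, 1.0
        )
        l_fel = engine.site_loglik(
            3, [(1.0, engine.spectral(fel.alpha, fel.beta))]
        )
        assert l_meme == pytest.approx(l_fel, abs=1e-6)

    def test_null_rejection_rate_moderate(self, deep_sim):
        aln, tree, fit = deep_sim
        rejections = sum(
            meme_site_test(aln, tree, s, fit).p_value <= 0.05
            for s in range(1, 41)
        )
        assert rejections <= 6

    def test_mixture_df_spec_changes_p(self, deep_sim):
        aln, tree, fit = deep_sim
        conservative = meme_site_test(aln, tree, 2, fit, df=2)
        mixture = meme_site_test(
            aln, tree, 2, fit, df=[(0.33, 0.0), (0.3, 1.0), (0.37, 2.0)]
        )
        if conservative.lrt_statistic > 0:
            assert mixture.p_value <= conservative.p_value


class TestBusted:
    def test_degenerate_alignment_untestable(self):
        phy = read_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment(
            taxa=["A", "B", "C"],
            codons=[["ATG", "ATG"], ["ATG", "ATG"], ["ATG", "ATG"]],
            code=STANDARD_CODE,
        )
        res = busted_gene_test(aln, phy, _fit(aln, phy))
        assert res.untestable

    def test_detects_strong_selection_class(self):
        tree = random_tree(12, seed=41, branch_length_range=(0.05, 0.35))
        sc = SimulationScenario(
            tree=tree, n_codons=300, kappa=2.0,
            omega_regime={
                "type": "site_classes",
                "classes": [(0.1, 0.7), (1.0, 0.2), (5.0, 0.1)],
            },
            seed=42,
        )
        aln, _ = simulate_codon_alignment(sc)
        fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
        res = busted_gene_test(aln, tree, fit)
        assert res.p_value <= 0.05
        assert res.omega_classes[2] > 1

    def test_null_data_not_rejected_and_conserved_site_er_near_one(self):
        tree = random_tree(12, seed=43, branch_length_range=(0.05, 0.35))
        sc = SimulationScenario(
            tree=tree, n_codons=200, kappa=2.0,
            omega_regime={
                "type": "site_classes",
                "classes": [(0.05, 0.5), (0.5, 0.5)],
            },
            seed=44,
        )
        aln, _ = simulate_codon_alignment(sc)
        # append a fully conserved column
        for row in aln.codons:
            row.append("ATG")
        aln2 = CodonAlignment(taxa=aln.taxa, codons=aln.codons,
                              code=aln.code)
        fit = fit_m0(aln2, tree, freq_model="equal", seed=0, n_starts=1)
        res = busted_gene_test(aln2, tree, fit)
        assert res.p_value > 0.05
        er_conserved = res.evidence_ratios[-1]
        assert 0.5 <= er_conserved <= 2.0

    def test_omega_classes_ordered_and_weights_simplex(self, deep_sim):
        aln, tree, fit = deep_sim
        res = busted_gene_test(aln, tree, fit)
        w1, w2, w3 = res.omega_classes
        assert w1 <= w2 <= 1.0 <= w3
        assert sum(res.weights) == pytest.approx(1.0, abs=1e-9)


class TestSummaries:
    def _res(self, site, test, p, call):
        from hifevol.site_tests import SiteTestResult

        return SiteTestResult(
            site=site, test=test, alpha=0.1, p_value=p, classification=call
        )

    def test_intersection_flagged(self):
        res = {
            "g": {
                "meme": [self._res(3, "MEME", 0.01, "positive"),
                         self._res(7, "MEME", 0.02, "positive")],
                "fel": [self._res(7, "FEL", 0.01, "positive")],
            }
        }
        out = summarize_selected_sites(res)["g"]
        assert out.meme_sites == [3, 7]
        assert out.fel_sites == [7]
        assert out.both == [7]

    def test_empty_results_give_empty_report(self):
        out = summarize_selected_sites({"g": {"meme": [], "fel": []}})["g"]
        assert out.meme_sites == [] and out.both == []

    def test_er_threshold_filters_meme_sites(self):
        from hifevol.site_tests import GeneWideResult

        er = np.array([1.5, 2.1, 9.0])
        busted = GeneWideResult(
            omega_classes=[0.1, 0.5, 3.0], weights=[0.5, 0.4, 0.1],
            lnL_unconstrained=-10, lnL_constrained=-12,
            lrt_statistic=4.0, p_value=0.04, evidence_ratios=er,
        )
        res = {
            "g": {
                "meme": [self._res(s, "MEME", 0.01, "positive")
                         for s in (1, 2, 3)],
                "fel": [],
                "busted": busted,
            }
        }
        out = summarize_selected_sites(res, er_threshold=2.0)["g"]
        assert out.meme_with_er_support == [2, 3]
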