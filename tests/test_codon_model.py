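"""GY94 rate matrix, transition probabilities, pruning, and branch fits."""

import numpy as np
import pytest

from hifevol.alignment import CodonAlignment
from hifevol.codon_model import (
    CodonModelParams,
    NestingError,
    build_rate_matrix,
    codon_frequencies,
    fit_m0,
    fit_two_ratio,
    likelihood_ratio_test,
    log_likelihood,
    transition_probs,
)
from hifevol.genetics import STANDARD_CODE, codon_diffs
from hifevol.phylo import read_newick
from hifevol.simulate import (
    SimulationScenario,
    random_tree,
    simulate_codon_alignment,
)

from conftest import enumeration_loglik

N = 61
EQUAL_PI = np.full(N, 1.0 / N)


def params(kappa=2.0, omega=0.3, pi=None):
    return CodonModelParams(
        kappa=kappa, omega_map={"all": omega},
        pi=EQUAL_PI if pi is None else pi, freq_model="equal",
    )


class TestRateMatrix:
    def test_rows_sum_to_zero_and_mean_rate_one(self):
        Q = build_rate_matrix(params())
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        assert abs(-(EQUAL_PI * np.diag(Q)).sum() - 1.0) < 1e-10

    def test_multistep_changes_forbidden(self):
        Q = build_rate_matrix(params())
        i = STANDARD_CODE.index["ATG"]
        j = STANDARD_CODE.index["CCC"]
        assert Q[i, j] == 0.0

    def test_neutral_equal_model_has_uniform_single_step_rates(self):
        Q = build_rate_matrix(params(kappa=1.0, omega=1.0))
        off = []
        for i, ci in enumerate(STANDARD_CODE.sense_codons):
            for j, cj in enumerate(STANDARD_CODE.sense_codons):
                if i != j and len(codon_diffs(ci, cj)) == 1:
                    off.append(Q[i, j])
        assert np.ptp(off) < 1e-12

    def test_detailed_balance(self):
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.ones(N))
        Q = build_rate_matrix(params(pi=pi))
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        Q = build_rate_matrix(params())
        P = transition_probs(Q, 0.0, EQUAL_PI)
        assert np.abs(P - np.eye(N)).max() < 1e-10

    def test_long_time_reaches_stationarity(self):
        Q = build_rate_matrix(params(omega=0.5))
        P = transition_probs(Q, 50.0, EQUAL_PI)
        assert np.abs(P - EQUAL_PI[None, :]).max() < 1e-6

    def test_long_time_stationarity_nonuniform_pi(self):
        rng = np.random.default_rng(7)
        pi = rng.dirichlet(np.ones(N) * 5)
        Q = build_rate_matrix(params(pi=pi))
        P = transition_probs(Q, 150.0, pi)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_semigroup_property(self):
        Q = build_rate_matrix(params())
        P1 = transition_probs(Q, 0.37, EQUAL_PI)
        P2 = transition_probs(Q, 0.74, EQUAL_PI)
        assert np.abs(P1 @ P1 - P2).max() < 1e-8

    def test_rows_are_distributions(self):
        Q = build_rate_matrix(params())
        P = transition_probs(Q, 1.3, EQUAL_PI)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(params())
        with pytest.raises(ValueError):
            transition_probs(Q, -0.1, EQUAL_PI)


class TestPruning:
    def test_single_leaf_is_log_pi(self):
        phy = read_newick("A;")
        aln = CodonAlignment(
            taxa=["A"], codons=[["ATG", "TTT", "GGA"]], code=STANDARD_CODE
        )
        pi = codon_frequencies(aln, "equal")
        lnl = log_likelihood(aln, phy, params(pi=pi))
        expected = sum(
            np.log(pi[STANDARD_CODE.index[c]]) for c in ["ATG", "TTT", "GGA"]
        )
        assert abs(lnl - expected) < 1e-10

    def test_identical_pair_at_zero_distance(self):
        phy = read_newick("(A:0,B:0);")
        aln = CodonAlignment(
            taxa=["A", "B"], codons=[["ATG", "TTT"]] * 2, code=STANDARD_CODE
        )
        lnl = log_likelihood(aln, phy, params())
        assert abs(lnl - 2 * np.log(1 / 61)) < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, tiny_tree, seed):
        rng = np.random.default_rng(seed)
        sense = STANDARD_CODE.sense_codons
        codons = [
            [sense[k] for k in rng.integers(0, 61, size=2)] for _ in range(4)
        ]
        aln = CodonAlignment(
            taxa=["A", "B", "C", "D"], codons=codons, code=STANDARD_CODE
        )
        p = params(kappa=2.5, omega=0.5)
        assert abs(
            log_likelihood(aln, tiny_tree, p)
            - enumeration_loglik(aln, tiny_tree, p)
        ) < 1e-8

    def test_oracle_with_gap_codon(self, tiny_tree, tiny_alignment):
        p = params(kappa=1.8, omega=0.4)
        assert abs(
            log_likelihood(tiny_alignment, tiny_tree, p)
            - enumeration_loglik(tiny_alignment, tiny_tree, p)
        ) < 1e-8

    def test_taxon_mismatch_raises(self, tiny_tree):
        aln = CodonAlignment(
            taxa=["A", "B", "C", "X"], codons=[["ATG"]] * 4, code=STANDARD_CODE
        )
        with pytest.raises(ValueError, match="mismatch"):
            log_likelihood(aln, tiny_tree, params())


class TestFits:
    def test_m0_recovers_omega_and_kappa(self, sim16):
        aln, tree, truth = sim16
        fit = fit_m0(aln, tree, freq_model="equal", seed=0, n_starts=1)
        assert abs(fit.params.omega_map["all"] - 0.2) < 0.05
        assert abs(fit.params.kappa - truth["kappa"]) < 0.4

    def test_fit_beats_generating_parameters(self, sim16, sim16_fit):
        aln, tree, truth = sim16
        pi = codon_frequencies(aln, "equal")
        at_truth = log_likelihood(
            aln, tree, params(kappa=truth["kappa"], omega=0.2, pi=pi)
        )
        assert sim16_fit.lnL >= at_truth - 1e-6

    def test_same_seed_is_bit_identical(self, sim16):
        aln, tree, _ = sim16
        f1 = fit_m0(aln, tree, seed=7, n_starts=2)
        f2 = fit_m0(aln, tree, seed=7, n_starts=2)
        assert f1.params.omega_map["all"] == f2.params.omega_map["all"]
        assert f1.lnL == f2.lnL

    def test_joint_branch_lengths_improve_on_scale_mode(self, tiny_tree):
        sc = SimulationScenario(
            tree=tiny_tree, n_codons=80, kappa=2.0,
            omega_regime={"type": "constant", "omega": 0.3}, seed=3,
        )
        aln, _ = simulate_codon_alignment(sc)
        scale = fit_m0(aln, tiny_tree, seed=0, n_starts=1,
                       optimize_branch_lengths="scale")
        joint = fit_m0(aln, tiny_tree, seed=0, n_starts=1,
                       optimize_branch_lengths="joint")
        assert joint.lnL >= scale.lnL - 1e-6

    def test_two_ratio_recovers_foreground_omega(self):
        tree = random_tree(16, seed=5)
        internal = [i for i in range(1, tree.n_nodes) if tree.children[i]]
        stack = [internal[0]]
        while stack:
            v = stack.pop()
            tree.foreground[v] = True
            stack.extend(tree.children[v])
        sc = SimulationScenario(
            tree=tree, n_codons=500, kappa=2.0,
            omega_regime={
                "type": "branch",
                "omega_background": 0.1,
                "omega_foreground": 1.5,
            },
            seed=8,
        )
        aln, _ = simulate_codon_alignment(sc)
        fit = fit_two_ratio(aln, tree, freq_model="equal", seed=0, n_starts=1)
        w0 = fit.params.omega_map["background"]
        w1 = fit.params.omega_map["foreground"]
        assert w1 > w0
        assert abs(w0 - 0.1) < 0.05

    def test_two_ratio_nests_m0(self, sim16):
        aln, tree, _ = sim16
        tree2 = tree.with_foreground({tree.leaf_labels[0]})
        m0 = fit_m0(aln, tree2, freq_model="equal", seed=0, n_starts=1)
        two = fit_two_ratio(aln, tree2, freq_model="equal", seed=0, n_starts=1)
        assert two.lnL >= m0.lnL - 1e-6

    def test_all_foreground_is_configuration_error(self, sim16):
        aln, tree, _ = sim16
        bad = tree.with_foreground(set(tree.labels))
        with pytest.raises(ValueError, match="background"):
            fit_two_ratio(aln, bad)

    def test_no_foreground_is_configuration_error(self, sim16):
        aln, tree, _ = sim16
        with pytest.raises(ValueError, match="foreground"):
            fit_two_ratio(aln, tree)

    def test_zero_length_foreground_flagged_unidentifiable(self):
        phy = read_newick("((A#1:0,B:0.2):0.1,(C:0.3,D:0.2):0.1);")
        sc = SimulationScenario(
            tree=phy, n_codons=60, kappa=2.0,
            omega_regime={"type": "constant", "omega": 0.3}, seed=4,
        )
        aln, _ = simulate_codon_alignment(sc)
        fit = fit_two_ratio(aln, phy, seed=0, n_starts=1,
                            optimize_branch_lengths="fixed")
        assert any("unidentifiable" in w for w in fit.warnings)


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        res = likelihood_ratio_test(-100.0, -100.0, 1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_quantile(self):
        res = likelihood_ratio_test(-100.0, -100.0 + 3.841 / 2, 1)
        assert res.p_value == pytest.approx(0.05, abs=2e-4)

    def test_mixture_null_distribution(self):
        res = likelihood_ratio_test(-50.0, -48.0, [(0.5, 0.0), (0.5, 1.0)])
        from scipy.stats import chi2 as chi2_dist

        assert res.p_value == pytest.approx(0.5 * chi2_dist.sf(4.0, 1))

    def test_worse_alternative_raises_nesting_error(self):
        with pytest.raises(NestingError):
            likelihood_ratio_test(-100.0, -101.0, 1)


class TestFrequencies:
    @pytest.mark.parametrize("model", ["equal", "F1x4", "F3x4"])
    def test_valid_distribution(self, sim16, model):
        aln, _, _ = sim16
        pi = codon_frequencies(aln, model)
        assert pi.shape == (61,)
        assert abs(pi.sum() - 1) < 1e-12
        assert pi.min() > 0
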