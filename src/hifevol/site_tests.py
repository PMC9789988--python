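"""Site-level and gene-wide selection tests.

Four tests share one machinery: branch lengths, kappa and codon
frequencies are frozen at a gene-wide Model 0 fit, and per-site (or
gene-wide) synonymous/nonsynonymous rate multipliers are then estimated
by maximum likelihood.

* SLAC — counting: marginal ML ancestral reconstruction, per-branch
  substitutions split into synonymous/nonsynonymous (multi-step codon
  changes averaged over all shortest stop-free mutational paths),
  binomial tail tests against the site's neutral synonymous fraction.
* FEL — pervasive: per-site alpha (syn) and beta (nonsyn); the null
  forces alpha = beta; LRT with 1 df.
* MEME — episodic: per-site mixture over branches with a constrained
  class (beta- <= alpha) and an unconstrained class (beta+, weight w+);
  the null forces beta+ = alpha; p-value from a chi-square mixture
  (conservative chi2(2) by default).
* BUSTED-style gene-wide test: three omega classes shared across
  branch-sites, the alternative allowing omega3 > 1; per-site evidence
  ratios compare the unconstrained and constrained fits. Synonymous
  rate variation is not modelled.

Site rate matrices are normalized so that alpha = beta = 1 is the
neutral (omega = 1) matrix with mean rate one; alpha and beta are
therefore rates relative to the gene-wide branch-length scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import binom, chi2

from .alignment import MISSING, CodonAlignment
from .codon_model import (
    FitResult,
    SpectralQ,
    TreeData,
    pattern_log_likelihoods,
    site_rate_matrix as _site_matrix,
)
from .genetics import GeneticCode
from .phylo import Phylogeny

DfSpec = float | list[tuple[float, float]]
# MEME null distribution: the boundary constraint (beta+ = alpha, with the
# mixture weight unidentified under the null) makes the LRT asymptotics
# non-standard. Default is the method's published chi-square mixture over
# df 0/1/2; chi2(2) is the conservative alternative (df=2).
MEME_DEFAULT_DF: DfSpec = [(0.33, 0.0), (0.30, 1.0), (0.37, 2.0)]


@dataclass
class SiteTestResult:
    site: int
    test: str  # "FEL" or "MEME"
    alpha: float
    beta: float | None = None  # FEL
    beta_minus: float | None = None  # MEME
    beta_plus: float | None = None
    weight_plus: float | None = None
    lrt_statistic: float = 0.0
    p_value: float = 1.0
    classification: str = "neutral"


@dataclass
class SlacSiteCounts:
    site: int
    observed_syn: float
    observed_nonsyn: float
    expected_syn_fraction: float
    p_positive: float
    p_negative: float
    untestable: bool = False


@dataclass
class GeneWideResult:
    omega_classes: list[float]
    weights: list[float]
    lnL_unconstrained: float
    lnL_constrained: float
    lrt_statistic: float
    p_value: float
    evidence_ratios: np.ndarray | None = None
    untestable: bool = False


# ---------------------------------------------------------------------------
# fast single-site likelihood via spectral message passing


class SiteEngine:
    """Per-site pruning working in the eigenbasis of each rate matrix.

    Messages along a branch are computed as A (exp(lam t) * (B' p))
    without ever forming the 61x61 transition matrix, which makes
    per-site optimization cheap.
    """

    def __init__(self, aln: CodonAlignment, fit: FitResult):
        self.aln = aln
        self.phy = fit.tree
        self.kappa = fit.params.kappa
        self.pi = fit.params.pi
        self.code = aln.code
        row_of = {t: k for k, t in enumerate(aln.taxa)}
        self.leaf_state = {
            node: aln.codes[row_of[self.phy.labels[node]]]
            for node in self.phy.leaves
        }
        self.lengths = self.phy.lengths
        # neutral spectral (alpha = beta = 1), reused by null models
        self.neutral = SpectralQ(
            _site_matrix(self.kappa, 1.0, 1.0, self.pi, self.code), self.pi
        )

    def spectral(self, alpha: float, beta: float) -> SpectralQ:
        if abs(alpha - beta) < 1e-12:
            # Q(a, a) = a * Q(1, 1): reuse the neutral eigendecomposition
            spec = SpectralQ.__new__(SpectralQ)
            spec.lam = self.neutral.lam * alpha
            spec.A = self.neutral.A
            spec.B = self.neutral.B
            return spec
        return SpectralQ(
            _site_matrix(self.kappa, alpha, beta, self.pi, self.code), self.pi
        )

    def site_loglik(
        self, site: int, classes: list[tuple[float, SpectralQ]]
    ) -> float:
        """Log-likelihood of one 1-based site; ``classes`` is a per-branch
        mixture [(weight, spectral)] applied independently on every branch."""
        phy = self.phy
        n = len(self.pi)
        # exp(lam * t) tables per class
        Es = [np.exp(np.outer(self.lengths, spec.lam)) for _, spec in classes]
        partials: dict[int, np.ndarray] = {}
        logscale = 0.0
        for v in phy.postorder:
            if not phy.children[v]:
                continue
            acc = np.ones(n)
            for c in phy.children[v]:
                if c in self.leaf_state:
                    s = self.leaf_state[c][site - 1]
                    if s == MISSING:
                        continue  # all-ones message
                    M = np.zeros(n)
                    for (w, spec), E in zip(classes, Es):
                        M += w * (spec.A @ (E[c] * spec.B[s]))
                else:
                    p = partials.pop(c)
                    M = np.zeros(n)
                    for (w, spec), E in zip(classes, Es):
                        M += w * (spec.A @ (E[c] * (spec.B.T @ p)))
                np.clip(M, 1e-300, None, out=M)
                acc *= M
            mx = acc.max()
            acc /= mx
            logscale += np.log(mx)
            partials[v] = acc
        root = partials[phy.postorder[-1]]
        return float(np.log(max(root @ self.pi, 1e-300)) + logscale)

    def site_is_variable(self, site: int) -> bool:
        obs = {
            int(s[site - 1])
            for s in self.leaf_state.values()
            if s[site - 1] != MISSING
        }
        return len(obs) > 1


_LOG_RATE_BOUNDS = (np.log(1e-4), np.log(100.0))


def _fit_null_rate(engine: SiteEngine, site: int) -> tuple[float, float]:
    """Null alpha = beta = r; returns (r_hat, lnL)."""

    def neg(logr):
        return -engine.site_loglik(
            site, [(1.0, engine.spectral(np.exp(logr), np.exp(logr)))]
        )

    res = minimize_scalar(
        neg, bounds=_LOG_RATE_BOUNDS, method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x)), -float(res.fun)


def fel_site_test(
    aln: CodonAlignment,
    tree: Phylogeny | None,
    site: int,
    global_fit: FitResult,
    p_threshold: float = 0.05,
) -> SiteTestResult:
    """FEL: per-site alpha/beta ML with the null alpha = beta (df 1)."""
    engine = global_fit.__dict__.setdefault(
        "_site_engine", SiteEngine(aln, global_fit)
    )
    if not engine.site_is_variable(site):
        return SiteTestResult(
            site=site, test="FEL", alpha=0.0, beta=0.0,
            classification="untestable",
        )
    r0, lnl0 = _fit_null_rate(engine, site)

    def neg(x):
        return -engine.site_loglik(
            site, [(1.0, engine.spectral(np.exp(x[0]), np.exp(x[1])))]
        )

    x0 = np.log([max(r0, 1e-3), max(r0, 1e-3)])
    res = minimize(
        neg, x0, method="L-BFGS-B", bounds=[_LOG_RATE_BOUNDS] * 2,
        options={"ftol": 1e-10},
    )
    lnl1 = max(-float(res.fun), lnl0)
    alpha, beta = np.exp(res.x)
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    p = float(chi2.sf(stat, 1))
    if p <= p_threshold and beta > alpha:
        call = "positive"
    elif p <= p_threshold and beta < alpha:
        call = "negative"
    else:
        call = "neutral"
    return SiteTestResult(
        site=site, test="FEL", alpha=float(alpha), beta=float(beta),
        lrt_statistic=stat, p_value=p, classification=call,
    )


def _mixture_p(stat: float, df: DfSpec) -> float:
    if isinstance(df, (int, float)):
        return float(chi2.sf(stat, df)) if df > 0 else float(stat <= 0)
    p = 0.0
    for w, d in df:
        p += w * (float(chi2.sf(stat, d)) if d > 0 else float(stat <= 0))
    return p


def meme_loglik(
    engine: SiteEngine,
    site: int,
    alpha: float,
    beta_minus: float,
    beta_plus: float,
    weight_plus: float,
) -> float:
    """MEME site likelihood: per-branch mixture of two (alpha, beta) classes."""
    classes = []
    if weight_plus < 1.0:
        classes.append((1.0 - weight_plus, engine.spectral(alpha, beta_minus)))
    if weight_plus > 0.0:
        classes.append((weight_plus, engine.spectral(alpha, beta_plus)))
    return engine.site_loglik(site, classes)


def meme_site_test(
    aln: CodonAlignment,
    tree: Phylogeny | None,
    site: int,
    global_fit: FitResult,
    p_threshold: float = 0.05,
    df: DfSpec = MEME_DEFAULT_DF,
) -> SiteTestResult:
    """MEME-style episodic test: null constrains beta+ = alpha."""
    engine = global_fit.__dict__.setdefault(
        "_site_engine", SiteEngine(aln, global_fit)
    )
    if not engine.site_is_variable(site):
        return SiteTestResult(
            site=site, test="MEME", alpha=0.0, beta_minus=0.0,
            beta_plus=0.0, weight_plus=0.0, classification="untestable",
        )
    r0, _ = _fit_null_rate(engine, site)
    la0 = np.log(max(r0, 1e-3))

    def unpack(x):
        alpha = np.exp(x[0])
        bminus = alpha * x[1]  # x[1] in [0, 1]
        return alpha, bminus

    def neg_null(x):  # x = [log alpha, b_frac, w+]; beta+ = alpha
        alpha, bminus = unpack(x)
        return -meme_loglik(engine, site, alpha, bminus, alpha, x[2])

    bounds_null = [_LOG_RATE_BOUNDS, (0.0, 1.0), (0.0, 1.0)]
    res0 = minimize(
        neg_null, np.array([la0, 1.0, 0.5]), method="L-BFGS-B",
        bounds=bounds_null, options={"ftol": 1e-10},
    )
    lnl0 = -float(res0.fun)

    def neg_alt(x):  # x = [log alpha, b_frac, log beta+, w+]
        alpha, bminus = unpack(x)
        return -meme_loglik(engine, site, alpha, bminus, np.exp(x[2]), x[3])

    bounds_alt = [_LOG_RATE_BOUNDS, (0.0, 1.0), _LOG_RATE_BOUNDS, (0.0, 1.0)]
    best = None
    for bplus0 in (la0, np.log(5.0)):
        x0 = np.array([res0.x[0], res0.x[1], bplus0, max(res0.x[2], 0.1)])
        res = minimize(
            neg_alt, x0, method="L-BFGS-B", bounds=bounds_alt,
            options={"ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    lnl1 = max(-float(best.fun), lnl0)
    alpha, bminus = unpack(best.x)
    bplus, wplus = float(np.exp(best.x[2])), float(best.x[3])
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    p = _mixture_p(stat, df)
    call = (
        "positive"
        if p <= p_threshold and bplus > alpha and wplus > 0
        else "neutral"
    )
    return SiteTestResult(
        site=site, test="MEME", alpha=float(alpha), beta_minus=float(bminus),
        beta_plus=bplus, weight_plus=wplus, lrt_statistic=stat, p_value=p,
        classification=call,
    )


# ---------------------------------------------------------------------------
# BUSTED-style gene-wide test


def _busted_mixture_P(
    td: TreeData,
    specs: list[SpectralQ],
    weights: np.ndarray,
    lengths: np.ndarray,
) -> np.ndarray:
    n = td.phy.n_nodes
    P = np.zeros((n, td.n_states, td.n_states))
    for w, spec in zip(weights, specs):
        if w > 0:
            P[1:] += w * spec.probs_many(lengths[1:])
    return P


def busted_gene_test(
    aln: CodonAlignment,
    tree: Phylogeny | None,
    global_fit: FitResult,
    df: DfSpec = 2,
    seed: int = 0,
) -> GeneWideResult:
    """Gene-wide episodic test with a 3-class omega distribution.

    Unconstrained: omega1 <= omega2 <= 1 <= omega3, weights on the
    simplex, classes drawn independently per branch-site. The null pins
    omega3 = 1. Per-site evidence ratios are the ratios of site
    likelihoods at the two optima.
    """
    phy = global_fit.tree
    td = TreeData(aln, phy)
    if td.patterns.shape[1] <= 2:
        return GeneWideResult(
            omega_classes=[], weights=[], lnL_unconstrained=np.nan,
            lnL_constrained=np.nan, lrt_statistic=0.0, p_value=1.0,
            untestable=True,
        )
    kappa, pi, code = global_fit.params.kappa, global_fit.params.pi, aln.code
    lengths = phy.lengths

    def omegas_from(x, constrained):
        w2 = x[0]  # omega2 in [0, 1]
        w1 = x[1] * w2  # omega1 = frac * omega2
        w3 = 1.0 if constrained else 1.0 + x[2]
        return np.array([w1, w2, w3])

    def weights_from(x, constrained):
        v1, v2 = (x[2], x[3]) if constrained else (x[3], x[4])
        return np.array([v1, (1 - v1) * v2, (1 - v1) * (1 - v2)])

    def neg(x, constrained):
        om = omegas_from(x, constrained)
        wt = weights_from(x, constrained)
        specs = [
            SpectralQ(_site_matrix(kappa, 1.0, w, pi, code), pi) for w in om
        ]
        P = _busted_mixture_P(td, specs, wt, lengths)
        return -float(pattern_log_likelihoods(td, P, pi) @ td.weights)

    w_hat = next(iter(global_fit.params.omega_map.values()))
    w_hat = min(max(w_hat, 1e-3), 0.95)
    x0_null = np.array([w_hat, 0.5, 0.4, 0.5])
    bounds_null = [(1e-4, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)]
    res0 = minimize(
        neg, x0_null, args=(True,), method="L-BFGS-B", bounds=bounds_null,
        options={"ftol": 1e-9},
    )
    x0_alt = np.array([res0.x[0], res0.x[1], 2.0, res0.x[2], res0.x[3]])
    bounds_alt = [(1e-4, 1.0), (0.0, 1.0), (0.0, 500.0),
                  (0.0, 1.0), (0.0, 1.0)]
    res1 = minimize(
        neg, x0_alt, args=(False,), method="L-BFGS-B", bounds=bounds_alt,
        options={"ftol": 1e-9},
    )
    lnl0, lnl1 = -float(res0.fun), max(-float(res1.fun), -float(res0.fun))
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    p = _mixture_p(stat, df)

    # per-site evidence ratios at the two optima
    def site_lnls(x, constrained):
        om = omegas_from(x, constrained)
        wt = weights_from(x, constrained)
        specs = [
            SpectralQ(_site_matrix(kappa, 1.0, w, pi, code), pi) for w in om
        ]
        P = _busted_mixture_P(td, specs, wt, lengths)
        return pattern_log_likelihoods(td, P, pi)[td.site_to_pattern]

    er = np.exp(site_lnls(res1.x, False) - site_lnls(res0.x, True))
    om = omegas_from(res1.x, False)
    wt = weights_from(res1.x, False)
    return GeneWideResult(
        omega_classes=[float(w) for w in om],
        weights=[float(w) for w in wt],
        lnL_unconstrained=lnl1, lnL_constrained=lnl0,
        lrt_statistic=stat, p_value=p, evidence_ratios=er,
    )


# ---------------------------------------------------------------------------
# SLAC


def marginal_ancestral_states(td: TreeData, P: np.ndarray, pi: np.ndarray):
    """Marginal ML ancestral codon states per (internal node, pattern)."""
    phy = td.phy
    npat = td.patterns.shape[1]
    n = td.n_states

    def upmsg_of(c, up):
        if c in td.leaf_index:
            states = td.patterns[td.leaf_index[c]]
            M = np.ones((npat, n))
            obs = states != MISSING
            M[obs] = P[c][:, states[obs]].T
            return M
        return up[c] @ P[c].T

    up: dict[int, np.ndarray] = {}
    for v in phy.postorder:
        if not phy.children[v]:
            continue
        acc = np.ones((npat, n))
        for c in phy.children[v]:
            acc *= upmsg_of(c, up)
        mx = acc.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        up[v] = acc / mx

    states = np.full((phy.n_nodes, npat), -1, dtype=np.int64)
    ctx: dict[int, np.ndarray] = {phy.postorder[-1]: np.tile(pi, (npat, 1))}
    for v in phy.postorder[::-1]:  # preorder
        if not phy.children[v]:
            continue
        marg = ctx[v] * up[v]
        states[v] = np.argmax(marg, axis=1)
        msgs = {c: upmsg_of(c, up) for c in phy.children[v]}
        for c in phy.children[v]:
            if c in td.leaf_index:
                continue
            other = ctx[v].copy()
            for c2 in phy.children[v]:
                if c2 != c:
                    other *= msgs[c2]
            ctx[c] = other @ P[c]
            mx = ctx[c].max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            ctx[c] /= mx
    for node in phy.leaves:
        states[node] = td.patterns[td.leaf_index[node]]
    return states


def shortest_path_syn_fraction(
    c1: str, c2: str, code: GeneticCode
) -> tuple[float, float] | None:
    """(syn, nonsyn) step counts averaged over shortest stop-free paths."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return (0.0, 0.0)
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            steps.append(code.translate(cur) != code.translate(nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return None  # no stop-free shortest path
    syn = float(np.mean([sum(1 for s in p if not s) for p in paths]))
    nonsyn = float(np.mean([sum(1 for s in p if s) for p in paths]))
    return syn, nonsyn


def _neutral_syn_fraction(
    codon: str, code: GeneticCode, kappa: float
) -> tuple[float, float]:
    """Kappa-weighted (syn, total) one-step mutation weights of a codon."""
    from .genetics import NUCLEOTIDES, is_transition

    syn_w = tot_w = 0.0
    for k in range(3):
        for b in NUCLEOTIDES:
            if b == codon[k]:
                continue
            nxt = codon[:k] + b + codon[k + 1 :]
            if code.is_stop(nxt):
                continue
            w = kappa if is_transition(codon[k], b) else 1.0
            tot_w += w
            if code.translate(nxt) == code.translate(codon):
                syn_w += w
    return syn_w, tot_w


def slac_site_counts(
    aln: CodonAlignment,
    tree: Phylogeny | None,
    global_fit: FitResult,
) -> list[SlacSiteCounts]:
    """SLAC counts for every site, with binomial tail probabilities."""
    phy = global_fit.tree
    td = TreeData(aln, phy)
    params = global_fit.params
    spec = SpectralQ(
        _site_matrix(params.kappa, 1.0,
                     next(iter(params.omega_map.values())),
                     params.pi, aln.code),
        params.pi,
    )
    n = phy.n_nodes
    P = np.empty((n, td.n_states, td.n_states))
    P[1:] = spec.probs_many(phy.lengths[1:])
    states = marginal_ancestral_states(td, P, params.pi)
    sense = aln.code.sense_codons
    results = []
    for site in range(1, td.n_sites + 1):
        pat = td.site_to_pattern[site - 1]
        col = states[:, pat]
        syn = nonsyn = 0.0
        parent_codons = []
        all_missing = True
        for v in range(1, n):
            s_child = col[v]
            s_parent = col[phy.parent[v]]
            if s_child == MISSING or s_parent == MISSING:
                continue
            all_missing = False
            parent_codons.append(sense[s_parent])
            contrib = shortest_path_syn_fraction(
                sense[s_parent], sense[s_child], aln.code
            )
            if contrib is None:
                continue
            syn += contrib[0]
            nonsyn += contrib[1]
        if all_missing:
            results.append(
                SlacSiteCounts(
                    site=site, observed_syn=0.0, observed_nonsyn=0.0,
                    expected_syn_fraction=0.5, p_positive=1.0, p_negative=1.0,
                    untestable=True,
                )
            )
            continue
        fracs = [_neutral_syn_fraction(c, aln.code, params.kappa)
                 for c in set(parent_codons)]
        syn_w = sum(f[0] for f in fracs)
        tot_w = sum(f[1] for f in fracs)
        p_syn = min(max(syn_w / tot_w if tot_w else 0.5, 1e-9), 1 - 1e-9)
        total = syn + nonsyn
        if total <= 0:
            p_pos = p_neg = 1.0
        else:
            ntot = int(round(total))
            k_syn = min(int(np.floor(syn + 1e-9)), ntot)
            # positive: fewer synonymous than the neutral expectation
            p_pos = float(binom.cdf(k_syn, ntot, p_syn))
            p_neg = float(binom.sf(k_syn - 1, ntot, p_syn))
        results.append(
            SlacSiteCounts(
                site=site, observed_syn=syn, observed_nonsyn=nonsyn,
                expected_syn_fraction=p_syn, p_positive=p_pos, p_negative=p_neg,
            )
        )
    return results


# ---------------------------------------------------------------------------
# summaries


@dataclass
class GeneSiteSummary:
    gene: str
    meme_sites: list[int]
    fel_sites: list[int]
    both: list[int] = field(init=False)
    meme_with_er_support: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.both = sorted(set(self.meme_sites) & set(self.fel_sites))


def summarize_selected_sites(
    results: dict[str, dict],
    p_threshold: float = 0.05,
    er_threshold: float = 2.0,
) -> dict[str, GeneSiteSummary]:
    """Per-gene site lists: episodic (MEME), pervasive (FEL), their
    intersection, and the MEME subset with gene-wide ER support.

    ``results[gene]`` holds keys "meme" and "fel" (lists of
    SiteTestResult) and optionally "busted" (GeneWideResult).
    """
    out = {}
    for gene, res in results.items():
        meme = sorted(
            r.site for r in res.get("meme", [])
            if r.classification == "positive" and r.p_value <= p_threshold
        )
        fel = sorted(
            r.site for r in res.get("fel", [])
            if r.classification == "positive" and r.p_value <= p_threshold
        )
        summary = GeneSiteSummary(gene=gene, meme_sites=meme, fel_sites=fel)
        busted = res.get("busted")
        if busted is not None and busted.evidence_ratios is not None:
            er = busted.evidence_ratios
            summary.meme_with_er_support = [
                s for s in meme if er[s - 1] > er_threshold
            ]
        out[gene] = summary
    return out
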