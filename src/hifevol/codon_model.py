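"""GY94-style codon substitution model and branch-model fits.

The model is the Goldman-Yang codon model: instantaneous rate from
codon *i* to codon *j* is zero when the codons differ at more than one
nucleotide and otherwise proportional to

    pi_j * kappa^[transition] * omega^[nonsynonymous],

with the matrix scaled so the mean rate at stationarity is one
substitution per codon per unit branch length. Branch models attach a
single omega to every branch (Model 0) or distinct omegas to foreground
and background branches (the two-ratio model); nested fits are compared
by likelihood-ratio tests.

Transition probabilities use the symmetric eigendecomposition available
for any reversible rate matrix, which is stable at large times where a
truncated series would not be.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import MISSING, CodonAlignment
from .genetics import STANDARD_CODE, GeneticCode, codon_diffs, is_transition
from .phylo import Phylogeny, check_taxa_match

_PI_FLOOR = 1e-8


class NestingError(ValueError):
    """Alternative model fit worse than the null: optimizer failure."""


# ---------------------------------------------------------------------------
# model structure


class CodonRateStructure:
    """Static single-step structure of the 61-state codon space."""

    def __init__(self, code: GeneticCode):
        self.code = code
        n = len(code.sense_codons)
        rows, cols, ts, ns = [], [], [], []
        for i, ci in enumerate(code.sense_codons):
            for j, cj in enumerate(code.sense_codons):
                if i == j:
                    continue
                d = codon_diffs(ci, cj)
                if len(d) != 1:
                    continue
                k = d[0]
                rows.append(i)
                cols.append(j)
                ts.append(is_transition(ci[k], cj[k]))
                ns.append(code.translate(ci) != code.translate(cj))
        self.n = n
        self.rows = np.array(rows)
        self.cols = np.array(cols)
        self.is_ts = np.array(ts)
        self.is_ns = np.array(ns)


_STRUCTURES: dict[int, CodonRateStructure] = {}


def get_structure(code: GeneticCode = STANDARD_CODE) -> CodonRateStructure:
    key = id(code)
    if key not in _STRUCTURES:
        _STRUCTURES[key] = CodonRateStructure(code)
    return _STRUCTURES[key]


@dataclass
class CodonModelParams:
    """Parameters of a GY94 branch model."""

    kappa: float
    omega_map: dict[str, float]  # e.g. {"all": w} or {"background": w0, "foreground": w1}
    pi: np.ndarray
    freq_model: str = "F3x4"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa < 0 or not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite and >= 0")
        for name, w in self.omega_map.items():
            if w < 0 or not np.isfinite(w):
                raise ValueError(f"omega[{name}] must be finite and >= 0")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector over 61 codons")


@dataclass
class FitResult:
    params: CodonModelParams
    lnL: float
    tree: Phylogeny  # with fitted branch lengths
    n_iterations: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


@dataclass
class LRTResult:
    statistic: float
    df: float | list[tuple[float, float]]
    p_value: float


# ---------------------------------------------------------------------------
# frequencies


def codon_frequencies(
    aln: CodonAlignment, freq_model: str = "F3x4"
) -> np.ndarray:
    """Empirical sense-codon frequencies: equal, F1x4 or F3x4."""
    code = aln.code
    n = len(code.sense_codons)
    if freq_model == "equal":
        return np.full(n, 1.0 / n)
    counts = np.zeros((3, 4))
    idx = {b: k for k, b in enumerate("ACGT")}
    for row in aln.codons:
        for codon in row:
            if any(ch not in "ACGT" for ch in codon):
                continue
            for pos, ch in enumerate(codon):
                counts[pos, idx[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous codons")
    if freq_model == "F1x4":
        nuc = counts.sum(axis=0)
        nuc = nuc / nuc.sum()
        counts = np.tile(nuc, (3, 1))
    elif freq_model == "F3x4":
        counts = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown freq_model {freq_model!r}")
    pi = np.array(
        [
            counts[0, idx[c[0]]] * counts[1, idx[c[1]]] * counts[2, idx[c[2]]]
            for c in code.sense_codons
        ]
    )
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities


def build_rate_matrix(
    params: CodonModelParams,
    code: GeneticCode = STANDARD_CODE,
    omega_class: str | None = None,
) -> np.ndarray:
    """GY94 rate matrix for one omega class, scaled to mean rate 1."""
    if omega_class is None:
        if len(params.omega_map) != 1:
            raise ValueError("omega_class required for multi-class params")
        omega_class = next(iter(params.omega_map))
    return _rate_matrix(
        params.kappa, params.omega_map[omega_class], params.pi, code
    )


def _rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, code: GeneticCode
) -> np.ndarray:
    s = get_structure(code)
    rates = pi[s.cols] * np.where(s.is_ts, kappa, 1.0)
    rates = rates * np.where(s.is_ns, omega, 1.0)
    Q = np.zeros((s.n, s.n))
    Q[s.rows, s.cols] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (mean rate 0)")
    return Q / mean_rate


def site_rate_matrix(
    kappa: float,
    alpha: float,
    beta: float,
    pi: np.ndarray,
    code: GeneticCode = STANDARD_CODE,
) -> np.ndarray:
    """Rate matrix with separate synonymous/nonsynonymous multipliers.

    Normalized by the neutral (alpha = beta = 1) mean rate, so the
    multipliers are rates relative to neutral evolution and rate
    matrices for different (alpha, beta) classes share one time scale —
    the convention required by site- and branch-site mixtures.
    """
    s = get_structure(code)
    base = pi[s.cols] * np.where(s.is_ts, kappa, 1.0)
    neutral = np.zeros((s.n, s.n))
    neutral[s.rows, s.cols] = base
    np.fill_diagonal(neutral, -neutral.sum(axis=1))
    C = -(pi * np.diag(neutral)).sum()
    rates = base * np.where(s.is_ns, beta, alpha) / C
    Q = np.zeros((s.n, s.n))
    Q[s.rows, s.cols] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class SpectralQ:
    """Eigendecomposition of a reversible Q for fast ``expm(Q t)``.

    With D = diag(pi), S = D^{1/2} Q D^{-1/2} is symmetric; then
    P(t) = D^{-1/2} U exp(L t) U' D^{1/2} with S = U L U'.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.maximum(pi, _PI_FLOOR))
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.A = U / d[:, None]  # D^{-1/2} U
        self.B = U * d[:, None]  # D^{1/2} U

    def probs(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.lam * t)) @ self.B.T
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def probs_many(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths."""
        E = np.exp(np.outer(ts, self.lam))  # (nb, 61)
        P = np.einsum("ik,bk,jk->bij", self.A, E, self.B, optimize=True)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_probs(
    Q: np.ndarray, t: float, pi: np.ndarray | None = None
) -> np.ndarray:
    """P(t) = expm(Q t) via the reversibility-symmetrized eigendecomposition."""
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    if pi is None:
        pi = stationary_distribution(Q)
    return SpectralQ(Q, pi).probs(t)


# ---------------------------------------------------------------------------
# pruning likelihood


class TreeData:
    """Site-pattern-compressed alignment mapped onto a tree."""

    def __init__(self, aln: CodonAlignment, phy: Phylogeny):
        check_taxa_match(phy, aln.taxa)
        self.phy = phy
        self.n_states = len(aln.code.sense_codons)
        row_of = {t: k for k, t in enumerate(aln.taxa)}
        leaf_rows = np.array([row_of[phy.labels[i]] for i in phy.leaves])
        mat = aln.codes[leaf_rows]  # (n_leaves, n_sites) in leaf order
        patterns, inverse, weights = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_leaves, n_patterns)
        self.site_to_pattern = inverse
        self.weights = weights.astype(float)
        self.n_sites = mat.shape[1]
        self.leaf_index = {node: k for k, node in enumerate(phy.leaves)}


def pattern_log_likelihoods(
    td: TreeData, P: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Per-pattern log-likelihood by Felsenstein pruning.

    ``P[i]`` is the transition matrix for the branch above node ``i``
    (row 0, the root, is ignored). Missing codons contribute all-ones
    partials.
    """
    phy = td.phy
    npat = td.patterns.shape[1]
    n_states = td.n_states
    if phy.n_nodes == 1:  # single-leaf "tree": lnL is just log pi per site
        states = td.patterns[0]
        out = np.zeros(npat)
        obs = states != MISSING
        out[obs] = np.log(pi[states[obs]])
        return out
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for v in phy.postorder:
        if not phy.children[v]:
            continue
        acc = np.ones((npat, n_states))
        for c in phy.children[v]:
            Pc = P[c]
            if c in td.leaf_index:
                states = td.patterns[td.leaf_index[c]]
                M = np.ones((npat, n_states))
                obs = states != MISSING
                M[obs] = Pc[:, states[obs]].T
            else:
                M = partials.pop(c) @ Pc.T
            acc *= M
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        acc /= mx[:, None]
        logscale += np.log(mx)
        partials[v] = acc
    root = partials[phy.postorder[-1]]
    site_l = root @ pi
    return np.log(np.maximum(site_l, 1e-300)) + logscale


def _branch_P(
    td: TreeData,
    kappa: float,
    omegas: dict[str, float],
    pi: np.ndarray,
    lengths: np.ndarray,
    code: GeneticCode,
) -> np.ndarray:
    """Per-node transition matrices for a branch model."""
    phy = td.phy
    n = phy.n_nodes
    P = np.empty((n, td.n_states, td.n_states))
    if len(omegas) == 1:
        spec = SpectralQ(_rate_matrix(kappa, next(iter(omegas.values())), pi, code), pi)
        P[1:] = spec.probs_many(lengths[1:])
    else:
        fg = phy.foreground
        spec_bg = SpectralQ(_rate_matrix(kappa, omegas["background"], pi, code), pi)
        spec_fg = SpectralQ(_rate_matrix(kappa, omegas["foreground"], pi, code), pi)
        idx_bg = [i for i in range(1, n) if not fg[i]]
        idx_fg = [i for i in range(1, n) if fg[i]]
        if idx_bg:
            P[idx_bg] = spec_bg.probs_many(lengths[idx_bg])
        if idx_fg:
            P[idx_fg] = spec_fg.probs_many(lengths[idx_fg])
    return P


def log_likelihood(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: CodonModelParams,
) -> float:
    """Alignment log-likelihood under a branch model (input branch lengths)."""
    td = TreeData(aln, tree)
    P = _branch_P(
        td, params.kappa, params.omega_map, params.pi, tree.lengths, aln.code
    )
    site = pattern_log_likelihoods(td, P, params.pi)
    return float(site @ td.weights)


# ---------------------------------------------------------------------------
# fitting

_LOG_KAPPA_BOUNDS = (np.log(0.02), np.log(100.0))
_LOG_OMEGA_BOUNDS = (np.log(1e-6), np.log(50.0))
_LOG_LEN_BOUNDS = (np.log(1e-7), np.log(80.0))
_FTOL = 1e-10


def _maximize(neg, x0_list, bounds):
    best = None
    total_nit = 0
    for x0 in x0_list:
        res = minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": _FTOL, "gtol": 1e-7, "maxiter": 500},
        )
        total_nit += res.nit
        if best is None or res.fun < best.fun:
            best = res
    return best, total_nit


def _fit_branch_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    omega_names: list[str],
    freq_model: str,
    seed: int,
    optimize_branch_lengths: str,
    n_starts: int,
) -> FitResult:
    td = TreeData(aln, tree)
    pi = codon_frequencies(aln, freq_model)
    code = aln.code
    base_len = np.maximum(tree.lengths, 1e-6)
    base_len[0] = 0.0
    n_om = len(omega_names)
    mode = optimize_branch_lengths
    branch_nodes = tree.branch_nodes()

    def unpack(x):
        kappa = np.exp(x[0])
        omegas = {nm: float(np.exp(x[1 + k])) for k, nm in enumerate(omega_names)}
        if mode == "scale":
            lengths = base_len * np.exp(x[1 + n_om])
        elif mode == "joint":
            lengths = np.zeros_like(base_len)
            lengths[branch_nodes] = np.exp(x[1 + n_om :])
        else:  # fixed
            lengths = base_len
        return kappa, omegas, lengths

    def neg(x):
        kappa, omegas, lengths = unpack(x)
        P = _branch_P(td, kappa, omegas, pi, lengths, code)
        return -float(pattern_log_likelihoods(td, P, pi) @ td.weights)

    x0 = [np.log(2.0)] + [np.log(0.2)] * n_om
    bounds = [_LOG_KAPPA_BOUNDS] + [_LOG_OMEGA_BOUNDS] * n_om
    if mode == "scale":
        x0 += [0.0]
        bounds += [(np.log(1e-3), np.log(1e3))]
    elif mode == "joint":
        x0 += list(np.log(base_len[branch_nodes]))
        bounds += [_LOG_LEN_BOUNDS] * len(branch_nodes)
    elif mode != "fixed":
        raise ValueError("optimize_branch_lengths must be scale|joint|fixed")
    x0 = np.array(x0)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        pert = x0.copy()
        pert[: 1 + n_om] += rng.normal(0, 0.7, size=1 + n_om)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts.append(np.clip(pert, lo, hi))

    best, nit = _maximize(neg, starts, bounds)
    kappa, omegas, lengths = unpack(best.x)
    fitted_tree = Phylogeny(
        parent=tree.parent.copy(), lengths=lengths,
        labels=list(tree.labels), foreground=tree.foreground.copy(),
    )
    params = CodonModelParams(
        kappa=kappa, omega_map=omegas, pi=pi, freq_model=freq_model
    )
    warnings = []
    if not best.success:
        warnings.append(f"optimizer: {best.message}")
    if n_om == 2:
        fg_total = lengths[tree.foreground].sum()
        if fg_total <= 1e-5:
            warnings.append("foreground_unidentifiable: total foreground branch length ~ 0")
    return FitResult(
        params=params, lnL=-best.fun, tree=fitted_tree,
        n_iterations=nit, converged=bool(best.success), warnings=warnings,
    )


def fit_m0(
    aln: CodonAlignment,
    tree: Phylogeny,
    freq_model: str = "F3x4",
    seed: int = 0,
    optimize_branch_lengths: str = "scale",
    n_starts: int = 3,
) -> FitResult:
    """One-ratio (Model 0) fit: single omega for every branch."""
    return _fit_branch_model(
        aln, tree, ["all"], freq_model, seed, optimize_branch_lengths, n_starts
    )


def fit_two_ratio(
    aln: CodonAlignment,
    tree: Phylogeny,
    freq_model: str = "F3x4",
    seed: int = 0,
    optimize_branch_lengths: str = "scale",
    n_starts: int = 3,
) -> FitResult:
    """Two-ratio fit: foreground branches get their own omega."""
    fg = tree.foreground.copy()
    fg[0] = False
    n_branches = tree.n_branches
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ValueError("two-ratio model needs at least one foreground branch")
    if n_fg == n_branches:
        raise ValueError("two-ratio model needs at least one background branch")
    return _fit_branch_model(
        aln, tree, ["background", "foreground"], freq_model, seed,
        optimize_branch_lengths, n_starts,
    )


def likelihood_ratio_test(
    null: FitResult | float,
    alt: FitResult | float,
    df: float | list[tuple[float, float]] = 1,
) -> LRTResult:
    """LRT of nested fits: statistic 2*(lnL_alt - lnL_null), chi2 or mixture.

    ``df`` may be a plain degrees-of-freedom value or a mixture
    specification ``[(weight, df), ...]`` where df 0 denotes a point
    mass at zero.
    """
    lnl0 = null.lnL if isinstance(null, FitResult) else float(null)
    lnl1 = alt.lnL if isinstance(alt, FitResult) else float(alt)
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -1e-6:
        raise NestingError(
            f"alternative lnL {lnl1:.6f} below null {lnl0:.6f}: optimizer failure"
        )
    stat = max(stat, 0.0)
    if isinstance(df, (int, float)):
        p = float(chi2.sf(stat, df)) if df > 0 else float(stat <= 0)
    else:
        weights = np.array([w for w, _ in df], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        p = 0.0
        for w, d in df:
            if d == 0:
                p += w * (1.0 if stat <= 0 else 0.0)
            else:
                p += w * float(chi2.sf(stat, d))
    return LRTResult(statistic=stat, df=df, p_value=min(max(p, 0.0), 1.0))
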