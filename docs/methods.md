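# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `hifevol`, and states what the test battery does and does not
demonstrate.

## Codon substitution model

All selection machinery is built on the Goldman–Yang (GY94) codon model
over the 61 sense codons of the standard code. The instantaneous rate
from codon *i* to codon *j* is

    q_ij = 0                                  if i and j differ at >1 position
    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]   otherwise

with κ the transition/transversion rate ratio, ω = dN/dS, and π the
stationary codon frequencies (options: equal, F1x4, F3x4 computed from
the data; default F3x4). For single-ω models the matrix is scaled so the
mean rate at stationarity is 1, making branch lengths expected
substitutions per codon under that model (the codeml convention).

Site and branch-site machinery replaces ω by separate synonymous (α)
and nonsynonymous (β) multipliers and normalizes by the **neutral**
(α = β = 1) mean rate instead, so that rate matrices of different
classes share one time scale. This matters: if each class were
normalized to mean rate 1 separately, a class with ω = 6 would differ
from the background only in its substitution *mix*, not in its
nonsynonymous *rate*, and most of the episodic-selection signal would
vanish. The simulator uses the same convention for its mixture regimes.

Transition probabilities P(t) = exp(Qt) are computed by eigendecomposition
of the reversibility-symmetrized matrix D^{1/2} Q D^{-1/2} (D = diag π),
which is stable at arbitrarily large t; a series expansion is never used.
Likelihoods use Felsenstein pruning over site patterns with per-node
rescaling; codons containing any gap or ambiguity are whole-codon
missing (partials of ones). Per-site tests use the same pruning in the
eigenbasis (messages A·(e^{λt} ∘ Bᵀp)) so that no 61×61 transition
matrix is ever formed per branch, which makes per-site optimization
cheap.

## Branch models and LRT

Model 0 fits a single ω; the two-ratio model gives branches flagged
foreground (Newick `#1` label suffix; `#1*` tags a whole clade) their
own ω. Optimization is bounded L-BFGS-B on log-transformed parameters
(κ, ω, branch-length scale), convergence `ftol` 1e-10, with seeded
random restarts (default 3; the calibration studies use one smart
start). Branch-length handling has three modes: `scale` (default —
input lengths times one free factor), `joint` (every length free), and
`fixed`. The two-ratio vs Model 0 LRT uses χ²(1).

A two-ratio fit whose foreground branches have (near-)zero total fitted
length is flagged unidentifiable rather than reported as a clean
estimate.

## Site-level tests

* **FEL** (pervasive): per site, ML over (α, β) with branch lengths, κ
  and π frozen at the gene-wide Model 0 fit; null α = β; χ²(1).
* **MEME** (episodic): per site, a two-class mixture applied
  independently on every branch — (α, β⁻ ≤ α) with weight 1−w⁺ and
  (α, β⁺) with weight w⁺; the null pins β⁺ = α. The asymptotics of this
  boundary test are non-standard (the weight is unidentified under the
  null), so p-values come from the method's published χ² mixture
  ⅓·χ²₀ + 0.30·χ²₁ + 0.37·χ²₂ by default; any mixture over df 0/1/2 —
  including the conservative pure χ²(2) — is configurable. Even under
  the mixture the null p-values are not uniform (mass at p = 1 from
  zero statistics), so the calibration suite asserts uniformity
  (Kolmogorov–Smirnov) for FEL and a bounded type-I error for MEME.
* **SLAC** (counting): marginal ML ancestral codons under the Model 0
  fit (two-pass belief propagation); per branch-site substitutions are
  split into synonymous/nonsynonymous counts, multi-nucleotide changes
  averaged over all shortest stop-free mutational paths; binomial tail
  tests against the site's κ-weighted neutral synonymous fraction.
* **Gene-wide episodic test** (BUSTED-style): three ω classes
  ω₁ ≤ ω₂ ≤ 1 ≤ ω₃ with simplex weights, drawn independently per
  branch-site; the null pins ω₃ = 1; χ²(2) by default. Per-site
  evidence ratios compare site likelihoods at the two optima; ER > 2 is
  the default corroboration threshold. Synonymous-rate variation (the
  full method's SRV component) is not modelled.

Site calls default to p ≤ 0.05 per test, configurable; raw p-values are
reported (a Benjamini–Hochberg column is available but not used for the
default calls). A gene's selected-site report lists MEME sites, FEL
sites, their intersection (episodic *and* pervasive), and the MEME
subset with ER > 2.

## Synteny rules

Neighborhoods are the 10 flanking genes up- and downstream of a focal
gene, matched by normalized symbol; "unknown" never matches and
duplicate symbols in a window count once. `shared_flank_count` is the
distinct-symbol intersection; `conserved_run` is the longest in-order
match walking outward (unknowns break it; strand differences do not,
strand agreement being reported separately). Naming rules: with an
ancestral (pre-WGD outgroup) window, the TGD copy sharing more flanks is
"a", the other "b", suffixes withheld when no lineage retains both
copies, ties unresolved; with a sister-group window, the SGD copy
sharing more flanks is "s1", the other "s2".

## Physicochemical profiling

Residues at selected sites are encoded by the five Sandberg z-scales
(z1 hydrophobicity, z2 steric bulk, z3 polarity, z4/z5 electronic;
values transcribed from the 1998 publication and bundled as constants).
Gaps/unknowns are imputed with the column mean and masked. Cluster
number is chosen by k-means with BIC(k) = n·ln(WSS_k/n) + k·d·ln(n) on
the full set of PCs: the k·d·ln(n) penalty counts the d coordinates of
each added centroid — a d-free penalty (k·ln n) is dominated by the WSS
decrease from splitting any Gaussian whenever d > 1 and then always
selects k_max, so it cannot recover even well-separated blobs. The full
BIC curve is returned so an elbow criterion can be applied instead.
DAPC centers/scales columns, reduces by SVD-based PCA (retaining the
smallest number of PCs explaining ≥ 80% variance, capped at
n − groups; configurable), and runs LDA on the retained PCs, reporting
discriminant coordinates, per-taxon membership probabilities and
reassignment accuracy.

## Expression

RPKM = count / (length_kb · library/10⁶); TPM = 10⁶·RPKM/ΣRPKM, summing
to one million per library by construction. The normalization universe
is the **full** count table of each (species, tissue) library, not just
the focal gene family — restricting the universe to a handful of genes
would make the family's TPMs sum to 10⁶ among themselves and destroy
cross-species comparability. The synthetic generator therefore always
supplies background genes. Paralog × tissue summaries take the median
TPM across species *possessing* the paralog; absence is a missing cell,
never a zero, so gene loss cannot masquerade as low expression.

## Synthetic data: what it emulates and what it does not

* Codon alignments: sequences evolve down a random bifurcating tree
  (pair-joining topology, uniform branch lengths) from a π-distributed
  root, under constant, site-class, branch (foreground), or episodic
  branch-site ω. No indels, no alignment error, no rate variation in
  synonymous rates, no recombination.
* Neighborhoods: a WGD duplicates a 10+10 ancestral window; each
  descendant slot is independently replaced (loss/turnover), blanked to
  "unknown", or strand-flipped. No tandem duplication or gene
  conversion.
* Expression: negative-binomial counts (Poisson in the dispersion → ∞
  limit) with paralog × tissue means emulating the observed pattern
  (broad HIF1A with heart maximum, gill-restricted HIF2A, embryo-high
  HIF3A, sparse low HIF4A), log-normal gene lengths, variable library
  depths and ~200 background genes per species.

Passing tests therefore demonstrate internal statistical correctness
(calibration, power ordering, estimator consistency, rule-engine
fidelity) under the model's own assumptions — not robustness to
alignment error, model misspecification or real RNA-seq artifacts.

## Study sizes and tree depths

Desk-scale defaults: 16 taxa × 300 codons and 200 replicates for the
branch-LRT calibration; 20 replicates × 500 codons for ω recovery;
300 neutral sites for site-test calibration; 50 sites for the paired
episodic power comparison. Branch-model studies use moderately diverged
trees (branch lengths U(0.02, 0.15), total ≈ 2.5); site-level studies
use deeply diverged trees (U(0.05, 0.35), total ≈ 6), because a single
codon column on a shallow tree carries too few substitutions for any
per-site test to have power — an a priori property of site tests, and
the regime (a gene family spanning a vertebrate class plus an
outgroup) where they are actually used.

## Numerical details and degenerate inputs

π entries are floored at 1e-8 and renormalized before symmetrization;
pruning partials are rescaled per node; P(t) rows are clipped to [0, ∞)
and renormalized. Optimizer bounds: κ ∈ [0.02, 100], ω and site rates
∈ [1e-6 … 1e-4, 50 … 100], lengths ∈ [1e-7, 80], all on log scale;
mixture weights bounded in [0, 1]. Invariant sites are untestable for
FEL/MEME (statistic 0, p 1); alignments with ≤ 2 distinct site patterns
are untestable gene-wide; an all-gap column yields an untestable SLAC
row rather than being dropped. LRT statistics are clamped at 0 and an
alternative fit worse than its null by more than 1e-6 raises a nesting
error (an optimizer-failure signal, never silently swallowed).

## Known limitations

No aBSREL-style adaptive branch complexity, no FUBAR, no synonymous
rate variation, no profile-likelihood intervals on ω. The gene-wide
test's χ²(2) null is conservative. SLAC's binomial test rounds the
(possibly fractional, path-averaged) substitution totals. The
neighborhood matcher takes symbols at face value — no sequence-level
orthology check behind a symbol.
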