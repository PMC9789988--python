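"""Physicochemical profiling of selected sites: z-scales, k-means/BIC, DAPC.

Amino acids at positively selected alignment columns are encoded by the
five z-descriptors of Sandberg, Eriksson, Jonsson, Sjostrom & Wold
(J. Med. Chem. 41:2481, 1998): z1 hydrophobicity, z2 steric bulk, z3
polarity, z4 and z5 electronic properties. The resulting taxa-by-
(site x descriptor) matrix is clustered (k-means, with a BIC curve to
choose k) and summarized by discriminant analysis of principal
components (DAPC): PCA for dimension reduction followed by linear
discriminant analysis on the retained components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

# Sandberg et al. (1998) extended z-scales, transcribed from the
# published Table 2 (z1..z5 per amino acid).
Z_SCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}


@dataclass
class ZMatrix:
    """Taxa-by-(site x descriptor) matrix with a missing-value mask."""

    taxa: list[str]
    sites: list[int]
    values: np.ndarray  # (n_taxa, 5 * n_sites), imputed
    mask: np.ndarray  # True where the residue was a gap/unknown

    @property
    def columns(self) -> list[str]:
        return [f"site{s}_z{k + 1}" for s in self.sites for k in range(5)]


@dataclass
class DAPCResult:
    retained_pcs: int
    groups: list[str]
    group_labels: list[str]  # per taxon
    discriminant_axes: np.ndarray  # (n_taxa, n_axes) coordinates
    memberships: np.ndarray  # (n_taxa, n_groups), rows sum to 1
    reassignment_accuracy: float
    explained_variance: np.ndarray = field(default=None)


def encode_zmatrix(
    msa: dict[str, str],
    sites: list[int],
    table: dict[str, tuple] | None = None,
    gap_policy: str = "impute_mean",
) -> ZMatrix:
    """Encode residues at selected 1-based columns by the five z-scales.

    Gaps and unknown residues (``X``) are missing; with the default
    policy they are imputed with the column mean (mask recorded), with
    ``gap_policy="zero"`` they become 0.
    """
    table = Z_SCALES if table is None else table
    taxa = list(msa)
    length = len(next(iter(msa.values())))
    for s in sites:
        if not 1 <= s <= length:
            raise IndexError(f"site {s} outside 1..{length}")
    n, m = len(taxa), 5 * len(sites)
    values = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for i, t in enumerate(taxa):
        for j, s in enumerate(sites):
            aa = msa[t][s - 1].upper()
            z = table.get(aa)
            if z is None:
                mask[i, 5 * j : 5 * j + 5] = True
            else:
                values[i, 5 * j : 5 * j + 5] = z
    if gap_policy == "impute_mean":
        for col in range(m):
            miss = mask[:, col]
            if miss.any() and not miss.all():
                values[miss, col] = values[~miss, col].mean()
    elif gap_policy != "zero":
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    return ZMatrix(taxa=taxa, sites=list(sites), values=values, mask=mask)


def _center_scale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _pca(X: np.ndarray):
    Xc = _center_scale(X)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    var = S**2 / max(len(X) - 1, 1)
    return scores, var


def select_k(
    matrix: ZMatrix | np.ndarray,
    k_max: int = 8,
    seed: int = 0,
    variance_retained: float = 1.0,
) -> tuple[int, dict[int, float]]:
    """Choose the k-means cluster number by BIC.

    k-means runs on the PCs retaining ``variance_retained`` of the
    variance (default: all of it — discarding components before
    clustering deflates within-cluster dispersion and biases BIC toward
    too many clusters); BIC(k) = n ln(WSS_k / n) + k d ln(n), where d is
    the clustering dimension: each added cluster buys d centroid
    coordinates, and a penalty that ignores d always prefers k_max.
    Returns the argmin and the full curve.
    """
    X = matrix.values if isinstance(matrix, ZMatrix) else np.asarray(matrix)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 rows to select k")
    if k_max >= n:
        k_max = n - 1
    scores, var = _pca(X)
    keep = _n_components(var, variance_retained, cap=scores.shape[1])
    Y = scores[:, :keep]
    bic: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((Y - Y.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Y)
            wss = float(km.inertia_)
        wss = max(wss, 1e-12)
        bic[k] = n * np.log(wss / n) + k * Y.shape[1] * np.log(n)
    best = min(bic, key=bic.get)
    return best, bic


def _n_components(var: np.ndarray, retain: float, cap: int) -> int:
    frac = np.cumsum(var) / var.sum()
    keep = int(np.searchsorted(frac, retain) + 1)
    return max(1, min(keep, cap))


def dapc(
    matrix: ZMatrix | np.ndarray,
    groups: list[str],
    n_pcs: int | str = "auto",
    variance_retained: float = 0.8,
) -> DAPCResult:
    """Discriminant analysis of principal components.

    Columns are centered/scaled, PCA retains ``n_pcs`` components
    ("auto": smallest number explaining ``variance_retained`` of the
    variance, capped at n - number of groups), and LDA on the retained
    PCs yields discriminant axes and per-taxon group memberships.
    """
    X = matrix.values if isinstance(matrix, ZMatrix) else np.asarray(matrix)
    taxa = matrix.taxa if isinstance(matrix, ZMatrix) else [
        str(i) for i in range(len(X))
    ]
    groups = [str(g) for g in groups]
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) != len(X):
        raise ValueError("one group label per row required")
    scores, var = _pca(X)
    rank = int((var > 1e-12).sum())
    if n_pcs == "auto":
        keep = _n_components(var, variance_retained, cap=rank)
        keep = min(keep, max(1, len(X) - len(uniq)))
    else:
        keep = int(n_pcs)
        if keep <= 0:
            raise ValueError("n_pcs must be >= 1")
        if keep > rank:
            raise ValueError(
                f"n_pcs={keep} exceeds matrix rank {rank}; reduce n_pcs "
                "or add variable sites"
            )
    Y = scores[:, :keep]
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(Y, groups)
    axes = lda.transform(Y)
    memberships = lda.predict_proba(Y)
    accuracy = float((lda.predict(Y) == np.array(groups)).mean())
    return DAPCResult(
        retained_pcs=keep,
        groups=list(lda.classes_),
        group_labels=groups,
        discriminant_axes=axes,
        memberships=memberships,
        reassignment_accuracy=accuracy,
        explained_variance=var,
    )
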