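"""Transcript-abundance normalization and paralog-by-tissue summaries.

RPKM = count / (length_kb * library_size / 1e6); TPM rescales RPKM to
sum to one million over the normalization universe of a tissue:
TPM = 1e6 * RPKM / sum(RPKM). The normalization universe is the full
count table supplied per tissue, not just the focal gene family — see
the methods note for why this matters.

The summary matrix holds, for each (paralog, tissue), the median TPM
over species that possess the paralog; species lacking it are excluded
rather than counted as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rpkm(
    count: float | np.ndarray,
    length_kb: float | np.ndarray,
    library_size: float,
) -> float | np.ndarray:
    """Reads per kilobase per million mapped reads."""
    length_kb = np.asarray(length_kb, dtype=float)
    if np.any(length_kb <= 0):
        raise ValueError("gene length must be > 0")
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    out = np.asarray(count, dtype=float) / (length_kb * library_size / 1e6)
    return float(out) if out.ndim == 0 else out


def tpm_from_rpkm(rpkm_vector: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """TPM = 1e6 * RPKM / sum(RPKM); invariant to uniform rescaling."""
    total = float(np.sum(rpkm_vector))
    if total <= 0:
        raise ValueError("all-zero RPKM vector: TPM undefined")
    return rpkm_vector * (1e6 / total)


def expression_table(
    counts: pd.DataFrame,
    lengths: pd.DataFrame,
) -> pd.DataFrame:
    """Per (species, gene, tissue) RPKM and TPM from tidy count input.

    ``counts`` columns: species, gene, tissue, count. ``lengths``
    columns: species, gene, length_kb. Library size is the total count
    of a (species, tissue) library; TPM is normalized within it.
    """
    df = counts.merge(lengths, on=["species", "gene"], how="left")
    if df["length_kb"].isna().any():
        missing = df.loc[df["length_kb"].isna(), "gene"].unique()[:5]
        raise ValueError(f"genes without length: {list(missing)}")
    out = []
    for (sp, tis), grp in df.groupby(["species", "tissue"], sort=False):
        lib = float(grp["count"].sum())
        if lib <= 0:
            raise ValueError(f"empty library for {sp}/{tis}")
        g = grp.copy()
        g["rpkm"] = rpkm(g["count"].values, g["length_kb"].values, lib)
        g["tpm"] = tpm_from_rpkm(g["rpkm"].values)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def median_heatmap(
    expr: pd.DataFrame,
    paralog_map: pd.DataFrame,
) -> pd.DataFrame:
    """Paralog x tissue matrix of median TPM across species.

    ``expr`` is the output of :func:`expression_table`; ``paralog_map``
    has columns species, gene, paralog and lists only the genes each
    species actually possesses. Cells where no species possesses the
    paralog are NaN (missing), never zero.
    """
    merged = expr.merge(paralog_map, on=["species", "gene"], how="inner")
    if merged.empty:
        raise ValueError("paralog map matches no rows of the expression table")
    mat = (
        merged.groupby(["paralog", "tissue"])["tpm"]
        .median()
        .unstack("tissue")
    )
    paralogs = list(dict.fromkeys(paralog_map["paralog"]))
    tissues = list(dict.fromkeys(expr["tissue"]))
    return mat.reindex(index=paralogs, columns=tissues)
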