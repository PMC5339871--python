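"""Expression-matrix preprocessing and imaging-trait redundancy detection.

The pipeline's central object is a genes x samples matrix of log-scale
expression values (a pandas DataFrame with gene ids as index and sample ids
as columns).  The per-sample imaging traits (AD, RD, MD, FA medians) live in
a samples x traits DataFrame.  This module provides quantile normalisation,
variance filtering, sample alignment across tables, and the detection of
mutually redundant traits — diffusivity metrics derived from the same tensor
are often near-collinear across a cohort and correlate with the same genes,
in which case a single representative (by convention MD) is carried forward.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "filter_top_variance",
    "trait_redundancy",
    "gene_trait_profiles",
    "align_samples",
    "read_expression",
    "read_traits",
    "read_survival",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common quantile distribution.

    Each column's sorted values are replaced by the across-column row means of
    the column-sorted matrix; tied values within a column receive the mean of
    the reference values their positions span.  Idempotent, and a fixed point
    for matrices whose columns are already identical distributions.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize with a single sample is the identity", stacklevel=2)
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    sorted_cols = np.sort(values, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties: every position holding the same value gets the mean of the
        # reference values spanned by that tie block
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_top_variance(matrix: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Keep the ``top_k`` most variable genes, preserving input row order."""
    if top_k <= 0:
        raise ValueError("top_k must be a positive count")
    if top_k > matrix.shape[0]:
        raise ValueError(f"top_k={top_k} exceeds gene count {matrix.shape[0]}")
    variances = matrix.to_numpy(dtype=float).var(axis=1, ddof=1)
    keep = np.sort(np.argsort(-variances, kind="stable")[:top_k])
    return matrix.iloc[keep]


def gene_trait_profiles(matrix: pd.DataFrame, traits: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Per-trait gene-correlation vectors (genes x traits).

    The column-wise correlation fingerprint of each trait against every gene;
    input to :func:`trait_redundancy`.
    """
    if not matrix.columns.equals(traits.index):
        raise ValueError("expression samples and trait samples must be aligned; see align_samples")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = matrix.to_numpy(dtype=float)
    t = traits.to_numpy(dtype=float)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
        t = np.apply_along_axis(stats.rankdata, 0, t)
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=0, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    tn = np.sqrt((tc**2).sum(axis=0))
    if np.any(xn == 0):
        bad = matrix.index[np.where(xn == 0)[0][0]]
        raise ValueError(f"zero-variance gene {bad!r}; filter before computing profiles")
    corr = (xc @ tc) / np.outer(xn, tn)
    return pd.DataFrame(corr, index=matrix.index, columns=traits.columns)


def trait_redundancy(
    profiles: pd.DataFrame,
    threshold: float = 0.9,
    preferred: tuple[str, ...] = ("MD",),
) -> tuple[list[list[str]], list[str]]:
    """Group traits whose gene-correlation profiles are near-identical.

    Traits are joined by single linkage: any pair with profile correlation
    >= ``threshold`` falls into the same group.  One representative per group
    is returned — the first trait of ``preferred`` present in the group
    (default MD, the conventional representative of the collinear diffusivity
    triplet AD/RD/MD), else the alphabetically first member.

    Returns ``(groups, representatives)`` with groups sorted by their
    representative; invariant to the input column order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 traits to assess redundancy")
    names = list(profiles.columns)
    corr = np.corrcoef(profiles.to_numpy(dtype=float).T)
    # single linkage == connected components of the thresholded graph
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if corr[i, j] >= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        clusters.setdefault(find(i), []).append(name)
    groups = [sorted(members) for members in clusters.values()]
    reps = []
    for group in groups:
        rep = next((p for p in preferred if p in group), group[0])
        reps.append(rep)
    order = np.argsort(reps)
    return [groups[i] for i in order], [reps[i] for i in order]


def align_samples(
    expression: pd.DataFrame,
    traits: pd.DataFrame,
    survival: pd.DataFrame | None = None,
):
    """Restrict all tables to their shared samples, in expression order.

    Hard failure on an empty intersection; dropped samples are reported via a
    warning so silently shrinking cohorts are visible in logs.
    """
    shared = [s for s in expression.columns if s in traits.index]
    if survival is not None:
        shared = [s for s in shared if s in survival.index]
    if not shared:
        raise ValueError("no samples shared between expression, traits and survival tables")
    dropped = (set(expression.columns) | set(traits.index) | (set(survival.index) if survival is not None else set())) - set(shared)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} unmatched samples: {sorted(dropped)}", stacklevel=2)
    out = (expression[shared], traits.loc[shared])
    if survival is not None:
        return out + (survival.loc[shared],)
    return out


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression table (TSV or CSV, sniffed)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ValueError(f"expression matrix {path} contains missing values")
    return df


def read_traits(path) -> pd.DataFrame:
    """Read a per-sample trait table (first column sample id)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def read_survival(path) -> pd.DataFrame:
    """Read a survival table with columns time, event (and optional group)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table {path} lacks columns {sorted(missing)}")
    return df
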