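"""Weighted co-expression network construction and module detection.

The weighted network is built from pairwise gene correlations raised to a
soft-thresholding power beta (unsigned by default, a_ij = |cor|^beta), which
emphasises strong co-expression while keeping the network fully connected.
Pairwise similarity is then refined by topological overlap — two genes are
similar when they are directly connected *and* share neighbours —

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,   k_i = sum_u a_iu,

and 1 - omega is the dissimilarity used for average-linkage hierarchical
clustering into modules.  Each module is summarised by its eigengene (first
principal component of the standardised module submatrix), and each gene by
its kME (correlation with a module eigengene, the intramodular-connectivity
measure used to rank hub genes).  Module eigengenes are correlated against
the imaging traits to find trait-associated modules, and the thresholded
TOM can be exported as a Cytoscape-compatible edge list.

Module detection uses a static tree cut at a configurable height followed by
an iterative eigengene-merge step — a deliberately simplified, fully
deterministic alternative to the dynamic hybrid tree cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "adjacency",
    "tom",
    "scale_free_fit",
    "soft_threshold_select",
    "SoftThresholdResult",
    "detect_modules",
    "module_eigengene",
    "kme",
    "module_trait_correlation",
    "export_network",
    "hub_genes",
]


def _corr_matrix(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = matrix.index[np.where(sd == 0)[0][0]]
        raise ValueError(f"zero-variance gene {bad!r}: correlations undefined; filter first")
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0)


def adjacency(matrix: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency with zero diagonal.

    Unsigned (default): a_ij = |cor(x_i, x_j)|^beta.  Signed variant:
    a_ij = ((1 + cor) / 2)^beta, which separates anti-correlated genes.
    """
    if beta < 1:
        raise ValueError("soft-thresholding power beta must be >= 1")
    c = _corr_matrix(matrix)
    a = ((1.0 + c) / 2.0) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    omega_ii = 1; the associated dissimilarity is 1 - omega.  Entries stay in
    [0, 1] whenever the adjacency entries do.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12, rtol=0.0):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.abs(np.diag(a)) > 1e-12):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0)
    shared = a @ a  # l_ij; diagonal of a is zero so u=i,j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    w = (shared + a) / denom
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=adj.index, columns=adj.columns)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10(freq(k)) ~ log10(k) regression over connectivity bins.

    Connectivity values are binned into ``n_bins`` equal-width bins; empty
    bins are dropped; each bin contributes (log10 mean k, log10 relative
    frequency).  Scale-free networks give a near-linear relation.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.unique(k).size < 8:
        raise ValueError("need >= 8 distinct connectivity values; reduce the bin count or check the network")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable connectivity bins; reduce the bin count")
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2)


def recommended_power(n_samples: int, signed: bool = False) -> int:
    """Sample-size-based soft power (the standard tabulated recommendation).

    The scale-free fit criterion is unreliable on small cohorts, where the
    community convention is a fixed power by sample size: unsigned networks
    use 9 (n < 20), 8 (n < 30), 7 (n <= 40) and 6 otherwise; signed networks
    double these.
    """
    if n_samples < 20:
        p = 9
    elif n_samples < 30:
        p = 8
    elif n_samples <= 40:
        p = 7
    else:
        p = 6
    return 2 * p if signed else p


@dataclass(frozen=True)
class SoftThresholdResult:
    power: int
    r_squared: dict[int, float]
    mean_connectivity: dict[int, float]
    reached_target: bool


def soft_threshold_select(
    matrix: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    signed: bool = False,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Pick the smallest power whose scale-free topology fit reaches target.

    Falls back to the argmax-R^2 power (with ``reached_target=False``) when no
    power in the grid reaches ``r2_target``.
    """
    powers = list(powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("powers must be a non-empty ascending list")
    r2: dict[int, float] = {}
    mean_k: dict[int, float] = {}
    chosen = None
    for beta in powers:
        a = adjacency(matrix, beta, signed=signed).to_numpy()
        k = a.sum(axis=0)
        mean_k[beta] = float(k.mean())
        r2[beta] = scale_free_fit(k, n_bins=n_bins)
        if chosen is None and r2[beta] >= r2_target:
            chosen = beta
    if chosen is None:
        chosen = max(r2, key=r2.get)
        warnings.warn(
            f"no power reached scale-free R^2 {r2_target}; using argmax power {chosen} "
            f"(R^2={r2[chosen]:.3f})",
            stacklevel=2,
        )
        return SoftThresholdResult(chosen, r2, mean_k, False)
    return SoftThresholdResult(chosen, r2, mean_k, True)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Make assigned labels contiguous from 1, sorted by descending size."""
    sizes = labels[labels > 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return labels.map(mapping)


def detect_modules(
    tom_dissimilarity: pd.DataFrame,
    min_module_size: int = 10,
    merge_height: float = 0.25,
    cut_height: float = 0.995,
    expression: pd.DataFrame | None = None,
) -> pd.Series:
    """Average-linkage module detection on the TOM dissimilarity.

    The dendrogram is cut at a static ``cut_height``; clusters smaller than
    ``min_module_size`` are relabelled 0 (unassigned, the conventional
    "grey" bucket).  When ``expression`` is given, modules whose eigengenes
    correlate above ``1 - merge_height`` are merged iteratively until stable.
    Final labels are positive integers sorted by descending module size.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    d = tom_dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10, rtol=0.0):
        raise ValueError("dissimilarity must be symmetric")
    if d.min() < -1e-10 or d.max() > 1.0 + 1e-10:
        raise ValueError("dissimilarity entries must lie in [0, 1]")
    dd = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(dd, 0.0)
    z = linkage(squareform(dd, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom_dissimilarity.index, dtype=int)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_module_size] = 0
    labels = _relabel_by_size(labels)

    if expression is not None and labels.max() >= 2:
        merge_threshold = 1.0 - merge_height
        while True:
            eig = module_eigengene(expression, labels)
            if eig.shape[0] < 2:
                break
            c = np.corrcoef(eig.to_numpy())
            np.fill_diagonal(c, -np.inf)
            i, j = np.unravel_index(np.argmax(c), c.shape)
            if c[i, j] < merge_threshold:
                break
            a, b = sorted((int(eig.index[i]), int(eig.index[j])))
            labels[labels == b] = a
            labels = _relabel_by_size(labels)
    return labels


def module_eigengene(matrix: pd.DataFrame, partition: pd.Series) -> pd.DataFrame:
    """First principal component summary profile per module (module x sample).

    Each module's gene submatrix is gene-standardised; the leading right
    singular vector over samples, rescaled to unit variance, is the
    eigengene.  Its sign is fixed to correlate positively with the module's
    mean standardised expression, removing the PC-sign ambiguity.
    """
    partition = partition.loc[matrix.index]
    modules = sorted(m for m in partition.unique() if m > 0)
    if not modules:
        raise ValueError("partition assigns no genes to modules")
    rows = {}
    n = matrix.shape[1]
    for m in modules:
        sub = matrix.loc[partition[partition == m].index].to_numpy(dtype=float)
        if sub.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene; eigengene is its standardised profile", stacklevel=2)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance gene in module {m}")
        zed = (sub - mu) / sd
        if zed.shape[0] == 1:
            e = zed[0]
        else:
            _, _, vt = np.linalg.svd(zed, full_matrices=False)
            e = vt[0]
        e = e / e.std(ddof=1)
        mean_profile = zed.mean(axis=0)
        r = np.dot(e - e.mean(), mean_profile - mean_profile.mean())
        if r < 0:
            e = -e
        rows[m] = e
    return pd.DataFrame(rows, index=matrix.columns).T.rename_axis("module")


def kme(matrix: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Gene x module correlations with the eigengenes (intramodular kME)."""
    if not matrix.columns.equals(eigengenes.columns):
        raise ValueError("expression and eigengene sample sets differ")
    x = matrix.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    en = np.sqrt((ec**2).sum(axis=1))
    if np.any(xn == 0):
        bad = matrix.index[np.where(xn == 0)[0][0]]
        raise ValueError(f"zero-variance gene {bad!r}")
    corr = (xc @ ec.T) / np.outer(xn, en)
    return pd.DataFrame(np.clip(corr, -1, 1), index=matrix.index, columns=eigengenes.index)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Eigengene-trait correlations with two-sided p-values.

    Returns a tidy table (module, trait, r, p); the p-value uses the
    t approximation with n - 2 degrees of freedom. Pivot on (module, trait)
    to render the usual module-trait heatmap.
    """
    if not eigengenes.columns.equals(pd.Index(traits.index)):
        raise ValueError("eigengene samples and trait samples must be aligned")
    n = eigengenes.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 shared samples, got {n}")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    records = []
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        for t in traits.columns:
            y = traits[t].to_numpy(dtype=float)
            if method == "pearson":
                r = float(stats.pearsonr(e, y).statistic)
            else:
                r = float(stats.spearmanr(e, y).statistic)
            r = float(np.clip(r, -1, 1))
            if abs(r) == 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1 - r**2))
                p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
            records.append({"module": m, "trait": t, "r": r, "p": p})
    return pd.DataFrame.from_records(records)


def export_network(
    tom_matrix: pd.DataFrame,
    partition: pd.Series,
    weight_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cytoscape-style edge and node tables from a thresholded TOM.

    Edges: unordered gene pairs with omega >= threshold (self-edges
    excluded).  Nodes: module label and intramodular connectivity — the sum
    of topological overlap to same-module genes — the quantity conventionally
    mapped to node size/colour in module network renderings.
    """
    if not 0.0 <= weight_threshold <= 1.0:
        raise ValueError("weight_threshold must lie in [0, 1]")
    w = tom_matrix.to_numpy(dtype=float)
    genes = list(tom_matrix.index)
    part = partition.loc[tom_matrix.index]
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = w[iu, ju] >= weight_threshold
    edges = pd.DataFrame(
        {
            "fromNode": [genes[i] for i in iu[keep]],
            "toNode": [genes[j] for j in ju[keep]],
            "weight": w[iu, ju][keep],
            "fromModule": part.iloc[iu[keep]].to_numpy(),
            "toModule": part.iloc[ju[keep]].to_numpy(),
        }
    )
    same = np.equal.outer(part.to_numpy(), part.to_numpy())
    np.fill_diagonal(same, False)
    conn = (w * same).sum(axis=1)
    nodes = pd.DataFrame(
        {"node": genes, "module": part.to_numpy(), "intramodularConnectivity": conn}
    )
    return edges, nodes


def hub_genes(kme_matrix: pd.DataFrame, partition: pd.Series, module: int, top_n: int) -> pd.Series:
    """Top module members ranked by kME to their own module.

    Ties break on gene id (lexicographic) for determinism; requesting more
    genes than the module holds returns the whole module with a warning.
    """
    if module not in set(partition.values):
        raise ValueError(f"module {module} not present in the partition")
    members = partition[partition == module].index
    scores = kme_matrix.loc[members, module]
    ranked = scores.sort_index().sort_values(ascending=False, kind="stable")
    if top_n > len(ranked):
        warnings.warn(f"top_n={top_n} exceeds module size {len(ranked)}; returning all members", stacklevel=2)
        top_n = len(ranked)
    return ranked.iloc[:top_n]
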