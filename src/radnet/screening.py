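"""Gene-wise trait correlation screening and radiogenomic subgrouping.

Each gene is screened against an imaging trait by Spearman rank correlation;
p-values come from the t approximation at usual cohort sizes and from the
exhaustive permutation distribution at very small n, then are adjusted by
Benjamini-Hochberg.  Genes passing an absolute-correlation cut (default
|rho| >= 0.6) define the trait's radiogenomic signature, on which samples
are split into two subgroups by average-linkage hierarchical clustering of
1 - Spearman distances between sample profiles.  Subgroups are named by
ascending trait mean (cluster II has the higher mean), which makes labels
deterministic and comparable across runs.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gene_trait_spearman",
    "bh_adjust",
    "select_correlated_genes",
    "cluster_samples",
    "fisher_module_overlap",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _spearman_rho(rank_matrix: np.ndarray, rank_trait: np.ndarray) -> np.ndarray:
    """Pearson correlation of midranked rows against a midranked trait."""
    xc = rank_matrix - rank_matrix.mean(axis=1, keepdims=True)
    tc = rank_trait - rank_trait.mean()
    xn = np.sqrt((xc**2).sum(axis=1))
    tn = np.sqrt((tc**2).sum())
    return np.clip((xc @ tc) / (xn * tn), -1.0, 1.0)


def _exact_permutation_p(rank_gene: np.ndarray, rank_trait: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (all n! trait orders)."""
    n = rank_trait.size
    total = math.factorial(n)
    xc = rank_gene - rank_gene.mean()
    xn = np.sqrt((xc**2).sum())
    tc = rank_trait - rank_trait.mean()
    tn = np.sqrt((tc**2).sum())
    count = 0
    target = abs(rho_obs) - 1e-12
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = np.abs((tc[np.array(chunk)] @ xc) / (xn * tn))
            count += int((rhos >= target).sum())
            chunk = []
    if chunk:
        rhos = np.abs((tc[np.array(chunk)] @ xc) / (xn * tn))
        count += int((rhos >= target).sum())
    return count / total


def gene_trait_spearman(
    matrix: pd.DataFrame,
    trait: pd.Series,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Spearman screening of every gene against one trait.

    Returns a DataFrame indexed by gene with columns ``rho``, ``p`` and
    ``q`` (Benjamini-Hochberg adjusted).  For n <= ``exact_max_n`` the
    p-value is the exhaustive two-sided permutation probability (so a
    perfectly monotone gene gets the attainable permutation minimum, never
    an unattainable 0); for larger n the usual t approximation
    t = rho*sqrt((n-2)/(1-rho^2)) with n - 2 degrees of freedom is used.
    """
    trait = trait.loc[matrix.columns]
    y = trait.to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait contains non-finite values")
    n = y.size
    if n < 5:
        raise ValueError(f"need >= 5 paired observations, got {n}")
    if np.unique(y).size == 1:
        raise ValueError("constant trait: Spearman correlation undefined for every gene")
    x = matrix.to_numpy(dtype=float)
    if np.any(x.std(axis=1) == 0):
        bad = matrix.index[np.where(x.std(axis=1) == 0)[0][0]]
        raise ValueError(f"zero-variance gene {bad!r}: filter before screening")
    rank_x = np.apply_along_axis(stats.rankdata, 1, x)
    rank_y = stats.rankdata(y)
    rho = _spearman_rho(rank_x, rank_y)
    if n <= exact_max_n:
        p = np.array([_exact_permutation_p(rank_x[i], rank_y, rho[i]) for i in range(len(rho))])
    else:
        with np.errstate(divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        p = np.where(np.abs(rho) == 1.0, 0.0, p)
        p = np.minimum(p, 1.0)
    return pd.DataFrame({"rho": rho, "p": p, "q": bh_adjust(p)}, index=matrix.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_correlated_genes(
    corr: pd.DataFrame,
    rho_threshold: float = 0.6,
    q_threshold: float = 1.0,
) -> list[str]:
    """Genes with |rho| >= rho_threshold and q <= q_threshold, input order.

    The q cut defaults to 1.0 (off): the absolute-correlation cut is the
    primary screening criterion, and the FDR knob is an independent option.
    """
    if not 0.0 <= rho_threshold <= 1.0:
        raise ValueError("rho_threshold must lie in [0, 1]")
    if not 0.0 < q_threshold <= 1.0:
        raise ValueError("q_threshold must lie in (0, 1]")
    mask = (corr["rho"].abs() >= rho_threshold) & (corr["q"] <= q_threshold)
    return list(corr.index[mask])


def cluster_samples(
    matrix: pd.DataFrame,
    trait: pd.Series,
    k: int = 2,
) -> tuple[pd.Series, pd.DataFrame]:
    """Split samples into k subgroups on the selected-gene expression.

    Distance between samples is 1 - Spearman correlation of their expression
    profiles; average-linkage clustering is cut to exactly ``k`` clusters.
    Clusters are named with roman numerals by ascending trait mean, so the
    last cluster ("II" for k=2) always has the highest trait mean.

    Returns ``(labels, summary)`` where summary holds per-cluster n, trait
    mean and sample standard deviation (NaN for singleton clusters).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_samples = matrix.shape[1]
    if n_samples < k:
        raise ValueError(f"cannot cut {n_samples} samples into {k} clusters")
    if k > 1 and matrix.shape[0] < 2:
        raise ValueError("need >= 2 selected genes to cluster samples")
    trait = trait.loc[matrix.columns]
    if k == 1:
        raw = np.ones(n_samples, dtype=int)
    else:
        ranks = np.apply_along_axis(stats.rankdata, 0, matrix.to_numpy(dtype=float))
        c = np.corrcoef(ranks.T)
        d = np.clip(1.0 - c, 0.0, None)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        z = linkage(squareform(d, checks=False), method="average")
        raw = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=matrix.columns)
    means = trait.groupby(labels).mean()
    order = sorted(means.index, key=lambda c: (means[c], c))
    mapping = {old: _ROMAN[i] for i, old in enumerate(order)}
    named = labels.map(mapping).rename("cluster")
    summary = pd.DataFrame(
        {
            "n": trait.groupby(named).size(),
            "trait_mean": trait.groupby(named).mean(),
            "trait_sd": trait.groupby(named).std(ddof=1),
        }
    ).loc[[_ROMAN[i] for i in range(len(order))]]
    return named, summary


def fisher_module_overlap(
    selected_genes,
    module_genes,
    universe,
) -> tuple[float, float]:
    """Fisher's exact test for selected-gene x module-membership overlap.

    2x2 table over the gene universe: selected/not x in-module/not.
    Returns (odds ratio, two-sided p). An optional companion to the
    correlation screen, quantifying whether a trait's signature concentrates
    in one co-expression module.
    """
    universe = set(universe)
    sel = set(selected_genes) & universe
    mod = set(module_genes) & universe
    a = len(sel & mod)
    b = len(sel - mod)
    c = len(mod - sel)
    d = len(universe) - a - b - c
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
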