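"""Pathway perturbation profiles and patient clustering.

Driver and helper gene lists are tested for enrichment against a filtered
pathway collection with a one-sided hypergeometric test (BH-corrected).
Enriched pathways containing at least one altered gene of a sample form that
sample's perturbation profile; pairwise profile similarity is the Jaccard
index A_ij = |P_i ∩ P_j| / |P_i ∪ P_j|. Samples are clustered by complete
linkage on Euclidean distances between rows of the similarity matrix, and
the cluster count is chosen by the median silhouette over k = 3..20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional hierarchy level per set."""

    sets: dict[str, frozenset[str]]
    levels: dict[str, int] | None = None
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        members = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        if self.universe is None:
            self.universe = members
        else:
            self.universe = frozenset(self.universe)
            if not members <= self.universe:
                raise ValueError("universe must contain all gene set members")

    def __len__(self) -> int:
        return len(self.sets)


def filter_collection(
    c: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    excluded_levels: tuple[int, ...] = (1, 2),
) -> GeneSetCollection:
    """Drop sets outside [min_size, max_size] and in excluded hierarchy levels.

    Without level annotation the level filter is skipped with a warning. The
    universe is recomputed as the union of the retained sets.
    """
    if c.levels is None:
        logger.warning("no hierarchy annotation; level filter skipped")
    kept = {}
    for name, members in c.sets.items():
        if not min_size <= len(members) <= max_size:
            continue
        if c.levels is not None and c.levels.get(name) in excluded_levels:
            continue
        kept[name] = members
    if not kept:
        raise ValueError("no gene sets survive the collection filter")
    levels = {k: c.levels[k] for k in kept if k in c.levels} if c.levels else None
    return GeneSetCollection(sets=kept, levels=levels)


def enrich(
    query: set[str], c: GeneSetCollection, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with BH correction.

    Query genes outside the collection universe are dropped and logged; an
    empty effective query is an error.
    """
    query = set(query)
    outside = query - c.universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(outside), ", ".join(sorted(outside)[:10]),
        )
    query &= c.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    N = len(c.universe)
    n = len(query)
    rows = []
    for name in sorted(c.sets):
        members = c.sets[name]
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway": name,
                "overlap": k,
                "query_size": n,
                "set_size": K,
                "universe_size": N,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(result["p"], method="fdr_bh")
    result["fdr"] = np.maximum(fdr, result["p"])
    result["enriched"] = result["fdr"] < fdr_threshold
    return result


def perturbation_profiles(
    enriched_pathways: set[str],
    altered_genes: dict[str, set[str]],
    c: GeneSetCollection,
) -> dict[str, frozenset[str]]:
    """P_i = enriched pathways containing >=1 altered gene of sample i."""
    out = {}
    for sample, genes in altered_genes.items():
        genes = set(genes)
        out[sample] = frozenset(
            pw for pw in enriched_pathways if c.sets[pw] & genes
        )
    return out


def jaccard_matrix(profiles: dict[str, frozenset[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of perturbation profiles.

    Two empty profiles have similarity 0 by convention (an unperturbed pair
    is not similar); the diagonal is 1 for non-empty profiles.
    """
    samples = sorted(profiles)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 profiles")
    A = np.zeros((n, n))
    for i, si in enumerate(samples):
        for j in range(i, n):
            sj = samples[j]
            union = profiles[si] | profiles[sj]
            A[i, j] = A[j, i] = (
                len(profiles[si] & profiles[sj]) / len(union) if union else 0.0
            )
    return pd.DataFrame(A, index=samples, columns=samples)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> cluster label (1..k)
    k: int
    silhouettes: pd.Series
    median_silhouette: float
    k_medians: pd.Series  # candidate k -> median silhouette


def cluster_and_select_k(
    J: pd.DataFrame, k_min: int = 3, k_max: int = 20
) -> ClusterAssignment:
    """Complete-linkage clustering of similarity-matrix rows with silhouette k-selection.

    Rows of ``J`` are treated as feature vectors under Euclidean distance.
    The tree is cut at every k in [k_min, k_max] (truncated to n-1 with a
    warning) and k* maximizes the median per-sample silhouette, ties going to
    the smallest k.
    """
    n = len(J)
    if n < 4:
        raise ValueError("need at least 4 samples to cluster")
    if k_max > n - 1:
        logger.warning("k_max truncated from %d to %d", k_max, n - 1)
        k_max = n - 1
    d = pdist(J.to_numpy(dtype=float), metric="euclidean")
    Z = linkage(d, method="complete")
    D = squareform(d)
    results: dict[int, tuple[pd.Series, pd.Series, float]] = {}
    medians = {}
    for k in range(k_min, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_samples(D, labels, metric="precomputed")
        med = float(np.median(sil))
        medians[k] = med
        results[k] = (
            pd.Series(labels, index=J.index, name="cluster"),
            pd.Series(sil, index=J.index, name="silhouette"),
            med,
        )
    if not results:
        raise ValueError("no candidate k produced a valid clustering")
    k_medians = pd.Series(medians).sort_index()
    best_k = int(k_medians.index[np.argmax(k_medians.to_numpy())])  # ties -> smallest k
    labels, sil, med = results[best_k]
    return ClusterAssignment(
        labels=labels, k=best_k, silhouettes=sil, median_silhouette=med,
        k_medians=k_medians,
    )


def cluster_associations(
    assignment: ClusterAssignment, covariates: pd.DataFrame
) -> pd.DataFrame:
    """One-vs-rest association of each cluster with each covariate.

    Categorical covariates: per-level 2x2 Fisher's exact test with odds
    ratio; continuous covariates: two-sided Wilcoxon rank-sum with the median
    shift. P values are BH-corrected across all tests; single-level
    covariates are skipped and logged.
    """
    labels = assignment.labels.reindex(covariates.index)
    rows = []
    for cov in covariates.columns:
        series = covariates[cov].dropna()
        lab = labels.reindex(series.index)
        continuous = pd.api.types.is_numeric_dtype(series) and series.nunique() > 2
        if series.nunique() < 2:
            logger.warning("covariate %r has a single level; skipped", cov)
            continue
        for cluster in sorted(lab.dropna().unique()):
            in_c = lab == cluster
            if continuous:
                a, b = series[in_c], series[~in_c]
                if len(a) == 0 or len(b) == 0:
                    continue
                stat, p = mannwhitneyu(a, b, alternative="two-sided")
                rows.append(
                    {
                        "cluster": cluster, "covariate": cov, "level": "",
                        "test": "ranksum", "effect": float(a.median() - b.median()),
                        "p": float(p),
                    }
                )
            else:
                for level in sorted(series.unique(), key=str):
                    has = series == level
                    table = [
                        [int((in_c & has).sum()), int((in_c & ~has).sum())],
                        [int((~in_c & has).sum()), int((~in_c & ~has).sum())],
                    ]
                    odds, p = fisher_exact(table, alternative="two-sided")
                    rows.append(
                        {
                            "cluster": cluster, "covariate": cov,
                            "level": str(level), "test": "fisher",
                            "effect": float(odds), "p": float(p),
                        }
                    )
    result = pd.DataFrame(rows, columns=["cluster", "covariate", "level", "test", "effect", "p"])
    if not result.empty:
        _, fdr, _, _ = multipletests(result["p"], method="fdr_bh")
        result["fdr"] = np.maximum(fdr, result["p"])
    else:
        result["fdr"] = []
    return result
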