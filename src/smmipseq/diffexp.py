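"""Cluster-based differential expression with a signed fold-change convention.

The analysis mirrors the standard targeted-RNA-seq workflow: mean-FPM
transcript expression is log2-transformed with a 0.01 pseudocount, samples
are clustered unsupervised with Manhattan distance and UPGMA (average
linkage), the tree is cut into its two head clusters, and each transcript
is tested between clusters with a two-sided Wilcoxon Mann-Whitney U test
followed by Benjamini-Hochberg correction.  Fold changes are reported on
the FPM scale with the signed convention: ratio b/a when it is at least 1,
otherwise the negative reciprocal -a/b, so a 4-fold drop reads -4 rather
than 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from skbio.tree import TreeNode
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.01
EXACT_TEST_MAX_N = 8


class DiffExpError(ValueError):
    pass


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 0.01); the pseudocount guards zero-FPM entries."""
    if (matrix.values < 0).any():
        raise DiffExpError("expression values must be non-negative")
    return np.log2(matrix + PSEUDOCOUNT)


@dataclass
class ClusterTree:
    """UPGMA merge tree over samples (ultrametric heights)."""

    linkage_matrix: np.ndarray  # scipy condensed linkage
    sample_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def is_ultrametric(self) -> bool:
        """Merge heights must be non-decreasing from leaves to root."""
        h = self.heights
        return bool(np.all(np.diff(h) >= -1e-9))

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.sample_ids)
        return str(tree).strip()


def cluster_samples(log_matrix: pd.DataFrame) -> ClusterTree:
    """UPGMA over pairwise Manhattan distances between sample columns."""
    if log_matrix.shape[1] < 2:
        raise DiffExpError("need at least 2 samples to cluster")
    if log_matrix.isna().any().any():
        raise DiffExpError("missing values in expression matrix")
    dists = pdist(log_matrix.T.values, metric="cityblock")
    z = linkage(dists, method="average")
    return ClusterTree(linkage_matrix=z, sample_ids=list(log_matrix.columns))


def cut_two(
    tree: ClusterTree, healthy_samples: set[str] | None = None
) -> tuple[list[str], list[str]]:
    """Split at the root merge into the two head clusters (a, b).

    With tissue labels available, cluster a is the side holding the larger
    share of healthy-labeled samples (ties to the first-by-leaf-order
    side); without labels, the side containing the first sample is a.
    """
    flat = fcluster(tree.linkage_matrix, t=2, criterion="maxclust")
    sides = {1: [], 2: []}
    for sample, lab in zip(tree.sample_ids, flat):
        sides[lab].append(sample)
    one, two = sides[1], sides[2]
    if healthy_samples:
        share_one = sum(s in healthy_samples for s in one) / max(len(one), 1)
        share_two = sum(s in healthy_samples for s in two) / max(len(two), 1)
        if share_two > share_one:
            one, two = two, one
    elif tree.sample_ids[0] in two:
        one, two = two, one
    return one, two


def wilcoxon_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have at most 8 observations and no
    ties cross the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.  A completely constant pooled sample
    carries no rank information and returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DiffExpError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= EXACT_TEST_MAX_N and b.size <= EXACT_TEST_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DiffExpError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Fold change b/a, reported as -a/b when the ratio is below 1.

    Zero means map to signed infinity (direction preserved); both-zero is
    undefined.
    """
    if mean_a < 0 or mean_b < 0:
        raise DiffExpError("means must be non-negative")
    if mean_a == 0 and mean_b == 0:
        raise DiffExpError("fold change undefined when both means are zero")
    if mean_a == 0:
        return math.inf
    if mean_b == 0:
        return -math.inf
    r = mean_b / mean_a
    return r if r >= 1 else -1.0 / r


def differential_expression(
    fpm: pd.DataFrame,
    cluster_a: list[str],
    cluster_b: list[str],
    alpha_p: float = 0.05,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript cluster means, Wilcoxon p, BH FDR, signed FC.

    The rank test runs on FPM values directly (rank tests are invariant
    under the monotone log transform); means for the fold change are on
    the FPM scale.  ``significant`` requires p < alpha_p and FDR <
    alpha_fdr.
    """
    if not cluster_a or not cluster_b:
        raise DiffExpError("both clusters must be non-empty")
    a = fpm[cluster_a]
    b = fpm[cluster_b]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    pvals = np.array(
        [wilcoxon_test(a.loc[t].values, b.loc[t].values) for t in fpm.index]
    )
    fdr = bh_adjust(pvals)
    fc = np.array(
        [signed_fold_change(ma, mb) for ma, mb in zip(mean_a.values, mean_b.values)]
    )
    out = pd.DataFrame(
        {
            "mean_fpm_cluster_a": mean_a,
            "mean_fpm_cluster_b": mean_b,
            "p_value": pvals,
            "fdr": fdr,
            "fold_change": fc,
            "significant": (pvals < alpha_p) & (fdr < alpha_fdr),
        },
        index=fpm.index,
    )
    return out.sort_values(["fdr", "p_value"])


def write_results_table(results: pd.DataFrame, path) -> None:
    """Results TSV shaped like a differential-expression summary table."""
    table = results.rename(
        columns={
            "mean_fpm_cluster_a": "Mean FPM cluster a",
            "mean_fpm_cluster_b": "Mean FPM cluster b",
            "p_value": "P-value",
            "fdr": "FDR",
            "fold_change": "FC cluster b/a",
            "significant": "Significant?",
        }
    ).copy()
    table["Significant?"] = np.where(table["Significant?"], "Y", "N")
    table.index.name = "Gene"
    table.to_csv(path, sep="\t")
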