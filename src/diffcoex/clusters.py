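"""Conserved and divergent within-pathway co-expression clusters.

For a pathway gene set, genes are clustered separately in each condition by
average-linkage hierarchical clustering on the distance 1 − r (Pearson).
Clusters are labelled C1, C2, … in control and K1, K2, … in knockdown;
intersections of a C and a K cluster that are large enough form conserved
overlap clusters O1, O2, …. Genes in an O cluster are conserved
co-expressed; genes clustered in only one condition are divergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, SampleDesign, UP_IN_CONTROL, UP_IN_KNOCKDOWN

#: Average pairwise within-cluster correlation a reported cluster must reach.
DEFAULT_MIN_AVG_R = 0.65
#: Minimum cluster size.
DEFAULT_MIN_SIZE = 5

_CONDITION_PREFIX = {"control": "C", "knockdown": "K", "overlap": "O"}


@dataclass
class CoexpressionCluster:
    """A co-expression cluster of a pathway gene set.

    ``avg_r_control``/``avg_r_knockdown`` are the mean pairwise Pearson r
    over the cluster's genes in that condition's samples; only the defining
    condition's value is guaranteed populated, overlap clusters carry both.
    """

    cluster_id: str
    condition: str  # control | knockdown | overlap
    genes: frozenset[str]
    avg_r_control: float | None = None
    avg_r_knockdown: float | None = None
    source: tuple[str, str] | None = None  # (C_i, K_j) for overlap clusters
    de_split: tuple[int, int] | None = field(default=None, compare=False)

    @property
    def size(self) -> int:
        return len(self.genes)


def _condition_profiles(
    matrix: ExpressionMatrix, genes: list[str], condition: str, design: SampleDesign
) -> np.ndarray:
    samples = [s for s in matrix.sample_ids if design.condition.get(s) == condition]
    if len(samples) < 3:
        raise ValueError(f"need ≥3 samples in condition {condition!r}")
    return matrix.values.loc[genes, samples].to_numpy(dtype=float)


def _pairwise_r(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; zero-variance rows get r = 0."""
    sd = x.std(axis=1)
    safe = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / (safe[:, None] * np.sqrt(x.shape[1]))
    r = np.clip(z @ z.T, -1.0, 1.0)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def average_pairwise_r(r: np.ndarray, idx: np.ndarray) -> float:
    """Mean of r over all unordered gene pairs within ``idx``."""
    sub = r[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        return 1.0
    return float((sub.sum() - m) / (m * (m - 1)))


def cluster_condition(
    matrix: ExpressionMatrix,
    gene_set: set[str] | list[str],
    condition: str,
    design: SampleDesign,
    min_avg_r: float = DEFAULT_MIN_AVG_R,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[CoexpressionCluster]:
    """Find co-expression clusters of a pathway gene set in one condition.

    Average-linkage hierarchical clustering on 1 − r using only the
    condition's samples. The dendrogram is cut per branch: walking down
    from the root, every maximal subtree whose leaf set qualifies
    (size ≥ ``min_size`` and average pairwise r ≥ ``min_avg_r``) is
    reported as one cluster — so each co-expression module is recovered at
    its own natural height and a tight module is never split merely
    because another branch is loose. Qualifying clusters are labelled
    C1/K1, C2/K2, … in decreasing size order (ties by smallest member gene
    ID); everything else is left unclustered.
    """
    genes = sorted(set(gene_set) & set(matrix.gene_ids))
    if len(genes) < min_size:
        warnings.warn(
            f"gene set smaller than min_size ({len(genes)} < {min_size}); no clusters"
        )
        return []
    x = _condition_profiles(matrix, genes, condition, design)
    r = _pairwise_r(x)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))

    # per-branch cut: report every maximal qualifying subtree
    qualifying: list[np.ndarray] = []
    stack = [to_tree(link)]
    while stack:
        node = stack.pop()
        idx = np.array(node.pre_order(lambda leaf: leaf.id))
        if len(idx) >= min_size and average_pairwise_r(r, idx) >= min_avg_r:
            qualifying.append(idx)
        elif not node.is_leaf():
            stack.append(node.get_left())
            stack.append(node.get_right())

    prefix = _CONDITION_PREFIX[condition]
    clusters: list[CoexpressionCluster] = []
    for idx in qualifying:
        avg = average_pairwise_r(r, idx)
        members = frozenset(genes[i] for i in idx)
        clusters.append(
            CoexpressionCluster(
                cluster_id="",  # assigned after sorting
                condition=condition,
                genes=members,
                avg_r_control=avg if condition == "control" else None,
                avg_r_knockdown=avg if condition == "knockdown" else None,
            )
        )
    clusters.sort(key=lambda c: (-c.size, min(c.genes)))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"{prefix}{i}"
    return clusters


def _avg_r_for(
    matrix: ExpressionMatrix, genes: list[str], condition: str, design: SampleDesign
) -> float:
    x = _condition_profiles(matrix, genes, condition, design)
    r = _pairwise_r(x)
    return average_pairwise_r(r, np.arange(len(genes)))


def find_overlap_clusters(
    clusters_ctl: list[CoexpressionCluster],
    clusters_kd: list[CoexpressionCluster],
    matrix: ExpressionMatrix | None = None,
    design: SampleDesign | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[CoexpressionCluster]:
    """Conserved clusters: C×K intersections of at least ``min_size`` genes.

    When the expression matrix and design are supplied each O cluster is
    annotated with its own average within-cluster r in both conditions.
    """
    overlaps: list[CoexpressionCluster] = []
    for c in clusters_ctl:
        for k in clusters_kd:
            inter = c.genes & k.genes
            if len(inter) < min_size:
                continue
            genes = sorted(inter)
            avg_c = avg_k = None
            if matrix is not None and design is not None:
                avg_c = _avg_r_for(matrix, genes, "control", design)
                avg_k = _avg_r_for(matrix, genes, "knockdown", design)
            overlaps.append(
                CoexpressionCluster(
                    cluster_id="",
                    condition="overlap",
                    genes=frozenset(inter),
                    avg_r_control=avg_c,
                    avg_r_knockdown=avg_k,
                    source=(c.cluster_id, k.cluster_id),
                )
            )
    overlaps.sort(key=lambda c: (-c.size, min(c.genes)))
    for i, c in enumerate(overlaps, start=1):
        c.cluster_id = f"O{i}"
    return overlaps


def classify_coexpression(
    gene_set: set[str] | list[str],
    clusters_ctl: list[CoexpressionCluster],
    clusters_kd: list[CoexpressionCluster],
    overlaps: list[CoexpressionCluster],
) -> pd.Series:
    """Label each pathway gene conserved, divergent or unclustered.

    Conserved: member of any overlap (O) cluster. Divergent: member of a C
    or K cluster but of no O cluster. Unclustered: everything else.
    """
    in_o = set().union(*(c.genes for c in overlaps)) if overlaps else set()
    in_ck = set().union(
        *(c.genes for c in clusters_ctl), *(c.genes for c in clusters_kd)
    ) if (clusters_ctl or clusters_kd) else set()
    labels = {}
    for g in sorted(set(gene_set)):
        if g in in_o:
            labels[g] = "conserved"
        elif g in in_ck:
            labels[g] = "divergent"
        else:
            labels[g] = "unclustered"
    return pd.Series(labels, name="coexpression_class")


def summarize_pathway(
    clusters: list[CoexpressionCluster],
    de: pd.DataFrame,
    fold_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-cluster summary: size, average r, DE member counts by direction.

    The DE split counts member genes at or above ``fold_threshold``,
    reported as under-/over-expressed in knockdown (i.e. higher in control /
    higher in knockdown), mirroring cluster summary tables.
    """
    rows = []
    for c in clusters:
        members = de.index.intersection(sorted(c.genes))
        sub = de.loc[members]
        hit = sub[sub["fold_change"] >= fold_threshold]
        under = int((hit["direction"] == UP_IN_CONTROL).sum())
        over = int((hit["direction"] == UP_IN_KNOCKDOWN).sum())
        c.de_split = (under, over)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "condition": c.condition,
                "n_genes": c.size,
                "avg_r_control": np.nan if c.avg_r_control is None else c.avg_r_control,
                "avg_r_knockdown": np.nan if c.avg_r_knockdown is None else c.avg_r_knockdown,
                "n_de_under": under,
                "n_de_over": over,
                "de_split": f"{under}/{over}",
            }
        )
    return pd.DataFrame(rows)
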