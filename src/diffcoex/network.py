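"""Condition-specific co-expression networks with scale-free threshold selection.

A co-expression network connects gene pairs whose Pearson correlation over
one condition's samples reaches a threshold r. The threshold is chosen by
the scale-free criterion: among a grid of candidate r values, keep the
smallest one whose degree distribution P(k) fits a power law, judged by the
squared correlation (R²) between log P(k) and log k. Connectivity (degree)
ranks define hub genes, and hub lists are compared across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, SampleDesign

#: Grid of candidate correlation thresholds scanned by default.
DEFAULT_THRESHOLD_GRID = (0.75, 0.80, 0.85, 0.90)

#: Minimum log-log fit R² for a degree distribution to count as scale-free.
DEFAULT_MIN_FIT_R2 = 0.80

#: Genes per block when forming the correlation matrix (bounds peak memory).
_CORR_BLOCK = 512


@dataclass
class CorrelationMatrix:
    """Symmetric gene × gene Pearson correlation matrix for one condition."""

    gene_ids: pd.Index
    values: np.ndarray
    zero_variance_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")


@dataclass
class ScaleFreeFit:
    """Least-squares line of log10 P(k) on log10 k and its goodness of fit."""

    slope: float
    intercept: float
    fit_r2: float
    n_points: int
    valid: bool


def pairwise_correlation(
    matrix: ExpressionMatrix, condition: str, design: SampleDesign
) -> CorrelationMatrix:
    """All-pairs Pearson r over the samples belonging to one condition.

    Genes with zero variance in the condition are assigned r = 0 against
    every other gene and listed in ``zero_variance_genes``. Computed in
    blocks so the full matrix, not intermediates, dominates memory.
    """
    samples = [s for s in matrix.sample_ids if design.condition.get(s) == condition]
    if len(samples) < 3:
        raise ValueError(f"need ≥3 samples in condition {condition!r}, found {len(samples)}")
    x = matrix.values[samples].to_numpy(dtype=float)
    n_genes = x.shape[0]

    sd = x.std(axis=1)
    zero_var = sd == 0
    centered = x - x.mean(axis=1, keepdims=True)
    denom = np.where(zero_var, 1.0, sd * np.sqrt(x.shape[1]))
    z = centered / denom[:, None]  # rows have unit norm (or zero)

    corr = np.empty((n_genes, n_genes), dtype=float)
    for i0 in range(0, n_genes, _CORR_BLOCK):
        i1 = min(i0 + _CORR_BLOCK, n_genes)
        corr[i0:i1] = z[i0:i1] @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    zv_genes = frozenset(matrix.gene_ids[zero_var])
    return CorrelationMatrix(matrix.gene_ids, corr, zv_genes)


def build_network(
    corr: CorrelationMatrix, threshold: float, absolute_r: bool = False
) -> nx.Graph:
    """Keep an edge wherever the (signed) correlation is at or above threshold.

    Signed r by default — only positive co-expression links; ``absolute_r``
    switches to |r| ≥ threshold. The comparison is inclusive. All genes are
    kept as nodes so degree-0 genes stay in the degree distribution.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    vals = np.abs(corr.values) if absolute_r else corr.values
    iu, ju = np.triu_indices(len(corr.gene_ids), k=1)
    keep = vals[iu, ju] >= threshold
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(corr.gene_ids)
    genes = corr.gene_ids.to_numpy()
    g.add_edges_from(
        (genes[i], genes[j], {"r": corr.values[i, j]})
        for i, j in zip(iu[keep], ju[keep])
    )
    return g


def degree_distribution(net: nx.Graph) -> pd.DataFrame:
    """Exact node counts and P(k) for every observed degree, k = 0 included."""
    degrees = np.array([d for _, d in net.degree()], dtype=int)
    ks, counts = np.unique(degrees, return_counts=True)
    total = len(degrees)
    return pd.DataFrame({"k": ks, "count": counts, "p_k": counts / total})


def scale_free_fit(dist: pd.DataFrame) -> ScaleFreeFit:
    """Fit log10 P(k) against log10 k over k ≥ 1 points.

    fit_r2 is the squared Pearson correlation of the log-log points; the fit
    is marked invalid (fit_r2 = 0) with fewer than 3 distinct k ≥ 1 points
    or zero variance in log P(k).
    """
    pts = dist[(dist["k"] >= 1) & (dist["p_k"] > 0)]
    if len(pts) < 3:
        return ScaleFreeFit(np.nan, np.nan, 0.0, len(pts), valid=False)
    log_k = np.log10(pts["k"].to_numpy(dtype=float))
    log_p = np.log10(pts["p_k"].to_numpy(dtype=float))
    if np.ptp(log_p) == 0 or np.ptp(log_k) == 0:
        return ScaleFreeFit(np.nan, np.nan, 0.0, len(pts), valid=False)
    slope, intercept = np.polyfit(log_k, log_p, 1)
    r = stats.pearsonr(log_k, log_p).statistic
    return ScaleFreeFit(slope, intercept, r * r, len(pts), valid=True)


def select_threshold(
    corr: CorrelationMatrix,
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    min_fit_r2: float = DEFAULT_MIN_FIT_R2,
    absolute_r: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Scan the threshold grid and pick the smallest r passing the criterion.

    Returns the selected threshold and a per-grid report (threshold, edges,
    fit R², slope, valid). Raises if no grid value reaches ``min_fit_r2``.
    """
    if list(grid) != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    rows = []
    selected = None
    for thr in grid:
        net = build_network(corr, thr, absolute_r=absolute_r)
        fit = scale_free_fit(degree_distribution(net))
        rows.append(
            {
                "threshold": thr,
                "n_edges": net.number_of_edges(),
                "fit_r2": fit.fit_r2,
                "slope": fit.slope,
                "valid": fit.valid,
            }
        )
        if selected is None and fit.valid and fit.fit_r2 >= min_fit_r2:
            selected = thr
    report = pd.DataFrame(rows)
    if selected is None:
        raise ValueError(
            "no grid threshold satisfies the scale-free criterion "
            f"(min fit R² = {min_fit_r2}):\n{report.to_string(index=False)}"
        )
    return selected, report


def connectivity(net: nx.Graph) -> pd.Series:
    """Degree (connectivity k) per gene."""
    return pd.Series(dict(net.degree()), name="k").sort_index()


def hub_ranking(net: nx.Graph) -> list[str]:
    """Genes ranked by descending connectivity, ties broken by gene ID."""
    deg = dict(net.degree())
    return sorted(deg, key=lambda g: (-deg[g], g))


def compare_networks(
    net_ctl: nx.Graph,
    net_kd: nx.Graph,
    top_n_list: tuple[int, ...] = (100, 300),
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-gene connectivity in both networks plus top-N hub-list overlaps.

    Genes absent from one network count as degree 0 there. Each gene is
    classified ``retained`` (edges in both), ``lost`` (control only),
    ``gained`` (knockdown only) or ``absent``. The overlap counts are the
    sizes of the intersections of the two top-N hub lists.
    """
    genes = sorted(set(net_ctl.nodes) | set(net_kd.nodes))
    k_ctl = pd.Series({g: net_ctl.degree(g) if g in net_ctl else 0 for g in genes})
    k_kd = pd.Series({g: net_kd.degree(g) if g in net_kd else 0 for g in genes})

    order_ctl = hub_ranking(net_ctl)
    order_kd = hub_ranking(net_kd)
    rank_ctl = {g: i + 1 for i, g in enumerate(order_ctl)}
    rank_kd = {g: i + 1 for i, g in enumerate(order_kd)}

    status = np.select(
        [
            (k_ctl > 0) & (k_kd > 0),
            (k_ctl > 0) & (k_kd == 0),
            (k_ctl == 0) & (k_kd > 0),
        ],
        ["retained", "lost", "gained"],
        default="absent",
    )
    table = pd.DataFrame(
        {
            "k_control": k_ctl,
            "k_knockdown": k_kd,
            "rank_control": [rank_ctl.get(g, np.nan) for g in genes],
            "rank_knockdown": [rank_kd.get(g, np.nan) for g in genes],
            "status": status,
        },
        index=pd.Index(genes, name="gene"),
    )
    overlaps = {
        n: len(set(order_ctl[:n]) & set(order_kd[:n])) for n in top_n_list
    }
    return table, overlaps
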