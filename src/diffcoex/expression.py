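"""Expression preprocessing and differential expression.

The pipeline's expression stage mirrors the standard two-channel-free
microarray workflow: quantile normalization across samples, conversion to
log2 ratios against each gene's mean, per-gene two-sample t-tests between
the control and knockdown groups with Benjamini-Hochberg FDR adjustment,
and fold-change classification at inclusive thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL = "control"
KNOCKDOWN = "knockdown"

#: Direction labels for differential expression.
UP_IN_CONTROL = "up_in_control"
UP_IN_KNOCKDOWN = "up_in_knockdown"
NONE = "none"

#: |Δlog2| below this is treated as no change (direction "none").
_DIRECTION_TIE_EPS = 1e-12


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    scale
        ``"intensity"`` (strictly positive raw/normalized intensities) or
        ``"log2ratio"`` (log2 of intensity over the per-gene mean).
    """

    values: pd.DataFrame
    scale: str = "intensity"

    def __post_init__(self) -> None:
        if self.scale not in ("intensity", "log2ratio"):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        if self.scale == "intensity" and (self.values.to_numpy() <= 0).any():
            bad = self.values.index[(self.values <= 0).any(axis=1)]
            raise ValueError(f"non-positive intensities, e.g. gene {bad[0]!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SampleDesign:
    """Maps each sample to its condition (control / knockdown) and replicate."""

    condition: dict[str, str]
    replicate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.condition.values()} - {CONTROL, KNOCKDOWN}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        cond = dict(zip(df["sample_id"], df["condition"]))
        rep = dict(zip(df["sample_id"], df["replicate"])) if "replicate" in df else {}
        return cls(condition=cond, replicate=rep)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "condition": c, "replicate": self.replicate.get(s, i + 1)}
            for i, (s, c) in enumerate(self.condition.items())
        ]
        return pd.DataFrame(rows)

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.condition.items() if c == condition]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.condition]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        for cond in (CONTROL, KNOCKDOWN):
            n = sum(1 for s in matrix.sample_ids if self.condition.get(s) == cond)
            if n < 2:
                raise ValueError(f"need ≥2 samples in {cond!r}, found {n}")


# ---------------------------------------------------------------------------
# normalization

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one value distribution.

    Each column's sorted values are replaced by the row means of the
    column-sorted matrix; within-column rank order is preserved (ties broken
    by position, which makes the operation exactly idempotent).
    """
    if matrix.scale != "intensity":
        raise ValueError("quantile normalization expects intensity scale")
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return ExpressionMatrix(matrix.values.copy(), scale="intensity")
    order = np.argsort(vals, axis=0, kind="stable")
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[order[:, j], j] = mean_sorted
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
        scale="intensity",
    )


def to_log2_ratio(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert intensities to log2 ratios over each gene's mean across samples.

    y_gs = log2(x_gs / mean_s x_g·), so per gene the mean of 2**y is 1.
    """
    if matrix.scale != "intensity":
        raise ValueError("expected intensity scale")
    vals = matrix.values.to_numpy(dtype=float)
    ratios = np.log2(vals / vals.mean(axis=1, keepdims=True))
    return ExpressionMatrix(
        pd.DataFrame(ratios, index=matrix.gene_ids, columns=matrix.sample_ids),
        scale="log2ratio",
    )


# ---------------------------------------------------------------------------
# differential expression

def differential_expression(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    detection_threshold: float,
    intensities: ExpressionMatrix | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between control and knockdown with BH FDR.

    Parameters
    ----------
    matrix
        log2-ratio (or otherwise log2-scale) matrix to test on.
    design
        Sample-to-condition assignment; ≥2 samples per condition.
    detection_threshold
        Mean-intensity level a gene must reach in at least one condition to
        be flagged ``expressed`` (evaluated on ``intensities``).
    intensities
        Pre-transform intensity matrix used for the expressed flag; when
        omitted every gene is flagged expressed.
    equal_var
        Use the pooled-variance Student t-test instead of Welch.

    Returns
    -------
    DataFrame indexed by gene with columns mean_control, mean_knockdown,
    fold_change, direction, t, p, q, expressed, zero_variance.
    Fold change is 2**|Δ| of the group means (a ratio ≥ 1); direction says
    which condition is higher. Zero-variance genes get p = 1 and a flag.
    """
    design.validate_against(matrix)
    ctl = [s for s in matrix.sample_ids if design.condition[s] == CONTROL]
    kd = [s for s in matrix.sample_ids if design.condition[s] == KNOCKDOWN]

    a = matrix.values[ctl].to_numpy(dtype=float)
    b = matrix.values[kd].to_numpy(dtype=float)
    mean_c, mean_k = a.mean(axis=1), b.mean(axis=1)
    delta = mean_c - mean_k

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger precision warnings; they are handled
        # explicitly below via the zero-variance flag
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t_stat = np.where(zero_var | ~np.isfinite(t_stat), 0.0, t_stat)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)

    q = benjamini_hochberg(p)

    fold = np.exp2(np.abs(delta))
    direction = np.where(
        np.abs(delta) < _DIRECTION_TIE_EPS, NONE,
        np.where(delta > 0, UP_IN_CONTROL, UP_IN_KNOCKDOWN),
    )

    if intensities is not None:
        iv = intensities.values.reindex(matrix.gene_ids)
        expressed = (
            (iv[ctl].mean(axis=1) >= detection_threshold)
            | (iv[kd].mean(axis=1) >= detection_threshold)
        ).to_numpy()
    else:
        expressed = np.ones(len(matrix.gene_ids), dtype=bool)

    return pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_knockdown": mean_k,
            "fold_change": fold,
            "direction": direction,
            "t": t_stat,
            "p": p,
            "q": q,
            "expressed": expressed,
            "zero_variance": zero_var,
        },
        index=matrix.gene_ids,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), monotone in p-rank."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def classify_by_fold(
    de: pd.DataFrame, thresholds: tuple[float, ...] = (1.5, 2.0)
) -> pd.DataFrame:
    """Count genes at or above each fold-change threshold, split by direction.

    The comparison is inclusive (fold_change ≥ threshold), matching how
    "≥1.5-fold" classes are reported.
    """
    rows = []
    for thr in thresholds:
        hit = de[de["fold_change"] >= thr]
        rows.append(
            {
                "threshold": thr,
                "total": len(hit),
                UP_IN_CONTROL: int((hit["direction"] == UP_IN_CONTROL).sum()),
                UP_IN_KNOCKDOWN: int((hit["direction"] == UP_IN_KNOCKDOWN).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("threshold")
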