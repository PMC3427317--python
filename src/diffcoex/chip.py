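"""ChIP peak → promoter target assignment and histone-state classification.

Peaks (BED, 0-based half-open) are intersected with strand-aware promoter
windows around annotated TSSs. Two window presets reflect the two mapping
conventions used for factor binding data: the tiling-array convention of
8 kb upstream / 2 kb downstream, and the tag-mapping convention of ±1 kb
around the TSS. Binding calls above a signal-ratio threshold (default 2.2×
over unbound background regions) are counted per replicate, and genes are
summarised by replicate support (bound in ≥1, ≥2, … all replicates).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

#: Signal ratio over unbound background at or above which a call is positive.
DEFAULT_SIGNAL_THRESHOLD = 2.2

#: Window presets: (upstream bp, downstream bp) of the TSS.
WINDOW_PRESETS = {"chipchip": (8000, 2000), "chipseq": (1000, 1000)}


@dataclass
class GenomeAnnotation:
    """Per-gene chromosome, TSS (0-based) and strand."""

    genes: pd.DataFrame  # columns: gene, chrom, tss, strand

    def __post_init__(self) -> None:
        df = self.genes
        if df["gene"].duplicated().any():
            raise ValueError("duplicate gene IDs in annotation")
        if (df["tss"] < 0).any():
            raise ValueError("negative TSS")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand for genes: {list(df.loc[bad, 'gene'])}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeAnnotation":
        return cls(df[["gene", "chrom", "tss", "strand"]].copy())

    def to_frame(self) -> pd.DataFrame:
        return self.genes.copy()


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter interval [start, end) around a gene's TSS."""

    gene: str
    chrom: str
    start: int
    end: int
    preset: str = "custom"


@dataclass(frozen=True)
class Peak:
    """A binding interval [start, end) for one factor in one replicate."""

    chrom: str
    start: int
    end: int
    factor: str
    replicate: int
    signal_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty peak interval [{self.start}, {self.end})")
        if self.signal_ratio is not None and self.signal_ratio <= 0:
            raise ValueError("signal_ratio must be positive")


@dataclass
class TargetCallSet:
    """Per-replicate promoter-binding calls for one factor."""

    factor: str
    replicate_targets: dict[int, set[str]]
    qc: dict[str, int] = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_targets)

    def support(self) -> pd.Series:
        """Number of replicates in which each gene is called bound."""
        counts: dict[str, int] = defaultdict(int)
        for targets in self.replicate_targets.values():
            for g in targets:
                counts[g] += 1
        return pd.Series(counts, name="support", dtype=int).sort_index()

    def targets_with_support(self, min_replicates: int) -> set[str]:
        s = self.support()
        return set(s.index[s >= min_replicates])


def promoter_windows(
    annot: GenomeAnnotation,
    upstream: int,
    downstream: int,
    preset: str = "custom",
) -> list[PromoterWindow]:
    """Build strand-aware promoter windows around each TSS.

    Plus strand: [tss − upstream, tss + downstream); minus strand the mirror
    image [tss − downstream, tss + upstream). Starts are clamped at 0.
    """
    if upstream < 0 or downstream < 0 or (upstream == 0 and downstream == 0):
        raise ValueError("need non-negative window sizes, not both zero")
    windows = []
    for row in annot.genes.itertuples(index=False):
        if row.strand == "+":
            start, end = row.tss - upstream, row.tss + downstream
        else:
            start, end = row.tss - downstream, row.tss + upstream
        windows.append(
            PromoterWindow(row.gene, row.chrom, max(0, start), end, preset)
        )
    return windows


def windows_preset(annot: GenomeAnnotation, preset: str) -> list[PromoterWindow]:
    up, down = WINDOW_PRESETS[preset]
    return promoter_windows(annot, up, down, preset=preset)


def call_bound_promoters(
    signals: pd.Series, threshold: float = DEFAULT_SIGNAL_THRESHOLD
) -> tuple[pd.Series, dict[str, int]]:
    """Flag promoters whose signal ratio over background reaches threshold.

    The comparison is inclusive (ratio ≥ threshold is bound). Missing
    ratios are treated as unbound and tallied in the QC report.
    """
    missing = int(signals.isna().sum())
    bound = signals.ge(threshold).fillna(False)
    return bound.astype(bool), {"missing_signal": missing}


def assign_targets(
    peaks: list[Peak], windows: list[PromoterWindow]
) -> dict[str, TargetCallSet]:
    """Assign each peak to every promoter window it overlaps by ≥ 1 bp.

    Overlap is half-open interval intersection; one peak may hit several
    windows and a gene becomes a replicate's target if any of that
    replicate's peaks overlaps its window. Peaks on chromosomes absent from
    the annotation are skipped and counted in the QC report.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for w in windows:
        if w.start < w.end:
            trees[w.chrom].addi(w.start, w.end, w.gene)
    known_chroms = set(trees)

    calls: dict[str, TargetCallSet] = {}
    skipped: dict[str, int] = defaultdict(int)
    for p in peaks:
        cs = calls.setdefault(
            p.factor, TargetCallSet(p.factor, replicate_targets={})
        )
        cs.replicate_targets.setdefault(p.replicate, set())
        if p.chrom not in known_chroms:
            skipped[p.factor] += 1
            continue
        for hit in trees[p.chrom].overlap(p.start, p.end):
            cs.replicate_targets[p.replicate].add(hit.data)
    for factor, cs in calls.items():
        cs.qc["peaks_on_unknown_chrom"] = skipped.get(factor, 0)
    return calls


def replicate_support(calls: TargetCallSet) -> pd.Series:
    """Cumulative counts of genes bound in at least t replicates, t = 1..n.

    "Bound in t samples" is read cumulatively (≥ t), so the counts are
    non-increasing in t by construction.
    """
    if calls.n_replicates < 1:
        raise ValueError("need at least one replicate")
    support = calls.support()
    counts = {
        t: int((support >= t).sum()) for t in range(1, calls.n_replicates + 1)
    }
    out = pd.Series(counts, name="n_genes")
    out.index.name = "min_replicates"
    assert (out.diff().dropna() <= 0).all(), "cumulative counts must be non-increasing"
    return out


def histone_state(
    genes: list[str] | set[str], k4_targets: set[str], k27_targets: set[str]
) -> pd.Series:
    """Four-way histone classification per gene.

    active: H3K4me3 only; repressed: H3K27me3 only; bivalent: both marks;
    none: neither. States are mutually exclusive and exhaustive.
    """
    labels = {}
    for g in sorted(set(genes)):
        k4, k27 = g in k4_targets, g in k27_targets
        if k4 and k27:
            labels[g] = "bivalent"
        elif k4:
            labels[g] = "active"
        elif k27:
            labels[g] = "repressed"
        else:
            labels[g] = "none"
    return pd.Series(labels, name="histone_state")


def histone_fractions(states: pd.Series) -> pd.DataFrame:
    """Counts and fractions of each histone state over a gene set."""
    counts = states.value_counts().reindex(
        ["active", "repressed", "bivalent", "none"], fill_value=0
    )
    return pd.DataFrame({"count": counts, "fraction": counts / max(len(states), 1)})
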