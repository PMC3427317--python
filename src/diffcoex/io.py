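"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything tabular is TSV with a header row; genomic intervals are 6-column
BED (0-based, half-open); gene sets are GMT. These formats are simple enough
that pandas covers them directly; the helpers here pin the column contracts
so every stage agrees on them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .expression import ExpressionMatrix, SampleDesign
from .chip import GenomeAnnotation, Peak

# ---------------------------------------------------------------------------
# expression matrix + design

def read_expression_tsv(path: str | Path, scale: str = "intensity") -> ExpressionMatrix:
    """Read a genes × samples matrix; first column is the gene ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_design_tsv(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleDesign.from_frame(df)


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome annotation + peaks

def read_annotation_tsv(path: str | Path) -> GenomeAnnotation:
    """Read gene/TSS annotation: columns gene, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    return GenomeAnnotation.from_frame(df)


def write_annotation_tsv(annot: GenomeAnnotation, path: str | Path) -> None:
    annot.to_frame().to_csv(path, sep="\t", index=False)


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peaks from 6-column BED; the name field encodes ``factor:replicate``."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            factor, _, rep = name.partition(":")
            score = fields[4] if len(fields) > 4 else "."
            signal = float(score) if score not in (".", "") else None
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, factor=factor,
                     replicate=int(rep) if rep else 0, signal_ratio=signal)
            )
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.signal_ratio is None else f"{p.signal_ratio:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.factor}:{p.replicate}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# JSON (truth, manifests)

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
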