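"""Peak-to-gene assignment via promoter windows and expression classification.

A gene is a candidate target when a high-confidence peak overlaps its promoter
window (default -1,200 bp to +300 bp around the TSS, strand-aware). Targets
are then classified by their relative expression level (REL, log2 ratio vs the
wild-type calibrator): up in the heterologous-expression (HE) line when
REL >= 1, down when REL <= -1, and "dependent" when a gene up in the HE line
is simultaneously down in the knockout/mutant line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import math

import pandas as pd
from intervaltree import IntervalTree

from .array_io import GeneModel
from .errors import ValidationError
from .peak_caller import Peak

DEFAULT_UPSTREAM = 1200
DEFAULT_DOWNSTREAM = 300
UP_THRESH = 1.0
DOWN_THRESH = -1.0

CATEGORY_UP = "up_in_HE"
CATEGORY_DOWN = "down_in_HE"
CATEGORY_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int   # 0-based half-open
    end: int
    strand: str


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    peak_ids: Tuple[str, ...]
    rel_he: float
    rel_m: float
    category: str
    esnac1_dependent: bool


def promoter_window(
    gene: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chrom_length: Optional[int] = None,
) -> PromoterWindow:
    """Strand-aware promoter window around the TSS, clipped to the chromosome."""
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream/downstream must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        raise ValidationError(f"gene {gene.gene_id}: promoter window lies off-chromosome")
    return PromoterWindow(gene.gene_id, gene.chrom, start, end, gene.strand)


def promoter_windows(
    genes: Iterable[GeneModel],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> List[PromoterWindow]:
    wins = [
        promoter_window(
            g, upstream, downstream,
            chrom_lengths.get(g.chrom) if chrom_lengths else None,
        )
        for g in genes
    ]
    wins.sort(key=lambda w: (w.chrom, w.start))
    return wins


def assign_peaks_to_genes(
    peaks: Sequence[Peak], windows: Sequence[PromoterWindow]
) -> Dict[str, List[str]]:
    """Map gene_id -> peak_ids for every window a peak overlaps by >= 1 bp.

    Half-open intervals: abutting peak/window pairs do not overlap. A peak
    spanning two windows is assigned to both genes.
    """
    trees: Dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w.gene_id)
    hits: Dict[str, set] = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start)):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(p.start, p.end):
            hits.setdefault(iv.data, set()).add(p.peak_id)
    return {g: sorted(ids) for g, ids in sorted(hits.items())}


def classify_expression(
    rel_he: float,
    rel_m: float,
    up_thresh: float = UP_THRESH,
    down_thresh: float = DOWN_THRESH,
) -> Tuple[str, bool]:
    """(category, dependent) from log2 RELs; thresholds are inclusive."""
    if not (math.isfinite(rel_he) and math.isfinite(rel_m)):
        raise ValidationError("REL values must be finite")
    if rel_he >= up_thresh:
        category = CATEGORY_UP
    elif rel_he <= down_thresh:
        category = CATEGORY_DOWN
    else:
        category = CATEGORY_UNCHANGED
    dependent = (rel_he >= up_thresh) and (rel_m <= down_thresh)
    return category, dependent


def build_target_calls(
    assignments: Mapping[str, Sequence[str]],
    expression: pd.DataFrame,
    up_thresh: float = UP_THRESH,
    down_thresh: float = DOWN_THRESH,
) -> List[TargetCall]:
    """TargetCalls for every gene with >= 1 assigned peak; sorted, unique."""
    expr = expression.set_index("gene_id")
    calls: List[TargetCall] = []
    for gene_id in sorted(assignments):
        if gene_id not in expr.index:
            raise ValidationError(f"gene {gene_id} has peaks but no expression entry")
        rel_he = float(expr.at[gene_id, "rel_he"])
        rel_m = float(expr.at[gene_id, "rel_m"])
        category, dependent = classify_expression(rel_he, rel_m, up_thresh, down_thresh)
        calls.append(TargetCall(
            gene_id=gene_id,
            peak_ids=tuple(sorted(assignments[gene_id])),
            rel_he=rel_he,
            rel_m=rel_m,
            category=category,
            esnac1_dependent=dependent,
        ))
    return calls


def target_calls_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "peak_ids": [",".join(c.peak_ids) for c in calls],
            "rel_he": [c.rel_he for c in calls],
            "rel_m": [c.rel_m for c in calls],
            "category": [c.category for c in calls],
            "dependent": [c.esnac1_dependent for c in calls],
        }
    )
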