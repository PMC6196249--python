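"""Promoter motif-context analysis: CATG/CACG counts and TATA-box distances.

Promoters are anchored on the start codon (the 2,000 bp ending at the A of
ATG), motifs are counted as overlapping exact forward-strand matches, the
TATA-box is located with the degenerate consensus TATAWAW (3'-most instance,
i.e. the one closest to the start codon), and each promoter contributes the
distance from its TATA-box to the nearest occurrence of each motif. CATG is
its own reverse complement, so strand choice cannot change its count; CACG is
counted on the promoter strand only by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .array_io import GeneModel
from .errors import ValidationError

DEFAULT_PROMOTER_LENGTH = 2000
DEFAULT_TATA_PATTERN = "TATAWAW"
DEFAULT_MOTIFS = ("CATG", "CACG")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifSummary:
    """Per-promoter motif counts, TATA position and nearest motif-TATA distances."""

    gene_id: str
    promoter_length: int
    count_catg: int
    count_cacg: int
    tata_position: Optional[int]
    dist_catg: Optional[int]
    dist_cacg: Optional[int]
    rel_he: float = float("nan")


def extract_promoter(
    genome: Mapping[str, str], gene: GeneModel, length: int = DEFAULT_PROMOTER_LENGTH
) -> str:
    """Promoter sequence 5'->3' with the start codon adjacent to the 3' end.

    '+' strand: bases [cds_start - length, cds_start), clipped at 0.
    '-' strand: reverse complement of [cds_start, cds_start + length), clipped
    at the chromosome end.
    """
    if length <= 0:
        raise ValidationError("promoter length must be positive")
    if gene.chrom not in genome:
        raise ValidationError(f"chromosome {gene.chrom!r} absent from genome")
    seq = genome[gene.chrom]
    if not (0 <= gene.cds_start < len(seq)):
        raise ValidationError(f"gene {gene.gene_id}: cds_start outside chromosome")
    if gene.strand == "+":
        return seq[max(0, gene.cds_start - length): gene.cds_start]
    fwd = seq[gene.cds_start: min(len(seq), gene.cds_start + length)]
    return str(Seq(fwd).reverse_complement())


def find_motif_positions(seq: str, motif: str) -> List[int]:
    """Start offsets of all (possibly overlapping) exact matches."""
    if not motif:
        raise ValidationError("motif must be non-empty")
    pat = re.compile(f"(?={re.escape(motif.upper())})")
    return [m.start() for m in pat.finditer(seq.upper())]


def count_motif(seq: str, motif: str, both_strands: bool = False) -> int:
    """Number of overlapping exact forward-strand occurrences (N never matches).

    ``both_strands=True`` additionally counts occurrences of the motif's
    reverse complement on the given strand (equivalent to scanning the other
    strand); off by default, and a no-op for palindromic motifs like CATG.
    """
    n = len(find_motif_positions(seq, motif))
    if both_strands:
        rc = str(Seq(motif.upper()).reverse_complement())
        if rc != motif.upper():
            n += len(find_motif_positions(seq, rc))
    return n


def iupac_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC[ch] for ch in pattern.upper())
    except KeyError as exc:
        raise ValidationError(f"invalid IUPAC code {exc.args[0]!r} in pattern {pattern!r}") from exc


def find_tata_box(promoter: str, pattern: str = DEFAULT_TATA_PATTERN) -> Optional[int]:
    """Start offset of the 3'-most TATA-box match; None when absent."""
    if not promoter:
        raise ValidationError("promoter sequence is empty")
    pat = re.compile(f"(?={iupac_regex(pattern)})")
    best: Optional[int] = None
    for m in pat.finditer(promoter.upper()):
        best = m.start()
    return best


def nearest_motif_to_tata(
    promoter: str, motif: str, tata_offset: int, rule: str = "nearest"
) -> Optional[int]:
    """Distance (bp) from the TATA-box to a motif occurrence; None if absent.

    ``rule='nearest'`` takes the minimum |start - tata_offset| over all
    occurrences; ``rule='threeprime'`` uses the 3'-most occurrence instead
    (the alternative reading of a "latest distance").
    """
    if not (0 <= tata_offset < len(promoter)):
        raise ValidationError("tata_offset outside the promoter")
    positions = find_motif_positions(promoter, motif)
    if not positions:
        return None
    if rule == "nearest":
        return min(abs(p - tata_offset) for p in positions)
    if rule == "threeprime":
        return abs(max(positions) - tata_offset)
    raise ValidationError(f"unknown distance rule {rule!r}")


def summarize_promoter(
    gene_id: str,
    promoter: str,
    rel_he: float = float("nan"),
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    tata_pattern: str = DEFAULT_TATA_PATTERN,
    distance_rule: str = "nearest",
) -> MotifSummary:
    counts = {m: count_motif(promoter, m) for m in motifs}
    tata = find_tata_box(promoter, tata_pattern)
    dists: Dict[str, Optional[int]] = {}
    for m in motifs:
        if tata is None or counts[m] == 0:
            dists[m] = None
        else:
            dists[m] = nearest_motif_to_tata(promoter, m, tata, distance_rule)
    catg, cacg = motifs[0], motifs[1] if len(motifs) > 1 else motifs[0]
    return MotifSummary(
        gene_id=gene_id,
        promoter_length=len(promoter),
        count_catg=counts[catg],
        count_cacg=counts[cacg],
        tata_position=tata,
        dist_catg=dists[catg],
        dist_cacg=dists[cacg],
        rel_he=rel_he,
    )


def summarize_promoters(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    rel_he: Optional[Mapping[str, float]] = None,
    length: int = DEFAULT_PROMOTER_LENGTH,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    tata_pattern: str = DEFAULT_TATA_PATTERN,
    distance_rule: str = "nearest",
) -> List[MotifSummary]:
    out = []
    for g in genes:
        seq = extract_promoter(genome, g, length)
        rel = float(rel_he.get(g.gene_id, float("nan"))) if rel_he else float("nan")
        out.append(summarize_promoter(g.gene_id, seq, rel, motifs, tata_pattern, distance_rule))
    return out


def mean_motif_frequency(summaries: Sequence[MotifSummary], motif: str) -> float:
    """Arithmetic mean of per-promoter counts for 'CATG' or 'CACG'."""
    if not summaries:
        raise ValidationError("mean_motif_frequency needs at least one summary")
    attr = {"CATG": "count_catg", "CACG": "count_cacg"}.get(motif.upper())
    if attr is None:
        raise ValidationError(f"no per-promoter counts tracked for motif {motif!r}")
    return float(np.mean([getattr(s, attr) for s in summaries]))


def summaries_to_frame(summaries: Sequence[MotifSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "promoter_length": [s.promoter_length for s in summaries],
            "count_catg": [s.count_catg for s in summaries],
            "count_cacg": [s.count_cacg for s in summaries],
            "tata_position": [s.tata_position for s in summaries],
            "dist_catg": [s.dist_catg for s in summaries],
            "dist_cacg": [s.dist_cacg for s in summaries],
            "rel_he": [s.rel_he for s in summaries],
        }
    )
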