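"""Self-contained synthetic inputs with machine-readable ground truth.

Emulates a two-color promoter tiling design: probes tile a window from
-1,200 bp to +300 bp around each TSS at 100 bp spacing, two dye-swapped
replicates carry log-normal background intensities with a multiplicative IP
enrichment (triangular kernel) at planted binding sites, promoters carry a
planted TATA-box plus CATG/CACG instances with configurable placement
relative to the TATA-box, and a REL expression table makes planted-site genes
up in the HE line and down in the mutant. Every random draw comes from one
seed through named substreams, so any subset of the outputs is reproducible
independently of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .array_io import (
    DYE_IP_CY3,
    DYE_IP_CY5,
    GeneModel,
    ProbeRecord,
    write_gene_models,
    write_genome,
    write_probe_table,
    write_expression_table,
)
from .errors import ValidationError

# named substreams off the top-level seed
_STREAM_GENOME = 0
_STREAM_SITES = 1
_STREAM_ARRAY_REP1 = 2
_STREAM_ARRAY_REP2 = 3
_STREAM_EXPRESSION = 4
_STREAM_MOTIFS = 5
_STREAM_SEQUENCE = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed) & 0x7FFFFFFF, stream]))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    The defaults emulate a ≈38,500-probe promoter tiling chip: 5 chromosomes
    carrying 2,600 promoters x 15 probes = 39,000 probes, 20 planted sites of
    6-fold enrichment spread over 5 probes each, log2-ratio noise sd 0.3, and
    a +/-0.2 log2 dye bias that the dye-swap merge must cancel.
    """

    n_chromosomes: int = 5
    chromosome_length: int = 2_500_000
    n_genes: int = 2600
    probe_spacing: int = 100
    probe_length: int = 50
    promoter_upstream: int = 1200     # window upstream of the TSS covered by probes
    promoter_downstream: int = 300
    n_planted_sites: int = 20
    enrichment_fold: float = 6.0
    site_width_probes: int = 5
    intensity_location: float = 7.0   # natural-log mean of the log-normal background
    intensity_scale: float = 0.8      # natural-log sd
    ratio_noise_sd: float = 0.3       # sd of the per-probe log2-ratio noise
    dye_bias: float = 0.2             # log2 units added to the Cy5-labeled channel
    utr_length: int = 150             # TSS -> ATG distance
    promoter_length: int = 2000       # motif-planting region upstream of the ATG
    catg_rate: float = 3.0            # planted CATG instances per promoter (Poisson)
    cacg_rate: float = 2.0
    catg_near_tata: bool = True
    catg_dist_scale: float = 50.0     # exponential scale of planted CATG-TATA distance
    cacg_dist_scale: float = 500.0
    tata_word: str = "TATAAAT"
    effect_he: float = 3.0            # mean log2 REL of bound genes in the HE line
    effect_m: float = -3.0            # mean log2 REL of bound genes in the mutant
    expression_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length, self.n_genes,
               self.probe_spacing, self.probe_length) <= 0:
            raise ValidationError("counts and sizes must be positive")
        if self.n_planted_sites < 0 or self.n_planted_sites > self.n_genes:
            raise ValidationError("n_planted_sites must lie in [0, n_genes]")
        if self.enrichment_fold <= 1.0 and self.n_planted_sites > 0:
            raise ValidationError("enrichment_fold must exceed 1 when sites are planted")
        if self.site_width_probes < 1 or self.site_width_probes % 2 == 0:
            raise ValidationError("site_width_probes must be odd and >= 1")
        if self.probes_per_promoter < 4:
            raise ValidationError("promoter window must hold at least 4 probes")

    @property
    def probes_per_promoter(self) -> int:
        span = self.promoter_upstream + self.promoter_downstream
        return (span - self.probe_length) // self.probe_spacing + 1


@dataclass
class PlantedSite:
    chrom: str
    center: int               # probe start position of the central probe
    width: int                # bp covered by the enriched probes
    enrichment_fold: float
    gene_id: str

    @property
    def interval(self) -> Tuple[int, int]:
        half = (self.width - 1) // 2
        return (self.center - half, self.center - half + self.width)


@dataclass
class SyntheticTruth:
    """Everything a downstream test needs: sites, bound genes, effects, motifs."""

    planted_sites: List[PlantedSite] = field(default_factory=list)
    bound_genes: List[str] = field(default_factory=list)
    rel_effects: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    motif_truth: Dict[str, Dict] = field(default_factory=dict)
    # per gene: {"tata_offset": int, "catg_offsets": [...], "cacg_offsets": [...]}

    def to_json(self, path) -> None:
        payload = {
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "bound_genes": sorted(self.bound_genes),
            "rel_effects": {g: list(v) for g, v in sorted(self.rel_effects.items())},
            "motif_truth": {g: self.motif_truth[g] for g in sorted(self.motif_truth)},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_sites=[PlantedSite(**s) for s in payload["planted_sites"]],
            bound_genes=list(payload["bound_genes"]),
            rel_effects={g: (float(a), float(b)) for g, (a, b) in payload["rel_effects"].items()},
            motif_truth=payload["motif_truth"],
        )


# ---------------------------------------------------------------------------
# genome + genes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> List[GeneModel]:
    """Non-overlapping genes with alternating strands, evenly slotted with jitter.

    Placement keeps both the probe window (-upstream..+downstream of the TSS)
    and the motif-planting promoter (promoter_length upstream of the ATG)
    fully on-chromosome.
    """
    margin = cfg.promoter_length + cfg.utr_length + cfg.promoter_upstream  # generous
    genes: List[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    gi = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = (cfg.chromosome_length - 2 * margin) / n
        if slot < 3200:
            raise ValidationError(
                "genes cannot be placed without overlap; increase chromosome_length"
            )
        jitter_max = int(min(400, slot / 8))
        for k in range(n):
            center = margin + (k + 0.5) * slot
            tss = int(center) + int(rng.integers(-jitter_max, jitter_max + 1))
            strand = "+" if gi % 2 == 0 else "-"
            if strand == "+":
                cds = tss + cfg.utr_length
                gene = GeneModel(f"G{gi:05d}", chrom, "+", tss, cds, cds + 1000)
            else:
                cds = tss - cfg.utr_length
                gene = GeneModel(f"G{gi:05d}", chrom, "-", tss, cds, cds - 1000)
            genes.append(gene)
            gi += 1
    return genes


def _promoter_offset_to_genome(gene: GeneModel, offset: int, length: int, word_len: int):
    """Genome (start, reverse?) for a word at a promoter offset (0 = -length bp)."""
    if gene.strand == "+":
        return gene.cds_start - length + offset, False
    return gene.cds_start + length - offset - word_len, True


def _write_word(chrom_seq: bytearray, start: int, word: str, reverse: bool) -> None:
    if reverse:
        word = "".join(_COMPLEMENT[b] for b in reversed(word))
    chrom_seq[start: start + len(word)] = word.encode()


def _plant_promoter_motifs(
    cfg: SimConfig,
    genes: List[GeneModel],
    seqs: Dict[str, bytearray],
    rng: np.random.Generator,
) -> Dict[str, Dict]:
    truth: Dict[str, Dict] = {}
    L = cfg.promoter_length
    tata_len = len(cfg.tata_word)
    for gene in genes:
        # TATA-box ~30 bp upstream of the TSS
        tss_offset = L - cfg.utr_length
        tata_offset = tss_offset - int(rng.integers(28, 38))
        occupied = [(tata_offset, tata_offset + tata_len)]
        gstart, rev = _promoter_offset_to_genome(gene, tata_offset, L, tata_len)
        _write_word(seqs[gene.chrom], gstart, cfg.tata_word, rev)

        def place(word: str, dist_scale: float, near: bool) -> Optional[int]:
            for _ in range(20):
                if near:
                    d = int(rng.exponential(dist_scale)) + len(word)
                    off = tata_offset + (d if rng.integers(2) else -d)
                else:
                    off = int(rng.integers(0, L - len(word)))
                if not (0 <= off <= L - len(word)):
                    continue
                if any(off < e and off + len(word) > s for s, e in occupied):
                    continue
                occupied.append((off, off + len(word)))
                g0, r = _promoter_offset_to_genome(gene, off, L, len(word))
                _write_word(seqs[gene.chrom], g0, word, r)
                return off
            return None

        catg_offsets, cacg_offsets = [], []
        for _ in range(rng.poisson(cfg.catg_rate)):
            off = place("CATG", cfg.catg_dist_scale, cfg.catg_near_tata)
            if off is not None:
                catg_offsets.append(off)
        for _ in range(rng.poisson(cfg.cacg_rate)):
            off = place("CACG", cfg.cacg_dist_scale, False)
            if off is not None:
                cacg_offsets.append(off)
        truth[gene.gene_id] = {
            "tata_offset": tata_offset,
            "catg_offsets": sorted(catg_offsets),
            "cacg_offsets": sorted(cacg_offsets),
        }
    return truth


def _window_start(cfg: SimConfig, gene: GeneModel) -> int:
    if gene.strand == "+":
        return gene.tss - cfg.promoter_upstream
    return gene.tss - cfg.promoter_downstream


def _plant_sites(
    cfg: SimConfig, genes: List[GeneModel], rng: np.random.Generator
) -> List[PlantedSite]:
    if cfg.n_planted_sites == 0:
        return []
    chosen = sorted(rng.choice(len(genes), size=cfg.n_planted_sites, replace=False))
    half = (cfg.site_width_probes - 1) // 2
    n_probes = cfg.probes_per_promoter
    width = (cfg.site_width_probes - 1) * cfg.probe_spacing + cfg.probe_length
    sites = []
    for gi in chosen:
        gene = genes[gi]
        j = int(rng.integers(half, n_probes - half))
        center = _window_start(cfg, gene) + j * cfg.probe_spacing
        sites.append(PlantedSite(gene.chrom, center, width, cfg.enrichment_fold, gene.gene_id))
    return sites


def generate_genome_and_genes(
    cfg: SimConfig, with_sequence: bool = True
) -> Tuple[Optional[Dict[str, str]], List[GeneModel], SyntheticTruth]:
    """Genome FASTA dict, gene models and the planted truth (deterministic in seed).

    ``with_sequence=False`` skips nucleotide synthesis and motif planting for
    intensity-level studies that only need the gene/probe layout; gene
    placement and site planting are unchanged.
    """
    cfg.validate()
    genes = _place_genes(cfg, _rng(cfg.seed, _STREAM_GENOME))
    sites = _plant_sites(cfg, genes, _rng(cfg.seed, _STREAM_SITES))
    truth = SyntheticTruth(
        planted_sites=sites,
        bound_genes=sorted({s.gene_id for s in sites}),
    )
    genome: Optional[Dict[str, str]] = None
    if with_sequence:
        seqs: Dict[str, bytearray] = {}
        seq_rng = _rng(cfg.seed, _STREAM_SEQUENCE)
        for ci in range(cfg.n_chromosomes):
            codes = seq_rng.integers(0, 4, size=cfg.chromosome_length)
            seqs[f"chr{ci + 1}"] = bytearray(_BASES[codes].tobytes())
        truth.motif_truth = _plant_promoter_motifs(cfg, genes, seqs, _rng(cfg.seed, _STREAM_MOTIFS))
        genome = {c: s.decode() for c, s in seqs.items()}
    return genome, genes, truth


# ---------------------------------------------------------------------------
# arrays


def _site_kernel(cfg: SimConfig) -> np.ndarray:
    """Triangular enrichment exponents across the site's probes (peak 1 at center)."""
    half = (cfg.site_width_probes - 1) // 2
    offs = np.arange(-half, half + 1)
    return 1.0 - np.abs(offs) / (half + 1.0)


def probe_layout(cfg: SimConfig, genes: List[GeneModel]) -> pd.DataFrame:
    """One row per probe: gene_id, chrom, start, probe index within the window."""
    rows = {"gene_id": [], "chrom": [], "start": [], "k": []}
    n = cfg.probes_per_promoter
    for gene in genes:
        ws = _window_start(cfg, gene)
        for k in range(n):
            rows["gene_id"].append(gene.gene_id)
            rows["chrom"].append(gene.chrom)
            rows["start"].append(ws + k * cfg.probe_spacing)
            rows["k"].append(k)
    return pd.DataFrame(rows)


def simulate_array(
    genes: List[GeneModel], truth: SyntheticTruth, cfg: SimConfig
) -> Tuple[List[ProbeRecord], List[ProbeRecord]]:
    """Two dye-swapped replicate probe sets over the promoter tiling layout.

    Input intensities are log-normal; IP = input * fold^kernel at planted
    sites times 2^N(0, ratio_noise_sd); the Cy5-labeled channel (IP in
    replicate 1, input in replicate 2) is multiplied by 2^dye_bias, giving
    equal and opposite log2-ratio biases that the dye-swap merge cancels.
    """
    cfg.validate()
    layout = probe_layout(cfg, genes)
    n = len(layout)
    if cfg.probes_per_promoter < 2:
        raise ValidationError("promoter window narrower than 2 probes")

    fold = np.ones(n, dtype=np.float64)
    kernel = _site_kernel(cfg)
    half = (cfg.site_width_probes - 1) // 2
    start_index = {}
    for gene_id, grp in layout.groupby("gene_id", sort=False):
        start_index[gene_id] = grp.index[0]
    spacing = cfg.probe_spacing
    for site in truth.planted_sites:
        base = start_index[site.gene_id]
        gene_rows = layout.iloc[base: base + cfg.probes_per_promoter]
        j = int(round((site.center - int(gene_rows["start"].iloc[0])) / spacing))
        for o, kern in zip(range(-half, half + 1), kernel):
            fold[base + j + o] = site.enrichment_fold ** kern

    records: List[List[ProbeRecord]] = []
    for rep, stream, dye in (
        ("rep1", _STREAM_ARRAY_REP1, DYE_IP_CY5),
        ("rep2", _STREAM_ARRAY_REP2, DYE_IP_CY3),
    ):
        rng = _rng(cfg.seed, stream)
        inp = rng.lognormal(cfg.intensity_location, cfg.intensity_scale, n)
        noise = rng.normal(0.0, cfg.ratio_noise_sd, n) if cfg.ratio_noise_sd > 0 else 0.0
        ip = inp * fold * np.exp2(noise)
        if dye == DYE_IP_CY5:
            ip = ip * 2.0 ** cfg.dye_bias
        else:
            inp = inp * 2.0 ** cfg.dye_bias
        recs = [
            ProbeRecord(
                probe_id=f"{g}_p{k:02d}",
                chrom=c,
                start=int(s),
                length=cfg.probe_length,
                ip_intensity=float(a),
                input_intensity=float(b),
                dye_orientation=dye,
                replicate_id=rep,
            )
            for g, c, s, k, a, b in zip(
                layout["gene_id"], layout["chrom"], layout["start"], layout["k"], ip, inp
            )
        ]
        recs.sort(key=lambda r: (r.chrom, r.start))
        records.append(recs)
    return records[0], records[1]


def simulate_expression(
    truth: SyntheticTruth, genes: List[GeneModel], cfg: SimConfig
) -> pd.DataFrame:
    """REL table (log2): bound genes up in HE / down in mutant, others null."""
    rng = _rng(cfg.seed, _STREAM_EXPRESSION)
    bound = set(truth.bound_genes)
    gene_ids = [g.gene_id for g in genes]
    mu_he = np.array([cfg.effect_he if g in bound else 0.0 for g in gene_ids])
    mu_m = np.array([cfg.effect_m if g in bound else 0.0 for g in gene_ids])
    sd = cfg.expression_sd
    rel_he = mu_he + (rng.normal(0.0, sd, len(gene_ids)) if sd > 0 else 0.0)
    rel_m = mu_m + (rng.normal(0.0, sd, len(gene_ids)) if sd > 0 else 0.0)
    truth.rel_effects = {g: (float(a), float(b)) for g, a, b in zip(gene_ids, mu_he, mu_m)}
    return pd.DataFrame(
        {"gene_id": gene_ids, "rel_he": rel_he, "rel_m": rel_m, "scale": "log2"}
    )


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset:
    cfg: SimConfig
    genome: Optional[Dict[str, str]]
    genes: List[GeneModel]
    probes_rep1: List[ProbeRecord]
    probes_rep2: List[ProbeRecord]
    expression: pd.DataFrame
    truth: SyntheticTruth


def generate_dataset(cfg: SimConfig, with_sequence: bool = True) -> SyntheticDataset:
    genome, genes, truth = generate_genome_and_genes(cfg, with_sequence=with_sequence)
    rep1, rep2 = simulate_array(genes, truth, cfg)
    expr = simulate_expression(truth, genes, cfg)
    return SyntheticDataset(cfg, genome, genes, rep1, rep2, expr, truth)


def write_dataset(ds: SyntheticDataset, outdir) -> Dict[str, Path]:
    """Write genome.fa, genes.gff3, probes_rep{1,2}.tsv, rel.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.gff3",
        "probes_rep1": outdir / "probes_rep1.tsv",
        "probes_rep2": outdir / "probes_rep2.tsv",
        "expression": outdir / "rel.tsv",
        "truth": outdir / "truth.json",
    }
    write_gene_models(ds.genes, paths["genes"])
    write_probe_table(ds.probes_rep1, paths["probes_rep1"])
    write_probe_table(ds.probes_rep2, paths["probes_rep2"])
    write_expression_table(ds.expression, paths["expression"])
    ds.truth.to_json(paths["truth"])
    if ds.genome is not None:
        paths["genome"] = outdir / "genome.fa"
        write_genome(ds.genome, paths["genome"])
    return paths
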