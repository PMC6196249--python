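"""Readers and writers for every on-disk format the pipeline touches.

Conventions: all internal coordinates are 0-based half-open; GFF3 is 1-based
inclusive on disk; BED is 0-based half-open. Probe tables are delimited text
with a header (a stand-in for vendor "pair" exports, whose binary schema is
not public); the column mapping is configurable so similarly shaped exports
can be adapted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .peak_caller import Peak
from .signal_model import RatioProfile

log = logging.getLogger(__name__)

DYE_IP_CY5 = "ip_cy5"
DYE_IP_CY3 = "ip_cy3"

#: Default probe-table dialect: tab-separated, these header names.
DEFAULT_DIALECT: Dict[str, object] = {
    "sep": "\t",
    "columns": {
        "probe_id": "probe_id",
        "chrom": "chrom",
        "start": "start",
        "length": "length",
        "ip_intensity": "ip",
        "input_intensity": "input",
        "dye_orientation": "dye",
        "replicate_id": "replicate",
    },
}


@dataclass(frozen=True)
class ProbeRecord:
    """One probe's genomic anchor plus its two channel intensities."""

    probe_id: str
    chrom: str
    start: int              # 0-based
    length: int             # bp
    ip_intensity: float
    input_intensity: float
    dye_orientation: str    # DYE_IP_CY5 or DYE_IP_CY3
    replicate_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"probe {self.probe_id}: start must be >= 0")
        if self.length <= 0:
            raise ValidationError(f"probe {self.probe_id}: length must be > 0")
        for name, x in (("ip", self.ip_intensity), ("input", self.input_intensity)):
            if not np.isfinite(x) or x < 0:
                raise ValidationError(
                    f"probe {self.probe_id}: {name} intensity must be finite and >= 0"
                )
        if self.dye_orientation not in (DYE_IP_CY5, DYE_IP_CY3):
            raise ValidationError(
                f"probe {self.probe_id}: dye_orientation must be "
                f"{DYE_IP_CY5!r} or {DYE_IP_CY3!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene anchors used by the pipeline: TSS, start codon, transcript end.

    For '+' genes the genomic span is [tss, gene_end) with
    tss <= cds_start < gene_end. For '-' genes the ordering mirrors:
    gene_end <= cds_start <= tss, where ``gene_end`` is the (0-based,
    inclusive) genomic position of the transcript's last base, so the span is
    [gene_end, tss + 1).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    cds_start: int          # 0-based position of the A of ATG
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+":
            ok = 0 <= self.tss <= self.cds_start < self.gene_end
        else:
            ok = 0 <= self.gene_end <= self.cds_start <= self.tss
        if not ok:
            raise ValidationError(f"gene {self.gene_id}: inconsistent coordinates")

    @property
    def span(self):
        """Genomic (start, end), 0-based half-open, strand-independent."""
        if self.strand == "+":
            return (self.tss, self.gene_end)
        return (self.gene_end, self.tss + 1)


# ---------------------------------------------------------------------------
# probe tables


def read_probe_table(path, dialect: Optional[Mapping] = None) -> List[ProbeRecord]:
    """Parse a delimited probe table into ProbeRecords sorted by (chrom, start)."""
    path = Path(path)
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    cols: Mapping[str, str] = d["columns"]  # type: ignore[assignment]
    df = pd.read_csv(path, sep=d["sep"], dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: List[ProbeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            rec = ProbeRecord(
                probe_id=row[cols["probe_id"]],
                chrom=row[cols["chrom"]],
                start=int(row[cols["start"]]),
                length=int(row[cols["length"]]),
                ip_intensity=float(row[cols["ip_intensity"]]),
                input_intensity=float(row[cols["input_intensity"]]),
                dye_orientation=row[cols["dye_orientation"]],
                replicate_id=row[cols["replicate_id"]],
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed value in data row {i}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}: data row {i}: {exc}") from exc
        records.append(rec)
    keys = {(r.probe_id, r.replicate_id) for r in records}
    if len(keys) != len(records):
        raise ValidationError(f"{path}: duplicate (probe_id, replicate_id) pairs")
    records.sort(key=lambda r: (r.chrom, r.start))
    log.info("read %d probe records from %s", len(records), path)
    return records


def write_probe_table(records: Iterable[ProbeRecord], path, dialect: Optional[Mapping] = None) -> None:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    cols: Mapping[str, str] = d["columns"]  # type: ignore[assignment]
    rows = [asdict(r) for r in sorted(records, key=lambda r: (r.chrom, r.start))]
    df = pd.DataFrame(rows, columns=list(cols.keys()))
    df = df.rename(columns=cols)
    df.to_csv(path, sep=d["sep"], index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# gene models (GFF3)


def read_gene_models(path) -> List[GeneModel]:
    """Load gene models from GFF3 (gene features + one CDS child each)."""
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises ValueError on duplicate IDs
        if "duplicate" in str(exc).lower() or "already" in str(exc).lower():
            raise ValidationError(f"{path}: duplicate feature IDs in GFF3: {exc}") from exc
        raise FormatError(f"{path}: cannot parse GFF3: {exc}") from exc
    genes: List[GeneModel] = []
    seen: Dict[str, int] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        seen[gene_id] = seen.get(gene_id, 0) + 1
        if feat.strand not in ("+", "-"):
            raise ValidationError(f"{path}: gene {gene_id} has no usable strand ({feat.strand!r})")
        if feat.start < 1:
            raise ValidationError(f"{path}: gene {gene_id} start < 1 in 1-based coordinates")
        cds = [c for c in db.children(feat.id, featuretype="CDS")]
        span_start0 = feat.start - 1        # 1-based inclusive -> 0-based
        span_end0 = feat.end                # exclusive
        if feat.strand == "+":
            tss = span_start0
            gene_end = span_end0
            cds_start = cds[0].start - 1 if cds else tss
        else:
            tss = span_end0 - 1             # highest covered base
            gene_end = span_start0          # lowest covered base, inclusive
            cds_start = cds[0].end - 1 if cds else tss
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, tss, cds_start, gene_end))
    dups = sorted(g for g, n in seen.items() if n > 1)
    if dups:
        raise ValidationError(f"{path}: duplicate gene_id(s): {', '.join(dups)}")
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    log.info("read %d gene models from %s", len(genes), path)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene feature plus a CDS child per gene)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
        s0, e0 = g.span
        gene_cols = [g.chrom, "esnacchip", "gene", str(s0 + 1), str(e0), ".",
                     g.strand, ".", f"ID={g.gene_id}"]
        if g.strand == "+":
            cds_1, cds_2 = g.cds_start + 1, g.gene_end
        else:
            cds_1, cds_2 = g.gene_end + 1, g.cds_start + 1
        cds_cols = [g.chrom, "esnacchip", "CDS", str(cds_1), str(cds_2), ".",
                    g.strand, "0", f"ID={g.gene_id}.cds;Parent={g.gene_id}"]
        lines.append("\t".join(gene_cols))
        lines.append("\t".join(cds_cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path) -> Dict[str, str]:
    """FASTA -> {chrom: uppercase sequence}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# peaks

PEAK_TSV_COLUMNS = [
    "peak_id", "chrom", "start", "end", "summit", "n_probes", "max_value",
    "detect_cutoff", "fdr_score", "score_ip", "score_input", "score_ratio",
]


def _check_sorted_unique(peaks: Sequence[Peak]) -> None:
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate peak ids")
    keys = [(p.chrom, p.start) for p in peaks]
    if keys != sorted(keys):
        raise ValidationError("peaks must be sorted by (chrom, start)")


def write_peaks(peaks: Sequence[Peak], path, format: str = "TSV") -> None:
    """Write peaks as full-precision TSV or BED6 (score = 100x peak score, clamped)."""
    peaks = list(peaks)
    _check_sorted_unique(peaks)
    path = Path(path)
    if format.upper() == "TSV":
        rows = []
        for p in peaks:
            rows.append({c: getattr(p, c) for c in PEAK_TSV_COLUMNS})
        df = pd.DataFrame(rows, columns=PEAK_TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")
    elif format.upper() == "BED":
        lines = []
        for p in peaks:
            s = 0.0 if p.score_ip is None else p.score_ip
            bed_score = int(min(1000, max(0, round(100 * s))))
            lines.append("\t".join(
                [p.chrom, str(p.start), str(p.end), p.peak_id, str(bed_score), "."]
            ))
        path.write_text("".join(line + "\n" for line in lines))
    else:
        raise ValidationError(f"unknown peak format {format!r}")


def read_peaks(path) -> List[Peak]:
    """Read back the TSV form written by :func:`write_peaks`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PEAK_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing peak column(s): {', '.join(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        def _opt(x):
            return None if pd.isna(x) else float(x)
        peaks.append(Peak(
            peak_id=str(row.peak_id), chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), summit=int(row.summit), n_probes=int(row.n_probes),
            max_value=float(row.max_value), detect_cutoff=_opt(row.detect_cutoff),
            fdr_score=_opt(row.fdr_score), score_ip=_opt(row.score_ip),
            score_input=_opt(row.score_input),
            score_ratio=float(row.score_ratio) if not pd.isna(row.score_ratio) else float("nan"),
        ))
    return peaks


# ---------------------------------------------------------------------------
# ratio profiles (wiggle-like TSV) and expression tables


def write_profile(profile: RatioProfile, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# replicate_id={profile.replicate_id}\n")
        fh.write(f"# scaled={int(profile.scaled)}\n")
        fh.write(f"# probe_length={profile.probe_length}\n")
        fh.write(f"# dye_orientation={profile.dye_orientation or ''}\n")
        fh.write("chrom\tposition\tvalue\n")
        for c, p, v in zip(profile.chroms, profile.positions, profile.values):
            fh.write(f"{c}\t{p}\t{v:.12g}\n")


def read_profile(path) -> RatioProfile:
    path = Path(path)
    meta: Dict[str, str] = {}
    lines = path.read_text().splitlines(keepends=True)
    body = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        body += 1
    df = pd.read_csv(io.StringIO("".join(lines[body:])), sep="\t")
    return RatioProfile(
        chroms=df["chrom"].to_numpy(dtype=object),
        positions=df["position"].to_numpy(),
        values=df["value"].to_numpy(),
        replicate_id=meta.get("replicate_id", "unknown"),
        scaled=bool(int(meta.get("scaled", "0"))),
        probe_length=int(meta.get("probe_length", "50")),
        dye_orientation=meta.get("dye_orientation") or None,
    )


def read_expression_table(path, scale: str = "log2") -> pd.DataFrame:
    """REL table: gene_id, rel_he, rel_m (+ optional per-file 'scale' column).

    ``scale='linear'`` (or a linear scale column) log2-transforms fold
    changes on input so the whole pipeline works on the log2 scale.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "rel_he", "rel_m"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing expression column {col!r}")
    if "scale" in df.columns:
        scales = set(df["scale"].unique())
        if not scales <= {"log2", "linear"}:
            raise ValidationError(f"{path}: unknown scale value(s) {scales - {'log2', 'linear'}}")
        linear = df["scale"] == "linear"
    else:
        if scale not in ("log2", "linear"):
            raise ValidationError(f"unknown scale {scale!r}")
        linear = pd.Series(scale == "linear", index=df.index)
    out = df[["gene_id", "rel_he", "rel_m"]].copy()
    for col in ("rel_he", "rel_m"):
        vals = out[col].to_numpy(dtype=float)
        if np.any(linear.to_numpy() & (vals <= 0)):
            raise ValidationError(f"{path}: linear-scale {col} values must be positive")
        out[col] = np.where(linear, np.log2(np.where(vals > 0, vals, 1.0)), vals)
    if out["gene_id"].duplicated().any():
        dups = sorted(out.loc[out["gene_id"].duplicated(), "gene_id"].unique())
        raise ValidationError(f"{path}: duplicate gene_id(s): {', '.join(map(str, dups))}")
    return out


def write_expression_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "scale" not in out.columns:
        out["scale"] = "log2"
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
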