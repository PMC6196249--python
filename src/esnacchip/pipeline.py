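"""End-to-end orchestration: normalize -> call peaks -> filter -> map targets
-> motif context, from a single config, with a reproducible run manifest.

All stage outputs are accumulated in memory and written together at the end,
so a failed stage leaves no partial files behind and a rerun with identical
config + inputs + seed is bit-identical (timestamps live in their own
manifest key and are the only varying field).
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Mapping, Optional

import yaml

from . import __version__
from .array_io import (
    read_expression_table,
    read_gene_models,
    read_genome,
    read_probe_table,
    write_peaks,
)
from .errors import ConfigError, EsnacchipError
from .motif_context import summaries_to_frame, summarize_promoters
from .peak_caller import (
    ALT_SCORE_MIN,
    DEFAULT_FDR_MAX,
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_PROBES,
    DEFAULT_N_PERM,
    DEFAULT_PERCENTAGES,
    DEFAULT_POISSON_WINDOW,
    DEFAULT_SCORE_MIN,
    build_cutoff_schedule,
    filter_targets,
    permutation_fdr,
    score_peaks,
)
from .signal_model import (
    BIWEIGHT_C,
    BIWEIGHT_EPS,
    BIWEIGHT_MAX_ITER,
    RATIO_FLOOR,
    compute_log2_ratio,
    input_reference_profile,
    merge_dye_swap,
    scale_profile,
)
from .target_mapper import (
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    build_target_calls,
    assign_peaks_to_genes,
    promoter_windows,
    target_calls_to_frame,
)


def default_config() -> Dict:
    """One auditable home for every pipeline constant."""
    return {
        "inputs": {
            "probes_rep1": None,
            "probes_rep2": None,   # optional second (dye-swapped) replicate
            "genes": None,
            "genome": None,        # optional; enables the motif stage
            "expression": None,
        },
        "ratio": {"floor": RATIO_FLOOR},
        "biweight": {"c": BIWEIGHT_C, "eps": BIWEIGHT_EPS, "max_iter": BIWEIGHT_MAX_ITER},
        "sweep": {"percentages": list(DEFAULT_PERCENTAGES)},
        "fdr": {"n_perm": DEFAULT_N_PERM, "within_chrom": False},
        "peak": {"min_probes": DEFAULT_MIN_PROBES, "max_gap": DEFAULT_MAX_GAP},
        "poisson": {"window": DEFAULT_POISSON_WINDOW},
        "filter": {
            "fdr_max": DEFAULT_FDR_MAX,
            "score_min": DEFAULT_SCORE_MIN,
            "score_min_relaxed": ALT_SCORE_MIN,
            "score_field": "score_ip",
        },
        "promoter": {"upstream": DEFAULT_UPSTREAM, "downstream": DEFAULT_DOWNSTREAM},
        "expression": {"up_thresh": 1.0, "down_thresh": -1.0, "scale": "log2"},
        "motif": {
            "motifs": ["CATG", "CACG"],
            "promoter_length": 2000,
            "tata_pattern": "TATAWAW",
            "distance_rule": "nearest",
            "gene_set": "dependent",   # dependent | up | all_targets
        },
        "seed": 0,
    }


def _deep_merge(base: Dict, override: Mapping) -> Dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path) -> Dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return validate_config(user)


def validate_config(user: Mapping) -> Dict:
    base = default_config()
    unknown = set(user) - set(base)
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    cfg = _deep_merge(base, user)
    for req in ("probes_rep1", "genes", "expression"):
        if not cfg["inputs"].get(req):
            raise ConfigError(f"inputs.{req} is required")
    pcts = cfg["sweep"]["percentages"]
    if any(b >= a for a, b in zip(pcts, pcts[1:])):
        raise ConfigError("sweep.percentages must be strictly decreasing")
    if cfg["fdr"]["n_perm"] < 1:
        raise ConfigError("fdr.n_perm must be >= 1")
    return cfg


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(EsnacchipError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: Mapping | str | Path, outdir) -> Dict:
    """Execute all stages; write outputs + manifest.json; return the manifest."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {k: v for k, v in cfg["inputs"].items() if v}
    for name, path in inputs.items():
        if not Path(path).exists():
            raise ConfigError(f"inputs.{name}: no such file: {path}")
    digests = {name: _digest(path) for name, path in sorted(inputs.items())}
    counts: Dict[str, int] = {}
    seed = int(cfg["seed"])
    stage = "load"
    try:
        rep1 = read_probe_table(inputs["probes_rep1"])
        counts["probes_read"] = len(rep1)
        rep2 = None
        if "probes_rep2" in inputs:
            rep2 = read_probe_table(inputs["probes_rep2"])
            counts["probes_read"] += len(rep2)
        genes = read_gene_models(inputs["genes"])
        counts["genes"] = len(genes)
        expr = read_expression_table(inputs["expression"], scale=cfg["expression"]["scale"])

        stage = "normalize"
        floor = cfg["ratio"]["floor"]
        bw = cfg["biweight"]
        p1 = scale_profile(compute_log2_ratio(rep1, floor), bw["c"], bw["eps"], bw["max_iter"])
        if rep2 is not None:
            p2 = scale_profile(compute_log2_ratio(rep2, floor), bw["c"], bw["eps"], bw["max_iter"])
            profile = merge_dye_swap(p1, p2)
            iref1 = input_reference_profile(rep1, floor)
            iref2 = input_reference_profile(rep2, floor)
            input_ref = merge_dye_swap(iref1, iref2)
        else:
            profile = p1
            input_ref = input_reference_profile(rep1, floor)

        stage = "call_peaks"
        schedule = build_cutoff_schedule(profile, tuple(cfg["sweep"]["percentages"]))
        result = permutation_fdr(
            profile,
            schedule,
            n_perm=int(cfg["fdr"]["n_perm"]),
            min_probes=int(cfg["peak"]["min_probes"]),
            max_gap=int(cfg["peak"]["max_gap"]),
            seed=seed,
            within_chrom=bool(cfg["fdr"]["within_chrom"]),
        )
        for i, p in enumerate(sorted(result.peaks, key=lambda p: (p.chrom, p.start))):
            p.peak_id = f"peak_{i + 1:05d}"
        score_peaks(result.peaks, profile, input_ref, window=int(cfg["poisson"]["window"]))
        counts["peaks_candidates"] = len(result.peaks)

        stage = "filter"
        filt = cfg["filter"]
        highconf = filter_targets(
            result.peaks, filt["fdr_max"], filt["score_min"], filt["score_field"]
        )
        counts["peaks_highconf"] = len(highconf)

        stage = "map_targets"
        windows = promoter_windows(
            genes, int(cfg["promoter"]["upstream"]), int(cfg["promoter"]["downstream"])
        )
        assignments = assign_peaks_to_genes(highconf, windows)
        calls = build_target_calls(
            assignments, expr,
            cfg["expression"]["up_thresh"], cfg["expression"]["down_thresh"],
        )
        counts["target_genes"] = len(calls)
        counts["dependent_targets"] = sum(c.esnac1_dependent for c in calls)

        stage = "motif_context"
        motif_df = None
        if "genome" in inputs:
            genome = read_genome(inputs["genome"])
            mcfg = cfg["motif"]
            if mcfg["gene_set"] == "dependent":
                wanted = {c.gene_id for c in calls if c.esnac1_dependent}
            elif mcfg["gene_set"] == "up":
                wanted = {c.gene_id for c in calls if c.category == "up_in_HE"}
            else:
                wanted = {c.gene_id for c in calls}
            gene_subset = [g for g in genes if g.gene_id in wanted]
            rel_map = dict(zip(expr["gene_id"], expr["rel_he"]))
            summaries = summarize_promoters(
                genome, gene_subset, rel_map,
                length=int(mcfg["promoter_length"]),
                motifs=tuple(mcfg["motifs"]),
                tata_pattern=mcfg["tata_pattern"],
                distance_rule=mcfg["distance_rule"],
            )
            motif_df = summaries_to_frame(summaries)
            counts["motif_promoters"] = len(summaries)
    except Exception as exc:  # abort with the failing stage's name
        raise StageFailure(stage, exc) from exc

    stage = "write"
    peaks_sorted = sorted(result.peaks, key=lambda p: (p.chrom, p.start))
    highconf_sorted = sorted(highconf, key=lambda p: (p.chrom, p.start))
    write_peaks(peaks_sorted, outdir / "peaks.tsv", "TSV")
    write_peaks(highconf_sorted, outdir / "peaks.bed", "BED")
    result.fdr_table.to_csv(outdir / "fdr_table.tsv", sep="\t", index=False,
                            float_format="%.12g")
    target_calls_to_frame(calls).to_csv(outdir / "targets.tsv", sep="\t", index=False,
                                        float_format="%.12g")
    if motif_df is not None:
        motif_df.to_csv(outdir / "motif_summary.tsv", sep="\t", index=False,
                        float_format="%.12g", na_rep="NA")

    manifest = {
        "config": cfg,
        "seed": seed,
        "inputs": digests,
        "counts": counts,
        "version": __version__,
        "timestamps": {"finished": time.strftime("%Y-%m-%dT%H:%M:%S%z")},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
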