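"""Two-channel probe intensities -> scaled, dye-swap-merged log2-ratio tracks.

The normalization follows the classic two-color tiling-array recipe: per-probe
log2(IP/input) ratios are centered by subtracting the Tukey bi-weight mean (a
robust location estimate that down-weights the enriched minority of probes),
and the two dye-swapped replicates are averaged probe-by-probe so that any
dye-specific additive bias on the log scale cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: Bi-weight tuning constant, censoring points beyond c * MAD from the center.
BIWEIGHT_C = 5.0
#: Convergence tolerance (relative to the MAD scale) and iteration cap.
BIWEIGHT_EPS = 1e-4
BIWEIGHT_MAX_ITER = 10
#: Intensities below the floor are clamped before taking logs.
RATIO_FLOOR = 1.0


@dataclass
class RatioProfile:
    """Ordered genome-wide track of per-probe log2(IP/input) values.

    Probes from all chromosomes live in one container (sorted by chromosome,
    then position, strictly increasing within each chromosome) because the
    downstream operations -- the hypothetical maximum, the genome-wide value
    shuffle and the local-Poisson background rate -- are defined over the
    whole array, not per chromosome.
    """

    chroms: np.ndarray          # per-probe chromosome name, dtype=object/str
    positions: np.ndarray       # per-probe 0-based start (bp)
    values: np.ndarray          # log2 ratio per probe
    replicate_id: str
    scaled: bool
    probe_length: int = 50
    dye_orientation: Optional[str] = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (self.chroms.size == self.positions.size == self.values.size):
            raise ValidationError("chroms, positions and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ratio values must be finite")
        same = self.chroms[1:] == self.chroms[:-1]
        if np.any(same & (np.diff(self.positions) <= 0)):
            raise ValidationError("positions must be strictly increasing within each chromosome")

    @property
    def n_probes(self) -> int:
        return int(self.values.size)

    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome codes (stable within this profile), for fast run scans."""
        _, codes = np.unique(self.chroms.astype(str), return_inverse=True)
        return codes.astype(np.int64)


def tukey_biweight_mean(
    values: Sequence[float] | np.ndarray,
    c: float = BIWEIGHT_C,
    eps: float = BIWEIGHT_EPS,
    max_iter: int = BIWEIGHT_MAX_ITER,
) -> float:
    """Iterated Tukey bi-weight location estimate.

    Starts at the median with the scale fixed at MAD + ``eps``; points farther
    than ``c`` scale units from the current center get zero weight, the rest a
    quartic weight ``(1 - u^2)^2``. Iterates the weighted mean until the step
    falls below ``eps * scale`` or ``max_iter`` is reached. Never hard-fails on
    finite input: if every weight vanishes the median is returned.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("tukey_biweight_mean requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValidationError("tukey_biweight_mean requires finite values")
    if c <= 0:
        raise ValidationError("tuning constant c must be positive")
    med = float(np.median(x))
    s = float(np.median(np.abs(x - med))) + eps
    t = med
    for _ in range(max_iter):
        u = (x - t) / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        wsum = w.sum()
        if wsum == 0.0:
            return med
        t_new = float(np.dot(w, x) / wsum)
        delta = abs(t_new - t)
        t = t_new
        if delta < eps * s:
            break
    return t


def compute_log2_ratio(records, floor: float = RATIO_FLOOR) -> RatioProfile:
    """Per-probe log2(max(ip, floor) / max(input, floor)) for one replicate.

    All records must share a replicate id; the result is unscaled and keeps
    the replicate's dye orientation for the dye-swap bookkeeping.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot compute ratios from an empty record set")
    if floor <= 0:
        raise ValidationError("intensity floor must be positive")
    rep_ids = {r.replicate_id for r in records}
    if len(rep_ids) != 1:
        raise ValidationError(f"records span multiple replicates: {sorted(rep_ids)}")
    dyes = {r.dye_orientation for r in records}
    dye = dyes.pop() if len(dyes) == 1 else None
    records = sorted(records, key=lambda r: (r.chrom, r.start))
    ip = np.array([r.ip_intensity for r in records], dtype=np.float64)
    inp = np.array([r.input_intensity for r in records], dtype=np.float64)
    if not (np.all(np.isfinite(ip)) and np.all(np.isfinite(inp))):
        raise ValidationError("probe intensities must be finite")
    vals = np.log2(np.maximum(ip, floor) / np.maximum(inp, floor))
    return RatioProfile(
        chroms=np.array([r.chrom for r in records], dtype=object),
        positions=np.array([r.start for r in records], dtype=np.int64),
        values=vals,
        replicate_id=records[0].replicate_id,
        scaled=False,
        probe_length=int(records[0].length),
        dye_orientation=dye,
    )


def scale_profile(
    profile: RatioProfile,
    c: float = BIWEIGHT_C,
    eps: float = BIWEIGHT_EPS,
    max_iter: int = BIWEIGHT_MAX_ITER,
) -> RatioProfile:
    """Center a track by subtracting its Tukey bi-weight mean (done once)."""
    if profile.scaled:
        raise ValidationError("profile is already scaled; refusing to scale twice")
    offset = tukey_biweight_mean(profile.values, c=c, eps=eps, max_iter=max_iter)
    return replace(profile, values=profile.values - offset, scaled=True)


def merge_dye_swap(a: RatioProfile, b: RatioProfile) -> RatioProfile:
    """Probe-wise mean of two scaled, dye-swapped replicate tracks."""
    for p in (a, b):
        if not p.scaled:
            raise ValidationError("merge_dye_swap requires scaled profiles")
    if a.n_probes != b.n_probes:
        raise ValidationError(
            f"replicates have different probe counts ({a.n_probes} vs {b.n_probes})"
        )
    mismatch = (a.chroms != b.chroms) | (a.positions != b.positions)
    if np.any(mismatch):
        first = int(np.flatnonzero(mismatch)[0])
        raise ValidationError(f"probe layouts differ starting at index {first}")
    if a.dye_orientation is not None and a.dye_orientation == b.dye_orientation:
        raise ValidationError(
            f"replicates share dye orientation {a.dye_orientation!r}; expected a swap"
        )
    return RatioProfile(
        chroms=a.chroms.copy(),
        positions=a.positions.copy(),
        values=(a.values + b.values) / 2.0,
        replicate_id="merged",
        scaled=True,
        probe_length=a.probe_length,
        dye_orientation=None,
    )


def input_reference_profile(records, floor: float = RATIO_FLOOR) -> RatioProfile:
    """Background track from the input channel alone.

    log2 of the (floored) input intensity, centered on its own bi-weight mean.
    Used to compute the peak score on the input side of the IP/input score
    ratio with the same local-Poisson machinery as the IP track.
    """
    records = sorted(records, key=lambda r: (r.chrom, r.start))
    if not records:
        raise ValidationError("cannot build an input reference from no records")
    inp = np.array([r.input_intensity for r in records], dtype=np.float64)
    vals = np.log2(np.maximum(inp, floor))
    vals -= tukey_biweight_mean(vals)
    return RatioProfile(
        chroms=np.array([r.chrom for r in records], dtype=object),
        positions=np.array([r.start for r in records], dtype=np.int64),
        values=vals,
        replicate_id=records[0].replicate_id,
        scaled=True,
        probe_length=int(records[0].length),
    )
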