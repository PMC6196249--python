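"""Peak detection on scaled ratio tracks with permutation FDR and Poisson scores.

The detection scheme mirrors the classic tiling-array workflow: cutoffs are a
sweep of percentages of a "hypothetical maximum" H = mean + 6*SD of the scaled
track; runs of above-cutoff probes become peaks; the track values are shuffled
across the (fixed) probe layout to estimate how many such runs arise by
chance, giving each peak an FDR score; and each peak additionally receives a
-log10 upper-tail Poisson probability comparing its local density of enriched
probes to the genome-wide background rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .errors import ValidationError
from .signal_model import RatioProfile

log = logging.getLogger(__name__)

#: Default cutoff sweep: 90% down to 15% of H in 5% steps.
DEFAULT_PERCENTAGES = tuple(p / 100.0 for p in range(90, 14, -5))
DEFAULT_N_PERM = 20          # the track is randomized 20 times
DEFAULT_MIN_PROBES = 2
DEFAULT_MAX_GAP = 300        # bp between consecutive above-cutoff probe starts
DEFAULT_POISSON_WINDOW = 600  # bp, centered on the peak summit
DEFAULT_FDR_MAX = 0.05
DEFAULT_SCORE_MIN = 1.3      # -log10 P >= 1.3, i.e. P <= 0.05
ALT_SCORE_MIN = 1.0          # the relaxed threshold used for the wider gene set


@dataclass(frozen=True)
class CutoffSchedule:
    """Detection cutoffs as decreasing percentages of the hypothetical maximum."""

    hypothetical_max: float
    percentages: tuple

    def __post_init__(self) -> None:
        pcts = tuple(float(p) for p in self.percentages)
        if not pcts:
            raise ValidationError("cutoff schedule needs at least one percentage")
        if any(not (0.0 < p <= 1.0) for p in pcts):
            raise ValidationError("percentages must lie in (0, 1]")
        if any(b >= a for a, b in zip(pcts, pcts[1:])):
            raise ValidationError("percentages must be strictly decreasing")
        object.__setattr__(self, "percentages", pcts)

    @property
    def cutoffs(self) -> np.ndarray:
        return self.hypothetical_max * np.asarray(self.percentages, dtype=np.float64)


@dataclass
class Peak:
    """A called enrichment interval (0-based half-open) with its evidence."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int              # leftmost position of the maximal value
    n_probes: int
    max_value: float
    detect_cutoff: Optional[float] = None   # highest cutoff at which detected
    fdr_score: Optional[float] = None       # estimated FDR in [0, 1]
    score_ip: Optional[float] = None        # -log10 local-Poisson P on the IP track
    score_input: Optional[float] = None     # same statistic on the input track
    score_ratio: Optional[float] = None     # score_ip / score_input (NaN if undefined)
    probe_index: tuple = field(default=(), repr=False)  # (first, last) probe indices


def hypothetical_maximum(profile: RatioProfile) -> float:
    """H = mean + 6 * sample standard deviation of the scaled track."""
    if not profile.scaled:
        raise ValidationError("hypothetical_maximum expects a scaled profile")
    if profile.n_probes < 2:
        raise ValidationError("need at least 2 probes to estimate a standard deviation")
    v = profile.values
    return float(v.mean() + 6.0 * v.std(ddof=1))


def build_cutoff_schedule(
    profile: RatioProfile, percentages: Sequence[float] = DEFAULT_PERCENTAGES
) -> CutoffSchedule:
    return CutoffSchedule(hypothetical_maximum(profile), tuple(percentages))


def _find_runs(
    codes: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray,
    cutoff: float,
    min_probes: int,
    max_gap: int,
):
    """Index ranges (first, last) of qualifying above-cutoff runs.

    Consecutive above-cutoff probes on the same chromosome whose starts are at
    most ``max_gap`` bp apart are joined; runs shorter than ``min_probes`` are
    dropped. Indices refer to the full probe arrays.
    """
    idx = np.flatnonzero(values >= cutoff)
    if idx.size < min_probes:
        return []
    brk = np.empty(idx.size, dtype=bool)
    brk[0] = True
    brk[1:] = (codes[idx[1:]] != codes[idx[:-1]]) | (
        positions[idx[1:]] - positions[idx[:-1]] > max_gap
    )
    starts = np.flatnonzero(brk)
    ends = np.append(starts[1:], idx.size)
    keep = (ends - starts) >= min_probes
    return [(int(idx[a]), int(idx[b - 1])) for a, b in zip(starts[keep], ends[keep])]


def _count_runs(codes, positions, values, cutoff, min_probes, max_gap) -> int:
    idx = np.flatnonzero(values >= cutoff)
    if idx.size < min_probes:
        return 0
    brk = np.empty(idx.size, dtype=bool)
    brk[0] = True
    brk[1:] = (codes[idx[1:]] != codes[idx[:-1]]) | (
        positions[idx[1:]] - positions[idx[:-1]] > max_gap
    )
    starts = np.flatnonzero(brk)
    lengths = np.diff(np.append(starts, idx.size))
    return int(np.count_nonzero(lengths >= min_probes))


def _peak_from_run(profile: RatioProfile, first: int, last: int, cutoff: float) -> Peak:
    pos = profile.positions
    vals = profile.values
    sub = slice(first, last + 1)
    above = np.flatnonzero(vals[sub] >= cutoff) + first
    vmax_i = above[int(np.argmax(vals[above]))]
    start = int(pos[first])
    end = int(pos[last]) + profile.probe_length
    return Peak(
        peak_id=f"{profile.chroms[first]}:{start}-{end}",
        chrom=str(profile.chroms[first]),
        start=start,
        end=end,
        summit=int(pos[vmax_i]),
        n_probes=int(above.size),
        max_value=float(vals[vmax_i]),
        probe_index=(first, last),
    )


def detect_peaks(
    profile: RatioProfile,
    cutoff: float,
    min_probes: int = DEFAULT_MIN_PROBES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> List[Peak]:
    """Maximal runs of probes with value >= cutoff, as raw (unscored) peaks."""
    if not profile.scaled:
        raise ValidationError("detect_peaks expects a scaled profile")
    if min_probes < 1:
        raise ValidationError("min_probes must be >= 1")
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    codes = profile.chrom_codes()
    runs = _find_runs(codes, profile.positions, profile.values, cutoff, min_probes, max_gap)
    return [_peak_from_run(profile, a, b, cutoff) for a, b in runs]


@dataclass
class PeakCallResult:
    """Peaks with FDR annotation plus the per-cutoff diagnostic table."""

    peaks: List[Peak]
    fdr_table: pd.DataFrame  # columns: cutoff, percentage, observed, mean_false, fdr

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self):
        return len(self.peaks)


def permutation_fdr(
    profile: RatioProfile,
    schedule: CutoffSchedule,
    n_perm: int = DEFAULT_N_PERM,
    min_probes: int = DEFAULT_MIN_PROBES,
    max_gap: int = DEFAULT_MAX_GAP,
    seed: int = 0,
    within_chrom: bool = False,
) -> PeakCallResult:
    """Peak calling over a cutoff sweep with permutation-estimated FDR.

    For each cutoff c the observed run count O(c) is compared to the mean
    count over ``n_perm`` genome-wide shuffles of the track values (probe
    layout fixed; ``within_chrom=True`` confines each shuffle to its
    chromosome): FDR(c) = min(1, mean_j F_j(c) / max(O(c), 1)). Candidate
    peaks are the runs at the lowest cutoff; each is assigned the highest
    cutoff at which it is (re-)detected and the minimum FDR over all cutoffs
    at which it is detected, which enforces a monotone non-increase of the
    FDR score with detection stringency. Shuffle streams are seeded as
    (seed, permutation index), so results do not depend on iteration order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not profile.scaled:
        raise ValidationError("permutation_fdr expects a scaled profile")
    cutoffs = schedule.cutoffs  # decreasing
    codes = profile.chrom_codes()
    pos = profile.positions
    vals = profile.values

    candidates = detect_peaks(profile, float(cutoffs[-1]), min_probes, max_gap)
    cand_first = np.array([p.probe_index[0] for p in candidates], dtype=np.int64)
    cand_last = np.array([p.probe_index[1] for p in candidates], dtype=np.int64)
    detect_idx = np.full(len(candidates), -1, dtype=np.int64)

    observed = np.zeros(cutoffs.size, dtype=np.int64)
    for k, c in enumerate(cutoffs):
        runs = _find_runs(codes, pos, vals, float(c), min_probes, max_gap)
        observed[k] = len(runs)
        for first, _last in runs:
            j = int(np.searchsorted(cand_first, first, side="right")) - 1
            # a run at a higher cutoff is always contained in a low-cutoff run
            if j < 0 or first > cand_last[j]:
                raise AssertionError("run at higher cutoff not contained in a candidate")
            if detect_idx[j] < 0:
                detect_idx[j] = k

    boundaries = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1], True])
    false_counts = np.zeros((n_perm, cutoffs.size), dtype=np.float64)
    for j in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(seed) & 0x7FFFFFFF, j]))
        if within_chrom:
            shuffled = vals.copy()
            for a, b in zip(boundaries[:-1], boundaries[1:]):
                shuffled[a:b] = rng.permutation(shuffled[a:b])
        else:
            shuffled = rng.permutation(vals)
        for k, c in enumerate(cutoffs):
            false_counts[j, k] = _count_runs(codes, pos, shuffled, float(c), min_probes, max_gap)

    mean_false = false_counts.mean(axis=0)
    fdr = np.minimum(1.0, mean_false / np.maximum(observed, 1))
    # min over this and all lower cutoffs (the cutoffs at which a peak first
    # detected at index k remains detected)
    suffix_min = np.minimum.accumulate(fdr[::-1])[::-1]

    for i, peak in enumerate(candidates):
        k = int(detect_idx[i])  # always >= 0: every candidate exists at the lowest cutoff
        peak.detect_cutoff = float(cutoffs[k])
        peak.fdr_score = float(suffix_min[k])

    table = pd.DataFrame(
        {
            "cutoff": cutoffs,
            "percentage": np.asarray(schedule.percentages, dtype=np.float64),
            "observed": observed,
            "mean_false": mean_false,
            "fdr": fdr,
        }
    )
    log.info(
        "permutation_fdr: %d candidate peaks over %d cutoffs (n_perm=%d)",
        len(candidates), cutoffs.size, n_perm,
    )
    return PeakCallResult(peaks=candidates, fdr_table=table)


def local_poisson_score(
    peak: Peak,
    profile: RatioProfile,
    exceed_cutoff: float,
    window: int = DEFAULT_POISSON_WINDOW,
) -> float:
    """-log10 upper-tail Poisson probability of the summit-local enrichment.

    k above-cutoff probes in a ``window``-bp interval centered on the summit
    are tested against lambda = (genome-wide above-cutoff fraction) * (probes
    in window). Returns 0 when k = 0; an empty window scores 0 with a warning.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    if not profile.scaled:
        raise ValidationError("local_poisson_score expects a scaled profile")
    half = window // 2
    lo, hi = peak.summit - half, peak.summit + half
    in_chrom = profile.chroms == peak.chrom
    in_win = in_chrom & (profile.positions >= lo) & (profile.positions < hi)
    m = int(np.count_nonzero(in_win))
    if m == 0:
        log.warning("empty Poisson window around %s summit %d", peak.chrom, peak.summit)
        return 0.0
    k = int(np.count_nonzero(profile.values[in_win] >= exceed_cutoff))
    if k == 0:
        return 0.0
    rho = float(np.count_nonzero(profile.values >= exceed_cutoff)) / profile.n_probes
    lam = rho * m
    p = float(poisson.sf(k - 1, lam))  # Pr[X >= k]
    if p <= 0.0:
        p = 5e-324  # smallest positive double; caps S rather than overflowing
    return max(0.0, -math.log10(p))


def score_peaks(
    peaks: Sequence[Peak],
    profile: RatioProfile,
    input_profile: Optional[RatioProfile] = None,
    window: int = DEFAULT_POISSON_WINDOW,
    exceed_cutoff: Optional[float] = None,
) -> List[Peak]:
    """Attach score_ip / score_input / score_ratio to each peak, in place.

    The exceed cutoff defaults to each peak's own detection cutoff and is
    applied unchanged to the input reference track.
    """
    for peak in peaks:
        cut = exceed_cutoff if exceed_cutoff is not None else peak.detect_cutoff
        if cut is None:
            raise ValidationError(f"peak {peak.peak_id} has no detect_cutoff to score against")
        peak.score_ip = local_poisson_score(peak, profile, cut, window)
        if input_profile is not None:
            peak.score_input = local_poisson_score(peak, input_profile, cut, window)
            if peak.score_input > 0.0:
                peak.score_ratio = peak.score_ip / peak.score_input
            else:
                peak.score_ratio = float("nan")  # undefined: input side scored 0
    return list(peaks)


def filter_targets(
    peaks: Sequence[Peak],
    fdr_max: float = DEFAULT_FDR_MAX,
    score_min: float = DEFAULT_SCORE_MIN,
    score_field: str = "score_ip",
) -> List[Peak]:
    """High-confidence peaks: FDR <= fdr_max and peak score >= score_min.

    Both thresholds are inclusive. ``score_field`` selects which peak score
    the threshold applies to (``score_ip`` by default, ``score_ratio`` as the
    alternative reading).
    """
    if score_field not in ("score_ip", "score_ratio", "score_input"):
        raise ValidationError(f"unknown score field {score_field!r}")
    kept = []
    for p in peaks:
        if p.fdr_score is None or getattr(p, score_field) is None:
            raise ValidationError(f"peak {p.peak_id} lacks fdr_score or {score_field}")
        s = getattr(p, score_field)
        if p.fdr_score <= fdr_max and not math.isnan(s) and s >= score_min:
            kept.append(p)
    return kept
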