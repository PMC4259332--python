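"""Peak calling on processed tracks and classification against origin annotations.

A peak is a local maximum of a smoothed track, at least ``min_height`` high,
with greedily enforced minimum separation and half-height extent.  Peaks are
classified against the genome model: *canonical* (nearest origin within the
assignment radius is intact), *residual* (nearest origin is deleted — the
non-canonical initiation the origin-depleted chromosome relies on), or *novel*
(no origin nearby).  Depletion detection runs the same caller on a wild-type
minus mutant ORC difference track and reports deleted origins with and without
a supporting depletion peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genome import DELETED, GenomeModel, GenomicInterval
from .track import ProbeTrack

CANONICAL = "canonical"
RESIDUAL = "residual"
NOVEL = "novel"

DEFAULT_ASSIGN_RADIUS_BP = 5_000
DEFAULT_MIN_SEPARATION_BP = 2_000


@dataclass
class Peak:
    """A called local maximum with half-height extent and origin assignment."""

    chrom: str
    summit: int
    height: float
    bounds: GenomicInterval
    label: str | None = None
    nearest_origin: str | None = None
    distance_to_origin: int | None = None


@dataclass
class DepletionReport:
    """Outcome of ORC-depletion detection on a WT - mutant difference track."""

    depletion_peaks: list[Peak] = field(default_factory=list)
    unassigned_peaks: list[Peak] = field(default_factory=list)
    missed_origins: list[str] = field(default_factory=list)

    @property
    def detected_origins(self) -> list[str]:
        return sorted({p.nearest_origin for p in self.depletion_peaks})


def robust_noise_scale(values) -> float:
    """MAD-based robust scale: ``1.4826 * median(|v - median(v)|)``."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("noise scale of an empty sample")
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau reports its leftmost position."""
    n = len(values)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        # a plateau spanning the whole track is flat signal, not a peak
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    return maxima


def _refine_summit(
    positions: np.ndarray, values: np.ndarray, idx: int, halfwidth_bp: float
) -> int:
    """Sub-grid summit estimate from a local quadratic fit around the argmax.

    Falls back to the discrete argmax position when the window is too small or
    the fit shows no measurable concavity (flat plateaus keep the leftmost-
    maximum convention).
    """
    p0 = positions[idx]
    sel = np.abs(positions - p0) <= halfwidth_bp
    if sel.sum() < 5:
        return int(p0)
    x = positions[sel].astype(np.float64) - p0
    y = values[sel]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= -1e-12:
        return int(p0)
    vertex = -b / (2.0 * a)
    if abs(vertex) > halfwidth_bp:
        return int(p0)
    return int(round(p0 + vertex))


def _position_offset(track: ProbeTrack) -> int:
    """Offset from probe start to probe center, when the track records its
    probe length; peaks are then reported in probe-center coordinates."""
    probe_length = track.metadata.get("probe_length")
    if probe_length is None:
        return 0
    try:
        return int(round((float(probe_length) - 1) / 2.0))
    except (TypeError, ValueError):
        return 0


def call_peaks(
    track: ProbeTrack,
    min_height: float | None = None,
    min_separation_bp: float = DEFAULT_MIN_SEPARATION_BP,
    refine_summits: bool = True,
    refine_halfwidth_bp: float = 150.0,
) -> list[Peak]:
    """Call local maxima of height >= ``min_height`` on a processed track.

    Candidates are selected greedily by decreasing height (ties toward the
    leftmost position), rejecting any candidate closer than
    ``min_separation_bp`` to an already accepted summit.  ``min_height``
    defaults to three times the track's MAD-based robust noise scale.  Peak
    bounds are the contiguous probe run around the summit with values at least
    half the peak height.  When the track metadata records the probe length,
    summits and bounds are shifted from probe-start to probe-center
    coordinates.  Returned peaks are sorted by position.
    """
    if len(track) == 0:
        return []
    if min_height is None:
        min_height = 3.0 * robust_noise_scale(track.values)
    pos = track.positions
    vals = track.values
    candidates = [i for i in _local_maxima(vals) if vals[i] >= min_height]
    candidates.sort(key=lambda i: (-vals[i], pos[i]))
    accepted: list[int] = []
    for i in candidates:
        if all(abs(pos[i] - pos[j]) >= min_separation_bp for j in accepted):
            accepted.append(i)
    accepted.sort()

    offset = _position_offset(track)
    out = []
    for i in accepted:
        height = float(vals[i])
        half = height / 2.0
        lo = i
        while lo > 0 and vals[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi + 1 < len(vals) and vals[hi + 1] >= half:
            hi += 1
        summit = int(pos[i])
        # run length of exactly equal values at the maximum: a run of >= 3 is
        # a flat plateau (keep the leftmost convention); a 2-probe tie is a
        # discretization artifact of window filters and is safe to refine
        run = 1
        while i + run < len(vals) and vals[i + run] == vals[i]:
            run += 1
        if refine_summits and run < 3:
            summit = _refine_summit(pos, vals, i, refine_halfwidth_bp)
        bounds = GenomicInterval(
            track.chrom, int(pos[lo]) + offset, int(pos[hi]) + offset
        )
        summit = int(np.clip(summit + offset, bounds.start, bounds.end))
        out.append(Peak(track.chrom, summit, height, bounds))
    return out


def _origin_distance(peak: Peak, locus: GenomicInterval) -> int:
    return peak.bounds.distance_to(locus)


def classify_peaks(
    peaks: list[Peak],
    genome: GenomeModel,
    assign_radius_bp: float = DEFAULT_ASSIGN_RADIUS_BP,
) -> list[Peak]:
    """Label each peak canonical / residual / novel against the annotation.

    The distance between a peak and an origin is the coordinate gap between
    the peak's half-height interval and the origin locus (0 when they
    overlap).  Ties are broken toward the origin whose midpoint is closer to
    the summit, then lexicographically by name.  Peaks are labeled in place
    and returned.
    """
    for peak in peaks:
        origins = genome.origins_on(peak.chrom)
        best = None
        for o in origins:
            d = _origin_distance(peak, o.locus)
            if d > assign_radius_bp:
                continue
            key = (d, abs(peak.summit - o.locus.midpoint), o.name)
            if best is None or key < best[0]:
                best = (key, o)
        if best is None:
            peak.label = NOVEL
            peak.nearest_origin = None
            peak.distance_to_origin = None
        else:
            (d, _, _), origin = best
            peak.label = RESIDUAL if origin.status == DELETED else CANONICAL
            peak.nearest_origin = origin.name
            peak.distance_to_origin = int(d)
    return peaks


def detect_depletion(
    diff_track: ProbeTrack,
    genome: GenomeModel,
    min_height: float | None = None,
    min_separation_bp: float = DEFAULT_MIN_SEPARATION_BP,
    assign_radius_bp: float = DEFAULT_ASSIGN_RADIUS_BP,
) -> DepletionReport:
    """Find ORC-depletion sites on a wild-type minus mutant difference track.

    Every called peak within ``assign_radius_bp`` of a deleted origin is a
    depletion peak for that origin; other peaks are reported unassigned.  The
    report also lists deleted origins on this chromosome with *no* supporting
    peak (misses), so absent depletion is visible, not silent.
    """
    called = call_peaks(
        diff_track, min_height=min_height, min_separation_bp=min_separation_bp
    )
    deleted = [o for o in genome.origins_on(diff_track.chrom) if o.status == DELETED]
    report = DepletionReport()
    for peak in called:
        best = None
        for o in deleted:
            d = _origin_distance(peak, o.locus)
            if d > assign_radius_bp:
                continue
            key = (d, abs(peak.summit - o.locus.midpoint), o.name)
            if best is None or key < best[0]:
                best = (key, o)
        if best is None:
            report.unassigned_peaks.append(peak)
        else:
            (d, _, _), origin = best
            peak.label = "depletion"
            peak.nearest_origin = origin.name
            peak.distance_to_origin = int(d)
            report.depletion_peaks.append(peak)
    covered = {p.nearest_origin for p in report.depletion_peaks}
    report.missed_origins = sorted(o.name for o in deleted if o.name not in covered)
    return report
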