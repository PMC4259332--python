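"""Robust track conditioning: Tukey biweight centering and pseudomedian smoothing.

Tiling-array log2 ratios are first re-centered with the Tukey biweight, a
redescending M-estimator of location that ignores gross outlier probes, and
then smoothed with a sliding-window pseudomedian (Hodges-Lehmann) filter to
suppress single-probe outliers while preserving peak shape.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .track import ProbeTrack

DEFAULT_BIWEIGHT_C = 5.0
DEFAULT_WINDOW_BP = 50.0


def tukey_biweight_location(
    values,
    c: float = DEFAULT_BIWEIGHT_C,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """Iteratively reweighted Tukey biweight estimate of location.

    Residuals are scaled by ``c * MAD`` (MAD about the sample median, computed
    once); observations with ``|u| >= 1`` receive zero weight.  A zero MAD
    (more than half the sample tied) degenerates to the median, which is then
    the natural robust location.
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("biweight location of an empty sample")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    scale = c * mad
    loc = med
    for _ in range(max_iter):
        u = (x - loc) / scale
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        wsum = w.sum()
        if wsum == 0.0:  # pathological: everything rejected
            return med
        new = float((w * x).sum() / wsum)
        if abs(new - loc) < tol:
            return new
        loc = new
    return loc


def biweight_adjust(
    track: ProbeTrack, c: float = DEFAULT_BIWEIGHT_C, tol: float = 1e-8
) -> ProbeTrack:
    """Subtract the track's biweight location so its robust center is zero."""
    loc = tukey_biweight_location(track.values, c=c, tol=tol)
    return track.with_values(track.values - loc, biweight_location=loc, biweight_c=c)


def pseudomedian(values) -> float:
    """Hodges-Lehmann one-sample estimator: median of all Walsh averages
    ``(x_i + x_j) / 2`` over ``i <= j`` (self-pairs included)."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("pseudomedian of an empty sample")
    i, j = np.triu_indices(x.size)
    return float(np.median((x[i] + x[j]) / 2.0))


def pseudomedian_filter(
    track: ProbeTrack, window_bp: float = DEFAULT_WINDOW_BP
) -> ProbeTrack:
    """Sliding-window pseudomedian smoother.

    The output value at probe ``p`` is the pseudomedian of all probe values
    whose position lies within ``window_bp / 2`` of ``p``'s position (inclusive
    on both sides).  Windows shrink at chromosome ends; probe positions are
    unchanged.
    """
    if window_bp < 1:
        raise ValidationError(f"window_bp must be >= 1, got {window_bp}")
    pos = track.positions.astype(np.float64)
    vals = track.values
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    out = np.empty_like(vals)
    widths = hi - lo
    for w in np.unique(widths):
        rows = np.nonzero(widths == w)[0]
        base = lo[rows]
        mat = vals[base[:, None] + np.arange(w)[None, :]]
        i, j = np.triu_indices(w)
        out[rows] = np.median((mat[:, i] + mat[:, j]) / 2.0, axis=1)
    return track.with_values(out, pseudomedian_window_bp=window_bp)
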