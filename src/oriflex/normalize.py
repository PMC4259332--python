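"""Background-region normalization and differential tracks.

BrdU tracks from different samples are put on a common scale by subtracting,
within each data set, the average signal of regions known to stay unreplicated
in 200 mM hydroxyurea.  Differential binding (wild-type minus mutant) is a
plain probe-wise subtraction; tracks must share their probe design exactly —
no interpolation is ever attempted.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .genome import GenomicInterval
from .track import ProbeTrack


def background_normalize(
    track: ProbeTrack, background: list[GenomicInterval]
) -> ProbeTrack:
    """Subtract the unweighted mean over probes inside the background regions.

    Probe membership is by probe start position; regions on other chromosomes
    are ignored.  Raises :class:`ValidationError` if no probe falls inside the
    background (naming the regions that were checked).
    """
    regions = [r for r in background if r.chrom == track.chrom]
    inside = np.zeros(len(track), dtype=bool)
    for r in regions:
        inside |= (track.positions >= r.start) & (track.positions <= r.end)
    if not inside.any():
        checked = ", ".join(f"{r.chrom}:{r.start}-{r.end}" for r in background) or "none"
        raise ValidationError(
            f"no probe of {track.chrom} falls inside any background region "
            f"(checked: {checked})"
        )
    offset = float(track.values[inside].mean())
    return track.with_values(track.values - offset, background_offset=offset)


def difference_track(a: ProbeTrack, b: ProbeTrack) -> ProbeTrack:
    """Probe-wise ``a - b`` for two tracks on the identical probe design."""
    if a.chrom != b.chrom:
        raise ValidationError(f"chromosome mismatch: {a.chrom} vs {b.chrom}")
    if len(a) != len(b) or np.any(a.positions != b.positions):
        n = min(len(a), len(b))
        neq = np.nonzero(a.positions[:n] != b.positions[:n])[0]
        first = a.positions[neq[0]] if neq.size else a.positions[n] if len(a) > n else b.positions[n]
        raise ValidationError(
            f"probe positions differ between tracks (first mismatch at "
            f"{a.chrom}:{int(first)}); refusing to interpolate"
        )
    meta = {
        "assay": a.metadata.get("assay", "?"),
        "derived": "difference",
        "minuend": a.metadata.get("genotype", "a"),
        "subtrahend": b.metadata.get("genotype", "b"),
    }
    if "probe_length" in a.metadata:
        meta["probe_length"] = a.metadata["probe_length"]
    return ProbeTrack(a.chrom, a.positions.copy(), a.values - b.values, meta)
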