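"""Probe-level signal tracks: the in-memory container shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class ProbeTrack:
    """One log2-ratio value per probe position on a single chromosome.

    ``positions`` are probe *start* positions (1-based, strictly increasing);
    ``values`` are log2 Cy5/Cy3 ratios.  ``metadata`` carries free-form labels
    (assay, genotype, seed, processing history) that I/O propagates to file
    headers.
    """

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("positions and values must be one-dimensional")
        if len(self.positions) != len(self.values):
            raise ValidationError(
                f"positions ({len(self.positions)}) and values ({len(self.values)}) "
                "differ in length"
            )
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("track values must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def with_values(self, values: np.ndarray, **extra_metadata) -> "ProbeTrack":
        """Copy of the track with new values and updated metadata."""
        meta = dict(self.metadata)
        meta.update(extra_metadata)
        return ProbeTrack(self.chrom, self.positions.copy(), values, meta)
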