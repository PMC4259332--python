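"""Chromosome models, ARS annotations and deletion-edit arithmetic.

Coordinates are 1-based and fully closed throughout the package: the interval
(chrom, 10, 12) covers the three bases 10, 11 and 12.  On-disk BED files use
the standard 0-based half-open convention; conversion happens only at the I/O
boundary (:mod:`oriflex.io`).

An edited ("origin-deleted") genome keeps the *reference* coordinate frame for
all annotations and probe positions, because tiling-array probes are designed
against the reference sequence.  The :class:`CoordinateMap` returned by
:func:`apply_edits` translates between edited-genome and reference positions
when the physical mutant chromosome is of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable

from .errors import ValidationError

INTACT = "intact"
DELETED = "deleted"

#: Length of a loxP scar left behind by Cre-mediated marker excision.
LOXP_LENGTH = 34


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored closed interval ``[start, end]`` in bp (1-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(
                f"interval start must be >= 1, got {self.start} on {self.chrom}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"malformed interval on {self.chrom}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, pos: float) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Coordinate gap between two intervals on the same chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ValidationError(
                f"cannot measure distance across chromosomes ({self.chrom} vs {other.chrom})"
            )
        if self.overlaps(other):
            return 0
        if other.start > self.end:
            return other.start - self.end
        return self.start - other.end


def span_length(interval: GenomicInterval) -> int:
    """Number of bases covered by a closed interval: ``end - start + 1``."""
    return interval.length


@dataclass
class OriginAnnotation:
    """A named ARS: locus, intact/deleted status, and simulation parameters.

    ``sim`` holds an :class:`oriflex.simulate.OriginSimParams` (or ``None`` for
    annotation-only models loaded from BED).
    """

    name: str
    locus: GenomicInterval
    status: str = INTACT
    sim: Any = None

    def __post_init__(self):
        if self.status not in (INTACT, DELETED):
            raise ValidationError(f"origin {self.name}: unknown status {self.status!r}")


@dataclass(frozen=True)
class DeletionEdit:
    """One origin-deletion edit: a removed interval and its replacement cassette."""

    origin_name: str
    removed: GenomicInterval
    replacement_label: str
    replacement_length: int

    def __post_init__(self):
        if self.replacement_length < 0:
            raise ValidationError(
                f"edit {self.origin_name}: negative replacement length"
            )
        if self.replacement_label == "loxP" and self.replacement_length != LOXP_LENGTH:
            raise ValidationError(
                f"edit {self.origin_name}: a loxP scar is {LOXP_LENGTH} bp, "
                f"got {self.replacement_length}"
            )


@dataclass
class GenomeModel:
    """Chromosome lengths plus origin annotations, applied edits and background regions.

    ``background_regions`` are intervals known to stay unreplicated under the
    simulated conditions; they anchor track normalization downstream.
    """

    chromosomes: dict[str, int]
    origins: list[OriginAnnotation] = field(default_factory=list)
    edits: list[DeletionEdit] = field(default_factory=list)
    background_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        names = [o.name for o in self.origins]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate origin names: {', '.join(dupes)}")
        for o in self.origins:
            self._check_bounds(o.locus, f"origin {o.name}")
        for region in self.background_regions:
            self._check_bounds(region, "background region")
        _check_edits(self.edits, self.chromosomes)
        edited_names = {e.origin_name for e in self.edits}
        for o in self.origins:
            if (o.status == DELETED) != (o.name in edited_names):
                raise ValidationError(
                    f"origin {o.name}: status {o.status!r} inconsistent with edit table"
                )

    def _check_bounds(self, iv: GenomicInterval, what: str) -> None:
        if iv.chrom not in self.chromosomes:
            raise ValidationError(f"{what}: unknown chromosome {iv.chrom}")
        if iv.end > self.chromosomes[iv.chrom]:
            raise ValidationError(
                f"{what}: interval {iv.start}-{iv.end} exceeds {iv.chrom} "
                f"length {self.chromosomes[iv.chrom]}"
            )

    # -- accessors --------------------------------------------------------

    def origin(self, name: str) -> OriginAnnotation:
        for o in self.origins:
            if o.name == name:
                return o
        raise KeyError(name)

    def origins_on(self, chrom: str) -> list[OriginAnnotation]:
        return [o for o in self.origins if o.locus.chrom == chrom]

    def removed_spans(self, chrom: str) -> list[GenomicInterval]:
        return sorted(
            (e.removed for e in self.edits if e.removed.chrom == chrom),
            key=lambda iv: iv.start,
        )

    def edited_chromosome_length(self, chrom: str) -> int:
        """Physical length of the edited chromosome (reference length minus
        removed bases plus replacement cassettes)."""
        length = self.chromosomes[chrom]
        for e in self.edits:
            if e.removed.chrom == chrom:
                length += e.replacement_length - e.removed.length
        return length


def _check_edits(edits: Iterable[DeletionEdit], chromosomes: dict[str, int]) -> None:
    by_chrom: dict[str, list[DeletionEdit]] = {}
    for e in edits:
        if e.removed.chrom not in chromosomes:
            raise ValidationError(
                f"edit {e.origin_name}: unknown chromosome {e.removed.chrom}"
            )
        if e.removed.end > chromosomes[e.removed.chrom]:
            raise ValidationError(
                f"edit {e.origin_name}: removed interval exceeds chromosome bounds"
            )
        by_chrom.setdefault(e.removed.chrom, []).append(e)
    for chrom, group in by_chrom.items():
        ordered = sorted(group, key=lambda e: e.removed.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.removed.end >= b.removed.start:
                raise ValidationError(
                    f"overlapping edits on {chrom}: {a.origin_name} "
                    f"({a.removed.start}-{a.removed.end}) and {b.origin_name} "
                    f"({b.removed.start}-{b.removed.end})"
                )


@dataclass(frozen=True)
class _Segment:
    edited_start: int
    edited_end: int
    ref_start: int | None  # None marks replacement (non-reference) sequence


class CoordinateMap:
    """Bidirectional translation between edited-genome and reference positions.

    * ``to_reference``: edited position -> reference position, or ``None`` for
      positions inside replacement cassettes (non-reference sequence).
    * ``to_edited``: reference position -> edited position, or ``None`` for
      reference positions that were removed by an edit.
    """

    def __init__(self, segments: dict[str, list[_Segment]], chromosomes: dict[str, int]):
        self._segments = segments
        self._chromosomes = chromosomes

    def to_reference(self, chrom: str, pos: int) -> int | None:
        for seg in self._segments_for(chrom):
            if seg.edited_start <= pos <= seg.edited_end:
                if seg.ref_start is None:
                    return None
                return seg.ref_start + (pos - seg.edited_start)
        raise ValidationError(f"position {pos} outside edited {chrom}")

    def to_edited(self, chrom: str, pos: int) -> int | None:
        if not (1 <= pos <= self._chromosomes[chrom]):
            raise ValidationError(f"position {pos} outside reference {chrom}")
        for seg in self._segments_for(chrom):
            if seg.ref_start is None:
                continue
            ref_end = seg.ref_start + (seg.edited_end - seg.edited_start)
            if seg.ref_start <= pos <= ref_end:
                return seg.edited_start + (pos - seg.ref_start)
        return None

    def edited_length(self, chrom: str) -> int:
        segs = self._segments_for(chrom)
        return segs[-1].edited_end if segs else 0

    def _segments_for(self, chrom: str) -> list[_Segment]:
        if chrom not in self._chromosomes:
            raise ValidationError(f"unknown chromosome {chrom}")
        if chrom in self._segments:
            return self._segments[chrom]
        # untouched chromosome: identity
        length = self._chromosomes[chrom]
        return [_Segment(1, length, 1)] if length else []


def apply_edits(
    genome: GenomeModel, edits: list[DeletionEdit]
) -> tuple[GenomeModel, CoordinateMap]:
    """Apply a deletion-edit table to a genome model.

    Marks the matching origins deleted and returns the edited model (still in
    reference coordinates) together with a :class:`CoordinateMap`.  Raises
    :class:`ValidationError` for overlapping edits or edits naming unknown
    origins.
    """
    _check_edits(edits, genome.chromosomes)
    known = {o.name for o in genome.origins}
    for e in edits:
        if e.origin_name not in known:
            raise ValidationError(f"edit references unknown origin {e.origin_name!r}")

    edited_names = {e.origin_name for e in edits}
    new_origins = [
        replace_status(o, DELETED if o.name in edited_names else INTACT)
        for o in genome.origins
    ]
    edited = GenomeModel(
        chromosomes=dict(genome.chromosomes),
        origins=new_origins,
        edits=list(edits),
        background_regions=list(genome.background_regions),
    )

    segments: dict[str, list[_Segment]] = {}
    for chrom, length in genome.chromosomes.items():
        chrom_edits = sorted(
            (e for e in edits if e.removed.chrom == chrom), key=lambda e: e.removed.start
        )
        if not chrom_edits:
            continue
        segs: list[_Segment] = []
        cursor_ref = 1
        cursor_ed = 1
        for e in chrom_edits:
            if e.removed.start > cursor_ref:
                n = e.removed.start - cursor_ref
                segs.append(_Segment(cursor_ed, cursor_ed + n - 1, cursor_ref))
                cursor_ed += n
            if e.replacement_length > 0:
                segs.append(
                    _Segment(cursor_ed, cursor_ed + e.replacement_length - 1, None)
                )
                cursor_ed += e.replacement_length
            cursor_ref = e.removed.end + 1
        if cursor_ref <= length:
            n = length - cursor_ref + 1
            segs.append(_Segment(cursor_ed, cursor_ed + n - 1, cursor_ref))
        segments[chrom] = segs

    return edited, CoordinateMap(segments, dict(genome.chromosomes))


def replace_status(origin: OriginAnnotation, status: str) -> OriginAnnotation:
    return replace(origin, status=status)
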