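"""Text-format I/O: BED annotations, bedGraph tracks, TSV edit tables and reports.

Disk formats follow the usual genome-browser conventions (BED and bedGraph are
0-based half-open); everything in memory is 1-based closed.  Conversion happens
here and only here.  Track files carry ``# key=value`` header comments with
the tool version, config hash and seed so any output can be traced to the run
that produced it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import DeletionEdit, GenomeModel, GenomicInterval, OriginAnnotation
from .track import ProbeTrack

_EDIT_COLUMNS = ["origin", "replacement_label", "chrom", "start", "end", "replacement_length"]


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------


def write_bedgraph(track: ProbeTrack, path, header: dict | None = None) -> None:
    """Write one single-base bedGraph line per probe (at the probe start)."""
    path = Path(path)
    meta = dict(header or {})
    meta.update(track.metadata)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        for pos, val in zip(track.positions, track.values):
            fh.write(f"{track.chrom}\t{pos - 1}\t{pos}\t{val:.6g}\n")


def read_bedgraph(path) -> ProbeTrack:
    """Read a single-chromosome bedGraph written by :func:`write_bedgraph`."""
    path = Path(path)
    meta: dict = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 bedGraph columns")
            rows.append((fields[0], int(fields[1]), float(fields[3])))
    if not rows:
        raise ValidationError(f"{path}: empty bedGraph")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValidationError(
            f"{path}: multi-chromosome bedGraph not supported ({sorted(chroms)})"
        )
    positions = np.array([r[1] + 1 for r in rows], dtype=np.int64)
    values = np.array([r[2] for r in rows], dtype=np.float64)
    return ProbeTrack(rows[0][0], positions, values, meta)


# ---------------------------------------------------------------------------
# BED annotations
# ---------------------------------------------------------------------------


def _parse_bed(path) -> list[tuple[int, str, int, int, str]]:
    """Yield (lineno, chrom, start1, end, name) from a BED file."""
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = fields[3] if len(fields) > 3 else f"feature{lineno}"
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            out.append((lineno, fields[0], start0 + 1, end, name))
    return out


def read_background_bed(path) -> list[GenomicInterval]:
    return [GenomicInterval(c, s, e) for _, c, s, e, _ in _parse_bed(path)]


def load_annotations(
    path,
    chromosomes: dict[str, int],
    background_path=None,
) -> GenomeModel:
    """Build an annotation-only genome model from an origin BED file.

    The BED name column is the ARS identifier.  All origins load as intact
    (statuses follow from applying an edit table) with no simulation
    parameters attached.  Duplicate names and out-of-bounds coordinates raise
    :class:`ValidationError` with the offending line number.
    """
    origins = []
    seen: dict[str, int] = {}
    for lineno, chrom, start, end, name in _parse_bed(path):
        if chrom not in chromosomes:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
        if end > chromosomes[chrom]:
            raise ValidationError(
                f"{path}:{lineno}: {chrom}:{start}-{end} exceeds chromosome "
                f"length {chromosomes[chrom]}"
            )
        if name in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate origin name {name!r} "
                f"(first seen on line {seen[name]})"
            )
        seen[name] = lineno
        origins.append(OriginAnnotation(name, GenomicInterval(chrom, start, end)))
    background = read_background_bed(background_path) if background_path else []
    return GenomeModel(dict(chromosomes), origins, [], background)


def write_annotations(genome: GenomeModel, path, background_path=None) -> None:
    with Path(path).open("w") as fh:
        for o in genome.origins:
            fh.write(
                f"{o.locus.chrom}\t{o.locus.start - 1}\t{o.locus.end}\t{o.name}\t0\t.\n"
            )
    if background_path:
        with Path(background_path).open("w") as fh:
            for r in genome.background_regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tbackground\t0\t.\n")


def write_probes_bed(probes, path, header: dict | None = None) -> None:
    """Write a probe design as BED (one line per probe)."""
    with Path(path).open("w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        for i, start in enumerate(probes.starts):
            fh.write(
                f"{probes.chrom}\t{start - 1}\t{start - 1 + probes.probe_length}"
                f"\tprobe{i}\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# edit tables
# ---------------------------------------------------------------------------


def read_edit_table(path) -> list[DeletionEdit]:
    """Read a TSV edit table (origin, replacement_label, chrom, start, end,
    replacement_length); coordinates are 1-based closed, as printed."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _EDIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing edit-table columns {missing}")
    return [
        DeletionEdit(
            origin_name=str(row.origin),
            removed=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
            replacement_label=str(row.replacement_label),
            replacement_length=int(row.replacement_length),
        )
        for row in df.itertuples()
    ]


def write_edit_table(edits: list[DeletionEdit], path) -> None:
    df = pd.DataFrame(
        [
            {
                "origin": e.origin_name,
                "replacement_label": e.replacement_label,
                "chrom": e.removed.chrom,
                "start": e.removed.start,
                "end": e.removed.end,
                "replacement_length": e.replacement_length,
            }
            for e in edits
        ],
        columns=_EDIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peak output
# ---------------------------------------------------------------------------


def write_peaks_bed(peaks, path, header: dict | None = None) -> None:
    """Peaks as BED6: name = label:nearest_origin, score scaled to the tallest peak."""
    max_h = max((p.height for p in peaks), default=1.0)
    with Path(path).open("w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        for p in peaks:
            name = f"{p.label or 'peak'}:{p.nearest_origin or 'NA'}"
            score = int(round(1000 * min(p.height / max_h, 1.0))) if max_h > 0 else 0
            fh.write(
                f"{p.chrom}\t{p.bounds.start - 1}\t{p.bounds.end}\t{name}\t{score}\t.\n"
            )


def peaks_to_frame(peaks) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "summit": p.summit,
                "height": round(p.height, 6),
                "start": p.bounds.start,
                "end": p.bounds.end,
                "label": p.label or "",
                "nearest_origin": p.nearest_origin or "",
                "distance_to_origin": "" if p.distance_to_origin is None else p.distance_to_origin,
            }
            for p in peaks
        ],
        columns=[
            "chrom", "summit", "height", "start", "end",
            "label", "nearest_origin", "distance_to_origin",
        ],
    )
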