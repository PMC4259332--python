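"""End-to-end orchestration: simulate -> condition -> normalize -> compare -> call.

A run produces, for the wild-type and origin-deleted genotypes of every
configured chromosome: raw and processed ORC and BrdU bedGraphs, the
wild-type-minus-mutant ORC difference track, classified BrdU peak calls, an
ORC-depletion report, and a per-origin summary TSV.  Every output carries the
tool version, config hash and seed in its header; a run is byte-reproducible
given its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, datasets, io
from .errors import PipelineError, ValidationError
from .genome import DELETED, GenomeModel, apply_edits
from .normalize import background_normalize, difference_track
from .peaks import (
    DEFAULT_ASSIGN_RADIUS_BP,
    DEFAULT_MIN_SEPARATION_BP,
    call_peaks,
    classify_peaks,
    detect_depletion,
    robust_noise_scale,
)
from .simulate import SimConfig, design_probes, simulate_brdu_track, simulate_orc_track
from .smoothing import biweight_adjust, pseudomedian_filter
from .track import ProbeTrack

logger = logging.getLogger("oriflex")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (serializable, hashable)."""

    chromosomes: tuple[str, ...] = ("chrVI", "chrIII")
    edits: str = "builtin"  # "builtin" (seven-origin table), "none", or a TSV path
    sim: SimConfig = field(default_factory=SimConfig)
    probe_length: int = 50
    step: int = 8
    window_bp: float = 50.0
    biweight_c: float = 5.0
    min_separation_bp: float = DEFAULT_MIN_SEPARATION_BP
    assign_radius_bp: float = DEFAULT_ASSIGN_RADIUS_BP
    outdir: str = "oriflex_run"

    @property
    def seed(self) -> int:
        return self.sim.seed

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, sim=replace(self.sim, seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosomes"] = list(self.chromosomes)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where outputs land is not part of the science
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        sim = SimConfig(**data.pop("sim", {}))
        if "chromosomes" in data:
            data["chromosomes"] = tuple(data["chromosomes"])
        return cls(sim=sim, **data)

    def to_toml(self, path) -> None:
        d = self.to_dict()
        sim = d.pop("sim")
        lines = []
        for key, value in d.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
        lines.append("[sim]")
        for key, value in sim.items():
            lines.append(f"{key} = {_toml_value(value)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ValidationError(f"cannot serialize config value {value!r}")


@dataclass
class RunReport:
    """Paths of all run outputs plus the per-origin summary table."""

    outdir: Path
    config_hash: str
    paths: dict[str, Path]
    summary: pd.DataFrame

    @property
    def summary_path(self) -> Path:
        return self.paths["summary"]


def _stage(name: str, path=None):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(name, str(exc), str(path) if path else None) from exc

    return wrap


def _background_noise(track: ProbeTrack, genome: GenomeModel) -> float:
    """Robust noise scale from background-region probes; whole track if none."""
    regions = [r for r in genome.background_regions if r.chrom == track.chrom]
    inside = np.zeros(len(track), dtype=bool)
    for r in regions:
        inside |= (track.positions >= r.start) & (track.positions <= r.end)
    values = track.values[inside] if inside.any() else track.values
    return robust_noise_scale(values)


def _load_genomes(config: RunConfig):
    wt = datasets.reference_genome(config.chromosomes)
    if config.edits == "none":
        edits = []
    elif config.edits == "builtin":
        edits = [
            e
            for e in datasets.seven_origin_edits()
            if e.removed.chrom in config.chromosomes
        ]
    else:
        edits = [
            e
            for e in io.read_edit_table(config.edits)
            if e.removed.chrom in config.chromosomes
        ]
    mutant, coord_map = apply_edits(wt, edits)
    return wt, mutant, coord_map


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic-profile analysis for one configuration."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {
        "oriflex_version": __version__,
        "config": config.config_hash(),
        "seed": config.seed,
    }
    paths: dict[str, Path] = {}

    wt, mutant, _ = _stage("genome")(_load_genomes, config)
    probes = _stage("probe-design")(design_probes, wt, config.probe_length, config.step)

    def process(track: ProbeTrack) -> ProbeTrack:
        adjusted = biweight_adjust(track, c=config.biweight_c)
        return pseudomedian_filter(adjusted, window_bp=config.window_bp)

    def save(key: str, track: ProbeTrack) -> None:
        path = outdir / f"{key}.bedGraph"
        io.write_bedgraph(track, path, header)
        paths[key] = path
        logger.info("stage=write output=%s n=%d", path.name, len(track))

    summary_rows = []
    for chrom in config.chromosomes:
        tracks = {}
        for label, genome in (("wt", wt), ("7ori", mutant)):
            orc = _stage(f"simulate-orc-{label}")(
                simulate_orc_track, genome, probes[chrom], config.sim
            )
            brdu = _stage(f"simulate-brdu-{label}")(
                simulate_brdu_track, genome, probes[chrom], config.sim
            )
            save(f"{chrom}_{label}_orc_raw", orc)
            save(f"{chrom}_{label}_brdu_raw", brdu)
            orc_p = _stage(f"process-orc-{label}")(process, orc)
            brdu_p = _stage(f"process-brdu-{label}")(process, brdu)
            brdu_n = _stage(f"normalize-brdu-{label}")(
                background_normalize, brdu_p, genome.background_regions
            )
            save(f"{chrom}_{label}_orc_processed", orc_p)
            save(f"{chrom}_{label}_brdu_processed", brdu_n)
            tracks[label] = {"orc": orc_p, "brdu": brdu_n}

        diff = _stage("orc-difference")(
            difference_track, tracks["wt"]["orc"], tracks["7ori"]["orc"]
        )
        save(f"{chrom}_orc_diff", diff)

        depletion = _stage("depletion-detection")(
            detect_depletion,
            diff,
            mutant,
            None,
            config.min_separation_bp,
            config.assign_radius_bp,
        )
        dep_frame = io.peaks_to_frame(depletion.depletion_peaks)
        dep_path = outdir / f"{chrom}_depletion.tsv"
        with dep_path.open("w") as fh:
            for key, value in header.items():
                fh.write(f"# {key}={value}\n")
            if depletion.missed_origins:
                fh.write(f"# missed_origins={','.join(depletion.missed_origins)}\n")
            dep_frame.to_csv(fh, sep="\t", index=False)
        paths[f"{chrom}_depletion"] = dep_path

        brdu_mut = tracks["7ori"]["brdu"]
        noise = _background_noise(brdu_mut, mutant)
        brdu_peaks = _stage("brdu-peaks")(
            call_peaks, brdu_mut, 3.0 * noise, config.min_separation_bp
        )
        brdu_peaks = classify_peaks(brdu_peaks, mutant, config.assign_radius_bp)
        bed_path = outdir / f"{chrom}_7ori_brdu_peaks.bed"
        io.write_peaks_bed(brdu_peaks, bed_path, header)
        paths[f"{chrom}_7ori_brdu_peaks"] = bed_path

        for origin in mutant.origins_on(chrom):
            dep_hits = [
                p for p in depletion.depletion_peaks if p.nearest_origin == origin.name
            ]
            dep_best = max(dep_hits, key=lambda p: p.height, default=None)
            brdu_hits = [
                p
                for p in brdu_peaks
                if p.bounds.distance_to(origin.locus) <= config.assign_radius_bp
            ]
            brdu_best = max(brdu_hits, key=lambda p: p.height, default=None)
            summary_rows.append(
                {
                    "origin": origin.name,
                    "chrom": chrom,
                    "status": origin.status,
                    "depletion_height": round(dep_best.height, 4) if dep_best else "",
                    "depletion_summit": dep_best.summit if dep_best else "",
                    "brdu_peak": "yes" if brdu_best else "no",
                    "brdu_label": brdu_best.label if brdu_best else "",
                    "brdu_summit": brdu_best.summit if brdu_best else "",
                    "brdu_height": round(brdu_best.height, 4) if brdu_best else "",
                }
            )

    summary = pd.DataFrame(summary_rows)
    summary_path = outdir / "summary.tsv"
    with summary_path.open("w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        summary.to_csv(fh, sep="\t", index=False)
    paths["summary"] = summary_path
    config.to_toml(outdir / "run_config.toml")
    paths["config"] = outdir / "run_config.toml"
    return RunReport(outdir, config.config_hash(), paths, summary)


def make_fixtures(outdir) -> dict[str, Path]:
    """Write the small, deterministic test inputs (idempotent, byte-stable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    chr6 = datasets.reference_genome(("chrVI",))
    paths["chrVI_origins"] = outdir / "chrVI_origins.bed"
    paths["chrVI_background"] = outdir / "chrVI_background.bed"
    io.write_annotations(chr6, paths["chrVI_origins"], paths["chrVI_background"])

    paths["edits"] = outdir / "edits_7ori.tsv"
    io.write_edit_table(datasets.seven_origin_edits(), paths["edits"])

    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    with paths["chrom_sizes"].open("w") as fh:
        for chrom, length in datasets.CHROMOSOME_LENGTHS.items():
            fh.write(f"{chrom}\t{length}\n")

    # 200 kb toy chromosome with two origins, for fast unit-style runs
    from .genome import GenomicInterval, OriginAnnotation
    from .simulate import OriginSimParams

    toy = GenomeModel(
        {"toy": 200_000},
        [
            OriginAnnotation(
                "TOY1",
                GenomicInterval("toy", 49_900, 50_100),
                sim=OriginSimParams(50_000.0, 0.8, orc_height=2.5),
            ),
            OriginAnnotation(
                "TOY2",
                GenomicInterval("toy", 149_900, 150_100),
                sim=OriginSimParams(150_000.0, 0.6, orc_height=2.0),
            ),
        ],
        background_regions=[GenomicInterval("toy", 95_000, 105_000)],
    )
    paths["toy_origins"] = outdir / "toy_origins.bed"
    paths["toy_background"] = outdir / "toy_background.bed"
    io.write_annotations(toy, paths["toy_origins"], paths["toy_background"])
    cfg = SimConfig(seed=0, noise_sd=0.1)
    toy_probes = design_probes(toy, probe_length=50, step=200)["toy"]
    header = {"oriflex_version": __version__, "fixture": "toy", "seed": 0}
    paths["toy_probes"] = outdir / "toy_probes.bed"
    io.write_probes_bed(toy_probes, paths["toy_probes"], header)
    paths["toy_orc"] = outdir / "toy_orc.bedGraph"
    io.write_bedgraph(simulate_orc_track(toy, toy_probes, cfg), paths["toy_orc"], header)
    paths["toy_brdu"] = outdir / "toy_brdu.bedGraph"
    io.write_bedgraph(
        simulate_brdu_track(toy, toy_probes, cfg), paths["toy_brdu"], header
    )
    return paths
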