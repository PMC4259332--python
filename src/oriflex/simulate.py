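"""Synthetic tiling-array data: probe designs, ORC binding and BrdU fork models.

The generator emulates the study conditions: a custom array of 50-mer probes
overlapping by 42 bp on average; Orc2 ChIP log2 ratios with discrete Gaussian
peaks at intact origins and low residual binding near deleted ones; and BrdU
incorporation tracks from cells released into 200 mM hydroxyurea for 60 min,
where stalled forks confine replication to the neighborhoods of fired origins.

Replication model
-----------------
Each origin ``i`` fires independently in a given cell with probability
``efficiency_i`` at ``fire_time_i`` minutes after release; a fired origin
replicates every position within ``fork_speed * (t_total - fire_time_i)`` of
its position.  The population replication fraction at position ``x`` is

    f(x) = 1 - prod_i (1 - efficiency_i * reach_i(x))

with ``reach_i(x)`` the 0/1 indicator that origin ``i`` can reach ``x``.
Fork collisions and passive-replication interactions between converging forks
are ignored (independence approximation): under 200 mM HU fork travel (~6 kb)
is short relative to inter-origin spacing.

A deleted origin is replaced by ``residual_subsites`` low-efficiency
initiation sites placed in the sequence flanking the removed span (mutant DNA
inside the span does not exist), sharing the residual initiation mass
``residual_fraction * efficiency``.  Probes that overlap a removed span report
background plus noise only: the mutant sample carries no DNA complementary to
reference-designed probes there.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .genome import DELETED, GenomeModel, OriginAnnotation
from .track import ProbeTrack

_ASSAY_ORC = 1
_ASSAY_BRDU = 2
_STREAM_LAYOUT = 3


def _chrom_code(chrom: str) -> int:
    return zlib.crc32(chrom.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class ProbeSet:
    """Ordered probe start positions (1-based) for one chromosome."""

    chrom: str
    starts: np.ndarray
    probe_length: int = 50

    def __post_init__(self):
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        if len(self.starts) == 0:
            raise ValidationError(f"empty probe set on {self.chrom}")
        if np.any(np.diff(self.starts) <= 0):
            raise ValidationError("probe starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + (self.probe_length - 1) / 2.0

    @property
    def mean_overlap(self) -> float:
        """Mean overlap in bp between consecutive probes."""
        if len(self.starts) < 2:
            return 0.0
        return float(self.probe_length - np.mean(np.diff(self.starts)))


@dataclass(frozen=True)
class OriginSimParams:
    """Per-origin simulation parameters.

    efficiency
        Probability that the origin fires in a given cell.
    fire_time
        Minutes after release into S phase at which the origin fires.
    orc_height
        Orc2 ChIP peak amplitude in log2 units.
    residual_fraction
        Multiplier applied to efficiency (split across residual sub-sites) and
        to orc_height when the origin is deleted.
    """

    position: float
    efficiency: float
    fire_time: float = 0.0
    orc_height: float = 2.5
    residual_fraction: float = 0.15

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValidationError(f"efficiency must be in [0,1], got {self.efficiency}")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValidationError(
                f"residual_fraction must be in [0,1], got {self.residual_fraction}"
            )
        if self.fire_time < 0:
            raise ValidationError(f"fire_time must be >= 0, got {self.fire_time}")


@dataclass(frozen=True)
class SimConfig:
    """Global simulation settings.

    fork_speed is in kb/min under hydroxyurea (default 0.1, an HU-stalled
    fork); t_total in minutes; orc_peak_sd in bp (half the 250 bp average
    chromatin fragment size); noise levels in log2 units.
    """

    fork_speed: float = 0.1
    t_total: float = 60.0
    hu_mM: float = 200.0
    orc_peak_sd: float = 125.0
    background_level: float = 0.0
    noise_sd: float = 0.12
    brdu_gain: float = 3.0
    seed: int = 0
    telomere_artifact: bool = False
    residual_subsites: int = 3
    residual_jitter_bp: float = 2000.0

    def __post_init__(self):
        for name in ("fork_speed", "t_total", "orc_peak_sd", "residual_jitter_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd < 0 or self.brdu_gain < 0:
            raise ValidationError("noise_sd and brdu_gain must be non-negative")
        if self.residual_subsites < 1:
            raise ValidationError("residual_subsites must be >= 1")

    @property
    def max_reach_bp(self) -> float:
        return self.fork_speed * 1000.0 * self.t_total


def default_sim_params(origin: OriginAnnotation) -> OriginSimParams:
    """Fallback parameters for annotation-only origins (e.g. loaded from BED)."""
    return OriginSimParams(position=origin.locus.midpoint, efficiency=0.8)


def design_probes(
    genome: GenomeModel, probe_length: int = 50, step: int = 8
) -> dict[str, ProbeSet]:
    """Deterministic tiling from position 1 with fixed step per chromosome.

    Consecutive probes overlap by ``probe_length - step`` bp (42 bp at the
    default 50-mer / 8 bp-step design).
    """
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    if probe_length < 1:
        raise ValidationError(f"probe_length must be >= 1, got {probe_length}")
    out = {}
    for chrom, length in genome.chromosomes.items():
        if step >= length or probe_length > length:
            raise ValidationError(
                f"cannot tile {chrom} (length {length}) with {probe_length}-mers "
                f"at step {step}"
            )
        starts = np.arange(1, length - probe_length + 2, step, dtype=np.int64)
        out[chrom] = ProbeSet(chrom, starts, probe_length)
    return out


# ---------------------------------------------------------------------------
# replication fraction
# ---------------------------------------------------------------------------


def _reach_bp(params: OriginSimParams, cfg: SimConfig) -> float:
    return max(0.0, cfg.fork_speed * 1000.0 * (cfg.t_total - params.fire_time))


def replication_fraction(
    x, origins: Sequence[OriginSimParams], cfg: SimConfig
) -> np.ndarray | float:
    """Population fraction of cells in which position ``x`` is replicated.

    Accepts a scalar or array of positions; origins fire independently.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=np.float64))
    not_repl = np.ones_like(xs)
    for o in origins:
        reach = _reach_bp(o, cfg)
        hit = np.abs(xs - o.position) <= reach
        not_repl *= np.where(hit, 1.0 - o.efficiency, 1.0)
    f = 1.0 - not_repl
    return float(f[0]) if np.isscalar(x) or np.ndim(x) == 0 else f


def replication_fraction_mc(
    x,
    origins: Sequence[OriginSimParams],
    cfg: SimConfig,
    n_cells: int = 100_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """Monte-Carlo estimate of :func:`replication_fraction` by simulating
    per-cell origin firing; the independent cross-check for the closed form."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    xs = np.atleast_1d(np.asarray(x, dtype=np.float64))
    replicated = np.zeros((n_cells, xs.size), dtype=bool)
    for o in origins:
        fired = rng.random(n_cells) < o.efficiency
        hit = np.abs(xs - o.position) <= _reach_bp(o, cfg)
        replicated |= fired[:, None] & hit[None, :]
    f = replicated.mean(axis=0)
    return float(f[0]) if np.isscalar(x) or np.ndim(x) == 0 else f


# ---------------------------------------------------------------------------
# genotype-aware initiator layout
# ---------------------------------------------------------------------------


def residual_sites(
    genome: GenomeModel, cfg: SimConfig
) -> dict[str, list[tuple[float, OriginSimParams]]]:
    """Residual initiation sites flanking each removed span, keyed by origin name.

    Site positions are drawn once per (seed, chromosome, origin): each of the
    ``residual_subsites`` sites falls uniformly within ``residual_jitter_bp``
    of one edge of the removed span, outside it.  Each site carries
    ``residual_fraction * efficiency / residual_subsites`` firing probability
    and the parent's firing time.
    """
    spans = {e.origin_name: e.removed for e in genome.edits}
    out: dict[str, list[tuple[float, OriginSimParams]]] = {}
    for chrom in genome.chromosomes:
        for idx, origin in enumerate(genome.origins_on(chrom)):
            if origin.status != DELETED:
                continue
            params = origin.sim or default_sim_params(origin)
            span = spans[origin.name]
            rng = np.random.default_rng(
                [cfg.seed, _STREAM_LAYOUT, _chrom_code(chrom), idx]
            )
            length = genome.chromosomes[chrom]
            k = cfg.residual_subsites
            sites = []
            for _ in range(k):
                offset = rng.uniform(0.0, cfg.residual_jitter_bp)
                if rng.integers(2) == 0:
                    pos = span.start - offset
                else:
                    pos = span.end + offset
                pos = float(np.clip(pos, 1, length))
                sub = replace(
                    params,
                    position=pos,
                    efficiency=params.residual_fraction * params.efficiency / k,
                )
                sites.append((pos, sub))
            out[origin.name] = sites
    return out


def effective_initiators(
    genome: GenomeModel, chrom: str, cfg: SimConfig
) -> list[OriginSimParams]:
    """Initiation sites active on ``chrom``: intact origins as annotated,
    deleted origins replaced by their residual flanking sites."""
    sites = residual_sites(genome, cfg)
    initiators: list[OriginSimParams] = []
    for origin in genome.origins_on(chrom):
        params = origin.sim or default_sim_params(origin)
        if origin.status == DELETED:
            initiators.extend(sub for _, sub in sites[origin.name])
        else:
            initiators.append(params)
    return initiators


def _masked_probes(genome: GenomeModel, probes: ProbeSet) -> np.ndarray:
    """Boolean mask of probes overlapping any removed span (absent in mutant DNA)."""
    mask = np.zeros(len(probes), dtype=bool)
    ends = probes.starts + probes.probe_length - 1
    for span in genome.removed_spans(probes.chrom):
        mask |= (probes.starts <= span.end) & (ends >= span.start)
    return mask


def _default_rng(genome: GenomeModel, chrom: str, cfg: SimConfig, assay: int):
    return np.random.default_rng(
        [cfg.seed, assay, _chrom_code(chrom), len(genome.edits)]
    )


def _genotype(genome: GenomeModel) -> str:
    return "edited" if genome.edits else "wild-type"


def simulate_brdu_track(
    genome: GenomeModel,
    probes: ProbeSet,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> ProbeTrack:
    """BrdU-IP log2 ratio track: ``brdu_gain * f(midpoint) + N(0, noise_sd)``.

    ``f`` is the replication fraction under the HU fork model evaluated at
    probe midpoints.  Probes inside removed spans carry noise only.  The
    optional telomere artifact adds a cross-hybridization bump near the left
    telomere of the edited genotype.
    """
    if rng is None:
        rng = _default_rng(genome, probes.chrom, cfg, _ASSAY_BRDU)
    initiators = effective_initiators(genome, probes.chrom, cfg)
    f = replication_fraction(probes.midpoints, initiators, cfg)
    signal = cfg.brdu_gain * np.asarray(f)
    signal[_masked_probes(genome, probes)] = 0.0
    if cfg.telomere_artifact and genome.edits:
        x = probes.midpoints
        signal = signal + 1.0 * np.exp(-((x - 3000.0) ** 2) / (2 * 1500.0**2))
    values = signal + rng.normal(0.0, cfg.noise_sd, size=len(probes))
    return ProbeTrack(
        probes.chrom,
        probes.starts,
        values,
        metadata={
            "assay": "BrdU-IP",
            "genotype": _genotype(genome),
            "seed": cfg.seed,
            "hu_mM": cfg.hu_mM,
            "t_total_min": cfg.t_total,
            "probe_length": probes.probe_length,
        },
    )


def simulate_orc_track(
    genome: GenomeModel,
    probes: ProbeSet,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> ProbeTrack:
    """Orc2 ChIP-chip log2 ratio track.

    Intact origins contribute Gaussian peaks of their ``orc_height`` (sd
    ``orc_peak_sd``, reflecting the chromatin fragment size); deleted origins
    contribute low residual peaks (``residual_fraction * orc_height``) at
    their residual initiation sites.  Probes inside removed spans report
    background plus noise only.
    """
    if rng is None:
        rng = _default_rng(genome, probes.chrom, cfg, _ASSAY_ORC)
    x = probes.midpoints
    signal = np.full(len(probes), cfg.background_level, dtype=np.float64)
    sites = residual_sites(genome, cfg)
    sd2 = 2.0 * cfg.orc_peak_sd**2
    for origin in genome.origins_on(probes.chrom):
        params = origin.sim or default_sim_params(origin)
        if origin.status == DELETED:
            h = params.residual_fraction * params.orc_height
            for pos, _ in sites[origin.name]:
                signal += h * np.exp(-((x - pos) ** 2) / sd2)
        else:
            signal += params.orc_height * np.exp(-((x - params.position) ** 2) / sd2)
    mask = _masked_probes(genome, probes)
    signal[mask] = cfg.background_level
    values = signal + rng.normal(0.0, cfg.noise_sd, size=len(probes))
    return ProbeTrack(
        probes.chrom,
        probes.starts,
        values,
        metadata={
            "assay": "Orc2-ChIP",
            "genotype": _genotype(genome),
            "seed": cfg.seed,
            "probe_length": probes.probe_length,
        },
    )
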