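"""Built-in genome fixtures: the chromosome VI origin-deletion system.

Chromosome lengths are the S288C reference lengths.  Deleted-origin loci are
the exact removed intervals from the published deletion table; intact-origin
loci are approximate (OriDB-style midpoints, flagged as such) — accurate to a
few hundred bp, which is immaterial for simulation and classification at the
5 kb assignment radius.  Per-origin firing efficiencies, times and ORC peak
heights are simulator parameters, not measurements.
"""

from __future__ import annotations

from .genome import (
    DeletionEdit,
    GenomeModel,
    GenomicInterval,
    OriginAnnotation,
    apply_edits,
)
from .simulate import OriginSimParams

CHROMOSOME_LENGTHS = {
    "chrIII": 316_620,
    "chrVI": 270_161,
    "chrXII": 1_078_177,
}

#: Known unreplicated regions in 200 mM HU, used for track normalization.
BACKGROUND_REGIONS = [
    ("chrIII", 184_000, 192_000),
    ("chrVI", 80_000, 86_000),
    ("chrXII", 845_000, 870_000),
]

# name, chrom, locus start, locus end, efficiency, fire_time (min), orc_height
# Deleted-origin loci are the removed intervals of the edit table below.
_ORIGINS = [
    ("ARS600",   "chrVI",   5_435,  20_826, 0.70,  0.0, 2.2),
    ("ARS601/2", "chrVI",  32_473,  33_247, 0.80,  0.0, 2.6),
    ("ARS602.5", "chrVI",  56_850,  57_150, 0.75,  0.0, 2.4),
    ("ARS603",   "chrVI",  68_693,  68_871, 0.85,  0.0, 2.8),
    ("ARS603.1", "chrVI",  97_850,  98_150, 0.70,  0.0, 2.3),
    ("ARS603.5", "chrVI", 118_637, 118_957, 0.75,  0.0, 2.4),
    ("ARS604",   "chrVI", 127_751, 128_071, 0.85,  0.0, 2.7),
    ("ARS605",   "chrVI", 135_985, 136_085, 0.80,  0.0, 2.5),
    ("ARS606",   "chrVI", 167_614, 168_048, 0.90,  0.0, 2.9),
    ("ARS607",   "chrVI", 199_250, 199_550, 0.90,  0.0, 3.0),
    ("ARS608",   "chrVI", 216_650, 216_950, 0.80,  0.0, 2.6),
    ("ARS609",   "chrVI", 255_350, 255_650, 0.40, 30.0, 2.2),
    ("ARS305",   "chrIII", 39_350,  39_650, 0.85,  0.0, 2.8),
    ("ARS306",   "chrIII", 74_350,  74_650, 0.75,  0.0, 2.5),
    ("ARS307",   "chrIII", 108_750, 109_050, 0.85, 0.0, 2.7),
    ("ARS309",   "chrIII", 134_050, 134_350, 0.60, 0.0, 2.3),
    ("ARS310",   "chrIII", 166_350, 166_650, 0.80, 0.0, 2.6),
    ("ARS315",   "chrIII", 224_550, 224_850, 0.70, 0.0, 2.4),
    ("ARS316",   "chrIII", 232_750, 233_050, 0.40, 30.0, 2.0),
]

#: Residual initiation/binding retained around a deleted origin, as a fraction
#: of the intact origin's efficiency and ORC peak height.
DEFAULT_RESIDUAL_FRACTION = 0.15

# The seven-origin deletion table (coordinates as printed; 1-based closed).
# Only the 34 bp loxP scar length is a published value; marker cassette
# lengths are plausible stand-ins.
_EDITS = [
    ("ARS600",   "LEU2",  5_435,  20_826, 2_230),
    ("ARS601/2", "loxP",  32_473, 33_247, 34),
    ("ARS603",   "loxP",  68_693, 68_871, 34),
    ("ARS603.5", "KanMX", 118_637, 118_957, 1_484),
    ("ARS604",   "loxP",  127_751, 128_071, 34),
    ("ARS605",   "loxP",  135_985, 136_085, 34),
    ("ARS606",   "ADE2",  167_614, 168_048, 2_271),
]


def reference_genome(
    chromosomes: tuple[str, ...] = ("chrVI", "chrIII", "chrXII"),
    residual_fraction: float = DEFAULT_RESIDUAL_FRACTION,
) -> GenomeModel:
    """Wild-type genome model for the requested chromosomes."""
    unknown = [c for c in chromosomes if c not in CHROMOSOME_LENGTHS]
    if unknown:
        raise KeyError(f"no built-in model for chromosome(s) {unknown}")
    chrom_lengths = {c: CHROMOSOME_LENGTHS[c] for c in chromosomes}
    origins = []
    for name, chrom, start, end, eff, fire, height in _ORIGINS:
        if chrom not in chrom_lengths:
            continue
        locus = GenomicInterval(chrom, start, end)
        origins.append(
            OriginAnnotation(
                name,
                locus,
                sim=OriginSimParams(
                    position=locus.midpoint,
                    efficiency=eff,
                    fire_time=fire,
                    orc_height=height,
                    residual_fraction=residual_fraction,
                ),
            )
        )
    background = [
        GenomicInterval(c, s, e) for c, s, e in BACKGROUND_REGIONS if c in chrom_lengths
    ]
    return GenomeModel(chrom_lengths, origins, [], background)


def seven_origin_edits(
    chromosomes: tuple[str, ...] = ("chrVI", "chrIII", "chrXII"),
) -> list[DeletionEdit]:
    """The seven-origin deletion-edit table (all edits are on chrVI)."""
    return [
        DeletionEdit(name, GenomicInterval(chrom_vi, start, end), label, repl)
        for name, label, start, end, repl in _EDITS
        if (chrom_vi := "chrVI") in chromosomes
    ]


def origin_depleted_genome(
    chromosomes: tuple[str, ...] = ("chrVI", "chrIII", "chrXII"),
    residual_fraction: float = DEFAULT_RESIDUAL_FRACTION,
):
    """Convenience: (edited genome, coordinate map) with all seven deletions."""
    wt = reference_genome(chromosomes, residual_fraction)
    return apply_edits(wt, seven_origin_edits(chromosomes))
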