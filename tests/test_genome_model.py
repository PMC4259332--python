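"""Interval arithmetic, deletion-edit application and annotation I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oriflex import (
    DeletionEdit,
    GenomeModel,
    GenomicInterval,
    OriginAnnotation,
    ValidationError,
    apply_edits,
    span_length,
)
from oriflex import datasets, io


@pytest.mark.parametrize(
    "start,end,expected",
    [
        (32_473, 33_247, 775),   # ARS601/2 deletion
        (68_693, 68_871, 179),   # ARS603
        (118_637, 118_957, 321), # ARS603.5
        (127_751, 128_071, 321), # ARS604
        (135_985, 136_085, 101), # ARS605
        (100, 100, 1),           # single base
    ],
)
def test_span_length_closed_convention(start, end, expected):
    assert span_length(GenomicInterval("chrVI", start, end)) == expected


def test_span_length_rejects_malformed_interval():
    with pytest.raises(ValidationError):
        GenomicInterval("chrVI", 100, 99)
    with pytest.raises(ValidationError):
        GenomicInterval("chrVI", 0, 10)


@given(st.integers(1, 10_000), st.integers(0, 500))
def test_span_length_counts_integer_positions(start, extra):
    iv = GenomicInterval("chr", start, start + extra)
    assert span_length(iv) == len(range(iv.start, iv.end + 1))


def _toy_genome(length=1000, origin=("ORI1", 480, 520)):
    name, s, e = origin
    return GenomeModel(
        {"toy": length}, [OriginAnnotation(name, GenomicInterval("toy", s, e))]
    )


def test_apply_empty_edits_is_identity():
    genome = _toy_genome()
    edited, cmap = apply_edits(genome, [])
    assert all(o.status == "intact" for o in edited.origins)
    assert edited.edited_chromosome_length("toy") == 1000
    for pos in (1, 500, 1000):
        assert cmap.to_reference("toy", pos) == pos
        assert cmap.to_edited("toy", pos) == pos


def test_apply_edits_conservation_against_symbolic_sequence():
    # independent oracle: materialize the edited chromosome as a symbol string
    genome = _toy_genome()
    edit = DeletionEdit("ORI1", GenomicInterval("toy", 450, 550), "loxP", 34)
    edited, cmap = apply_edits(genome, [edit])
    reference = [f"r{i}" for i in range(1, 1001)]
    materialized = reference[:449] + ["N"] * 34 + reference[550:]
    assert len(materialized) == 1000 - 101 + 34 == 933
    assert edited.edited_chromosome_length("toy") == len(materialized)
    assert cmap.edited_length("toy") == len(materialized)
    # the map agrees with the symbol string position by position
    for pos in range(1, len(materialized) + 1):
        symbol = materialized[pos - 1]
        ref = cmap.to_reference("toy", pos)
        if symbol == "N":
            assert ref is None
        else:
            assert symbol == f"r{ref}"


def test_seven_origin_edit_table_marks_seven_deleted(reference_pair):
    _, mutant = reference_pair
    deleted = [o for o in mutant.origins if o.status == "deleted"]
    assert len(deleted) == 7
    assert {o.locus.chrom for o in deleted} == {"chrVI"}


def test_apply_edits_rejects_unknown_origin_and_overlaps():
    genome = _toy_genome()
    with pytest.raises(ValidationError, match="unknown origin"):
        apply_edits(
            genome, [DeletionEdit("NOPE", GenomicInterval("toy", 10, 20), "loxP", 34)]
        )
    g2 = GenomeModel(
        {"toy": 1000},
        [
            OriginAnnotation("A", GenomicInterval("toy", 100, 110)),
            OriginAnnotation("B", GenomicInterval("toy", 150, 160)),
        ],
    )
    with pytest.raises(ValidationError, match="overlapping"):
        apply_edits(
            g2,
            [
                DeletionEdit("A", GenomicInterval("toy", 90, 200), "loxP", 34),
                DeletionEdit("B", GenomicInterval("toy", 150, 300), "loxP", 34),
            ],
        )


def test_loxp_replacement_must_be_34_bp():
    with pytest.raises(ValidationError):
        DeletionEdit("X", GenomicInterval("toy", 10, 20), "loxP", 100)


def test_length_conservation_on_random_edit_sets():
    rng = np.random.default_rng(42)
    for _ in range(200):
        length = int(rng.integers(200, 20_000))
        n_edits = int(rng.integers(0, 6))
        cuts = np.sort(rng.choice(np.arange(1, length + 1), 2 * n_edits, replace=False))
        origins, edits = [], []
        for k in range(n_edits):
            s, e = int(cuts[2 * k]), int(cuts[2 * k + 1] - 1)
            if e < s:
                continue
            name = f"O{k}"
            origins.append(OriginAnnotation(name, GenomicInterval("c", s, e)))
            repl = int(rng.integers(0, 200))
            edits.append(DeletionEdit(name, GenomicInterval("c", s, e), "marker", repl))
        genome = GenomeModel({"c": length}, origins)
        edited, cmap = apply_edits(genome, edits)
        expected = (
            length
            - sum(e.removed.length for e in edits)
            + sum(e.replacement_length for e in edits)
        )
        assert edited.edited_chromosome_length("c") == expected
        assert cmap.edited_length("c") == expected


def test_coordinate_map_is_injective_and_order_preserving():
    genome = GenomeModel(
        {"c": 500},
        [
            OriginAnnotation("A", GenomicInterval("c", 100, 150)),
            OriginAnnotation("B", GenomicInterval("c", 300, 320)),
        ],
    )
    edits = [
        DeletionEdit("A", GenomicInterval("c", 100, 150), "loxP", 34),
        DeletionEdit("B", GenomicInterval("c", 300, 320), "marker", 5),
    ]
    _, cmap = apply_edits(genome, edits)
    mapped = [
        cmap.to_reference("c", p)
        for p in range(1, cmap.edited_length("c") + 1)
    ]
    refs = [r for r in mapped if r is not None]
    assert len(refs) == len(set(refs))          # injective
    assert refs == sorted(refs)                 # order-preserving
    # removed reference positions map to nothing, others round-trip
    for p in range(1, 501):
        e = cmap.to_edited("c", p)
        if 100 <= p <= 150 or 300 <= p <= 320:
            assert e is None
        else:
            assert cmap.to_reference("c", e) == p


def test_bed_round_trip_and_validation(tmp_path):
    bed = tmp_path / "origins.bed"
    content = (
        "chrVI\t56849\t57150\tARS602.5\t0\t.\n"
        "chrVI\t199249\t199550\tARS607\t0\t.\n"
        "chrVI\t216649\t216950\tARS608\t0\t.\n"
    )
    bed.write_text(content)
    sizes = {"chrVI": 270_161}
    genome = io.load_annotations(bed, sizes)
    assert [o.name for o in genome.origins] == ["ARS602.5", "ARS607", "ARS608"]
    assert genome.origins[0].locus.start == 56_850  # 0-based -> 1-based
    out = tmp_path / "rt.bed"
    io.write_annotations(genome, out)
    assert out.read_text().split() == content.split()

    empty = tmp_path / "empty.bed"
    empty.write_text("")
    assert io.load_annotations(empty, sizes).origins == []

    dup = tmp_path / "dup.bed"
    dup.write_text("chrVI\t10\t20\tA\nchrVI\t30\t40\tA\n")
    with pytest.raises(ValidationError, match="dup.bed:2"):
        io.load_annotations(dup, sizes)

    oob = tmp_path / "oob.bed"
    oob.write_text("chrVI\t10\t999999999\tA\n")
    with pytest.raises(ValidationError, match="oob.bed:1"):
        io.load_annotations(oob, sizes)


def test_edit_table_tsv_round_trip(tmp_path):
    edits = datasets.seven_origin_edits()
    path = tmp_path / "edits.tsv"
    io.write_edit_table(edits, path)
    assert io.read_edit_table(path) == edits
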