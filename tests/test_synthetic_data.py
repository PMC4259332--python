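"""Probe design, the HU fork-progression model and track simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oriflex import (
    GenomeModel,
    GenomicInterval,
    OriginAnnotation,
    OriginSimParams,
    SimConfig,
    ValidationError,
    design_probes,
    replication_fraction,
    replication_fraction_mc,
    simulate_brdu_track,
    simulate_orc_track,
)
from oriflex.genome import apply_edits, DeletionEdit
from oriflex.simulate import ProbeSet


class TestDesignProbes:
    def test_default_design_overlaps_by_42_bp(self):
        genome = GenomeModel({"c": 10_000})
        probes = design_probes(genome, probe_length=50, step=8)["c"]
        assert probes.mean_overlap == 42.0
        assert np.all(np.diff(probes.starts) == 8)

    def test_non_overlapping_design(self):
        genome = GenomeModel({"c": 10_000})
        assert design_probes(genome, 50, 50)["c"].mean_overlap == 0.0

    def test_probe_count_matches_enumeration(self):
        # floor((1000-50)/8)+1 = 119, verified by explicit enumeration
        genome = GenomeModel({"c": 1_000})
        probes = design_probes(genome, 50, 8)["c"]
        enumerated = [s for s in range(1, 1001, 8) if s + 49 <= 1000]
        assert len(probes) == len(enumerated) == 119
        assert probes.starts[0] == 1 and probes.starts[-1] == enumerated[-1]

    def test_step_larger_than_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            design_probes(GenomeModel({"c": 100}), 50, 100)


def _cfg(**kw):
    kw.setdefault("seed", 11)
    return SimConfig(**kw)


class TestReplicationFraction:
    def test_certain_origin_replicates_itself(self):
        o = OriginSimParams(10_000.0, efficiency=1.0, fire_time=0.0)
        assert replication_fraction(10_000.0, [o], _cfg()) == 1.0

    def test_unreachable_position_is_zero(self):
        # max reach = 0.1 kb/min * 60 min = 6 kb
        o = OriginSimParams(10_000.0, efficiency=1.0, fire_time=0.0)
        assert replication_fraction(20_000.0, [o], _cfg()) == 0.0

    def test_two_independent_half_efficient_origins(self):
        origins = [
            OriginSimParams(10_000.0, 0.5),
            OriginSimParams(12_000.0, 0.5),
        ]
        assert replication_fraction(11_000.0, origins, _cfg()) == pytest.approx(0.75)

    def test_matches_montecarlo_cell_simulation(self):
        origins = [
            OriginSimParams(10_000.0, 0.5),
            OriginSimParams(14_000.0, 0.7, fire_time=20.0),
        ]
        cfg = _cfg()
        xs = np.array([8_000.0, 11_000.0, 12_500.0, 15_000.0, 30_000.0])
        f = replication_fraction(xs, origins, cfg)
        fhat = replication_fraction_mc(
            xs, origins, cfg, n_cells=50_000, rng=np.random.default_rng(5)
        )
        se = np.sqrt(np.maximum(f * (1 - f), 1e-12) / 50_000)
        assert np.all(np.abs(f - fhat) <= np.maximum(3 * se, 1e-9))

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 60.0),
        st.floats(0.0, 50_000.0),
    )
    def test_bounded_and_monotone_in_distance(self, eff, fire, dist):
        o = OriginSimParams(25_000.0, eff, fire_time=fire)
        cfg = _cfg()
        f_near = replication_fraction(25_000.0 + dist / 2, [o], cfg)
        f_far = replication_fraction(25_000.0 + dist, [o], cfg)
        assert 0.0 <= f_far <= f_near <= 1.0


def _single_origin_genome(noise=0.0, **origin_kw):
    origin_kw.setdefault("efficiency", 0.8)
    return GenomeModel(
        {"c": 60_000},
        [
            OriginAnnotation(
                "ORI1",
                GenomicInterval("c", 29_900, 30_100),
                sim=OriginSimParams(30_000.0, **origin_kw),
            )
        ],
    )


class TestTrackSimulation:
    def test_identical_seed_gives_bit_identical_tracks(self, reference_pair):
        _, mutant = reference_pair
        probes = design_probes(mutant, 50, 8)["chrVI"]
        cfg = _cfg(seed=3)
        a = simulate_brdu_track(mutant, probes, cfg)
        b = simulate_brdu_track(mutant, probes, cfg)
        assert np.array_equal(a.values, b.values)
        c = simulate_orc_track(mutant, probes, cfg)
        d = simulate_orc_track(mutant, probes, cfg)
        assert np.array_equal(c.values, d.values)

    def test_noiseless_brdu_without_origins_is_zero(self):
        genome = GenomeModel({"c": 20_000})
        probes = design_probes(genome, 50, 8)["c"]
        track = simulate_brdu_track(genome, probes, _cfg(noise_sd=0.0))
        assert np.all(track.values == 0.0)

    def test_noiseless_brdu_peaks_at_origin(self):
        genome = _single_origin_genome()
        probes = design_probes(genome, 50, 8)["c"]
        track = simulate_brdu_track(genome, probes, _cfg(noise_sd=0.0))
        nearest = np.argmin(np.abs(probes.midpoints - 30_000.0))
        assert track.values[nearest] == track.values.max() > 0

    def test_noiseless_orc_peak_height(self):
        genome = _single_origin_genome(orc_height=2.5)
        probes = design_probes(genome, 50, 8)["c"]
        track = simulate_orc_track(genome, probes, _cfg(noise_sd=0.0))
        nearest = np.argmin(np.abs(probes.midpoints - 30_000.0))
        assert track.values[nearest] == pytest.approx(2.5, abs=1e-3)
        far = np.abs(probes.midpoints - 30_000.0) > 2_000
        assert np.allclose(track.values[far], 0.0, atol=1e-6)

    def test_deleted_span_probes_receive_background_only(self):
        genome = _single_origin_genome(orc_height=2.5)
        edit = DeletionEdit("ORI1", GenomicInterval("c", 29_000, 31_000), "loxP", 34)
        mutant, _ = apply_edits(genome, [edit])
        probes = design_probes(mutant, 50, 8)["c"]
        cfg = _cfg(noise_sd=0.0, background_level=0.3)
        track = simulate_orc_track(mutant, probes, cfg)
        ends = probes.starts + 49
        inside = (probes.starts <= 31_000) & (ends >= 29_000)
        assert np.allclose(track.values[inside], 0.3)

    def test_zero_residual_fraction_leaves_deleted_region_flat(self):
        genome = _single_origin_genome(orc_height=2.5, residual_fraction=0.0)
        edit = DeletionEdit("ORI1", GenomicInterval("c", 29_900, 30_100), "loxP", 34)
        mutant, _ = apply_edits(genome, [edit])
        probes = design_probes(mutant, 50, 8)["c"]
        track = simulate_orc_track(mutant, probes, _cfg(noise_sd=0.0))
        assert np.allclose(track.values, 0.0, atol=1e-9)
        brdu = simulate_brdu_track(mutant, probes, _cfg(noise_sd=0.0))
        assert np.allclose(brdu.values, 0.0, atol=1e-9)

    def test_noiseless_wt_minus_mutant_orc_localizes_to_deleted_origins(
        self, reference_pair
    ):
        wt, mutant = reference_pair
        probes = design_probes(wt, 50, 8)["chrVI"]
        cfg = _cfg(noise_sd=0.0)
        diff = (
            simulate_orc_track(wt, probes, cfg).values
            - simulate_orc_track(mutant, probes, cfg).values
        )
        deleted = [o for o in mutant.origins_on("chrVI") if o.status == "deleted"]
        near_deleted = np.zeros(len(probes), dtype=bool)
        for o in deleted:
            near_deleted |= (probes.midpoints >= o.locus.start - 5_000) & (
                probes.midpoints <= o.locus.end + 5_000
            )
        assert np.allclose(diff[~near_deleted], 0.0, atol=1e-6)
        assert diff[near_deleted].max() > 1.0

    def test_background_mean_is_near_zero_in_unreachable_region(self):
        # CLT check: >=1000 pure-noise probes at the default noise level
        genome = _single_origin_genome()
        probes = design_probes(genome, 50, 8)["c"]
        cfg = _cfg(seed=123)
        track = simulate_brdu_track(genome, probes, cfg)
        unreachable = np.abs(probes.midpoints - 30_000.0) > cfg.max_reach_bp + 100
        sample = track.values[unreachable][:1_000]
        assert len(sample) == 1_000
        assert abs(sample.mean()) <= 4 * cfg.noise_sd / np.sqrt(1_000)

    def test_residual_sites_flank_the_removed_span(self, reference_pair):
        from oriflex.simulate import residual_sites

        _, mutant = reference_pair
        cfg = _cfg()
        sites = residual_sites(mutant, cfg)
        spans = {e.origin_name: e.removed for e in mutant.edits}
        assert set(sites) == set(spans)
        for name, subs in sites.items():
            span = spans[name]
            assert len(subs) == cfg.residual_subsites
            for pos, sub in subs:
                assert not span.contains(pos)
                assert (
                    span.start - cfg.residual_jitter_bp
                    <= pos
                    <= span.end + cfg.residual_jitter_bp
                )
                parent = mutant.origin(name).sim
                assert sub.efficiency == pytest.approx(
                    parent.residual_fraction * parent.efficiency / cfg.residual_subsites
                )


def test_probe_set_rejects_unsorted_starts():
    with pytest.raises(ValidationError):
        ProbeSet("c", np.array([10, 5, 20]))
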