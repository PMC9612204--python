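"""Generator contracts: paradigm structure, determinism, spatial structure of
the simulated rhythms and artifacts, cohort composition and metadata."""

import numpy as np
import pytest

from capcompare.spectral import welch_psd
from capcompare.synthdata import (
    CapType,
    SegmentKind,
    SimulationConfig,
    alpha_weights,
    blink_weights,
    short_config,
    simulate_cohort,
    simulate_session,
    _simulate_metadata,
)


@pytest.fixture(scope="module")
def config():
    return short_config(n_subjects=2, seed=21)


class TestParadigmStructure:
    def test_segments_in_order(self, one_session):
        rec, _ = one_session
        kinds = [s.kind for s in rec.segments]
        assert kinds == [SegmentKind.EYES_OPEN, SegmentKind.EYES_CLOSED,
                         SegmentKind.BLINK, SegmentKind.VEP]

    def test_vep_trigger_count_matches_config(self, config, ten_twenty):
        cfg = short_config(n_subjects=1, seed=1, n_vep_epochs=30)
        rec, _ = simulate_session(cfg, "S1", CapType.GEL, ten_twenty)
        assert len(rec.segment(SegmentKind.VEP).trigger_times) == 30

    def test_default_config_gives_150_vep_epochs(self):
        assert SimulationConfig().n_vep_epochs == 150

    def test_blink_trigger_count_from_interval(self, ten_twenty):
        # 2-s beep interval in a 60-s blink segment -> 30 triggers
        cfg = short_config(n_subjects=1, seed=1, duration_blink=60.0)
        rec, _ = simulate_session(cfg, "S1", CapType.GEL, ten_twenty)
        assert len(rec.segment(SegmentKind.BLINK).trigger_times) == 30

    def test_same_seed_bit_identical(self, config, equidistant):
        a, _ = simulate_session(config, "S1", CapType.DRY, equidistant, seed=5)
        b, _ = simulate_session(config, "S1", CapType.DRY, equidistant, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self, config, equidistant):
        a, _ = simulate_session(config, "S1", CapType.DRY, equidistant, seed=5)
        b, _ = simulate_session(config, "S1", CapType.DRY, equidistant, seed=6)
        assert not np.array_equal(a.data, b.data)


class TestSignalContent:
    @pytest.fixture(scope="class")
    def clean_session(self, ten_twenty):
        cfg = short_config(n_subjects=1, seed=8,
                           bad_channel_prob={"gel": 0.0, "dry": 0.0})
        return simulate_session(cfg, "S8", CapType.GEL, ten_twenty)

    def test_eyes_closed_alpha_dominates_spectrum_occipitally(self, clean_session):
        rec, _ = clean_session
        occ = rec.layout.index_of("Oz")
        psd = welch_psd(rec.segment_data(SegmentKind.EYES_CLOSED)[occ], rec.sampling_rate)
        peak = psd.freqs[np.argmax(psd.power[0, psd.freqs >= 2]) + int(np.sum(psd.freqs < 2))]
        assert 8.0 <= peak <= 13.0

    def test_eyes_closed_alpha_exceeds_eyes_open(self, clean_session):
        rec, _ = clean_session
        occ = rec.layout.index_of("Oz")
        band = lambda seg: _band_power(rec.segment_data(seg)[occ], rec.sampling_rate)
        assert band(SegmentKind.EYES_CLOSED) > band(SegmentKind.EYES_OPEN)

    def test_blink_frontal_to_occipital_ratio(self, ten_twenty):
        w = blink_weights(ten_twenty)
        assert w[ten_twenty.index_of("Fp1")] >= 5 * w[ten_twenty.index_of("Oz")]

    def test_alpha_weighting_peaks_posteriorly(self, ten_twenty):
        w = alpha_weights(ten_twenty)
        assert w[ten_twenty.index_of("Oz")] > w[ten_twenty.index_of("Fz")]

    def test_bad_channel_prob_zero_gives_no_bad_channels(self, ten_twenty):
        cfg = short_config(n_subjects=1, seed=3,
                           bad_channel_prob={"gel": 0.0, "dry": 0.0})
        rec, _ = simulate_session(cfg, "S1", CapType.DRY, ten_twenty)
        assert all(len(v) == 0 for v in rec.true_bad_channels.values())

    def test_no_nan_anywhere(self, one_session):
        rec, _ = one_session
        assert np.all(np.isfinite(rec.data))


def _band_power(x, fs, band=(8.0, 13.0)):
    psd = welch_psd(x, fs)
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    return psd.power[0, mask].mean()


class TestCohort:
    def test_counts(self):
        cfg = short_config(n_subjects=5, seed=9)
        cohort = simulate_cohort(cfg)
        assert len(cohort.sessions) == 5
        assert len(cohort.metadata) == 10
        assert len(cohort.metadata_table()) == 10

    def test_each_pair_is_gel_then_dry(self):
        cohort = simulate_cohort(short_config(n_subjects=3, seed=9))
        for gel, dry in cohort.sessions:
            assert gel.cap_type is CapType.GEL
            assert dry.cap_type is CapType.DRY
            assert gel.subject_id == dry.subject_id

    def test_prep_time_direction_at_cohort_scale(self, ten_twenty):
        # metadata-only draws for 50 subjects: dry preparation is faster and
        # dry comfort values are higher (less comfortable), as in the study
        cfg = short_config(n_subjects=50, seed=17)
        gel, dry = [], []
        comfort_gel, comfort_dry = [], []
        for i in range(50):
            mg = _simulate_metadata(cfg, f"S{i}", CapType.GEL, ten_twenty, cfg.seed)
            md = _simulate_metadata(cfg, f"S{i}", CapType.DRY, ten_twenty, cfg.seed)
            gel.append(mg.prep_time)
            dry.append(md.prep_time)
            comfort_gel.append(mg.comfort_start)
            comfort_dry.append(md.comfort_start)
        assert np.mean(dry) < np.mean(gel)
        assert np.mean(comfort_dry) >= np.mean(comfort_gel)

    def test_dry_impedance_exceeds_gel(self, ten_twenty):
        cfg = short_config(n_subjects=1, seed=23)
        mg = _simulate_metadata(cfg, "S1", CapType.GEL, ten_twenty, 23)
        md = _simulate_metadata(cfg, "S1", CapType.DRY, ten_twenty, 23)
        assert np.mean(list(md.impedance_start.values())) > np.mean(
            list(mg.impedance_start.values())
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sampling_rate": 100.0},
            {"noise_sd": -1.0},
            {"bad_channel_prob": {"gel": 1.5, "dry": 0.1}},
            {"n_subjects": 0},
            {"duration_blink": 12.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            short_config(**kwargs)
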