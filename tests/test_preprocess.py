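"""Epoching, rejection, SEF95 and stable-segment selection contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegage.preprocess import (
    EpochSet,
    RawRecord,
    burst_suppression_ratio,
    epoch,
    flag_suppression_epochs,
    n_epochs_for,
    reject_epochs,
    sef95,
    sef95_from_psd,
    select_stable_segment,
    welch_psd_array,
)

FS = 63.0


def _noise_record(duration_s: float, seed: int = 0, scale: float = 20.0) -> RawRecord:
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * FS))
    return RawRecord(rng.normal(0, scale, size=(4, n)), FS)


class TestEpoching:
    @pytest.mark.parametrize("duration,expected", [(600, 55), (60, 1), (120, 7)])
    def test_epoch_count(self, duration, expected):
        es = epoch(_noise_record(duration))
        assert es.n_epochs == expected

    def test_too_short_record_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            es = epoch(_noise_record(59))
        assert es.n_epochs == 0

    @given(st.floats(min_value=60.0, max_value=2400.0))
    @settings(max_examples=25, deadline=None)
    def test_epoch_count_formula(self, duration):
        n = int(round(duration * FS))
        sig = np.zeros((4, n))
        es = epoch(RawRecord(sig, FS))
        assert es.n_epochs == n_epochs_for(n / FS)
        assert es.n_epochs == int(np.floor((n / FS - 60) / 10)) + 1

    def test_onsets_evenly_spaced(self):
        es = epoch(_noise_record(300))
        np.testing.assert_allclose(np.diff(es.onsets_s), 10.0)

    def test_epochs_do_not_share_storage(self):
        rec = _noise_record(120)
        es = epoch(rec)
        before = rec.signal.copy()
        es.epochs[:] = 0.0
        np.testing.assert_array_equal(rec.signal, before)


class TestRejection:
    def test_flat_channel_rejected(self):
        rec = _noise_record(120)
        rec.signal[2] = 0.0  # suppressed / disconnected channel
        es = reject_epochs(epoch(rec))
        assert not es.retained.any()

    def test_high_voltage_artifact_rejected(self):
        rec = _noise_record(120)
        rec.signal[:, 4000] += 400.0
        es = reject_epochs(epoch(rec))
        contaminated = np.flatnonzero(~es.retained)
        assert contaminated.size > 0
        assert 4000 / FS <= es.onsets_s[contaminated[-1]] + 60

    def test_clean_synthetic_epochs_fully_retained(self, clean_record):
        rec, _ = clean_record
        es = reject_epochs(epoch(rec))
        assert es.retained.all()

    def test_rejection_does_not_mutate_signal(self, clean_record):
        rec, _ = clean_record
        before = rec.signal.copy()
        es = epoch(rec)
        reject_epochs(es)
        sef95(es)
        np.testing.assert_array_equal(rec.signal, before)


def _sine_epoch(freqs_amps, duration=60.0, seed=0):
    t = np.arange(int(duration * FS)) / FS
    x = sum(a * np.sin(2 * np.pi * f * t + 0.1 * i) for i, (f, a) in enumerate(freqs_amps))
    return np.tile(x, (4, 1))


class TestSEF95:
    def test_pure_sine_sef_at_line(self):
        es = EpochSet(_sine_epoch([(10.0, 30.0)])[None], np.array([0.0]), FS)
        es.retained = np.array([True])
        es = sef95(es)
        assert es.sef95_mean_hz[0] == pytest.approx(10.0, abs=0.26)

    def test_flat_spectrum_analytic(self):
        # on an exactly flat PSD the edge sits at fmin + 0.95 * (fmax - fmin)
        freqs = np.arange(0.0, 31.6, 0.25)
        flat = np.ones_like(freqs)
        assert sef95_from_psd(freqs, flat) == pytest.approx(28.5, abs=0.26)

    def test_white_noise_estimate_near_analytic(self):
        rng = np.random.default_rng(4)
        es = EpochSet(rng.normal(0, 10, (20, 4, int(60 * FS))), np.arange(20) * 10.0, FS)
        es.retained = np.ones(20, bool)
        es = sef95(es)
        assert np.median(es.sef95_mean_hz) == pytest.approx(28.5, abs=1.0)

    def test_mixture_crosses_at_upper_line(self):
        # 90% of power at 5 Hz, 10% at 20 Hz: the 95% threshold needs the
        # upper line
        amp5, amp20 = 30.0, 10.0  # power ratio 9:1
        es = EpochSet(_sine_epoch([(5.0, amp5), (20.0, amp20)])[None], np.array([0.0]), FS)
        es.retained = np.array([True])
        es = sef95(es)
        assert es.sef95_mean_hz[0] == pytest.approx(20.0, abs=0.26)

    def test_zero_power_marks_epoch_invalid(self):
        es = EpochSet(np.zeros((1, 4, int(60 * FS))), np.array([0.0]), FS)
        es.retained = np.array([True])
        es = sef95(es)
        assert np.isnan(es.sef95_mean_hz[0])
        assert not es.retained[0]

    @given(st.floats(5.0, 20.0), st.floats(0.5, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_spectral_shift(self, center, shift):
        freqs = np.arange(0.0, 31.6, 0.25)
        bump = lambda c: np.exp(-0.5 * ((freqs - c) / 1.5) ** 2) + 1e-6
        assert sef95_from_psd(freqs, bump(center + shift)) >= sef95_from_psd(freqs, bump(center))


def _eset_with_sef(sef_values, retained=None):
    n = len(sef_values)
    es = EpochSet(np.zeros((n, 4, 10)), np.arange(n) * 10.0, FS)
    es.retained = np.ones(n, bool) if retained is None else np.asarray(retained)
    es.sef95_mean_hz = np.asarray(sef_values, dtype=float)
    es.sef95_hz = np.tile(es.sef95_mean_hz[:, None], (1, 4))
    return es


class TestStableSegment:
    def test_enumerated_example(self):
        seg = select_stable_segment(_eset_with_sef([7, 9, 10, 12, 14, 9, 9]))
        assert (seg.first_epoch, seg.last_epoch, seg.n_epochs) == (1, 3, 3)

    def test_all_in_band_selects_everything(self):
        seg = select_stable_segment(_eset_with_sef([9] * 12))
        assert (seg.first_epoch, seg.last_epoch) == (0, 11)

    def test_tie_broken_by_earliest(self):
        seg = select_stable_segment(_eset_with_sef([9, 9, 9, 14, 10, 10, 10]))
        assert (seg.first_epoch, seg.last_epoch) == (0, 2)

    def test_rejected_epoch_breaks_run(self):
        seg = select_stable_segment(
            _eset_with_sef([9, 9, 9, 9], retained=[True, False, True, True])
        )
        assert (seg.first_epoch, seg.last_epoch) == (2, 3)

    def test_no_qualifying_epoch_returns_none(self):
        assert select_stable_segment(_eset_with_sef([5, 6, 14, 15])) is None

    def test_invariant_to_out_of_run_epochs(self):
        base = [7, 9, 10, 12, 14, 9, 9]
        seg1 = select_stable_segment(_eset_with_sef(base))
        perturbed = list(base)
        perturbed[0], perturbed[4] = 3.0, 20.0  # outside-band values changed
        seg2 = select_stable_segment(_eset_with_sef(perturbed))
        assert seg1 == seg2


class TestBurstSuppression:
    def test_fully_suppressed_record(self):
        # near-isoelectric throughout
        rec = RawRecord(np.random.default_rng(0).normal(0, 0.1, (4, int(300 * FS))), FS)
        assert burst_suppression_ratio(rec) == 1.0

    def test_clean_record_zero(self, clean_record):
        rec, _ = clean_record
        assert burst_suppression_ratio(rec) == 0.0

    def test_flag_suppression_epochs_drops_contaminated(self, default_truth):
        from dataclasses import replace

        from eegage.synthetic import CohortSpec, generate_patient, synthesize_record

        spec = CohortSpec(n_patients=1, duration_s=600, seed=8)
        _, pt = generate_patient(spec, default_truth, 0)
        pt = replace(pt, true_bs_proportion=0.25)
        rec = synthesize_record(pt, spec, default_truth, with_artifacts=False)
        es = reject_epochs(epoch(rec))
        n_before = es.retained.sum()
        es = flag_suppression_epochs(es, rec)
        assert es.retained.sum() < n_before
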