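"""Feature-extraction contracts: Welch PSD, band covariances, tangent-space
vectors, and the 1/1/16/50 dimensional bundle."""

import numpy as np
import pytest

from eegage.features import (
    BANDS,
    BandCovarianceSet,
    band_covariances,
    geometric_mean_spd,
    make_feature_bundle,
    tangent_vectors,
    unvec_symmetric,
    welch_psd,
)
from eegage.preprocess import EpochSet, RawRecord, epoch

FS = 63.0


def _eset(signal: np.ndarray) -> EpochSet:
    es = epoch(RawRecord(signal, FS))
    es.retained = np.ones(es.n_epochs, bool)
    return es


class TestWelch:
    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        es = _eset(rng.normal(0, 1, (4, int(600 * FS))))
        grid = welch_psd(es, fmax=31.5)
        power = np.trapezoid(grid.channel_mean, grid.freqs_hz)
        assert power == pytest.approx(1.0, rel=0.05)

    def test_sinusoid_power(self):
        amp = 5.0
        t = np.arange(int(600 * FS)) / FS
        rng = np.random.default_rng(1)
        x = amp * np.sin(2 * np.pi * 10 * t) + rng.normal(0, 0.1, t.size)
        grid = welch_psd(_eset(np.tile(x, (4, 1))))
        near = (grid.freqs_hz > 9) & (grid.freqs_hz < 11)
        power = grid.channel_mean[near].sum() * 0.25
        assert power == pytest.approx(amp**2 / 2, rel=0.05)

    def test_average_of_identical_epochs_is_single_epoch(self):
        rng = np.random.default_rng(2)
        one = rng.normal(0, 1, (4, int(60 * FS)))
        stacked = np.concatenate([one] * 3, axis=1)  # 3 identical windows
        es = EpochSet(np.stack([one] * 3), np.arange(3) * 60.0, FS)
        single = EpochSet(one[None], np.array([0.0]), FS)
        np.testing.assert_allclose(welch_psd(es).psd, welch_psd(single).psd)


class TestBandCovariances:
    def test_identical_channels_fully_correlated(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 10, int(300 * FS))
        covs = band_covariances(_eset(np.tile(x, (4, 1))))
        for C in covs.cov:
            r = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
            assert r.min() > 0.95  # rank one up to shrinkage

    def test_independent_channels_small_off_diagonals(self):
        rng = np.random.default_rng(4)
        covs = band_covariances(_eset(rng.normal(0, 10, (4, int(600 * FS)))))
        for C in covs.cov:
            r = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
            off = r[~np.eye(4, dtype=bool)]
            assert np.abs(off).max() < 0.05

    def test_sine_power_lands_in_alpha_band(self):
        t = np.arange(int(300 * FS)) / FS
        rng = np.random.default_rng(5)
        x = 10 * np.sin(2 * np.pi * 10 * t) + rng.normal(0, 0.3, t.size)
        covs = band_covariances(_eset(np.tile(x, (4, 1))))
        diag = {name: np.diag(C).mean() for (name, *_), C in zip(BANDS, covs.cov)}
        for other in ("low", "delta", "theta", "beta"):
            assert diag["alpha"] / diag[other] > 10

    def test_band_power_consistent_with_psd_integral(self, clean_record):
        rec, _ = clean_record
        es = _eset(rec.signal)
        grid = welch_psd(es)
        covs = band_covariances(es, record_signal=rec.signal)
        f = grid.freqs_hz
        for (name, lo, hi), C in zip(BANDS, covs.cov):
            sel = (f >= lo) & (f <= hi)
            integral = np.trapezoid(grid.psd[:, sel], f[sel], axis=1)
            ratio = np.diag(C) / integral
            tol = 0.40 if name == "low" else 0.15  # low edge below grid resolution
            assert np.all(np.abs(ratio - 1) < tol), (name, ratio)

    def test_concatenated_vs_per_epoch_average(self):
        # non-overlapping windows whose concatenation is the record itself
        rng = np.random.default_rng(6)
        mix = np.array([[1.0, 0.4, 0.1, 0.0], [0.4, 1.0, 0.3, 0.1],
                        [0.1, 0.3, 1.0, 0.5], [0.0, 0.1, 0.5, 1.0]])
        sig = mix @ rng.normal(0, 10, (4, int(300 * FS)))
        es = epoch(RawRecord(sig, FS), shift_s=60.0)
        es.retained = np.ones(es.n_epochs, bool)
        per_epoch = band_covariances(es, record_signal=sig)
        whole = band_covariances(
            EpochSet(sig[None], np.array([0.0]), FS), record_signal=sig
        )
        for a, b in zip(per_epoch.cov, whole.cov):
            np.testing.assert_allclose(a, b, atol=0.10 * np.diag(b).max())


class TestTangentGeometry:
    def test_geometric_mean_of_identical_matrices(self):
        C = np.array([[2.0, 0.5, 0, 0], [0.5, 1.5, 0, 0], [0, 0, 1.0, 0.2], [0, 0, 0.2, 0.8]])
        M = geometric_mean_spd(np.stack([C] * 5))
        np.testing.assert_allclose(M, C, atol=1e-6)

    def test_vectorization_round_trip(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(4, 4))
        S = A @ A.T + np.eye(4)
        from eegage.features import _vec_symmetric

        np.testing.assert_allclose(unvec_symmetric(_vec_symmetric(S)), S)

    def test_tangent_at_own_reference_is_zero(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(4, 4))
        S = A @ A.T + np.eye(4)
        np.testing.assert_allclose(tangent_vectors(S[None], S), 0.0, atol=1e-8)


class TestFeatureBundle:
    def _bundle(self, rec, reference=None):
        es = _eset(rec.signal)
        return make_feature_bundle(
            welch_psd(es), band_covariances(es, record_signal=rec.signal), reference
        )

    def test_dimensional_contract(self, clean_record):
        rec, _ = clean_record
        fb = self._bundle(rec)
        assert fb.spectrum.shape == (16,) and fb.spatial.shape == (50,)
        assert np.isfinite(fb.total_power) and np.isfinite(fb.alpha_power)

    def test_amplitude_doubling_shifts_log_power(self, clean_record):
        rec, _ = clean_record
        fb1 = self._bundle(rec)
        fb2 = self._bundle(RawRecord(2 * rec.signal, rec.fs_hz))
        assert fb2.total_power - fb1.total_power == pytest.approx(np.log(4), rel=1e-3)
        np.testing.assert_allclose(fb2.spectrum - fb1.spectrum, np.log(4), rtol=1e-3)
        # identity-reference tangent diagonals shift by log 4
        diag_idx = np.array([i for b in range(5) for i in (b * 10 + 0, b * 10 + 4, b * 10 + 7, b * 10 + 9)])
        np.testing.assert_allclose(
            (fb2.spatial - fb1.spatial)[diag_idx], np.log(4), atol=0.02
        )

    def test_channel_permutation_equivariance(self, clean_record):
        rec, _ = clean_record
        perm = [2, 0, 3, 1]
        rec_p = RawRecord(rec.signal[perm], rec.fs_hz)
        es, es_p = _eset(rec.signal), _eset(rec_p.signal)
        fb = make_feature_bundle(welch_psd(es), band_covariances(es, record_signal=rec.signal))
        fb_p = make_feature_bundle(welch_psd(es_p), band_covariances(es_p, record_signal=rec_p.signal))
        assert fb_p.total_power == pytest.approx(fb.total_power, rel=1e-9)
        assert fb_p.alpha_power == pytest.approx(fb.alpha_power, rel=1e-9)
        np.testing.assert_allclose(fb_p.spectrum, fb.spectrum)
        C = unvec_symmetric(fb.spatial.reshape(5, 10))
        C_p = unvec_symmetric(fb_p.spatial.reshape(5, 10))
        P = np.eye(4)[perm]
        np.testing.assert_allclose(C_p, P @ C @ P.T, atol=1e-8)

    def test_table_frame_round_trip(self, small_table):
        from eegage.features import FeatureTable

        back = FeatureTable.from_frame(small_table.to_frame(), small_table.psd_frame())
        np.testing.assert_allclose(back.design_matrix(), small_table.design_matrix())
        np.testing.assert_allclose(back.covs, small_table.covs, atol=1e-12)
        np.testing.assert_allclose(back.psd, small_table.psd)

    def test_zero_power_raises_naming_problem(self):
        es = _eset(np.zeros((4, int(120 * FS))) + 1e-12)
        grid = welch_psd(es)
        grid.psd[:] = 0.0
        covs = BandCovarianceSet(np.stack([np.eye(4)] * 5))
        with pytest.raises(ValueError):
            make_feature_bundle(grid, covs)
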