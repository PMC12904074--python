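"""Masked-EMD decomposition, co-participation features and ICA barcodes."""

import numpy as np
import pytest

from oscibar.barcode import (
    AmplitudeMatrix,
    amplitude_matrix,
    barcode_score,
    barcode_strength,
    coparticipation,
    feature_index_for,
    fit_barcodes,
    masked_emd,
    select_imfs,
    window_times,
    BarcodeModel,
    StrengthSeries,
)
from oscibar.core import DEFAULT_BANDS, EventTable, ValidationError
from oscibar.simulate import simulate_lfp

FS = 1000.0


def two_tone(duration=20.0):
    t = np.arange(0, duration, 1 / FS)
    return np.cos(2 * np.pi * 5 * t) + 0.7 * np.cos(2 * np.pi * 40 * t), t


class TestMaskedEMD:
    def test_completeness_exact(self, rng):
        x = rng.standard_normal(8000)
        s = masked_emd(x, FS)
        assert s.reconstruction_error() < 1e-6

    def test_two_tone_separation(self):
        x, t = two_tone()
        s = masked_emd(x, FS)
        tone5 = np.cos(2 * np.pi * 5 * t)
        tone40 = 0.7 * np.cos(2 * np.pi * 40 * t)
        best5 = max(abs(np.corrcoef(m.signal, tone5)[0, 1]) for m in s.imfs)
        best40 = max(abs(np.corrcoef(m.signal, tone40)[0, 1]) for m in s.imfs)
        assert best5 > 0.95 and best40 > 0.95
        peaks = sorted(
            m.peak_freq_hz for m in s.imfs if m.signal.std() > 0.1 * x.std()
        )
        assert any(abs(p - 5) < 1 for p in peaks)
        assert any(abs(p - 40) < 1 for p in peaks)

    def test_pure_tone_single_imf(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.cos(2 * np.pi * 40 * t)
        s = masked_emd(x, FS)
        # one IMF carries the tone; everything else is negligible
        energies = sorted((np.linalg.norm(m.signal) for m in s.imfs), reverse=True)
        rest = np.sqrt(sum(e * e for e in energies[1:]) + np.linalg.norm(s.residual) ** 2)
        assert rest / np.linalg.norm(x) < 0.05

    def test_mask_above_nyquist_rejected(self, rng):
        with pytest.raises(ValidationError):
            masked_emd(rng.standard_normal(2000), FS, mask_freqs=np.array([600.0]))

    def test_nonfinite_input_rejected(self):
        x = np.zeros(1000)
        x[5] = np.inf
        with pytest.raises(ValidationError):
            masked_emd(x, FS)


class TestSelectIMFs:
    def test_two_tone_band_assignment(self):
        x, _ = two_tone()
        env = select_imfs(masked_emd(x, FS), DEFAULT_BANDS)
        assert env["theta"].mean() > 0.3   # 5 Hz tone -> theta channel
        assert env["gamma"].mean() > 0.2   # 40 Hz tone -> gamma channel
        assert env["beta"].mean() < 0.15   # nothing planted in beta

    def test_between_band_imf_dropped(self):
        # 13.5 Hz sits between theta (hi 12) and beta (lo 15)
        t = np.arange(0, 20, 1 / FS)
        x = np.cos(2 * np.pi * 13.5 * t)
        s = masked_emd(x, FS)
        env = select_imfs(s, DEFAULT_BANDS)
        total_assigned = sum(env[b.name].mean() for b in DEFAULT_BANDS)
        assert total_assigned < 0.2

    def test_broadband_noise_populates_all_bands(self):
        rec = simulate_lfp([], {"alpha": 1.0, "sigma": 1.0}, 30.0, FS, 5, regions=["OB"])
        env = select_imfs(masked_emd(rec.lfp[0], FS), DEFAULT_BANDS)
        for b in DEFAULT_BANDS:
            assert env[b.name].mean() > 0


@pytest.fixture(scope="module")
def imfsets():
    per = {}
    for i, region in enumerate(["OB", "aPC", "LEC"]):
        rec = simulate_lfp([], {"alpha": 1.0, "sigma": 1.0}, 20.0, FS, i,
                           regions=[region])
        per[region] = masked_emd(rec.lfp[0], FS, region=region)
    return per


class TestAmplitudeMatrix:

    def test_channel_order_region_major(self, imfsets):
        M = amplitude_matrix(imfsets, DEFAULT_BANDS, regions=["OB", "aPC", "LEC"])
        assert M.channels == [
            (r, b.name) for r in ["OB", "aPC", "LEC"] for b in DEFAULT_BANDS
        ]
        assert M.A_std.shape[0] == 9

    def test_standardization_unit_sd_and_roundtrip(self, imfsets):
        M = amplitude_matrix(imfsets, DEFAULT_BANDS)
        np.testing.assert_allclose(M.A_std.std(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(M.A_std * M.sd[:, None], M.A_raw, rtol=1e-12)
        assert (M.A_raw >= 0).all()

    def test_duration_mismatch_rejected(self, imfsets):
        bad = dict(imfsets)
        rec = simulate_lfp([], {"alpha": 1.0, "sigma": 1.0}, 10.0, FS, 9, regions=["X"])
        bad["X"] = masked_emd(rec.lfp[0], FS, region="X")
        with pytest.raises(ValidationError):
            amplitude_matrix(bad, DEFAULT_BANDS)


class TestCoparticipation:
    def test_outer_product_arithmetic(self):
        M = AmplitudeMatrix(
            channels=[("OB", "a"), ("OB", "b")],
            A_std=np.array([[1.0] * 250, [2.0] * 250]),
            A_raw=np.array([[1.0] * 250, [2.0] * 250]),
            sd=np.array([1.0, 1.0]), fs_hz=FS,
        )
        F = coparticipation(M, 0.25, use_std=True)
        np.testing.assert_allclose(F, [[1.0, 2.0, 4.0]])

    def test_window_count(self, rng):
        n_ch, n_s = 3, 10_000  # 10 s -> 40 windows of 250 ms
        A = np.abs(rng.standard_normal((n_ch, n_s))) + 0.1
        M = AmplitudeMatrix([("r", str(i)) for i in range(n_ch)], A, A,
                            np.ones(n_ch), FS)
        F = coparticipation(M, 0.25)
        assert F.shape == (40, 6)
        assert window_times(40)[0] == 0.125

    def test_zero_window_zero_features(self):
        A = np.ones((2, 500))
        A[:, :250] = 0.0
        M = AmplitudeMatrix([("r", "0"), ("r", "1")], A, A, np.ones(2), FS)
        F = coparticipation(M, 0.25)
        np.testing.assert_array_equal(F[0], 0.0)


@pytest.fixture(scope="module")
def features():
    g = np.random.default_rng(0)
    n_win, n_ch = 400, 6
    V = np.abs(g.standard_normal((n_win, n_ch))) + 0.2
    # two sparse latent co-activation sources
    z1 = np.clip(g.standard_normal(n_win), 0, None) * (g.uniform(size=n_win) < 0.3)
    z2 = np.clip(g.standard_normal(n_win), 0, None) * (g.uniform(size=n_win) < 0.3)
    V[:, 0] *= 1 + z1
    V[:, 1] *= 1 + z1
    V[:, 4] *= 1 + z2
    V[:, 5] *= 1 + z2
    iu, ju = np.triu_indices(n_ch)
    return (V[:, iu] * V[:, ju])


class TestFitBarcodes:

    def test_determinism(self, features):
        a = fit_barcodes(features, 4, seed=3)
        b = fit_barcodes(features, 4, seed=3)
        np.testing.assert_array_equal(a.W, b.W)

    def test_rows_unit_norm_and_sign_fixed(self, features):
        m = fit_barcodes(features, 4, seed=3)
        np.testing.assert_allclose(np.linalg.norm(m.W, axis=1), 1.0, atol=1e-9)
        for row in m.W:
            assert row[np.argmax(np.abs(row))] > 0

    def test_row_permutation_invariance(self, features):
        g = np.random.default_rng(1)
        perm = g.permutation(features.shape[0])
        a = fit_barcodes(features, 4, seed=3)
        b = fit_barcodes(features[perm], 4, seed=3)
        # same components up to order: match by absolute cosine
        C = np.abs(a.W @ b.W.T)
        from scipy.optimize import linear_sum_assignment

        ri, ci = linear_sum_assignment(-C)
        assert np.all(C[ri, ci] > 0.99)

    def test_too_few_windows_rejected(self, features):
        with pytest.raises(ValidationError, match="windows"):
            fit_barcodes(features[:30], 8, seed=0)

    def test_feature_index_covers_upper_triangle(self):
        idx = feature_index_for(4)
        assert len(idx) == 10
        assert idx[0] == (0, 0) and idx[-1] == (3, 3)
        assert all(i <= j for i, j in idx)


class TestStrengthAndScore:
    def make_model(self, n_ch=3):
        n_feat = n_ch * (n_ch + 1) // 2
        W = np.zeros((1, n_feat))
        W[0, 1] = 1.0  # one-hot on feature (ch0 x ch1)
        return BarcodeModel(
            feature_index=feature_index_for(n_ch),
            channels=[("r", str(i)) for i in range(n_ch)],
            W=W, window_s=0.25, seed=0, converged=True, n_iter=1,
        )

    def test_one_hot_strength_is_raw_product(self, rng):
        model = self.make_model()
        F_raw = np.abs(rng.standard_normal((20, 6)))
        series = barcode_strength(model, F_raw)
        np.testing.assert_array_equal(series[0].strength, F_raw[:, 1])

    def test_feature_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            barcode_strength(self.make_model(), np.ones((10, 10)))

    def test_perfect_ranking_scores_one(self):
        times = window_times(40)
        strength = np.where(times < 5.0, 10.0, 1.0)
        ser = StrengthSeries(0, times, strength)
        rows = [dict(epoch_id=f"n{i}", label="e", start_s=i, end_s=i + 1.0,
                     condition="novel") for i in range(5)]
        rows += [dict(epoch_id=f"f{i}", label="e", start_s=5 + i, end_s=6 + i,
                      condition="familiar") for i in range(5)]
        score = barcode_score(ser, EventTable.from_rows(rows), "novel", "familiar")
        assert score == 1.0

    def test_uninformative_strength_near_half(self):
        scores = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            times = window_times(160)
            ser = StrengthSeries(0, times, g.standard_normal(160))
            rows = [dict(epoch_id=f"n{i}", label="e", start_s=2 * i, end_s=2 * i + 1,
                         condition="novel") for i in range(10)]
            rows += [dict(epoch_id=f"f{i}", label="e", start_s=2 * i + 1,
                          end_s=2 * i + 2, condition="familiar") for i in range(10)]
            scores.append(
                barcode_score(ser, EventTable.from_rows(rows), "novel", "familiar")
            )
        assert np.mean(scores) == pytest.approx(0.5, abs=0.1)

    def test_single_condition_rejected(self):
        ser = StrengthSeries(0, window_times(8), np.ones(8))
        rows = [dict(epoch_id="a", label="e", start_s=0, end_s=1, condition="novel"),
                dict(epoch_id="b", label="e", start_s=1, end_s=2, condition="novel")]
        with pytest.raises(ValidationError):
            barcode_score(ser, EventTable.from_rows(rows), "novel", "familiar")


class TestPipelineEquivariance:
    def test_global_scale_invariance_of_weights(self):
        from oscibar.barcode import fit_barcode_pipeline
        from oscibar.core import Recording

        rec = simulate_lfp([], {"alpha": 1.0, "sigma": 10.0}, 40.0, FS, 17,
                           regions=["OB", "aPC"])
        scaled = Recording(
            subject_id=rec.subject_id, group=rec.group, regions=list(rec.regions),
            lfp=rec.lfp * 3.0, fs_hz=rec.fs_hz,
        )
        m1, s1, _ = fit_barcode_pipeline(rec, n_barcodes=3, seed=1)
        m2, s2, _ = fit_barcode_pipeline(scaled, n_barcodes=3, seed=1)
        # standardized features absorb the scale: weights identical
        np.testing.assert_allclose(m1.W, m2.W, atol=5e-3)
        # raw-feature strengths scale as c^2
        np.testing.assert_allclose(
            s2[0].strength, 9.0 * s1[0].strength, rtol=1e-2
        )
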