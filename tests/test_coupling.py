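"""Band-limited phase/amplitude, PAC, spike-phase locking and STA contracts."""

import numpy as np
import pytest
from scipy.special import i0, i1

from oscibar.core import GAMMA, THETA, SpikeUnit, ValidationError
from oscibar.coupling import (
    AnalyticBand,
    bandpass_analytic,
    classify_locked,
    comodulogram,
    pac_mi,
    phase_at_times,
    rayleigh_p,
    spike_phase_locking,
    spike_triggered_average,
)

FS = 1000.0


def tone(freq, duration=20.0, amp=1.0):
    t = np.arange(0, duration, 1 / FS)
    return amp * np.cos(2 * np.pi * freq * t)


class TestBandpassAnalytic:
    def test_tone_amplitude_and_frequency(self):
        ab = bandpass_analytic(tone(8.0, amp=2.5), FS, THETA)
        core = slice(2000, -2000)
        assert np.allclose(ab.amplitude[core], 2.5, rtol=0.02)
        inst = np.diff(np.unwrap(ab.phase)[core]) * FS / (2 * np.pi)
        assert np.mean(inst) == pytest.approx(8.0, abs=0.05)

    def test_cosine_phase_convention(self):
        x = tone(8.0)
        ab = bandpass_analytic(x, FS, THETA)
        peaks = np.arange(16, 144) * 125  # 8 Hz period = 125 samples, peak at t=0
        assert np.max(np.abs(ab.phase[peaks])) < 0.05

    def test_chirp_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp

        t = np.arange(0, 30, 1 / FS)
        x = chirp(t, f0=4.0, f1=11.0, t1=30.0, method="linear", phi=90)
        ab = bandpass_analytic(x, FS, THETA)
        inst = np.diff(np.unwrap(ab.phase)) * FS / (2 * np.pi)
        truth = 4.0 + (11.0 - 4.0) * t[:-1] / 30.0
        core = slice(3000, -3000)
        rel = np.abs(inst[core] - truth[core]) / truth[core]
        assert np.median(rel) < 0.05

    def test_too_short_signal(self):
        with pytest.raises(ValidationError, match="cycles"):
            bandpass_analytic(np.zeros(100), FS, THETA)

    def test_zero_phase_no_lag(self):
        x = tone(8.0) + 0.1 * np.random.default_rng(0).standard_normal(20_000)
        ab = bandpass_analytic(x, FS, THETA)
        filt = ab.amplitude * np.cos(ab.phase)
        full = np.correlate(filt - filt.mean(), tone(8.0), mode="full")
        lag = np.argmax(np.abs(full)) - (20_000 - 1)
        assert lag == 0


def make_band(phase, amplitude, band=THETA):
    return AnalyticBand(band=band, phase=phase, amplitude=amplitude, fs_hz=FS)


class TestPACMI:
    def test_independent_amplitude_gives_near_zero(self, rng):
        n = 100_000
        phase = rng.uniform(-np.pi, np.pi, n)
        amp = rng.gamma(2.0, 1.0, n)
        res = pac_mi(make_band(phase, amp), make_band(phase, amp, GAMMA))
        assert res.mi < 0.01

    def test_single_bin_amplitude_gives_one(self, rng):
        n = 18_000
        phase = np.tile(np.linspace(-np.pi, np.pi, 18, endpoint=False) + np.pi / 18, 1000)
        amp = np.where(np.abs(phase - phase[0]) < 1e-9, 1.0, 0.0)
        res = pac_mi(make_band(phase, amp), make_band(phase, amp, GAMMA))
        assert res.mi == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_scale_invariance_exact(self, rng):
        n = 50_000
        phase = rng.uniform(-np.pi, np.pi, n)
        amp = rng.gamma(2.0, 1.0, n) * (1 + 0.4 * np.cos(phase))
        a = pac_mi(make_band(phase, amp), make_band(phase, amp, GAMMA)).mi
        b = pac_mi(make_band(phase, amp), make_band(phase, 7.3 * amp, GAMMA)).mi
        assert a == pytest.approx(b, rel=1e-10)

    def test_quadrature_oracle_for_cosine_profile(self):
        # amplitude exactly (1 + m cos(phi - phi0)): MI from numeric integration
        m, phi0, n_bins = 0.5, 0.7, 18
        edges = np.linspace(-np.pi, np.pi, 10_001)
        centers = (edges[:-1] + edges[1:]) / 2
        profile = 1 + m * np.cos(centers - phi0)
        bins = np.clip(
            np.digitize(centers, np.linspace(-np.pi, np.pi, n_bins + 1)) - 1,
            0, n_bins - 1,
        )
        binned = np.bincount(bins, weights=profile, minlength=n_bins)
        binned /= binned.sum()
        oracle_mi = np.sum(binned * np.log(binned * n_bins)) / np.log(n_bins)

        n = 200_000
        g = np.random.default_rng(3)
        phase = g.uniform(-np.pi, np.pi, n)
        amp = 1 + m * np.cos(phase - phi0)
        res = pac_mi(make_band(phase, amp), make_band(phase, amp, GAMMA))
        assert res.mi == pytest.approx(oracle_mi, rel=0.02)
        assert abs(np.angle(np.exp(1j * (res.preferred_phase - phi0)))) < 0.05

    def test_mvl_alternative_estimator(self, rng):
        n = 100_000
        phase = rng.uniform(-np.pi, np.pi, n)
        amp = 1 + 0.5 * np.cos(phase)
        res = pac_mi(make_band(phase, amp), make_band(phase, amp, GAMMA), method="mvl")
        assert res.mi == pytest.approx(0.25, abs=0.01)  # m/2 for cosine profile

    def test_phase_band_must_be_slower(self, rng):
        n = 10_000
        b = make_band(rng.uniform(-np.pi, np.pi, n), np.ones(n), GAMMA)
        with pytest.raises(ValidationError, match="slower"):
            pac_mi(b, make_band(b.phase, b.amplitude, THETA))


class TestComodulogram:
    def test_planted_coupling_localized(self):
        t = np.arange(0, 60, 1 / FS)
        g = np.random.default_rng(1)
        theta_phase = 2 * np.pi * 8.0 * t
        x = (
            np.cos(theta_phase)
            + 0.3 * (1 + 0.8 * np.cos(theta_phase)) * np.cos(2 * np.pi * 60.0 * t)
            + 0.1 * g.standard_normal(t.size)
        )
        mi, pf, af = comodulogram(
            x, FS, phase_freqs_hz=[5.0, 8.0, 11.0], amp_freqs_hz=[40.0, 60.0, 80.0]
        )
        i, j = np.unravel_index(np.argmax(mi), mi.shape)
        assert (pf[i], af[j]) == (8.0, 60.0)

    def test_grid_beyond_nyquist_rejected(self, rng):
        with pytest.raises(ValidationError):
            comodulogram(rng.standard_normal(5000), FS, [8.0], [495.0])


class TestSpikePhaseLocking:
    def test_perfectly_locked_unit(self):
        x = tone(8.0, duration=30.0)
        spikes = np.arange(0.125, 29.5, 0.125)  # every theta peak
        unit = SpikeUnit("u", "OB", spikes)
        res = spike_phase_locking(unit, x, FS, THETA)
        assert res.mrl > 0.99
        assert res.rayleigh_p < 1e-10
        assert abs(res.preferred_phase) < 0.05
        assert classify_locked(res)

    def test_mrl_rotation_invariance(self, rng):
        phases = rng.vonmises(0.5, 2.0, 500)
        mrl = np.abs(np.mean(np.exp(1j * phases)))
        mrl_rot = np.abs(np.mean(np.exp(1j * (phases + 1.234))))
        assert mrl == pytest.approx(mrl_rot, abs=1e-12)

    def test_rayleigh_null_uniform(self):
        # p-values under uniform phases are approximately uniform
        from scipy.stats import kstest

        ps = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            phases = g.uniform(-np.pi, np.pi, 1000)
            mrl = np.abs(np.mean(np.exp(1j * phases)))
            ps.append(rayleigh_p(1000, mrl))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_low_n_guard(self):
        x = tone(8.0)
        unit = SpikeUnit("u", "OB", np.arange(0.125, 1.3, 0.125))  # < 20 spikes
        res = spike_phase_locking(unit, x, FS, THETA)
        assert res.low_n and not classify_locked(res)

    def test_no_spikes_rejected(self):
        with pytest.raises(ValidationError):
            spike_phase_locking(SpikeUnit("u", "OB", np.array([])), tone(8.0), FS, THETA)

    def test_phase_interpolation_no_wrap_artifact(self):
        x = tone(8.0, duration=30.0)
        ab = bandpass_analytic(x, FS, THETA)
        # times straddling the -pi/pi wrap (troughs of the cosine)
        troughs = np.arange(2.0625, 28.0, 0.125)
        ph = phase_at_times(ab, troughs)
        assert np.all(np.abs(np.abs(ph) - np.pi) < 0.05)


class TestSTA:
    def test_locked_spikes_recover_tone(self):
        x = tone(8.0, duration=60.0, amp=3.0)
        spikes = np.arange(0.5, 59.5, 0.125)
        res = spike_triggered_average(SpikeUnit("u", "OB", spikes), x, FS, 0.1)
        assert res.sta.size == 201
        assert np.max(res.sta) == pytest.approx(3.0, rel=0.05)

    def test_incoherent_averaging_shrinks(self):
        g = np.random.default_rng(5)
        x = g.standard_normal(400_000)
        spikes = np.sort(g.uniform(1, 399, 400))
        res400 = spike_triggered_average(SpikeUnit("u", "OB", spikes), x, FS, 0.05)
        res100 = spike_triggered_average(SpikeUnit("u", "OB", spikes[:100]), x, FS, 0.05)
        ratio = res100.sta.std() / res400.sta.std()
        assert ratio == pytest.approx(2.0, rel=0.35)  # 1/sqrt(n) law

    def test_edge_spikes_dropped(self):
        x = tone(8.0, duration=2.0)
        spikes = np.array([0.01, 1.0, 1.99])
        res = spike_triggered_average(SpikeUnit("u", "OB", spikes), x, FS, 0.1)
        assert res.n_spikes == 1

    def test_gamma_locked_unit_has_higher_sta_gamma_power(self):
        from oscibar.simulate import OscSpec, UnitSpec, simulate_lfp, simulate_spikes

        rec = simulate_lfp(
            [OscSpec("OB", GAMMA, 60.0, 20.0, phase_diffusion=10.0)],
            {"alpha": 1.0, "sigma": 5.0}, 120.0, FS, 7,
        )
        rec = simulate_spikes(
            rec,
            [UnitSpec("OB", 8.0, GAMMA, 2.0), UnitSpec("OB", 8.0, GAMMA, 0.0)],
            8,
        )
        locked, unlocked = rec.units
        x = rec.region_signal("OB")
        p_locked = spike_triggered_average(locked, x, FS, 0.1).sta_band_power(GAMMA, FS)
        p_unlocked = spike_triggered_average(unlocked, x, FS, 0.1).sta_band_power(GAMMA, FS)
        assert p_locked > p_unlocked


class TestMRLOracle:
    def test_von_mises_bessel_ratio(self):
        from oscibar.simulate import OscSpec, UnitSpec, simulate_lfp, simulate_spikes

        rec = simulate_lfp(
            [OscSpec("OB", THETA, 8.0, 50.0, phase_diffusion=2.0)],
            {"alpha": 1.0, "sigma": 5.0}, 200.0, FS, 11,
        )
        rec = simulate_spikes(rec, [UnitSpec("OB", 5.0, THETA, 2.0)], 12)
        res = spike_phase_locking(rec.units[0], rec.region_signal("OB"), FS, THETA)
        assert res.n_spikes >= 500
        assert res.mrl == pytest.approx(i1(2) / i0(2), abs=0.03)

    def test_mrl_monotone_in_kappa(self):
        from oscibar.simulate import OscSpec, UnitSpec, simulate_lfp, simulate_spikes

        rec = simulate_lfp(
            [OscSpec("OB", THETA, 8.0, 50.0, phase_diffusion=2.0)],
            {"alpha": 1.0, "sigma": 5.0}, 150.0, FS, 13,
        )
        mrls = []
        for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
            r = simulate_spikes(rec, [UnitSpec("OB", 6.0, THETA, kappa)], 14)
            res = spike_phase_locking(r.units[0], r.region_signal("OB"), FS, THETA)
            mrls.append(res.mrl)
        assert all(a < b for a, b in zip(mrls, mrls[1:]))
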