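"""Phase/amplitude coupling measures on band-limited LFP.

Band-pass filtering is zero-phase (forward-backward 4th-order Butterworth)
followed by the Hilbert transform, giving instantaneous phase under the
cosine convention (phase 0 at a peak) and a nonnegative amplitude envelope.

Phase-amplitude coupling uses the Tort modulation index: the amplitude of
the fast band is binned by the phase of the slow band (18 bins), the binned
profile is normalized to sum 1, and MI is the Kullback-Leibler divergence
from uniform divided by log(n_bins), so MI lies in [0, 1].  A
mean-vector-length estimator is available as ``method="mvl"``.

Spike-phase locking interpolates the unwrapped band phase at spike times;
non-uniformity is assessed with the Rayleigh test and units with
significantly non-uniform phase distributions (and at least 20 spikes) are
classified as phase-locked.  The mean resultant length (MRL) serves as the
locking-consistency metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BandDef, Recording, SpikeUnit, ValidationError

__all__ = [
    "AnalyticBand",
    "PACResult",
    "PhaseLockResult",
    "STAResult",
    "bandpass_analytic",
    "pac_mi",
    "comodulogram",
    "spike_phase_locking",
    "spike_triggered_average",
    "classify_locked",
    "rayleigh_p",
]

MIN_SPIKES_FOR_LOCKING = 20


@dataclass
class AnalyticBand:
    band: BandDef
    phase: np.ndarray      # [-pi, pi), cosine convention
    amplitude: np.ndarray  # >= 0
    fs_hz: float
    filter_order: int = 4

    @property
    def n_samples(self) -> int:
        return self.phase.size


@dataclass
class PACResult:
    phase_band: BandDef
    amp_band: BandDef
    n_bins: int
    bin_amp_profile: np.ndarray  # sums to 1
    mi: float
    preferred_phase: float


@dataclass
class PhaseLockResult:
    unit_id: str
    band: BandDef
    n_spikes: int
    spike_phases: np.ndarray
    mrl: float
    preferred_phase: float
    rayleigh_p: float
    low_n: bool


@dataclass
class STAResult:
    unit_id: str
    window_s: float
    sta: np.ndarray
    n_spikes: int
    lags_s: np.ndarray

    def sta_band_power(self, band: BandDef, fs_hz: float) -> float:
        """Band power (dB re 1 uV^2) of the short STA waveform (periodogram)."""
        freqs, psd = sps.periodogram(self.sta, fs=fs_hz, window="hann")
        mask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
        power = float(np.trapezoid(psd[mask], freqs[mask]))
        return -np.inf if power <= 0 else 10.0 * np.log10(power)


def bandpass_analytic(x: np.ndarray, fs_hz: float, band: BandDef) -> AnalyticBand:
    """Zero-phase Butterworth band-pass followed by the analytic signal."""
    x = np.asarray(x, dtype=np.float64)
    band.validate_for_fs(fs_hz)
    min_len = int(np.ceil(10 * fs_hz / band.lo_hz))
    if x.size < min_len:
        raise ValidationError(
            f"signal of {x.size} samples shorter than 10 cycles of "
            f"{band.lo_hz} Hz ({min_len} samples)"
        )
    sos = sps.butter(4, [band.lo_hz, band.hi_hz], btype="band", fs=fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    analytic = sps.hilbert(filtered)
    return AnalyticBand(
        band=band,
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        fs_hz=fs_hz,
    )


def _phase_bins(n_bins: int) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def pac_mi(
    phase: AnalyticBand,
    amp: AnalyticBand,
    n_bins: int = 18,
    method: str = "tort",
) -> PACResult:
    """Phase-amplitude coupling between a slow phase and a fast amplitude."""
    if phase.n_samples != amp.n_samples:
        raise ValidationError("phase and amplitude series differ in length")
    if phase.band.lo_hz >= amp.band.lo_hz:
        raise ValidationError(
            f"phase band {phase.band.name!r} must be slower than amplitude "
            f"band {amp.band.name!r}"
        )
    edges = _phase_bins(n_bins)
    idx = np.clip(np.digitize(phase.phase, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise ValidationError(
            f"empty phase bin(s) {np.nonzero(counts == 0)[0].tolist()}: "
            f"signal too short for {n_bins} phase bins"
        )
    sums = np.bincount(idx, weights=amp.amplitude, minlength=n_bins)
    mean_amp = sums / counts
    profile = mean_amp / mean_amp.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    pref = float(np.angle(np.sum(profile * np.exp(1j * centers))))
    if method == "tort":
        nz = profile > 0  # 0 log 0 = 0 in the KL sum
        kl = float(np.sum(profile[nz] * np.log(profile[nz] * n_bins)))
        mi = kl / np.log(n_bins)
    elif method == "mvl":
        mi = float(np.abs(np.mean(amp.amplitude * np.exp(1j * phase.phase)))
                   / np.mean(amp.amplitude))
    else:
        raise ValueError(f"unknown PAC method {method!r}")
    return PACResult(phase.band, amp.band, n_bins, profile, mi, pref)


def comodulogram(
    x: np.ndarray,
    fs_hz: float,
    phase_freqs_hz: np.ndarray,
    amp_freqs_hz: np.ndarray,
    phase_bw_hz: float = 2.0,
    amp_bw_hz: float = 20.0,
    n_bins: int = 18,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tort MI over a (phase frequency x amplitude frequency) grid.

    Returns ``(mi_matrix, phase_freqs, amp_freqs)`` where
    ``mi_matrix[i, j]`` couples phase at ``phase_freqs[i]`` with amplitude
    at ``amp_freqs[j]``; each candidate is a narrow band of width
    ``phase_bw_hz`` / ``amp_bw_hz`` centered on the grid frequency.
    """
    phase_freqs_hz = np.asarray(phase_freqs_hz, float)
    amp_freqs_hz = np.asarray(amp_freqs_hz, float)
    for f, bw in [(phase_freqs_hz, phase_bw_hz), (amp_freqs_hz, amp_bw_hz)]:
        if np.any(f + bw / 2 >= fs_hz / 2) or np.any(f - bw / 2 <= 0):
            raise ValidationError("comodulogram grid band exceeds (0, Nyquist)")
    phase_bands = [
        bandpass_analytic(x, fs_hz, BandDef(f"p{f:g}", f - phase_bw_hz / 2, f + phase_bw_hz / 2))
        for f in phase_freqs_hz
    ]
    amp_bands = [
        bandpass_analytic(x, fs_hz, BandDef(f"a{f:g}", f - amp_bw_hz / 2, f + amp_bw_hz / 2))
        for f in amp_freqs_hz
    ]
    mi = np.zeros((phase_freqs_hz.size, amp_freqs_hz.size))
    for i, pb in enumerate(phase_bands):
        for j, ab in enumerate(amp_bands):
            mi[i, j] = pac_mi(pb, ab, n_bins=n_bins).mi
    return mi, phase_freqs_hz, amp_freqs_hz


def phase_at_times(ab: AnalyticBand, times_s: np.ndarray, t0_s: float = 0.0) -> np.ndarray:
    """Band phase at arbitrary times by linear interpolation of unwrapped phase."""
    t_grid = t0_s + np.arange(ab.n_samples) / ab.fs_hz
    unwrapped = np.unwrap(ab.phase)
    ph = np.interp(times_s, t_grid, unwrapped)
    return np.angle(np.exp(1j * ph))


def rayleigh_p(n: int, mrl: float) -> float:
    """Rayleigh test p-value for circular non-uniformity (standard approximation)."""
    R = n * mrl
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - R * R)) - (1 + 2 * n))
    # the approximation can exceed 1 for tiny effects; clamp into (0, 1]
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def spike_phase_locking(
    unit: SpikeUnit,
    lfp_signal: np.ndarray,
    fs_hz: float,
    band: BandDef,
    t0_s: float = 0.0,
) -> PhaseLockResult:
    """Spike phases in ``band`` with MRL and Rayleigh non-uniformity test."""
    if unit.n_spikes == 0:
        raise ValidationError(f"unit {unit.unit_id}: no spikes to align")
    ab = bandpass_analytic(lfp_signal, fs_hz, band)
    phases = phase_at_times(ab, unit.spike_times_s, t0_s)
    vec = np.mean(np.exp(1j * phases))
    mrl = float(np.abs(vec))
    n = unit.n_spikes
    return PhaseLockResult(
        unit_id=unit.unit_id,
        band=band,
        n_spikes=n,
        spike_phases=phases,
        mrl=mrl,
        preferred_phase=float(np.angle(vec)),
        rayleigh_p=rayleigh_p(n, mrl),
        low_n=n < MIN_SPIKES_FOR_LOCKING,
    )


def spike_triggered_average(
    unit: SpikeUnit,
    lfp_signal: np.ndarray,
    fs_hz: float,
    window_s: float = 0.1,
    t0_s: float = 0.0,
) -> STAResult:
    """Mean LFP segment around each spike; edge-truncated spikes are dropped."""
    lfp_signal = np.asarray(lfp_signal, dtype=np.float64)
    w = int(round(window_s * fs_hz))
    centers = np.floor((unit.spike_times_s - t0_s) * fs_hz).astype(int)
    usable = centers[(centers - w >= 0) & (centers + w < lfp_signal.size)]
    if usable.size == 0:
        raise ValidationError(
            f"unit {unit.unit_id}: no spikes with a full +/-{window_s} s window"
        )
    offsets = np.arange(-w, w + 1)
    segments = lfp_signal[usable[:, None] + offsets[None, :]]
    return STAResult(
        unit_id=unit.unit_id,
        window_s=window_s,
        sta=segments.mean(axis=0),
        n_spikes=int(usable.size),
        lags_s=offsets / fs_hz,
    )


def classify_locked(result: PhaseLockResult, alpha: float = 0.05) -> bool:
    """Phase-locked iff Rayleigh p < alpha and the unit has >= 20 spikes."""
    return bool(result.rayleigh_p < alpha and result.n_spikes >= MIN_SPIKES_FOR_LOCKING)


def spike_phases_in_recording(
    rec: Recording, band: BandDef
) -> list[PhaseLockResult]:
    """Phase-locking of every unit against its own region's LFP."""
    return [
        spike_phase_locking(
            u, rec.region_signal(u.region), rec.fs_hz, band, t0_s=rec.t0_s
        )
        for u in rec.units
    ]
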