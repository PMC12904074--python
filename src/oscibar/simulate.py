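"""Synthetic multi-region LFP/spike cohorts with planted ground truth.

The generator emulates the structure of cross-olfactory-network recordings
(olfactory bulb OB, anterior piriform cortex aPC, lateral entorhinal cortex
LEC, 1000 Hz LFP) so that every analysis stage has a quantitative oracle:

* per-region LFP = band-limited oscillators + 1/f^alpha Gaussian noise.
  Each oscillator carries Wiener phase diffusion, so coherence below 1 is
  achievable and band spectra have realistic width;
* cross-region coherence is controlled by band-limited common noise between
  region pairs (frequency-domain mixing coefficient ``c`` gives in-band
  magnitude-squared coherence ``c^2``) and optionally by oscillators that
  share one phase realization (``shared_source_id``);
* theta-phase -> gamma-amplitude coupling is generated multiplicatively on
  the fast oscillator's envelope, ``A(t) = A0 (1 + m cos(phi_theta - phi0))``,
  matching the analysis-side modulation-index estimator;
* spikes are inhomogeneous Poisson with a von Mises phase kernel,
  ``r(t) = r0 exp(kappa cos(theta(t) - mu)) / I0(kappa)``, sampled by exact
  thinning so the mean rate stays ``r0`` for every kappa;
* recurring cross-regional co-activation patterns are planted by
  co-modulating the envelopes of loaded (region, band) channels with a
  shared slow latent course during activation epochs;
* behavior: novel/familiar exploration epochs whose durations encode a
  group-dependent discrimination index, and a neural-feature shift (OB
  theta envelope gain during novel epochs) of configurable effect size.

Group defaults for the two-group (control vs lesion) design encode the
effect directions and magnitudes characteristic of a unilateral 6-OHDA
Parkinsonian lesion: reduced OB gamma power and OB-aPC gamma coherence,
reduced OB/aPC theta with increased LEC theta, reduced theta->gamma PAC,
doubled spontaneous firing with selectively degraded gamma phase locking,
and a collapsed novel-object discrimination index.  Calibration constants
mapping generator knobs to measured values were fixed once by simulation
sweep and are frozen here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import i0

from .core import (
    DEFAULT_BANDS,
    GAMMA,
    THETA,
    BandDef,
    EventTable,
    Recording,
    SpikeUnit,
    ValidationError,
)
from .coupling import bandpass_analytic

__all__ = [
    "OscSpec",
    "UnitSpec",
    "NoiseLink",
    "BarcodePattern",
    "CohortSpec",
    "GroundTruth",
    "simulate_lfp",
    "simulate_spikes",
    "plant_barcode_patterns",
    "simulate_cohort",
    "simulate_trial_table",
    "default_cohort_spec",
]


@dataclass
class OscSpec:
    """One band-limited oscillator in one region.

    ``shared_source_id``: oscillators sharing an id reuse one phase-noise
    realization (perfectly coherent drive).  ``amp_mod`` plants
    phase-amplitude coupling: ``(phase_source_id, depth m, preferred phi0)``
    modulates this oscillator's envelope by the phase of the named source.
    """

    region: str
    band: BandDef
    center_hz: float
    amp: float  # microvolts (envelope amplitude)
    phase_diffusion: float = 1.0  # rad^2/s Wiener phase-noise rate
    shared_source_id: str | None = None
    osc_id: str | None = None
    amp_mod: tuple[str, float, float] | None = None  # (source osc_id, m, phi0)

    def __post_init__(self) -> None:
        if not (self.band.lo_hz <= self.center_hz <= self.band.hi_hz):
            raise ValidationError(
                f"oscillator center {self.center_hz} Hz outside band "
                f"{self.band.name!r} [{self.band.lo_hz}, {self.band.hi_hz}]"
            )
        if self.amp_mod is not None:
            m = self.amp_mod[1]
            if not (0 <= m <= 1):
                raise ValidationError(f"PAC depth m={m} must lie in [0, 1]")


@dataclass
class UnitSpec:
    """Generative model of one phase-locked Poisson unit."""

    region: str
    base_rate_hz: float
    lock_band: BandDef
    kappa: float  # von Mises concentration, >= 0
    mu: float = 0.0  # preferred phase

    def __post_init__(self) -> None:
        if self.base_rate_hz <= 0:
            raise ValidationError("base_rate_hz must be positive")
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")


@dataclass
class NoiseLink:
    """Band-limited common noise between two regions.

    Within ``band`` the two regions' noise spectra share a common source
    with power fraction ``c``, i.e. ``X_r = sqrt(1-c) N_r + sqrt(c) S``, so
    the in-band coherence magnitude (sqrt of magnitude-squared coherence)
    of the noise floor is exactly ``c``.
    """

    region_a: str
    region_b: str
    band: BandDef
    c: float

    def __post_init__(self) -> None:
        if not (0 <= self.c <= 1):
            raise ValidationError(f"coherence fraction c={self.c} must lie in [0, 1]")


@dataclass
class BarcodePattern:
    """A planted cross-regional co-activation motif.

    ``loadings`` maps (region, band name) channels to gains; during each
    activation epoch the envelopes of loaded channels are co-modulated by a
    shared nonnegative slow latent ``z(t)``:
    ``x_band <- x_band * (1 + g * z(t))``.
    """

    name: str
    loadings: dict[tuple[str, str], float]
    epochs: list[tuple[float, float]]
    latent_std: float = 1.5
    latent_tau_s: float = 0.5  # smoothing time constant of the latent course


@dataclass
class PatternTruth:
    name: str
    loadings: dict[tuple[str, str], float]
    epochs: list[tuple[float, float]]
    latent: np.ndarray  # z(t) at fs resolution
    signature: np.ndarray | None = None  # planted co-participation signature
    channels: list[tuple[str, str]] | None = None


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    osc_amps: dict[tuple[str, str], float]
    coherence_links: list[NoiseLink]
    pac_depth: float
    unit_params: list[UnitSpec]
    patterns: list[PatternTruth]
    novel_gain: float
    di_target: float


@dataclass
class GroundTruth:
    """Every planted parameter of a simulated cohort, for recovery tests."""

    subjects: list[SubjectTruth]
    spec: "CohortSpec"

    def by_group(self, group: str) -> list[SubjectTruth]:
        return [s for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(
    rng: np.random.Generator,
    regions: Sequence[str],
    n: int,
    fs_hz: float,
    alpha: float,
    sigma: float,
    links: Sequence[NoiseLink] = (),
) -> np.ndarray:
    """Per-region 1/f^alpha noise with band-limited common components."""
    freqs = np.fft.rfftfreq(n, d=1 / fs_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2)
    nf = freqs.size

    def cnoise() -> np.ndarray:
        return rng.standard_normal(nf) + 1j * rng.standard_normal(nf)

    spectra = {r: cnoise() for r in regions}
    for link in links:
        for r in (link.region_a, link.region_b):
            if r not in spectra:
                raise ValidationError(f"noise link references unknown region {r!r}")
        mask = (freqs >= link.band.lo_hz) & (freqs <= link.band.hi_hz)
        shared = cnoise()
        a = np.sqrt(link.c)
        for r in (link.region_a, link.region_b):
            spectra[r][mask] = (
                np.sqrt(1 - link.c) * spectra[r][mask] + a * shared[mask]
            )
    out = np.empty((len(regions), n))
    for i, r in enumerate(regions):
        x = np.fft.irfft(spectra[r] * shape, n=n)
        sd = x.std()
        out[i] = x * (sigma / sd) if sd > 0 else x
    return out


def _diffused_phase(
    rng: np.random.Generator, n: int, fs_hz: float, center_hz: float, rate: float
) -> np.ndarray:
    dt = 1 / fs_hz
    phi0 = rng.uniform(-np.pi, np.pi)
    drift = 2 * np.pi * center_hz * dt * np.arange(n)
    if rate > 0:
        wiener = np.cumsum(rng.standard_normal(n)) * np.sqrt(rate * dt)
    else:
        wiener = 0.0
    return phi0 + drift + wiener


def simulate_lfp(
    osc_specs: Sequence[OscSpec],
    noise: dict | None,
    duration_s: float,
    fs_hz: float = 1000.0,
    seed: int | np.random.Generator = 0,
    regions: Sequence[str] | None = None,
    noise_links: Sequence[NoiseLink] = (),
    subject_id: str = "sim",
    group: str = "control",
) -> Recording:
    """Simulate a multi-region LFP Recording (no spike units).

    ``noise`` is ``{"alpha": spectral exponent, "sigma": uV}`` or None for a
    noiseless recording.  Regions default to the union of oscillator regions
    in first-appearance order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if regions is None:
        regions = list(dict.fromkeys(s.region for s in osc_specs))
    n = int(round(duration_s * fs_hz))
    for s in osc_specs:
        if s.center_hz >= fs_hz / 2:
            raise ValidationError(
                f"oscillator at {s.center_hz} Hz >= Nyquist {fs_hz / 2} Hz"
            )
        if s.region not in regions:
            raise ValidationError(f"oscillator region {s.region!r} not in {regions}")

    if noise is not None and noise.get("sigma", 0) > 0:
        lfp = _one_over_f_noise(
            rng, regions, n, fs_hz,
            alpha=noise.get("alpha", 1.0), sigma=noise["sigma"], links=noise_links,
        )
    else:
        lfp = np.zeros((len(regions), n))

    # phase processes: shared sources reuse one realization
    shared: dict[str, np.ndarray] = {}
    phases: dict[int, np.ndarray] = {}
    by_id: dict[str, int] = {}
    for k, s in enumerate(osc_specs):
        if s.shared_source_id is not None:
            if s.shared_source_id not in shared:
                shared[s.shared_source_id] = _diffused_phase(
                    rng, n, fs_hz, s.center_hz, s.phase_diffusion
                )
            phases[k] = shared[s.shared_source_id]
        else:
            phases[k] = _diffused_phase(rng, n, fs_hz, s.center_hz, s.phase_diffusion)
        if s.osc_id is not None:
            by_id[s.osc_id] = k

    for k, s in enumerate(osc_specs):
        env = np.full(n, s.amp)
        if s.amp_mod is not None:
            src_id, m, phi0 = s.amp_mod
            if src_id not in by_id:
                raise ValidationError(f"amp_mod references unknown osc_id {src_id!r}")
            env = s.amp * (1 + m * np.cos(phases[by_id[src_id]] - phi0))
        lfp[regions.index(s.region)] += env * np.cos(phases[k])

    return Recording(
        subject_id=subject_id, group=group, regions=list(regions),
        lfp=lfp, fs_hz=fs_hz, t0_s=0.0,
    )


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def simulate_spikes(
    rec: Recording,
    units: Sequence[UnitSpec],
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Attach von Mises phase-locked Poisson units to ``rec`` (by thinning).

    The modulating phase is the Hilbert phase of the band-passed region
    signal, exactly the phase the locking analysis extracts.  Thinning
    against the rate ceiling ``r0 exp(kappa)/I0(kappa)`` is exact, and
    the expected rate is ``r0`` for every kappa.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = rec.duration_s
    new_units = list(rec.units)
    phase_cache: dict[tuple[str, str], np.ndarray] = {}
    for j, spec in enumerate(units):
        key = (spec.region, spec.lock_band.name)
        if key not in phase_cache:
            ab = bandpass_analytic(rec.region_signal(spec.region), rec.fs_hz, spec.lock_band)
            phase_cache[key] = np.unwrap(ab.phase)
        unwrapped = phase_cache[key]
        r0, kappa = spec.base_rate_hz, spec.kappa
        if kappa == 0:
            n_exp = rng.poisson(r0 * duration)
            times = np.sort(rng.uniform(0, duration, n_exp))
        else:
            lam_max = r0 * np.exp(kappa) / i0(kappa)
            n_cand = rng.poisson(lam_max * duration)
            cand = np.sort(rng.uniform(0, duration, n_cand))
            t_grid = np.arange(rec.n_samples) / rec.fs_hz
            ph = np.interp(cand, t_grid, unwrapped)
            rate = r0 * np.exp(kappa * np.cos(ph - spec.mu)) / i0(kappa)
            keep = rng.uniform(0, lam_max, n_cand) < rate
            times = cand[keep]
        times = np.unique(times) + rec.t0_s
        new_units.append(
            SpikeUnit(unit_id=f"u{len(new_units):03d}", region=spec.region,
                      spike_times_s=times)
        )
    return Recording(
        subject_id=rec.subject_id, group=rec.group, regions=list(rec.regions),
        lfp=rec.lfp, fs_hz=rec.fs_hz, t0_s=rec.t0_s, units=new_units,
    )


# ---------------------------------------------------------------------------
# Planted co-activation patterns
# ---------------------------------------------------------------------------

def _slow_latent(
    rng: np.random.Generator, n: int, fs_hz: float, tau_s: float, std: float
) -> np.ndarray:
    """Nonnegative slow latent: rectified, smoothed Gaussian noise."""
    raw = rng.standard_normal(n)
    width = max(int(tau_s * fs_hz), 1)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.clip(smooth, 0, None) * std


def plant_barcode_patterns(
    rec: Recording,
    patterns: Sequence[BarcodePattern],
    seed: int | np.random.Generator = 0,
    bands: Sequence[BandDef] = DEFAULT_BANDS,
    window_s: float = 0.25,
) -> tuple[Recording, list[PatternTruth]]:
    """Plant co-activation patterns into ``rec``; returns planted truths.

    Each loaded (region, band) component is band-passed out and re-injected
    with envelope gain ``1 + g * z(t)`` where ``z`` is the pattern's shared
    latent, nonzero only inside its activation epochs.  The returned
    :class:`PatternTruth` carries the realized latent course and the
    pattern's predicted co-participation signature: the generator measures
    its own (Butterworth-envelope) channel statistics, predicts the
    window-mean standardized amplitude vector with and without activation,
    and stores the normalized mean feature difference.  The analysis
    pipeline recovers patterns through a fully independent route.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    band_by_name = {b.name: b for b in bands}
    channels = [(r, b.name) for r in rec.regions for b in bands]
    n = rec.n_samples
    fs = rec.fs_hz
    t = np.arange(n) / fs

    lfp = rec.lfp.copy()
    # per-channel band components measured once on the input recording
    comp: dict[tuple[str, str], np.ndarray] = {}
    for r, bname in channels:
        ab = bandpass_analytic(rec.region_signal(r), fs, band_by_name[bname])
        comp[(r, bname)] = ab.amplitude * np.cos(ab.phase)

    truths: list[PatternTruth] = []
    gains: dict[tuple[str, str], np.ndarray] = {}
    for pat in patterns:
        for ch in pat.loadings:
            if ch[0] not in rec.regions or ch[1] not in band_by_name:
                raise ValidationError(
                    f"pattern {pat.name!r} loads unknown channel {ch}"
                )
        z_full = _slow_latent(rng, n, fs, pat.latent_tau_s, pat.latent_std)
        active = np.zeros(n, dtype=bool)
        for s, e in pat.epochs:
            active |= (t >= s) & (t < e)
        z = np.where(active, z_full, 0.0)
        for ch, g in pat.loadings.items():
            if g == 0:
                continue
            gains.setdefault(ch, np.zeros(n))
            gains[ch] = gains[ch] + g * z
        truths.append(PatternTruth(pat.name, dict(pat.loadings), list(pat.epochs), z))

    for ch, gain in gains.items():
        region_row = rec.regions.index(ch[0])
        lfp[region_row] += comp[ch] * gain

    out = Recording(
        subject_id=rec.subject_id, group=rec.group, regions=list(rec.regions),
        lfp=lfp, fs_hz=fs, t0_s=rec.t0_s, units=list(rec.units),
    )

    # planted co-participation signatures from the generator's own envelopes
    env = {}
    for r, bname in channels:
        ab = bandpass_analytic(out.region_signal(r), fs, band_by_name[bname])
        env[(r, bname)] = ab.amplitude
    wlen = int(round(window_s * fs))
    n_win = n // wlen
    # mirror the analysis order: standardize sample-level envelopes by their
    # SD, then take window means
    V = np.stack([
        (env[ch] / env[ch].std())[: n_win * wlen].reshape(n_win, wlen).mean(axis=1)
        for ch in channels
    ])  # [n_channels, n_windows]
    iu, ju = np.triu_indices(len(channels))
    F = (V[iu] * V[ju]).T  # [n_windows, n_features]
    win_t = (np.arange(n_win) + 0.5) * window_s
    for pat, truth in zip(patterns, truths):
        active_w = np.zeros(n_win, dtype=bool)
        for s, e in pat.epochs:
            active_w |= (win_t >= s) & (win_t < e)
        if active_w.any() and (~active_w).any():
            diff = F[active_w].mean(axis=0) - F[~active_w].mean(axis=0)
            nrm = np.linalg.norm(diff)
            truth.signature = diff / nrm if nrm > 0 else diff
        truth.channels = channels
    return out, truths


# ---------------------------------------------------------------------------
# Cohort generation with group effects
# ---------------------------------------------------------------------------

# Frozen calibration (one-time simulation sweep): oscillator envelope
# amplitudes (uV) per (region, band) chosen so Welch band power lands on the
# control-group anchor levels; lesion deltas applied in dB.  The noise floor
# is alpha=1, sigma=15 uV.
NOISE_ALPHA = 1.0
NOISE_SIGMA_UV = 15.0

CONTROL_OSC_AMP = {
    ("OB", "theta"): 68.3,   # ~34.8 dB band power incl. novel-epoch gain
    ("OB", "beta"): 18.0,
    ("OB", "gamma"): 14.64,  # ~21.5 dB
    ("aPC", "theta"): 64.6,  # ~33.1 dB
    ("aPC", "beta"): 18.0,
    ("aPC", "gamma"): 14.0,
    ("LEC", "theta"): 77.45,  # ~34.5 dB
    ("LEC", "beta"): 18.0,
    ("LEC", "gamma"): 12.0,
}

# lesion-minus-control band-power shifts in dB
# oscillator-level shifts differ from the measured band-power shifts
# (-2.33/-2.82/-2.81/+2.67 dB) because the 1/f floor adds a group-independent
# pedestal inside each band and the novelty gain (strong in controls only)
# raises whole-recording OB theta power (sweep-calibrated)
LESION_DB_SHIFT = {
    ("OB", "theta"): -1.85,
    ("OB", "gamma"): -2.99,
    ("aPC", "theta"): -2.86,
    ("LEC", "theta"): +2.70,
}

BAND_CENTER_HZ = {"theta": 8.0, "beta": 25.0, "gamma": 60.0}
PHASE_DIFFUSION = {"theta": 4.0, "beta": 12.0, "gamma": 40.0}

# target band-mean coherence magnitudes per (region pair, band)
CONTROL_COH = {("OB", "aPC", "gamma"): 0.62, ("OB", "LEC", "theta"): 0.27}
LESION_COH = {("OB", "aPC", "gamma"): 0.396, ("OB", "LEC", "theta"): 0.43}
# frozen knob values (shared power fraction) from the calibration sweep;
# the knob applies identically to the in-band noise floor and to the band
# oscillators of the linked pair (split into shared + independent parts)
COH_KNOB = {
    ("control", "OB", "aPC", "gamma"): 0.775,
    ("lesion", "OB", "aPC", "gamma"): 0.476,
    ("control", "OB", "LEC", "theta"): 0.278,
    ("lesion", "OB", "LEC", "theta"): 0.452,
}

# theta->gamma PAC generative depth m in OB (measured Tort MI ~0.0034/0.0017)
CONTROL_PAC_M = 0.292
LESION_PAC_M = 0.327

# OB unit defaults: doubled lesion rate; gamma locking collapses (~75% MRL
# drop: I1/I0(0.85)=0.40 -> I1/I0(0.20)=0.10) while theta locking is spared.
CONTROL_UNITS = dict(r0=5.0, kappa_gamma=0.85, kappa_theta=0.8)
LESION_UNITS = dict(r0=10.0, kappa_gamma=0.20, kappa_theta=0.8)

# behavior: discrimination-index targets (fractions, not %)
CONTROL_DI = 0.31
LESION_DI = -0.085


@dataclass
class CohortSpec:
    """Study-condition defaults for a two-group synthetic cohort."""

    n_per_group: int = 8
    duration_s: float = 120.0
    fs_hz: float = 1000.0
    regions: tuple[str, ...] = ("OB", "aPC", "LEC")
    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    n_units_per_subject: int = 3
    epochs_per_condition: int = 20
    epoch_len_s: float = 2.0
    novel_gain_control: float = 0.35  # OB theta envelope gain in novel epochs
    novel_gain_lesion: float = 0.05
    barcode_patterns: tuple[BarcodePattern, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        # each bout pair needs at least ~1.7 s (two 0.3-s bouts + two gaps)
        need = 1.9 * self.epochs_per_condition + 4.0
        if self.duration_s < need:
            raise ValidationError(
                f"duration {self.duration_s} s too short for "
                f"{2 * self.epochs_per_condition} exploration bouts"
            )


def default_cohort_spec(**overrides) -> CohortSpec:
    return CohortSpec(**overrides)


def _subject_osc_specs(group: str, spec: CohortSpec) -> list[OscSpec]:
    """Per-region oscillators with group effects and coherence splitting.

    A (region, band) channel that participates in a coherence link is
    emitted as two oscillators: a pair-shared phase source carrying the
    knob's power fraction and an independent remainder, so both the noise
    floor and the oscillatory line contribute the same in-band coherence.
    """
    # linked channels: (region, band) -> (shared_source_id, power fraction)
    links: dict[tuple[str, str], tuple[str, float]] = {}
    for (g, a, b, bn), knob in COH_KNOB.items():
        if g != group:
            continue
        src = f"{a}-{b}-{bn}"
        links[(a, bn)] = (src, knob)
        links[(b, bn)] = (src, knob)

    out = []
    for region in spec.regions:
        for band in spec.bands:
            amp = CONTROL_OSC_AMP[(region, band.name)]
            shift = LESION_DB_SHIFT.get((region, band.name), 0.0)
            if group == "lesion" and shift:
                amp = amp * 10 ** (shift / 20.0)
            kwargs = {}
            if region == "OB" and band.name == "theta":
                kwargs["osc_id"] = "OB_theta"
            if region == "OB" and band.name == "gamma":
                m = CONTROL_PAC_M if group == "control" else LESION_PAC_M
                kwargs["amp_mod"] = ("OB_theta", m, 0.0)
            common = dict(
                region=region, band=band, center_hz=BAND_CENTER_HZ[band.name],
                phase_diffusion=PHASE_DIFFUSION[band.name],
            )
            link = links.get((region, band.name))
            if link is None:
                out.append(OscSpec(amp=amp, **common, **kwargs))
            else:
                src, frac = link
                out.append(
                    OscSpec(amp=amp * np.sqrt(frac), shared_source_id=src,
                            **common, **{k: v for k, v in kwargs.items() if k != "osc_id"})
                )
                out.append(OscSpec(amp=amp * np.sqrt(1 - frac), **common, **kwargs))
    return out


def _subject_noise_links(group: str, spec: CohortSpec) -> list[NoiseLink]:
    band_by_name = {b.name: b for b in spec.bands}
    return [
        NoiseLink(a, b, band_by_name[bn], knob)
        for (g, a, b, bn), knob in COH_KNOB.items()
        if g == group
    ]


def _behavior_events(
    rng: np.random.Generator, group: str, spec: CohortSpec
) -> EventTable:
    """Alternating novel/familiar exploration bouts with group-typical DI.

    Bout durations are gamma-distributed; the novel/familiar mean ratio is
    set from the group's DI target, di = (Tn - Tf)/(Tn + Tf).
    """
    di = CONTROL_DI if group == "control" else LESION_DI
    ratio = (1 + di) / (1 - di)
    # familiar-bout mean scaled so the expected bout train (plus 0.5-s gaps)
    # fills at most ~90% of the recording regardless of the DI ratio
    budget = 0.90 * spec.duration_s - 2.0
    base = min(
        spec.epoch_len_s,
        (budget / spec.epochs_per_condition - 1.0) / (1 + ratio),
    )
    if base <= 0.3:
        raise ValidationError(
            f"duration {spec.duration_s} s too short for "
            f"{2 * spec.epochs_per_condition} exploration bouts"
        )
    rows = []
    t = 2.0
    for i in range(spec.epochs_per_condition):
        for cond in ("novel", "familiar"):
            mean = base * (ratio if cond == "novel" else 1.0)
            dur = float(rng.gamma(shape=25.0, scale=mean / 25.0))
            dur = min(max(dur, 0.3), mean * 2)
            rows.append(
                dict(
                    epoch_id=f"{cond}_{i:02d}", label="exploration",
                    start_s=round(t, 3), end_s=round(t + dur, 3), condition=cond,
                )
            )
            t += dur + 0.5
    table = EventTable.from_rows(rows)
    if t > spec.duration_s:
        raise ValidationError(
            f"behavioral epochs overran the recording ({t:.1f} > {spec.duration_s} s)"
        )
    return table


def _apply_novel_gain(
    rec: Recording, events: EventTable, gain: float
) -> Recording:
    """Scale the OB theta component by (1 + gain) inside novel epochs."""
    if gain == 0:
        return rec
    ab = bandpass_analytic(rec.region_signal("OB"), rec.fs_hz, THETA)
    comp = ab.amplitude * np.cos(ab.phase)
    t = np.arange(rec.n_samples) / rec.fs_hz
    mask = np.zeros(rec.n_samples)
    for _, row in events.select(condition="novel").iterrows():
        mask[(t >= row.start_s) & (t < row.end_s)] = 1.0
    lfp = rec.lfp.copy()
    lfp[rec.regions.index("OB")] += comp * gain * mask
    return Recording(
        subject_id=rec.subject_id, group=rec.group, regions=list(rec.regions),
        lfp=lfp, fs_hz=rec.fs_hz, t0_s=rec.t0_s, units=list(rec.units),
    )


def simulate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[tuple[Recording, EventTable]], GroundTruth]:
    """Simulate ``n_per_group`` control and lesion subjects with ground truth."""
    spec = spec or CohortSpec()
    master = np.random.default_rng(spec.rng_seed)
    subjects: list[tuple[Recording, EventTable]] = []
    truths: list[SubjectTruth] = []
    for group in ("control", "lesion"):
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(master.integers(2**31))
            sid = f"{group[:3]}{i:02d}"
            oscs = _subject_osc_specs(group, spec)
            links = _subject_noise_links(group, spec)
            rec = simulate_lfp(
                oscs, {"alpha": NOISE_ALPHA, "sigma": NOISE_SIGMA_UV},
                spec.duration_s, spec.fs_hz, rng, regions=list(spec.regions),
                noise_links=links, subject_id=sid, group=group,
            )
            events = _behavior_events(rng, group, spec)
            gain = (
                spec.novel_gain_control if group == "control" else spec.novel_gain_lesion
            )
            rec = _apply_novel_gain(rec, events, gain)
            pattern_truths: list[PatternTruth] = []
            if spec.barcode_patterns:
                rec, pattern_truths = plant_barcode_patterns(
                    rec, spec.barcode_patterns, rng, bands=spec.bands
                )
            uspec = CONTROL_UNITS if group == "control" else LESION_UNITS
            units = []
            for _ in range(spec.n_units_per_subject):
                units.append(UnitSpec("OB", uspec["r0"], GAMMA, uspec["kappa_gamma"]))
                units.append(UnitSpec("OB", uspec["r0"], THETA, uspec["kappa_theta"]))
            rec = simulate_spikes(rec, units, rng)
            subjects.append((rec, events))
            truths.append(
                SubjectTruth(
                    subject_id=sid, group=group,
                    osc_amps={(o.region, o.band.name): o.amp for o in oscs},
                    coherence_links=links,
                    pac_depth=CONTROL_PAC_M if group == "control" else LESION_PAC_M,
                    unit_params=units,
                    patterns=pattern_truths,
                    novel_gain=gain,
                    di_target=CONTROL_DI if group == "control" else LESION_DI,
                )
            )
    return subjects, GroundTruth(subjects=truths, spec=spec)


def simulate_habituation_events(
    group: str = "control",
    n_odors: int = 3,
    n_presentations: int = 3,
    seed: int | np.random.Generator = 0,
    base_sniff_s: float = 6.0,
    habituation_decay: float = 0.55,
    dishabituation_gain_control: float = 0.9,
    dishabituation_gain_lesion: float = 0.25,
) -> EventTable:
    """Odor habituation-dishabituation presentation sequence.

    Each odor is presented ``n_presentations`` times; sniffing decays by
    ``habituation_decay`` per repeat, and the first presentation of a new
    odor rebounds toward baseline by the group's dishabituation gain
    (lesion animals dishabituate weakly).  First presentations of odors
    after the first are labeled ``novel``, repeats ``habituation``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gain = (
        dishabituation_gain_control if group == "control" else dishabituation_gain_lesion
    )
    rows = []
    t = 2.0
    level = base_sniff_s
    for odor in range(n_odors):
        for p in range(n_presentations):
            if p == 0:
                if odor > 0:
                    level = level + gain * (base_sniff_s - level)
                cond = "novel" if odor > 0 else "habituation"
            else:
                level = level * habituation_decay
                cond = "habituation"
            dur = max(float(level * rng.uniform(0.9, 1.1)), 0.2)
            rows.append(
                dict(
                    epoch_id=f"odor{odor}_p{p}", label=f"odor{odor}",
                    start_s=round(t, 3), end_s=round(t + dur, 3), condition=cond,
                )
            )
            t += dur + 3.0
    return EventTable.from_rows(rows)


# ---------------------------------------------------------------------------
# Trial-level feature simulation (decoding calibration surface)
# ---------------------------------------------------------------------------

def simulate_trial_table(
    n_subjects: int = 14,
    n_trials_per_condition: int = 40,
    n_features: int = 3,
    effect_d: float = 0.0,
    subject_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    group_split: bool = True,
):
    """Trial feature table with a planted novel-vs-familiar effect.

    Features are unit-variance Gaussian with subject-level random
    intercepts (``subject_sd``); ``effect_d`` shifts feature 0 on novel
    trials by ``d`` within-trial standard deviations.  ``effect_d = 0``
    gives the null world used for chance-level calibration.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        group = "control" if (not group_split or s < (n_subjects + 1) // 2) else "lesion"
        intercept = rng.normal(0, subject_sd, n_features)
        for cond in ("familiar", "novel"):
            x = rng.standard_normal((n_trials_per_condition, n_features)) + intercept
            if cond == "novel":
                x[:, 0] += effect_d
            for k in range(n_trials_per_condition):
                rows.append(
                    dict(
                        subject_id=f"s{s:02d}", group=group,
                        trial_id=f"s{s:02d}_{cond}_{k:02d}", condition=cond,
                        **{f"f{j}": x[k, j] for j in range(n_features)},
                    )
                )
    return pd.DataFrame(rows)
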