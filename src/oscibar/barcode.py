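"""Co-activation "Barcodes": masked EMD + ICA over co-participation features.

The method characterizes recurring cross-regional oscillatory motifs:

1. each region's LFP is decomposed by *masked* empirical mode decomposition
   (EMD) into intrinsic mode functions (IMFs); sinusoidal masks at a
   descending frequency ladder prevent mode mixing;
2. IMFs are assigned to the canonical bands by their amplitude-weighted
   mean instantaneous frequency, giving one Hilbert amplitude envelope per
   (region, band) channel; envelopes are standardized by their SD (no mean
   removal - envelopes are nonnegative);
3. in every non-overlapping 250-ms window the channel amplitude vector v is
   expanded to a co-participation vector, the vectorized upper triangle
   (including the diagonal) of the outer product v v^T, capturing pairwise
   co-activation including within-channel power;
4. ICA (fixed-point, log-cosh contrast, deflation, seeded) on the window x
   feature matrix of standardized amplitudes yields unit-norm weight
   vectors - the Barcodes;
5. the dot product of each weight vector with the co-participation features
   of the *non-standardized* amplitudes gives that barcode's strength time
   series at 4 Hz resolution;
6. a barcode's behavior score is the ROC-AUC with which its per-epoch mean
   strength separates a positive behavioral condition from the contrast
   condition (0.5 = uninformative); the score definition is this package's
   own, stated here because the original method leaves it unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert
from sklearn.decomposition import FastICA
from sklearn.metrics import roc_auc_score

from .core import BandDef, DEFAULT_BANDS, EventTable, Recording, ValidationError

__all__ = [
    "IMF",
    "IMFSet",
    "AmplitudeMatrix",
    "BarcodeModel",
    "StrengthSeries",
    "masked_emd",
    "select_imfs",
    "amplitude_matrix",
    "coparticipation",
    "fit_barcodes",
    "barcode_strength",
    "barcode_score",
    "fit_barcode_pipeline",
]


@dataclass
class IMF:
    signal: np.ndarray
    amplitude: np.ndarray
    inst_freq_hz: np.ndarray
    peak_freq_hz: float
    assigned_band: BandDef | None = None


@dataclass
class IMFSet:
    region: str
    fs_hz: float
    imfs: list[IMF]
    residual: np.ndarray
    source: np.ndarray

    def reconstruction_error(self) -> float:
        """Relative L2 error of sum(IMFs) + residual against the input."""
        recon = self.residual + sum(m.signal for m in self.imfs)
        denom = np.linalg.norm(self.source)
        if denom == 0:
            return float(np.linalg.norm(recon))
        return float(np.linalg.norm(recon - self.source) / denom)


@dataclass
class AmplitudeMatrix:
    channels: list[tuple[str, str]]  # (region, band name), region-major
    A_std: np.ndarray  # [n_channels, n_samples], per-channel SD = 1
    A_raw: np.ndarray
    sd: np.ndarray
    fs_hz: float
    empty_channels: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class BarcodeModel:
    feature_index: list[tuple[int, int]]  # channel index pairs, i <= j
    channels: list[tuple[str, str]]
    W: np.ndarray  # [n_barcodes, n_features], rows unit-norm
    window_s: float
    seed: int
    converged: bool
    n_iter: int


@dataclass
class StrengthSeries:
    barcode_id: int
    times_s: np.ndarray  # window centers
    strength: np.ndarray


# ---------------------------------------------------------------------------
# masked EMD
# ---------------------------------------------------------------------------

def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    sign = np.sign(d)
    # treat flats by propagating the previous slope sign
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.nonzero(flips < 0)[0] + 1
    minima = np.nonzero(flips > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirrored end padding."""
    if idx.size < 2:
        return np.full(n, x[idx[0]] if idx.size else 0.0)
    # mirror two extrema beyond each end to tame spline end swings
    left = 2 * 0 - idx[:2][::-1]
    right = 2 * (n - 1) - idx[-2:][::-1]
    xi = np.concatenate([left, idx, right])
    yi = np.concatenate([x[idx[:2]][::-1], x[idx], x[idx[-2:]][::-1]])
    # guard against duplicate knots at the boundary
    keep = np.concatenate([[True], np.diff(xi) > 0])
    return CubicSpline(xi[keep], yi[keep])(np.arange(n))


def _sift(x: np.ndarray, sift_tol: float = 0.2, max_sift: int = 12) -> np.ndarray:
    """Extract one IMF by standard sifting with an SD-style stopping rule."""
    h = x
    n = x.size
    for _ in range(max_sift):
        maxima, minima = _extrema_indices(h)
        if maxima.size + minima.size < 3:
            break
        upper = _envelope(h, maxima, n)
        lower = _envelope(h, minima, n)
        mean = (upper + lower) / 2
        h_new = h - mean
        denom = np.sum(h * h)
        if denom == 0:
            h = h_new
            break
        sd = np.sum((h - h_new) ** 2) / denom
        h = h_new
        if sd < sift_tol:
            break
    return h


def default_mask_freqs(fs_hz: float, max_imfs: int = 8) -> np.ndarray:
    """Descending octave ladder starting at fs/4 (e.g. 250, 125, ... Hz)."""
    return fs_hz / 4 / (2.0 ** np.arange(max_imfs))


def masked_emd(
    x: np.ndarray,
    fs_hz: float,
    mask_freqs: np.ndarray | None = None,
    n_mask_phases: int = 4,
    max_imfs: int = 8,
    sift_tol: float = 0.2,
    mask_amp_ratio: float = 2.0,
    region: str = "",
) -> IMFSet:
    """Masked empirical mode decomposition of one LFP channel.

    For each mask frequency (descending), the next IMF is the average of
    first IMFs sifted from ``x + mask`` over ``n_mask_phases`` equispaced
    mask phases (the masks cancel in the average); the IMF is subtracted
    and the ladder recurses.  Masking pins each IMF's passband near its
    mask frequency and prevents mode mixing between transient rhythms.
    The sum of IMFs plus the residual reconstructs the input to floating
    precision by construction.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValidationError("input contains non-finite samples")
    if mask_freqs is None:
        mask_freqs = default_mask_freqs(fs_hz, max_imfs)
    mask_freqs = np.asarray(mask_freqs, dtype=np.float64)
    if np.any(mask_freqs >= fs_hz / 2):
        raise ValidationError(
            f"mask frequency {mask_freqs.max()} Hz at or above Nyquist {fs_hz / 2} Hz"
        )
    if np.any(np.diff(mask_freqs) > 0):
        raise ValidationError("mask_freqs must be descending")

    n = x.size
    t = np.arange(n) / fs_hz
    residual = x.copy()
    imfs: list[IMF] = []
    for f_mask in mask_freqs[:max_imfs]:
        sd = residual.std()
        if sd == 0:
            break
        amp = mask_amp_ratio * sd
        # refinement passes: the masked sift leaves a coherent remainder of
        # the fast content (~10%); a second pass at the same mask frequency
        # collects it before descending the ladder
        imf_sig = np.zeros(n)
        for _pass in range(2):
            acc = np.zeros(n)
            for p in range(n_mask_phases):
                mask = amp * np.cos(
                    2 * np.pi * f_mask * t + 2 * np.pi * p / n_mask_phases
                )
                acc += _sift(residual - imf_sig + mask, sift_tol) - mask
            delta = acc / n_mask_phases
            imf_sig = imf_sig + delta
            if np.linalg.norm(delta) < 0.05 * np.linalg.norm(imf_sig):
                break
        residual = residual - imf_sig
        analytic = hilbert(imf_sig)
        amp_env = np.abs(analytic)
        phase = np.unwrap(np.angle(analytic))
        inst = np.gradient(phase) * fs_hz / (2 * np.pi)
        wsum = amp_env.sum()
        peak = float(np.sum(amp_env * inst) / wsum) if wsum > 0 else 0.0
        imfs.append(IMF(imf_sig, amp_env, inst, peak))
    return IMFSet(region=region, fs_hz=fs_hz, imfs=imfs, residual=residual, source=x)


def select_imfs(imfset: IMFSet, bands: tuple[BandDef, ...] = DEFAULT_BANDS) -> dict[str, np.ndarray]:
    """Assign IMFs to bands and return one envelope per band.

    An IMF belongs to the band containing its amplitude-weighted mean
    instantaneous frequency; IMFs falling between bands are dropped, and
    multiple IMFs in one band have their envelopes summed.  A band with no
    IMF yields a zero envelope (callers treat it as an empty channel).
    """
    n = imfset.source.size
    out: dict[str, np.ndarray] = {b.name: np.zeros(n) for b in bands}
    for imf in imfset.imfs:
        for b in bands:
            if b.contains(imf.peak_freq_hz):
                imf.assigned_band = b
                out[b.name] = out[b.name] + imf.amplitude
                break
    return out


def amplitude_matrix(
    per_region: dict[str, IMFSet],
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
    regions: list[str] | None = None,
) -> AmplitudeMatrix:
    """Standardized (region, band) amplitude matrix from assigned IMF sets."""
    regions = regions or list(per_region)
    lengths = {per_region[r].source.size for r in regions}
    fs = {per_region[r].fs_hz for r in regions}
    if len(lengths) != 1 or len(fs) != 1:
        raise ValidationError("all regions must share duration and sampling rate")
    channels = [(r, b.name) for r in regions for b in bands]
    rows = []
    empty = []
    for r in regions:
        env = select_imfs(per_region[r], bands)
        for b in bands:
            rows.append(env[b.name])
            if not env[b.name].any():
                empty.append((r, b.name))
    A_raw = np.stack(rows)
    sd = A_raw.std(axis=1)
    zero_var = [channels[i] for i in np.nonzero(sd == 0)[0] if channels[i] not in empty]
    if zero_var:
        raise ValidationError(f"zero-variance amplitude channel(s): {zero_var}")
    safe_sd = np.where(sd == 0, 1.0, sd)
    return AmplitudeMatrix(
        channels=channels, A_std=A_raw / safe_sd[:, None], A_raw=A_raw,
        sd=sd, fs_hz=fs.pop(), empty_channels=empty,
    )


# ---------------------------------------------------------------------------
# co-participation features and ICA
# ---------------------------------------------------------------------------

def feature_index_for(n_channels: int) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(n_channels)
    return list(zip(iu.tolist(), ju.tolist()))


def coparticipation(
    M: AmplitudeMatrix, window_s: float = 0.25, use_std: bool = True
) -> np.ndarray:
    """Windowed co-participation feature matrix ``[n_windows, n_features]``.

    Per non-overlapping window the channel envelopes are averaged into a
    vector v and expanded to the upper triangle (with diagonal) of
    ``v v^T``; a 10-s recording yields 40 rows at the default 250 ms.
    """
    A = M.A_std if use_std else M.A_raw
    wlen = int(round(window_s * M.fs_hz))
    n_win = A.shape[1] // wlen
    if n_win < 1:
        raise ValidationError(f"recording shorter than one {window_s}-s window")
    V = A[:, : n_win * wlen].reshape(A.shape[0], n_win, wlen).mean(axis=2)
    iu, ju = np.triu_indices(A.shape[0])
    return (V[iu] * V[ju]).T


def window_times(n_windows: int, window_s: float = 0.25) -> np.ndarray:
    return (np.arange(n_windows) + 0.5) * window_s


def fit_barcodes(
    F_std: np.ndarray,
    n_barcodes: int = 8,
    seed: int = 0,
    channels: list[tuple[str, str]] | None = None,
    window_s: float = 0.25,
    max_iter: int = 1000,
) -> BarcodeModel:
    """ICA weight vectors ("Barcodes") from standardized co-participation.

    Features are centered and PCA-whitened to ``n_barcodes`` dimensions,
    then unmixed by fixed-point ICA (log-cosh, deflation).  Each barcode is
    the *pattern* of its independent component - the normalized column of
    the fitted mixing matrix, i.e. the co-participation motif that the
    component contributes to the data.  (The unmixing filters are shaped by
    nuisance covariance and do not render the motif; the mixing patterns
    are what barcode grid graphics display.)  Rows are unit-normed with the
    largest-magnitude element made positive, so the decomposition is
    reproducible up to component order given a seed.
    """
    F_std = np.asarray(F_std, dtype=np.float64)
    n_windows, n_features = F_std.shape
    if n_windows < 10 * n_barcodes:
        raise ValidationError(
            f"{n_windows} windows < 10 x {n_barcodes} barcodes; record longer"
        )
    rank = np.linalg.matrix_rank(F_std - F_std.mean(axis=0))
    if n_barcodes > rank:
        raise ValidationError(f"n_barcodes={n_barcodes} exceeds feature rank {rank}")
    ica = FastICA(
        n_components=n_barcodes, algorithm="deflation", fun="logcosh",
        whiten="unit-variance", max_iter=max_iter, random_state=seed,
    )
    ica.fit(F_std)
    W = np.asarray(ica.mixing_, dtype=np.float64).T  # component patterns
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    W = W / norms
    for row in W:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    n_ch = int((np.sqrt(8 * n_features + 1) - 1) / 2)
    return BarcodeModel(
        feature_index=feature_index_for(n_ch),
        channels=channels or [("", str(i)) for i in range(n_ch)],
        W=W, window_s=window_s, seed=seed,
        converged=ica.n_iter_ < max_iter, n_iter=int(ica.n_iter_),
    )


def barcode_strength(model: BarcodeModel, F_raw: np.ndarray) -> list[StrengthSeries]:
    """Strength time series: weight vectors dotted with raw-amplitude features."""
    F_raw = np.asarray(F_raw, dtype=np.float64)
    if F_raw.shape[1] != model.W.shape[1]:
        raise ValidationError(
            f"feature dimension {F_raw.shape[1]} does not match model "
            f"({model.W.shape[1]})"
        )
    S = F_raw @ model.W.T  # [n_windows, n_barcodes]
    times = window_times(F_raw.shape[0], model.window_s)
    return [
        StrengthSeries(barcode_id=k, times_s=times, strength=S[:, k])
        for k in range(model.W.shape[0])
    ]


def barcode_score(
    series: StrengthSeries,
    events: EventTable,
    positive_condition: str,
    contrast_condition: str | None = None,
) -> float:
    """ROC-AUC of per-epoch mean strength, positive vs contrast condition."""
    labels, values = [], []
    for _, row in events.df.iterrows():
        if contrast_condition is None:
            is_pos = row.condition == positive_condition
        elif row.condition == positive_condition:
            is_pos = True
        elif row.condition == contrast_condition:
            is_pos = False
        else:
            continue
        mask = (series.times_s >= row.start_s) & (series.times_s < row.end_s)
        if not mask.any():
            continue
        labels.append(int(is_pos))
        values.append(series.strength[mask].mean())
    if len(set(labels)) < 2 or min(sum(labels), len(labels) - sum(labels)) < 2:
        raise ValidationError(
            "barcode_score needs >= 2 epochs in each of the two conditions"
        )
    return float(roc_auc_score(labels, values))


def fit_barcode_pipeline(
    rec: Recording,
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
    n_barcodes: int = 8,
    window_s: float = 0.25,
    seed: int = 0,
    **emd_kwargs,
) -> tuple[BarcodeModel, list[StrengthSeries], AmplitudeMatrix]:
    """End-to-end barcode fit for one recording."""
    per_region = {
        r: masked_emd(rec.region_signal(r), rec.fs_hz, region=r, **emd_kwargs)
        for r in rec.regions
    }
    M = amplitude_matrix(per_region, bands, regions=list(rec.regions))
    F_std = coparticipation(M, window_s, use_std=True)
    F_raw = coparticipation(M, window_s, use_std=False)
    model = fit_barcodes(F_std, n_barcodes, seed, channels=M.channels, window_s=window_s)
    return model, barcode_strength(model, F_raw), M
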