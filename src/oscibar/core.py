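"""Shared data model for multi-region LFP/spike recordings.

The atoms consumed by every analysis stage: a :class:`Recording` holds a
regions-by-samples LFP matrix (microvolts) plus sorted spike times per unit,
an :class:`EventTable` holds labeled behavioral epochs, :class:`BandDef`
names a frequency band, and :class:`PipelineConfig` collects the analysis
defaults (Welch segments, co-participation window, decoding iterations).

Time convention: seconds as floats; sample indices via ``floor(t * fs)``;
all epoch intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandDef",
    "SpikeUnit",
    "Recording",
    "EventTable",
    "PipelineConfig",
    "THETA",
    "BETA",
    "GAMMA",
    "DEFAULT_BANDS",
    "ValidationError",
    "SchemaError",
]

EVENT_COLUMNS = ["epoch_id", "label", "start_s", "end_s", "condition"]
CONDITIONS = ("familiar", "novel", "habituation", "other")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


class SchemaError(ValueError):
    """Raised when a file does not follow the documented layout."""


@dataclass(frozen=True)
class BandDef:
    """A named frequency band ``[lo_hz, hi_hz]``."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValidationError(
                f"band {self.name!r}: need 0 < lo_hz < hi_hz, got "
                f"({self.lo_hz}, {self.hi_hz})"
            )

    def contains(self, freq_hz: float) -> bool:
        """Closed-interval membership: ``lo_hz <= f <= hi_hz``."""
        return self.lo_hz <= freq_hz <= self.hi_hz

    def validate_for_fs(self, fs_hz: float) -> None:
        if self.hi_hz >= fs_hz / 2:
            raise ValidationError(
                f"band {self.name!r} upper edge {self.hi_hz} Hz reaches the "
                f"Nyquist frequency {fs_hz / 2} Hz"
            )


THETA = BandDef("theta", 3.0, 12.0)
BETA = BandDef("beta", 15.0, 35.0)
GAMMA = BandDef("gamma", 36.0, 95.0)
DEFAULT_BANDS: tuple[BandDef, ...] = (THETA, BETA, GAMMA)


@dataclass
class SpikeUnit:
    """Sorted spike times (seconds) of one isolated unit."""

    unit_id: str
    region: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=np.float64)
        if self.spike_times_s.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike times must be 1-D")
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if self.spike_times_s.size and self.spike_times_s[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def mean_rate_hz(self, duration_s: float) -> float:
        return self.n_spikes / duration_s


@dataclass
class Recording:
    """Multi-region LFP matrix plus spike units and sampling metadata.

    ``lfp`` is ``[n_regions, n_samples]`` in microvolts, sampled at
    ``fs_hz``; row order matches ``regions``.
    """

    subject_id: str
    group: str
    regions: list[str]
    lfp: np.ndarray
    fs_hz: float = 1000.0
    t0_s: float = 0.0
    units: list[SpikeUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=np.float64)
        self.regions = list(self.regions)
        self.validate()

    def validate(self) -> None:
        if self.group not in ("control", "lesion"):
            raise ValidationError(f"group must be control/lesion, got {self.group!r}")
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.lfp.ndim != 2:
            raise ValidationError("lfp must be a 2-D [n_regions, n_samples] matrix")
        if len(self.regions) != self.lfp.shape[0]:
            raise ValidationError(
                f"{len(self.regions)} region labels for {self.lfp.shape[0]} LFP rows"
            )
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError(f"duplicate region labels in {self.regions}")
        bad = ~np.isfinite(self.lfp)
        if bad.any():
            idx = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite LFP sample at region row {idx[0]}, sample {idx[1]}"
            )
        t_end = self.t0_s + self.duration_s
        for u in self.units:
            if u.region not in self.regions:
                raise ValidationError(
                    f"unit {u.unit_id} references unknown region {u.region!r}"
                )
            if u.n_spikes and (
                u.spike_times_s[0] < self.t0_s or u.spike_times_s[-1] > t_end
            ):
                raise ValidationError(
                    f"unit {u.unit_id} has spikes outside [{self.t0_s}, {t_end}] s"
                )

    @property
    def n_samples(self) -> int:
        return int(self.lfp.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def region_signal(self, region: str) -> np.ndarray:
        try:
            return self.lfp[self.regions.index(region)]
        except ValueError:
            raise KeyError(f"region {region!r} not in {self.regions}") from None

    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz


class EventTable:
    """Labeled behavioral epochs aligning neural data to behavior.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``epoch_id, label, start_s, end_s, condition``.  Epochs sharing a label
    stream (same ``label``) may not overlap.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"event table missing columns {missing}")
        df["start_s"] = df["start_s"].astype(float)
        df["end_s"] = df["end_s"].astype(float)
        for col in ("epoch_id", "label", "condition"):
            df[col] = df[col].astype(str)
        self.df = df[EVENT_COLUMNS].reset_index(drop=True)
        self.validate()

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "EventTable":
        return cls(pd.DataFrame(list(rows)))

    def validate(self) -> None:
        df = self.df
        bad = df[df.end_s <= df.start_s]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"epoch {r.epoch_id!r}: end_s {r.end_s} <= start_s {r.start_s}"
            )
        unknown = set(df.condition) - set(CONDITIONS)
        if unknown:
            raise ValidationError(
                f"unknown condition labels {sorted(unknown)}; allowed {CONDITIONS}"
            )
        for label, sub in df.groupby("label", sort=False):
            sub = sub.sort_values("start_s")
            starts = sub.start_s.to_numpy()
            ends = sub.end_s.to_numpy()
            overlap = np.nonzero(starts[1:] < ends[:-1])[0]
            if overlap.size:
                i = overlap[0]
                raise ValidationError(
                    f"label stream {label!r}: epochs "
                    f"{sub.epoch_id.iloc[i]!r} and {sub.epoch_id.iloc[i + 1]!r} overlap"
                )

    def check_within(self, rec: Recording) -> None:
        t_end = rec.t0_s + rec.duration_s
        bad = self.df[(self.df.start_s < rec.t0_s) | (self.df.end_s > t_end)]
        if len(bad):
            raise ValidationError(
                f"epoch {bad.iloc[0].epoch_id!r} lies outside the recording "
                f"[{rec.t0_s}, {t_end}] s"
            )

    def select(self, condition: str | None = None, label: str | None = None) -> pd.DataFrame:
        df = self.df
        if condition is not None:
            df = df[df.condition == condition]
        if label is not None:
            df = df[df.label == label]
        return df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)


@dataclass
class PipelineConfig:
    """Analysis defaults shared across stages.

    Defaults follow the study conventions: theta/beta/gamma bands of
    3-12 / 15-35 / 36-95 Hz, 2-s Welch segments with 50% overlap, 250-ms
    co-participation windows, 18 phase bins for the modulation index,
    80/20 subject-wise decoding splits with 500 cross-validation iterations
    and a chance interval from 100 label shuffles.
    """

    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    psd_segment_s: float = 2.0
    psd_overlap: float = 0.5
    coparticipation_window_s: float = 0.25
    n_barcodes: int = 8
    pac_phase_band: BandDef = THETA
    pac_amp_band: BandDef = GAMMA
    pac_n_bins: int = 18
    decode_train_frac: float = 0.8
    decode_n_iter: int = 500
    null_n_shuffles: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.decode_train_frac < 1):
            raise ValidationError("decode_train_frac must lie in (0, 1)")
        if self.pac_n_bins < 4:
            raise ValidationError("pac_n_bins must be >= 4")
        if self.coparticipation_window_s <= 0:
            raise ValidationError("coparticipation_window_s must be positive")
        self.bands = tuple(self.bands)

    def band(self, name: str) -> BandDef:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"no band named {name!r}")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        d["pac_phase_band"] = dataclasses.asdict(self.pac_phase_band)
        d["pac_amp_band"] = dataclasses.asdict(self.pac_amp_band)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("bands",):
            if key in d:
                d[key] = tuple(BandDef(**b) for b in d[key])
        for key in ("pac_phase_band", "pac_amp_band"):
            if key in d and isinstance(d[key], dict):
                d[key] = BandDef(**d[key])
        return cls(**d)
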