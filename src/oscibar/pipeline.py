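"""End-to-end orchestration: simulate -> features -> barcodes -> decode -> report.

A single JSON config drives the run; all stage seeds derive from one master
seed via ``numpy.random.SeedSequence.spawn``.  Outputs land in a run
directory with a ``manifest.json`` listing every artifact with its SHA-256
checksum, so reruns of deterministic stages can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decode
from .barcode import barcode_score, fit_barcode_pipeline
from .core import PipelineConfig, ValidationError
from .coupling import bandpass_analytic, pac_mi, spike_phases_in_recording
from .io import write_events, write_recording
from .simulate import CohortSpec, simulate_cohort
from .spectral import band_coherence, band_power_db

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Per-stage blocks of the pipeline configuration."""

    seed: int = 0
    n_per_group: int = 4
    duration_s: float = 60.0
    epochs_per_condition: int = 10
    with_barcodes: bool = True
    n_barcodes: int = 8
    decode_features: tuple[str, ...] = ("OB_theta_db",)
    decode_n_iter: int = 100
    null_n_shuffles: int = 50

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        if "decode_features" in d:
            d["decode_features"] = tuple(d["decode_features"])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    seed: int
    started: str
    outputs: dict[str, str]  # relative path -> sha256
    stages: list[str]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute all stages into ``out_dir``; returns the manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_json(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    outputs: dict[str, str] = {}
    stages: list[str] = []
    cfg = PipelineConfig(
        decode_n_iter=config.decode_n_iter,
        null_n_shuffles=config.null_n_shuffles,
        rng_seed=stage_seed[3],
    )

    # --- simulate ---
    spec = CohortSpec(
        n_per_group=config.n_per_group,
        duration_s=config.duration_s,
        epochs_per_condition=config.epochs_per_condition,
        rng_seed=stage_seed[0],
    )
    subjects, truth = simulate_cohort(spec)
    for rec, events in subjects:
        write_recording(rec, out / f"{rec.subject_id}.h5")
        write_events(events, out / f"{rec.subject_id}_events.csv")
        outputs[f"{rec.subject_id}.h5"] = _sha256(out / f"{rec.subject_id}.h5")
        outputs[f"{rec.subject_id}_events.csv"] = _sha256(
            out / f"{rec.subject_id}_events.csv"
        )
    stages.append("simulate")

    # --- spectral / coupling features ---
    rows = []
    for rec, events in subjects:
        row = dict(subject_id=rec.subject_id, group=rec.group)
        for region in rec.regions:
            for band in cfg.bands:
                row[f"{region}_{band.name}_db"] = band_power_db(
                    rec.region_signal(region), rec.fs_hz, band, cfg
                ).power_db
        for ra, rb in [("OB", "aPC"), ("OB", "LEC")]:
            for band in cfg.bands:
                row[f"{ra}_{rb}_{band.name}_coh"] = band_coherence(
                    rec.region_signal(ra), rec.region_signal(rb), rec.fs_hz, band, cfg
                ).band_mean
        pb = bandpass_analytic(rec.region_signal("OB"), rec.fs_hz, cfg.pac_phase_band)
        ab = bandpass_analytic(rec.region_signal("OB"), rec.fs_hz, cfg.pac_amp_band)
        row["OB_pac_mi"] = pac_mi(pb, ab, cfg.pac_n_bins).mi
        locks_g = spike_phases_in_recording(rec, cfg.band("gamma"))
        locks_t = spike_phases_in_recording(rec, cfg.band("theta"))
        row["gamma_mrl"] = float(np.mean([r.mrl for r in locks_g])) if locks_g else np.nan
        row["theta_mrl"] = float(np.mean([r.mrl for r in locks_t])) if locks_t else np.nan
        row["mean_rate_hz"] = (
            float(np.mean([u.mean_rate_hz(rec.duration_s) for u in rec.units]))
            if rec.units else np.nan
        )
        di = behavior.discrimination_from_events(events)
        row["discrimination_index"] = di.di
        rows.append(row)
    features = pd.DataFrame(rows)
    features.to_csv(out / "subject_features.csv", index=False)
    outputs["subject_features.csv"] = _sha256(out / "subject_features.csv")
    stages.append("features")

    # --- barcodes ---
    if config.with_barcodes:
        score_rows = []
        for rec, events in subjects:
            model, strengths, _ = fit_barcode_pipeline(
                rec, cfg.bands, config.n_barcodes, cfg.coparticipation_window_s,
                seed=stage_seed[1],
            )
            for ser in strengths:
                try:
                    s = barcode_score(ser, events, "novel", "familiar")
                except ValidationError:
                    s = np.nan
                score_rows.append(
                    dict(subject_id=rec.subject_id, group=rec.group,
                         barcode=ser.barcode_id, score=s)
                )
        pd.DataFrame(score_rows).to_csv(out / "barcode_scores.csv", index=False)
        outputs["barcode_scores.csv"] = _sha256(out / "barcode_scores.csv")
        stages.append("barcode")

    # --- trials + decoding ---
    trials = pd.concat(
        [
            decode.build_trial_features(rec, events, list(config.decode_features), cfg)
            for rec, events in subjects
        ],
        ignore_index=True,
    )
    trials.to_csv(out / "trials.csv", index=False)
    outputs["trials.csv"] = _sha256(out / "trials.csv")
    res = decode.decode_with_null(trials, cfg)
    with open(out / "decode.json", "w") as fh:
        json.dump(
            dict(
                mean_accuracy=res.mean_accuracy,
                chance_interval=list(res.chance_interval),
                significant=res.significant,
                config=res.config,
            ),
            fh, indent=2,
        )
    outputs["decode.json"] = _sha256(out / "decode.json")
    stages.append("decode")

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=outputs,
        stages=stages,
    )
    manifest.save(out / "manifest.json")
    _ = truth
    return manifest


def report(out_dir: str | Path) -> str:
    """Summarize a completed run directory as a markdown document."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json in {out}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    missing = [s for s in ("simulate", "features", "decode") if s not in manifest["stages"]]
    if missing:
        raise ValidationError(f"incomplete run: missing stages {missing}")
    features = pd.read_csv(out / "subject_features.csv")
    lines = ["# Run report", ""]
    lines.append("## Band power (dB) and coupling, group means")
    lines.append("")
    db_cols = [c for c in features.columns if c.endswith("_db") or c.endswith("_coh")
               or c in ("OB_pac_mi", "gamma_mrl", "theta_mrl", "mean_rate_hz",
                        "discrimination_index")]
    summary = features.groupby("group")[db_cols].mean().round(4)
    lines.append(summary.to_markdown())
    lines.append("")
    scores_path = out / "barcode_scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path)
        lines.append("## Barcode discrimination scores (group mean of best barcode)")
        lines.append("")
        best = scores.groupby(["group", "subject_id"]).score.max().groupby("group").mean()
        lines.append(best.round(3).to_markdown())
        lines.append("")
    with open(out / "decode.json") as fh:
        dec = json.load(fh)
    sig = "significant" if dec["significant"] else "not significant"
    lines.append(
        f"## Decoding: mean accuracy {dec['mean_accuracy']:.3f}, chance interval "
        f"[{dec['chance_interval'][0]:.3f}, {dec['chance_interval'][1]:.3f}] ({sig})"
    )
    lines.append("")
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
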