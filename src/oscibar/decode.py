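"""Population decoding of familiar-vs-novel trials and outcome forecasting.

The decoder follows the animal-wise cross-validation protocol: on each of
``n_iter`` (default 500) iterations a random 80% of subjects form the
training set and the rest the test set, training trials are balanced by
random down-sampling to equal class counts, features are z-scored on
training statistics, a linear support vector machine (C = 1) is fit, and
accuracy is pooled over held-out trials.  Significance is assessed against
a chance interval of 0.5 +/- 2 SD of null mean accuracies obtained from
(default 100) within-subject label shuffles, each running the full
decoding procedure.

Forecasting uses early-window features aggregated per subject to predict a
later binary outcome (cognitively impaired = later discrimination index
below 0) with a seeded random forest, subject-level 80/20 split, held-out
ROC-AUC and confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.svm import LinearSVC

try:  # fast path: liblinear binding without per-fit estimator overhead
    from sklearn.svm._base import _fit_liblinear as _liblinear
except ImportError:  # pragma: no cover
    _liblinear = None

from .core import EventTable, PipelineConfig, Recording, ValidationError
from .io import slice_epoch
from .spectral import band_coherence


def _linear_svm_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """L2-regularized linear SVM (squared hinge, C=1) -> (coef, intercept).

    Solved by liblinear; equivalent to ``LinearSVC(C=1, dual=False)`` (a
    unit test asserts the equivalence).  The decision score
    ``X @ coef + intercept > 0`` predicts the "novel" class (label 1).
    """
    if _liblinear is not None:
        coef, intercept, _ = _liblinear(
            X, y, C=1.0, fit_intercept=True, intercept_scaling=1.0,
            class_weight=None, penalty="l2", dual=False, verbose=0,
            max_iter=1000, tol=1e-4, random_state=0,
            multi_class="ovr", loss="squared_hinge",
        )
        return coef[0], float(intercept[0])
    clf = LinearSVC(C=1.0, dual=False)
    clf.fit(X, y)
    return clf.coef_[0], float(clf.intercept_[0])

__all__ = [
    "DecodingResult",
    "ForecastResult",
    "build_trial_features",
    "svm_decode",
    "chance_interval",
    "decode_with_null",
    "forecast_outcome",
    "validate_trials",
]

TRIAL_META = ["subject_id", "group", "trial_id", "condition"]


@dataclass
class DecodingResult:
    accuracies: np.ndarray
    mean_accuracy: float
    chance_interval: tuple[float, float] | None = None
    significant: bool | None = None
    null_means: np.ndarray | None = None
    config: dict = field(default_factory=dict)


@dataclass
class ForecastResult:
    auc: float
    confusion_train: np.ndarray
    confusion_test: np.ndarray
    feature_importances: np.ndarray
    feature_names: list[str]
    test_subjects: list[str]


def validate_trials(trials: pd.DataFrame) -> list[str]:
    """Check TrialTable invariants; returns the feature column names."""
    missing = [c for c in TRIAL_META if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns {missing}")
    features = [c for c in trials.columns if c not in TRIAL_META]
    if not features:
        raise ValidationError("trial table has no feature columns")
    if trials[features].isna().any().any():
        bad = trials[features].isna().any()
        raise ValidationError(f"missing feature values in {list(bad[bad].index)}")
    conds = set(trials.condition)
    if conds != {"familiar", "novel"}:
        raise ValidationError(f"conditions must be exactly familiar/novel, got {conds}")
    if trials.subject_id.nunique() < 2:
        raise ValidationError("need >= 2 subjects for subject-wise splitting")
    return features


def build_trial_features(
    rec: Recording,
    events: EventTable,
    feature_spec: list[str],
    cfg: PipelineConfig | None = None,
    barcode_strengths=None,
) -> pd.DataFrame:
    """One row of named features per behavioral epoch.

    Feature names: ``"<region>_<band>_db"`` (per-epoch Welch band power),
    ``"<regionA>_<regionB>_<band>_coh"`` (per-epoch band coherence), and
    ``"barcode_<k>"`` (per-epoch mean strength; requires
    ``barcode_strengths`` from a fitted model).
    """
    cfg = cfg or PipelineConfig()
    events.check_within(rec)
    rows = []
    for _, ev in events.df.iterrows():
        if ev.condition not in ("familiar", "novel"):
            continue
        ep = slice_epoch(rec, ev.start_s, ev.end_s)
        row = dict(
            subject_id=rec.subject_id, group=rec.group,
            trial_id=ev.epoch_id, condition=ev.condition,
        )
        for name in feature_spec:
            parts = name.split("_")
            if name.startswith("barcode_"):
                if barcode_strengths is None:
                    raise ValidationError(
                        f"feature {name!r} requires a fitted barcode model"
                    )
                k = int(parts[1])
                ser = barcode_strengths[k]
                mask = (ser.times_s >= ev.start_s) & (ser.times_s < ev.end_s)
                if not mask.any():
                    raise ValidationError(
                        f"epoch {ev.epoch_id!r}: no barcode windows inside epoch"
                    )
                row[name] = float(ser.strength[mask].mean())
            elif name.endswith("_db") and len(parts) == 3:
                region, band = parts[0], cfg.band(parts[1])
                seg = min(cfg.psd_segment_s, ep.duration_s / 2)
                from .spectral import welch_psd, band_power_from_psd
                res = welch_psd(ep.region_signal(region), ep.fs_hz, seg, cfg.psd_overlap)
                row[name] = band_power_from_psd(res, band).power_db
            elif name.endswith("_coh") and len(parts) == 4:
                ra, rb, band = parts[0], parts[1], cfg.band(parts[2])
                short_cfg = PipelineConfig(
                    bands=cfg.bands,
                    psd_segment_s=min(cfg.psd_segment_s, ep.duration_s / 4),
                    psd_overlap=cfg.psd_overlap,
                )
                row[name] = band_coherence(
                    ep.region_signal(ra), ep.region_signal(rb), ep.fs_hz, band,
                    short_cfg,
                ).band_mean
            else:
                raise ValidationError(f"unrecognized feature spec {name!r}")
        rows.append(row)
    if not rows:
        raise ValidationError("no familiar/novel epochs in the event table")
    return pd.DataFrame(rows)


def _decode_core(
    X: np.ndarray,
    y: np.ndarray,
    subj_codes: np.ndarray,
    n_subjects: int,
    train_frac: float,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inner loop shared by decoding and the shuffle null."""
    n_train = max(1, min(n_subjects - 1, int(round(train_frac * n_subjects))))
    # subject membership matrix for fast split masks
    member = subj_codes[None, :] == np.arange(n_subjects)[:, None]
    y = y.astype(np.float64)
    accs = np.empty(n_iter)
    with config_context(assume_finite=True):
        for it in range(n_iter):
            for _attempt in range(100):
                perm = rng.permutation(n_subjects)
                train_mask = member[perm[:n_train]].any(axis=0)
                ytr, yte = y[train_mask], y[~train_mask]
                if (
                    yte.size and ytr.size
                    and ytr.min() != ytr.max() and yte.min() != yte.max()
                ):
                    break
            else:
                raise ValidationError(
                    "could not draw a subject split with both classes in training"
                )
            # balance training classes by down-sampling
            idx_tr = np.nonzero(train_mask)[0]
            pos = idx_tr[y[idx_tr] == 1]
            neg = idx_tr[y[idx_tr] == 0]
            m = min(pos.size, neg.size)
            sel = np.concatenate([
                rng.permutation(pos)[:m], rng.permutation(neg)[:m]
            ])
            Xtr, ytr = X[sel], y[sel]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            coef, intercept = _linear_svm_fit((Xtr - mu) / sd, ytr)
            score = ((X[~train_mask] - mu) / sd) @ coef + intercept
            accs[it] = np.mean((score > 0) == (yte == 1))
    return accs


def _prepare(trials: pd.DataFrame):
    features = validate_trials(trials)
    X = trials[features].to_numpy(dtype=np.float64)
    y = (trials.condition == "novel").to_numpy().astype(np.int64)
    subjects, subj_codes = np.unique(trials.subject_id, return_inverse=True)
    return X, y, subj_codes, len(subjects), features


def svm_decode(trials: pd.DataFrame, cfg: PipelineConfig | None = None) -> DecodingResult:
    """Linear-SVM decoding with subject-wise 80/20 splits and balancing."""
    cfg = cfg or PipelineConfig()
    X, y, subj_codes, n_subjects, features = _prepare(trials)
    rng = np.random.default_rng(cfg.rng_seed)
    accs = _decode_core(
        X, y, subj_codes, n_subjects, cfg.decode_train_frac, cfg.decode_n_iter, rng
    )
    return DecodingResult(
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        config=dict(
            train_frac=cfg.decode_train_frac, n_iter=cfg.decode_n_iter,
            n_shuffles=cfg.null_n_shuffles, seed=cfg.rng_seed, features=features,
        ),
    )


def _shuffle_within_subject(
    y: np.ndarray, subj_codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute labels within each subject, preserving per-subject class counts."""
    y_null = y.copy()
    for s in np.unique(subj_codes):
        idx = np.nonzero(subj_codes == s)[0]
        y_null[idx] = y[rng.permutation(idx)]
    return y_null


def chance_interval(
    trials: pd.DataFrame, cfg: PipelineConfig | None = None
) -> tuple[tuple[float, float], np.ndarray]:
    """Shuffle-null chance interval 0.5 +/- 2 SD of null mean accuracies."""
    cfg = cfg or PipelineConfig()
    X, y, subj_codes, n_subjects, _ = _prepare(trials)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    null_means = np.empty(cfg.null_n_shuffles)
    for k in range(cfg.null_n_shuffles):
        y_null = _shuffle_within_subject(y, subj_codes, rng)
        accs = _decode_core(
            X, y_null, subj_codes, n_subjects, cfg.decode_train_frac,
            cfg.decode_n_iter, rng,
        )
        null_means[k] = accs.mean()
    sd = float(null_means.std(ddof=1))
    return (0.5 - 2 * sd, 0.5 + 2 * sd), null_means


def decode_with_null(
    trials: pd.DataFrame, cfg: PipelineConfig | None = None
) -> DecodingResult:
    """Decoding plus shuffle-null significance in one call."""
    cfg = cfg or PipelineConfig()
    res = svm_decode(trials, cfg)
    interval, null_means = chance_interval(trials, cfg)
    res.chance_interval = interval
    res.null_means = null_means
    res.significant = bool(
        res.mean_accuracy < interval[0] or res.mean_accuracy > interval[1]
    )
    return res


def forecast_outcome(
    early_features: pd.DataFrame,
    outcome: pd.Series | dict,
    cfg: PipelineConfig | None = None,
    n_trees: int = 500,
    test_frac: float = 0.2,
) -> ForecastResult:
    """Forecast a later binary outcome from per-subject early features.

    ``early_features``: one row per subject, indexed by ``subject_id``
    column plus numeric feature columns.  ``outcome``: binary (1 =
    impaired) per subject_id.  A seeded random forest is trained on a
    subject-level 80/20 split; AUC comes from held-out class scores and
    confusion matrices threshold the score at 0.5.
    """
    cfg = cfg or PipelineConfig()
    df = early_features.copy()
    if "subject_id" not in df.columns:
        raise ValidationError("early_features needs a subject_id column")
    if isinstance(outcome, dict):
        outcome = pd.Series(outcome)
    y = df.subject_id.map(outcome)
    if y.isna().any():
        raise ValidationError("outcome missing for some subjects")
    y = y.to_numpy().astype(int)
    feats = [c for c in df.columns if c not in ("subject_id", "group")]
    X = df[feats].to_numpy(dtype=np.float64)
    if min((y == 0).sum(), (y == 1).sum()) < 4:
        raise ValidationError("need >= 4 subjects per outcome class")
    rng = np.random.default_rng(cfg.rng_seed)
    n = len(df)
    n_test = max(2, int(round(test_frac * n)))
    for _attempt in range(200):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        if len(np.unique(y[train_idx])) == 2 and len(np.unique(y[test_idx])) == 2:
            break
    else:
        raise ValidationError("could not split subjects with both classes on each side")
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31))
    )
    clf.fit(X[train_idx], y[train_idx])
    score_te = clf.predict_proba(X[test_idx])[:, 1]
    score_tr = clf.predict_proba(X[train_idx])[:, 1]
    auc = float(roc_auc_score(y[test_idx], score_te))
    return ForecastResult(
        auc=auc,
        confusion_train=confusion_matrix(y[train_idx], score_tr >= 0.5),
        confusion_test=confusion_matrix(y[test_idx], score_te >= 0.5),
        feature_importances=clf.feature_importances_,
        feature_names=feats,
        test_subjects=df.subject_id.iloc[test_idx].tolist(),
    )
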