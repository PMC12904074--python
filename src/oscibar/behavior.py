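"""Behavioral indices: discrimination index, exploration times, habituation.

The discrimination index (DI) is
``(T_novel - T_familiar) / (T_novel + T_familiar)`` on exploration seconds,
bounded in [-1, 1]; positive values indicate novelty preference.  The same
formula serves object (NOR) and odor paradigms.  Exploration is defined
purely from the event table - bout detection is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventTable, ValidationError

__all__ = [
    "DiscriminationResult",
    "discrimination_index",
    "exploration_times",
    "discrimination_from_events",
    "habituation_curve",
]


@dataclass
class DiscriminationResult:
    t_novel_s: float
    t_familiar_s: float
    di: float


def discrimination_index(t_novel_s: float, t_familiar_s: float) -> DiscriminationResult:
    """DI = (novel - familiar) / (novel + familiar) exploration time."""
    if t_novel_s < 0 or t_familiar_s < 0:
        raise ValidationError(
            f"exploration times must be nonnegative, got ({t_novel_s}, {t_familiar_s})"
        )
    total = t_novel_s + t_familiar_s
    if total == 0:
        raise ValidationError("discrimination index undefined: no exploration at all")
    return DiscriminationResult(
        t_novel_s=float(t_novel_s),
        t_familiar_s=float(t_familiar_s),
        di=float((t_novel_s - t_familiar_s) / total),
    )


def exploration_times(
    events: EventTable, conditions: tuple[str, ...] = ("novel", "familiar")
) -> dict[str, float]:
    """Total exploration seconds per condition; absent conditions yield 0.0."""
    out = {}
    for cond in conditions:
        if cond not in ("familiar", "novel", "habituation", "other"):
            raise ValidationError(f"unknown condition label {cond!r}")
        sub = events.df[events.df.condition == cond]
        out[cond] = float((sub.end_s - sub.start_s).sum())
    return out


def discrimination_from_events(events: EventTable) -> DiscriminationResult:
    t = exploration_times(events)
    return discrimination_index(t["novel"], t["familiar"])


def habituation_curve(events: EventTable, label: str | None = None) -> pd.DataFrame:
    """Per-presentation exploration seconds in presentation order.

    Returns a DataFrame (presentation order, epoch_id, condition, seconds)
    plus a ``dishabituation_s`` attribute: exploration at the first novel
    presentation minus the last habituation presentation before it.
    """
    df = events.df if label is None else events.df[events.df.label == label]
    df = df.sort_values("start_s").reset_index(drop=True)
    if len(df) < 2:
        raise ValidationError("habituation curve needs >= 2 presentations")
    out = pd.DataFrame(
        dict(
            presentation=np.arange(len(df)),
            epoch_id=df.epoch_id,
            condition=df.condition,
            seconds=(df.end_s - df.start_s).to_numpy(),
        )
    )
    dishab = None
    novel_idx = np.nonzero((df.condition == "novel").to_numpy())[0]
    if novel_idx.size:
        first_novel = novel_idx[0]
        prior_hab = df.index[
            (df.condition == "habituation") & (df.index < first_novel)
        ]
        if len(prior_hab):
            dishab = float(
                out.seconds.iloc[first_novel] - out.seconds.iloc[prior_hab[-1]]
            )
    out.attrs["dishabituation_s"] = dishab
    return out
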