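"""Attention-based model explanation.

The attention pooling layer assigns one weight per 8-s feature step of a
night.  To interpret what the classifier attends to, each step's weight is
spread uniformly over the seconds it covers, summed within categories —
sleep stages from a hypnogram, or the second's dominant EEG band — and
renormalized over the categories present.  PD-vs-control contrasts of these
normalized category scores use one-tailed Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .qeeg_labels import BAND_NAMES, QEEGSeries

STAGES = ("Wake", "N1", "N2", "N3", "REM")


@dataclass
class Hypnogram:
    """Sleep-stage label per 30-s epoch."""

    stages: np.ndarray  # array of stage names
    epoch_s: float = 30.0

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.stages.size

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def stage_per_second(self, n_seconds: int | None = None) -> np.ndarray:
        per_sec = np.repeat(self.stages, int(self.epoch_s))
        if n_seconds is None:
            return per_sec
        if n_seconds <= per_sec.size:
            return per_sec[:n_seconds]
        return np.concatenate([per_sec, np.repeat(per_sec[-1:], n_seconds - per_sec.size)])


@dataclass
class AttentionSummary:
    """Normalized per-category attention for one night."""

    scores: dict[str, float]
    mode: str  # "stage" | "band"

    def __post_init__(self):
        total = sum(self.scores.values())
        if total > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError("category scores must be normalized to 1")


def save_hypnogram_tsv(h: Hypnogram, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"epoch_index": np.arange(h.n_epochs), "stage": h.stages})
    df.to_csv(path, sep="\t", index=False)
    return path


def load_hypnogram_tsv(path, epoch_s: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    return Hypnogram(stages=df["stage"].to_numpy(), epoch_s=epoch_s)


def _second_categories(labels, mode: str, n_seconds: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if mode == "stage":
        if not isinstance(labels, Hypnogram):
            raise TypeError("stage mode requires a Hypnogram")
        return labels.stage_per_second(n_seconds), STAGES
    if mode == "band":
        if not isinstance(labels, QEEGSeries):
            raise TypeError("band mode requires a QEEGSeries")
        # dominant band per second; argmax takes the first maximum, i.e. ties
        # break toward the lower-frequency band
        idx = np.argmax(labels.rel_power, axis=1)
        names = np.asarray(BAND_NAMES, dtype=object)[idx]
        if n_seconds <= names.size:
            return names[:n_seconds], BAND_NAMES
        return (np.concatenate([names, np.repeat(names[-1:], n_seconds - names.size)]),
                BAND_NAMES)
    raise ValueError(f"unknown mode {mode!r}")


def attention_by_category(attention: np.ndarray, step_s: float, labels,
                          mode: str) -> AttentionSummary:
    """Aggregate an attention profile over sleep stages or dominant EEG bands.

    ``attention`` holds one nonnegative weight per feature step of ``step_s``
    seconds (weights sum to 1).  Each step's weight is spread uniformly over
    its covered seconds; seconds are labelled by the hypnogram stage or the
    argmax relative-power band, summed per category, and renormalized over
    the categories present in the night.
    """
    attention = np.asarray(attention, dtype=np.float64)
    if attention.ndim != 1 or attention.size == 0:
        raise ValueError("attention profile must be a nonempty 1D array")
    step = int(round(step_s))
    per_sec = np.repeat(attention / step, step)
    label_sec = (labels.duration_s if isinstance(labels, Hypnogram)
                 else labels.n_seconds)
    n = min(per_sec.size, int(label_sec))
    if n == 0:
        raise ValueError("no overlap between attention support and labels")
    cats, cat_set = _second_categories(labels, mode, n)
    w = per_sec[:n]
    raw = {c: float(w[cats == c].sum()) for c in cat_set}
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("attention has no mass over the labelled period")
    return AttentionSummary(scores={c: v / total for c, v in raw.items()}, mode=mode)


def save_summary_tsv(summary: AttentionSummary, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"category": list(summary.scores),
                       "score": list(summary.scores.values())})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def cohort_attention_contrast(summaries_pd: list[AttentionSummary],
                              summaries_control: list[AttentionSummary],
                              alternative: str = "greater"
                              ) -> dict[str, dict[str, float]]:
    """Per-category PD-vs-control comparison of normalized attention.

    Returns, for each category, the effect direction (sign of the PD minus
    control mean difference) and the one-tailed Wilcoxon rank-sum p-value for
    ``alternative`` ("greater": PD group exceeds the control group).
    Requires at least three nights per group.
    """
    if len(summaries_pd) < 3 or len(summaries_control) < 3:
        raise ValueError("at least 3 nights per group are required")
    modes = {s.mode for s in summaries_pd + summaries_control}
    if len(modes) != 1:
        raise ValueError("summaries mix aggregation modes")
    cats = list(summaries_pd[0].scores)
    out: dict[str, dict[str, float]] = {}
    for c in cats:
        a = np.array([s.scores[c] for s in summaries_pd])
        b = np.array([s.scores[c] for s in summaries_control])
        if np.ptp(np.concatenate([a, b])) == 0:
            # category carries no attention variation in either group
            out[c] = {"direction": 0.0, "p": 1.0}
            continue
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        out[c] = {"direction": float(np.sign(a.mean() - b.mean())),
                  "p": float(res.pvalue)}
    return out
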