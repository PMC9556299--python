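"""Per-second qEEG relative band power, the auxiliary supervision target.

A night of EEG (C4-M1 by convention) is reduced to one 4-vector per second:
the relative spectral power in the delta (0.5-4 Hz), theta (4-8 Hz), alpha
(8-13 Hz) and beta (13-30 Hz) bands, normalized so the four bands sum to one.
Each second's spectrum comes from a Hann-windowed 4-s periodogram centered on
that second (Welch-style short-time estimate); band edges are half-open
[lo, hi) so power at exactly 4/8/13 Hz belongs to the upper band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}
BAND_NAMES = tuple(BAND_EDGES)


@dataclass
class EEGSignal:
    samples: np.ndarray
    fs: float
    channel: str = "C4-M1"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("EEG signal must be one-dimensional")
        if self.fs < 60.0:
            raise ValueError(
                f"fs={self.fs} Hz cannot resolve the 13-30 Hz beta band")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class QEEGSeries:
    """Per-second relative band power; rows lie on the 4-band simplex."""

    rel_power: np.ndarray  # (n_seconds, 4) in BAND_NAMES order
    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES))
    mask: np.ndarray | None = None  # False where padded (excluded from loss)

    def __post_init__(self):
        self.rel_power = np.asarray(self.rel_power, dtype=np.float64)
        if self.rel_power.ndim != 2 or self.rel_power.shape[1] != 4:
            raise ValueError("rel_power must be (n_seconds, 4)")
        if self.mask is None:
            self.mask = np.ones(self.rel_power.shape[0], dtype=bool)
        if np.any(self.rel_power < -1e-9):
            raise ValueError("relative powers must be nonnegative")
        sums = self.rel_power.sum(axis=1)
        if self.rel_power.shape[0] and np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("each per-second 4-vector must sum to 1")

    @property
    def n_seconds(self) -> int:
        return self.rel_power.shape[0]


def band_powers_from_psd(freqs: np.ndarray, psd: np.ndarray,
                         edges: dict[str, tuple[float, float]] = BAND_EDGES
                         ) -> np.ndarray:
    """Integrate a PSD (or batch of PSDs, bands on last axis' freqs) over
    half-open band intervals [lo, hi).  Returns unnormalized band powers."""
    out = []
    for lo, hi in edges.values():
        sel = (freqs >= lo) & (freqs < hi)
        out.append(psd[..., sel].sum(axis=-1))
    return np.stack(out, axis=-1)


def compute_band_powers(eeg: EEGSignal, window_s: float = 4.0,
                        overlap_frac: float = 0.5) -> QEEGSeries:
    """One relative-power 4-vector per second of EEG.

    For each integer second ``t`` a ``window_s``-long Hann-windowed slice
    centered on ``t + 0.5`` is transformed (periodogram); near the edges the
    window is shifted inward so it stays inside the night.  ``overlap_frac``
    is part of the label-generation contract (windows of adjacent seconds
    overlap by ``1 - 1/window_s``); it is validated but the per-second
    placement above already realizes the overlap.
    """
    if window_s < 2.0:
        raise ValueError("window must be >= 2 s to resolve 0.5 Hz")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must be in [0, 1)")
    n_sec = int(np.floor(eeg.duration_s))
    win = int(round(window_s * eeg.fs))
    if eeg.samples.size < win or n_sec < 1:
        raise ValueError("night shorter than one analysis window")
    x = eeg.samples
    taper = np.hanning(win)
    # slice start per second: window centered on the second, clamped inside
    centers = (np.arange(n_sec) + 0.5) * eeg.fs
    starts = np.clip(np.round(centers - win / 2.0).astype(int), 0, x.size - win)
    idx = starts[:, None] + np.arange(win)[None, :]
    segs = x[idx] * taper[None, :]
    spec = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / eeg.fs)
    bp = band_powers_from_psd(freqs, spec)
    tot = bp.sum(axis=1, keepdims=True)
    tot[tot <= 0] = 1.0
    return QEEGSeries(rel_power=bp / tot)


def align_qeeg_to_features(q: QEEGSeries, n_out: int,
                           max_mismatch_s: int = 8) -> QEEGSeries:
    """Pad/truncate a qEEG series to the decoder's output length.

    The decoder upsamples encoder features back to 1 Hz, whose length can
    differ from the label length by up to one feature step (8 s).  Padding
    replicates the last second and is masked out of the loss; larger
    mismatches are an error.
    """
    n_q = q.n_seconds
    if abs(n_q - n_out) > max_mismatch_s:
        raise ValueError(f"qEEG/feature length mismatch beyond {max_mismatch_s} s: "
                         f"{n_q} vs {n_out}")
    if n_q == n_out:
        return q
    if n_q > n_out:
        return QEEGSeries(rel_power=q.rel_power[:n_out].copy(),
                          band_edges=dict(q.band_edges),
                          mask=q.mask[:n_out].copy())
    pad = n_out - n_q
    rp = np.vstack([q.rel_power, np.repeat(q.rel_power[-1:], pad, axis=0)])
    mask = np.concatenate([q.mask, np.zeros(pad, dtype=bool)])
    return QEEGSeries(rel_power=rp, band_edges=dict(q.band_edges), mask=mask)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_qeeg_tsv(q: QEEGSeries, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(q.rel_power, columns=list(BAND_NAMES))
    df.insert(0, "second", np.arange(q.n_seconds))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def load_qeeg_tsv(path) -> QEEGSeries:
    df = pd.read_csv(path, sep="\t")
    rp = df[list(BAND_NAMES)].to_numpy(dtype=np.float64)
    rp = rp / rp.sum(axis=1, keepdims=True)  # re-simplex after rounding
    return QEEGSeries(rel_power=rp)
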