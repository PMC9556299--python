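"""Reading, screening and normalization of nocturnal breathing signals.

Defines the on-disk data model shared by the whole package:

* nights of respiratory effort as EDF channels or columnar text files with a
  JSON sidecar ``{subject_id, date, domain, f_b}``;
* a UTF-8 TSV cohort manifest (one row per subject, ISO-8601 dates, missing
  values as empty strings);
* quality screening (minimum duration, flat-line/clip/spectral distortion
  rules) and the clip-then-standardize normalization applied to every night
  before it reaches the model.

Signals are stored at a common sampling rate ``f_b`` (10 Hz); sources at other
rates are resampled on load with a polyphase filter.
"""

from __future__ import annotations

import json
import math

from dataclasses import dataclass, field, replace
from datetime import date, datetime
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

F_B_DEFAULT = 10.0  # Hz, common breathing-signal rate
CLIP_RANGE_DEFAULT = (-6.0, 6.0)
MIN_HOURS_DEFAULT = 2.0

DOMAINS = ("belt", "wireless")
PD_STATUSES = ("PD", "control", "unknown")


class UnusableNightError(ValueError):
    """Raised when a night cannot be normalized (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BreathingNight:
    """One night of 1D respiratory effort signal with subject metadata."""

    subject_id: str
    night_date: date
    domain: str
    signal: np.ndarray
    f_b: float = F_B_DEFAULT
    preprocessed: bool = False

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("breathing signal must be one-dimensional")
        if self.f_b <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown acquisition domain {self.domain!r}")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.f_b

    @property
    def n_samples(self) -> int:
        return self.signal.size


@dataclass
class KeepDecision:
    keep: bool
    reason: str  # ok | too_short | distorted | absent

    def __post_init__(self):
        if self.keep != (self.reason == "ok"):
            raise ValueError("keep flag inconsistent with reason")


@dataclass
class SubjectRecord:
    """Per-subject diagnosis, severity labels, visit dates and nights."""

    subject_id: str
    domain: str
    pd_status: str = "unknown"
    mds_updrs_total: float | None = None
    mds_updrs_parts: tuple[float, float, float, float] | None = None
    hy_stage: float | None = None
    baseline_date: date | None = None
    m6_date: date | None = None
    m12_date: date | None = None
    updrs_m6: float | None = None
    updrs_m12: float | None = None
    institution: str | None = None
    nights: list[BreathingNight] = field(default_factory=list)

    def __post_init__(self):
        if self.pd_status not in PD_STATUSES:
            raise ValueError(f"unknown pd_status {self.pd_status!r}")

    def validate(self) -> None:
        for n in self.nights:
            if n.subject_id != self.subject_id:
                raise ValueError(
                    f"night subject {n.subject_id!r} != record {self.subject_id!r}")


@dataclass
class DistortionConfig:
    """Operational definition of a distorted/nonexistent night.

    A raw night is rejected when any of the following holds:

    * more than ``clip_frac_max`` of samples sit at/beyond the clip bound;
    * more than ``flat_frac_max`` of 30-s windows have sd below
      ``flat_sd_ratio`` x the median window sd (flat-line);
    * no spectral peak in the respiratory band exceeds ``peak_ratio_min`` x
      the mean power in the high-frequency floor band.
    """

    clip_bound: float = 6.0
    clip_frac_max: float = 0.20
    flat_window_s: float = 30.0
    flat_sd_ratio: float = 0.05
    flat_frac_max: float = 0.25
    breath_band: tuple[float, float] = (0.1, 0.5)
    floor_band: tuple[float, float] = (1.0, 5.0)
    peak_ratio_min: float = 3.0


# ---------------------------------------------------------------------------
# night file I/O
# ---------------------------------------------------------------------------

def _parse_date(s: str) -> date:
    return datetime.strptime(s, "%Y-%m-%d").date()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_night_columnar(night: BreathingNight, path) -> Path:
    """Write a night as one float per line plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, night.signal, fmt="%.17g")  # exact float64 round-trip
    meta = {
        "subject_id": night.subject_id,
        "date": night.night_date.isoformat(),
        "domain": night.domain,
        "f_b": night.f_b,
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def _resample(x: np.ndarray, fs_src: float, fs_dst: float) -> np.ndarray:
    if math.isclose(fs_src, fs_dst, rel_tol=1e-9):
        return x
    frac = Fraction(fs_dst / fs_src).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def load_night(path, format: str = "columnar", channel: str = "THOR RES",
               f_b: float = F_B_DEFAULT) -> BreathingNight:
    """Load one night, resampling to ``f_b`` if the source rate differs.

    ``columnar``: text file of floats with a JSON sidecar.  ``edf``: a PSG
    recording; ``channel`` names the respiratory effort trace.  Metadata for
    EDF files is taken from a JSON sidecar when present, otherwise from the
    file name/header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "columnar":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        x = np.loadtxt(path, dtype=np.float64, ndmin=1)
        if x.size == 0:
            raise UnusableNightError(f"empty night file {path}")
        src_fb = float(meta.get("f_b", f_b))
        x = _resample(x, src_fb, f_b)
        return BreathingNight(
            subject_id=str(meta["subject_id"]),
            night_date=_parse_date(meta["date"]),
            domain=meta.get("domain", "belt"),
            signal=x, f_b=f_b)
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, include=[channel], preload=True,
                                  verbose="error")
        if channel not in raw.ch_names:
            raise KeyError(f"channel {channel!r} not in {path}")
        x = raw.get_data(picks=[channel])[0]
        if x.size == 0:
            raise UnusableNightError(f"empty channel {channel!r} in {path}")
        fs_src = float(raw.info["sfreq"])
        x = _resample(np.asarray(x, dtype=np.float64), fs_src, f_b)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            sid = str(meta["subject_id"])
            nd = _parse_date(meta["date"])
            domain = meta.get("domain", "belt")
        else:
            sid = path.stem
            nd = raw.info["meas_date"].date() if raw.info["meas_date"] else date(2000, 1, 1)
            domain = "belt"
        return BreathingNight(subject_id=sid, night_date=nd, domain=domain,
                              signal=x, f_b=f_b)
    raise ValueError(f"unknown format {format!r}")


def write_edf(path, channels: dict[str, np.ndarray], fs: float,
              start: datetime | None = None, physical_dim: str = "") -> Path:
    """Write a minimal single-rate EDF file (integer Hz, 1-s data records).

    Small, self-contained writer used for interchange and for generating EDF
    test inputs; readers (e.g. mne) see a standard EDF with 16-bit samples
    scaled to each channel's physical range.
    """
    path = Path(path)
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    names = list(channels)
    n_rec = min(len(np.asarray(v).ravel()) // spr for v in channels.values())
    if n_rec < 1:
        raise ValueError("signals shorter than one data record")
    start = start or datetime(2000, 1, 1, 22, 0, 0)
    ns = len(names)

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad(start.strftime("%d.%m.%y"), 8), pad(start.strftime("%H.%M.%S"), 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44), pad(str(n_rec), 8),
        pad("1", 8), pad(str(ns), 4),
    ])
    phys_lo, phys_hi, scaled = [], [], []
    for name in names:
        x = np.asarray(channels[name], dtype=np.float64).ravel()[: n_rec * spr]
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        dig = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))
        phys_lo.append(lo)
        phys_hi.append(hi)
    fields = [
        [pad(n, 16) for n in names],
        [pad("", 80)] * ns,
        [pad(physical_dim, 8)] * ns,
        [pad(f"{lo:.6g}"[:8], 8) for lo in phys_lo],
        [pad(f"{hi:.6g}"[:8], 8) for hi in phys_hi],
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(spr), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(col) for col in fields)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for sig in scaled:
                fh.write(sig[r * spr:(r + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# screening and normalization
# ---------------------------------------------------------------------------

def screen_night(night: BreathingNight, min_hours: float = MIN_HOURS_DEFAULT,
                 distortion_cfg: DistortionConfig | None = None) -> KeepDecision:
    """Decide whether a raw night enters the dataset.

    Nights shorter than ``min_hours`` are dropped; all-constant signals are
    `absent`; otherwise the distortion rules of :class:`DistortionConfig`
    apply.  Always returns a decision, never raises.
    """
    cfg = distortion_cfg or DistortionConfig()
    x = night.signal
    if night.duration_s < min_hours * 3600.0:
        return KeepDecision(False, "too_short")
    if x.size == 0 or float(np.ptp(x)) == 0.0:
        return KeepDecision(False, "absent")
    # clip saturation
    if np.mean(np.abs(x) >= cfg.clip_bound) > cfg.clip_frac_max:
        return KeepDecision(False, "distorted")
    # flat-line windows
    w = int(round(cfg.flat_window_s * night.f_b))
    if w >= 2 and x.size >= 2 * w:
        n_win = x.size // w
        sds = x[: n_win * w].reshape(n_win, w).std(axis=1)
        med = np.median(sds)
        if med > 0 and np.mean(sds < cfg.flat_sd_ratio * med) > cfg.flat_frac_max:
            return KeepDecision(False, "distorted")
        if med == 0:
            return KeepDecision(False, "absent")
    # respiratory spectral peak must stand clear of the broadband floor
    nper = int(min(x.size, 4096))
    freqs, psd = sps.welch(x - x.mean(), fs=night.f_b, nperseg=nper)
    band = (freqs >= cfg.breath_band[0]) & (freqs <= cfg.breath_band[1])
    floor = (freqs >= cfg.floor_band[0]) & (freqs <= cfg.floor_band[1])
    if band.any() and floor.any():
        floor_level = float(psd[floor].mean())
        if floor_level > 0 and float(psd[band].max()) < cfg.peak_ratio_min * floor_level:
            return KeepDecision(False, "distorted")
    return KeepDecision(True, "ok")


def preprocess_night(night: BreathingNight,
                     clip_range: tuple[float, float] = CLIP_RANGE_DEFAULT
                     ) -> BreathingNight:
    """Clip to ``clip_range`` then standardize to zero mean, unit sd.

    Mean and sd (population convention, divide by n) are computed on the
    clipped signal.  Raises :class:`UnusableNightError` when the clipped
    signal has zero variance.
    """
    x = np.clip(night.signal, clip_range[0], clip_range[1])
    mu = x.mean()
    sd = x.std()  # population sd
    if sd < 1e-12:
        raise UnusableNightError(
            f"night {night.subject_id}/{night.night_date}: zero variance after clipping")
    return replace(night, signal=(x - mu) / sd, preprocessed=True)


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "subject_id", "domain", "pd_status", "mds_updrs_total",
    "updrs_1", "updrs_2", "updrs_3", "updrs_4", "hy_stage",
    "baseline_date", "m6_date", "m12_date", "updrs_m6", "updrs_m12",
    "institution",
]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, date):
        return v.isoformat()
    if isinstance(v, float) and float(v).is_integer():
        return str(int(v))
    return str(v)


def write_manifest(subjects: list[SubjectRecord], path) -> Path:
    path = Path(path)
    rows = []
    for s in subjects:
        parts = s.mds_updrs_parts or (None, None, None, None)
        rows.append([
            s.subject_id, s.domain, s.pd_status, _fmt(s.mds_updrs_total),
            _fmt(parts[0]), _fmt(parts[1]), _fmt(parts[2]), _fmt(parts[3]),
            _fmt(s.hy_stage), _fmt(s.baseline_date), _fmt(s.m6_date),
            _fmt(s.m12_date), _fmt(s.updrs_m6), _fmt(s.updrs_m12),
            _fmt(s.institution),
        ])
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    subjects = []
    for _, r in df.iterrows():
        def num(col):
            v = r.get(col, "")
            return float(v) if v not in ("", None) else None

        def day(col):
            v = r.get(col, "")
            return _parse_date(v) if v not in ("", None) else None

        parts = tuple(num(f"updrs_{i}") for i in range(1, 5))
        subjects.append(SubjectRecord(
            subject_id=str(r["subject_id"]), domain=str(r["domain"]),
            pd_status=str(r.get("pd_status", "unknown") or "unknown"),
            mds_updrs_total=num("mds_updrs_total"),
            mds_updrs_parts=None if all(p is None for p in parts) else parts,
            hy_stage=num("hy_stage"), baseline_date=day("baseline_date"),
            m6_date=day("m6_date"), m12_date=day("m12_date"),
            updrs_m6=num("updrs_m6"), updrs_m12=num("updrs_m12"),
            institution=(str(r["institution"]) or None) if "institution" in r else None,
        ))
    return subjects


def load_cohort(directory, nights_subdir: str = "nights") -> list[SubjectRecord]:
    """Load a manifest plus all columnar night files under ``directory``."""
    directory = Path(directory)
    subjects = read_manifest(directory / "manifest.tsv")
    by_id = {s.subject_id: s for s in subjects}
    nights_dir = directory / nights_subdir
    if nights_dir.exists():
        for sidecar in sorted(nights_dir.glob("*.json")):
            data_file = sidecar.with_suffix(".txt")
            if not data_file.exists():
                continue
            night = load_night(data_file, format="columnar")
            if night.subject_id in by_id:
                by_id[night.subject_id].nights.append(night)
    for s in subjects:
        s.validate()
    return subjects


# ---------------------------------------------------------------------------
# label imputation
# ---------------------------------------------------------------------------

def impute_control_labels(cohort: list[SubjectRecord]) -> list[SubjectRecord]:
    """Fill missing control severity labels with the observed-control mean.

    Controls missing MDS-UPDRS (total and subparts) or H&Y receive the mean
    of the observed control values; PD subjects are never imputed.  Raises if
    no control has an observed MDS-UPDRS total.
    """
    controls = [s for s in cohort if s.pd_status == "control"]
    observed = [s.mds_updrs_total for s in controls if s.mds_updrs_total is not None]
    if not observed:
        raise ValueError("no control subject has an observed MDS-UPDRS total")
    mean_total = float(np.mean(observed))
    hy_obs = [s.hy_stage for s in controls if s.hy_stage is not None]
    mean_hy = float(np.mean(hy_obs)) if hy_obs else None
    parts_obs = [s.mds_updrs_parts for s in controls if s.mds_updrs_parts is not None
                 and all(p is not None for p in s.mds_updrs_parts)]
    mean_parts = tuple(np.mean(parts_obs, axis=0)) if parts_obs else None
    for s in controls:
        if s.mds_updrs_total is None:
            s.mds_updrs_total = mean_total
        if s.hy_stage is None and mean_hy is not None:
            s.hy_stage = mean_hy
        if s.mds_updrs_parts is None and mean_parts is not None:
            s.mds_updrs_parts = mean_parts
    return cohort
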