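"""Synthetic polysomnography cohorts with the structure the method assumes.

The simulator produces, per subject, many nights of breathing at 10 Hz from
two acquisition domains (chest belt, wireless), a Markov-chain hypnogram, and
per-second qEEG relative band powers — together with the generating ground
truth, so every downstream stage is testable without clinical data.

Generative model of one night
-----------------------------
* Breathing is an amplitude-modulated quasi-sinusoid whose instantaneous
  rate follows an Ornstein-Uhlenbeck process around a per-subject base rate
  (default 0.25 Hz).  Disease raises rate variability, amplitude
  irregularity, and the rate of brief arousal events (rate/amplitude bursts)
  in proportion to severity; arousal events are placed inside Wake/N1 epochs
  so sleep fragmentation and the breathing signature co-occur.
* The hypnogram is a 5-stage Markov chain over 30-s epochs; disease shifts
  transition mass toward Wake/N1 (fragmentation).
* qEEG is drawn per second from a Dirichlet around a stage-specific band
  template; disease lowers delta and raises beta, scaled by severity.
* Domains differ: wireless adds coloured noise and an amplitude scale,
  and its cohorts are near-balanced, while belt cohorts are low-prevalence.
* Longitudinal cohorts drift severity linearly (points/year) with nights at
  baseline, month-6 and month-12 windows.

Severity is on the MDS-UPDRS total scale (PD uniform 20-80, controls 0-10 by
default).  All effect magnitudes are configuration; the defaults give a
strong, desk-scale-learnable class signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .breathing_io import BreathingNight, SubjectRecord, save_night_columnar, write_manifest
from .interpretation import Hypnogram, STAGES, save_hypnogram_tsv
from .qeeg_labels import QEEGSeries, save_qeeg_tsv

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# per-stage mean relative power (delta, theta, alpha, beta)
STAGE_BAND_TEMPLATE: dict[str, tuple[float, float, float, float]] = {
    "Wake": (0.15, 0.20, 0.40, 0.25),
    "N1":   (0.30, 0.35, 0.20, 0.15),
    "N2":   (0.45, 0.30, 0.15, 0.10),
    "N3":   (0.70, 0.15, 0.10, 0.05),
    "REM":  (0.30, 0.30, 0.20, 0.20),
}

# 30-s epoch transition matrix, rows/cols in STAGES order (control subjects)
STAGE_TRANSITIONS = np.array([
    #  W     N1    N2    N3    REM
    [0.50, 0.30, 0.20, 0.00, 0.00],   # Wake
    [0.10, 0.30, 0.55, 0.00, 0.05],   # N1
    [0.03, 0.07, 0.70, 0.15, 0.05],   # N2
    [0.01, 0.02, 0.25, 0.70, 0.02],   # N3
    [0.05, 0.10, 0.25, 0.00, 0.60],   # REM
])


@dataclass
class SimConfig:
    """Cohort-level generating parameters (defaults = study conditions)."""

    # cohort composition: domain -> (n_pd, n_control)
    n_subjects: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"wireless": (20, 20)})
    nights_per_subject: int = 3
    night_s: float = 1800.0       # 30-min default keeps desk-scale budgets
    f_b: float = 10.0

    # breathing dynamics
    base_rate: float = 0.25       # Hz; per-subject jitter below
    base_rate_jitter: float = 0.02
    ou_sigma: float = 0.015       # stationary sd of instantaneous rate (Hz)
    ou_tau: float = 60.0          # s
    amp_irreg_sd: float = 0.10    # amplitude-modulation depth
    amp_tau: float = 20.0         # s
    raw_scale: float = 1.5        # raw signal units (clip range [-6, 6] inert)

    # arousal events
    control_arousal_per_h: float = 2.0
    arousal_duration_s: float = 8.0
    arousal_rate_mult: float = 1.6
    arousal_amp_mult: float = 1.8

    # PD effect sizes, each scaled by severity/80
    rate_var_effect: float = 2.0      # rate-variability multiplier - 1 at s=80
    arousal_effect_per_h: float = 38.0
    amp_irreg_effect: float = 1.0     # amplitude-irregularity gain - 1 at s=80
    fragmentation_effect: float = 0.25  # extra Wake/N1 transition mass at s=80
    delta_suppression: float = 0.35     # qEEG delta reduction at s=80
    beta_elevation: float = 0.60        # qEEG beta gain at s=80

    # severity distributions (MDS-UPDRS total)
    pd_severity_range: tuple[float, float] = (20.0, 80.0)
    control_severity_range: tuple[float, float] = (0.0, 10.0)
    clinician_noise_sd: float = 2.0

    # domain effects
    wireless_noise_sd: float = 0.20   # coloured (AR(1), alpha 0.9)
    wireless_amp_scale: float = 0.80
    # RF-derived breathing is smoother than a chest belt trace: wireless
    # nights are low-passed, attenuating the waveform's harmonic content
    wireless_lowpass_hz: float = 0.6  # 0 disables
    # environmental interference (fans, pets) leaks a slow periodic artifact
    # into wireless recordings; frequency jitters per night within the band
    wireless_artifact_amp: float = 0.3
    wireless_artifact_band: tuple[float, float] = (0.6, 0.8)  # Hz
    # RF extraction compresses rapid large motions: wireless arousal bursts
    # keep only this fraction of their excess amplitude above baseline
    wireless_burst_atten: float = 0.5
    belt_noise_sd: float = 0.05       # white

    # qEEG noise
    qeeg_concentration: float = 60.0  # Dirichlet concentration around template

    # longitudinal structure
    with_followup: bool = False
    drift_per_year: float = 6.0       # MDS-UPDRS points/year in PD
    baseline: date = date(2023, 3, 1)

    # which domains carry EEG-derived labels (synthetic cohorts may attach
    # qEEG to both; real wireless acquisitions have none)
    qeeg_domains: tuple[str, ...] = ("belt", "wireless")

    def validate(self) -> None:
        for d, (a, b) in self.n_subjects.items():
            if d not in ("belt", "wireless") or a < 0 or b < 0:
                raise ValueError(f"invalid cohort spec {d}: {(a, b)}")
        if self.night_s <= 60 or self.f_b <= 0 or self.nights_per_subject < 1:
            raise ValueError("invalid night geometry")
        if not 0 <= self.fragmentation_effect < 1:
            raise ValueError("fragmentation_effect must be in [0, 1)")


def null_config(**overrides) -> SimConfig:
    """All disease effect sizes zero: PD and control nights are exchangeable."""
    cfg = SimConfig(**overrides)
    return dataclasses.replace(
        cfg, rate_var_effect=0.0, arousal_effect_per_h=0.0, amp_irreg_effect=0.0,
        fragmentation_effect=0.0, delta_suppression=0.0, beta_elevation=0.0)


def strong_effect_config(n_per_class: int = 40, nights: int = 3,
                         night_s: float = 1800.0, **overrides) -> SimConfig:
    """Single-domain cohort with the default (strong) disease effects."""
    return SimConfig(n_subjects={"wireless": (n_per_class, n_per_class)},
                     nights_per_subject=nights, night_s=night_s, **overrides)


def two_domain_config(n_per_cell: int = 10, nights: int = 2,
                      night_s: float = 600.0, **overrides) -> SimConfig:
    """Balanced belt+wireless cohort for domain-adaptation experiments.

    The acquisition gap is pronounced (heavy coloured wireless noise floor
    on the low-passed RF waveform), so encoder features pick up the domain
    unless adversarial training suppresses it.  As in real acquisitions,
    only the belt (PSG) domain carries EEG-derived qEEG labels."""
    overrides.setdefault("wireless_noise_sd", 0.4)
    overrides.setdefault("qeeg_domains", ("belt",))
    return SimConfig(n_subjects={"belt": (n_per_cell, n_per_cell),
                                 "wireless": (n_per_cell, n_per_cell)},
                     nights_per_subject=nights, night_s=night_s, **overrides)


def belt_counts(n_subjects: int, prevalence: float = 0.02) -> tuple[int, int]:
    """(n_pd, n_control) for a belt cohort at the stated PD prevalence."""
    n_pd = int(round(n_subjects * prevalence))
    return n_pd, n_subjects - n_pd


# ---------------------------------------------------------------------------
# per-subject parameters
# ---------------------------------------------------------------------------

@dataclass
class SubjectParams:
    subject_id: str
    domain: str
    is_pd: bool
    severity: float           # generating MDS-UPDRS at baseline
    base_rate: float

    def severity_at(self, cfg: SimConfig, days: float) -> float:
        if not self.is_pd:
            return self.severity
        return self.severity + cfg.drift_per_year * days / 365.0


def _severity_scale(severity: float) -> float:
    return float(np.clip(severity, 0.0, None)) / 80.0


# ---------------------------------------------------------------------------
# night simulation
# ---------------------------------------------------------------------------

def _simulate_hypnogram(cfg: SimConfig, sev_scale: float,
                        rng: np.random.Generator) -> Hypnogram:
    n_epochs = int(np.ceil(cfg.night_s / 30.0))
    P = STAGE_TRANSITIONS.copy()
    frag = cfg.fragmentation_effect * sev_scale
    if frag > 0:
        # move transition mass toward Wake/N1, taken from deeper stages
        P = (1.0 - frag) * P
        P[:, 0] += 0.6 * frag
        P[:, 1] += 0.4 * frag
    P /= P.sum(axis=1, keepdims=True)
    states = np.empty(n_epochs, dtype=int)
    s = 0  # nights start awake
    for i in range(n_epochs):
        s = rng.choice(5, p=P[s])
        states[i] = s
    return Hypnogram(stages=np.asarray(STAGES, dtype=object)[states])


def _simulate_qeeg(cfg: SimConfig, hyp: Hypnogram, sev_scale: float,
                   rng: np.random.Generator) -> QEEGSeries:
    n_sec = int(cfg.night_s)
    stages = hyp.stage_per_second(n_sec)
    rel = np.empty((n_sec, 4))
    for stage in STAGES:
        sel = stages == stage
        if not sel.any():
            continue
        tpl = np.array(STAGE_BAND_TEMPLATE[stage])
        tpl = tpl * np.array([1.0 - cfg.delta_suppression * sev_scale, 1.0, 1.0,
                              1.0 + cfg.beta_elevation * sev_scale])
        tpl /= tpl.sum()
        rel[sel] = rng.dirichlet(cfg.qeeg_concentration * tpl, size=int(sel.sum()))
    return QEEGSeries(rel_power=rel)


def _ar1(n: int, alpha: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    from scipy.signal import lfilter

    innov_sd = sd * np.sqrt(1.0 - alpha * alpha)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -alpha], eps)


def simulate_night(cfg: SimConfig, params: SubjectParams, night_date: date,
                   seed: int, severity: float | None = None
                   ) -> tuple[BreathingNight, Hypnogram, QEEGSeries]:
    """Generate one night (breathing, hypnogram, qEEG) deterministically.

    ``severity`` overrides the subject's baseline severity (used for drifted
    follow-up nights).  The same (cfg, params, date, seed) reproduces
    bit-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    sev = params.severity if severity is None else severity
    # both classes pass severity through the same effect channels (controls
    # have low severity), so severity regression has signal across the cohort
    s = _severity_scale(sev)
    hyp = _simulate_hypnogram(cfg, s, rng)
    qeeg = _simulate_qeeg(cfg, hyp, s, rng)

    n = int(round(cfg.night_s * cfg.f_b))
    dt = 1.0 / cfg.f_b
    # instantaneous breathing rate: OU around the subject's base rate
    sigma = cfg.ou_sigma * (1.0 + cfg.rate_var_effect * s)
    alpha = float(np.exp(-dt / cfg.ou_tau))
    rate_dev = _ar1(n, alpha, sigma, rng)
    rate = np.clip(params.base_rate + rate_dev, 0.05, 1.2)

    # amplitude irregularity (slow AR(1) modulation)
    amp_sd = cfg.amp_irreg_sd * (1.0 + cfg.amp_irreg_effect * s)
    amp_alpha = float(np.exp(-dt / cfg.amp_tau))
    amp = np.clip(1.0 + _ar1(n, amp_alpha, amp_sd, rng), 0.2, None)

    # arousal events inside Wake/N1 epochs
    hours = cfg.night_s / 3600.0
    lam = (cfg.control_arousal_per_h + cfg.arousal_effect_per_h * s) * hours
    n_events = rng.poisson(lam)
    stages_sec = hyp.stage_per_second(int(cfg.night_s))
    light = np.flatnonzero((stages_sec == "Wake") | (stages_sec == "N1"))
    event_mask = np.zeros(n, dtype=bool)
    dur = int(round(cfg.arousal_duration_s * cfg.f_b))
    for _ in range(int(n_events)):
        start_sec = int(rng.choice(light)) if light.size else int(rng.integers(0, int(cfg.night_s)))
        i0 = int(start_sec * cfg.f_b)
        event_mask[i0:i0 + dur] = True
    amp_mult = cfg.arousal_amp_mult
    if params.domain == "wireless":
        amp_mult = 1.0 + (amp_mult - 1.0) * cfg.wireless_burst_atten
    rate = np.where(event_mask, rate * cfg.arousal_rate_mult, rate)
    amp = np.where(event_mask, amp * amp_mult, amp)

    phase = 2.0 * np.pi * np.cumsum(rate) * dt
    x = amp * (np.sin(phase) + 0.15 * np.sin(2.0 * phase))
    if params.domain == "wireless":
        if cfg.wireless_lowpass_hz > 0:
            from scipy.signal import butter, filtfilt
            b, a = butter(2, cfg.wireless_lowpass_hz, fs=cfg.f_b)
            x = filtfilt(b, a, x)
        if cfg.wireless_artifact_amp > 0:
            f_art = rng.uniform(*cfg.wireless_artifact_band)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            t = np.arange(n) * dt
            x = x + cfg.wireless_artifact_amp * np.sin(2 * np.pi * f_art * t + phi)
        x = cfg.wireless_amp_scale * x + _ar1(n, 0.9, cfg.wireless_noise_sd, rng)
    else:
        x = x + rng.normal(0.0, cfg.belt_noise_sd, size=n)
    night = BreathingNight(subject_id=params.subject_id, night_date=night_date,
                           domain=params.domain, signal=cfg.raw_scale * x,
                           f_b=cfg.f_b)
    return night, hyp, qeeg


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    params: dict[str, SubjectParams]
    hypnograms: dict[tuple[str, date], Hypnogram]
    qeeg: dict[tuple[str, date], QEEGSeries]
    ground_truth: pd.DataFrame  # subject_id, night_date, domain, is_pd, true_severity
    config: SimConfig


def _updrs_parts(total: float, rng: np.random.Generator) -> tuple[float, ...]:
    frac = np.array([0.15, 0.30, 0.50, 0.05])
    parts = np.clip(total * frac + rng.normal(0, 0.5, 4), 0.0, None)
    return tuple(np.round(parts, 1))


def _hy_stage(severity: float) -> float:
    edges = [10, 30, 45, 60, 75]
    return float(np.searchsorted(edges, severity, side="right"))


def simulate_cohort(cfg: SimConfig, seed: int) -> SyntheticCohort:
    """Generate a full cohort; deterministic in (cfg, seed)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    params: dict[str, SubjectParams] = {}
    hyps: dict[tuple[str, date], Hypnogram] = {}
    qeegs: dict[tuple[str, date], QEEGSeries] = {}
    gt_rows = []
    sid_counter = 0
    for domain in sorted(cfg.n_subjects):
        n_pd, n_ctl = cfg.n_subjects[domain]
        for is_pd, n_group in ((True, n_pd), (False, n_ctl)):
            for _ in range(n_group):
                sid = f"S{sid_counter:04d}"
                sid_counter += 1
                lo, hi = (cfg.pd_severity_range if is_pd
                          else cfg.control_severity_range)
                sev = float(rng.uniform(lo, hi))
                p = SubjectParams(
                    subject_id=sid, domain=domain, is_pd=is_pd, severity=sev,
                    base_rate=float(rng.normal(cfg.base_rate, cfg.base_rate_jitter)))
                params[sid] = p
                windows = [(cfg.baseline, 0.0)]
                m6 = m12 = None
                if cfg.with_followup:
                    m6 = cfg.baseline + timedelta(days=182)
                    m12 = cfg.baseline + timedelta(days=365)
                    windows += [(m6, 182.0), (m12, 365.0)]
                rec = SubjectRecord(
                    subject_id=sid, domain=domain,
                    pd_status="PD" if is_pd else "control",
                    mds_updrs_total=round(max(0.0, sev + rng.normal(0, cfg.clinician_noise_sd)), 1),
                    mds_updrs_parts=_updrs_parts(sev, rng),
                    hy_stage=_hy_stage(sev), baseline_date=cfg.baseline,
                    m6_date=m6, m12_date=m12, institution=None)
                for visit_date, day_offset in windows:
                    true_sev = p.severity_at(cfg, day_offset)
                    if day_offset == 182.0:
                        rec.updrs_m6 = round(max(0.0, true_sev + rng.normal(0, cfg.clinician_noise_sd)), 1)
                    elif day_offset == 365.0:
                        rec.updrs_m12 = round(max(0.0, true_sev + rng.normal(0, cfg.clinician_noise_sd)), 1)
                    for k in range(cfg.nights_per_subject):
                        nd = visit_date + timedelta(days=k + 1)
                        night_seed = int(rng.integers(0, 2**31 - 1))
                        night, hyp, q = simulate_night(cfg, p, nd, night_seed,
                                                       severity=true_sev)
                        rec.nights.append(night)
                        hyps[(sid, nd)] = hyp
                        if domain in cfg.qeeg_domains:
                            qeegs[(sid, nd)] = q
                        gt_rows.append((sid, nd, domain, is_pd, true_sev))
                subjects.append(rec)
    gt = pd.DataFrame(gt_rows, columns=["subject_id", "night_date", "domain",
                                        "is_pd", "true_severity"])
    return SyntheticCohort(subjects=subjects, params=params, hypnograms=hyps,
                           qeeg=qeegs, ground_truth=gt, config=cfg)


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write the full on-disk layout: manifest + night/hypnogram/qEEG files."""
    directory = Path(directory)
    (directory / "nights").mkdir(parents=True, exist_ok=True)
    (directory / "hypnograms").mkdir(exist_ok=True)
    (directory / "qeeg").mkdir(exist_ok=True)
    write_manifest(cohort.subjects, directory / "manifest.tsv")
    for s in cohort.subjects:
        for night in s.nights:
            stem = f"{s.subject_id}_{night.night_date.isoformat()}"
            save_night_columnar(night, directory / "nights" / f"{stem}.txt")
            key = (s.subject_id, night.night_date)
            if key in cohort.hypnograms:
                save_hypnogram_tsv(cohort.hypnograms[key],
                                   directory / "hypnograms" / f"{stem}.tsv")
            if key in cohort.qeeg:
                save_qeeg_tsv(cohort.qeeg[key], directory / "qeeg" / f"{stem}.tsv")
    cohort.ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return directory


# ---------------------------------------------------------------------------
# prediction-level simulators (statistics experiments without the network)
# ---------------------------------------------------------------------------

def simulate_nightly_scores(n_per_class: int, n_nights: int, effect: float = 0.8,
                            noise_sd: float = 1.2, seed: int = 0
                            ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Nightly PD scores sigma(mu_i + eps) with mu = +/- effect by class.

    Emulates a per-night classifier output whose subject-level aggregate
    improves with more nights; used for aggregation/reliability experiments.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    base = date(2023, 3, 2)
    for cls, sign in (("PD", 1.0), ("control", -1.0)):
        for i in range(n_per_class):
            sid = f"{cls}{i:03d}"
            labels[sid] = int(sign > 0)
            z = sign * effect + rng.normal(0.0, noise_sd, size=n_nights)
            scores = 1.0 / (1.0 + np.exp(-z))
            for k in range(n_nights):
                rows.append((sid, base + timedelta(days=k), float(scores[k])))
    df = pd.DataFrame(rows, columns=["subject_id", "night_date", "pd_score"])
    return df, labels


def simulate_variance_components(n_subjects: int, n_windows: int,
                                 var_between: float = 9.0, var_within: float = 1.0,
                                 seed: int = 0) -> np.ndarray:
    """(n_subjects, n_windows) window aggregates with known variance split.

    The population ICC is var_between / (var_between + var_within)."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, np.sqrt(var_between), size=(n_subjects, 1))
    return mu + rng.normal(0.0, np.sqrt(var_within), size=(n_subjects, n_windows))


def simulate_prediction_drift(n_subjects: int = 12, drift_per_year: float = 6.0,
                              noise_sd: float = 8.0, nights_per_window: int = 30,
                              baseline_severity: tuple[float, float] = (20.0, 60.0),
                              seed: int = 0
                              ) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    """Nightly severity predictions for a progressing PD cohort.

    Per-night prediction = (baseline severity + linear drift) + N(0, noise_sd),
    with ``nights_per_window`` nights in each of the baseline, month-6 and
    month-12 windows.  Returns the prediction frame and subject records with
    visit dates and clinician scores equal to the drifted truth.
    """
    rng = np.random.default_rng(seed)
    baseline = date(2023, 3, 1)
    rows, records = [], []
    for i in range(n_subjects):
        sid = f"P{i:03d}"
        sev0 = float(rng.uniform(*baseline_severity))
        rec = SubjectRecord(
            subject_id=sid, domain="wireless", pd_status="PD",
            mds_updrs_total=sev0, baseline_date=baseline,
            m6_date=baseline + timedelta(days=182),
            m12_date=baseline + timedelta(days=365),
            updrs_m6=sev0 + drift_per_year * 182.0 / 365.0,
            updrs_m12=sev0 + drift_per_year)
        records.append(rec)
        for visit in (baseline, rec.m6_date, rec.m12_date):
            for k in range(nights_per_window):
                nd = visit + timedelta(days=k + 1)
                days = (nd - baseline).days
                truth = sev0 + drift_per_year * days / 365.0
                rows.append((sid, nd, float(truth + rng.normal(0.0, noise_sd))))
    df = pd.DataFrame(rows, columns=["subject_id", "night_date", "severity_pred"])
    return df, records
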