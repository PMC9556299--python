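"""Night I/O, screening, normalization and manifest round-trips."""

from datetime import date

import numpy as np
import pytest
from scipy import signal as sps

from breathpd import breathing_io as bio
from conftest import breathing_like

D = date(2023, 3, 2)


def make_night(x, f_b=10.0, domain="belt", sid="S1"):
    return bio.BreathingNight(subject_id=sid, night_date=D, domain=domain,
                              signal=np.asarray(x, float), f_b=f_b)


# ---------------------------------------------------------------------------
# load/save
# ---------------------------------------------------------------------------

def test_columnar_round_trip(tmp_path):
    night = make_night(breathing_like(72_000), domain="wireless", sid="S42")
    path = bio.save_night_columnar(night, tmp_path / "n.txt")
    back = bio.load_night(path, format="columnar")
    assert back.subject_id == "S42"
    assert back.night_date == night.night_date
    assert back.domain == "wireless"
    assert back.f_b == night.f_b
    assert back.duration_s == 7200.0
    assert np.abs(back.signal - night.signal).max() < 1e-9


def test_edf_duration_and_sample_count(tmp_path):
    # 10 Hz THOR RES channel: an 8-h recording loads to 288,000 samples
    x = breathing_like(8 * 3600 * 10)
    path = tmp_path / "psg.edf"
    bio.write_edf(path, {"THOR RES": x}, fs=10.0)
    night = bio.load_night(path, format="edf")
    assert night.n_samples == 288_000
    assert night.duration_s == 8 * 3600


def test_edf_resampling_preserves_spectral_peak(tmp_path):
    # 25 Hz source, 2 h -> 72,000 samples at 10 Hz; peak stays at 0.3 Hz
    fs_src, rate, dur = 25.0, 0.3, 7200
    t = np.arange(int(dur * fs_src)) / fs_src
    x = np.sin(2 * np.pi * rate * t)
    path = tmp_path / "src.edf"
    bio.write_edf(path, {"THOR RES": x}, fs=fs_src)
    night = bio.load_night(path, format="edf")
    assert night.n_samples == 72_000

    def peak_freq(sig, fs):
        f, p = sps.welch(sig, fs=fs, nperseg=8192)
        return f[np.argmax(p)]

    # independent oracle: Fourier resampling of the same source
    oracle = sps.resample(x, 72_000)
    assert abs(peak_freq(night.signal, 10.0) - rate) < 0.01
    assert abs(peak_freq(night.signal, 10.0) - peak_freq(oracle, 10.0)) < 0.01


def test_load_night_missing_file_and_sidecar(tmp_path):
    with pytest.raises(FileNotFoundError):
        bio.load_night(tmp_path / "absent.txt")
    p = tmp_path / "bare.txt"
    np.savetxt(p, np.ones(10))
    with pytest.raises(FileNotFoundError):
        bio.load_night(p)  # no metadata sidecar


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_screen_keeps_exactly_clean_long_nights():
    # constructed fixture: 2 short, 1 flat, 3 clean -> 3 kept
    clean = lambda seed: make_night(breathing_like(8 * 36000, seed=seed))
    nights = [
        make_night(breathing_like(int(1.9 * 36000))),          # 1.9 h
        make_night(breathing_like(36000)),                     # 1 h
        make_night(np.zeros(8 * 36000)),                       # flat
        clean(1), clean(2), clean(3),
    ]
    decisions = [bio.screen_night(n) for n in nights]
    assert [d.reason for d in decisions[:3]] == ["too_short", "too_short", "absent"]
    assert all(d.keep for d in decisions[3:])
    assert sum(d.keep for d in decisions) == 3


def test_screen_distortion_rules():
    n = 8 * 36000
    # saturated at the clip bound
    sat = breathing_like(n)
    sat[: int(0.3 * n)] = 6.5
    assert bio.screen_night(make_night(sat)).reason == "distorted"
    # no respiratory spectral peak (broadband noise)
    noise = np.random.default_rng(0).normal(size=n)
    assert bio.screen_night(make_night(noise)).reason == "distorted"
    # belt detached for 40% of the night: those windows flat-line
    flat = breathing_like(n, seed=9)
    flat[: int(0.4 * n)] = 1e-5 * np.random.default_rng(1).normal(size=int(0.4 * n))
    assert bio.screen_night(make_night(flat)).reason == "distorted"


def test_keep_decision_consistency_enforced():
    with pytest.raises(ValueError):
        bio.KeepDecision(keep=True, reason="too_short")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_preprocess_clip_then_standardize_toy():
    # clip [-10, 0, 10] to [-6, 0, 6]; mean 0; population sd sqrt(24)
    night = make_night([-10.0, 0.0, 10.0])
    out = bio.preprocess_night(night)
    s = np.sqrt(24.0)  # population sd of [-6, 0, 6]
    np.testing.assert_allclose(out.signal, [-6.0 / s, 0.0, 6.0 / s], atol=1e-12)
    assert out.preprocessed


def test_preprocess_standardizes_and_is_idempotent():
    night = make_night(breathing_like(72_000))
    once = bio.preprocess_night(night)
    assert abs(once.signal.mean()) < 1e-6
    assert abs(once.signal.std() - 1.0) < 1e-6
    twice = bio.preprocess_night(once)
    assert np.abs(twice.signal - once.signal).max() < 1e-6


def test_preprocess_constant_signal_errors():
    with pytest.raises(bio.UnusableNightError):
        bio.preprocess_night(make_night(np.full(1000, 3.3)))


# ---------------------------------------------------------------------------
# manifest and imputation
# ---------------------------------------------------------------------------

def _subject(sid, status, total=None, hy=None, domain="wireless"):
    return bio.SubjectRecord(subject_id=sid, domain=domain, pd_status=status,
                             mds_updrs_total=total, hy_stage=hy,
                             baseline_date=date(2023, 3, 1))


def test_impute_control_mean():
    cohort = [_subject("c1", "control", 2.0), _subject("c2", "control", 4.0),
              _subject("c3", "control", None), _subject("p1", "PD", None)]
    bio.impute_control_labels(cohort)
    assert cohort[2].mds_updrs_total == 3.0
    assert cohort[3].mds_updrs_total is None  # PD never imputed


def test_impute_requires_observed_controls():
    with pytest.raises(ValueError):
        bio.impute_control_labels([_subject("c1", "control"),
                                   _subject("p1", "PD", 40.0)])


def test_manifest_round_trip(tmp_path):
    subjects = [
        bio.SubjectRecord(subject_id="a", domain="belt", pd_status="PD",
                          mds_updrs_total=42.5, mds_updrs_parts=(5, 12, 20, 1.5),
                          hy_stage=2.0, baseline_date=date(2023, 1, 3),
                          m6_date=date(2023, 7, 4), updrs_m6=45.0,
                          institution="mayo"),
        bio.SubjectRecord(subject_id="b", domain="wireless", pd_status="control"),
    ]
    path = bio.write_manifest(subjects, tmp_path / "manifest.tsv")
    back = bio.read_manifest(path)
    assert back[0].mds_updrs_total == 42.5
    assert back[0].mds_updrs_parts == (5.0, 12.0, 20.0, 1.5)
    assert back[0].m6_date == date(2023, 7, 4)
    assert back[0].updrs_m6 == 45.0
    assert back[0].institution == "mayo"
    assert back[1].mds_updrs_total is None
    assert back[1].baseline_date is None
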