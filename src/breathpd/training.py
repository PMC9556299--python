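"""Multitask/adversarial training and Platt-scaled 4-fold ensembling.

The composite objective per subject-step combines, over that subject's
nights: a class-weighted cross-entropy for PD classification, a weighted
squared-error loss on MDS-UPDRS, an L2 loss on predicted qEEG relative
powers, an adversarial domain term per diagnosis group (gradient reversal
into the group's discriminator), and a transductive consistency term — the
variance of the severity predictions across the subject's nights within the
1-month window.  Loss terms whose labels are missing are excluded exactly
(they contribute no value and no gradient).

Calibration follows the four-subset scheme: subjects are split into four
equal parts; each model trains on three and learns two Platt scalars (A, B)
on the fourth by minimizing cross-entropy of sigma(A z + B) against labels,
with z the classifier's pre-sigmoid logit; the final model averages the four
calibrated members.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit

from ._nn import (Adam, Tensor, binary_cross_entropy_logit,
                  binary_cross_entropy_logits_mean)
from .breathing_io import (SubjectRecord, preprocess_night,
                           screen_night)
from .model_core import ModelBundle, ModelConfig, PDBreathingModel
from .qeeg_labels import QEEGSeries, align_qeeg_to_features


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings and loss weights (all tunable).

    Loss weights follow order-of-magnitude balancing: w_sev = 0.01 brings
    squared MDS-UPDRS errors to O(1); the adversarial and consistency terms
    act as regularizers at 0.1.  ``crop_s`` trains on random fixed-length
    crops of each night (0 disables cropping); evaluation always uses full
    nights.
    """

    epochs: int = 30
    lr: float = 1e-3
    lr_cosine: bool = True   # cosine decay of lr to ~0 over the run
    disc_lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    w_cls: float = 1.0
    w_sev: float = 1.0
    w_qeeg: float = 1.0
    w_adv: float = 0.1
    w_cons: float = 0.1
    sev_scale: float = 25.0  # MDS-UPDRS units per standardized residual unit
    grl_lambda: float = 1.0
    # adversarial formulation for the encoder step: "grl" maximizes the
    # discriminator's cross-entropy through gradient reversal; "confusion"
    # drives the discriminator's output toward 1/2 (uniform).  Both update
    # the discriminator itself on detached features.
    adversarial_mode: str = "confusion"
    disc_steps: int = 1       # discriminator updates per night step
    disc_refit_steps: int = 50  # full-batch refit steps per epoch and group
    disc_refit_l2: float = 0.05  # ridge penalty keeps refit logits calibrated
    grad_clip: float = 5.0   # global gradient-norm clip (0 disables)
    crop_s: float = 300.0
    use_qeeg: bool = True
    use_adversarial: bool = True
    use_consistency: bool = True
    class_weighting: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class CalibrationParams:
    A: float
    B: float
    fold_id: int = 0

    def __call__(self, logit: float | np.ndarray) -> float | np.ndarray:
        return expit(self.A * np.asarray(logit) + self.B)


@dataclass
class LossBreakdown:
    l_cls: float = 0.0
    l_sev: float = 0.0
    l_qeeg: float = 0.0
    l_adv: float = 0.0
    l_cons: float = 0.0
    total: float = 0.0
    available: dict = field(default_factory=dict)


@dataclass
class TrainNight:
    x: np.ndarray                       # preprocessed signal
    night_date: date
    qeeg_target: np.ndarray | None = None   # (seconds, 4)
    qeeg_mask: np.ndarray | None = None


@dataclass
class TrainSubject:
    subject_id: str
    y: int                              # 1 = PD
    group: str                          # "PD" | "control"
    domain: str
    domain_y: int                       # 1 = belt
    severity: float | None
    nights: list[TrainNight]


def prepare_training_data(subjects: list[SubjectRecord],
                          qeeg: dict[tuple[str, date], QEEGSeries] | None = None,
                          window_days: int = 30,
                          screen: bool = True,
                          min_hours: float = 2.0) -> list[TrainSubject]:
    """Screen, normalize and window a cohort into training units.

    Only nights within ``window_days`` after the baseline visit enter the
    training window (the consistency term assumes stable severity over that
    period); subjects without a baseline date contribute all nights.
    Subjects with unknown PD status are dropped.
    """
    out = []
    for s in subjects:
        if s.pd_status not in ("PD", "control"):
            continue
        nights = []
        for n in s.nights:
            if s.baseline_date is not None and not (
                    s.baseline_date < n.night_date
                    <= s.baseline_date + timedelta(days=window_days)):
                continue
            if screen and not screen_night(n, min_hours=min_hours).keep:
                continue
            x = n.signal if n.preprocessed else preprocess_night(n).signal
            tn = TrainNight(x=x, night_date=n.night_date)
            if qeeg is not None:
                q = qeeg.get((s.subject_id, n.night_date))
                if q is not None:
                    tn.qeeg_target = q.rel_power
                    tn.qeeg_mask = q.mask
            nights.append(tn)
        if not nights:
            continue
        out.append(TrainSubject(
            subject_id=s.subject_id, y=int(s.pd_status == "PD"),
            group=s.pd_status if s.pd_status == "PD" else "control",
            domain=s.domain, domain_y=int(s.domain == "belt"),
            severity=s.mds_updrs_total, nights=nights))
    return out


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def consistency_loss(preds: list[Tensor]) -> tuple[Tensor, bool]:
    """Population variance of one subject's per-night severity predictions.

    Zero iff all predictions are equal; permutation invariant.  With fewer
    than two nights the term is not applicable and contributes zero.
    """
    if len(preds) < 2:
        return Tensor(0.0), False
    stack = preds[0].reshape(1)
    for p in preds[1:]:
        stack = _nn_concat(stack, p.reshape(1))
    mean = stack.mean()
    var = ((stack - mean) ** 2.0).mean()
    return var, True


def _nn_concat(a: Tensor, b: Tensor) -> Tensor:
    from ._nn import concat
    return concat([a, b], axis=0)


def composite_loss(night_outputs: list[dict], labels: dict, availability: dict,
                   weights: dict, class_weights: tuple[float, float] = (1.0, 1.0),
                   sev_weight: float = 1.0) -> tuple[Tensor, LossBreakdown]:
    """Total loss for one subject-step over its nights.

    ``night_outputs`` come from :meth:`PDBreathingModel.forward_night` (plus
    a ``disc_logit`` entry when the adversarial term is active); ``labels``
    holds ``y`` (0/1), ``severity`` (float or None), ``domain_y`` and
    per-night qEEG targets inside the night outputs' companion TrainNights.
    Unavailable terms contribute exactly zero and propagate no gradient.
    """
    avail = {k: bool(availability.get(k, False))
             for k in ("cls", "sev", "qeeg", "adv", "cons")}
    if not any(avail.values()):
        raise ValueError("no loss term available for this subject")
    n_nights = len(night_outputs)
    total = Tensor(0.0)
    bd = LossBreakdown(available=avail)

    if avail["cls"]:
        y = float(labels["y"])
        w = class_weights[int(labels["y"])]
        term = None
        for out in night_outputs:
            t = binary_cross_entropy_logit(out["logit"], y, weight=w)
            term = t if term is None else term + t
        term = term * (1.0 / n_nights)
        bd.l_cls = float(term.data)
        total = total + weights["w_cls"] * term

    sev_preds = [out["severity"]["total"] for out in night_outputs
                 if "total" in out.get("severity", {})]
    sev_scale = weights.get("sev_scale", 25.0)  # residuals standardized
    if avail["sev"]:
        target = float(labels["severity"])
        term = None
        for p in sev_preds:
            t = (((p - target) * (1.0 / sev_scale)) ** 2.0) * sev_weight
            term = t if term is None else term + t
        term = term * (1.0 / len(sev_preds))
        bd.l_sev = float(term.data)
        total = total + weights["w_sev"] * term

    if avail["qeeg"]:
        term = None
        n_q = 0
        for out, tgt, mask in zip(night_outputs, labels["qeeg_targets"],
                                  labels["qeeg_masks"]):
            if tgt is None:
                continue
            pred = out["qeeg_pred"]                     # (4, S)
            m = (mask if mask is not None
                 else np.ones(tgt.shape[0], dtype=bool)).astype(float)
            diff = pred - Tensor(tgt.T)
            sq = (diff ** 2.0) * Tensor(m.reshape(1, -1))
            t = sq.sum() * (1.0 / max(1.0, 4.0 * m.sum()))
            term = t if term is None else term + t
            n_q += 1
        if term is not None:
            term = term * (1.0 / n_q)
            bd.l_qeeg = float(term.data)
            total = total + weights["w_qeeg"] * term

    if avail["adv"]:
        dy = float(labels.get("adv_target", labels["domain_y"]))
        term = None
        for out in night_outputs:
            t = binary_cross_entropy_logit(out["disc_logit"], dy)
            term = t if term is None else term + t
        term = term * (1.0 / n_nights)
        bd.l_adv = float(term.data)
        total = total + weights["w_adv"] * term

    if avail["cons"]:
        # anchor predictions from the subject's other nights enter as
        # constants (no gradient), pulling the current nights toward them
        anchors = [Tensor(np.asarray(v, dtype=float))
                   for v in labels.get("prev_severity_preds", ())]
        term, applicable = consistency_loss(anchors + sev_preds)
        if applicable:
            term = term * (1.0 / sev_scale ** 2)  # same standardized scale
            bd.l_cons = float(term.data)
            total = total + weights["w_cons"] * term

    bd.total = float(total.data)
    return total, bd


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _crop(night: TrainNight, crop_s: float, f_b: float,
          rng: np.random.Generator) -> TrainNight:
    n_sec = int(night.x.size / f_b)
    c = int(crop_s)
    if crop_s <= 0 or n_sec <= c:
        return night
    start = int(rng.integers(0, n_sec - c + 1))
    x = night.x[int(start * f_b): int((start + c) * f_b)]
    tgt = mask = None
    if night.qeeg_target is not None:
        tgt = night.qeeg_target[start:start + c]
        mask = (night.qeeg_mask[start:start + c]
                if night.qeeg_mask is not None else None)
    return TrainNight(x=x, night_date=night.night_date, qeeg_target=tgt,
                      qeeg_mask=mask)


def _main_parameters(model: PDBreathingModel) -> list[Tensor]:
    disc_ids = {id(p) for p in model.discriminators.parameters()}
    return [p for p in model.parameters() if id(p) not in disc_ids]


def _clip_gradients(params: list[Tensor], max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = 0.0
    for p in params:
        g = p.grad
        if g is not None:
            g = g.ravel()
            total += float(g @ g)
    total = np.sqrt(total)
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def train_model(train_set: list[TrainSubject], cfg: TrainConfig, seed: int = 0
                ) -> tuple[PDBreathingModel, list[dict]]:
    """Train one (uncalibrated) model.

    Each optimizer step consumes one night (the one-night minibatch);
    subjects are visited in shuffled order and their nights processed
    together, so the transductive consistency term can pull every night
    toward the subject's other predictions from the same window (earlier
    nights enter as constant anchors).  Discriminators are updated in
    alternation — their own cross-entropy on detached features after each
    main step; the encoder sees the reversed gradient through the
    gradient-reversal layer during the main step.  Deterministic given
    (train_set, cfg, seed) in single-threaded numpy.
    """
    if len({s.y for s in train_set}) < 2 or min(
            sum(1 for s in train_set if s.y == c) for c in (0, 1)) < 2:
        raise ValueError("need at least two subjects per class to train")
    rng = np.random.default_rng(seed)
    model = PDBreathingModel(dataclasses.replace(cfg.model, seed=seed))
    model.train()
    main_opt = Adam(_main_parameters(model), lr=cfg.lr, betas=cfg.betas)
    disc_params = model.discriminators.parameters()
    disc_opt = Adam(disc_params, lr=cfg.disc_lr, betas=cfg.betas)

    n_nights = sum(len(s.nights) for s in train_set)
    counts = {c: sum(len(s.nights) for s in train_set if s.y == c) for c in (0, 1)}
    if cfg.class_weighting and counts[0] and counts[1]:
        class_weights = (n_nights / (2.0 * counts[0]), n_nights / (2.0 * counts[1]))
    else:
        class_weights = (1.0, 1.0)
    domains = {s.domain for s in train_set}
    adversarial = cfg.use_adversarial and len(domains) > 1
    dom_counts = {d: sum(len(s.nights) for s in train_set if s.domain == d)
                  for d in domains}
    weights = {"w_cls": cfg.w_cls, "w_sev": cfg.w_sev, "w_qeeg": cfg.w_qeeg,
               "w_adv": cfg.w_adv, "w_cons": cfg.w_cons,
               "sev_scale": cfg.sev_scale}

    log: list[dict] = []
    d_dim = cfg.model.d
    disc_norm: dict[str, tuple[np.ndarray, np.ndarray]] = {
        g: (np.zeros(d_dim), np.ones(d_dim)) for g in ("PD", "control")}
    order = np.arange(len(train_set))
    for epoch in range(cfg.epochs):
        if cfg.lr_cosine:
            main_opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
        rng.shuffle(order)
        sums: dict[str, float] = {}
        n_steps = 0
        feat_buffer: dict[str, list] = {"PD": [], "control": []}
        for si in order:
            subj = train_set[si]
            nights = [_crop(n, cfg.crop_s, cfg.model.f_b, rng)
                      for n in subj.nights]
            rng.shuffle(nights)
            sev_weight = 1.0
            if len(domains) > 1:
                sev_weight = n_nights / (len(domains) * dom_counts[subj.domain])
            prev_preds: list[float] = []
            for night in nights:
                out = model.forward_night(night.x, parts=("total",),
                                          with_qeeg=cfg.use_qeeg)
                adv_target = float(subj.domain_y)
                if adversarial:
                    mu, sd = disc_norm[subj.group]
                    g_std = (out["g"] - Tensor(mu)) * Tensor(1.0 / sd)
                    if cfg.adversarial_mode == "confusion":
                        # encoder pulls the (frozen) discriminator toward 1/2
                        out["disc_logit"] = model.discriminate(
                            g_std, subj.group, reverse=False)
                        adv_target = 0.5
                    else:
                        out["disc_logit"] = model.discriminate(
                            g_std, subj.group, reverse=True,
                            lam=cfg.grl_lambda)
                if cfg.use_qeeg and night.qeeg_target is not None:
                    n_out = out["qeeg_pred"].data.shape[1]
                    q = align_qeeg_to_features(
                        QEEGSeries(rel_power=night.qeeg_target,
                                   mask=night.qeeg_mask), n_out)
                    target, mask = q.rel_power, q.mask
                else:
                    target = mask = None
                availability = {
                    "cls": True,
                    "sev": subj.severity is not None,
                    "qeeg": cfg.use_qeeg and target is not None,
                    "adv": adversarial,
                    "cons": cfg.use_consistency and bool(prev_preds),
                }
                labels = {"y": subj.y, "severity": subj.severity,
                          "domain_y": subj.domain_y, "adv_target": adv_target,
                          "qeeg_targets": [target], "qeeg_masks": [mask],
                          "prev_severity_preds": prev_preds}
                total, bd = composite_loss([out], labels, availability,
                                           weights, class_weights, sev_weight)
                if not np.isfinite(bd.total):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, "
                        f"subject {subj.subject_id}: {bd}")
                model.zero_grad()
                total.backward()
                _clip_gradients(main_opt.params, cfg.grad_clip)
                main_opt.step()
                model.zero_grad()
                if adversarial:
                    # discriminator steps: own cross-entropy, features detached
                    mu, sd = disc_norm[subj.group]
                    g_det = Tensor((out["g"].data - mu) / sd)
                    for _ in range(max(0, cfg.disc_steps)):
                        logit = model.discriminate(g_det, subj.group)
                        d_loss = binary_cross_entropy_logit(
                            logit, float(subj.domain_y))
                        d_loss.backward()
                        disc_opt.step()
                        model.zero_grad()
                    feat_buffer[subj.group].append(
                        (out["g"].data.copy(), float(subj.domain_y)))
                prev_preds.append(float(out["severity"]["total"].data))
                n_steps += 1
                for k in ("l_cls", "l_sev", "l_qeeg", "l_adv", "l_cons", "total"):
                    sums[k] = sums.get(k, 0.0) + getattr(bd, k)
        if adversarial and cfg.disc_refit_steps > 0:
            # refit each group's discriminator to near-optimality on the
            # epoch's detached features (standardized by buffer statistics),
            # so the encoder's confusion gradient follows the actual domain
            # direction rather than a lagging one
            for group, rows in feat_buffer.items():
                tgt = np.array([r[1] for r in rows])
                if rows and len(np.unique(tgt)) == 2:
                    X = np.stack([r[0] for r in rows], axis=1)  # (d, N)
                    mu = X.mean(axis=1)
                    sd = X.std(axis=1) + 1e-8
                    disc_norm[group] = (mu, sd)
                    Xs = Tensor((X - mu[:, None]) / sd[:, None])
                    refit_opt = Adam(model._disc[group].parameters(), lr=0.05)
                    for _ in range(cfg.disc_refit_steps):
                        logits = model._disc[group](Xs).reshape(-1)
                        d_loss = binary_cross_entropy_logits_mean(logits, tgt)
                        for p in model._disc[group].parameters():
                            d_loss = d_loss + (p ** 2.0).sum() * cfg.disc_refit_l2
                        model.zero_grad()
                        d_loss.backward()
                        refit_opt.step()
                        model.zero_grad()
        entry = {"epoch": epoch,
                 **{k: v / max(1, n_steps) for k, v in sums.items()}}
        log.append(entry)
    model.eval()
    return model, log


# ---------------------------------------------------------------------------
# inference over cohorts
# ---------------------------------------------------------------------------

def predict_cohort(model: PDBreathingModel | ModelBundle,
                   subjects: list[SubjectRecord],
                   parts: tuple[str, ...] = ("total",),
                   collect_attention: bool = False):
    """Per-night predictions for a cohort.

    Returns a DataFrame (subject_id, night_date, pd_score, pd_logit,
    severity_pred) and, when requested, a dict of attention profiles keyed by
    (subject_id, night_date).  Bundles report calibrated ensemble scores
    (pd_logit is NaN for bundles).
    """
    rows, attention = [], {}
    for s in subjects:
        for night in s.nights:
            x = night.signal if night.preprocessed else preprocess_night(night).signal
            if isinstance(model, ModelBundle):
                out = model.predict_night(x, parts=parts)
                score, logit = out["pd_score"], np.nan
                sev = out["severity"].get("total", np.nan)
                attn = out["attention"]
            else:
                out = model.forward_night(x, parts=parts, with_qeeg=False)
                logit = float(out["logit"].data)
                score = out["score"]
                sev = float(out["severity"]["total"].data)
                attn = out["attention"].data
            rows.append((s.subject_id, night.night_date, score, logit, sev))
            if collect_attention:
                attention[(s.subject_id, night.night_date)] = np.asarray(attn)
    df = pd.DataFrame(rows, columns=["subject_id", "night_date", "pd_score",
                                     "pd_logit", "severity_pred"])
    return (df, attention) if collect_attention else df


# ---------------------------------------------------------------------------
# Platt calibration and ensembling
# ---------------------------------------------------------------------------

def _platt_ce(z: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    zp = a * z + b
    return float(np.mean(np.logaddexp(0.0, zp) - y * zp))


def platt_calibrate(logits: np.ndarray, labels: np.ndarray, fold_id: int = 0,
                    tol: float = 1e-8, max_iter: int = 100) -> CalibrationParams:
    """Fit sigma(A z + B) to labels by cross-entropy (damped Newton).

    Starts at the identity (A, B) = (1, 0), so the calibrated cross-entropy
    never exceeds the uncalibrated one.  z is the pre-sigmoid logit.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if z.shape != y.shape or z.ndim != 1:
        raise ValueError("logits and labels must be 1D arrays of equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("calibration subset must contain both classes")
    a, b = 1.0, 0.0
    ce = _platt_ce(z, y, a, b)
    for _ in range(max_iter):
        p = expit(a * z + b)
        r = p - y
        g = np.array([np.mean(r * z), np.mean(r)])
        if np.linalg.norm(g) < tol:
            break
        w = p * (1.0 - p)
        H = np.array([[np.mean(w * z * z), np.mean(w * z)],
                      [np.mean(w * z), np.mean(w)]])
        H[0, 0] += 1e-10
        H[1, 1] += 1e-10
        step = np.linalg.solve(H, g)
        t = 1.0
        while t > 1e-8:  # backtracking keeps CE monotone
            ce_new = _platt_ce(z, y, a - t * step[0], b - t * step[1])
            if ce_new <= ce - 1e-6 * t * float(g @ step):
                a, b = a - t * step[0], b - t * step[1]
                ce = ce_new
                break
            t *= 0.5
        else:
            break
    return CalibrationParams(A=float(a), B=float(b), fold_id=fold_id)


def domain_adaptation_train_config(epochs: int = 30, **overrides) -> TrainConfig:
    """Training recipe for domain-invariant transfer between acquisitions.

    Strong confusion pressure (w_adv = 10) against per-group discriminators
    that are refit to near-optimality each epoch with a light ridge penalty,
    so their logits stay calibrated and the encoder's invariance gradient
    tracks the probe-visible domain direction.
    """
    overrides.setdefault("w_adv", 10.0)
    overrides.setdefault("disc_refit_steps", 200)
    overrides.setdefault("disc_refit_l2", 0.02)
    return TrainConfig(epochs=epochs, **overrides)


def _stratified_subsets(train_set: list[TrainSubject], k: int,
                        rng: np.random.Generator) -> list[list[int]]:
    subsets: list[list[int]] = [[] for _ in range(k)]
    for cls in (1, 0):
        idx = [i for i, s in enumerate(train_set) if s.y == cls]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            subsets[j % k].append(i)
    return subsets


def build_ensemble(train_set: list[TrainSubject], cfg: TrainConfig,
                   seed: int = 0) -> ModelBundle:
    """Four calibrated members, each subject subset used once for calibration.

    Subjects are split (subject-level, class-stratified) into four equal
    subsets; member k trains on three and fits its Platt scalars on the
    held-out subset; the bundle averages the members' calibrated scores.
    """
    if len(train_set) < 8:
        raise ValueError("ensemble calibration needs at least 8 subjects")
    rng = np.random.default_rng(seed)
    subsets = _stratified_subsets(train_set, 4, rng)
    members, calibrations = [], []
    for fold in range(4):
        train_idx = [i for f, sub in enumerate(subsets) if f != fold for i in sub]
        calib_idx = subsets[fold]
        sub_train = [train_set[i] for i in train_idx]
        member, _ = train_model(sub_train, cfg, seed=(seed * 4 + fold) % (2**31 - 1))
        logits, labels = [], []
        for i in calib_idx:
            s = train_set[i]
            for night in s.nights:
                out = member.forward_night(night.x, parts=(), with_qeeg=False)
                logits.append(float(out["logit"].data))
                labels.append(s.y)
        cal = platt_calibrate(np.asarray(logits), np.asarray(labels), fold_id=fold)
        members.append(member)
        calibrations.append({"A": cal.A, "B": cal.B, "fold_id": fold})
    return ModelBundle(members=members, calibrations=calibrations,
                       config=cfg.model)


# ---------------------------------------------------------------------------
# domain-invariance probe
# ---------------------------------------------------------------------------

def domain_probe_accuracy(model: PDBreathingModel, probe_set: list[TrainSubject],
                          seed: int = 0, n_folds: int = 4) -> float:
    """Held-out accuracy of a fresh domain classifier on pooled features.

    Trains a logistic-regression probe (standardized features) to tell belt
    from wireless nights using the encoder's global features, scored by
    subject-level grouped cross-validation.  Low accuracy indicates
    domain-invariant features.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import GroupKFold, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    feats, doms, sids = [], [], []
    for s in probe_set:
        for night in s.nights:
            out = model.forward_night(night.x, parts=(), with_qeeg=False)
            feats.append(out["g"].data.copy())
            doms.append(s.domain_y)
            sids.append(s.subject_id)
    feats = np.asarray(feats)
    doms = np.asarray(doms)
    if len(np.unique(doms)) < 2:
        raise ValueError("both domains required in the probe set")
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=1000, C=0.5,
                                           random_state=seed))
    scores = cross_val_score(clf, feats, doms, groups=np.asarray(sids),
                             cv=GroupKFold(n_splits=n_folds))
    return float(np.mean(scores))
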