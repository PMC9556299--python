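"""The network: breathing encoder E, attention-pooling PD encoder G, PD
classifier M, severity predictor N, qEEG decoder F and per-group domain
discriminators D_PD / D_Control.

Architecture
------------
* E: a stride-5 convolutional stem followed by eight 1D bottleneck residual
  blocks (stride 2 at blocks 1, 3, 5 and 7) and three SRU layers.  Total
  temporal stride S = 5 * 2^4 = 80 samples, so 10 Hz input becomes a feature
  sequence at 0.125 Hz (one step per 8 s).
* G: two stride-1 convolutions produce a scalar score per step; a softmax
  over time normalizes the scores into attention weights, and the global
  feature is the attention-weighted time average of the encoder features.
* M: three fully connected layers and a sigmoid; a night's PD score.
* N: four fully connected layers per severity head (total MDS-UPDRS by
  default; subpart heads are drop-in replacements).
* F: three x2-upsampling deconvolution blocks (each: upsample + three
  convolutions with channel normalization, ReLU and a residual connection),
  with UNet-style skip connections concatenating the SRU layer outputs,
  followed by two per-second fully connected layers and a softmax over the
  four EEG bands.  2^3 upsampling returns the 0.125 Hz features to the 1 Hz
  qEEG label rate.
* D_PD / D_Control: small MLPs on the global feature estimating the
  probability that it came from the belt domain; each group's features only
  ever touch its own discriminator.

Channel widths default to a CPU-sized plan; all widths are configuration.
Forward passes are deterministic given parameters and input (dropout is the
only stochastic layer and is inactive in eval mode; normalization layers use
per-night statistics in both modes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (Conv1d, ChannelNorm, Dropout, MLP, Module, ModuleList,
                  SRULayer, Tensor, concat, grad_reverse, softmax, upsample2,
                  upsample_to)
from .breathing_io import BreathingNight

GROUPS = ("PD", "control")


# ---------------------------------------------------------------------------
# configuration and feature containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Network geometry.  The stride plan is fixed by the qEEG label rate:
    total stride S must satisfy (f_b / S) * 2^3 == 1 Hz, i.e. S = 80 at
    f_b = 10 Hz, so three x2 deconvolution blocks reach per-second output."""

    f_b: float = 10.0
    stem_channels: int = 12
    stem_kernel: int = 25
    stem_stride: int = 5
    block_widths: tuple[int, ...] = (16, 16, 24, 24, 24, 24, 32, 32)
    block_strides: tuple[int, ...] = (2, 1, 2, 1, 2, 1, 2, 1)
    bottleneck_reduce: int = 2
    sru_layers: int = 3
    d: int = 32                      # SRU hidden size == global feature dim
    attn_hidden: int = 16
    classifier_widths: tuple[int, ...] = (32, 16, 1)      # three FC layers
    severity_widths: tuple[int, ...] = (32, 16, 8, 1)     # four FC layers
    decoder_channels: int = 16
    decoder_fc: int = 16
    # fixed gain on the severity output: prediction = offset + scale * h, so
    # the head regresses on a standardized scale while reporting MDS-UPDRS
    severity_offset: float = 0.0
    severity_out_scale: float = 25.0
    disc_widths: tuple[int, ...] = (16, 1)
    dropout: float = 0.3
    severity_parts: tuple[str, ...] = ("total",)
    seed: int = 0

    @property
    def total_stride(self) -> int:
        s = self.stem_stride
        for st in self.block_strides:
            s *= st
        return s

    @property
    def feature_step_s(self) -> float:
        return self.total_stride / self.f_b

    @property
    def upsample_factor(self) -> int:
        return 8  # three x2 deconvolution blocks

    def validate(self) -> None:
        if len(self.block_widths) != 8 or len(self.block_strides) != 8:
            raise ValueError("encoder uses exactly eight bottleneck blocks")
        rate = self.f_b / self.total_stride
        if abs(rate * self.upsample_factor - 1.0) > 1e-9:
            raise ValueError(
                f"feature rate {rate} Hz x 8 must equal the 1 Hz qEEG rate; "
                f"total stride is {self.total_stride} at f_b={self.f_b}")
        if len(self.classifier_widths) != 3 or len(self.severity_widths) != 4:
            raise ValueError("classifier has three FC layers, severity head four")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        raw = json.loads(text)
        for key in ("block_widths", "block_strides", "classifier_widths",
                    "severity_widths", "disc_widths", "severity_parts"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class FeatureSequence:
    """Encoder output at the feature rate: (time_steps, channels)."""

    data: np.ndarray
    step_s: float
    _tensor: Tensor | None = None
    _sru_tensors: list[Tensor] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("feature sequence must be (time_steps, channels)")
        if not np.isfinite(self.data).all():
            raise ValueError("feature sequence contains non-finite values")

    @property
    def time_steps(self) -> int:
        return self.data.shape[0]


@dataclass
class AttentionProfile:
    """Nonnegative attention weights over feature time steps; sums to 1."""

    weights: np.ndarray
    step_s: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < -1e-9):
            raise ValueError("attention weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must sum to 1")


@dataclass
class GlobalFeature:
    vector: np.ndarray
    _tensor: Tensor | None = None

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class BottleneckBlock(Module):
    """1D bottleneck residual block: 1x1 reduce, k3 (strided), 1x1 expand.

    The encoder is norm-free: per-night normalization layers would equalize
    every night's feature statistics, discarding the between-night amplitude
    and variability differences the classifier relies on (the input is
    already standardized per night).  Depth is stabilized instead by a
    down-scaled residual branch, so each block starts near the identity.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, reduce: int,
                 rng: np.random.Generator):
        super().__init__()
        mid = max(4, c_out // reduce)
        self.conv1 = Conv1d(c_in, mid, 1, rng, pad=0)
        self.conv2 = Conv1d(mid, mid, 3, rng, stride=stride)
        self.conv3 = Conv1d(mid, c_out, 1, rng, pad=0)
        self.conv3.w.data *= 0.1  # near-identity start
        self.shortcut = None
        if stride != 1 or c_in != c_out:
            self.shortcut = Conv1d(c_in, c_out, 1, rng, stride=stride, pad=0)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h)
        sc = self.shortcut(x) if self.shortcut is not None else x
        # strided 3-tap conv can run one step short of the strided 1x1 shortcut
        if sc.data.shape[1] != h.data.shape[1]:
            sc = _crop_time(sc, h.data.shape[1])
        return (h + sc).relu()


def _crop_time(x: Tensor, length: int) -> Tensor:
    out = Tensor(x.data[:, :length], _parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, :length] = g
        x._accumulate(full)
    out._backward = bw
    return out


class BreathingEncoder(Module):
    """E: stem + eight bottleneck blocks + three SRU layers."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.stem = Conv1d(1, cfg.stem_channels, cfg.stem_kernel, rng,
                           stride=cfg.stem_stride)
        blocks = []
        c = cfg.stem_channels
        for w, s in zip(cfg.block_widths, cfg.block_strides):
            blocks.append(BottleneckBlock(c, w, s, cfg.bottleneck_reduce, rng))
            c = w
        self.blocks = ModuleList(blocks)
        srus = []
        for i in range(cfg.sru_layers):
            srus.append(SRULayer(c if i == 0 else cfg.d, cfg.d, rng))
        self.srus = ModuleList(srus)

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        h = self.stem(x).relu()
        for block in self.blocks:
            h = block(h)
        sru_outputs = []
        for sru in self.srus:
            h = sru(h)
            sru_outputs.append(h)
        return h, sru_outputs


class AttentionPool(Module):
    """G: per-step scalar scores from two stride-1 convolutions, softmax over
    time, then the attention-weighted time average of the features."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(cfg.d, cfg.attn_hidden, 3, rng)
        self.conv2 = Conv1d(cfg.attn_hidden, 1, 3, rng)
        # zero-init scores: attention starts uniform and learns to sharpen
        self.conv2.w.data[:] = 0.0
        self.conv2.bias.data[:] = 0.0

    def __call__(self, f: Tensor) -> tuple[Tensor, Tensor]:
        scores = self.conv2(self.conv1(f).relu())      # (1, T)
        a = softmax(scores, axis=1)                    # normalization layer
        g = (f @ a.T).reshape(-1)                      # (d,)
        return g, a.reshape(-1)


class SeverityHeads(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.heads = ModuleList()
        self._parts: dict[str, MLP] = {}
        self.offset = cfg.severity_offset
        self.scale = cfg.severity_out_scale
        for part in cfg.severity_parts:
            head = MLP((cfg.d,) + cfg.severity_widths, rng)
            self.heads.append(head)
            self._parts[part] = head

    def __call__(self, g: Tensor, part: str = "total") -> Tensor:
        if part not in self._parts:
            raise ValueError(f"no severity head trained for part {part!r}; "
                             f"available: {sorted(self._parts)}")
        return self._parts[part](g).reshape(()) * self.scale + self.offset

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self._parts)


class DeconvBlock(Module):
    """x2 upsampling block: three convolutions with channel normalization and
    ReLU on the upsampled input, plus a residual connection."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv1d(c_in, c_out, 1, rng, pad=0)
        self.convs = ModuleList([Conv1d(c_out, c_out, 3, rng) for _ in range(3)])
        self.norms = ModuleList([ChannelNorm(c_out) for _ in range(3)])

    def __call__(self, x: Tensor) -> Tensor:
        up = self.proj(upsample2(x))
        h = up
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h)).relu()
        return h + up


class QEEGDecoder(Module):
    """F: three deconvolution blocks with SRU skip connections, then two
    per-second fully connected layers (1x1 convolutions) and a band softmax."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dc = cfg.decoder_channels
        self.entry = Conv1d(cfg.d, dc, 1, rng, pad=0)
        self.blocks = ModuleList(
            [DeconvBlock(dc + cfg.d, dc, rng) for _ in range(3)])
        self.fc1 = Conv1d(dc, cfg.decoder_fc, 1, rng, pad=0)
        self.fc2 = Conv1d(cfg.decoder_fc, 4, 1, rng, pad=0)

    def __call__(self, sru_outputs: list[Tensor], use_skips: bool = True) -> Tensor:
        h = self.entry(sru_outputs[-1])
        for i, block in enumerate(self.blocks):
            skip = sru_outputs[min(i, len(sru_outputs) - 1)]
            if not use_skips:
                skip = Tensor(np.zeros_like(skip.data))
            skip = upsample_to(skip, h.data.shape[1])
            h = block(concat([h, skip], axis=0))
        h = self.fc2(self.fc1(h).relu())               # (4, seconds)
        return softmax(h, axis=0)


class PDBreathingModel(Module):
    """Complete model; one instance is one (uncalibrated) ensemble member."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = BreathingEncoder(cfg, rng)
        self.pool = AttentionPool(cfg, rng)
        self.classifier = MLP((cfg.d,) + cfg.classifier_widths, rng)
        self.severity = SeverityHeads(cfg, rng)
        self.decoder = QEEGDecoder(cfg, rng)
        self.discriminators = ModuleList()
        self._disc: dict[str, MLP] = {}
        for group in GROUPS:
            disc = MLP((cfg.d,) + cfg.disc_widths, rng)
            self.discriminators.append(disc)
            self._disc[group] = disc
        self.drop = Dropout(cfg.dropout, rng)
        self.eval()

    # -- forward pieces ------------------------------------------------------
    def encode(self, x: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        x = np.asarray(x, dtype=np.float64)
        min_len = self.cfg.total_stride * 8
        if x.size < min_len:
            raise ValueError(f"night of {x.size} samples is shorter than the "
                             f"minimum receptive field ({min_len} samples)")
        return self.encoder(Tensor(x.reshape(1, -1)))

    def forward_night(self, x: np.ndarray, parts: tuple[str, ...] | None = None,
                      with_qeeg: bool = True) -> dict:
        """Full forward pass for one preprocessed night.

        Returns tensors (graph-connected, usable for training) plus plain
        floats/arrays for inference use.
        """
        feats, sru_outputs = self.encode(x)
        g, attn = self.pool(feats)
        g = self.drop(g)
        logit = self.classifier(g).reshape(())
        out = {
            "features": feats, "sru_outputs": sru_outputs, "g": g,
            "attention": attn, "logit": logit,
            "score": float(_sigmoid(logit.data)),
            "severity": {},
        }
        for part in parts or self.severity.parts:
            out["severity"][part] = self.severity(g, part)
        if with_qeeg:
            out["qeeg_pred"] = self.decoder(sru_outputs)   # (4, seconds)
        return out

    def discriminate(self, g: Tensor, group: str, reverse: bool = False,
                     lam: float = 1.0) -> Tensor:
        if group not in self._disc:
            raise ValueError(f"unknown discriminator group {group!r}")
        h = grad_reverse(g, lam) if reverse else g
        return self._disc[group](h).reshape(())


def _sigmoid(z: float) -> float:
    from scipy.special import expit
    return float(expit(z))


# ---------------------------------------------------------------------------
# operation-level API (thin wrappers over the model)
# ---------------------------------------------------------------------------

def encode_breathing(model: PDBreathingModel, night: BreathingNight | np.ndarray
                     ) -> FeatureSequence:
    """E(x): feature sequence at one step per S samples (8 s at defaults)."""
    x = night.signal if isinstance(night, BreathingNight) else np.asarray(night)
    feats, sru_outputs = model.encode(x)
    return FeatureSequence(data=feats.data.T.copy(),
                           step_s=model.cfg.feature_step_s,
                           _tensor=feats, _sru_tensors=sru_outputs)


def attend_pool(model: PDBreathingModel, f: FeatureSequence
                ) -> tuple[GlobalFeature, AttentionProfile]:
    """G(E(x)): attention-weighted time average of the features."""
    tensor = f._tensor if f._tensor is not None else Tensor(f.data.T)
    g, attn = model.pool(tensor)
    return (GlobalFeature(vector=g.data.copy(), _tensor=g),
            AttentionProfile(weights=attn.data.copy(), step_s=f.step_s))


def classify_pd(model: PDBreathingModel, g: GlobalFeature) -> float:
    """M(G(E(x))): PD score in (0, 1); diagnosis = score > 0.5."""
    tensor = g._tensor if g._tensor is not None else Tensor(g.vector)
    return _sigmoid(model.classifier(tensor).reshape(()).data)


def predict_severity(model: PDBreathingModel, g: GlobalFeature,
                     part: str = "total") -> float:
    """N(G(E(x))): MDS-UPDRS estimate for the requested (sub)scale."""
    tensor = g._tensor if g._tensor is not None else Tensor(g.vector)
    return float(model.severity(tensor, part).data)


def predict_qeeg(model: PDBreathingModel, f: FeatureSequence,
                 use_skips: bool = True) -> np.ndarray:
    """F(E(x)): predicted per-second relative band powers, (seconds, 4)."""
    if f._sru_tensors is None:
        raise ValueError("feature sequence lacks SRU skip tensors; "
                         "obtain it from encode_breathing")
    pred = model.decoder(f._sru_tensors, use_skips=use_skips)
    return pred.data.T.copy()


def discriminate_domain(model: PDBreathingModel, g: GlobalFeature,
                        group: str) -> float:
    """D_group(g): probability the feature came from the belt domain."""
    tensor = g._tensor if g._tensor is not None else Tensor(g.vector)
    return _sigmoid(model.discriminate(tensor, group).data)


# ---------------------------------------------------------------------------
# bundles (ensemble members + calibration)
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Calibrated ensemble: member models with per-fold Platt scalars."""

    members: list[PDBreathingModel]
    calibrations: list[dict]         # {"A": float, "B": float, "fold_id": int}
    config: ModelConfig

    def __post_init__(self):
        if len(self.members) != len(self.calibrations):
            raise ValueError("one calibration per ensemble member required")

    def predict_night(self, x: np.ndarray, parts: tuple[str, ...] | None = None
                      ) -> dict:
        """Ensemble prediction: mean of the members' calibrated scores (and
        mean severity across members)."""
        scores, sevs, attns = [], {}, []
        for model, cal in zip(self.members, self.calibrations):
            out = model.forward_night(x, parts=parts, with_qeeg=False)
            z = float(out["logit"].data)
            scores.append(_sigmoid(cal["A"] * z + cal["B"]))
            for part, t in out["severity"].items():
                sevs.setdefault(part, []).append(float(t.data))
            attns.append(out["attention"].data.copy())
        return {
            "pd_score": float(np.mean(scores)),
            "member_scores": scores,
            "severity": {p: float(np.mean(v)) for p, v in sevs.items()},
            "attention": np.mean(attns, axis=0),
        }

    # -- serialization -------------------------------------------------------
    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(self.config.to_json())
        (directory / "calibration.json").write_text(json.dumps(self.calibrations))
        for i, model in enumerate(self.members):
            _nn.save_state(model.state_dict(), directory / f"member_{i}.npz")
        return directory

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        cfg = ModelConfig.from_json((directory / "config.json").read_text())
        calibrations = json.loads((directory / "calibration.json").read_text())
        members = []
        for i in range(len(calibrations)):
            model = PDBreathingModel(cfg)
            model.load_state_dict(_nn.load_state(directory / f"member_{i}.npz"))
            members.append(model)
        return cls(members=members, calibrations=calibrations, config=cfg)
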