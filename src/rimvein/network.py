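"""The 3-D patch network: convolutional encoder, mirrored decoder, and the
fully-connected label-dependency predictor.

The encoder maps a 4-channel 24^3 patch (T1w, FLAIR, EPI magnitude, EPI phase)
through five 3x3x3 convolutions (each followed by batch normalization and
ReLU; the last three additionally 2x2x2 max-pooled), so the spatial path is
24 -> 24 -> 24 -> 12 -> 6 -> 3.  Global average pooling over the final 3^3
grid yields a flat latent whose width equals the last convolution's channel
count.

The predictor encodes the biological dependency "a rim lesion or a central-vein
lesion is necessarily a lesion": lesion probability is produced first from the
128-wide hidden layer, then concatenated back onto a copy of that layer (129
units) before the final 2-unit sigmoid layer that outputs the rim (PRL) and
central-vein (CVS) probabilities.  The lesion node is not gradient-detached,
so the PRL/CVS losses can shape the lesion pathway.

``width_scale`` uniformly scales every channel/width for desk-scale training;
``width_scale=1`` reproduces the full architecture (channels 64, 128, 512,
2048, 2048; predictor widths 2048, 512, 128, 129, 2).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import (
    Adam,  # noqa: F401  (re-exported for callers configuring training)
    BatchNorm3d,
    Conv3d,
    Linear,
    Module,
    Tensor,
    concat,
    dropout,
    global_avg_pool3d,
    max_pool3d,
    no_grad,
    relu,
    sigmoid,
    upsample_nearest3d,
)

__all__ = [
    "NetworkConfig",
    "CandidatePrediction",
    "Encoder",
    "Decoder",
    "Predictor",
    "JointModel",
    "Autoencoder",
    "build_encoder",
    "build_decoder",
    "build_predictor",
    "build_joint_model",
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 4
    encoder_channels: tuple[int, ...] = (64, 128, 512, 2048, 2048)
    patch_size: int = 24
    dropout_rate: float = 0.2
    predictor_widths: tuple[int, ...] = (2048, 512, 128)
    width_scale: float = 1.0
    seed: int = 0

    def _scale(self, w: int) -> int:
        return max(1, int(round(w * self.width_scale)))

    @property
    def scaled_encoder_channels(self) -> tuple[int, ...]:
        return tuple(self._scale(c) for c in self.encoder_channels)

    @property
    def scaled_predictor_widths(self) -> tuple[int, ...]:
        return tuple(self._scale(w) for w in self.predictor_widths)

    @property
    def latent_width(self) -> int:
        return self.scaled_encoder_channels[-1]

    def validate(self) -> None:
        if self.patch_size % 8 != 0:
            raise ValueError(
                f"patch_size must be divisible by 8 (three 2x pools); got {self.patch_size}")
        if self.scaled_predictor_widths[0] != self.latent_width:
            raise ValueError("predictor input width must equal the final encoder width")

    def layer_summary(self) -> dict:
        """Architecture shapes, computed analytically (no parameters allocated)."""
        self.validate()
        p = self.patch_size
        spatial = [p, p, p, p // 2, p // 4, p // 8]
        w0, w1, w2 = self.scaled_predictor_widths
        return {
            "encoder_spatial_path": spatial,
            "encoder_channels": [self.in_channels, *self.scaled_encoder_channels],
            "predictor_widths": [w0, w1, w2, w2 + 1, 2],
        }

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        d["predictor_widths"] = tuple(d["predictor_widths"])
        return cls(**d)


@dataclass(frozen=True)
class CandidatePrediction:
    """Per-candidate probabilities for lesion, rim (PRL), and vein (CVS) status."""

    p_lesion: float
    p_prl: float
    p_cvs: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_lesion, self.p_prl, self.p_cvs])


class Encoder(Module):
    """Five 3x3x3 convolutions; max pooling after the last three."""

    POOL_AFTER = (2, 3, 4)  # 0-based layer indices

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        config.validate()
        channels = [config.in_channels, *config.scaled_encoder_channels]
        self.convs = [Conv3d(channels[i], channels[i + 1], rng) for i in range(5)]
        self.bns = [BatchNorm3d(c) for c in channels[1:]]

    def __call__(self, x: Tensor) -> Tensor:
        """Return the final feature grid (N, C5, 3, 3, 3)."""
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            x = relu(bn(conv(x)))
            if i in self.POOL_AFTER:
                x = max_pool3d(x)
        return x


class Decoder(Module):
    """Mirror of the encoder: upsample at the mirrored pool positions, then
    convolve with the reversed channel list.  The final convolution is linear
    (no BN/ReLU) so reconstructions of z-scored intensities can be negative."""

    UPSAMPLE_BEFORE = (0, 1, 2)

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        enc = [config.in_channels, *config.scaled_encoder_channels]
        rev = enc[::-1]  # e.g. [2048, 2048, 512, 128, 64, 4]
        self.convs = [Conv3d(rev[i], rev[i + 1], rng) for i in range(5)]
        self.bns = [BatchNorm3d(c) for c in rev[1:-1]]

    def __call__(self, x: Tensor) -> Tensor:
        for i, conv in enumerate(self.convs):
            if i in self.UPSAMPLE_BEFORE:
                x = upsample_nearest3d(x)
            x = conv(x)
            if i < 4:
                x = relu(self.bns[i](x))
        return x


class Predictor(Module):
    """Fully connected latent -> 512 -> 128, lesion head, 129-wide
    concatenation, final 2-unit sigmoid layer (PRL, CVS)."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        w0, w1, w2 = config.scaled_predictor_widths
        self.fc1 = Linear(w0, w1, rng)
        self.fc2 = Linear(w1, w2, rng)
        self.lesion_head = Linear(w2, 1, rng)
        self.out = Linear(w2 + 1, 2, rng)
        self.dropout_rate = config.dropout_rate

    def __call__(self, latent_grid: Tensor, rng: np.random.Generator) -> Tensor:
        h = global_avg_pool3d(latent_grid)
        h = dropout(relu(self.fc1(h)), self.dropout_rate, rng, self.training)
        h = dropout(relu(self.fc2(h)), self.dropout_rate, rng, self.training)
        p_lesion = sigmoid(self.lesion_head(h))
        z = concat([h, p_lesion], axis=1)  # 128 + 1 = 129 units
        p_pc = sigmoid(self.out(z))
        return concat([p_lesion, p_pc], axis=1)  # (N, 3): lesion, prl, cvs


class JointModel(Module):
    """Encoder + predictor; outputs (p_lesion, p_prl, p_cvs) per patch."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        config.validate()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.predictor = Predictor(config, rng)
        self.dropout_rng = np.random.default_rng(config.seed + 1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.predictor(self.encoder(x), self.dropout_rng)

    def forward(self, x: Tensor) -> Tensor:
        return self(x)

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Probabilities for a batch of patches (N, 4, s, s, s), eval mode."""
        was_training = self.training
        self.eval()
        with no_grad():
            out = self(Tensor(np.asarray(patches, np.float32))).data
        self.train(was_training)
        return out

    def predict_one(self, patch: np.ndarray) -> CandidatePrediction:
        p = self.predict(np.asarray(patch)[None])[0]
        return CandidatePrediction(float(p[0]), float(p[1]), float(p[2]))

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        arrays = {f"param:{k}": v.data for k, v in self.named_parameters()}
        arrays.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        np.savez(path, __config__=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8),
            __meta__=np.frombuffer(
                json.dumps(metadata or {}).encode(), dtype=np.uint8),
            **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "JointModel":
        with np.load(path) as z:
            config = NetworkConfig.from_json(bytes(z["__config__"]).decode())
            model = cls(config)
            params = dict(model.named_parameters())
            for key in z.files:
                if key.startswith("param:"):
                    params[key[6:]].data = z[key].copy()
            buffers = dict(model.named_buffers())
            for key in z.files:
                if key.startswith("buffer:"):
                    buffers[key[7:]][...] = z[key]
        return model

    def architecture_json(self) -> str:
        return json.dumps(self.config.layer_summary(), indent=2)


class Autoencoder(Module):
    """Encoder + mirrored decoder used for unsupervised pretraining."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        config.validate()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.decoder = Decoder(config, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))


def build_encoder(config: NetworkConfig, rng: np.random.Generator | None = None) -> Encoder:
    return Encoder(config, rng if rng is not None else np.random.default_rng(config.seed))


def build_decoder(config: NetworkConfig, rng: np.random.Generator | None = None) -> Decoder:
    return Decoder(config, rng if rng is not None else np.random.default_rng(config.seed))


def build_predictor(config: NetworkConfig, rng: np.random.Generator | None = None) -> Predictor:
    return Predictor(config, rng if rng is not None else np.random.default_rng(config.seed))


def build_joint_model(config: NetworkConfig) -> JointModel:
    return JointModel(config)
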