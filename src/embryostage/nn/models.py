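"""Stage classifier architectures.

Two variants mirror the two reference designs: an image-only classifier
(convolutional feature extractor plus one classification head) and a
fused image+time classifier.  In the fused variant the pooled image
feature is projected to the fusion width, combined with a linearly
embedded one-hot time vector as a two-token sequence through a single
self-attention encoder layer, and classified by a second head; the first
head reads the raw image features directly so gradients always reach the
backbone, and inference uses the fused head.

The ``tiny`` backbone is the default for tests; the ``reference``
backbone is a far larger convolutional stack (1280-dim features at a
380-pixel input, the scale of an EfficientNet-V2-L-class extractor)
that is buildable and trainable but not exercised at full size in CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..time_encoding import VECTOR_LENGTH
from . import autograd as ag
from .autograd import Tensor
from .layers import (
    Conv2d,
    GlobalAvgPool,
    Linear,
    Module,
    ReLU,
    Sequential,
    TransformerEncoderLayer,
)

__all__ = ["ModelConfig", "StageClassifier", "FusedStageClassifier", "build_model", "combined_loss"]


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny"
    image_size: int = 32
    num_classes: int = 17
    fused: bool = False
    fusion_hidden: int = 512
    fusion_heads: int = 4
    fusion_layers: int = 1
    time_vector_length: int = VECTOR_LENGTH

    def __post_init__(self) -> None:
        if self.backbone not in ("tiny", "reference"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.fused:
            if self.fusion_hidden % self.fusion_heads:
                raise ValueError("fusion_hidden must be divisible by fusion_heads")
            if self.fusion_layers < 1:
                raise ValueError("fusion_layers must be >= 1")


def _tiny_backbone(rng: np.random.Generator) -> tuple[Sequential, int]:
    # three stride-2 conv blocks, feature width 32
    return (
        Sequential(
            Conv2d(3, 8, 3, rng, stride=2, padding=1),
            ReLU(),
            Conv2d(8, 16, 3, rng, stride=2, padding=1),
            ReLU(),
            Conv2d(16, 32, 3, rng, stride=2, padding=1),
            ReLU(),
            GlobalAvgPool(),
        ),
        32,
    )


def _reference_backbone(rng: np.random.Generator) -> tuple[Sequential, int]:
    # deeper/wider stack standing in for an EfficientNet-V2-L-class
    # extractor: five downsampling stages ending in 1280-dim features
    widths = [32, 64, 96, 192, 256]
    blocks: list[Module] = []
    cin = 3
    for w in widths:
        blocks += [Conv2d(cin, w, 3, rng, stride=2, padding=1), ReLU(),
                   Conv2d(w, w, 3, rng, stride=1, padding=1), ReLU()]
        cin = w
    blocks += [Conv2d(cin, 1280, 1, rng), ReLU(), GlobalAvgPool()]
    return Sequential(*blocks), 1280


class StageClassifier(Module):
    """Image-only variant: backbone features, one classification head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        builder = _tiny_backbone if config.backbone == "tiny" else _reference_backbone
        self.backbone, self.feature_dim = builder(rng)
        self.head = Linear(self.feature_dim, config.num_classes, rng)

    def forward(self, images: np.ndarray | Tensor) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        return self.head(self.backbone(x))

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images).data


class FusedStageClassifier(Module):
    """Image + time variant with two classification heads."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        if not config.fused:
            raise ValueError("config.fused must be true for the fused classifier")
        self.config = config
        builder = _tiny_backbone if config.backbone == "tiny" else _reference_backbone
        self.backbone, self.feature_dim = builder(rng)
        h = config.fusion_hidden
        self.img_proj = Linear(self.feature_dim, h, rng)
        self.time_embed = Linear(config.time_vector_length, h, rng)
        self.encoder = [
            TransformerEncoderLayer(h, config.fusion_heads, rng)
            for _ in range(config.fusion_layers)
        ]
        self.head1 = Linear(self.feature_dim, config.num_classes, rng)
        self.head2 = Sequential(
            Linear(h, h // 2, rng), ReLU(), Linear(h // 2, config.num_classes, rng)
        )

    def forward(
        self, images: np.ndarray | Tensor, time_vectors: np.ndarray | Tensor
    ) -> tuple[Tensor, Tensor]:
        x = images if isinstance(images, Tensor) else Tensor(images)
        t = time_vectors if isinstance(time_vectors, Tensor) else Tensor(time_vectors)
        feats = self.backbone(x)  # (B, feature_dim)
        logits1 = self.head1(feats)
        tokens = ag.stack([self.img_proj(feats), self.time_embed(t)], axis=1)
        for layer in self.encoder:
            tokens = layer(tokens)
        logits2 = self.head2(ag.take_token(tokens, 0, axis=1))
        return logits1, logits2

    def predict_logits(self, images: np.ndarray, time_vectors: np.ndarray) -> np.ndarray:
        # inference reads the fused head
        return self.forward(images, time_vectors)[1].data


def build_model(
    config: ModelConfig, seed: int = 0
) -> StageClassifier | FusedStageClassifier:
    """Instantiate the configured architecture with seeded initialisation."""
    rng = np.random.default_rng(seed)
    if config.fused:
        return FusedStageClassifier(config, rng)
    return StageClassifier(config, rng)


def combined_loss(
    logits_head1: Tensor,
    logits_head2: Tensor,
    targets: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> Tensor:
    """Sum of the two heads' weighted cross-entropy losses."""
    if logits_head1.shape != logits_head2.shape:
        raise ValueError(
            f"head logit shapes differ: {logits_head1.shape} vs {logits_head2.shape}"
        )
    return ag.add(
        ag.cross_entropy(logits_head1, targets, class_weights),
        ag.cross_entropy(logits_head2, targets, class_weights),
    )
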