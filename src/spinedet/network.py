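"""A configurable encoder-decoder with the six landmark output pathways.

The topology mirrors the full-scale detector -- a U-shaped convolutional
encoder-decoder with skip connections, emitting one head per supervision
pathway (heatmap, center offset, polar corner offsets, CPIE, AVIE, and a
vertebral-line coordinate regressor) -- but the default ``toy`` preset is
small enough to train on a CPU in minutes, which is exactly its purpose:
demonstrating end-to-end that the composite objective carries a learning
signal from every pathway.  A ``resnet34-like`` preset expresses the
full-scale widths and depth; training it on real data is outside this
package's scope.

Two normalised coordinate channels are appended to the input image
(a CoordConv-style positional encoding): the grid heads supervise only a
handful of absolute pixel positions per image, and a purely
translation-equivariant stack has no way to regress absolute positions.

Runs on the package's own numpy autodiff core; no deep-learning
framework is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .annotations import N_VERTEBRAE
from .label_codec import CodecConfig, EncodedTargets, decode_landmarks, encode_all, topk_centers
from .losses import EPS, FOCAL_ALPHA, LossWeights

__all__ = ["ModelConfig", "LandmarkModel", "build_model", "train_toy", "decode_predictions"]

HEAD_CHANNELS = {
    "heatmap": 1,
    "center_offset": 2,
    "corner_polar": 8,
    "cpie": 2,
    "avie": 4,
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``encoder_blocks``/``encoder_strides`` define the downsampling
    stack; ``decoder_blocks`` upsample back (2x each, concatenating the
    encoder feature at the matching resolution) until the grid stride
    equals ``downsample_k``.  ``vil_samples`` and ``vil_lines`` size the
    vertebral-line regression head (2 coordinates per sample per enabled
    line, squashed to [0, 1] image-normalised units).
    """

    preset: str = "toy"
    encoder_blocks: tuple = (12, 24, 32, 48)
    encoder_strides: tuple = (1, 2, 2, 2)
    decoder_blocks: tuple = (32,)
    downsample_k: int = 4
    vil_samples: int = 100
    vil_lines: tuple = ("middle",)
    learning_rate: float = 5e-3

    @classmethod
    def toy(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def resnet34_like(cls) -> "ModelConfig":
        """Full-scale widths (not intended for CPU training)."""
        return cls(
            preset="resnet34-like",
            encoder_blocks=(64, 64, 128, 256, 512),
            encoder_strides=(4, 1, 2, 2, 2),
            decoder_blocks=(256, 128, 64),
            learning_rate=1.25e-4,
        )

    def final_stride(self) -> int:
        stride = 1
        for s in self.encoder_strides:
            stride *= s
        return stride >> len(self.decoder_blocks)


class LandmarkModel:
    """The U-shaped multi-head network as a parameter dict + forward."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.final_stride() != config.downsample_k:
            raise ValueError(
                f"encoder/decoder strides give output stride "
                f"{config.final_stride()}, but downsample_k is {config.downsample_k}"
            )
        self.config = config
        self.params: dict[str, ad.Tensor] = {}
        rng = np.random.default_rng(seed)
        in_ch = 3  # image + 2 coordinate channels
        for i, width in enumerate(config.encoder_blocks):
            self._add_conv(rng, f"enc{i}", in_ch, width)
            in_ch = width

        # resolution (stride) after each encoder block, for skip wiring
        strides, s = [], 1
        for st in config.encoder_strides:
            s *= st
            strides.append(s)
        self._enc_strides = strides

        ch = config.encoder_blocks[-1]
        s = strides[-1]
        self._skip_sources = []
        for j, width in enumerate(config.decoder_blocks):
            s //= 2
            skip = self._deepest_at_stride(s)
            skip_ch = config.encoder_blocks[skip] if skip is not None else 0
            self._skip_sources.append(skip)
            self._add_conv(rng, f"dec{j}", ch + skip_ch, width)
            ch = width

        for head, out_ch in HEAD_CHANNELS.items():
            self._add_conv(rng, f"head_{head}", ch, out_ch, head=True)
        n_vil = 2 * config.vil_samples * len(config.vil_lines)
        self._add_param(
            "vil_w", rng.standard_normal((ch, n_vil)) * np.sqrt(1.0 / ch)
        )
        self._add_param("vil_b", np.zeros(n_vil))

    # -- parameter helpers -------------------------------------------------
    def _add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = ad.Tensor(value, requires_grad=True)

    def _add_conv(self, rng, name: str, c_in: int, c_out: int, head: bool = False) -> None:
        scale = np.sqrt(2.0 / (c_in * 9))
        self._add_param(f"{name}_w", rng.standard_normal((c_out, c_in, 3, 3)) * scale)
        bias = np.zeros(c_out)
        if name == "head_heatmap":
            bias[:] = -2.19  # sigmoid(-2.19) ~ 0.1: a calm initial heatmap
        self._add_param(f"{name}_b", bias)

    def _deepest_at_stride(self, stride: int):
        best = None
        for i, s in enumerate(self._enc_strides):
            if s == stride:
                best = i
        return best

    def num_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=float)

    # -- forward -----------------------------------------------------------
    def _conv(self, name: str, x: ad.Tensor, stride: int = 1) -> ad.Tensor:
        return ad.conv2d(x, self.params[f"{name}_w"], self.params[f"{name}_b"], stride)

    def forward(self, images: np.ndarray) -> dict[str, ad.Tensor]:
        """Run the network on a (B, 1, H, W) image batch in [0, 1].

        Returns one tensor per head; grid heads have spatial size
        (H/k, W/k), the ``vil`` head a flat coordinate vector per image.
        """
        images = np.asarray(images, dtype=float)
        b, _, h, w = images.shape
        ys, xs = np.meshgrid(
            np.linspace(0.0, 1.0, h), np.linspace(0.0, 1.0, w), indexing="ij"
        )
        coords = np.broadcast_to(np.stack([xs, ys]), (b, 2, h, w))
        x = ad.Tensor(np.concatenate([images, coords], axis=1))

        feats = []
        for i, stride in enumerate(self.config.encoder_strides):
            x = self._conv(f"enc{i}", x, stride).relu()
            feats.append(x)

        for j, skip in enumerate(self._skip_sources):
            x = ad.upsample2x(x)
            if skip is not None:
                x = ad.concat([x, feats[skip]], axis=1)
            x = self._conv(f"dec{j}", x).relu()

        out = {name: self._conv(f"head_{name}", x) for name in HEAD_CHANNELS}
        out["heatmap"] = out["heatmap"].sigmoid()
        pooled = x.mean_axes((2, 3))                       # (B, C)
        out["vil"] = (pooled @ self.params["vil_w"] + self.params["vil_b"]).sigmoid()
        return out


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> LandmarkModel:
    """Construct a model with seed-reproducible initial parameters."""
    return LandmarkModel(config, seed=seed)


# ---------------------------------------------------------------------------
# Differentiable composite loss (mirrors spinedet.losses numerically)
# ---------------------------------------------------------------------------


def _masked_l1_t(pred: ad.Tensor, gt: np.ndarray, mask: np.ndarray) -> ad.Tensor:
    mask_full = np.broadcast_to(mask, pred.data.shape).astype(float)
    count = mask_full.sum()
    if count == 0:
        return ad.Tensor(0.0)
    return ((pred - ad.Tensor(gt)).abs() * ad.Tensor(mask_full)).sum() * (1.0 / count)


def _focal_t(pred: ad.Tensor, gt: np.ndarray) -> ad.Tensor:
    pos = (gt >= 1.0).astype(float)
    neg_w = (1.0 - gt) ** 4 * (1.0 - pos)
    n_peaks = max(pos.sum(), 1.0)
    p = pred.clamp(EPS, 1.0 - EPS)
    pos_term = ((1.0 - p).pow(FOCAL_ALPHA) * p.log()) * ad.Tensor(pos)
    neg_term = (p.pow(FOCAL_ALPHA) * (1.0 - p).log()) * ad.Tensor(neg_w)
    return (pos_term.sum() + neg_term.sum()) * (-1.0 / n_peaks)


def _wrapped_theta_l1_t(pred: ad.Tensor, gt: np.ndarray, mask: np.ndarray) -> ad.Tensor:
    mask_full = np.broadcast_to(mask, pred.data.shape).astype(float)
    count = mask_full.sum()
    if count == 0:
        return ad.Tensor(0.0)
    d = pred - ad.Tensor(gt)
    # wrap into (-pi, pi] via a stop-gradient shift of whole turns, then L1;
    # gradient is sign(wrapped difference) almost everywhere
    shift = 2.0 * np.pi * np.round(d.data / (2.0 * np.pi))
    wrapped = (d - ad.Tensor(shift)).abs()
    return (wrapped * ad.Tensor(mask_full)).sum() * (1.0 / count)


def _batch_loss(
    outputs: dict[str, ad.Tensor],
    targets: list[EncodedTargets],
    config: ModelConfig,
    codec: CodecConfig,
    weights: LossWeights,
) -> tuple[ad.Tensor, dict[str, float]]:
    hm_gt = np.stack([t.heatmap for t in targets])[:, None]
    center_gt = np.stack([t.center_offset for t in targets])
    center_mask = np.stack([t.center_mask for t in targets])[:, None]
    polar_gt = np.stack([t.corner_polar for t in targets])
    cpie_gt = np.stack([t.cpie for t in targets])
    cpie_mask = np.stack([t.cpie_mask for t in targets])[:, None]
    avie_gt = np.stack([t.avie for t in targets])
    avie_mask = np.stack([t.avie_mask for t in targets])[:, None]

    l_hm = _focal_t(outputs["heatmap"], hm_gt)
    l_center = _masked_l1_t(outputs["center_offset"], center_gt, center_mask)
    # radii take a plain L1, angles a wrapped L1; route via channel masks
    r_mask = np.zeros((1, 8, 1, 1))
    r_mask[:, 0:4] = 1.0
    theta_mask = 1.0 - r_mask
    l_r = _masked_l1_t(
        outputs["corner_polar"], polar_gt, center_mask * r_mask.astype(bool)
    )
    l_theta = _wrapped_theta_l1_t(
        outputs["corner_polar"], polar_gt, center_mask * theta_mask.astype(bool)
    )
    l_corner = l_r + l_theta
    l_cpie = _masked_l1_t(outputs["cpie"], cpie_gt, cpie_mask)
    l_avie = _masked_l1_t(outputs["avie"], avie_gt, avie_mask)

    scale = np.array([codec.input_width, codec.input_height], dtype=float)
    vil_gt = []
    for t in targets:
        flat = []
        for side in config.vil_lines:
            pts = getattr(t.vertebral_lines, side)
            flat.append((pts / scale).ravel())
        vil_gt.append(np.concatenate(flat))
    vil_gt = np.stack(vil_gt)
    l_vil = (outputs["vil"] - ad.Tensor(vil_gt)).abs().mean()

    total = (
        weights.alpha1 * l_hm
        + weights.alpha2 * l_center
        + weights.alpha3 * l_corner
        + weights.alpha4 * l_cpie
        + weights.alpha5 * l_avie
        + weights.alpha6 * l_vil
    )
    terms = {
        "L_hm": float(l_hm.data),
        "L_center": float(l_center.data),
        "L_corner": float(l_corner.data),
        "L_CPIE": float(l_cpie.data),
        "L_AVIE": float(l_avie.data),
        "L_VIL": float(l_vil.data),
        "L_total": float(total.data),
    }
    return total, terms


class _Adam:
    def __init__(self, params: dict[str, ad.Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _codec_for(cases, config: ModelConfig) -> CodecConfig:
    from .vertebral_lines import SplineConfig

    h, w = cases[0].annotation.image_height, cases[0].annotation.image_width
    return CodecConfig(
        downsample_k=config.downsample_k,
        input_height=h,
        input_width=w,
        spline=SplineConfig(
            n_samples=config.vil_samples,
            lines_enabled=frozenset(config.vil_lines),
        ),
    )


def train_toy(
    model: LandmarkModel,
    cases,
    steps: int,
    seed: int = 0,
    weights: LossWeights = LossWeights(),
    learning_rate: float | None = None,
) -> tuple[LandmarkModel, list[float]]:
    """Full-batch Adam training on a handful of simulated cases.

    Encodes every case's supervision targets, then optimises the
    composite loss for ``steps`` iterations, returning the per-step total
    loss trace.  ``steps=0`` leaves the model untouched.  A non-finite
    loss aborts with the offending step's term values.  Deterministic for
    a fixed model seed (full-batch, no stochastic layers).
    """
    if not cases:
        raise ValueError("need at least one simulated case")
    del seed  # training itself is deterministic; kept for interface parity
    codec = _codec_for(cases, model.config)
    targets = [encode_all(c.annotation, codec) for c in cases]
    images = np.stack(
        [c.image.astype(float)[None] / 255.0 for c in cases]
    )
    trace: list[float] = []
    if steps == 0:
        return model, trace
    opt = _Adam(model.params, learning_rate or model.config.learning_rate)
    for step in range(steps):
        opt.zero_grad()
        outputs = model.forward(images)
        loss, terms = _batch_loss(outputs, targets, model.config, codec, weights)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at step {step}: {terms}"
            )
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return model, trace


def decode_predictions(
    model: LandmarkModel, image: np.ndarray, codec: CodecConfig, k_points: int = N_VERTEBRAE
) -> np.ndarray:
    """Run the model on one image and decode (k_points, 4, 2) landmarks."""
    out = model.forward(image.astype(float)[None, None] / 255.0)
    heatmap = out["heatmap"].data[0, 0]
    center_offset = out["center_offset"].data[0]
    corner_polar = out["corner_polar"].data[0]
    centers = topk_centers(heatmap, center_offset, codec, k_points)
    return decode_landmarks(centers, corner_polar, codec)
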