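"""Desk-scale multi-head segmentation network.

A compact U-Net-style encoder–decoder with ``m_heads`` parallel 1x1 output
projections sharing one backbone. The heads emulate a model that natively
produces several candidate masks per image, which is what makes the
ensemble-variance uncertainty map nondegenerate. The primary probability
map — the one fed to the loss, the entropy map, the conformal scores and
Dice — is the arithmetic mean of the head probabilities.

Everything runs on CPU in float64 numpy; construction is deterministic from
the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["SegModelSpec", "MultiHeadUNet", "build_model", "predict_probs"]


@dataclass(frozen=True)
class SegModelSpec:
    """Architecture and initialisation of the fixture network.

    in_channels : image channels (1 for grayscale).
    base_width : feature channels at the first encoder level; doubles per level.
    depth : number of 2x downsampling levels; inputs must be divisible by 2**depth.
    m_heads : number of parallel output heads (>= 2 for the variance method).
    seed : weight-initialisation seed; identical spec+seed -> identical weights.
    head_init : "random" (default; heads differ, variance is informative) or
        "zero" (all logits start at 0, probabilities at 0.5).
    head_bias : initial output-head bias (ignored for head_init="zero").
        Segmentation foregrounds are small, so the bias starts at the logit
        of a ~0.1 foreground prior; starting near the class prior prevents
        the early all-background collapse that drives sigmoid heads into
        dead saturation on imbalanced masks.
    """

    in_channels: int = 1
    base_width: int = 8
    depth: int = 2
    m_heads: int = 3
    seed: int = 0
    head_init: str = "random"
    head_bias: float = -2.0

    def __post_init__(self):
        if self.in_channels < 1 or self.base_width < 1 or self.depth < 1:
            raise ValueError("in_channels, base_width and depth must be >= 1")
        if self.m_heads < 1:
            raise ValueError("m_heads must be >= 1")
        if self.head_init not in ("random", "zero"):
            raise ValueError("head_init must be 'random' or 'zero'")


class MultiHeadUNet:
    """U-Net-style encoder–decoder with M parallel output heads.

    forward(x) maps (N, C, H, W) images to (N, M, H, W) logits; backward
    propagates a logit gradient back to every parameter.
    """

    def __init__(self, spec: SegModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {}
        w, d = spec.base_width, spec.depth
        c_in = spec.in_channels
        for lvl in range(d):
            c_out = w * 2 ** lvl
            self._add_conv(rng, f"enc{lvl}", c_in, c_out, 3)
            c_in = c_out
        self._add_conv(rng, "bottleneck", c_in, w * 2 ** d, 3)
        for lvl in reversed(range(d)):
            c_skip = w * 2 ** lvl
            c_above = w * 2 ** (lvl + 1)
            self._add_conv(rng, f"dec{lvl}", c_above + c_skip, c_skip, 3)
        for m in range(spec.m_heads):
            zero = spec.head_init == "zero"
            self._add_conv(rng, f"head{m}", w, 1, 1, zero=zero,
                           bias=0.0 if zero else spec.head_bias)

    def _add_conv(self, rng, name, c_in, c_out, k, zero=False, bias=0.0):
        fan_in = c_in * k * k
        if zero:
            weight = np.zeros((c_out, c_in, k, k))
        else:
            weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.params[f"{name}.w"] = weight
        self.params[f"{name}.b"] = np.full(c_out, float(bias))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _conv(self, name, x, caches):
        y, cache = nn.conv_forward(x, self.params[f"{name}.w"], self.params[f"{name}.b"])
        caches[name] = cache
        return y

    def forward(self, x: np.ndarray):
        """Return (logits (N, M, H, W), cache for backward)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4:
            raise ValueError("expected a (N, C, H, W) batch")
        d = self.spec.depth
        h, w = x.shape[2], x.shape[3]
        if h % 2 ** d or w % 2 ** d:
            raise ValueError(
                f"spatial size {h}x{w} is not divisible by 2**depth = {2 ** d}"
            )
        caches: dict = {}
        relu_masks: dict = {}
        skips = []
        hcur = x
        for lvl in range(d):
            hcur, relu_masks[f"enc{lvl}"] = nn.relu_forward(
                self._conv(f"enc{lvl}", hcur, caches))
            skips.append(hcur)
            hcur = nn.avgpool2_forward(hcur)
        hcur, relu_masks["bottleneck"] = nn.relu_forward(
            self._conv("bottleneck", hcur, caches))
        for lvl in reversed(range(d)):
            up = nn.upsample2_forward(hcur)
            cat = np.concatenate([up, skips[lvl]], axis=1)
            caches[f"cat{lvl}"] = (up.shape[1], skips[lvl].shape[1])
            hcur, relu_masks[f"dec{lvl}"] = nn.relu_forward(
                self._conv(f"dec{lvl}", cat, caches))
        logits = np.concatenate(
            [self._conv(f"head{m}", hcur, caches) for m in range(self.spec.m_heads)],
            axis=1,
        )
        cache = {"caches": caches, "relu": relu_masks}
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt every parameter, given dL/dlogits."""
        caches, relu_masks = cache["caches"], cache["relu"]
        d = self.spec.depth
        grads: dict[str, np.ndarray] = {}
        dh = None
        for m in range(self.spec.m_heads):
            dxm, dw, db = nn.conv_backward(dlogits[:, m:m + 1], caches[f"head{m}"])
            grads[f"head{m}.w"], grads[f"head{m}.b"] = dw, db
            dh = dxm if dh is None else dh + dxm
        dskips = [None] * d
        for lvl in range(d):
            dh = nn.relu_backward(dh, relu_masks[f"dec{lvl}"])
            dcat, dw, db = nn.conv_backward(dh, caches[f"dec{lvl}"])
            grads[f"dec{lvl}.w"], grads[f"dec{lvl}.b"] = dw, db
            c_up, _ = caches[f"cat{lvl}"]
            dskips[lvl] = dcat[:, c_up:]
            dh = nn.upsample2_backward(dcat[:, :c_up])
        dh = nn.relu_backward(dh, relu_masks["bottleneck"])
        dh, grads["bottleneck.w"], grads["bottleneck.b"] = nn.conv_backward(
            dh, caches["bottleneck"])
        for lvl in reversed(range(d)):
            dh = nn.avgpool2_backward(dh) + dskips[lvl]
            dh = nn.relu_backward(dh, relu_masks[f"enc{lvl}"])
            dh, grads[f"enc{lvl}.w"], grads[f"enc{lvl}.b"] = nn.conv_backward(
                dh, caches[f"enc{lvl}"])
        return grads

    def head_probs(self, x: np.ndarray) -> np.ndarray:
        """(N, M, H, W) sigmoid probabilities, checked finite."""
        logits, _ = self.forward(x)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("model produced non-finite activations")
        return nn.sigmoid(logits)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k][...] = state[k]

    def save(self, path) -> None:
        np.savez(str(path), **self.params)

    def load(self, path) -> None:
        with np.load(str(path)) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(spec: SegModelSpec, method: str | None = None) -> MultiHeadUNet:
    """Construct the network; rejects ``m_heads < 2`` when the variance
    uncertainty method is requested."""
    if method == "variance" and spec.m_heads < 2:
        raise ValueError("the variance method requires m_heads >= 2")
    return MultiHeadUNet(spec)


def predict_probs(model: MultiHeadUNet, image):
    """Head probabilities and the primary (mean-of-heads) probability map.

    ``image`` is a single (H, W) or (C, H, W) image; returns
    ``(multi (M, H, W), primary (H, W))``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3:
        raise ValueError("expected a single (H, W) or (C, H, W) image")
    heads = model.head_probs(img[None])[0]
    return heads, heads.mean(axis=0)
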