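"""Class activation maps at a single layer under selectable weighting schemes.

A CAM is a linearly weighted combination of a layer's channel activation maps

    L^c = ReLU( combine_k( alpha_k^c, A_k^l ) ),

upsampled bilinearly to input resolution.  The weighting alpha distinguishes
the schemes: gradient-based (GradCAM family), perturbation-based (ScoreCAM,
AblationCAM), principal-component (EigenCAM) and the RandomCAM control.
Rectification is applied before upsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .model_graph import LayerRef, capture, resolve_target
from .nn import Sequential, softmax

logger = logging.getLogger(__name__)

_EPS = 1e-8


@dataclass(frozen=True)
class WeightScheme:
    """A named channel-weighting rule and its computational requirements."""

    name: str
    requires_gradients: bool
    requires_forward_evals: bool = False
    rng_seed: int = 0


SCHEMES: dict[str, WeightScheme] = {
    "gradcam": WeightScheme("gradcam", True),
    "gradcampp": WeightScheme("gradcampp", True),
    "xgradcam": WeightScheme("xgradcam", True),
    "hirescam": WeightScheme("hirescam", True),
    "gradcam_elementwise": WeightScheme("gradcam_elementwise", True),
    "layercam": WeightScheme("layercam", True),
    "eigencam": WeightScheme("eigencam", False),
    "eigengradcam": WeightScheme("eigengradcam", True),
    "scorecam": WeightScheme("scorecam", False, requires_forward_evals=True),
    "ablationcam": WeightScheme("ablationcam", False, requires_forward_evals=True),
    "randomcam": WeightScheme("randomcam", False),
}


def get_scheme(name: str, rng_seed: int = 0) -> WeightScheme:
    try:
        scheme = SCHEMES[name]
    except KeyError:
        raise KeyError(
            f"unknown CAM scheme {name!r}; supported: {', '.join(sorted(SCHEMES))}"
        ) from None
    if scheme.name == "randomcam":
        return WeightScheme("randomcam", False, False, rng_seed)
    return scheme


@dataclass
class CAMFrame:
    """One 2-D activation map for a (layer, scheme, class) triple.

    ``pre_relu_map`` is the signed map at the layer's native resolution;
    ``raw_map`` is its rectification upsampled to input resolution.
    """

    layer: LayerRef
    method: str
    target_class: int
    raw_map: np.ndarray
    pre_relu_map: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.raw_map)):
            raise ValueError("CAM map contains non-finite values")
        if (self.raw_map < 0).any():
            raise ValueError("rectified CAM map must be non-negative")


class ForwardOracle:
    """Forward-evaluation closures for perturbation schemes.

    ``score_masked_input`` runs the full model on the image modulated by a
    unit-scaled mask; ``score_ablated`` re-runs the tail of the network after
    zeroing one channel of the captured layer activation.  Scores are
    pre-softmax logits of the target class.
    """

    def __init__(self, model: Sequential, image: np.ndarray, layer: LayerRef,
                 activation: np.ndarray, target: int):
        self.model = model
        self.image = np.asarray(image, dtype=float)
        self.layer = layer
        self.activation = activation  # (1, C, H, W)
        self.target = target

    def baseline_score(self) -> float:
        return float(self.model.forward(self.image)[0, self.target])

    def score_masked_input(self, mask: np.ndarray) -> float:
        masked = self.image * mask  # mask broadcast over channels
        return float(self.model.forward(masked)[0, self.target])

    def score_ablated(self, channel: int) -> float:
        ablated = self.activation.copy()
        ablated[:, channel] = 0.0
        out = self.model.forward_from(self.layer.raw_index, ablated)
        return float(out[0, self.target])


def upsample(map2d: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear interpolation of a 2-D map to ``out_shape``."""
    map2d = np.asarray(map2d, dtype=float)
    h, w = map2d.shape
    oh, ow = int(out_shape[0]), int(out_shape[1])
    if oh <= 0 or ow <= 0:
        raise ValueError(f"target shape {out_shape} must be positive")
    if (h, w) == (oh, ow):
        return map2d.copy()
    rows = np.linspace(0.0, h - 1.0, oh) if h > 1 else np.zeros(oh)
    cols = np.linspace(0.0, w - 1.0, ow) if w > 1 else np.zeros(ow)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(map2d, [rr, cc], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# channel weighting


def _unit_scale(a: np.ndarray) -> np.ndarray:
    mn, mx = a.min(), a.max()
    if mx == mn:
        return np.zeros_like(a)
    return (a - mn) / (mx - mn)


def channel_weights(scheme: WeightScheme, activations: np.ndarray,
                    gradients: np.ndarray | None = None,
                    oracle: ForwardOracle | None = None):
    """Per-channel (or per-pixel) CAM weights for one layer.

    Returns ``(kind, value)`` where ``kind`` is ``"channel"`` (``value`` is a
    length-C vector combined as ``sum_k alpha_k A_k``), ``"pixel"`` (``value``
    is a C×H×W weight tensor combined as ``sum_k W_k * A_k``) or ``"map"``
    (``value`` is the finished pre-ReLU 2-D map, for schemes that are not a
    weighted sum of raw channels).
    """
    a = np.asarray(activations, dtype=float)
    g = None if gradients is None else np.asarray(gradients, dtype=float)
    name = scheme.name
    if scheme.requires_gradients and g is None:
        raise ValueError(f"scheme {name!r} requires gradients")

    if name == "gradcam":
        return "channel", g.mean(axis=(1, 2))
    if name == "gradcampp":
        g2, g3 = g * g, g * g * g
        denom = 2.0 * g2 + (a * g3).sum(axis=(1, 2), keepdims=True) + _EPS
        w = g2 / denom
        return "channel", (w * np.maximum(g, 0.0)).sum(axis=(1, 2))
    if name == "xgradcam":
        norm = a.sum(axis=(1, 2), keepdims=True) + _EPS
        return "channel", ((a / norm) * g).sum(axis=(1, 2))
    if name == "hirescam":
        return "map", (g * a).sum(axis=0)
    if name == "gradcam_elementwise":
        return "map", np.maximum(g * a, 0.0).sum(axis=0)
    if name == "layercam":
        return "pixel", np.maximum(g, 0.0)
    if name in ("eigencam", "eigengradcam"):
        basis = a if name == "eigencam" else g * a
        c, h, w_ = basis.shape
        mat = basis.reshape(c, h * w_)
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        v = vt[0]
        if v.sum() < 0:
            v = -v
        return "map", v.reshape(h, w_)
    if name == "scorecam":
        if oracle is None:
            raise ValueError("scorecam requires a forward-evaluation oracle")
        c = a.shape[0]
        in_hw = oracle.image.shape[-2:]
        if all(ch.max() == ch.min() for ch in a):
            # degenerate all-constant activations: no informative masks
            return "channel", np.zeros(c)
        scores = np.empty(c)
        for k in range(c):
            mask = _unit_scale(upsample(a[k], in_hw))
            scores[k] = oracle.score_masked_input(mask)
        return "channel", softmax(scores)
    if name == "ablationcam":
        if oracle is None:
            raise ValueError("ablationcam requires a forward-evaluation oracle")
        y0 = oracle.baseline_score()
        c = a.shape[0]
        alpha = np.empty(c)
        for k in range(c):
            alpha[k] = (y0 - oracle.score_ablated(k)) / (abs(y0) + _EPS)
        return "channel", alpha
    if name == "randomcam":
        rng = np.random.default_rng(scheme.rng_seed)
        return "channel", rng.uniform(-1.0, 1.0, size=a.shape[0])
    raise KeyError(f"unknown CAM scheme {name!r}; supported: {', '.join(sorted(SCHEMES))}")


def _combine(kind: str, value: np.ndarray, a: np.ndarray) -> np.ndarray:
    if kind == "channel":
        return np.tensordot(value, a, axes=(0, 0))
    if kind == "pixel":
        return (value * a).sum(axis=0)
    return value  # "map": already combined


def compute_cam(model: Sequential, image: np.ndarray, layer: LayerRef,
                target, scheme: WeightScheme | str,
                reshape_rule: tuple[int, int] | None = None) -> CAMFrame:
    """Compute one CAM frame at ``layer`` for ``target`` under ``scheme``.

    1-D (``vector1d``) layers are refused: a 2-D rendering of a 1-D vector is
    meaningless and such frames are filtered out of the animation.  Token
    sequences are mapped only when a token-grid ``reshape_rule`` (H, W) is
    supplied.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if layer.shape_class == "vector1d":
        raise ValueError(
            f"layer {layer.name!r} has a 1-D output and is filtered out of CAM rendering"
        )
    if layer.shape_class == "token_sequence" and reshape_rule is None:
        raise ValueError(
            f"layer {layer.name!r} is a token sequence; supply a token-grid reshape rule"
        )

    acts = capture(model, image, [layer], target=target,
                   need_gradients=scheme.requires_gradients)
    tgt = acts.target_class
    a = acts.activation(layer)[0]
    g = acts.gradient(layer)
    if scheme.requires_gradients:
        if layer.index in acts.gradient_free:
            raise ValueError(
                f"layer {layer.name!r} has no gradient path; scheme {scheme.name!r} needs one"
            )
        g = g[0]
    if layer.shape_class == "token_sequence":
        th, tw = reshape_rule
        # (tokens, embed) -> (embed, th, tw): embedding channels as map channels
        a = a.reshape(th, tw, -1).transpose(2, 0, 1)
        if g is not None:
            g = g.reshape(th, tw, -1).transpose(2, 0, 1)

    oracle = None
    if scheme.requires_forward_evals:
        oracle = ForwardOracle(model, np.asarray(image, dtype=float), layer,
                               acts.activation(layer), tgt)
    kind, value = channel_weights(scheme, a, g, oracle)
    pre_relu = _combine(kind, value, a)
    in_hw = tuple(model.input_shape[-2:])
    raw = upsample(np.maximum(pre_relu, 0.0), in_hw)
    # bilinear interpolation of a non-negative map can introduce tiny negative
    # round-off; clamp to keep the non-negativity invariant exact
    raw = np.maximum(raw, 0.0)
    return CAMFrame(layer=layer, method=scheme.name, target_class=tgt,
                    raw_map=raw, pre_relu_map=pre_relu)


def resolve_target_for_image(model: Sequential, image: np.ndarray, target) -> int:
    """Resolve 'argmax' once against the unperturbed image (then hold fixed)."""
    return resolve_target(model.forward(image), target)
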