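"""Layer enumeration, activation/gradient capture and parameter profiling.

A "target layer" is any leaf layer whose forward output is a numeric tensor,
excluding pure pass-throughs (identity, inference-mode dropout).  Layers are
addressed by :class:`LayerRef`, whose ``index`` runs 0..N-1 over the target
layers in forward execution order — the layer axis along which the per-layer
CAM sequence and the layer-wise ROAD series are indexed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Sequential, softmax

logger = logging.getLogger(__name__)

SHAPE_CLASSES = ("spatial2d", "vector1d", "token_sequence")


class EmptyEnumerationError(RuntimeError):
    """The model exposes no qualifying target layers."""


@dataclass(frozen=True)
class LayerRef:
    """An addressable layer: enumeration ordinal, dotted name, output-shape class."""

    index: int
    name: str
    shape_class: str
    param_count: int
    #: position within the underlying container's layer list (implementation handle)
    raw_index: int = -1

    def to_dict(self) -> dict:
        return {"index": self.index, "name": self.name,
                "shape_class": self.shape_class, "param_count": self.param_count}


@dataclass
class ActivationSet:
    """Per-layer activations and (optionally) gradients of the class logit."""

    activations: dict[int, np.ndarray]
    gradients: dict[int, np.ndarray | None] = field(default_factory=dict)
    gradient_free: set[int] = field(default_factory=set)
    target_class: int | None = None
    logits: np.ndarray | None = None

    def activation(self, ref: LayerRef) -> np.ndarray:
        return self.activations[ref.index]

    def gradient(self, ref: LayerRef) -> np.ndarray | None:
        return self.gradients.get(ref.index)


@dataclass
class ModelProfile:
    model_name: str
    total_params: int
    n_target_layers: int
    per_layer: list[LayerRef]

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "total_params": self.total_params,
            "n_target_layers": self.n_target_layers,
            "layers": [ref.to_dict() for ref in self.per_layer],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def classify_output_shape(shape: tuple[int, ...]) -> str:
    """Classify a layer output shape for rendering purposes.

    ``spatial2d``: at least two trailing spatial axes of extent > 1 (rank >= 4,
    batch x channels x H x W) — renderable as a 2-D map.  ``token_sequence``:
    rank-3 batch x tokens x embedding outputs (attention blocks), renderable
    only given a token-grid reshape rule.  ``vector1d``: everything compressed
    to a 1-D representation; such layers are filtered out of rendering because
    a 2-D visualization of a 1-D vector is meaningless.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) == 0:
        raise ValueError("empty shape cannot be classified")
    if any(s <= 0 for s in shape):
        raise ValueError(f"shape {shape} has a zero or negative extent")
    if len(shape) <= 2:
        return "vector1d"
    if len(shape) == 3:
        return "token_sequence"
    spatial = shape[2:]
    if sum(1 for s in spatial if s > 1) >= 2:
        return "spatial2d"
    return "vector1d"


def enumerate_target_layers(model: Sequential, include_filter=None) -> list[LayerRef]:
    """Enumerate a model's target layers in forward execution order.

    A probe forward pass with a zero dummy input assigns each layer its
    output-shape class.  Pass-through layers are excluded; ``include_filter``
    (a predicate on ``(name, layer)``) further restricts the census.  Layers
    executed more than once per forward pass contribute one entry, taken from
    their final invocation.
    """
    dummy = np.zeros((1,) + tuple(model.input_shape))
    _, acts = model.forward_collect(dummy)

    # weight-shared layers: keep only the last invocation
    last_pos: dict[int, int] = {}
    for pos, (name, layer) in enumerate(model.layers):
        if id(layer) in last_pos:
            logger.warning("layer %r executed more than once per forward pass; "
                           "using its last invocation", name)
        last_pos[id(layer)] = pos

    refs: list[LayerRef] = []
    for pos, (name, layer) in enumerate(model.layers):
        if last_pos[id(layer)] != pos:
            continue
        if not layer.enumerable:
            continue
        if include_filter is not None and not include_filter(name, layer):
            continue
        out = acts[pos]
        if not isinstance(out, np.ndarray) or not np.issubdtype(out.dtype, np.number):
            continue
        refs.append(LayerRef(index=len(refs), name=name,
                             shape_class=classify_output_shape(out.shape),
                             param_count=layer.param_count, raw_index=pos))
    if not refs:
        raise EmptyEnumerationError("model has no qualifying target layers")
    return refs


def resolve_target(logits: np.ndarray, target) -> int:
    """Resolve a class spec (integer index or ``"argmax"``) against 1-sample logits."""
    n_classes = logits.shape[-1]
    if isinstance(target, str):
        if target != "argmax":
            raise ValueError(f"unknown target spec {target!r}; use an int or 'argmax'")
        return int(np.argmax(logits.reshape(-1)))
    t = int(target)
    if not 0 <= t < n_classes:
        raise IndexError(f"target class {t} out of range for a {n_classes}-class model")
    return t


def capture(model: Sequential, image: np.ndarray, layers: list[LayerRef],
            target="argmax", need_gradients: bool = False) -> ActivationSet:
    """One forward (and optional backward) pass collecting per-layer tensors.

    Gradients are of the pre-softmax class logit ``y^c`` with respect to each
    requested layer's output.  The model is run in inference mode and is left
    unmodified.  Layers with no gradient path to the logit are recorded in
    ``gradient_free`` rather than silently zeroed.
    """
    logits, acts = model.forward_collect(image)
    tgt = resolve_target(logits, target)
    result = ActivationSet(activations={}, target_class=tgt, logits=logits.copy())
    for ref in layers:
        result.activations[ref.index] = acts[ref.raw_index].copy()
    if need_gradients:
        seed_grad = np.zeros_like(logits)
        seed_grad[:, tgt] = 1.0
        grads = model.backward_collect(seed_grad)
        for ref in layers:
            g = grads[ref.raw_index]
            if g is None:
                result.gradient_free.add(ref.index)
                result.gradients[ref.index] = None
                logger.warning("layer %r has no gradient path to the class logit", ref.name)
            else:
                result.gradients[ref.index] = g.copy()
                if g.shape != result.activations[ref.index].shape:
                    raise AssertionError("gradient/activation shape mismatch")
    return result


def predict_proba(model: Sequential, image: np.ndarray) -> np.ndarray:
    """Post-softmax class probabilities for a single image."""
    return softmax(model.forward(image, train=False))[0]


def profile(model, model_name: str = "model") -> ModelProfile:
    """Exact parameter census: total and per-leaf-layer counts.

    Accepts either a runnable :class:`~camroad.nn.Sequential` (probed with a
    forward pass) or a static architecture spec from the model zoo registry
    (an object with ``leaves`` and ``total_params``).
    """
    if hasattr(model, "leaves"):  # static zoo architecture spec
        refs = [LayerRef(index=i, name=leaf.name, shape_class=leaf.shape_class,
                         param_count=leaf.param_count, raw_index=i)
                for i, leaf in enumerate(model.leaves)]
        return ModelProfile(model_name=getattr(model, "name", model_name),
                            total_params=int(model.total_params),
                            n_target_layers=len(refs), per_layer=refs)
    refs = enumerate_target_layers(model)
    return ModelProfile(model_name=model_name, total_params=model.total_params,
                        n_target_layers=len(refs), per_layer=refs)
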