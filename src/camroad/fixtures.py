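"""Synthetic two-class lesion imagery and a tiny trainable CNN test-bed.

Emulates a malignant-vs-normal ultrasound classification task at desk scale:
single-channel 64x64 images with a speckle-textured background, where the
positive class carries a filled elliptical lesion of known support.  The
ground-truth mask makes CAM localization quantifiable, and the paired CNN
(three conv-norm-relu-pool blocks, global average pooling, linear head) is
small enough to train deterministically in seconds, so every introspection
operation can be exercised end-to-end with no downloads or pretrained
weights.

Speckle is modelled as Gaussian-smoothed multiplicative noise — visually
ultrasound-like while remaining fully parameterized; no augmentations are
applied.  Everything here is reproducible from (parameters, seed) alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import nn

IMAGE_SIZE = 64
BACKGROUND_LEVEL = 0.25


@dataclass
class SyntheticSample:
    """One image with its class label and ground-truth lesion support."""

    image: np.ndarray  # (64, 64) float in [0, 1]
    label: int  # 0 = normal, 1 = lesion
    truth_mask: np.ndarray  # boolean (64, 64)

    def __post_init__(self):
        has_lesion = bool(self.truth_mask.any())
        if has_lesion != (self.label == 1):
            raise ValueError("label must be 1 iff the truth mask is non-empty")


@dataclass
class FixtureSplit:
    """Disjoint train/val/test sample lists in 80-10-10 proportions."""

    train: list[SyntheticSample]
    val: list[SyntheticSample]
    test: list[SyntheticSample]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def _ellipse(rng: np.random.Generator, size: int, center_rng: tuple[float, float],
             a_rng: tuple[float, float], b_rng: tuple[float, float]) -> np.ndarray:
    cx, cy = rng.uniform(center_rng[0] * size, center_rng[1] * size, 2)
    a = rng.uniform(*a_rng)
    b = rng.uniform(*b_rng)
    theta = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def make_sample(label: int, contrast: float, noise_level: float,
                rng: np.random.Generator, size: int = IMAGE_SIZE) -> SyntheticSample:
    """One synthetic image; label 1 carries a bright compact lesion.

    Both classes share class-independent anatomy-like clutter — bright
    elongated fascia bands and dark shadow bands — so the lesion (a compact
    filled ellipse raised by ``contrast``) is the only class evidence, not
    overall brightness.  Clutter never overlaps lesion support, so in the
    noiseless limit lesion pixels sit exactly at background + contrast.
    """
    mask = _ellipse(rng, size, (0.3, 0.7), (8.0, 16.0), (8.0, 16.0)) if label == 1 \
        else np.zeros((size, size), dtype=bool)
    clean = np.full((size, size), BACKGROUND_LEVEL)
    for _ in range(rng.integers(1, 4)):  # bright fascia-like streaks
        band = _ellipse(rng, size, (0.05, 0.95), (2.0, 5.0), (9.0, 22.0))
        clean[band & ~mask] += rng.uniform(0.1, 0.3)
    for _ in range(rng.integers(0, 3)):  # dark acoustic-shadow streaks
        band = _ellipse(rng, size, (0.05, 0.95), (2.5, 5.0), (9.0, 22.0))
        clean[band & ~mask] -= rng.uniform(0.05, 0.15)
    clean = np.clip(clean, 0.05, None)
    clean[mask] = BACKGROUND_LEVEL + contrast
    if noise_level > 0:
        gain = 1.0 + noise_level * rng.uniform(-0.5, 0.5)  # per-image gain jitter
        field = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=1.5)
        field /= max(field.std(), 1e-12)
        img = clean * gain * np.clip(1.0 + noise_level * field, 0.0, None)
    else:
        img = clean
    return SyntheticSample(image=np.clip(img, 0.0, 1.0), label=label, truth_mask=mask)


def make_dataset(n: int = 400, contrast: float = 0.4, noise_level: float = 0.15,
                 seed: int = 0, size: int = IMAGE_SIZE) -> FixtureSplit:
    """A class-balanced, seeded dataset split 80-10-10 into train/val/test.

    The split is stratified per class so both classes appear in every subset.
    """
    if n < 20:
        raise ValueError("need n >= 20 for a meaningful 80-10-10 split")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    rng = np.random.default_rng(seed)
    per_class = [make_sample(lbl, contrast, noise_level, rng, size)
                 for lbl in (0, 1) for _ in range(n // 2 + (lbl == 0) * (n % 2))]
    by_label = {0: [s for s in per_class if s.label == 0],
                1: [s for s in per_class if s.label == 1]}
    train, val, test = [], [], []
    for lbl, samples in by_label.items():
        order = rng.permutation(len(samples))
        m = len(samples)
        n_val = int(round(0.1 * m))
        n_test = int(round(0.1 * m))
        n_train = m - n_val - n_test
        shuffled = [samples[i] for i in order]
        train += shuffled[:n_train]
        val += shuffled[n_train:n_train + n_val]
        test += shuffled[n_train + n_val:]
    return FixtureSplit(train=train, val=val, test=test, seed=seed)


def make_tiny_cnn(seed: int = 0, size: int = IMAGE_SIZE) -> nn.Sequential:
    """The deterministic test-bed CNN: 3 conv blocks (8/16/32 ch) + GAP + linear(2)."""
    rng = np.random.default_rng(seed)
    layers = []
    cin = 1
    for bi, cout in enumerate((8, 16, 32)):
        layers += [
            (f"block{bi}.conv", nn.Conv2d(cin, cout, 3, padding=1, rng=rng)),
            (f"block{bi}.norm", nn.BatchNorm2d(cout)),
            (f"block{bi}.relu", nn.ReLU()),
            (f"block{bi}.pool", nn.MaxPool2d()),
        ]
        cin = cout
    layers += [
        ("gap", nn.GlobalAvgPool()),
        ("flatten", nn.Flatten()),
        ("head", nn.Linear(32, 2, rng=rng)),
    ]
    return nn.Sequential(layers, input_shape=(1, size, size))


def _accuracy(model: nn.Sequential, samples: list[SyntheticSample]) -> float:
    x = np.stack([s.image[None] for s in samples])
    y = np.array([s.label for s in samples])
    pred = model.forward(x, train=False).argmax(axis=1)
    return float((pred == y).mean())


def train_fixture(model: nn.Sequential, split: FixtureSplit, epochs: int = 10,
                  lr: float = 1e-2, seed: int = 0, batch_size: int = 32) -> dict:
    """Deterministic seeded training; returns metrics including val/test accuracy.

    Divergence (validation accuracy below 0.6 after training) is flagged in
    the returned metrics rather than raised.
    """
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model, lr=lr)
    x = np.stack([s.image[None] for s in split.train])
    y = np.array([s.label for s in split.train])
    losses = []
    for _ in range(epochs):
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for start in range(0, len(y), batch_size):
            idx = order[start:start + batch_size]
            model.zero_grad()
            logits = model.forward(x[idx], train=True)
            loss, glogits = nn.cross_entropy(logits, y[idx])
            # backprop through the whole chain, accumulating parameter grads
            g = glogits
            for _, layer in reversed(model.layers):
                g = layer.backward(g)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / len(y))
    model.eval()
    val_acc = _accuracy(model, split.val) if split.val else float("nan")
    test_acc = _accuracy(model, split.test) if split.test else float("nan")
    return {
        "epoch_losses": losses,
        "val_accuracy": val_acc,
        "test_accuracy": test_acc,
        "diverged": bool(epochs > 0 and split.val and val_acc < 0.6),
    }


def localization_iou(frame_or_map, truth_mask: np.ndarray, threshold: float = 0.5) -> float:
    """IoU between the thresholded unit-scaled CAM and the ground-truth lesion."""
    unit = frame_or_map.raw_map if hasattr(frame_or_map, "raw_map") else np.asarray(frame_or_map)
    truth = np.asarray(truth_mask, dtype=bool)
    if not truth.any():
        raise ValueError("empty truth mask: localization is undefined for a normal sample")
    pred = unit >= threshold
    union = (pred | truth).sum()
    return float((pred & truth).sum() / union) if union else 0.0


def spatial_entropy(saliency_map: np.ndarray, normalized: bool = True) -> float:
    """Shannon entropy of a non-negative map treated as a spatial distribution.

    With ``normalized=True`` the entropy is divided by ``log(n_pixels)`` so
    maps of different native resolutions are comparable (1 = perfectly
    diffuse, 0 = a single pixel).  Diffuse early-layer maps score high;
    focused late-layer maps score low.  An all-zero map has no support and
    returns NaN.
    """
    m = np.maximum(np.asarray(saliency_map, dtype=float), 0.0)
    total = m.sum()
    if total <= 0:
        return float("nan")
    p = (m / total).reshape(-1)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(m.size) if normalized else h


def export_dataset(split: FixtureSplit, out_dir: str | Path) -> Path:
    """Write the split as PNG directories plus a labels CSV (for CLI runs)."""
    out_dir = Path(out_dir)
    rows = []
    for part in ("train", "val", "test"):
        part_dir = out_dir / part
        part_dir.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(getattr(split, part)):
            name = f"{part}_{i:04d}.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8)).save(part_dir / name)
            rows.append({"split": part, "file": f"{part}/{name}", "label": s.label})
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["split", "file", "label"])
        writer.writeheader()
        writer.writerows(rows)
    return out_dir
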