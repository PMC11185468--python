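"""Remove-and-Debias (ROAD) faithfulness scoring and the per-layer series.

ROAD perturbs the input by *noisy linear imputation*: the selected pixels are
replaced by the solution of a linear system in which each imputed pixel
equals the mean of its 4-neighbours (a discrete Laplace / diffusion fill),
plus small Gaussian noise so the mask shape itself leaks no information.
The confidence change C of the target class is measured after imputing the
least-relevant (LRP) and most-relevant (MRP) pixels of a saliency map at a
set of perturbation fractions; the combined score aggregates

    (C_LRP - C_MRP) / 2

over fractions.  A faithful map loses little confidence when irrelevant
pixels vanish but much when its top pixels do, so higher is better.

Scoring every target layer of a network yields the layer-wise ROAD series
(ybROAD); its maximum identifies the most faithful explanatory layer and its
mean summarizes the whole network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .cam_engine import compute_cam, get_scheme, WeightScheme
from .model_graph import LayerRef, enumerate_target_layers, predict_proba, resolve_target
from .nn import Sequential
from .normalize_render import normalize_local

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoadConfig:
    """Perturbation fractions, imputation noise and aggregation rule."""

    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    noise_sd: float = 0.01
    neighbor_weighting: str = "uniform4"
    aggregate: str = "mean"  # "mean" (bounded in [-1, 1]) or "sum"
    confidence: str = "change"  # "change" (imputed minus original) or "probability"
    seed: int = 0

    def __post_init__(self):
        fr = tuple(float(f) for f in self.fractions)
        if not fr:
            raise ValueError("at least one perturbation fraction is required")
        if any(not 0.0 < f < 1.0 for f in fr):
            raise ValueError(f"fractions must lie in (0, 1): {fr}")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError(f"fractions must be strictly increasing: {fr}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.aggregate not in ("mean", "sum"):
            raise ValueError("aggregate must be 'mean' or 'sum'")
        if self.confidence not in ("change", "probability"):
            raise ValueError("confidence must be 'change' or 'probability'")
        object.__setattr__(self, "fractions", fr)


@dataclass
class RoadResult:
    """Per-fraction confidence changes for both orderings plus the combined score."""

    layer: LayerRef | None
    fractions: tuple[float, ...]
    c_lrp: np.ndarray  # confidence change after imputing least-relevant pixels
    c_mrp: np.ndarray  # confidence change after imputing most-relevant pixels
    combined: float


@dataclass
class YbRoadSeries:
    """Ordered per-layer ROAD scores with their summaries."""

    entries: list[tuple[LayerRef, RoadResult]]
    skipped: list[LayerRef] = field(default_factory=list)
    scheme: str = ""
    target_class: int = -1

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.combined for _, r in self.entries])

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean())

    @property
    def max_score(self) -> float:
        return float(self.scores.max())

    @property
    def argmax_layer(self) -> LayerRef:
        return self.entries[int(np.argmax(self.scores))][0]

    def __len__(self):
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ref, res in self.entries:
            row = {"layer_index": ref.index, "layer_name": ref.name}
            for p, c in zip(res.fractions, res.c_lrp):
                row[f"C_LRP_{p:g}"] = c
            for p, c in zip(res.fractions, res.c_mrp):
                row[f"C_MRP_{p:g}"] = c
            row["combined"] = res.combined
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "mean": self.mean_score,
            "max": self.max_score,
            "argmax_layer_index": self.argmax_layer.index,
            "argmax_layer_name": self.argmax_layer.name,
            "n_layers": len(self),
            "scheme": self.scheme,
            "target_class": self.target_class,
        }


# ---------------------------------------------------------------------------
# pixel selection


def select_pixels(unit_map: np.ndarray, fraction: float, order: str) -> np.ndarray:
    """Boolean mask of exactly round(fraction * H * W) pixels by saliency rank.

    ``order`` is ``"most_relevant"`` or ``"least_relevant"``.  Ties are broken
    by ascending flat index so the selection is deterministic.
    """
    if order not in ("most_relevant", "least_relevant"):
        raise ValueError(f"order must be 'most_relevant' or 'least_relevant', got {order!r}")
    m = np.asarray(unit_map, dtype=float)
    flat = m.reshape(-1)
    n = int(round(fraction * flat.size))
    idx = np.arange(flat.size)
    key = -flat if order == "most_relevant" else flat
    # lexsort: primary key last; ties fall back to ascending flat index
    chosen = np.lexsort((idx, key))[:n]
    mask = np.zeros(flat.size, dtype=bool)
    mask[chosen] = True
    return mask.reshape(m.shape)


# ---------------------------------------------------------------------------
# noisy linear imputation


def _impute_system(mask: np.ndarray):
    """Sparse system (A, neighbor lists) for mean-of-4-neighbours imputation."""
    h, w = mask.shape
    midx = np.flatnonzero(mask.reshape(-1))
    pos = {int(i): j for j, i in enumerate(midx)}
    rows, cols, vals = [], [], []
    const_terms: list[list[tuple[int, float]]] = []  # (flat unmasked neighbor, weight)
    for j, fi in enumerate(midx):
        r, c = divmod(int(fi), w)
        nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
        nbrs = [(rr, cc) for rr, cc in nbrs if 0 <= rr < h and 0 <= cc < w]
        wgt = 1.0 / len(nbrs)
        rows.append(j), cols.append(j), vals.append(1.0)
        consts = []
        for rr, cc in nbrs:
            nf = rr * w + cc
            if nf in pos:
                rows.append(j), cols.append(pos[nf]), vals.append(-wgt)
            else:
                consts.append((nf, wgt))
        const_terms.append(consts)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(len(midx), len(midx)))
    return a, midx, const_terms


def noisy_linear_impute(image: np.ndarray, mask: np.ndarray, noise_sd: float = 0.01,
                        seed: int = 0) -> np.ndarray:
    """Replace masked pixels by the neighbour-mean diffusion fill plus noise.

    Each masked pixel is set to the mean of its in-bounds 4-neighbours, with
    unmasked neighbours entering as constants; the coupled system is solved
    per channel with a sparse solver.  Independent Gaussian noise of standard
    deviation ``noise_sd`` is then added to the imputed pixels only.  Unmasked
    pixels are returned bit-unchanged.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    squeeze = img.ndim == 2
    chans = img[None] if squeeze else img
    if mask.shape != chans.shape[-2:]:
        raise ValueError(f"mask shape {mask.shape} does not match image {chans.shape[-2:]}")
    out = chans.copy()
    rng = np.random.default_rng(seed)
    if not mask.any():
        return out[0] if squeeze else out
    if mask.all():
        warnings.warn("fully masked image: diffusion fill is ill-posed; using channel-mean fill")
        for ch in range(out.shape[0]):
            fill = float(chans[ch].mean())
            out[ch][mask] = fill + rng.normal(0.0, noise_sd, int(mask.sum()))
        return out[0] if squeeze else out

    a, midx, const_terms = _impute_system(mask)
    a = a.tocsc()
    flat_mask = mask.reshape(-1)
    for ch in range(out.shape[0]):
        flat = chans[ch].reshape(-1)
        b = np.array([sum(wgt * flat[nf] for nf, wgt in consts) for consts in const_terms])
        x = spsolve(a, b) if len(midx) > 1 else np.atleast_1d(b / a.toarray()[0, 0])
        noisy = x + rng.normal(0.0, noise_sd, x.shape)
        filled = flat.copy()
        filled[flat_mask] = noisy
        out[ch] = filled.reshape(mask.shape)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# ROAD score and the per-layer series


def _order_seed(base_seed: int, fraction_index: int, order: str) -> int:
    # deterministic per (fraction, semantic order); shared regardless of slot
    return (base_seed * 1000 + fraction_index * 2 + (0 if order == "least_relevant" else 1)) % (2**31)


def road_score(model: Sequential, image: np.ndarray, unit_map: np.ndarray,
               target: int, config: RoadConfig = RoadConfig(),
               layer: LayerRef | None = None, swap_orders: bool = False) -> RoadResult:
    """Combined LRP/MRP ROAD score of one saliency map for a fixed target class.

    Confidence is the post-softmax probability of ``target``; with the default
    ``confidence='change'`` convention, C is the probability on the imputed
    image minus that on the original.  ``swap_orders`` exchanges which
    ordering fills the LRP and MRP slots (the noise draw for each semantic
    ordering is unchanged), so the combined score negates exactly.
    """
    target = int(target)
    p0 = float(predict_proba(model, image)[target])

    def confidence(order: str, fi: int, fraction: float) -> float:
        mask = select_pixels(unit_map, fraction, order)
        imputed = noisy_linear_impute(image, mask, config.noise_sd,
                                      seed=_order_seed(config.seed, fi, order))
        p = float(predict_proba(model, imputed)[target])
        return p - p0 if config.confidence == "change" else p

    lrp_order, mrp_order = ("least_relevant", "most_relevant")
    if swap_orders:
        lrp_order, mrp_order = mrp_order, lrp_order
    c_lrp = np.array([confidence(lrp_order, fi, p) for fi, p in enumerate(config.fractions)])
    c_mrp = np.array([confidence(mrp_order, fi, p) for fi, p in enumerate(config.fractions)])
    per_fraction = (c_lrp - c_mrp) / 2.0
    combined = float(per_fraction.mean() if config.aggregate == "mean" else per_fraction.sum())
    return RoadResult(layer=layer, fractions=config.fractions,
                      c_lrp=c_lrp, c_mrp=c_mrp, combined=combined)


def ybroad(model: Sequential, image: np.ndarray, scheme: WeightScheme | str,
           target="argmax", config: RoadConfig = RoadConfig(),
           layers: list[LayerRef] | None = None,
           reshape_rule: tuple[int, int] | None = None) -> YbRoadSeries:
    """The layer-wise ROAD series: one score per scorable target layer.

    The target class is resolved once from the unperturbed image and held
    fixed for every layer and every perturbation.  Layers whose output is not
    a renderable 2-D map are skipped and reported separately.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme, rng_seed=config.seed)
    if layers is None:
        layers = enumerate_target_layers(model)
    tgt = resolve_target(model.forward(image), target)

    entries: list[tuple[LayerRef, RoadResult]] = []
    skipped: list[LayerRef] = []
    for ref in layers:
        scorable = ref.shape_class == "spatial2d" or (
            ref.shape_class == "token_sequence" and reshape_rule is not None)
        if not scorable:
            skipped.append(ref)
            continue
        try:
            frame = compute_cam(model, image, ref, tgt, scheme, reshape_rule=reshape_rule)
        except Exception as exc:
            raise RuntimeError(f"CAM evaluation failed at layer {ref.name!r}") from exc
        unit = normalize_local(frame)
        res = road_score(model, image, unit, tgt, config, layer=ref)
        entries.append((ref, res))
    if not entries:
        raise RuntimeError("no scorable layers: every target layer was skipped")
    return YbRoadSeries(entries=entries, skipped=skipped,
                        scheme=scheme.name, target_class=tgt)
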