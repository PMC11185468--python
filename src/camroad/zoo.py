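"""Static architecture registry for parameter profiling.

Each entry reconstructs the leaf-layer census of a published ImageNet
classifier architecture (1000 classes, standard configuration) from its
public definition, so exact parameter totals can be profiled without any
pretrained weights or deep-learning runtime.  Only parameter-bearing leaves
are censused; activation and pooling layers carry no parameters and are
omitted from these static specs (the census convention is documented in the
methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ArchLeaf:
    name: str
    kind: str
    param_count: int
    shape_class: str = "spatial2d"


@dataclass(frozen=True)
class ArchSpec:
    name: str
    leaves: tuple[ArchLeaf, ...]

    @property
    def total_params(self) -> int:
        return sum(leaf.param_count for leaf in self.leaves)


def _conv(cin, cout, k, bias=True, groups=1):
    return cout * (cin // groups) * k * k + (cout if bias else 0)


def _norm(c):  # batchnorm / layernorm affine: weight + bias
    return 2 * c


def _linear(i, o, bias=True):
    return i * o + (o if bias else 0)


class _Census:
    def __init__(self):
        self.leaves: list[ArchLeaf] = []

    def add(self, name, kind, count, shape_class="spatial2d"):
        self.leaves.append(ArchLeaf(name, kind, int(count), shape_class))

    def spec(self, model_name) -> ArchSpec:
        return ArchSpec(model_name, tuple(self.leaves))


def alexnet() -> ArchSpec:
    c = _Census()
    convs = [(3, 64, 11), (64, 192, 5), (192, 384, 3), (384, 256, 3), (256, 256, 3)]
    for i, (cin, cout, k) in enumerate(convs):
        c.add(f"features.conv{i}", "conv", _conv(cin, cout, k))
    c.add("classifier.fc0", "linear", _linear(9216, 4096), "vector1d")
    c.add("classifier.fc1", "linear", _linear(4096, 4096), "vector1d")
    c.add("classifier.fc2", "linear", _linear(4096, 1000), "vector1d")
    return c.spec("alexnet")


def squeezenet1_0() -> ArchSpec:
    c = _Census()
    c.add("features.conv0", "conv", _conv(3, 96, 7))
    fires = [(96, 16, 64, 64), (128, 16, 64, 64), (128, 32, 128, 128), (256, 32, 128, 128),
             (256, 48, 192, 192), (384, 48, 192, 192), (384, 64, 256, 256), (512, 64, 256, 256)]
    for i, (cin, s, e1, e3) in enumerate(fires):
        c.add(f"features.fire{i}.squeeze", "conv", _conv(cin, s, 1))
        c.add(f"features.fire{i}.expand1x1", "conv", _conv(s, e1, 1))
        c.add(f"features.fire{i}.expand3x3", "conv", _conv(s, e3, 3))
    c.add("classifier.conv", "conv", _conv(512, 1000, 1))
    return c.spec("squeezenet1_0")


def densenet161() -> ArchSpec:
    growth, bn_size, init_feat = 48, 4, 96
    c = _Census()
    c.add("features.conv0", "conv", _conv(3, init_feat, 7, bias=False))
    c.add("features.norm0", "norm", _norm(init_feat))
    ch = init_feat
    for bi, n_layers in enumerate([6, 12, 36, 24]):
        for li in range(n_layers):
            pre = f"features.denseblock{bi + 1}.denselayer{li + 1}"
            c.add(f"{pre}.norm1", "norm", _norm(ch))
            c.add(f"{pre}.conv1", "conv", _conv(ch, bn_size * growth, 1, bias=False))
            c.add(f"{pre}.norm2", "norm", _norm(bn_size * growth))
            c.add(f"{pre}.conv2", "conv", _conv(bn_size * growth, growth, 3, bias=False))
            ch += growth
        if bi < 3:
            c.add(f"features.transition{bi + 1}.norm", "norm", _norm(ch))
            c.add(f"features.transition{bi + 1}.conv", "conv", _conv(ch, ch // 2, 1, bias=False))
            ch //= 2
    c.add("features.norm5", "norm", _norm(ch))
    c.add("classifier", "linear", _linear(ch, 1000), "vector1d")
    return c.spec("densenet161")


def convnext_base() -> ArchSpec:
    dims, depths = [128, 256, 512, 1024], [3, 3, 27, 3]
    c = _Census()
    c.add("features.stem.conv", "conv", _conv(3, dims[0], 4))
    c.add("features.stem.norm", "norm", _norm(dims[0]))
    for si, (d, dep) in enumerate(zip(dims, depths)):
        for bi in range(dep):
            pre = f"features.stage{si + 1}.block{bi}"
            c.add(f"{pre}.dwconv", "conv", _conv(d, d, 7, groups=d))
            c.add(f"{pre}.norm", "norm", _norm(d))
            c.add(f"{pre}.pwconv1", "linear", _linear(d, 4 * d))
            c.add(f"{pre}.pwconv2", "linear", _linear(4 * d, d))
            c.add(f"{pre}.layer_scale", "scale", d)
        if si < 3:
            c.add(f"features.downsample{si + 1}.norm", "norm", _norm(d))
            c.add(f"features.downsample{si + 1}.conv", "conv", _conv(d, 2 * d, 2))
    c.add("classifier.norm", "norm", _norm(dims[-1]), "vector1d")
    c.add("classifier.fc", "linear", _linear(dims[-1], 1000), "vector1d")
    return c.spec("convnext_base")


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def efficientnet_b7() -> ArchSpec:
    width_mult, depth_mult = 2.0, 3.1
    # MBConv base config: expand_ratio, kernel, stride, in_ch, out_ch, repeats
    base = [(1, 3, 1, 32, 16, 1), (6, 3, 2, 16, 24, 2), (6, 5, 2, 24, 40, 2),
            (6, 3, 2, 40, 80, 3), (6, 5, 1, 80, 112, 3), (6, 5, 2, 112, 192, 4),
            (6, 3, 1, 192, 320, 1)]
    c = _Census()
    stem = _make_divisible(32 * width_mult)
    c.add("features.stem.conv", "conv", _conv(3, stem, 3, bias=False))
    c.add("features.stem.norm", "norm", _norm(stem))
    prev = stem
    for si, (er, k, _s, _ci, co, reps) in enumerate(base):
        cout = _make_divisible(co * width_mult)
        for bi in range(math.ceil(depth_mult * reps)):
            pre = f"features.stage{si + 1}.block{bi}"
            cin, exp = prev, prev * er
            if er != 1:
                c.add(f"{pre}.expand.conv", "conv", _conv(cin, exp, 1, bias=False))
                c.add(f"{pre}.expand.norm", "norm", _norm(exp))
            c.add(f"{pre}.dwconv.conv", "conv", _conv(exp, exp, k, bias=False, groups=exp))
            c.add(f"{pre}.dwconv.norm", "norm", _norm(exp))
            sq = max(1, cin // 4)  # squeeze-excitation sized from block input channels
            c.add(f"{pre}.se.fc1", "conv", _conv(exp, sq, 1))
            c.add(f"{pre}.se.fc2", "conv", _conv(sq, exp, 1))
            c.add(f"{pre}.project.conv", "conv", _conv(exp, cout, 1, bias=False))
            c.add(f"{pre}.project.norm", "norm", _norm(cout))
            prev = cout
    head = 4 * prev
    c.add("features.head.conv", "conv", _conv(prev, head, 1, bias=False))
    c.add("features.head.norm", "norm", _norm(head))
    c.add("classifier.fc", "linear", _linear(head, 1000), "vector1d")
    return c.spec("efficientnet_b7")


def maxvit_t() -> ArchSpec:
    partition, head_dim = 7, 32
    chans, layers = [64, 128, 256, 512], [2, 2, 5, 2]
    c = _Census()
    c.add("stem.conv0", "conv", _conv(3, 64, 3, bias=False))
    c.add("stem.norm0", "norm", _norm(64))
    c.add("stem.conv1", "conv", _conv(64, 64, 3))
    prev = 64
    for si, (co, nl) in enumerate(zip(chans, layers)):
        for bi in range(nl):
            pre = f"blocks.stage{si}.layer{bi}"
            cin, mid, sq = prev, 4 * co, co // 4
            c.add(f"{pre}.mbconv.pre_norm", "norm", _norm(cin))
            if bi == 0 or cin != co:  # downsampling residual projection
                c.add(f"{pre}.mbconv.proj", "conv", _conv(cin, co, 1))
            c.add(f"{pre}.mbconv.conv_a", "conv", _conv(cin, mid, 1, bias=False))
            c.add(f"{pre}.mbconv.norm_a", "norm", _norm(mid))
            c.add(f"{pre}.mbconv.conv_b", "conv", _conv(mid, mid, 3, bias=False, groups=mid))
            c.add(f"{pre}.mbconv.norm_b", "norm", _norm(mid))
            c.add(f"{pre}.mbconv.se.fc1", "conv", _conv(mid, sq, 1))
            c.add(f"{pre}.mbconv.se.fc2", "conv", _conv(sq, mid, 1))
            c.add(f"{pre}.mbconv.conv_c", "conv", _conv(mid, co, 1))
            n_heads = co // head_dim
            for attn in ("window", "grid"):
                ap = f"{pre}.{attn}_attention"
                c.add(f"{ap}.norm1", "norm", _norm(co), "token_sequence")
                c.add(f"{ap}.to_qkv", "linear", _linear(co, 3 * co), "token_sequence")
                c.add(f"{ap}.rel_pos_bias", "bias", (2 * partition - 1) ** 2 * n_heads, "token_sequence")
                c.add(f"{ap}.merge", "linear", _linear(co, co), "token_sequence")
                c.add(f"{ap}.norm2", "norm", _norm(co), "token_sequence")
                c.add(f"{ap}.mlp.fc1", "linear", _linear(co, 4 * co), "token_sequence")
                c.add(f"{ap}.mlp.fc2", "linear", _linear(4 * co, co), "token_sequence")
            prev = co
    c.add("classifier.norm", "norm", _norm(chans[-1]), "vector1d")
    c.add("classifier.pre_logits", "linear", _linear(chans[-1], chans[-1]), "vector1d")
    c.add("classifier.fc", "linear", _linear(chans[-1], 1000, bias=False), "vector1d")
    return c.spec("maxvit_t")


def _resnet(name: str, blocks: list[int]) -> ArchSpec:
    c = _Census()
    c.add("conv1", "conv", _conv(3, 64, 7, bias=False))
    c.add("bn1", "norm", _norm(64))
    cin = 64
    for si, nb in enumerate(blocks):
        width = 64 * 2 ** si
        cout = width * 4
        for bi in range(nb):
            pre = f"layer{si + 1}.{bi}"
            c.add(f"{pre}.conv1", "conv", _conv(cin, width, 1, bias=False))
            c.add(f"{pre}.bn1", "norm", _norm(width))
            c.add(f"{pre}.conv2", "conv", _conv(width, width, 3, bias=False))
            c.add(f"{pre}.bn2", "norm", _norm(width))
            c.add(f"{pre}.conv3", "conv", _conv(width, cout, 1, bias=False))
            c.add(f"{pre}.bn3", "norm", _norm(cout))
            if bi == 0:
                c.add(f"{pre}.downsample.conv", "conv", _conv(cin, cout, 1, bias=False))
                c.add(f"{pre}.downsample.bn", "norm", _norm(cout))
            cin = cout
    c.add("fc", "linear", _linear(2048, 1000), "vector1d")
    return c.spec(name)


def resnet50() -> ArchSpec:
    return _resnet("resnet50", [3, 4, 6, 3])


def resnet152() -> ArchSpec:
    return _resnet("resnet152", [3, 8, 36, 3])


REGISTRY = {
    "alexnet": alexnet,
    "convnext_base": convnext_base,
    "densenet161": densenet161,
    "efficientnet_b7": efficientnet_b7,
    "maxvit_t": maxvit_t,
    "squeezenet1_0": squeezenet1_0,
    "resnet50": resnet50,
    "resnet152": resnet152,
}


def get_architecture(name: str) -> ArchSpec:
    try:
        return REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; registry has: {', '.join(sorted(REGISTRY))}") from None
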