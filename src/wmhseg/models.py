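"""The three segmentation networks and their arithmetic.

Families
--------
``unet``
    Classic encoder/decoder with skip concatenations.  First level uses two
    5 x 5 x 64 convolutions (which is why a second input channel adds exactly
    5*5*64 = 1,600 weights), deeper levels 3 x 3 kernels with widths doubling
    to a 512-channel bottleneck, and a 1 x 1 x 3 softmax head.
``saliency_unet``
    Two independent encoder branches -- one for the raw T2-FLAIR image, one
    for the irregularity map used as a regional guidance map -- fused by
    channel concatenation before a shared decoder.  Each branch: two 5 x 5 x 64
    convolutions, pool, two 3 x 3 x 128 convolutions, pool.  The decoder
    mirrors the encoder (256, 256 -> 128, 128 -> 64, 64) and concatenates the
    matching feature maps of *both* branches at every up-sampling step.
    14 CONV blocks in total, where a CONV block is convolution -> ReLU ->
    batch normalisation.
``dilated_saliency_unet``
    Same layout, but the four branch convolutions are all 3 x 3 with a
    dilation schedule (default 1, 2, 4, 2) widening their receptive fields to
    k*(n-1)+1 pixels per side without extra parameters.

Parameter counting supports two bookkeeping conventions for batch
normalisation -- trainable only (scale + shift, 2 per channel) or total
(plus running mean/variance, 4 per channel).  Published totals for these
architectures mix the two, so each family records which convention its
reported count uses (see ``count_convention`` in the model summary).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .errors import ContractViolation, ParameterError
from .nn import Adam, BatchNorm2d, Conv2d, MaxPool2d, Param, ReLU, SoftmaxCrossEntropy, Upsample2d, softmax

__all__ = [
    "ConvBlockSpec",
    "ArchitectureSpec",
    "DILATION_SCHEDULES",
    "receptive_field",
    "dilated_conv2d_reference",
    "build_model",
    "count_parameters",
    "depth_sweep_specs",
    "summarize",
    "save_weights",
    "load_weights",
    "UNet",
    "SaliencyUNet",
]

DILATION_SCHEDULES = {(1, 2, 2, 4), (4, 2, 2, 1), (1, 2, 4, 2)}

FAMILIES = ("unet", "saliency_unet", "dilated_saliency_unet")


@dataclass(frozen=True)
class ConvBlockSpec:
    """One CONV block: ``filter_size`` x ``filter_size`` x ``channels``."""

    filter_size: int
    channels: int
    dilation: int = 1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a network.

    ``base_width`` scales every channel width; 64 reproduces the published
    architectures, smaller values give desk-scale models with the same shape.
    ``n_conv_blocks`` applies to the saliency families (14, 20 or 26; each
    step of 6 adds/removes one resolution level).
    """

    family: str = "saliency_unet"
    in_channels: int = 1  # per branch for the saliency families
    base_width: int = 64
    n_conv_blocks: int = 14
    dilation_schedule: tuple[int, int, int, int] = (1, 2, 4, 2)
    output_labels: int = 3

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        if self.base_width < 1 or self.in_channels < 1:
            raise ParameterError("base_width and in_channels must be positive")
        if self.family != "unet":
            if (self.n_conv_blocks - 14) % 6 or self.n_conv_blocks < 14:
                raise ParameterError("n_conv_blocks must be 14 + 6k (k >= 0)")
        if self.family == "dilated_saliency_unet":
            sched = tuple(self.dilation_schedule)
            if len(sched) != 4 or any(d < 1 for d in sched):
                raise ParameterError("dilation_schedule needs four factors >= 1")

    @property
    def n_levels(self) -> int:
        """Pooling levels per encoder branch (saliency families)."""
        return 2 + (self.n_conv_blocks - 14) // 6


def receptive_field(n: int, k: int) -> int:
    """Side length of the receptive field of an n x n filter at dilation k."""
    if n < 1 or k < 1:
        raise ParameterError("filter side and dilation factor must be >= 1")
    return k * (n - 1) + 1


def dilated_conv2d_reference(I: np.ndarray, W: np.ndarray, k: int = 1) -> np.ndarray:
    """Literal double-sum dilated convolution (cross-correlation orientation).

    ``F(r, c) = sum_i sum_j W(i, j) I(r + k i, c + k j)`` with offsets running
    over the filter half-width, zero padding outside the image, output the
    same size as ``I``.  Slow by construction; it is the oracle the fast
    im2col layer is checked against.
    """
    I = np.asarray(I, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ParameterError("W must be a square filter")
    if W.shape[0] % 2 == 0:
        raise ParameterError("even filter sides are not supported")
    if k < 1:
        raise ParameterError("dilation factor must be >= 1")
    n = W.shape[0]
    h = n // 2
    rows, cols = I.shape
    F = np.zeros_like(I)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for i in range(-h, h + 1):
                for j in range(-h, h + 1):
                    rr, cc = r + k * i, c + k * j
                    if 0 <= rr < rows and 0 <= cc < cols:
                        acc += W[i + h, j + h] * I[rr, cc]
            F[r, c] = acc
    return F


# ---------------------------------------------------------------------------
# network building blocks


class ConvBlock:
    """convolution -> ReLU -> batch normalisation."""

    def __init__(self, in_ch, out_ch, kernel, dilation, rng, name):
        self.name = name
        self.conv = Conv2d(in_ch, out_ch, kernel, dilation, rng, name=name)
        self.act = ReLU()
        self.bn = BatchNorm2d(out_ch, name=name)

    @property
    def spec(self) -> ConvBlockSpec:
        return ConvBlockSpec(self.conv.kernel, self.conv.out_ch, self.conv.dilation)

    def params(self):
        return self.conv.params() + self.bn.params()

    def layers(self):
        return [self.conv, self.bn]

    def forward(self, x, training=True):
        return self.bn.forward(self.act.forward(self.conv.forward(x, training)), training)

    def backward(self, dy):
        return self.conv.backward(self.act.backward(self.bn.backward(dy)))


class _Stage:
    """A run of conv blocks applied in sequence."""

    def __init__(self, blocks):
        self.blocks = blocks

    def forward(self, x, training=True):
        for b in self.blocks:
            x = b.forward(x, training)
        return x

    def backward(self, dy):
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy


def _concat(parts):
    return np.concatenate(parts, axis=1)


def _split(dy, widths):
    out, at = [], 0
    for w in widths:
        out.append(dy[:, at : at + w])
        at += w
    return out


class _ModelBase:
    family: str
    count_convention: str
    spec: ArchitectureSpec

    def conv_blocks(self) -> list[ConvBlock]:
        raise NotImplementedError

    def head_layers(self) -> list:
        raise NotImplementedError

    def layers(self):
        out = []
        for b in self.conv_blocks():
            out.extend(b.layers())
        out.extend(self.head_layers())
        return out

    def parameters(self) -> list[Param]:
        out = []
        for b in self.conv_blocks():
            out.extend(b.params())
        for l in self.head_layers():
            out.extend(l.params())
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, labels, H, W), summing to 1 per pixel."""
        return softmax(self.forward(x, training=False), axis=1)


class UNet(_ModelBase):
    """Single-branch U-Net; input (N, in_channels, H, W), H and W
    divisible by 8."""

    family = "unet"
    count_convention = "total"

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = spec.base_width
        self.spec = spec
        mk = lambda i, o, k, name: ConvBlock(i, o, k, 1, rng, name)
        self.enc = [
            _Stage([mk(spec.in_channels, w, 5, "enc1a"), mk(w, w, 5, "enc1b")]),
            _Stage([mk(w, 2 * w, 3, "enc2a"), mk(2 * w, 2 * w, 3, "enc2b")]),
            _Stage([mk(2 * w, 4 * w, 3, "enc3a"), mk(4 * w, 4 * w, 3, "enc3b")]),
        ]
        self.bottleneck = _Stage([mk(4 * w, 8 * w, 3, "bot_a"), mk(8 * w, 8 * w, 3, "bot_b")])
        self.dec = [
            _Stage([mk(8 * w + 4 * w, 4 * w, 3, "dec3a"), mk(4 * w, 4 * w, 3, "dec3b")]),
            _Stage([mk(4 * w + 2 * w, 2 * w, 3, "dec2a"), mk(2 * w, 2 * w, 3, "dec2b")]),
            _Stage([mk(2 * w + w, w, 3, "dec1a"), mk(w, w, 3, "dec1b")]),
        ]
        self.pools = [MaxPool2d() for _ in range(3)]
        self.ups = [Upsample2d() for _ in range(3)]
        self.head = Conv2d(w, spec.output_labels, 1, 1, rng, name="head")
        self._skip_widths = [w, 2 * w, 4 * w]

    def conv_blocks(self):
        out = []
        for st in self.enc + [self.bottleneck] + self.dec:
            out.extend(st.blocks)
        return out

    def head_layers(self):
        return [self.head]

    def forward(self, x, training=True):
        skips = []
        for st, pool in zip(self.enc, self.pools):
            x = st.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        for st, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = st.forward(_concat([up.forward(x, training), skip]), training)
        return self.head.forward(x, training)

    def backward(self, dlogits):
        # decoder stage i consumed ups[i] output concatenated with the
        # encoder feature of level L-1-i
        dy = self.head.backward(dlogits)
        L = len(self.dec)
        dskips = [None] * L
        for i in range(L - 1, -1, -1):
            lev = L - 1 - i
            d = self.dec[i].backward(dy)
            up_w = d.shape[1] - self._skip_widths[lev]
            dup, ds = _split(d, [up_w, self._skip_widths[lev]])
            dskips[lev] = ds
            dy = self.ups[i].backward(dup)
        dy = self.bottleneck.backward(dy)
        for lev in range(L - 1, -1, -1):
            dy = self.pools[lev].backward(dy)
            dy = dy + dskips[lev]
            dy = self.enc[lev].backward(dy)
        return dy


class SaliencyUNet(_ModelBase):
    """Two-branch (image + regional map) U-Net, optionally dilated.

    Input is (N, 2 * in_channels_per_branch, H, W); the first half of the
    channels feeds the raw-image branch and the second half the regional-map
    branch.  H and W must be divisible by 2**n_levels.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.family = spec.family
        self.count_convention = "trainable"
        w = spec.base_width
        L = spec.n_levels
        dilated = spec.family == "dilated_saliency_unet"
        k12 = 3 if dilated else 5
        sched = list(spec.dilation_schedule) if dilated else [1, 1, 1, 1]
        widths = [w * 2**i for i in range(L)]

        def branch(tag):
            stages = []
            cin = spec.in_channels
            di = iter(sched + [1] * (2 * L - 4))
            for lev, width in enumerate(widths, start=1):
                kern = k12 if lev == 1 else 3
                a = ConvBlock(cin, width, kern, next(di), rng, f"{tag}_enc{lev}a")
                b = ConvBlock(width, width, kern, next(di), rng, f"{tag}_enc{lev}b")
                stages.append(_Stage([a, b]))
                cin = width
            return stages

        self.branch1 = branch("img")
        self.branch2 = branch("map")
        self.pools1 = [MaxPool2d() for _ in range(L)]
        self.pools2 = [MaxPool2d() for _ in range(L)]

        fused = 2 * widths[-1]
        mk = lambda i, o, name: ConvBlock(i, o, 3, 1, rng, name)
        self.dec_deep = _Stage([mk(fused, fused, "dec0a"), mk(fused, fused, "dec0b")])
        self.dec = []
        cur = fused
        for lev in range(L, 0, -1):
            wi = widths[lev - 1]
            self.dec.append(_Stage([mk(cur + 2 * wi, wi, f"dec{lev}a"), mk(wi, wi, f"dec{lev}b")]))
            cur = wi
        self.ups = [Upsample2d() for _ in range(L)]
        self.head = Conv2d(widths[0], spec.output_labels, 1, 1, rng, name="head")
        self._widths = widths

    def conv_blocks(self):
        out = []
        for st in self.branch1 + self.branch2 + [self.dec_deep] + self.dec:
            out.extend(st.blocks)
        return out

    def head_layers(self):
        return [self.head]

    def forward(self, x, training=True):
        c = self.spec.in_channels
        if x.shape[1] != 2 * c:
            raise ContractViolation(
                f"saliency input needs {2*c} channels (image then regional map), got {x.shape[1]}"
            )
        x1, x2 = x[:, :c], x[:, c:]
        self._skips1, self._skips2 = [], []
        for st, pool in zip(self.branch1, self.pools1):
            x1 = st.forward(x1, training)
            self._skips1.append(x1)
            x1 = pool.forward(x1, training)
        for st, pool in zip(self.branch2, self.pools2):
            x2 = st.forward(x2, training)
            self._skips2.append(x2)
            x2 = pool.forward(x2, training)
        y = self.dec_deep.forward(_concat([x1, x2]), training)
        L = len(self.dec)
        for i, (st, up) in enumerate(zip(self.dec, self.ups)):
            lev = L - 1 - i  # skip level used by this stage
            y = st.forward(
                _concat([up.forward(y, training), self._skips1[lev], self._skips2[lev]]),
                training,
            )
        return self.head.forward(y, training)

    def backward(self, dlogits):
        L = len(self.dec)
        widths = self._widths
        dy = self.head.backward(dlogits)
        dskips1 = [None] * L
        dskips2 = [None] * L
        for i in range(L - 1, -1, -1):
            lev = L - 1 - i
            d = self.dec[i].backward(dy)
            cur_w = d.shape[1] - 2 * widths[lev]
            dup, ds1, ds2 = _split(d, [cur_w, widths[lev], widths[lev]])
            dskips1[lev], dskips2[lev] = ds1, ds2
            dy = self.ups[i].backward(dup)
        d = self.dec_deep.backward(dy)
        half = d.shape[1] // 2
        d1, d2 = _split(d, [half, half])

        def back_branch(stages, pools, dskips, dtop):
            dcur = dtop
            for lev in range(len(stages) - 1, -1, -1):
                dcur = pools[lev].backward(dcur)
                dcur = dcur + dskips[lev]
                dcur = stages[lev].backward(dcur)
            return dcur

        g1 = back_branch(self.branch1, self.pools1, dskips1, d1)
        g2 = back_branch(self.branch2, self.pools2, dskips2, d2)
        return _concat([g1, g2])


def build_model(spec: ArchitectureSpec, seed: int = 0) -> _ModelBase:
    """Instantiate a network with He-initialised weights (seeded)."""
    if spec.family == "unet":
        return UNet(spec, seed)
    return SaliencyUNet(spec, seed)


def count_parameters(model: _ModelBase, include_running_stats: bool | None = None) -> int:
    """Exact parameter count over convolutions and batch-norm layers.

    ``include_running_stats=None`` uses the convention the model family
    reports with (``model.count_convention``): running mean/variance are
    counted for ``"total"``, excluded for ``"trainable"``.
    """
    if include_running_stats is None:
        include_running_stats = model.count_convention == "total"
    total = 0
    for layer in model.layers():
        if isinstance(layer, Conv2d):
            total += layer.weight.value.size + layer.bias.value.size
        elif isinstance(layer, BatchNorm2d):
            per_ch = 4 if include_running_stats else 2
            total += per_ch * layer.ch
    return total


def depth_sweep_specs(base: ArchitectureSpec, n_conv_blocks: int) -> ArchitectureSpec:
    """Saliency-family depth variant with 14, 20 or 26 CONV blocks.

    Each step of 6 adds one resolution level: 4 encoder blocks (2 per branch)
    plus 2 decoder blocks, wired through an additional skip connection.
    """
    if base.family == "unet":
        raise ParameterError("depth sweep applies to the saliency families")
    if n_conv_blocks not in (14, 20, 26):
        raise ParameterError("supported depths are 14, 20 and 26 CONV blocks")
    return replace(base, n_conv_blocks=n_conv_blocks)


def summarize(model: _ModelBase) -> str:
    """Human-readable block table plus the parameter count and the batch-norm
    bookkeeping convention it uses."""
    lines = [
        f"family: {model.family}",
        f"count_convention: {model.count_convention} "
        f"(batch-norm {'incl.' if model.count_convention == 'total' else 'excl.'} running stats)",
        f"{'block':<12}{'kernel':<8}{'in':>5}{'out':>5}{'dil':>4}{'params':>10}",
    ]
    for b in model.conv_blocks():
        c = b.conv
        p = c.weight.value.size + c.bias.value.size
        p += (4 if model.count_convention == "total" else 2) * b.bn.ch
        lines.append(
            f"{b.name:<12}{c.kernel}x{c.kernel:<6}{c.in_ch:>5}{c.out_ch:>5}{c.dilation:>4}{p:>10,}"
        )
    for l in model.head_layers():
        p = l.weight.value.size + l.bias.value.size
        lines.append(f"{'head':<12}{l.kernel}x{l.kernel:<6}{l.in_ch:>5}{l.out_ch:>5}{1:>4}{p:>10,}")
    lines.append(f"total parameters: {count_parameters(model):,}")
    return "\n".join(lines)


def save_weights(model: _ModelBase, path) -> None:
    """Checkpoint every parameter and batch-norm running statistic to .npz."""
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"p{i}"] = p.value
    for i, layer in enumerate(model.layers()):
        if isinstance(layer, BatchNorm2d):
            arrays[f"rm{i}"] = layer.running_mean
            arrays[f"rv{i}"] = layer.running_var
    np.savez(path, **arrays)


def load_weights(model: _ModelBase, path) -> None:
    data = np.load(path)
    for i, p in enumerate(model.parameters()):
        p.value[...] = data[f"p{i}"]
    for i, layer in enumerate(model.layers()):
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = data[f"rm{i}"]
            layer.running_var[...] = data[f"rv{i}"]
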