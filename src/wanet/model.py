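"""WA-Net: a wide-activation residual encoder-decoder for vessel segmentation.

The architectural idea is to widen the feature channels *inside* each
residual block before the nonlinearity (by an expansion factor ``r``)
while slimming the identity pathway, so that more low-level feature
information survives the activation at unchanged parameter complexity:
a wide block with slim width c_hat and expanded width r*c_hat has exactly
as many conv weights as an original residual block of width
c1 = sqrt(r) * c_hat.

At the bottleneck an ASPP-like module (LASPP) runs parallel 3x3 atrous
convolutions with dilations 1, 2, 4, 8 and sums their outputs, capturing
vessels of mixed calibre; those convolutions are weight-normalized. The
decoder mirrors the encoder with nearest-neighbour upsampling, skip
concatenations and wide blocks, and the head merges a leaky-ReLU global
shortcut from the (batch-normalized) input before a 1x1 two-class softmax.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Layer,
    LeakyReLU,
    MaxPool2,
    Param,
    ReLU,
    SoftmaxChannels,
    UpsampleNearest2,
)

VARIANTS = ("wa_net", "network_1", "network_2", "network_3", "network_4")


# ---------------------------------------------------------------------------
# analytic calculators


def receptive_field(k: int, d: int) -> int:
    """Receptive field of a single k x k conv with dilation d.

    Rf = (k - 1)(d - 1) + k: the kernel taps sit d pixels apart, so the
    span per axis is d*(k-1) + 1. E.g. a 3x3 kernel at d = 3 sees 7
    pixels per axis.
    """
    if k < 1 or d < 1:
        raise ValueError(f"kernel and dilation must be positive, got k={k}, d={d}")
    return (k - 1) * (d - 1) + k


def original_block_params(c1: int, k: int) -> int:
    """Conv-weight count of an original residual block of width c1.

    Two k x k convolutions with c1 input and output channels each:
    2 * c1^2 * k^2 (kernel weights only, no biases).
    """
    if c1 < 1 or k < 1:
        raise ValueError("c1 and k must be positive")
    return 2 * c1 * c1 * k * k


@dataclass
class BlockSpec:
    """Widths of one wide-activation residual block.

    slim_width is the identity-pathway width c_hat1, expanded_width the
    pre-activation width c_hat2 = r * c_hat1, and equivalent_width the
    original-block width c1 with c1^2 = c_hat1 * c_hat2. ``exact`` flags
    whether both derived widths are exact integers.
    """

    slim_width: int
    expansion: float = 4.0
    kernel: int = 3
    expanded_width: int = field(init=False)
    equivalent_width: int = field(init=False)
    exact: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.slim_width < 1 or self.expansion <= 0:
            raise ValueError("slim_width >= 1 and expansion > 0 required")
        c2 = self.expansion * self.slim_width
        self.expanded_width = int(round(c2))
        c1 = math.sqrt(self.slim_width * self.expanded_width)
        self.equivalent_width = int(round(c1))
        self.exact = (
            abs(c2 - self.expanded_width) < 1e-9
            and abs(c1 - self.equivalent_width) < 1e-9
        )

    def conv_weight_count(self) -> int:
        k2 = self.kernel * self.kernel
        return 2 * self.slim_width * self.expanded_width * k2


def wide_block_widths(slim_width: int, expansion: float = 4.0, kernel: int = 3) -> BlockSpec:
    """Derive the expanded and equivalent-original widths of a wide block."""
    return BlockSpec(slim_width=slim_width, expansion=expansion, kernel=kernel)


def weight_normalize(direction: np.ndarray, g: float) -> np.ndarray:
    """Effective weight w = g * N / ||N|| of the weight-norm reparameterization.

    ||w|| equals g exactly and w is invariant to positive rescaling of N.
    """
    n = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(n))
    if norm == 0.0:
        raise FloatingPointError("weight normalization undefined for zero-norm N")
    return (g / norm) * n


def leaky_relu(x: np.ndarray, alpha: float = 0.3) -> np.ndarray:
    """Elementwise f(x) = x if x > 0 else alpha * x; alpha = 0 gives ReLU."""
    x = np.asarray(x)
    return np.where(x > 0, x, alpha * x)


# ---------------------------------------------------------------------------
# specs


@dataclass
class LasppSpec:
    """Parallel atrous pyramid at the bottleneck: 3x3 branches whose
    dilations are powers of two, outputs summed."""

    channels: int = 128
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    kernel: int = 3

    def __post_init__(self) -> None:
        d = tuple(self.dilations)
        if not d or any(x < 1 for x in d):
            raise ValueError("dilations must be positive")
        if list(d) != sorted(set(d)):
            raise ValueError("dilations must be strictly increasing")
        self.dilations = d

    def receptive_fields(self) -> tuple[int, ...]:
        return tuple(receptive_field(self.kernel, d) for d in self.dilations)


@dataclass
class NetworkConfig:
    """Full hyperparameter record of a WA-Net build.

    encoder_widths are the slim (identity-path) widths of the three
    encoder wide blocks; the decoder mirrors them. For the preactivated
    variants they are the plain block widths instead.
    """

    encoder_widths: tuple[int, int, int] = (16, 32, 64)
    laspp: LasppSpec = field(default_factory=LasppSpec)
    expansion: float = 4.0
    leaky_slope: float = 0.3
    patch_size: int = 48
    in_channels: int = 1
    n_classes: int = 2
    wn_laspp: bool = True
    wn_all: bool = False
    block_type: str = "wdsr_a"  # or "preact"
    variant: str = "wa_net"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        n_pools = 3
        if self.patch_size % (2 ** n_pools):
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by {2 ** n_pools}"
            )
        self.encoder_widths = tuple(self.encoder_widths)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["laspp"] = LasppSpec(**d["laspp"])
        return cls(**d)


# ---------------------------------------------------------------------------
# composite blocks


class WdsrABlock(Layer):
    """Wide-activation residual block.

    y = identity(x) + conv_{k,slim<-expanded}(ReLU(conv_{k,expanded<-cin}(x)));
    the identity path is a 1x1 conv iff input channels differ from the
    slim width, otherwise a pass-through.
    """

    def __init__(
        self,
        in_channels: int,
        spec: BlockSpec,
        weight_norm: bool = False,
        name: str = "wdsr",
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.spec = spec
        self.conv1 = Conv2d(in_channels, spec.expanded_width, spec.kernel,
                            weight_norm=weight_norm, name=f"{name}.conv1", rng=rng)
        self.relu = ReLU()
        self.conv2 = Conv2d(spec.expanded_width, spec.slim_width, spec.kernel,
                            weight_norm=weight_norm, name=f"{name}.conv2", rng=rng)
        self.adapter = (
            Conv2d(in_channels, spec.slim_width, 1, name=f"{name}.adapter", rng=rng)
            if in_channels != spec.slim_width
            else None
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        body = self.conv2(self.relu(self.conv1(x, train), train), train)
        skip = self.adapter(x, train) if self.adapter is not None else x
        return body + skip

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dbody = self.conv1.backward(self.relu.backward(self.conv2.backward(dy)))
        dskip = self.adapter.backward(dy) if self.adapter is not None else dy
        return dbody + dskip

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.conv2.params()
        if self.adapter is not None:
            ps += self.adapter.params()
        return ps


class PreactBlock(Layer):
    """Preactivated residual block: BN-ReLU-Conv -> BN-ReLU-Conv + identity."""

    def __init__(
        self,
        in_channels: int,
        width: int,
        kernel: int = 3,
        name: str = "preact",
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.width = width
        self.bn1 = BatchNorm2d(in_channels, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv2d(in_channels, width, kernel, name=f"{name}.conv1", rng=rng)
        self.bn2 = BatchNorm2d(width, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv2d(width, width, kernel, name=f"{name}.conv2", rng=rng)
        self.adapter = (
            Conv2d(in_channels, width, 1, name=f"{name}.adapter", rng=rng)
            if in_channels != width
            else None
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1(self.relu1(self.bn1(x, train), train), train)
        h = self.conv2(self.relu2(self.bn2(h, train), train), train)
        skip = self.adapter(x, train) if self.adapter is not None else x
        return h + skip

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.bn2.backward(self.relu2.backward(self.conv2.backward(dy)))
        dh = self.bn1.backward(self.relu1.backward(self.conv1.backward(dh)))
        dskip = self.adapter.backward(dy) if self.adapter is not None else dy
        return dh + dskip

    def params(self) -> list[Param]:
        ps = (self.bn1.params() + self.conv1.params()
              + self.bn2.params() + self.conv2.params())
        if self.adapter is not None:
            ps += self.adapter.params()
        return ps


class LasppBlock(Layer):
    """Parallel 3x3 atrous branches on a shared input, ReLU'd and summed."""

    def __init__(
        self,
        in_channels: int,
        spec: LasppSpec,
        weight_norm: bool = True,
        name: str = "laspp",
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.spec = spec
        self.branches = [
            Conv2d(in_channels, spec.channels, spec.kernel, dilation=d,
                   weight_norm=weight_norm, name=f"{name}.d{d}", rng=rng)
            for d in spec.dilations
        ]
        self.relus = [ReLU() for _ in self.branches]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        largest = receptive_field(self.spec.kernel, self.spec.dilations[-1])
        if min(x.shape[1], x.shape[2]) < largest:
            warnings.warn(
                f"{self.name}: input {x.shape[1]}x{x.shape[2]} is smaller than "
                f"the largest branch receptive field ({largest}); zero padding "
                "dominates")
        out = None
        for conv, relu in zip(self.branches, self.relus):
            y = relu(conv(x, train), train)
            out = y if out is None else out + y
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        for conv, relu in zip(self.branches, self.relus):
            d = conv.backward(relu.backward(dy))
            dx = d if dx is None else dx + d
        return dx

    def params(self) -> list[Param]:
        return [p for conv in self.branches for p in conv.params()]


def build_wdsr_a(
    spec: BlockSpec,
    weight_norm: bool = False,
    in_channels: int | None = None,
    name: str = "wdsr",
    rng: np.random.Generator | None = None,
) -> WdsrABlock:
    """Build a single wide-activation residual block."""
    cin = spec.slim_width if in_channels is None else in_channels
    return WdsrABlock(cin, spec, weight_norm=weight_norm, name=name, rng=rng)


def build_laspp(
    spec: LasppSpec,
    weight_norm: bool = True,
    in_channels: int | None = None,
    name: str = "laspp",
    rng: np.random.Generator | None = None,
) -> LasppBlock:
    """Build the atrous pyramid block (input channels default to spec.channels)."""
    cin = spec.channels if in_channels is None else in_channels
    return LasppBlock(cin, spec, weight_norm=weight_norm, name=name, rng=rng)


class _UpConv(Layer):
    """Nearest 2x upsample followed by a 3x3 conv without activation."""

    def __init__(self, cin: int, cout: int, name: str, rng: np.random.Generator):
        self.up = UpsampleNearest2()
        self.conv = Conv2d(cin, cout, 3, name=f"{name}.conv", rng=rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.conv(self.up(x, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.up.backward(self.conv.backward(dy))

    def params(self) -> list[Param]:
        return self.conv.params()


# ---------------------------------------------------------------------------
# the full network


class SegmentationModel(Layer):
    """Encoder-decoder mapping an S x S x 1 patch to S x S per-pixel
    two-class probabilities (channels-last; channel 1 = vessel).

    Encoder: input BN -> block(w1) -> pool -> block(w2) -> pool ->
    block(w3) -> pool -> LASPP. Decoder mirrors with (upsample + 3x3
    conv), skip concatenation and a block per level. Head: leaky ReLU on
    the decoder output summed with a leaky-ReLU'd 1x1-conv global
    shortcut from the post-BN input, then a 1x1 conv to 2 channels and a
    per-pixel softmax.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w1, w2, w3 = cfg.encoder_widths
        wn_block = cfg.wn_all and cfg.block_type == "wdsr_a"
        wn_laspp = cfg.wn_laspp

        def make_block(cin: int, width: int, name: str) -> Layer:
            if cfg.block_type == "wdsr_a":
                spec = BlockSpec(width, cfg.expansion)
                return WdsrABlock(cin, spec, weight_norm=wn_block, name=name, rng=rng)
            return PreactBlock(cin, width, name=name, rng=rng)

        self.bn_in = BatchNorm2d(cfg.in_channels, name="bn_in")
        self.enc1 = make_block(cfg.in_channels, w1, "enc1")
        self.pool1 = MaxPool2()
        self.enc2 = make_block(w1, w2, "enc2")
        self.pool2 = MaxPool2()
        self.enc3 = make_block(w2, w3, "enc3")
        self.pool3 = MaxPool2()
        self.laspp = LasppBlock(w3, cfg.laspp, weight_norm=wn_laspp,
                                name="laspp", rng=rng)
        c = cfg.laspp.channels
        self.up3 = _UpConv(c, w3, "up3", rng)
        self.dec3 = make_block(2 * w3, w3, "dec3")
        self.up2 = _UpConv(w3, w2, "up2", rng)
        self.dec2 = make_block(2 * w2, w2, "dec2")
        self.up1 = _UpConv(w2, w1, "up1", rng)
        self.dec1 = make_block(2 * w1, w1, "dec1")
        self.leaky_dec = LeakyReLU(cfg.leaky_slope)
        self.shortcut = Conv2d(cfg.in_channels, w1, 1, name="shortcut", rng=rng)
        self.leaky_short = LeakyReLU(cfg.leaky_slope)
        self.head = Conv2d(w1, cfg.n_classes, 1, name="head", rng=rng)
        self.softmax = SoftmaxChannels()

        self._order = [
            self.bn_in, self.enc1, self.enc2, self.enc3, self.laspp,
            self.up3, self.dec3, self.up2, self.dec2, self.up1, self.dec1,
            self.shortcut, self.head,
        ]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x0 = self.bn_in(x, train)
        e1 = self.enc1(x0, train)
        e2 = self.enc2(self.pool1(e1, train), train)
        e3 = self.enc3(self.pool2(e2, train), train)
        b = self.laspp(self.pool3(e3, train), train)
        d3 = self.dec3(np.concatenate([self.up3(b, train), e3], axis=-1), train)
        d2 = self.dec2(np.concatenate([self.up2(d3, train), e2], axis=-1), train)
        d1 = self.dec1(np.concatenate([self.up1(d2, train), e1], axis=-1), train)
        h = self.leaky_dec(d1, train) + self.leaky_short(self.shortcut(x0, train), train)
        self._w1 = d1.shape[-1]
        return self.softmax(self.head(h, train), train)

    def backward(self, dprob: np.ndarray, from_logits: bool = False) -> np.ndarray:
        """Backpropagate from d(loss)/d(probabilities), or — with
        ``from_logits`` — from d(loss)/d(pre-softmax logits), skipping
        the softmax jacobian (used with the fused training loss)."""
        dh = self.head.backward(
            dprob if from_logits else self.softmax.backward(dprob))
        dx0 = self.shortcut.backward(self.leaky_short.backward(dh))
        dd1 = self.leaky_dec.backward(dh)
        dcat1 = self.dec1.backward(dd1)
        w1 = self._w1
        dd2 = self.up1.backward(dcat1[..., :w1])
        de1 = dcat1[..., w1:]
        dcat2 = self.dec2.backward(dd2)
        w2 = self.up2.conv.cout
        dd3 = self.up2.backward(dcat2[..., :w2])
        de2 = dcat2[..., w2:]
        dcat3 = self.dec3.backward(dd3)
        w3 = self.up3.conv.cout
        db = self.up3.backward(dcat3[..., :w3])
        de3 = dcat3[..., w3:]
        de3 = de3 + self.pool3.backward(self.laspp.backward(db))
        de2 = de2 + self.pool2.backward(self.enc3.backward(de3))
        de1 = de1 + self.pool1.backward(self.enc2.backward(de2))
        dx0 = dx0 + self.enc1.backward(de1)
        return self.bn_in.backward(dx0)

    # -- registry -----------------------------------------------------------

    def params(self) -> list[Param]:
        return [p for layer in self._order for p in layer.params()]

    def param_registry(self) -> dict[str, np.ndarray]:
        return {p.name: p.val for p in self.params()}

    def n_parameters(self) -> int:
        return sum(int(p.val.size) for p in self.params())

    def conv_weight_count(self) -> int:
        return sum(int(p.val.size) for p in self.params() if p.kind == "conv_weight")

    def predict_proba(self, patches: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Forward patches (N, S, S, 1) in eval mode, batched."""
        outs = []
        for i in range(0, len(patches), batch_size):
            outs.append(self.forward(patches[i:i + batch_size], train=False))
        return np.concatenate(outs, axis=0)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-archive checkpoint: parameter registry + config JSON +
        batch-norm running statistics."""
        arrays = {f"param/{p.name}": p.val for p in self.params()}
        for name, layer in self._bn_layers():
            arrays[f"bnstat/{name}/mean"] = layer.running_mean
            arrays[f"bnstat/{name}/var"] = layer.running_var
        arrays["config_json"] = np.frombuffer(
            self.cfg.to_json().encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def _bn_layers(self):
        found = []
        stack = list(self.__dict__.items())
        for name, obj in stack:
            if isinstance(obj, BatchNorm2d):
                found.append((name, obj))
            elif isinstance(obj, (WdsrABlock, PreactBlock)):
                for sub, subobj in obj.__dict__.items():
                    if isinstance(subobj, BatchNorm2d):
                        found.append((f"{name}.{sub}", subobj))
        return found

    @classmethod
    def load(cls, path: str) -> "SegmentationModel":
        with np.load(path) as z:
            cfg = NetworkConfig.from_json(bytes(z["config_json"]).decode())
            model = cls(cfg)
            by_name = {p.name: p for p in model.params()}
            for key in z.files:
                if key.startswith("param/"):
                    by_name[key[len("param/"):]].val = z[key].astype(np.float32)
            for name, layer in model._bn_layers():
                layer.running_mean = z[f"bnstat/{name}/mean"]
                layer.running_var = z[f"bnstat/{name}/var"]
        return model


def build_wa_net(cfg: NetworkConfig | None = None, seed: int = 0) -> SegmentationModel:
    """Build the full network from a config (defaults to the reference WA-Net)."""
    return SegmentationModel(cfg or NetworkConfig(), seed=seed)


def variant_config(name: str, base: NetworkConfig | None = None) -> NetworkConfig:
    """Config for an ablation variant.

    network_1: preactivated residual blocks, LASPP without weight norm.
    network_2: network_1 with channels 32-64-128-256-128-64-32
               (encoder 32/64/128, bottleneck 256; decoder mirrored).
    network_3: WA-Net with 3 LASPP branches (d = 1, 2, 4).
    network_4: WA-Net with 5 LASPP branches (d = 1, 2, 4, 8, 16).
    """
    base = base or NetworkConfig()
    kw = dict(
        encoder_widths=base.encoder_widths,
        laspp=base.laspp,
        expansion=base.expansion,
        leaky_slope=base.leaky_slope,
        patch_size=base.patch_size,
        in_channels=base.in_channels,
        n_classes=base.n_classes,
    )
    if name == "wa_net":
        return NetworkConfig(variant="wa_net", **kw)
    if name == "network_1":
        return NetworkConfig(variant="network_1", block_type="preact",
                             wn_laspp=False, **kw)
    if name == "network_2":
        kw["encoder_widths"] = (32, 64, 128)
        kw["laspp"] = LasppSpec(channels=256, dilations=base.laspp.dilations)
        return NetworkConfig(variant="network_2", block_type="preact",
                             wn_laspp=False, **kw)
    if name == "network_3":
        kw["laspp"] = LasppSpec(channels=base.laspp.channels, dilations=(1, 2, 4))
        return NetworkConfig(variant="network_3", **kw)
    if name == "network_4":
        kw["laspp"] = LasppSpec(channels=base.laspp.channels,
                                dilations=(1, 2, 4, 8, 16))
        return NetworkConfig(variant="network_4", **kw)
    raise ValueError(f"unknown variant {name!r}; one of {VARIANTS}")


def build_variant(name: str, base: NetworkConfig | None = None,
                  seed: int = 0) -> SegmentationModel:
    """Build one of the ablation variants (network_1 .. network_4) or wa_net."""
    return SegmentationModel(variant_config(name, base), seed=seed)
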