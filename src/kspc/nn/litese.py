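"""LiteSE-Net: a slim 3D U-Net with squeeze-excitation normalization.

Encoder of residual blocks (identity shortcuts at constant width, 1x1x1
projection shortcuts across width/stride changes), decoder of convolution
blocks, SE-Norm after every convolution, and additional upsampling paths
that carry low-resolution decoder features straight to the output
resolution. Feature widths along the U are 6, 12, 24, 48, 96, 48, 24, 12, 6;
the default build totals ~1.36M learnable parameters. Two heads: a sigmoid
segmentation probability per voxel, and an optional softplus-positive
3-channel bandwidth feature volume.

Implemented in NumPy with explicit backward passes; batch size 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv3d, Layer, ReLU, SENorm, Sequential, Sigmoid, Softplus, Upsample2x


@dataclass(frozen=True)
class BackboneConfig:
    input_patch: tuple = (144, 144, 144)
    channels: tuple = (6, 12, 24, 48, 96, 48, 24, 12, 6)
    bandwidth_head: bool = True
    seed: int = 0

    def __post_init__(self):
        ch = self.channels
        if len(ch) < 3 or len(ch) % 2 == 0:
            raise ValueError("channel list must have odd length >= 3")
        if any(c <= 0 for c in ch):
            raise ValueError("channel widths must be positive")
        mid = len(ch) // 2
        if ch[mid] != max(ch) or tuple(ch) != tuple(reversed(ch)):
            raise ValueError("channel list must be symmetric around its maximum")

    @property
    def encoder_channels(self) -> tuple:
        return self.channels[: len(self.channels) // 2 + 1]

    @property
    def decoder_channels(self) -> tuple:
        return self.channels[len(self.channels) // 2 + 1 :]


class ConvBlock(Layer):
    """conv3x3x3 -> SE-Norm -> ReLU."""

    def __init__(self, cin, cout, rng, kernel=3, stride=1):
        super().__init__()
        self.seq = Sequential(
            Conv3d(cin, cout, kernel=kernel, stride=stride, rng=rng),
            SENorm(cout, rng=rng),
            ReLU(),
        )

    def forward(self, x):
        return self.seq.forward(x)

    def backward(self, dout):
        return self.seq.backward(dout)

    def iter_named(self, prefix):
        yield f"{prefix}.conv", self.seq.layers[0]
        yield f"{prefix}.senorm", self.seq.layers[1]


class ResBlock(Layer):
    """Residual block: two conv+SE-Norm stages plus identity/projection shortcut."""

    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, kernel=3, stride=stride, rng=rng)
        self.sen1 = SENorm(cout, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, kernel=3, stride=1, rng=rng)
        self.sen2 = SENorm(cout, rng=rng)
        self.proj = (
            Conv3d(cin, cout, kernel=1, stride=stride, rng=rng)
            if (cin != cout or stride != 1)
            else None
        )
        self.relu_out = ReLU()
        self._stride = stride

    def forward(self, x):
        main = self.sen2.forward(
            self.conv2.forward(self.relu1.forward(self.sen1.forward(self.conv1.forward(x))))
        )
        if self.proj is not None:
            short = self.proj.forward(x)
        elif self._stride != 1:
            short = x[:, :: self._stride, :: self._stride, :: self._stride]
        else:
            short = x
        return self.relu_out.forward(main + short)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dx = self.conv1.backward(
            self.sen1.backward(self.relu1.backward(self.conv2.backward(self.sen2.backward(d))))
        )
        if self.proj is not None:
            dx = dx + self.proj.backward(d)
        else:
            dx = dx + d
        return dx

    def iter_named(self, prefix):
        yield f"{prefix}.conv1", self.conv1
        yield f"{prefix}.senorm1", self.sen1
        yield f"{prefix}.conv2", self.conv2
        yield f"{prefix}.senorm2", self.sen2
        if self.proj is not None:
            yield f"{prefix}.proj", self.proj


class DecoderBlock(Layer):
    """Upsample, reduce channels, concatenate the skip, two conv blocks."""

    def __init__(self, cin, width, rng):
        super().__init__()
        self.up = Upsample2x()
        self.reduce = Conv3d(cin, width, kernel=1, rng=rng)
        self.sen_r = SENorm(width, rng=rng)
        self.relu_r = ReLU()
        self.block1 = ConvBlock(2 * width, width, rng)
        self.block2 = ConvBlock(width, width, rng)
        self.width = width

    def forward(self, x, skip):
        u = self.relu_r.forward(self.sen_r.forward(self.reduce.forward(self.up.forward(x))))
        cat = np.concatenate([u, skip], axis=0)
        return self.block2.forward(self.block1.forward(cat))

    def backward(self, dout):
        dcat = self.block1.backward(self.block2.backward(dout))
        du, dskip = dcat[: self.width], dcat[self.width :]
        dx = self.up.backward(
            self.reduce.backward(self.sen_r.backward(self.relu_r.backward(du)))
        )
        return dx, dskip

    def iter_named(self, prefix):
        yield f"{prefix}.reduce", self.reduce
        yield f"{prefix}.senorm", self.sen_r
        yield from self.block1.iter_named(f"{prefix}.conv_a")
        yield from self.block2.iter_named(f"{prefix}.conv_b")


class LiteSENet:
    """The coarse-segmentation backbone; see module docstring."""

    DOWNSAMPLE_FACTOR = 16

    def __init__(self, config: BackboneConfig = BackboneConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc = config.encoder_channels  # e.g. (6, 12, 24, 48, 96)
        dec = config.decoder_channels  # e.g. (48, 24, 12, 6)

        self.stem = ConvBlock(1, enc[0], rng)
        self.enc_blocks = [ResBlock(enc[0], enc[0], rng, stride=1)]
        for cin, cout in zip(enc[:-1], enc[1:]):
            self.enc_blocks.append(ResBlock(cin, cout, rng, stride=2))
        self.bottleneck = ResBlock(enc[-1], enc[-1], rng, stride=1)

        self.dec_blocks = []
        cin = enc[-1]
        for width in dec:
            self.dec_blocks.append(DecoderBlock(cin, width, rng))
            cin = width

        # extra upsampling paths: deep decoder features lifted to full resolution
        self.deep_paths = []
        for i, width in enumerate(dec[:-1]):
            hops = len(dec) - 1 - i
            layers = [Conv3d(width, dec[-1], kernel=1, rng=rng)]
            layers += [Upsample2x() for _ in range(hops)]
            self.deep_paths.append(Sequential(*layers))

        self.head_seg = Conv3d(dec[-1], 1, kernel=1, rng=rng)
        self.seg_act = Sigmoid()
        if config.bandwidth_head:
            self.head_bw = Conv3d(dec[-1], 3, kernel=1, rng=rng)
            # start the predicted bandwidth near 2 mm: softplus(1.854) ~ 2
            self.head_bw.params["b"][:] = 1.854
            self.bw_act = Softplus()
        else:
            self.head_bw = None

    # -- bookkeeping ---------------------------------------------------------
    def iter_named_layers(self):
        yield from self.stem.iter_named("stem")
        for i, blk in enumerate(self.enc_blocks):
            yield from blk.iter_named(f"encoder{i}")
        yield from self.bottleneck.iter_named("bottleneck")
        for i, blk in enumerate(self.dec_blocks):
            yield from blk.iter_named(f"decoder{i}")
        for i, path in enumerate(self.deep_paths):
            yield f"deep_path{i}.conv", path.layers[0]
        yield "head.segmentation", self.head_seg
        if self.head_bw is not None:
            yield "head.bandwidth", self.head_bw

    def parameter_audit(self):
        """Per-layer learnable-parameter counts, (name, count) rows."""
        return [(name, layer.parameter_count()) for name, layer in self.iter_named_layers()]

    def parameters(self):
        for name, layer in self.iter_named_layers():
            for pname, arr in layer.params.items():
                yield f"{name}.{pname}", layer, pname, arr

    def zero_grad(self):
        for _, layer in self.iter_named_layers():
            layer.zero_grad()

    # -- forward / backward --------------------------------------------------
    def forward(self, volume: np.ndarray):
        """volume: (D, H, W) with every dim divisible by 16.

        Returns (seg_probs (D,H,W), bandwidth (3,D,H,W) or None).
        """
        if any(d % self.DOWNSAMPLE_FACTOR for d in volume.shape):
            raise ValueError(
                f"input dims {volume.shape} must be divisible by {self.DOWNSAMPLE_FACTOR}"
            )
        x = volume[None, ...].astype(float)
        x = self.stem.forward(x)
        skips = []
        x = self.enc_blocks[0].forward(x)
        skips.append(x)
        for blk in self.enc_blocks[1:-1]:
            x = blk.forward(x)
            skips.append(x)
        x = self.enc_blocks[-1].forward(x)
        x = self.bottleneck.forward(x)

        deep_feats = []
        for blk, skip in zip(self.dec_blocks, reversed(skips)):
            x = blk.forward(x, skip)
            deep_feats.append(x)

        feat = x
        for path, deep in zip(self.deep_paths, deep_feats[:-1]):
            feat = feat + path.forward(deep)
        self._head_input_shape = feat.shape

        seg = self.seg_act.forward(self.head_seg.forward(feat))[0]
        bw = self.bw_act.forward(self.head_bw.forward(feat)) if self.head_bw else None
        return seg, bw

    def backward(self, dseg: np.ndarray, dbw: np.ndarray | None = None):
        """Backpropagate gradients w.r.t. the two head outputs."""
        dfeat = self.head_seg.backward(self.seg_act.backward(dseg[None, ...]))
        if dbw is not None and self.head_bw is not None:
            dfeat = dfeat + self.head_bw.backward(self.bw_act.backward(dbw))

        ddeep = [np.zeros(1)] * len(self.dec_blocks)
        dx = dfeat
        for i, path in enumerate(self.deep_paths):
            ddeep[i] = path.backward(dfeat)
        ddeep[-1] = dx

        dskips = []
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dcur = ddeep[i] if i == len(self.dec_blocks) - 1 else ddeep[i] + dx
            dx, dskip = self.dec_blocks[i].backward(dcur)
            dskips.append(dskip)
        dskips.reverse()

        # dskips is now ordered deepest skip first (for enc_blocks[-2]) to the
        # full-resolution skip last (for enc_blocks[0]).
        dx = self.bottleneck.backward(dx)
        dx = self.enc_blocks[-1].backward(dx)
        for blk, dskip in zip(reversed(self.enc_blocks[1:-1]), dskips[:-1]):
            dx = blk.backward(dx + dskip)
        dx = self.enc_blocks[0].backward(dx + dskips[-1])
        dx = self.stem.backward(dx)
        return dx[0]


def build_litese_net(config: BackboneConfig = BackboneConfig()) -> LiteSENet:
    """Build the backbone from a config (deterministic in config.seed)."""
    return LiteSENet(config)


def count_parameters(model: LiteSENet) -> int:
    """Total number of learnable scalars in the model."""
    return sum(count for _, count in model.parameter_audit())
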