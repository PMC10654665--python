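"""High-resolution multi-branch convolutional backbone for heatmap regression.

The network keeps a high-resolution stream throughout and adds progressively
lower-resolution branches (halved resolution, doubled width) across four
stages.  Branches exchange information through fusion units that downsample
with strided 3x3 convolutions and upsample with nearest-neighbour sampling
followed by a 1x1 convolution.  The head concatenates all branches at the
highest resolution and maps them to one output channel per landmark, so the
output spatial side is always input_side / 4.

Defaults are a desk-scale instance (base width 8, one multi-resolution block
per stage); the full-scale widths/depths (18/36/72/144, blocks 1/4/3, four
residual units per block) are reachable through :class:`BackboneConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tape, Var
from .core import ContractError
from .nn import Adam, BatchNorm2d, Conv2d, ConvBNReLU, Linear, Module


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    """Topology and width configuration.

    ``stage_blocks`` counts multi-resolution blocks in stages 2-4 (full scale:
    (1, 4, 3)); each block holds ``units_per_block`` residual units per branch
    followed by a fusion unit.  Branch widths are (C, 2C, 4C, 8C).
    """

    input_side: int = 256
    in_channels: int = 1
    base_width: int = 8  # full scale: 18
    stage_blocks: Tuple[int, int, int] = (1, 1, 1)  # full scale: (1, 4, 3)
    units_per_block: int = 2  # full scale: 4
    stage1_units: int = 2  # full scale: 4
    bottleneck_width: int = 16  # full scale: 64
    bottleneck_expansion: int = 2  # full scale: 4
    head_width: int = 64
    out_channels: int = 23

    def __post_init__(self) -> None:
        if self.input_side % 32 != 0:
            raise ConfigError(f"input side must be divisible by 32, got {self.input_side}")
        if len(self.stage_blocks) != 3:
            raise ConfigError("stage_blocks must list block counts for stages 2-4")
        if min(self.stage_blocks) < 1 or self.units_per_block < 1:
            raise ConfigError("block and unit counts must be >= 1")

    @property
    def branch_widths(self) -> Tuple[int, int, int, int]:
        c = self.base_width
        return (c, 2 * c, 4 * c, 8 * c)

    @property
    def output_side(self) -> int:
        return self.input_side // 4

    @classmethod
    def full_scale(cls, input_side: int = 256, in_channels: int = 1) -> "BackboneConfig":
        return cls(
            input_side=input_side,
            in_channels=in_channels,
            base_width=18,
            stage_blocks=(1, 4, 3),
            units_per_block=4,
            stage1_units=4,
            bottleneck_width=64,
            bottleneck_expansion=4,
        )


class BasicUnit(Module):
    """Residual unit: two 3x3 convolutions with an identity skip."""

    def __init__(self, c: int, rng: np.random.Generator) -> None:
        self.cb1 = ConvBNReLU(c, c, 3, rng)
        self.cb2 = ConvBNReLU(c, c, 3, rng, act=False)

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        y = self.cb2(tape, self.cb1(tape, x, train), train)
        return ad.relu(tape, ad.add(tape, x, y))


class BottleneckUnit(Module):
    """1x1 reduce / 3x3 / 1x1 expand residual unit with optional projection."""

    def __init__(self, cin: int, width: int, cout: int, rng: np.random.Generator) -> None:
        self.cb1 = ConvBNReLU(cin, width, 1, rng)
        self.cb2 = ConvBNReLU(width, width, 3, rng)
        self.cb3 = ConvBNReLU(width, cout, 1, rng, act=False)
        self.proj = ConvBNReLU(cin, cout, 1, rng, act=False) if cin != cout else None

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        y = self.cb3(tape, self.cb2(tape, self.cb1(tape, x, train), train), train)
        skip = self.proj(tape, x, train) if self.proj is not None else x
        return ad.relu(tape, ad.add(tape, skip, y))


class _DownPath(Module):
    """Chain of strided 3x3 convolutions carrying branch i down to branch j."""

    def __init__(self, cin: int, cout: int, steps: int, rng: np.random.Generator) -> None:
        layers = []
        for s in range(steps):
            last = s == steps - 1
            layers.append(ConvBNReLU(cin if s == 0 else cin, cout if last else cin,
                                     3, rng, stride=2, act=not last))
        self.layers = layers

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        for layer in self.layers:
            x = layer(tape, x, train)
        return x


class _UpPath(Module):
    """Nearest-neighbour upsample followed by a 1x1 convolution."""

    def __init__(self, cin: int, cout: int, factor: int, rng: np.random.Generator) -> None:
        self.factor = factor
        self.cb = ConvBNReLU(cin, cout, 1, rng, act=False)

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        return self.cb(tape, ad.upsample_nearest(tape, x, self.factor), train)


class FuseUnit(Module):
    """Full cross-branch exchange: every output branch sums a transform of
    every input branch (identity on the diagonal)."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator) -> None:
        self.n = len(widths)
        self.cross_enabled = True  # test hook: disable off-diagonal paths
        paths: List[List[Optional[Module]]] = []
        for j in range(self.n):
            row: List[Optional[Module]] = []
            for i in range(self.n):
                if i == j:
                    row.append(None)
                elif i < j:
                    row.append(_DownPath(widths[i], widths[j], j - i, rng))
                else:
                    row.append(_UpPath(widths[i], widths[j], 2 ** (i - j), rng))
            paths.append(row)
        self.paths = paths

    def __call__(self, tape: Tape, xs: Sequence[Var], train: bool) -> List[Var]:
        outs: List[Var] = []
        for j in range(self.n):
            acc = xs[j]
            if self.cross_enabled:
                for i in range(self.n):
                    if i == j:
                        continue
                    acc = ad.add(tape, acc, self.paths[j][i](tape, xs[i], train))
            outs.append(ad.relu(tape, acc))
        return outs


class MultiResBlock(Module):
    """Per-branch residual units followed by a fusion unit."""

    def __init__(self, widths: Sequence[int], units: int, rng: np.random.Generator) -> None:
        self.branches = [
            [BasicUnit(c, rng) for _ in range(units)] for c in widths
        ]
        self.fuse = FuseUnit(widths, rng)

    def __call__(self, tape: Tape, xs: Sequence[Var], train: bool) -> List[Var]:
        ys = []
        for units, x in zip(self.branches, xs):
            for unit in units:
                x = unit(tape, x, train)
            ys.append(x)
        return self.fuse(tape, ys, train)

    def named_params(self, prefix: str = ""):  # branches is a list of lists
        out = []
        for bi, units in enumerate(self.branches):
            for ui, unit in enumerate(units):
                out.extend(unit.named_params(prefix=f"{prefix}branches.{bi}.{ui}."))
        out.extend(self.fuse.named_params(prefix=f"{prefix}fuse."))
        return out

    def named_buffers(self, prefix: str = ""):
        out = []
        for bi, units in enumerate(self.branches):
            for ui, unit in enumerate(units):
                out.extend(unit.named_buffers(prefix=f"{prefix}branches.{bi}.{ui}."))
        out.extend(self.fuse.named_buffers(prefix=f"{prefix}fuse."))
        return out


class Backbone(Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator) -> None:
        widths = cfg.branch_widths
        stem_w = cfg.bottleneck_width
        s1_out = cfg.bottleneck_width * cfg.bottleneck_expansion

        self.stem1 = ConvBNReLU(cfg.in_channels, stem_w, 3, rng, stride=2)
        self.stem2 = ConvBNReLU(stem_w, stem_w, 3, rng, stride=2)

        self.stage1 = [
            BottleneckUnit(stem_w if u == 0 else s1_out, cfg.bottleneck_width, s1_out, rng)
            for u in range(cfg.stage1_units)
        ]
        # transitions create the new branch for each stage
        self.trans_b0 = ConvBNReLU(s1_out, widths[0], 3, rng)
        self.trans_b1 = ConvBNReLU(s1_out, widths[1], 3, rng, stride=2)
        self.stage2 = [
            MultiResBlock(widths[:2], cfg.units_per_block, rng)
            for _ in range(cfg.stage_blocks[0])
        ]
        self.trans_b2 = ConvBNReLU(widths[1], widths[2], 3, rng, stride=2)
        self.stage3 = [
            MultiResBlock(widths[:3], cfg.units_per_block, rng)
            for _ in range(cfg.stage_blocks[1])
        ]
        self.trans_b3 = ConvBNReLU(widths[2], widths[3], 3, rng, stride=2)
        self.stage4 = [
            MultiResBlock(widths, cfg.units_per_block, rng)
            for _ in range(cfg.stage_blocks[2])
        ]
        self.head1 = ConvBNReLU(sum(widths), cfg.head_width, 1, rng)
        self.head2 = Conv2d(cfg.head_width, cfg.out_channels, 1, rng, bias=True)

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        x = self.stem2(tape, self.stem1(tape, x, train), train)
        for unit in self.stage1:
            x = unit(tape, x, train)
        xs = [self.trans_b0(tape, x, train), self.trans_b1(tape, x, train)]
        for block in self.stage2:
            xs = block(tape, xs, train)
        xs = xs + [self.trans_b2(tape, xs[-1], train)]
        for block in self.stage3:
            xs = block(tape, xs, train)
        xs = xs + [self.trans_b3(tape, xs[-1], train)]
        for block in self.stage4:
            xs = block(tape, xs, train)
        ups = [xs[0]] + [
            ad.upsample_nearest(tape, xb, 2 ** k) for k, xb in enumerate(xs[1:], start=1)
        ]
        y = self.head1(tape, ad.concat_channels(tape, ups), train)
        return self.head2(tape, y)

    def set_cross_branch(self, enabled: bool) -> None:
        for stage in (self.stage2, self.stage3, self.stage4):
            for block in stage:
                block.fuse.cross_enabled = enabled


class HeatmapModel:
    """A backbone plus its config, optimizer state hook, and training counters."""

    def __init__(self, cfg: BackboneConfig, net: Backbone) -> None:
        self.cfg = cfg
        self.net = net
        self.epoch = 0

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Heatmaps (N, 23, S/4, S/4) for an image batch (N, C, S, S)."""
        x = self._check_images(images)
        tape = Tape()
        return self.net(tape, Var(x), train).data

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ContractError(f"expected (N, {self.cfg.in_channels}, S, S) images, got {x.shape}")
        if x.shape[2] != self.cfg.input_side or x.shape[3] != self.cfg.input_side:
            raise ContractError(
                f"expected input side {self.cfg.input_side}, got {x.shape[2]}x{x.shape[3]}"
            )
        return x

    def set_cross_branch(self, enabled: bool) -> None:
        self.net.set_cross_branch(enabled)

    def save(self, path) -> None:
        import json

        state = self.net.state_dict()
        meta = dict(asdict(self.cfg))
        meta["epoch"] = self.epoch
        np.savez(path, __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path) -> "HeatmapModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"].tobytes()).decode())
            epoch = meta.pop("epoch", 0)
            meta["stage_blocks"] = tuple(meta["stage_blocks"])
            cfg = BackboneConfig(**meta)
            model = build(cfg, seed=0)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.net.load_state_dict(state)
        model.epoch = epoch
        return model


def build(cfg: BackboneConfig, seed: int = 0) -> HeatmapModel:
    """Deterministically initialize a backbone from a config and a seed."""
    rng = np.random.default_rng(seed)
    return HeatmapModel(cfg, Backbone(cfg, rng))


def make_optimizer(model: HeatmapModel, lr: float = 1e-4) -> Adam:
    return Adam(model.net.params(), lr=lr)


def train_backbone_epoch(
    model: HeatmapModel,
    images: np.ndarray,
    target_maps: np.ndarray,
    optimizer: Adam,
    batch_size: int = 16,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """One pass over the dataset minimizing the summed per-channel L2 loss.

    ``target_maps`` has shape (N, 23, S/4, S/4).  Returns the mean per-image
    loss over the epoch.
    """
    x = model._check_images(images)
    t = np.asarray(target_maps, dtype=float)
    n = x.shape[0]
    if n == 0:
        raise DataError("empty dataset")
    if t.shape[0] != n:
        raise ContractError("images and targets differ in count")
    order = np.arange(n) if rng is None else rng.permutation(n)
    total = 0.0
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        tape = Tape()
        xb = Var(x[idx])
        pred = model.net(tape, xb, train=True)
        loss = ad.sse_loss(tape, pred, t[idx], scale=1.0 / len(idx))
        optimizer.zero_grad()
        tape.backward(loss)
        optimizer.step()
        total += float(loss.data) * len(idx)
    model.epoch += 1
    return total / n
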