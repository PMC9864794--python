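"""Encoder–decoder segmentation network (U-Net style) in numpy.

The network maps an Nf-channel indicator stack to per-pixel class logits over
Nc contrast classes: repeated (conv 3×3 + ReLU)×2 blocks with 2× max-pool
downsampling, a bottleneck, then symmetric nearest-neighbour upsampling with
channel-concatenation skip connections and a final 1×1 projection.  Softmax is
applied by the loss during training and by :meth:`UNet.predict_proba` at
inference.

Two presets are provided: ``paper`` is the classic 4-level / base-64 design;
``reduced`` (2 levels, base 8) trains in minutes on one CPU and is the default
for desk-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers import Conv2d, Layer, MaxPool2, ReLU, UpsampleNearest2, softmax


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters."""

    input_channels: int
    output_classes: int
    image_side: int
    depth: int = 2
    base_channels: int = 8
    preset: str = "reduced"

    def __post_init__(self) -> None:
        if self.image_side % (2**self.depth) != 0:
            raise ValueError(
                f"image side {self.image_side} not divisible by 2^depth={2**self.depth}"
            )

    @classmethod
    def paper(cls, input_channels: int, output_classes: int, image_side: int = 64):
        return cls(input_channels, output_classes, image_side, depth=4,
                   base_channels=64, preset="paper")

    @classmethod
    def reduced(cls, input_channels: int, output_classes: int, image_side: int = 32):
        return cls(input_channels, output_classes, image_side, depth=2,
                   base_channels=8, preset="reduced")


class _ConvBlock:
    """(conv 3×3 → ReLU) × 2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers: list[Layer] = [
            Conv2d(c_in, c_out, 3, rng), ReLU(), Conv2d(c_out, c_out, 3, rng), ReLU()
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Encoder–decoder with skip connections; deterministic given the seed."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, c0 = spec.depth, spec.base_channels
        ch = [c0 * 2**i for i in range(d + 1)]

        self.encoders = []
        c_in = spec.input_channels
        for i in range(d):
            self.encoders.append(_ConvBlock(c_in, ch[i], rng))
            c_in = ch[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _ConvBlock(ch[d - 1], ch[d], rng)
        self.upsamples = [UpsampleNearest2() for _ in range(d)]
        self.up_reduce = [Conv2d(ch[i + 1], ch[i], 3, rng) for i in reversed(range(d))]
        self.up_relu = [ReLU() for _ in range(d)]
        self.decoders = [_ConvBlock(2 * ch[i], ch[i], rng) for i in reversed(range(d))]
        self.head = Conv2d(ch[0], spec.output_classes, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.encoders:
            out += b.layers
        out += self.bottleneck.layers
        out += self.up_reduce
        for b in self.decoders:
            out += b.layers
        out.append(self.head)
        return out

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for l in self._layers() for p in l.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for l in self._layers() for g in l.grads]

    def zero_grad(self) -> None:
        for l in self._layers():
            for g in l.grads:
                g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class logits, shape (N, Nc, H, W)."""
        x = np.ascontiguousarray(x, np.float32)
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} input channels, got {x.shape[1]}"
            )
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, red, relu, dec, skip in zip(
            self.upsamples, self.up_reduce, self.up_relu, self.decoders, reversed(skips)
        ):
            x = relu.forward(red.forward(up.forward(x)))
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for dec, relu, red, up, c_skip in zip(
            reversed(self.decoders),
            reversed(self.up_relu),
            reversed(self.up_reduce),
            reversed(self.upsamples),
            reversed(self._skip_channels),
        ):
            dy = dec.backward(dy)
            dskip, dy = dy[:, :c_skip], dy[:, c_skip:]
            dskips.append(dskip)
            dy = up.backward(red.backward(relu.backward(dy)))
        dy = self.bottleneck.backward(dy)
        dskips.reverse()  # deepest level first, matching reversed(encoders)
        for enc, pool, dskip in zip(
            reversed(self.encoders), reversed(self.pools), dskips
        ):
            dy = pool.backward(dy) + dskip
            dy = enc.backward(dy)

    # -- inference ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=1)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: npz of parameters plus a plain-text spec sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.parameters)})
        sidecar = {
            "input_channels": self.spec.input_channels,
            "output_classes": self.spec.output_classes,
            "image_side": self.spec.image_side,
            "depth": self.spec.depth,
            "base_channels": self.spec.base_channels,
            "preset": self.spec.preset,
            "n_parameters": self.n_parameters(),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "UNet":
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        spec = NetworkSpec(
            sidecar["input_channels"], sidecar["output_classes"], sidecar["image_side"],
            depth=sidecar["depth"], base_channels=sidecar["base_channels"],
            preset=sidecar["preset"],
        )
        net = cls(spec, seed=0)
        with np.load(path if str(path).endswith(".npz") else str(path)) as data:
            for i, p in enumerate(net.parameters):
                p[...] = data[f"p{i}"]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet:
    """Construct a deterministic, seed-initialized segmentation network."""
    return UNet(spec, seed)
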