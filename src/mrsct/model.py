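"""U-NET encoder-decoder for MRI -> synthetic-CT translation.

The network takes a three-channel image (three consecutive axial MRI
slices), and returns a one-channel image of the same in-plane size: the
synthetic CT of the middle slice.  Encoder levels are two (conv -> batch
norm -> ReLU) stages followed by 2x2 max pooling with filter doubling;
decoder levels mirror them with a 2x2 transposed-convolution upsample and a
skip concatenation from the matching encoder level.  The final layer is a
linear 1x1 convolution — HU regression has no natural output bound, so no
activation is applied.

Training happens in scaled units for numerical conditioning: MRI divided by
1000, CT mapped by (HU + 1000) / 2000.  ``predict_sct`` inverts the output
scaling, so predictions are always reported in HU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .core import TrainingExample, Volume3D
from .nn import BatchNorm2d, Conv2d, Layer, MaxPool2x2, ReLU, UpConv2x2

#: Input/output value scaling used for optimization.
MRI_SCALE = 1.0 / 1000.0


def hu_to_unit(hu: np.ndarray) -> np.ndarray:
    """Map Hounsfield units onto the [0, ~1.1] training scale."""
    return (hu + 1000.0) / 2000.0


def unit_to_hu(y: np.ndarray) -> np.ndarray:
    return y * 2000.0 - 1000.0


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling steps; input spatial dims must be
    divisible by ``2**depth``.  ``base_filters`` is the channel count of the
    first encoder level and doubles at every level.
    """

    depth: int = 4
    base_filters: int = 64
    in_channels: int = 3
    out_channels: int = 1
    kernel_size: int = 3
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class ConvBlock(Layer):
    """(conv -> BN -> ReLU) x 2."""

    def __init__(self, c_in, c_out, k, rng, dtype):
        self.layers = [
            Conv2d(c_in, c_out, k, rng, dtype),
            BatchNorm2d(c_out, dtype=dtype),
            ReLU(),
            Conv2d(c_out, c_out, k, rng, dtype),
            BatchNorm2d(c_out, dtype=dtype),
            ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class UNet:
    """The full encoder-decoder with skip connections."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dt = config.np_dtype
        k = config.kernel_size
        f = config.base_filters
        d = config.depth
        self.encoders: list[ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        c_in = config.in_channels
        for level in range(d):
            c_out = f * 2**level
            self.encoders.append(ConvBlock(c_in, c_out, k, rng, dt))
            self.pools.append(MaxPool2x2())
            c_in = c_out
        self.bottleneck = ConvBlock(c_in, f * 2**d, k, rng, dt)
        self.upconvs: list[UpConv2x2] = []
        self.decoders: list[ConvBlock] = []
        for level in range(d):  # index = level, shallowest first
            c_lvl = f * 2**level
            self.upconvs.append(UpConv2x2(c_lvl * 2, c_lvl, rng, dt))
            self.decoders.append(ConvBlock(c_lvl * 2, c_lvl, k, rng, dt))
        self.final = Conv2d(f, config.out_channels, 1, rng, dt)
        self._skip_channels = [f * 2**level for level in range(d)]
        self._dskips: list[np.ndarray] | None = None

    # -- parameter plumbing -------------------------------------------------
    def _ordered_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        layers.extend(self.encoders)
        layers.append(self.bottleneck)
        layers.extend(self.upconvs)
        layers.extend(self.decoders)
        layers.append(self.final)
        return layers

    def params(self) -> list[np.ndarray]:
        return [p for l in self._ordered_layers() for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self._ordered_layers() for g in l.grads()]

    def state_arrays(self) -> list[np.ndarray]:
        """Trainable parameters plus batch-norm running statistics."""
        arrays = list(self.params())
        for l in self._ordered_layers():
            if isinstance(l, ConvBlock):
                for sub in l.layers:
                    if isinstance(sub, BatchNorm2d):
                        arrays.extend([sub.running_mean, sub.running_var])
        return arrays

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Forward pass on an NHWC batch (B, H, W, in_channels)."""
        d = self.config.depth
        h_dim, w_dim = x.shape[1], x.shape[2]
        if h_dim % 2**d or w_dim % 2**d:
            raise ValueError(
                f"input {h_dim}x{w_dim} not divisible by 2^depth = {2**d}"
            )
        skips = []
        h = x.astype(self.config.np_dtype, copy=False)
        for enc, pool in zip(self.encoders, self.pools):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for level in range(d - 1, -1, -1):
            h = self.upconvs[level].forward(h, train)
            h = np.concatenate([skips[level], h], axis=-1)
            h = self.decoders[level].forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dout: np.ndarray) -> None:
        d = self.config.depth
        grad = self.final.backward(dout)
        dskips: list[np.ndarray | None] = [None] * d
        for level in range(d):  # shallowest decoder first (reverse of forward)
            grad = self.decoders[level].backward(grad)
            c_skip = self._skip_channels[level]
            dskips[level] = grad[..., :c_skip]
            grad = self.upconvs[level].backward(grad[..., c_skip:])
        grad = self.bottleneck.backward(grad)
        for level in range(d - 1, -1, -1):
            grad = self.pools[level].backward(grad)
            grad = grad + dskips[level]
            grad = self.encoders[level].backward(grad)

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)


def build_unet(config: UNetConfig) -> UNet:
    """Construct a seeded U-NET from its configuration."""
    return UNet(config)


def predict_sct(model: UNet, example: TrainingExample) -> np.ndarray:
    """Synthetic CT (HU) for the middle slice of one three-channel input."""
    x = example.mri.transpose(1, 2, 0)[None].astype(model.config.np_dtype) * MRI_SCALE
    y = model.forward(x, train=False)
    if y.shape[1:3] != example.ct.shape:
        raise ValueError(f"output {y.shape[1:3]} != target {example.ct.shape}")
    return unit_to_hu(y[0, :, :, 0].astype(np.float64))


def predict_volume(model: UNet, examples: list[TrainingExample], spacing=(3.0, 1.5, 1.5)) -> Volume3D:
    """Stack per-slice predictions into a synthetic-CT volume (HU)."""
    ordered = sorted(examples, key=lambda e: e.slice_index)
    return Volume3D(np.stack([predict_sct(model, e) for e in ordered]), spacing)


def save_checkpoint(model: UNet, path) -> None:
    """Serialize config + parameters + BN running stats (npz container).

    The file keeps exactly the given name (e.g. ``epoch_3.ckpt``).
    """
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        config = UNetConfig(**json.loads(str(data["config"])))
        model = UNet(config)
        targets = model.state_arrays()
        for i, target in enumerate(targets):
            src = data[f"arr_{i}"]
            if src.shape != target.shape:
                raise ValueError(f"checkpoint array {i} shape mismatch")
            target[...] = src
    return model


def clone_state(model: UNet) -> list[np.ndarray]:
    """In-memory snapshot of the model state (for per-epoch checkpoints)."""
    return [a.copy() for a in model.state_arrays()]


def restore_state(model: UNet, state: list[np.ndarray]) -> None:
    for target, src in zip(model.state_arrays(), state):
        target[...] = src
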