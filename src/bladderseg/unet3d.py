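"""Progressive-dilated 3D U-Net family (4, 5 or 6 encoder blocks).

Each encoder level stacks three 3x3x3 convolutions whose dilation rate
alternates 1 -> 2 -> 4, so the receptive field grows within the level without
extra parameters. The first convolution of every level carries stride 2
(downsampling). A bridge of two convolutions plus a residual block (two
convolutions with no normalization, PReLU only, added to the block input)
sits at the bottom. The decoder upsamples level by level, concatenating each
upsampled map with the dilation-4 encoder output at the matching resolution,
and ends in a 3-filter (1,1,1) convolution with softmax over the three
classes (background, bladder wall, tumor).

Because every encoder level downsamples, there is no full-resolution encoder
feature map; the final decoder level therefore upsamples to full resolution
without a skip concatenation. All convolutions except the residual pair are
followed by batch normalization and PReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import Adam, BatchNorm, Conv3D, Parameter, PReLU, Softmax, Upsample3D

__all__ = [
    "ModelSpec",
    "LayerRecord",
    "LayerSummary",
    "UNet3D",
    "build_model",
    "summarize",
    "default_stride_policy",
    "ShapeFeasibilityError",
]


class ShapeFeasibilityError(ValueError):
    """A stride policy that cannot be inverted by x2 upsampling."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters for one member of the U-Net family."""

    num_blocks: int = 5
    base_filters: int = 16
    filter_growth: float = 2.0
    filter_cap: int = 256
    kernel: tuple[int, int, int] = (3, 3, 3)
    dilation_schedule: tuple[int, int, int] = (1, 2, 4)
    input_shape: tuple[int, int, int, int] = (128, 128, 32, 1)
    num_classes: int = 3
    stride_policy: tuple[tuple[int, int, int], ...] | None = None
    merge_mode: str = "concat"  # "concat" (default) or "add"
    seed: int = 0

    def filters_at(self, level: int) -> int:
        """Channel width of encoder level ``level`` (0-based)."""
        return min(self.filter_cap,
                   int(round(self.base_filters * self.filter_growth ** level)))

    def resolved_strides(self) -> tuple[tuple[int, int, int], ...]:
        if self.stride_policy is not None:
            return tuple(tuple(int(c) for c in s) for s in self.stride_policy)
        return default_stride_policy(self.num_blocks, self.input_shape)

    def validate(self) -> None:
        if self.num_blocks not in (4, 5, 6):
            raise ValueError(f"num_blocks must be 4, 5 or 6, got {self.num_blocks}")
        if self.merge_mode not in ("concat", "add"):
            raise ValueError(f"merge_mode must be 'concat' or 'add', got {self.merge_mode!r}")
        strides = self.resolved_strides()
        if len(strides) != self.num_blocks:
            raise ValueError(
                f"stride_policy has {len(strides)} entries for {self.num_blocks} blocks"
            )
        spatial = list(self.input_shape[:3])
        for level, stride in enumerate(strides):
            for axis, (d, s) in enumerate(zip(spatial, stride)):
                if s not in (1, 2):
                    raise ValueError(f"stride components must be 1 or 2, got {s}")
                if d < s or (s == 2 and d % 2 != 0):
                    raise ShapeFeasibilityError(
                        f"level {level}, axis {axis}: size {d} cannot be halved "
                        f"and restored by x2 upsampling"
                    )
                spatial[axis] = d // s


def default_stride_policy(
    num_blocks: int, input_shape: Sequence[int]
) -> tuple[tuple[int, int, int], ...]:
    """Stride (2,2,2) per level until an axis can no longer halve.

    An axis whose current size is odd or already 1 gets stride 1 for the
    remaining levels; the other axes keep halving. For a (128,128,32) input
    this yields full (2,2,2) striding for up to 5 blocks (depth 32 -> 1) and
    clamps the depth axis at block 6.
    """
    spatial = list(int(d) for d in input_shape[:3])
    policy = []
    for _ in range(num_blocks):
        stride = []
        for axis in range(3):
            if spatial[axis] >= 2 and spatial[axis] % 2 == 0:
                stride.append(2)
                spatial[axis] //= 2
            else:
                stride.append(1)
        policy.append(tuple(stride))
    return tuple(policy)


@dataclass(frozen=True)
class LayerRecord:
    """One convolutional layer's structural facts."""

    role: str  # encoder / bridge / residual / decoder / head
    level: int | None
    kernel: tuple[int, int, int]
    dilation: int
    stride: tuple[int, int, int]
    in_channels: int
    filters: int
    normalized: bool
    activation: str


@dataclass
class LayerSummary:
    """Structural table of a built model, for counting-query verification."""

    spec: ModelSpec
    records: list[LayerRecord] = field(default_factory=list)

    def count(self, role: str | None = None, **conditions) -> int:
        n = 0
        for r in self.records:
            if role is not None and r.role != role:
                continue
            if all(getattr(r, k) == v for k, v in conditions.items()):
                n += 1
        return n

    @property
    def encoder_convs(self) -> int:
        return self.count("encoder")

    @property
    def decoder_convs(self) -> int:
        return self.count("decoder")

    @property
    def unnormalized_convs(self) -> int:
        return self.count(normalized=False)

    @property
    def head(self) -> LayerRecord:
        return next(r for r in self.records if r.role == "head")

    def parameter_count(self) -> int:
        """Closed-form trainable parameter total derived from the table.

        Per convolution: k0*k1*k2*c_in*c_out weights + c_out biases; each
        normalized convolution adds 2*c_out (scale, shift) and every
        convolution's PReLU adds c_out slopes.
        """
        total = 0
        for r in self.records:
            k = int(np.prod(r.kernel))
            total += k * r.in_channels * r.filters + r.filters
            if r.normalized:
                total += 2 * r.filters
            total += r.filters  # PReLU slope per channel
        return total


class UNet3D:
    """A built model: explicit forward/backward over the numpy layer stack."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        strides = spec.resolved_strides()
        self.strides = strides
        rng = np.random.default_rng(spec.seed)
        records: list[LayerRecord] = []

        def conv_unit(in_ch, out_ch, stride, dilation, role, level, name,
                      needs_input_grad=True):
            conv = Conv3D(in_ch, out_ch, kernel=spec.kernel, stride=stride,
                          dilation=dilation, rng=rng, name=name,
                          needs_input_grad=needs_input_grad)
            records.append(LayerRecord(role, level, spec.kernel, dilation,
                                       tuple(stride), in_ch, out_ch, True, "prelu"))
            return [conv, BatchNorm(out_ch, name=f"{name}.bn"),
                    PReLU(out_ch, name=f"{name}.act")]

        b = spec.num_blocks
        in_ch = spec.input_shape[3]
        self.encoder: list[list] = []
        for level in range(b):
            layers = []
            out_ch = spec.filters_at(level)
            for j, dil in enumerate(spec.dilation_schedule):
                stride = strides[level] if j == 0 else (1, 1, 1)
                layers += conv_unit(
                    in_ch, out_ch, stride, dil, "encoder", level,
                    f"enc{level}.conv{j}",
                    # no layer sits below the very first conv
                    needs_input_grad=not (level == 0 and j == 0),
                )
                in_ch = out_ch
            self.encoder.append(layers)

        bridge_ch = spec.filters_at(b)
        self.bridge = []
        for j in range(2):
            self.bridge += conv_unit(in_ch, bridge_ch, (1, 1, 1), 1, "bridge",
                                     None, f"bridge.conv{j}")
            in_ch = bridge_ch

        # residual pair: dilation 1, PReLU only, no normalization
        self.residual = []
        for j in range(2):
            name = f"res.conv{j}"
            conv = Conv3D(bridge_ch, bridge_ch, kernel=spec.kernel,
                          stride=(1, 1, 1), dilation=1, rng=rng, name=name)
            records.append(LayerRecord("residual", None, spec.kernel, 1,
                                       (1, 1, 1), bridge_ch, bridge_ch, False,
                                       "prelu"))
            self.residual += [conv, PReLU(bridge_ch, name=f"{name}.act")]

        self.decoder: list[dict] = []
        cur_ch = bridge_ch
        for i in range(b):
            skip_index = b - 2 - i if i < b - 1 else None
            up_stride = strides[b - 1 - i]
            out_ch = spec.filters_at(skip_index if skip_index is not None else 0)
            stage = {"up": Upsample3D(up_stride, name=f"dec{i}.up"),
                     "skip_index": skip_index, "convs": []}
            if skip_index is not None and spec.merge_mode == "concat":
                conv_in = cur_ch + spec.filters_at(skip_index)
            else:
                conv_in = cur_ch
            for j in range(2):
                stage["convs"] += conv_unit(conv_in, out_ch, (1, 1, 1), 1,
                                            "decoder", i, f"dec{i}.conv{j}")
                conv_in = out_ch
            cur_ch = out_ch
            self.decoder.append(stage)

        name = "head.conv"
        head_conv = Conv3D(cur_ch, spec.num_classes, kernel=(1, 1, 1),
                           stride=(1, 1, 1), dilation=1, rng=rng, name=name)
        records.append(LayerRecord("head", None, (1, 1, 1), 1, (1, 1, 1),
                                   cur_ch, spec.num_classes, True,
                                   "prelu+softmax"))
        self.head = [head_conv, BatchNorm(spec.num_classes, name=f"{name}.bn"),
                     PReLU(spec.num_classes, name=f"{name}.act"), Softmax()]

        self.summary = LayerSummary(spec=spec, records=records)
        self._skips = None
        self._skip_channels = None

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self):
        for level in self.encoder:
            yield from level
        yield from self.bridge
        yield from self.residual
        for stage in self.decoder:
            yield stage["up"]
            yield from stage["convs"]
        yield from self.head

    def params(self) -> list[Parameter]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm):
                state[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{layer.name}.running_mean"]
                layer.running_var[...] = state[f"{layer.name}.running_var"]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Map a (N, rows, cols, slices, 1) volume to per-voxel class probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[None]
        skips = []
        for level in self.encoder:
            for layer in level:
                x = layer.forward(x, training)
            skips.append(x)
        self._skips = skips
        self._skip_channels = [s.shape[-1] for s in skips]
        for layer in self.bridge:
            x = layer.forward(x, training)
        r = x
        h = x
        for layer in self.residual:
            h = layer.forward(h, training)
        x = h + r
        for stage in self.decoder:
            x = stage["up"].forward(x, training)
            si = stage["skip_index"]
            if si is not None:
                if self.spec.merge_mode == "concat":
                    x = np.concatenate([x, skips[si]], axis=-1)
                else:
                    x = x + skips[si]
            for layer in stage["convs"]:
                x = layer.forward(x, training)
        for layer in self.head:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        for stage in reversed(self.decoder):
            for layer in reversed(stage["convs"]):
                grad = layer.backward(grad)
            si = stage["skip_index"]
            if si is not None:
                if self.spec.merge_mode == "concat":
                    ch = self._skip_channels[si]
                    skip_grads[si] = grad[..., -ch:]
                    grad = grad[..., :-ch]
                else:
                    skip_grads[si] = grad
            grad = stage["up"].backward(grad)
        g_res = grad
        g = grad
        for layer in reversed(self.residual):
            g = layer.backward(g)
        grad = g + g_res
        for layer in reversed(self.bridge):
            grad = layer.backward(grad)
        for li in reversed(range(len(self.encoder))):
            if li in skip_grads:
                grad = grad + skip_grads[li]
            for layer in reversed(self.encoder[li]):
                grad = layer.backward(grad)
        return grad

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities for one (rows, cols, slices, 1) volume."""
        return self.forward(x, training=False)


def build_model(spec: ModelSpec) -> UNet3D:
    """Validate ``spec`` and construct the network."""
    return UNet3D(spec)


def summarize(model: UNet3D) -> LayerSummary:
    """Structural layer table of a built model."""
    return model.summary


def load_checkpoint(path) -> UNet3D:
    """Rebuild a model from a checkpoint with its embedded ModelSpec."""
    import json

    state = dict(np.load(path))
    if "spec_json" not in state:
        raise ValueError(f"{path}: checkpoint carries no embedded ModelSpec")
    raw = json.loads(str(state.pop("spec_json")))
    for key in ("kernel", "dilation_schedule", "input_shape"):
        raw[key] = tuple(raw[key])
    if raw.get("stride_policy") is not None:
        raw["stride_policy"] = tuple(tuple(s) for s in raw["stride_policy"])
    model = UNet3D(ModelSpec(**raw))
    model.load_state_dict(state)
    return model


def make_optimizer(model: UNet3D, lr: float = 5e-4) -> Adam:
    return Adam(model.params(), lr=lr)
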