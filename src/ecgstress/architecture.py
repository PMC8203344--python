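"""Layer shape calculus and the 14-row CNN-LSTM architecture table.

The convolution and pooling output sizes follow the usual integer
arithmetic::

    OH = (H + 2P - FH) / S + 1      (convolution)
    ORs = H / P                     (pooling)

with non-divisible combinations rejected rather than silently floored,
so the architecture trace is exact by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ConvSpec:
    """Convolution geometry: input H×W, filter FH×FW, stride S, padding P."""

    h: int
    w: int
    fh: int
    fw: int
    stride: int = 1
    padding: int = 0
    n_filters: int = 1

    def validate(self) -> None:
        for name in ("h", "w", "fh", "fw", "stride", "n_filters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")


@dataclass(frozen=True)
class PoolSpec:
    """Square pooling of size ``pool`` (stride defaults to the pool size)."""

    pool: int
    stride: int | None = None

    def validate(self) -> None:
        if self.pool < 1:
            raise ValueError("pool size must be a positive integer")


def conv_output_shape(spec: ConvSpec) -> tuple[int, int]:
    """(OH, OW) for a convolution; errors on non-integer arithmetic."""
    spec.validate()
    out = []
    for size, filt in ((spec.h, spec.fh), (spec.w, spec.fw)):
        num = size + 2 * spec.padding - filt
        if num < 0:
            raise ValueError(f"filter {filt} larger than padded input {size + 2 * spec.padding}")
        if num % spec.stride != 0:
            raise ValueError(
                f"(H + 2P - FH) = {num} not divisible by stride {spec.stride}"
            )
        out.append(num // spec.stride + 1)
    return out[0], out[1]


def pool_output_shape(h: int, w: int, pool: PoolSpec) -> tuple[int, int]:
    """(H/P, W/P) for pooling; errors when the sizes do not divide."""
    pool.validate()
    if h % pool.pool or w % pool.pool:
        raise ValueError(f"input {h}×{w} not divisible by pool size {pool.pool}")
    return h // pool.pool, w // pool.pool


def same_padding(filter_size: int) -> int:
    """Padding that preserves spatial size at stride 1 (odd filters only)."""
    if filter_size % 2 == 0:
        raise ValueError("same-size padding requires an odd filter")
    return (filter_size - 1) // 2


@dataclass(frozen=True)
class LayerSpec:
    """One architecture-table row: layer name, activation shape, weight/bias shapes."""

    name: str
    activation: tuple | int | None
    weights: str = "—"
    bias: str = "—"


@dataclass
class ModelArchitecture:
    """Ordered layer specifications with a computable shape trace."""

    layers: list[LayerSpec] = field(default_factory=list)

    def trace(self) -> list[tuple | int | None]:
        return [layer.activation for layer in self.layers]

    def __getitem__(self, i: int) -> LayerSpec:
        return self.layers[i]

    def __len__(self) -> int:
        return len(self.layers)


def cnn_lstm_architecture(
    image_size: int = 124,
    channels: int = 3,
    conv1: tuple[int, int] = (5, 6),
    conv2: tuple[int, int] = (3, 12),
    pool: int = 2,
    hidden_size: int = 200,
    n_classes: int = 2,
) -> ModelArchitecture:
    """The 14-row CNN-LSTM table with every activation computed.

    Defaults give the canonical full-size network: 124×124×3 input,
    5×5×3×6 and 3×3×6×12 convolutions with same-size padding, 2×2 max
    pooling twice, flatten width 31·31·12 = 11532, LSTM hidden size 200
    (stacked gate blocks 800×11532 and 800×200), a 2-way fully connected
    layer and softmax.  Sequence folding/unfolding wrap the convolutional
    stack; with length-1 sequences they are structural no-ops but are
    kept (and shape-checked) so the layer count and ordering match the
    canonical design.

    Any shape inconsistency raises at construction, naming the layer.
    """
    (f1, k1), (f2, k2) = conv1, conv2
    h = w = image_size
    rows: list[LayerSpec] = [
        LayerSpec("sequence_input", (h, w, channels)),
        LayerSpec("sequence_folding", (h, w, channels)),
    ]
    p1 = same_padding(f1)
    oh, ow = conv_output_shape(ConvSpec(h, w, f1, f1, 1, p1, k1))
    if (oh, ow) != (h, w):
        raise ValueError(f"conv_1: expected same-size output, got {oh}×{ow}")
    rows.append(
        LayerSpec("conv_1", (oh, ow, k1), f"{f1} × {f1} × {channels} × {k1}", f"1 × 1 × {k1}")
    )
    rows.append(LayerSpec("batch_norm_1", (oh, ow, k1)))
    oh, ow = pool_output_shape(oh, ow, PoolSpec(pool))
    rows.append(LayerSpec("max_pool_1", (oh, ow, k1)))

    p2 = same_padding(f2)
    oh2, ow2 = conv_output_shape(ConvSpec(oh, ow, f2, f2, 1, p2, k2))
    if (oh2, ow2) != (oh, ow):
        raise ValueError(f"conv_2: expected same-size output, got {oh2}×{ow2}")
    rows.append(
        LayerSpec("conv_2", (oh2, ow2, k2), f"{f2} × {f2} × {k1} × {k2}", f"1 × 1 × {k2}")
    )
    rows.append(LayerSpec("batch_norm_2", (oh2, ow2, k2)))
    oh2, ow2 = pool_output_shape(oh2, ow2, PoolSpec(pool))
    rows.append(LayerSpec("max_pool_2", (oh2, ow2, k2)))
    rows.append(LayerSpec("sequence_unfolding", (oh2, ow2, k2)))

    flat = oh2 * ow2 * k2
    rows.append(LayerSpec("flatten", flat))
    stacked = 4 * hidden_size
    rows.append(
        LayerSpec(
            "lstm",
            hidden_size,
            f"Input: {stacked} × {flat} recurrent: {stacked} × {hidden_size}",
            f"{stacked} × 1",
        )
    )
    rows.append(LayerSpec("fully_connected", n_classes, f"{n_classes} × {hidden_size}", f"{n_classes} × 1"))
    rows.append(LayerSpec("softmax", n_classes))
    rows.append(LayerSpec("classification", None))
    return ModelArchitecture(rows)
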