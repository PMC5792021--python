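"""Declarative CNN architecture descriptors and the output-shape calculus.

A convolutional network is described as an ordered list of layer
specifications.  The spatial side length after a convolution or pooling layer
with receptive field ``k`` x ``k``, stride ``S`` and zero-padding ``P`` on an
``H_in`` x ``H_in`` input is

    H_out = floor((H_in - k + 2*P) / S) + 1

with ``W_out = H_out`` (square convention throughout).  The reference
architecture is an AlexNet-style 12-stage network for 256 x 256 grayscale
input; :func:`scaled_architecture` produces desk-scale variants with the same
layer pattern but smaller input and channel widths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "LayerSpec",
    "ArchitectureDescriptor",
    "ShapeTrace",
    "ShapeError",
    "output_size",
    "reference_architecture",
    "trace_shapes",
    "scaled_architecture",
]

#: Layer kinds understood by the shape calculus and the compiler.
LAYER_KINDS = (
    "input",
    "convolution",
    "pooling",
    "normalization",
    "fully_connected",
    "dropout",
    "relu",
    "softmax",
    "loss",
)


class ShapeError(ValueError):
    """The layer chain produces an invalid (non-positive) feature shape."""


@dataclass(frozen=True)
class LayerSpec:
    """Specification of a single layer.

    ``k``/``stride``/``padding`` apply to convolution and pooling;
    ``out_channels`` is the number of receptive fields of a convolution or the
    width of a fully connected layer; ``rate`` is the dropout fraction.
    """

    kind: str
    k: int | None = None
    stride: int | None = None
    padding: int | None = None
    out_channels: int | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("convolution", "pooling"):
            if self.k is None or self.k < 1:
                raise ValueError(f"{self.kind}: receptive field k must be >= 1")
            if self.stride is None or self.stride < 1:
                raise ValueError(f"{self.kind}: stride must be >= 1")
            if (self.padding or 0) < 0:
                raise ValueError(f"{self.kind}: padding must be >= 0")
        if self.kind == "convolution" and (self.out_channels or 0) < 1:
            raise ValueError("convolution: out_channels must be >= 1")
        if self.kind == "fully_connected" and (self.out_channels or 0) < 1:
            raise ValueError("fully_connected: out_channels must be >= 1")
        if self.kind == "dropout" and not (0.0 < (self.rate or 0.0) < 1.0):
            raise ValueError("dropout: rate must lie in (0, 1)")


@dataclass
class ArchitectureDescriptor:
    """Ordered layer specifications plus input geometry and label count."""

    layers: list[LayerSpec]
    input_size: int
    input_channels: int = 1
    n_labels: int = 2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].kind != "input":
            raise ValueError("first layer must be the input layer")
        kinds = [l.kind for l in self.layers]
        if kinds[-2:] != ["softmax", "loss"]:
            raise ValueError("last two layers must be softmax then loss")
        if self.input_size < 1 or self.input_channels < 1 or self.n_labels < 2:
            raise ValueError("invalid input geometry or label count")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "input_size": self.input_size,
            "input_channels": self.input_channels,
            "n_labels": self.n_labels,
            "metadata": self.metadata,
            "layers": [
                {k: v for k, v in asdict(l).items() if v is not None}
                for l in self.layers
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureDescriptor":
        doc = json.loads(text)
        layers = [LayerSpec(**l) for l in doc["layers"]]
        return cls(
            layers=layers,
            input_size=doc["input_size"],
            input_channels=doc.get("input_channels", 1),
            n_labels=doc["n_labels"],
            metadata=doc.get("metadata", {}),
        )


@dataclass
class ShapeTrace:
    """Per-layer ``(H_out, W_out, C_out)`` triples (square convention)."""

    entries: list[tuple[int, str, int, int, int]]  # (layer index, kind, H, W, C)

    def feature_dims(self) -> list[tuple[int, int, int]]:
        """The shape after each shape-changing layer (conv, pool, fc)."""
        return [
            (h, w, c)
            for _, kind, h, w, c in self.entries
            if kind in ("convolution", "pooling", "fully_connected")
        ]

    def final(self) -> tuple[int, int, int]:
        return self.entries[-1][2:]

    def to_table(self) -> str:
        lines = [f"{'layer':>5}  {'kind':<16} {'shape':>14}"]
        for i, kind, h, w, c in self.entries:
            lines.append(f"{i:>5}  {kind:<16} {h:>4} x {w} x {c}")
        return "\n".join(lines)


def output_size(h_in: int, k: int, padding: int, stride: int) -> int:
    """Spatial output side of a conv/pool layer: floor((H-k+2P)/S) + 1.

    Raises when the (padded) input is smaller than the receptive field.
    """
    if h_in < 1 or k < 1 or stride < 1 or padding < 0:
        raise ValueError("require H_in >= 1, k >= 1, S >= 1, P >= 0")
    if h_in + 2 * padding < k:
        raise ShapeError(
            f"receptive field k={k} exceeds padded input {h_in}+2*{padding}"
        )
    return (h_in - k + 2 * padding) // stride + 1


def _conv_block(k: int, stride: int, padding: int, channels: int) -> list[LayerSpec]:
    return [
        LayerSpec("convolution", k=k, stride=stride, padding=padding,
                  out_channels=channels),
        LayerSpec("relu"),
    ]


def reference_architecture(
    n_labels: int = 57,
    input_size: int = 256,
    dropout_rate: float = 0.5,
) -> ArchitectureDescriptor:
    """The AlexNet-style 12-stage reference network for grayscale input.

    Stages: 11x11/4 convolution (96) -> 3x3/2 max pool + normalization ->
    dimension-preserving convolutions (256; 384; 384; 256) interleaved with
    two more 3x3/2 pools and one normalization -> two 4096-wide fully
    connected layers with dropout -> ``n_labels``-wide softmax output.  The
    shape chain on 256 x 256 input is 63 -> 31 -> 31 -> 15 -> 15 -> 15 -> 15
    -> 7 spatially, then 4096, 4096, ``n_labels``.

    The middle convolutions preserve the spatial dimension via stride 1 and
    padding ``(k-1)/2`` with kernel sizes 5, 3, 3, 3; the first convolution
    uses padding 2 (the only value consistent with 256 -> 63 under floor
    division).  These choices are recorded in ``metadata['assumptions']``.
    """
    layers = [LayerSpec("input")]
    layers += _conv_block(11, 4, 2, 96)
    layers += [LayerSpec("pooling", k=3, stride=2, padding=0),
               LayerSpec("normalization")]
    layers += _conv_block(5, 1, 2, 256)
    layers += [LayerSpec("pooling", k=3, stride=2, padding=0),
               LayerSpec("normalization")]
    layers += _conv_block(3, 1, 1, 384)
    layers += _conv_block(3, 1, 1, 384)
    layers += _conv_block(3, 1, 1, 256)
    layers += [LayerSpec("pooling", k=3, stride=2, padding=0)]
    for width in (4096, 4096):
        layers += [LayerSpec("fully_connected", out_channels=width),
                   LayerSpec("relu"),
                   LayerSpec("dropout", rate=dropout_rate)]
    layers += [LayerSpec("fully_connected", out_channels=n_labels),
               LayerSpec("softmax"), LayerSpec("loss")]
    return ArchitectureDescriptor(
        layers=layers,
        input_size=input_size,
        input_channels=1,
        n_labels=n_labels,
        metadata={
            "family": "alexnet-style",
            "assumptions": [
                "first convolution padding 2 (reproduces 256->63)",
                "dimension-preserving convolution kernels 5,3,3,3 with "
                "stride 1, padding (k-1)/2",
                "max pooling; local response normalization with "
                "n=5, alpha=1e-4, beta=0.75, k=1",
            ],
        },
    )


def trace_shapes(arch: ArchitectureDescriptor) -> ShapeTrace:
    """Apply the output-size formula layer by layer.

    Fully connected layers collapse the spatial grid to 1x1 with
    ``out_channels`` channels.  Raises :class:`ShapeError` naming the first
    offending layer when a non-positive shape arises.
    """
    h = arch.input_size
    c = arch.input_channels
    entries: list[tuple[int, str, int, int, int]] = []
    for i, layer in enumerate(arch.layers):
        if layer.kind in ("convolution", "pooling"):
            try:
                h = output_size(h, layer.k, layer.padding or 0, layer.stride)
            except ShapeError as exc:
                raise ShapeError(f"layer {i} ({layer.kind}): {exc}") from exc
            if layer.kind == "convolution":
                c = layer.out_channels
        elif layer.kind == "fully_connected":
            h, c = 1, layer.out_channels
        if h < 1 or c < 1:
            raise ShapeError(f"layer {i} ({layer.kind}): non-positive shape")
        entries.append((i, layer.kind, h, h, c))
    return ShapeTrace(entries)


def scaled_architecture(
    input_size: int,
    n_labels: int,
    width_factor: float = 1.0,
    dropout_rate: float = 0.5,
) -> ArchitectureDescriptor:
    """The reference layer pattern at reduced input size and channel widths.

    Channel counts and fully-connected widths are scaled by ``width_factor``
    (rounded up, floor of 8).  With ``width_factor=1`` and 256 input this is
    exactly the reference architecture.  Raises :class:`ShapeError` when the
    input is too small for the pooling chain.
    """
    if input_size < 32:
        raise ValueError("input_size must be >= 32")
    if n_labels < 2:
        raise ValueError("n_labels must be >= 2")
    if not (0.0 < width_factor <= 1.0):
        raise ValueError("width_factor must lie in (0, 1]")

    def scale(c: int) -> int:
        return max(8, math.ceil(c * width_factor))

    ref = reference_architecture(n_labels=n_labels, input_size=input_size,
                                 dropout_rate=dropout_rate)
    layers: list[LayerSpec] = []
    n_fc = sum(1 for l in ref.layers if l.kind == "fully_connected")
    fc_seen = 0
    for layer in ref.layers:
        if layer.kind == "convolution":
            layers.append(LayerSpec("convolution", k=layer.k, stride=layer.stride,
                                    padding=layer.padding,
                                    out_channels=scale(layer.out_channels)))
        elif layer.kind == "fully_connected":
            fc_seen += 1
            width = n_labels if fc_seen == n_fc else scale(layer.out_channels)
            layers.append(LayerSpec("fully_connected", out_channels=width))
        else:
            layers.append(layer)
    arch = ArchitectureDescriptor(
        layers=layers,
        input_size=input_size,
        input_channels=1,
        n_labels=n_labels,
        metadata={**ref.metadata, "width_factor": width_factor},
    )
    trace_shapes(arch)  # validates; raises ShapeError if the chain collapses
    return arch
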