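"""The nine workload-classifier architectures.

Three families, three sizes each, all ending in the shared tail
Flatten -> Dense(64) -> Dropout(0.25) -> Dense(16) -> Dense(3, softmax):

* CNN variants C-A/C-B/C-C consume the 16x16 connectivity matrix as a
  one-channel image (stride-1 'same' convolutions, ReLU, one 2x2 max
  pool);
* LSTM variants L-A/L-B/L-C consume the row-major flattened matrix as
  a length-256 sequence of scalars (ReLU state activation);
* Conv-LSTM variants CL-A/CL-B/CL-C run the conv stack, reshape the
  8x8x64 tensor to a 256-step sequence of 16 features, then stack LSTMs.

Architectures are declared as plain layer descriptors (ModelSpec) and
realized on the numpy backend by build_model, so the structure can be
inspected, serialized and tested independently of any weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from cogload import nn
from cogload.containers import ConnectivityMatrix
from cogload.errors import InvalidArgumentError

N_CLASSES = 3

_SHARED_TAIL = [
    ("flatten",),
    ("dense", 64, "relu"),
    ("dropout", 0.25),
    ("dense", 16, "relu"),
    ("dense", N_CLASSES, "softmax"),
]

#: Sequence length x features after reshaping the conv stack's 8x8x64
#: output for the recurrent section of the Conv-LSTM variants. The
#: element count (4096) forces 16 features per step at 256 steps.
CONV_LSTM_RESHAPE = (256, 16)

_CONV_INPUT = (16, 16, 1)
_SEQ_INPUT = (256, 1)

_VARIANT_BODIES: dict[str, list[tuple]] = {
    "C-A": [
        ("conv", 32, (5, 5)),
        ("conv", 64, (3, 3)),
        ("maxpool", 2),
        ("conv", 128, (5, 5)),
    ],
    "C-B": [
        ("conv", 32, (5, 5)),
        ("conv", 64, (3, 3)),
        ("maxpool", 2),
        ("conv", 128, (5, 5)),
        ("conv", 128, (5, 5)),
    ],
    "C-C": [
        ("conv", 32, (5, 5)),
        ("conv", 64, (5, 5)),
        ("maxpool", 2),
        ("conv", 128, (3, 3)),
    ],
    "L-A": [("lstm", 32), ("lstm", 16), ("lstm", 8)],
    "L-B": [("lstm", 64), ("lstm", 32), ("lstm", 16), ("lstm", 8)],
    "L-C": [("lstm", 64), ("lstm", 32), ("lstm", 16), ("lstm", 16)],
    "CL-A": [
        ("conv", 32, (3, 3)),
        ("conv", 32, (3, 3)),
        ("maxpool", 2),
        ("conv", 64, (3, 3)),
        ("conv", 64, (3, 3)),
        ("reshape", CONV_LSTM_RESHAPE),
        ("lstm", 32),
        ("lstm", 16),
    ],
    "CL-B": [
        ("conv", 16, (3, 3)),
        ("conv", 16, (3, 3)),
        ("maxpool", 2),
        ("conv", 64, (3, 3)),
        ("conv", 64, (3, 3)),
        ("reshape", CONV_LSTM_RESHAPE),
        ("lstm", 64),
        ("lstm", 16),
    ],
    "CL-C": [
        ("conv", 32, (3, 3)),
        ("conv", 32, (3, 3)),
        ("maxpool", 2),
        ("conv", 64, (3, 3)),
        ("conv", 64, (3, 3)),
        ("reshape", CONV_LSTM_RESHAPE),
        ("lstm", 64),
        ("lstm", 32),
        ("lstm", 16),
    ],
}

VARIANTS = tuple(_VARIANT_BODIES)


@dataclass
class ModelSpec:
    """Declarative description of one classifier variant."""

    variant: str
    layer_list: list[tuple]
    input_shape: tuple[int, ...]
    n_classes: int = N_CLASSES

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "input_shape": list(self.input_shape),
                "n_classes": self.n_classes,
                "layers": [list(d) for d in self.layer_list],
            },
            indent=2,
        )


def model_spec(variant: str) -> ModelSpec:
    """The full layer list (body + shared tail) for one variant."""
    if variant not in _VARIANT_BODIES:
        raise InvalidArgumentError(
            f"unknown variant {variant!r}; expected one of {', '.join(VARIANTS)}"
        )
    input_shape = _SEQ_INPUT if variant.startswith("L") else _CONV_INPUT
    return ModelSpec(
        variant=variant,
        layer_list=list(_VARIANT_BODIES[variant]) + list(_SHARED_TAIL),
        input_shape=input_shape,
    )


def _realize(descriptor: tuple, is_last_lstm: bool) -> nn.Layer:
    kind = descriptor[0]
    if kind == "conv":
        return nn.Conv2D(descriptor[1], descriptor[2])
    if kind == "maxpool":
        return nn.MaxPool2D(descriptor[1])
    if kind == "lstm":
        return nn.LSTM(descriptor[1], return_sequences=not is_last_lstm)
    if kind == "reshape":
        return nn.Reshape(tuple(descriptor[1]))
    if kind == "flatten":
        return nn.Flatten()
    if kind == "dense":
        return nn.Dense(descriptor[1], activation=descriptor[2])
    if kind == "dropout":
        return nn.Dropout(descriptor[1])
    raise InvalidArgumentError(f"unknown layer kind {kind!r}")


def build_model(variant: str, seed: int = 0, dtype=np.float32) -> nn.Network:
    """Realize a variant as a trainable network with seeded weights.

    Recurrent layers return full sequences when followed by another
    recurrent layer; the final one emits its last hidden state into the
    shared tail.
    """
    spec = model_spec(variant)
    lstm_positions = [i for i, d in enumerate(spec.layer_list) if d[0] == "lstm"]
    last_lstm = lstm_positions[-1] if lstm_positions else -1
    layers = [
        _realize(d, is_last_lstm=(i == last_lstm))
        for i, d in enumerate(spec.layer_list)
    ]
    return nn.Network(layers, input_shape=spec.input_shape, seed=seed, dtype=dtype)


def flatten_for_recurrent(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Row-major flattening of a 16x16 matrix to a (256, 1) sequence."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if values.shape != (16, 16):
        raise InvalidArgumentError(f"expected a 16x16 matrix, got {values.shape}")
    return values.reshape(256, 1)


def unflatten_from_recurrent(sequence: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_for_recurrent`."""
    seq = np.asarray(sequence)
    if seq.size != 256:
        raise InvalidArgumentError("expected 256 elements")
    return seq.reshape(16, 16)


def prepare_inputs(matrices: np.ndarray, variant: str) -> np.ndarray:
    """Shape a stack of (n, 16, 16) matrices for a variant's input layer."""
    matrices = np.asarray(matrices)
    if matrices.ndim != 3 or matrices.shape[1:] != (16, 16):
        raise InvalidArgumentError("expected an (n, 16, 16) matrix stack")
    if variant.startswith("L"):
        return matrices.reshape(-1, 256, 1)
    return matrices[..., None]
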