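"""The RCNN and CFF-RCNN gesture classifiers.

Both models share a time-distributed CNN feature extractor feeding a
single-layer LSTM sequence recognizer and a softmax head:

    RCNN:      Conv64k3 + BN + ReLU -> MaxPool2 -> Conv64k3 + BN + ReLU
               -> MaxPool2 -> Flatten -> FC512 -> FC512 -> FC128
               -> LSTM512 (dropout 0.5) -> FC(G) -> softmax

    CFF-RCNN:  identical, except the FIRST MaxPool2 is replaced by the
               concatenate-feature-fusion block [MaxPool2 || Conv64k3 s=2],
               so the second conv sees 128 channels instead of 64.

The pool branch of the fusion block contributes zero trainable parameters;
everything extra in CFF-RCNN is the stride-2 conv branch plus the widened
second conv.  Batch normalization is applied to the 1-stride convolutions
only; the stride-2 branch is left un-normalized by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn


@dataclass
class ModelSpec:
    """Architecture description for :func:`build_model`.

    Defaults are the full-size stacks (64 conv filters, FC 512/512/128, LSTM
    512 with dropout 0.5); shrink them for quick experiments on small frames.
    """

    variant: str  # 'rcnn' or 'cff_rcnn'
    input_shape: tuple  # (W, H, C) of one frame
    num_classes: int
    conv_filters: int = 64
    kernel: int = 3
    fc_sizes: tuple = (512, 512, 128)
    lstm_units: int = 512
    lstm_dropout: float = 0.5
    seq_len: int = 1
    cff_bias: bool = True

    def __post_init__(self):
        if self.variant not in ("rcnn", "cff_rcnn"):
            raise ValueError("variant must be 'rcnn' or 'cff_rcnn'")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    def to_rcnn(self) -> "ModelSpec":
        """The plain-RCNN spec this one reduces to when the conv branch of the
        fusion block is removed and the concatenation halved."""
        d = asdict(self)
        d["variant"] = "rcnn"
        d["input_shape"] = tuple(d["input_shape"])
        d["fc_sizes"] = tuple(d["fc_sizes"])
        return ModelSpec(**d)


@dataclass
class ParamReport:
    layers: list  # (name, count) pairs
    total: int

    @classmethod
    def from_layers(cls, named_counts):
        layers = list(named_counts)
        return cls(layers=layers, total=sum(c for _, c in layers))


def _ceil2(x):
    return -(-x // 2)


def build_model(spec: ModelSpec, seed: int = 0) -> nn.SequenceClassifier:
    """Instantiate the layer stack for ``spec`` with seeded initialization.

    Raises ``ValueError`` if the two spatial halvings collapse an axis to
    zero before the flatten.
    """
    W, H, C = spec.input_shape
    rng = np.random.default_rng(seed)

    def sub():
        return rng.integers(2**31)

    F, k = spec.conv_filters, spec.kernel
    layers = [
        nn.Conv2D(C, F, kernel=k, stride=1, padding="same", rng=sub()),
        nn.BatchNorm(F),
        nn.ReLU(),
    ]
    if spec.variant == "cff_rcnn":
        layers.append(nn.CFFBlock2D(F, F, kernel=k, rng=sub(), bias=spec.cff_bias))
        c_mid = 2 * F
    else:
        layers.append(nn.MaxPool2D())
        c_mid = F
    layers += [
        nn.Conv2D(c_mid, F, kernel=k, stride=1, padding="same", rng=sub()),
        nn.BatchNorm(F),
        nn.ReLU(),
        nn.MaxPool2D(),
        nn.Flatten(),
    ]
    w2, h2 = _ceil2(_ceil2(W)), _ceil2(_ceil2(H))
    if w2 == 0 or h2 == 0:
        raise ValueError(
            f"spatial extent {spec.input_shape[:2]} collapses to zero at the "
            "second max-pool")
    d = w2 * h2 * F
    for width in spec.fc_sizes:
        layers.append(nn.Dense(d, width, rng=sub()))
        layers.append(nn.ReLU())
        d = width
    lstm = nn.LSTM(d, spec.lstm_units, rng=sub())
    dropout = nn.Dropout(spec.lstm_dropout, rng=sub())
    head = nn.Dense(spec.lstm_units, spec.num_classes, rng=sub())
    model = nn.SequenceClassifier(layers, lstm, dropout, head)
    model.spec = spec
    return model


def count_parameters(model: nn.SequenceClassifier) -> ParamReport:
    """Per-layer trainable-parameter counts; pooling/flatten/concat report 0."""
    return ParamReport.from_layers(
        (layer.name, layer.n_params()) for layer in model.layers
    )


def predict(model: nn.SequenceClassifier, frames: np.ndarray):
    """Class probabilities and argmax labels for a frame batch.

    ``frames`` may be ``(n, W, H, C)`` (treated as length-1 sequences) or
    ``(n, T, W, H, C)``.  Inference mode: dropout disabled, batch-norm uses
    running statistics, so repeated calls are deterministic.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4:
        frames = frames[:, None]
    probs = model.predict_proba(frames)
    return probs, probs.argmax(axis=1)


def save_model(path, model: nn.SequenceClassifier):
    """Save weights + spec to ``<path>.npz`` / ``<path>.spec.json``."""
    path = str(path)
    arrays = {}
    for i, layer in enumerate(model.layers):
        for k, p in layer.params.items():
            arrays[f"{i}:{layer.name}:{k}"] = p
        if isinstance(layer, nn.BatchNorm):
            arrays[f"{i}:{layer.name}:running_mean"] = layer.running_mean
            arrays[f"{i}:{layer.name}:running_var"] = layer.running_var
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".spec.json", "w") as fh:
        json.dump(asdict(model.spec), fh, indent=2)


def load_model(path, seed: int = 0) -> nn.SequenceClassifier:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".spec.json") as fh:
        d = json.load(fh)
    d["input_shape"] = tuple(d["input_shape"])
    d["fc_sizes"] = tuple(d["fc_sizes"])
    model = build_model(ModelSpec(**d), seed=seed)
    arrays = np.load(base + ".npz")
    for i, layer in enumerate(model.layers):
        for k in layer.params:
            layer.params[k][...] = arrays[f"{i}:{layer.name}:{k}"]
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean = arrays[f"{i}:{layer.name}:running_mean"]
            layer.running_var = arrays[f"{i}:{layer.name}:running_var"]
    return model
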