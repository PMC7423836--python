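"""AlexNet-style CNN classification of per-nucleus crops.

Eight weighted layers: five convolution layers (max pooling after the
first, second and fifth) followed by three fully connected layers ending
in a 2-way softmax (CTC vs non-CTC).  Hyper-parameters are selected on a
3 x 2 x 2 grid — activation in {softmax, ReLU, tanh}, kernel regularizer
in {l1, l2}, regularization factor in {0.01, 0.02} — by stratified
five-fold cross-validation.  "softmax" as a hidden activation is unusual
but kept so the grid is faithful; it normalizes over the channel axis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold

from ._nn import Activation, Conv2D, Dense, Flatten, MaxPool2, Model
from .caller import CallLabel
from .io import ChannelRole, ChannelStack
from .segmentation import NucleusRegion

__all__ = [
    "CnnConfig",
    "LabeledCrop",
    "DEFAULT_GRID",
    "TrainedClassifier",
    "extract_crops",
    "crops_to_arrays",
    "build_model",
    "weight_count",
    "grid_search_cv",
    "train",
    "predict",
    "save_classifier",
    "load_classifier",
]

CHANNEL_ORDER = (ChannelRole.DAPI, ChannelRole.CD45, ChannelRole.CEP8, ChannelRole.CEP17)

#: Hyper-parameter grid searched under 5-fold CV (activation x regularizer x factor).
DEFAULT_GRID: dict[str, list] = {
    "activation": ["softmax", "ReLU", "tanh"],
    "regularizer": ["l1", "l2"],
    "reg_factor": [0.01, 0.02],
}

_MIN_CONVERGENT_FILTERS = 16
_MAX_USEFUL_FILTER_SIZE = 10


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training settings of the 8-weighted-layer network.

    Defaults follow the selected operating point (ReLU, l2, factor 0.01)
    with filter counts inside the empirically convergent 16-128 range and
    a filter size within the <= 10 px useful feature scale.
    """

    activation: str = "ReLU"
    regularizer: str = "l2"
    reg_factor: float = 0.01
    n_conv_layers: int = 5
    n_fc_layers: int = 3
    filters_per_layer: tuple[int, ...] = (32, 64, 64, 96, 128)
    filter_size_px: int = 5
    input_size_px: int = 64
    fc_units: tuple[int, ...] = (128, 32)
    n_classes: int = 2
    n_input_channels: int = 4
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30

    def __post_init__(self) -> None:
        if self.activation.lower() not in ("softmax", "relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.regularizer not in ("l1", "l2"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.n_conv_layers != 5 or self.n_fc_layers != 3:
            raise ValueError(
                "the architecture has 8 weighted layers: 5 convolutional + 3 fully connected"
            )
        if len(self.filters_per_layer) != self.n_conv_layers:
            raise ValueError("filters_per_layer must list one count per convolution layer")
        if len(self.fc_units) != self.n_fc_layers - 1:
            raise ValueError("fc_units must list the two hidden fully connected widths")
        if self.input_size_px % 8 != 0:
            raise ValueError("input_size_px must be divisible by 8 (three 2x2 poolings)")
        if min(self.filters_per_layer) < _MIN_CONVERGENT_FILTERS:
            warnings.warn(
                f"filter counts below {_MIN_CONVERGENT_FILTERS} lie in the observed "
                "non-convergence range",
                stacklevel=2,
            )
        if self.filter_size_px > _MAX_USEFUL_FILTER_SIZE:
            warnings.warn(
                f"filter size {self.filter_size_px} exceeds the ~{_MAX_USEFUL_FILTER_SIZE} px "
                "scale of probe/nucleus features; convergence slows with no accuracy gain",
                stacklevel=2,
            )


@dataclass
class LabeledCrop:
    """One per-nucleus crop: 4 planes (DAPI, CD45, CEP8, CEP17) in [0, 1]."""

    pixels: np.ndarray  # (4, size, size) float32
    label: CallLabel | None = None
    provenance: str = ""
    missing_channels: frozenset[ChannelRole] = field(default_factory=frozenset)


def extract_crops(
    stack: ChannelStack,
    regions: Sequence[NucleusRegion],
    size_px: int = 64,
    labels: Sequence[CallLabel] | None = None,
) -> list[LabeledCrop]:
    """Cut a square crop around each nucleus and resize it for the network.

    The crop is centered on the centroid with side 1.5x the larger
    bounding-box side, reflectively padded at field borders, stacked in
    fixed channel order (a missing channel contributes a zero plane and is
    recorded), and intensity-scaled to [0, 1].
    """
    h, w = stack.height, stack.width
    crops = []
    for i, region in enumerate(regions):
        r0, r1, c0, c1 = region.bbox
        side = max(2, int(np.ceil(1.5 * max(r1 - r0, c1 - c0))))
        cr, cc = int(round(region.centroid[0])), int(round(region.centroid[1]))
        a0, b0 = cr - side // 2, cc - side // 2
        a1, b1 = a0 + side, b0 + side
        pad_t, pad_l = max(0, -a0), max(0, -b0)
        pad_b, pad_r = max(0, a1 - h), max(0, b1 - w)
        planes = []
        missing = set()
        for role in CHANNEL_ORDER:
            img = stack.get(role)
            if img is None:
                missing.add(role)
                planes.append(np.zeros((size_px, size_px), dtype=np.float32))
                continue
            window = img.pixels[max(a0, 0) : min(a1, h), max(b0, 0) : min(b1, w)]
            if pad_t or pad_b or pad_l or pad_r:
                window = np.pad(window, ((pad_t, pad_b), (pad_l, pad_r)), mode="reflect")
            plane = resize(
                window.astype(np.float64) / img.max_intensity,
                (size_px, size_px),
                order=1,
                preserve_range=True,
                anti_aliasing=window.shape[0] > size_px,
            )
            planes.append(plane.astype(np.float32))
        crops.append(
            LabeledCrop(
                pixels=np.stack(planes),
                label=None if labels is None else labels[i],
                provenance=f"{stack.field_id}:{region.label}",
                missing_channels=frozenset(missing),
            )
        )
    return crops


def crops_to_arrays(crops: Sequence[LabeledCrop]) -> tuple[np.ndarray, np.ndarray]:
    """Stack crops into (X, y) arrays; y is 1 for CTC-positive."""
    x = np.stack([c.pixels for c in crops]).astype(np.float32)
    y = np.array(
        [1 if c.label is CallLabel.CTC_POSITIVE else 0 for c in crops], dtype=np.int64
    )
    return x, y


def weight_count(config: CnnConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    k = config.filter_size_px
    total = 0
    c_prev = config.n_input_channels
    for f in config.filters_per_layer:
        total += f * (c_prev * k * k) + f
        c_prev = f
    spatial = config.input_size_px // 8
    n_in = c_prev * spatial * spatial
    for units in (*config.fc_units, config.n_classes):
        total += n_in * units + units
        n_in = units
    return total


def build_model(config: CnnConfig) -> Model:
    """Instantiate the seeded 8-weighted-layer network.

    Two builds with equal seeds have identical initial weights; the final
    2-way softmax is applied by the loss/prediction path.
    """
    rng = np.random.default_rng(config.seed)
    act = config.activation
    layers: list = []
    c_prev = config.n_input_channels
    for i, f in enumerate(config.filters_per_layer):
        layers.append(Conv2D(c_prev, f, config.filter_size_px, rng))
        layers.append(Activation(act))
        if i in (0, 1, config.n_conv_layers - 1):
            layers.append(MaxPool2())
        c_prev = f
    layers.append(Flatten())
    spatial = config.input_size_px // 8
    n_in = c_prev * spatial * spatial
    for units in config.fc_units:
        layers.append(Dense(n_in, units, rng, config.regularizer, config.reg_factor))
        layers.append(Activation(act))
        n_in = units
    layers.append(Dense(n_in, config.n_classes, rng, config.regularizer, config.reg_factor))
    model = Model(layers)
    assert model.n_weights == weight_count(config)
    return model


@dataclass
class TrainedClassifier:
    """A trained network with its configuration and training history."""

    model: Model
    config: CnnConfig
    history: dict


def train(
    config: CnnConfig,
    crops: Sequence[LabeledCrop] | np.ndarray,
    labels: Sequence | None = None,
    epochs: int | None = None,
    seed: int | None = None,
) -> TrainedClassifier:
    """Train a network on labeled crops; deterministic for a fixed seed."""
    if isinstance(crops, np.ndarray):
        x = crops.astype(np.float32)
        y = np.asarray(labels, dtype=np.int64)
    else:
        x, y = crops_to_arrays(crops)
        if labels is not None:
            y = np.asarray(labels, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("cannot train on an empty dataset")
    seed = config.seed if seed is None else seed
    epochs = config.epochs if epochs is None else epochs
    model = build_model(replace(config, seed=seed))
    history = model.fit(
        x,
        y,
        epochs=epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        seed=seed + 1,
    )
    return TrainedClassifier(model=model, config=config, history=history)


def predict(
    classifier: TrainedClassifier, crops: Sequence[LabeledCrop] | np.ndarray
) -> tuple[np.ndarray, list[CallLabel]]:
    """Class probabilities (summing to 1 per crop) and argmax labels."""
    if isinstance(crops, np.ndarray):
        x = crops.astype(np.float32)
    else:
        x = np.stack([c.pixels for c in crops]).astype(np.float32)
    s = classifier.config.input_size_px
    if x.ndim != 4 or x.shape[1:] != (4, s, s):
        raise ValueError(f"crops must have shape (n, 4, {s}, {s}), got {x.shape}")
    probs = classifier.model.predict_proba(x)
    labels = [
        CallLabel.CTC_POSITIVE if p == 1 else CallLabel.CTC_NEGATIVE
        for p in probs.argmax(axis=1)
    ]
    return probs, labels


def save_classifier(classifier: TrainedClassifier, path) -> None:
    """Checkpoint a trained classifier (weights + config + history) as .npz."""
    import dataclasses
    import json

    arrays = {
        f"layer{i}__{name}": p
        for i, lay in enumerate(classifier.model.layers)
        for name, p in lay.params.items()
    }
    meta = json.dumps(
        {"config": dataclasses.asdict(classifier.config), "history": classifier.history}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_classifier(path) -> TrainedClassifier:
    """Restore a checkpoint written by :func:`save_classifier`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        for key in ("filters_per_layer", "fc_units"):
            cfg[key] = tuple(cfg[key])
        config = CnnConfig(**cfg)
        model = build_model(config)
        for i, lay in enumerate(model.layers):
            for name in lay.params:
                lay.params[name] = data[f"layer{i}__{name}"].copy()
    return TrainedClassifier(model=model, config=config, history=meta["history"])


def grid_search_cv(
    dataset: Sequence[LabeledCrop],
    grid: dict[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
    base_config: CnnConfig | None = None,
    epochs: int | None = None,
) -> tuple[CnnConfig, pd.DataFrame]:
    """Exhaustive hyper-parameter search under stratified k-fold CV.

    Scores every (activation, regularizer, factor) cell by mean validation
    accuracy over the same seeded folds and returns the argmax
    configuration plus the full score table (rows: activation x
    regularizer, columns: factor).  Ties break in grid order.
    """
    grid = grid or DEFAULT_GRID
    base = base_config or CnnConfig()
    x, y = crops_to_arrays(list(dataset))
    if len(np.unique(y)) < 2:
        raise ValueError("grid search requires both classes in the dataset")
    if k < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    activations = list(grid["activation"])
    regularizers = list(grid["regularizer"])
    factors = list(grid["reg_factor"])
    index = pd.MultiIndex.from_product(
        [activations, regularizers], names=["activation", "regularizer"]
    )
    table = pd.DataFrame(np.nan, index=index, columns=pd.Index(factors, name="reg_factor"))
    best_score, best_config = -np.inf, None
    for act, reg, fac in itertools.product(activations, regularizers, factors):
        config = replace(base, activation=act, regularizer=reg, reg_factor=fac)
        accs = []
        for fold_i, (tr, va) in enumerate(folds):
            clf = train(config, x[tr], y[tr], epochs=epochs, seed=seed + fold_i)
            pred = clf.model.predict_proba(x[va]).argmax(axis=1)
            accs.append(float((pred == y[va]).mean()))
        score = float(np.mean(accs))
        table.loc[(act, reg), fac] = score
        if score > best_score:  # strict: ties keep the earlier grid cell
            best_score, best_config = score, config
    return best_config, table
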