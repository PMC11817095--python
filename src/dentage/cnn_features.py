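"""Deep 2-D and 1-D CNN feature extractors for OPG images and records.

Two small convolutional networks map each modality to a fixed-width
feature vector (default 128 per path): the image path stacks 3x3
convolution blocks with 2x2 max pooling, the record path stacks 1-D
convolutions with a global max pool. Although the downstream task is
regression, the extractors are trained as *classifiers* over integer-year
age bins with softmax cross-entropy: a temporary classification head sits
above the linear feature layer during training and is discarded at
extraction time, so extracted features are the penultimate linear
activations.

Training uses Adam on mini-batches; everything is seeded and pure numpy,
so identical data/config/seed give bit-identical extractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .fusion import FeatureMatrix

__all__ = [
    "ArchSpec2D",
    "ArchSpec1D",
    "TrainConfig",
    "TrainedExtractor",
    "build_extractor",
    "train_extractor",
    "extract_features",
    "bin_ages",
]


@dataclass(frozen=True)
class ArchSpec2D:
    """Image-path architecture: conv/pool blocks then dense layers.

    Defaults follow the reference layout: four blocks of 3x3 convolutions
    with 32/64/128/256 filters, 2x2 max pooling after each, a 512-unit
    ReLU dense layer and a 128-unit linear feature layer on a
    (224, 224, 3) input. Grayscale OPGs are replicated across the three
    channels by the pipeline.
    """

    input_shape: tuple[int, int, int] = (224, 224, 3)
    conv_blocks: tuple = ((32, 3), (64, 3), (128, 3), (256, 3))
    pool_size: int = 2
    dense_units: int = 512
    feature_units: int = 128

    def __post_init__(self):
        if not self.conv_blocks:
            raise ValueError("conv_blocks must be non-empty")
        if self.feature_units < 1 or self.dense_units < 1:
            raise ValueError("dense/feature units must be >= 1")
        h, w, c = self.input_shape
        if c < 1:
            raise ValueError("need at least one input channel")
        for _ in self.conv_blocks:
            h, w = h // self.pool_size, w // self.pool_size
            if h < 1 or w < 1:
                raise ValueError(
                    f"input {self.input_shape[:2]} too small for "
                    f"{len(self.conv_blocks)} poolings of size {self.pool_size}"
                )

    @property
    def modality(self) -> str:
        return "image"


@dataclass(frozen=True)
class ArchSpec1D:
    """Record-path architecture: 1-D conv stack, global max pool, dense.

    Defaults: 16/32/64 filters with kernel sizes 5/3/3 (two stacked
    kernel-3 layers cover the same receptive field as one kernel-5 with
    fewer parameters), a 256-unit ReLU dense layer and a 128-unit linear
    feature layer.
    """

    input_length: int = 16
    conv_blocks: tuple = ((16, 5), (32, 3), (64, 3))
    dense_units: int = 256
    feature_units: int = 128

    def __post_init__(self):
        if not self.conv_blocks:
            raise ValueError("conv_blocks must be non-empty")
        if self.input_length < 1:
            raise ValueError("input_length must be >= 1")
        if self.feature_units < 1 or self.dense_units < 1:
            raise ValueError("dense/feature units must be >= 1")

    @property
    def modality(self) -> str:
        return "record"


@dataclass(frozen=True)
class TrainConfig:
    """Training settings for an extractor's classification head.

    ``n_age_bins`` controls the auxiliary softmax target: ages are binned
    into equal-width classes over the training age range (default one bin
    per integer year of a 6-15-year cohort).
    """

    n_age_bins: int = 9
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_age_bins < 2:
            raise ValueError("n_age_bins must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainedExtractor:
    """A feature trunk plus its (training-only) classification head."""

    spec: ArchSpec2D | ArchSpec1D
    trunk: nn.Sequential
    head: nn.Dense
    modality: str
    training_history: list = field(default_factory=list)
    trained: bool = False


def build_extractor(
    spec: ArchSpec2D | ArchSpec1D, seed: int, n_age_bins: int = 9
) -> TrainedExtractor:
    """Construct an untrained extractor with seeded initialisation.

    The softmax head over ``n_age_bins`` classes is attached above the
    feature layer; it is used only by :func:`train_extractor` and never at
    extraction time.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if isinstance(spec, ArchSpec2D):
        h, w, c_in = spec.input_shape
        for filters, k in spec.conv_blocks:
            layers += [nn.Conv2D(c_in, filters, k, rng), nn.ReLU(), nn.MaxPool2D(spec.pool_size)]
            c_in = filters
            h, w = h // spec.pool_size, w // spec.pool_size
        layers.append(nn.Flatten())
        flat = c_in * h * w
    elif isinstance(spec, ArchSpec1D):
        c_in = 1
        for filters, k in spec.conv_blocks:
            layers += [nn.Conv1D(c_in, filters, k, rng), nn.ReLU()]
            c_in = filters
        layers.append(nn.GlobalMaxPool1D())
        flat = c_in
    else:
        raise TypeError(f"unsupported architecture spec: {type(spec).__name__}")
    layers += [
        nn.Dense(flat, spec.dense_units, rng),
        nn.ReLU(),
        nn.Dense(spec.dense_units, spec.feature_units, rng),  # linear feature layer
    ]
    head = nn.Dense(spec.feature_units, n_age_bins, rng)
    return TrainedExtractor(spec=spec, trunk=nn.Sequential(layers), head=head,
                            modality=spec.modality)


def _to_internal(inputs: np.ndarray, spec: ArchSpec2D | ArchSpec1D) -> np.ndarray:
    """Coerce user-facing input batches to the layout the layers expect."""
    x = np.asarray(inputs, dtype=float)
    if isinstance(spec, ArchSpec2D):
        h, w, c = spec.input_shape
        if x.ndim == 3:  # (N, H, W) grayscale -> replicate channels
            x = np.repeat(x[:, None, :, :], c, axis=1)
        elif x.ndim == 4 and x.shape[-1] == c:  # (N, H, W, C)
            x = x.transpose(0, 3, 1, 2)
        elif x.ndim != 4 or x.shape[1] != c:
            raise ValueError(f"cannot interpret image batch of shape {x.shape}")
        if x.shape[2] != h or x.shape[3] != w:
            raise ValueError(
                f"image batch spatial size {x.shape[2:]} does not match spec {(h, w)}"
            )
        return x
    if x.ndim != 2 or x.shape[1] != spec.input_length:
        raise ValueError(
            f"record batch shape {x.shape} does not match input_length {spec.input_length}"
        )
    return x[:, None, :]  # (N, 1, L)


def bin_ages(ages: np.ndarray, n_bins: int, age_range: tuple[float, float] | None = None
             ) -> np.ndarray:
    """Assign each age to an equal-width bin index in [0, n_bins)."""
    a = np.asarray(ages, dtype=float)
    lo, hi = age_range if age_range is not None else (float(a.min()), float(a.max()))
    if hi <= lo:
        raise ValueError("degenerate age range for binning")
    idx = np.floor((a - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def train_extractor(
    model: TrainedExtractor,
    inputs: np.ndarray,
    ages: np.ndarray,
    cfg: TrainConfig,
    age_range: tuple[float, float] | None = None,
) -> TrainedExtractor:
    """Train trunk + head on age-bin classification; record per-epoch loss.

    Only the rows passed in are touched — the caller is responsible for
    passing the training split exclusively. Raises if the loss becomes
    non-finite, naming the epoch.
    """
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if model.head.W.shape[1] != cfg.n_age_bins:
        raise ValueError(
            f"model head has {model.head.W.shape[1]} classes but cfg.n_age_bins="
            f"{cfg.n_age_bins}; rebuild the extractor with matching bins"
        )
    x = _to_internal(inputs, model.spec)
    labels = bin_ages(ages, cfg.n_age_bins, age_range)
    n = x.shape[0]
    rng = np.random.default_rng(cfg.rng_seed)
    opt = nn.Adam(model.trunk.params() + model.head.params(), lr=cfg.learning_rate)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            feats = model.trunk.forward(x[idx])
            logits = model.head.forward(feats)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch + 1}")
            model.trunk.backward(model.head.backward(dlogits))
            opt.step()
            losses.append(loss)
        model.training_history.append(float(np.mean(losses)))
    model.trained = True
    return model


def extract_features(
    model: TrainedExtractor,
    inputs: np.ndarray,
    patient_ids: list | None = None,
    batch_size: int = 64,
) -> FeatureMatrix:
    """Forward inputs through the trunk only; return an n x d FeatureMatrix.

    Pure function of (model, inputs): no gradient or optimizer state is
    mutated, and repeated calls are bitwise identical. An empty batch
    yields a 0 x feature_units matrix.
    """
    x = np.asarray(inputs, dtype=float)
    n = x.shape[0]
    if patient_ids is None:
        patient_ids = [f"row_{i}" for i in range(n)]
    if len(patient_ids) != n:
        raise ValueError("patient_ids length must match the number of inputs")
    d = model.spec.feature_units
    if n == 0:
        return FeatureMatrix(patient_ids=[], values=np.empty((0, d)), modality=model.modality)
    xi = _to_internal(x, model.spec)
    chunks = [
        model.trunk.forward(xi[s : s + batch_size]) for s in range(0, n, batch_size)
    ]
    values = np.vstack(chunks)
    if not np.all(np.isfinite(values)):
        raise RuntimeError("extractor produced non-finite features")
    return FeatureMatrix(patient_ids=patient_ids, values=values, modality=model.modality)
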