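"""Synthetic dataset generators and CSV I/O.

Three generator kinds emulate the shapes of typical cancer
classification benchmarks so the whole pipeline runs with no downloads:

``gaussian_float``
    Class-conditional Gaussians over tabular clinical features.  Class
    means sit at a common positive baseline and are separated by
    ``separation`` within-class standard deviations along random
    orthonormal directions.  By default the features are recorded at a
    finite measurement resolution of one noise-SD per step — emulating
    ordinal laboratory scores (e.g. cytology grades 1-10 stored as
    floats).  Discretisation is what makes count-based measures such as
    Hamming informative; set ``resolution=0`` for genuinely continuous
    features (on which Hamming degenerates to a constant).

``integer_sparse``
    The same Gaussian construction rounded to integers and clipped to a
    small ``value_range`` — small-n, high-dimensional ordinal survey data.

``image_like``
    Per-class smooth 2-D templates (low-pass-filtered random fields,
    orthonormalised) plus per-pixel Gaussian noise, rounded to integer
    intensities in [0, 255] and flattened row-major — grayscale medical
    image slices.

All generators are deterministic per seed, produce balanced classes
(±1 sample) and finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import CSVFormatError, ParameterError
from .knn import LabeledDataset

__all__ = [
    "DatasetSpec",
    "generate_dataset",
    "preset",
    "PRESET_NAMES",
    "default_k_values",
    "read_csv",
    "write_csv",
]

_KINDS = ("gaussian_float", "integer_sparse", "image_like")


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one synthetic dataset.

    ``separation`` is the Euclidean distance between class means in units
    of the within-class standard deviation ``noise_sd``.  ``resolution``
    is the measurement grid step for ``gaussian_float`` (None → one
    noise-SD; 0 → continuous).  ``value_range`` applies to
    ``integer_sparse`` only (default (0, 3)).
    """

    kind: str
    n_samples: int
    n_features: int
    n_classes: int = 2
    separation: float = 4.0
    noise_sd: float = 1.0
    value_range: tuple[int, int] | None = None
    resolution: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown dataset kind {self.kind!r}; known: {_KINDS}")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.n_samples < 2 * self.n_classes:
            raise ParameterError("n_samples must be >= 2 * n_classes")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if self.n_classes > self.n_features:
            raise ParameterError("n_classes must not exceed n_features (orthogonal class directions)")
        if self.separation < 0:
            raise ParameterError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.resolution is not None and self.resolution < 0:
            raise ParameterError("resolution must be >= 0 (0 = continuous)")
        if self.kind == "image_like":
            side = int(round(self.n_features**0.5))
            if side * side != self.n_features:
                raise ParameterError("image_like requires n_features to be a perfect square")
        if self.value_range is not None:
            lo, hi = self.value_range
            if hi <= lo:
                raise ParameterError("value_range upper bound must exceed lower bound")


def _balanced_labels(n: int, c: int, rng: np.random.Generator) -> np.ndarray:
    counts = np.full(c, n // c)
    counts[: n % c] += 1
    labels = np.repeat(np.arange(c), counts)
    rng.shuffle(labels)
    return labels


def _orthonormal_directions(
    n_classes: int, n_features: int, rng: np.random.Generator, smooth_side: int | None = None
) -> np.ndarray:
    """Random orthonormal class-mean directions, optionally smooth 2-D fields."""
    raw = rng.standard_normal((n_features, n_classes))
    if smooth_side is not None:
        fields = raw.T.reshape(n_classes, smooth_side, smooth_side)
        # low-pass filter gives spatially coherent templates
        fields = np.stack(
            [ndimage.gaussian_filter(f, sigma=smooth_side / 8.0) for f in fields]
        )
        raw = fields.reshape(n_classes, -1).T
    q, _ = np.linalg.qr(raw)
    return q.T  # (n_classes, n_features), orthonormal rows


def generate_dataset(spec: DatasetSpec) -> LabeledDataset:
    """Draw a labeled dataset according to ``spec``; deterministic per seed.

    Class means are placed at ``baseline + (separation * noise_sd / sqrt(2))
    * u_c`` with orthonormal ``u_c``, so every pair of class means is
    exactly ``separation * noise_sd`` apart.
    """
    rng = np.random.default_rng(spec.seed)
    y = _balanced_labels(spec.n_samples, spec.n_classes, rng)
    scale = spec.separation * spec.noise_sd / np.sqrt(2.0)

    if spec.kind == "image_like":
        side = int(round(spec.n_features**0.5))
        dirs = _orthonormal_directions(spec.n_classes, spec.n_features, rng, smooth_side=side)
        baseline = 128.0
    else:
        dirs = _orthonormal_directions(spec.n_classes, spec.n_features, rng)
        if spec.kind == "integer_sparse":
            lo, hi = spec.value_range or (0, 3)
            baseline = (lo + hi) / 2.0
        else:
            baseline = 8.0 * spec.noise_sd

    means = baseline + scale * dirs  # (n_classes, n_features)
    X = means[y] + rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))

    if spec.kind == "gaussian_float":
        res = spec.noise_sd if spec.resolution is None else spec.resolution
        if res > 0:
            X = np.round(X / res) * res
    elif spec.kind == "integer_sparse":
        lo, hi = spec.value_range or (0, 3)
        X = np.clip(np.round(X), lo, hi)
    else:  # image_like: 8-bit-like integer intensities
        res = 1.0 if spec.resolution is None else spec.resolution
        if res > 0:
            X = np.round(X / res) * res
        X = np.clip(X, 0.0, 255.0)

    kind_tag = spec.kind.split("_")[0]
    return LabeledDataset(
        features=X,
        labels=np.array([f"class{c}" for c in y]),
        name=f"{kind_tag}_n{spec.n_samples}_f{spec.n_features}_c{spec.n_classes}_s{spec.seed}",
    )


# Shapes follow the four benchmark cancer datasets (brain MRI 3064 × 64×64
# in 3 classes, breast cytology 699 × 9, lung 32 × 55 integer, prostate
# clinical 97 × 9); separations are chosen once to give comparable
# difficulty (hard 3-class images, easy breast, hard lung, intermediate
# continuous prostate).  The brain preset is scaled to n=300 by default;
# pass full=True for the original instance count.
_PRESETS: dict[str, DatasetSpec] = {
    "brain_like": DatasetSpec(
        kind="image_like", n_samples=300, n_features=64 * 64, n_classes=3,
        separation=1.5, noise_sd=20.0,
    ),
    "breast_like": DatasetSpec(
        kind="gaussian_float", n_samples=699, n_features=9, n_classes=2,
        separation=6.0, noise_sd=1.0,
    ),
    "lung_like": DatasetSpec(
        kind="integer_sparse", n_samples=32, n_features=55, n_classes=2,
        separation=2.0, noise_sd=1.0, value_range=(0, 3),
    ),
    "prostate_like": DatasetSpec(
        kind="gaussian_float", n_samples=97, n_features=9, n_classes=2,
        separation=4.0, noise_sd=1.0, resolution=0.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, *, full: bool = False, seed: int | None = None) -> DatasetSpec:
    """Return the DatasetSpec for a named preset.

    ``full=True`` restores the original instance count for the scaled
    ``brain_like`` preset (3064 images).
    """
    if name not in _PRESETS:
        raise LookupError(f"unknown preset {name!r}; known: {', '.join(_PRESETS)}")
    spec = _PRESETS[name]
    if full and name == "brain_like":
        spec = replace(spec, n_samples=3064)
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec


def default_k_values(preset_name: str | None) -> tuple[int, ...]:
    """Default neighbourhood grid: k = 1..20, but 1..11 for the small lung-like set."""
    if preset_name == "lung_like":
        return tuple(range(1, 12))
    return tuple(range(1, 21))


def write_csv(data: LabeledDataset, path, label_col: str = "class") -> None:
    """Write a dataset as CSV: one numeric column per feature plus a label column."""
    frame = pd.DataFrame(
        data.features, columns=[f"x{i + 1}" for i in range(data.n_features)]
    )
    frame[label_col] = data.labels
    frame.to_csv(path, index=False)


def read_csv(path, label_col: str = "class", name: str | None = None) -> LabeledDataset:
    """Load a labeled dataset from CSV.

    All non-label columns must parse as finite numbers; a missing label
    column or a missing/non-numeric cell raises :class:`CSVFormatError`
    naming the offending location.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if label_col not in frame.columns:
        raise CSVFormatError(
            f"{path}: label column {label_col!r} not found (columns: {list(frame.columns)})"
        )
    labels = frame[label_col].astype(str).to_numpy()
    features = frame.drop(columns=[label_col])
    numeric = features.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise CSVFormatError(
            f"{path}: missing or non-numeric value at row {row}, column {col!r}"
        )
    return LabeledDataset(
        features=numeric.to_numpy(dtype=float),
        labels=labels,
        name=name or path.stem,
    )
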