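"""Distance measures for kNN classification of numeric feature vectors.

The module implements twelve dissimilarity measures used for benchmarking
kNN on biomedical data: the Minkowski family (Manhattan, Euclidean,
Chebyshev), Canberra, Hamming, Bhattacharyya, Bray-Curtis (Sorensen),
Clark, Soergel (Ruzicka), Hassanat, a Sobolev distance computed through
the discrete Fourier transform, and the Fisher information geodesic on
the probability simplex.

All distance functions are pure, operate on array-likes, and broadcast
over leading axes: inputs of shape ``(..., n)`` give a result of shape
``(...)``, so a full distance matrix can be computed as
``fn(X[:, None, :], Y[None, :, :])``.  Scalar results are returned as
plain Python floats.

Every measure is also available through a name-keyed registry
(:func:`get_metric`), which attaches property flags (true metric?
requires non-negative input?) and handles parameterisation, e.g.
``get_metric("minkowski", p=3)`` or ``get_metric("sobolev", k=1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

from .exceptions import (
    DegenerateInputError,
    DimensionError,
    DomainError,
    ParameterError,
    UnknownMetricError,
)

__all__ = [
    "minkowski",
    "euclidean",
    "manhattan",
    "chebyshev",
    "canberra",
    "hamming",
    "bhattacharyya",
    "bray_curtis",
    "clark",
    "soergel",
    "hassanat",
    "dft",
    "Spectrum",
    "sobolev",
    "simplex_project",
    "fisher",
    "MetricSpec",
    "get_metric",
    "parse_metric_string",
    "list_metrics",
    "DEFAULT_METRICS",
]

#: The twelve benchmark measures, in registry order.  ``minkowski`` is the
#: parameterised family behind euclidean/manhattan and is registered
#: separately.
DEFAULT_METRICS = (
    "euclidean",
    "manhattan",
    "chebyshev",
    "canberra",
    "hamming",
    "bhattacharyya",
    "bray_curtis",
    "clark",
    "soergel",
    "hassanat",
    "sobolev",
    "fisher",
)


def _pair(x: Any, y: Any) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a pair of vector arguments to float arrays with matching last axis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 0 or y.ndim == 0:
        raise DimensionError("distance operands must be vectors, got scalars")
    if x.shape[-1] != y.shape[-1]:
        raise DimensionError(
            f"length mismatch: {x.shape[-1]} vs {y.shape[-1]} features"
        )
    if x.shape[-1] == 0:
        raise DimensionError("empty feature vectors")
    return x, y


def _scalarize(value: np.ndarray) -> Any:
    if np.ndim(value) == 0:
        return float(value)
    return value


def minkowski(x, y, p: float) -> float:
    """Minkowski distance ``(sum |x_i - y_i|^p)^(1/p)``.

    ``p=1`` is the Manhattan distance, ``p=2`` the Euclidean distance.
    ``p`` must be a positive real; the Chebyshev (``p → ∞``) limit is
    provided separately by :func:`chebyshev`.
    """
    if not np.isfinite(p) or p <= 0:
        raise ParameterError(f"minkowski order p must be positive, got {p!r}")
    x, y = _pair(x, y)
    d = np.abs(x - y)
    if p == 1:
        return _scalarize(d.sum(axis=-1))
    if p == 2:
        return _scalarize(np.sqrt((d * d).sum(axis=-1)))
    return _scalarize((d**p).sum(axis=-1) ** (1.0 / p))


def euclidean(x, y) -> float:
    """Euclidean distance (Minkowski with p=2)."""
    return minkowski(x, y, 2)


def manhattan(x, y) -> float:
    """Manhattan / city-block distance (Minkowski with p=1)."""
    return minkowski(x, y, 1)


def chebyshev(x, y) -> float:
    """Chebyshev (maximum-value, chessboard) distance ``max_i |x_i - y_i|``."""
    x, y = _pair(x, y)
    return _scalarize(np.abs(x - y).max(axis=-1))


def canberra(x, y) -> float:
    """Canberra distance ``sum |x_i - y_i| / (|x_i| + |y_i|)``.

    A weighted Manhattan distance.  Terms with ``|x_i| + |y_i| = 0``
    (which forces ``x_i = y_i = 0``) contribute 0, keeping ``d(0, 0) = 0``.
    The result is bounded by the number of features.
    """
    x, y = _pair(x, y)
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    # den == 0 implies num == 0, so dividing by a substituted 1 yields the
    # conventional 0/0 := 0 without emitting warnings.
    safe = np.where(den == 0.0, 1.0, den)
    return _scalarize((num / safe).sum(axis=-1))


def hamming(x, y):
    """Hamming distance: the number of positions where the vectors differ.

    Uses exact inequality of the stored values (no tolerance), so it is
    mainly informative for nominal or discretised numeric data.
    """
    x, y = _pair(x, y)
    count = (x != y).sum(axis=-1)
    if np.ndim(count) == 0:
        return int(count)
    return count.astype(np.int64)


def bhattacharyya(x, y) -> float:
    """Bhattacharyya distance ``-ln sum sqrt(x_i * y_i)``.

    Quantifies the overlap of two probability distributions; on a pair of
    simplex vectors the value is >= 0 and is 0 iff the vectors coincide.
    Applied to unnormalised non-negative features, exactly as defined
    here, the value can be negative (``-ln`` of a sum exceeding 1); callers
    wanting probability semantics should :func:`simplex_project` first.
    Disjoint support returns ``+inf`` (a documented sentinel rather than an
    error, so nearest-neighbour ranking still works: the point is simply
    maximally far).
    """
    x, y = _pair(x, y)
    prod = x * y
    if np.any(prod < 0):
        raise DomainError("bhattacharyya requires x_i * y_i >= 0 for every i")
    s = np.sqrt(prod).sum(axis=-1)
    with np.errstate(divide="ignore"):
        return _scalarize(np.where(s == 0.0, np.inf, -np.log(np.where(s == 0.0, 1.0, s))))


def bray_curtis(x, y) -> float:
    """Bray-Curtis (Sorensen) dissimilarity ``sum |x_i - y_i| / sum (x_i + y_i)``.

    Lies in [0, 1] when all entries are non-negative.  A zero denominator
    is degenerate and raises.
    """
    x, y = _pair(x, y)
    num = np.abs(x - y).sum(axis=-1)
    den = (x + y).sum(axis=-1)
    if np.any(den == 0.0):
        raise DegenerateInputError("bray_curtis denominator sum(x_i + y_i) is zero")
    return _scalarize(num / den)


def clark(x, y) -> float:
    """Clark distance ``sqrt(sum ((x_i - y_i) / (|x_i| + |y_i|))^2)``.

    Also known as the coefficient of divergence; the square root of half
    the divergence distance.  0/0 terms contribute 0; bounded by sqrt(n).
    """
    x, y = _pair(x, y)
    den = np.abs(x) + np.abs(y)
    safe = np.where(den == 0.0, 1.0, den)
    t = (x - y) / safe
    return _scalarize(np.sqrt((t * t).sum(axis=-1)))


def soergel(x, y) -> float:
    """Soergel (Ruzicka) distance ``sum |x_i - y_i| / sum max(x_i, y_i)``.

    The complement of the Jaccard/Tanimoto similarity for binary data; a
    true metric provided all attributes are non-negative, where it lies in
    [0, 1].  A zero denominator is degenerate and raises.
    """
    x, y = _pair(x, y)
    num = np.abs(x - y).sum(axis=-1)
    den = np.maximum(x, y).sum(axis=-1)
    if np.any(den == 0.0):
        raise DegenerateInputError("soergel denominator sum(max(x_i, y_i)) is zero")
    return _scalarize(num / den)


def hassanat(x, y) -> float:
    """Hassanat distance: a bounded, non-convex per-dimension dissimilarity.

    Each dimension contributes, with ``lo = min(x_i, y_i)`` and
    ``hi = max(x_i, y_i)``::

        1 - (1 + lo) / (1 + hi)                          if lo >= 0
        1 - (1 + lo + |lo|) / (1 + hi + |lo|)            if lo <  0

    (for ``lo < 0`` the numerator collapses to 1).  Every term lies in
    [0, 1) and vanishes iff ``x_i == y_i``, so the total is in [0, n).
    The scale-insensitivity of the per-dimension ratio is what makes the
    measure robust across heterogeneous feature ranges.
    """
    x, y = _pair(x, y)
    lo = np.minimum(x, y)
    hi = np.maximum(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        nonneg = 1.0 - (1.0 + lo) / (1.0 + hi)
        neg = 1.0 - 1.0 / (1.0 + hi - lo)
    terms = np.where(lo >= 0, nonneg, neg)
    return _scalarize(terms.sum(axis=-1))


@dataclass(frozen=True)
class Spectrum:
    """Discrete Fourier spectrum of a real vector.

    ``coefficients[j]`` is ``sum_m v_m exp(-i 2π j m / N)`` and
    ``frequencies[j] = 2π j / N`` for ``j = 0..N-1``.  The j=0 coefficient
    therefore equals the plain sum of the input entries.
    """

    coefficients: np.ndarray
    frequencies: np.ndarray

    def __len__(self) -> int:
        return len(self.coefficients)


def dft(v) -> Spectrum:
    """Unnormalised discrete Fourier transform of a vector."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise DimensionError("dft expects a non-empty 1-D vector")
    n = v.size
    coeff = np.fft.fft(v)
    freq = 2.0 * np.pi * np.arange(n) / n
    return Spectrum(coefficients=coeff, frequencies=freq)


def sobolev(x, y, k: int = 1, dialect: str = "full") -> float:
    """Sobolev distance of degree k computed through the DFT.

    With ``δ = x - y`` and ``δ̂`` its unnormalised DFT over N points,

        d(x, y) = sqrt( Σ_j (1 + ω_j)^k |δ̂(ω_j)|² ),   ω_j = 2π j / N.

    The ``(1 + ω)^k`` weight penalises high-frequency disagreement, i.e.
    it compares the vectors together with their first k discrete
    derivatives.  ``dialect="full"`` sums j = 0..N-1 (the default; a true
    metric, and for k=0 it reduces to ``sqrt(N)``-scaled Euclidean by
    Parseval).  ``dialect="literal"`` drops the j=0 (DC) term, summing
    j = 1..N-1; it is then blind to a constant offset between x and y.
    Frequencies are indexed as printed, without negative-frequency
    symmetrisation, so the upper half of the spectrum is weighted more
    heavily than its conjugate-symmetric lower half.
    """
    if dialect not in ("full", "literal"):
        raise ParameterError(f"unknown sobolev dialect {dialect!r}")
    if not (isinstance(k, (int, np.integer)) and k >= 0):
        raise ParameterError(f"sobolev degree k must be a non-negative integer, got {k!r}")
    x, y = _pair(x, y)
    delta = x - y
    n = delta.shape[-1]
    spec = np.fft.fft(delta, axis=-1)
    omega = 2.0 * np.pi * np.arange(n) / n
    weights = (1.0 + omega) ** k
    power = spec.real**2 + spec.imag**2
    if dialect == "literal":
        weights = weights[1:]
        power = power[..., 1:]
    return _scalarize(np.sqrt((weights * power).sum(axis=-1)))


def simplex_project(x) -> np.ndarray:
    """Map arbitrary feature vectors onto the probability simplex.

    If any entry is negative the vector is shifted by ``-min(x)``; the
    result is then divided by its sum, giving non-negative entries summing
    to 1.  Broadcasts over leading axes (each trailing-axis vector is
    projected independently).  An all-constant-minimum vector (e.g. all
    zeros) has a zero post-shift sum and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 0 or x.shape[-1] == 0:
        raise DimensionError("simplex_project expects non-empty vectors")
    lo = x.min(axis=-1, keepdims=True)
    shifted = np.where(lo < 0, x - lo, x)
    total = shifted.sum(axis=-1, keepdims=True)
    if np.any(total == 0.0):
        raise DegenerateInputError(
            "cannot project a constant-minimum (e.g. all-zero) vector onto the simplex"
        )
    return shifted / total


_SIMPLEX_TOL = 1e-9


def fisher(x, y) -> float:
    """Fisher information geodesic distance between simplex vectors.

    The square-root map ``x ↦ sqrt(x)`` embeds the simplex isometrically
    (up to a factor) into the positive orthant of the unit sphere, pulling
    the spherical metric back to the Fisher information metric.  The
    distance is the great-circle arc length between the embedded points:

        d(x, y) = arccos( Σ_i sqrt(x_i y_i) )  ∈  [0, π/2].

    Inputs must already lie on the simplex (non-negative, summing to 1
    within 1e-9); use :func:`simplex_project` for raw features — the
    registry-wrapped ``fisher`` metric does this automatically.  The
    arccos argument is clipped to [0, 1] to absorb floating-point
    overshoot of the Cauchy-Schwarz bound.
    """
    x, y = _pair(x, y)
    for v, name in ((x, "x"), (y, "y")):
        if np.any(v < -_SIMPLEX_TOL) or np.any(np.abs(v.sum(axis=-1) - 1.0) > _SIMPLEX_TOL):
            raise DomainError(
                f"fisher operand {name} is not on the probability simplex "
                "(entries >= 0 summing to 1); apply simplex_project first"
            )
    sx = np.sqrt(np.clip(x, 0.0, None))
    sy = np.sqrt(np.clip(y, 0.0, None))
    # arc length via the chord, 2*arcsin(|sx - sy| / 2): mathematically
    # identical to arccos(<sx, sy>) but well-conditioned near 0, so
    # d(x, x) is exactly 0 instead of O(sqrt(eps)).
    chord = np.sqrt(((sx - sy) ** 2).sum(axis=-1))
    return _scalarize(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))


# --------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class MetricSpec:
    """A named, parameterised distance function with property flags.

    ``fn`` broadcasts over leading axes (see module docstring).
    ``preprocess``, when set, is applied independently to each operand
    before ``fn`` (used by ``fisher`` to simplex-project raw features).
    """

    name: str
    fn: Callable[..., Any]
    is_true_metric: bool
    requires_nonnegative: bool
    parameters: Mapping[str, Any] = field(default_factory=dict)
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, x, y):
        if self.preprocess is not None:
            x = self.preprocess(np.asarray(x, dtype=float))
            y = self.preprocess(np.asarray(y, dtype=float))
        return self.fn(x, y)

    def pairwise(self, X, Y, max_chunk_elements: int = 4_000_000) -> np.ndarray:
        """Distance matrix of shape (len(X), len(Y)).

        Rows of ``X`` are chunked so the broadcast intermediate stays below
        roughly ``max_chunk_elements`` floats, which keeps memory bounded
        for wide (image-like) feature matrices.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
            raise DimensionError("pairwise expects 2-D arrays with equal feature counts")
        if self.preprocess is not None:
            X = self.preprocess(X)
            Y = self.preprocess(Y)
        out = np.empty((X.shape[0], Y.shape[0]), dtype=float)
        step = max(1, int(max_chunk_elements // max(1, Y.size)))
        for i in range(0, X.shape[0], step):
            out[i : i + step] = self.fn(X[i : i + step, None, :], Y[None, :, :])
        return out

    def label(self) -> str:
        """Canonical string form, e.g. ``minkowski:p=3``; default parameter
        values are omitted (the default Sobolev is just ``sobolev``)."""
        defaults = _DEFAULT_PARAMETERS.get(self.name, {})
        shown = {k: v for k, v in self.parameters.items() if defaults.get(k) != v}
        if not shown:
            return self.name
        parts = ",".join(f"{k}={v}" for k, v in sorted(shown.items()))
        return f"{self.name}:{parts}"


def _validate_minkowski(params: dict) -> dict:
    if "p" not in params:
        raise ParameterError("minkowski requires parameter p")
    p = float(params["p"])
    if not math.isfinite(p) or p <= 0:
        raise ParameterError(f"minkowski order p must be positive, got {p!r}")
    return {"p": p}


def _validate_sobolev(params: dict) -> dict:
    k = params.get("k", 1)
    if isinstance(k, float) and k.is_integer():
        k = int(k)
    if not (isinstance(k, (int, np.integer)) and k >= 0):
        raise ParameterError(f"sobolev degree k must be a non-negative integer, got {k!r}")
    dialect = params.get("dialect", "full")
    if dialect not in ("full", "literal"):
        raise ParameterError(f"unknown sobolev dialect {dialect!r}")
    return {"k": int(k), "dialect": dialect}


_DEFAULT_PARAMETERS: dict[str, dict] = {"sobolev": {"k": 1, "dialect": "full"}}

# name -> (builder(params) -> (fn, preprocess), param validator, true metric?, nonneg?)
_REGISTRY: dict[str, tuple] = {
    "euclidean": (lambda p: (euclidean, None), None, True, False),
    "manhattan": (lambda p: (manhattan, None), None, True, False),
    "chebyshev": (lambda p: (chebyshev, None), None, True, False),
    "minkowski": (
        lambda p: ((lambda x, y, _p=p["p"]: minkowski(x, y, _p)), None),
        _validate_minkowski,
        True,  # for p >= 1; quasi-metric below
        False,
    ),
    "canberra": (lambda p: (canberra, None), None, True, False),
    "hamming": (lambda p: (hamming, None), None, True, False),
    # Bhattacharyya is a distance between probability distributions; the
    # registry-wrapped metric therefore simplex-projects its arguments
    # (the raw printed formula stays available as the plain function).
    "bhattacharyya": (lambda p: (bhattacharyya, simplex_project), None, False, True),
    "bray_curtis": (lambda p: (bray_curtis, None), None, False, True),
    "clark": (lambda p: (clark, None), None, False, False),
    "soergel": (lambda p: (soergel, None), None, True, True),
    "hassanat": (lambda p: (hassanat, None), None, True, False),
    "sobolev": (
        lambda p: ((lambda x, y, _k=p["k"], _d=p["dialect"]: sobolev(x, y, _k, _d)), None),
        _validate_sobolev,
        True,  # dialect=full; literal is a pseudometric
        False,
    ),
    "fisher": (lambda p: (fisher, simplex_project), None, True, False),
}


def list_metrics() -> tuple[str, ...]:
    """Names accepted by :func:`get_metric`."""
    return tuple(_REGISTRY)


def get_metric(name: str, parameters: Mapping[str, Any] | None = None, **kwargs) -> MetricSpec:
    """Look up a distance measure by name and build a validated MetricSpec.

    Parameters may be given as a mapping or as keyword arguments
    (``get_metric("minkowski", p=3)``).  The returned spec's ``fn`` closes
    over the validated parameters; ``fisher`` composes
    :func:`simplex_project` on both arguments.
    """
    params = dict(parameters or {})
    params.update(kwargs)
    if name not in _REGISTRY:
        raise UnknownMetricError(
            f"unknown metric {name!r}; known: {', '.join(sorted(_REGISTRY))}"
        )
    builder, validator, true_metric, nonneg = _REGISTRY[name]
    if validator is not None:
        params = validator(params)
    elif params:
        raise ParameterError(f"metric {name!r} takes no parameters, got {sorted(params)}")
    fn, preprocess = builder(params)
    if name == "minkowski" and params["p"] < 1:
        true_metric = False  # triangle inequality fails for 0 < p < 1
    if name == "sobolev" and params["dialect"] == "literal":
        true_metric = False  # DC-blind: d(x, x + c) == 0
    return MetricSpec(
        name=name,
        fn=fn,
        is_true_metric=true_metric,
        requires_nonnegative=nonneg,
        parameters=params,
        preprocess=preprocess,
    )


def _parse_value(text: str):
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def parse_metric_string(spec: str) -> MetricSpec:
    """Parse a CLI/config metric string like ``minkowski:p=3`` or ``sobolev:k=1,dialect=full``."""
    name, _, tail = spec.partition(":")
    params: dict[str, Any] = {}
    if tail:
        for item in tail.split(","):
            key, sep, value = item.partition("=")
            if not sep or not key:
                raise ParameterError(f"malformed metric parameter {item!r} in {spec!r}")
            params[key.strip()] = _parse_value(value.strip())
    return get_metric(name.strip(), params)
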