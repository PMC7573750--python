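"""Unit and property tests for the twelve distance measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import knnbench as kb
from knnbench.exceptions import (
    DegenerateInputError,
    DimensionError,
    DomainError,
    ParameterError,
    UnknownMetricError,
)

ALL_NAMES = kb.DEFAULT_METRICS


# ---------------------------------------------------------------------------
# Worked values


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (kb.minkowski, ((1, 2, 3), (1, 2, 3), 1), 0.0),
        (kb.minkowski, ((0, 0), (3, 4), 2), 5.0),
        (kb.minkowski, ((1, 5), (4, 1), 1), 7.0),
        (kb.chebyshev, ((1, 5), (4, 1)), 4.0),
        (kb.chebyshev, ((2,), (7,)), 5.0),
        (kb.canberra, ((0, 0), (0, 0)), 0.0),
        (kb.canberra, ((1, 1), (1, 3)), 0.5),
        (kb.canberra, ((1,) * 5, (-1,) * 5), 5.0),
        (kb.hamming, ((1, 2, 3), (1, 0, 3)), 1),
        (kb.hamming, ((1, 2, 3, 4), (0, 0, 0, 0)), 4),
        (kb.bhattacharyya, ((0.5, 0.5), (0.5, 0.5)), 0.0),
        (kb.bhattacharyya, ((0.5, 0.5), (0.9, 0.1)), -math.log(math.sqrt(0.45) + math.sqrt(0.05))),
        (kb.bray_curtis, ((1, 1), (3, 1)), 1 / 3),
        (kb.bray_curtis, ((1, 0), (0, 1)), 1.0),
        (kb.clark, ((1, 3), (3, 1)), math.sqrt(0.5)),
        (kb.clark, ((1,), (-1,)), 1.0),
        (kb.soergel, ((1, 3), (2, 1)), 0.6),
        (kb.soergel, ((1, 0), (0, 1)), 1.0),
        (kb.hassanat, ((1,), (3,)), 0.5),
        (kb.hassanat, ((1, -1), (3, 1)), 7 / 6),
        (kb.sobolev, ((1, 0), (0, 0)), math.sqrt(2 + math.pi)),
        (kb.fisher, ((1.0, 0.0), (0.0, 1.0)), math.pi / 2),
        (kb.fisher, ((0.25, 0.75), (0.75, 0.25)), math.pi / 6),
    ],
)
def test_worked_values(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-9)


def test_bhattacharyya_disjoint_support_is_infinite():
    assert kb.bhattacharyya((1, 0), (0, 1)) == math.inf


def test_dft_closed_forms():
    spec = kb.dft([1.0, 0.0])
    np.testing.assert_allclose(spec.coefficients, [1.0, 1.0], atol=1e-12)
    a, b = 2.5, -1.5
    spec = kb.dft([a, b])
    np.testing.assert_allclose(spec.coefficients, [a + b, a - b], atol=1e-12)
    np.testing.assert_allclose(kb.dft(np.zeros(8)).coefficients, np.zeros(8), atol=0)
    # DC coefficient equals the plain sum
    v = np.arange(1.0, 10.0)
    assert kb.dft(v).coefficients[0] == pytest.approx(v.sum())
    assert kb.dft(v).frequencies[3] == pytest.approx(2 * math.pi * 3 / 9)


def test_simplex_project_cases():
    np.testing.assert_allclose(kb.simplex_project([2.0, 2.0]), [0.5, 0.5])
    np.testing.assert_allclose(kb.simplex_project([-1.0, 1.0]), [0.0, 1.0])
    with pytest.raises(DegenerateInputError):
        kb.simplex_project([0.0, 0.0])


def test_sobolev_literal_dialect_drops_dc_term():
    # literal range j=1..N-1 is blind to constant offsets
    x = np.array([1.0, 2.0, 3.0])
    assert kb.sobolev(x, x + 5.0, k=1, dialect="literal") == pytest.approx(0.0, abs=1e-9)
    assert kb.sobolev(x, x + 5.0, k=1, dialect="full") > 1.0


# ---------------------------------------------------------------------------
# Errors


@pytest.mark.parametrize("name", ALL_NAMES)
def test_length_mismatch_raises(name):
    metric = kb.get_metric(name)
    with pytest.raises(DimensionError):
        metric(np.ones(3), np.ones(4))


def test_parameter_errors():
    with pytest.raises(ParameterError):
        kb.minkowski((1,), (2,), p=0)
    with pytest.raises(ParameterError):
        kb.get_metric("minkowski", p=-1)
    with pytest.raises(ParameterError):
        kb.get_metric("minkowski")
    with pytest.raises(ParameterError):
        kb.get_metric("sobolev", dialect="bogus")
    with pytest.raises(ParameterError):
        kb.get_metric("euclidean", p=2)
    with pytest.raises(UnknownMetricError):
        kb.get_metric("mahalanobis")


def test_domain_and_degenerate_errors():
    with pytest.raises(DomainError):
        kb.bhattacharyya((1.0, -1.0), (1.0, 1.0))
    with pytest.raises(DegenerateInputError):
        kb.bray_curtis((1.0, -1.0), (-1.0, 1.0))
    with pytest.raises(DegenerateInputError):
        kb.soergel((0.0, 0.0), (0.0, 0.0))
    with pytest.raises(DomainError):
        kb.fisher((0.5, 0.2), (0.5, 0.5))


def test_parse_metric_string():
    spec = kb.parse_metric_string("minkowski:p=3")
    assert spec.parameters == {"p": 3.0}
    assert spec((0.0, 0.0), (1.0, 1.0)) == pytest.approx(2 ** (1 / 3))
    spec = kb.parse_metric_string("sobolev:k=2,dialect=literal")
    assert spec.parameters == {"k": 2, "dialect": "literal"}
    with pytest.raises(ParameterError):
        kb.parse_metric_string("sobolev:k")


# ---------------------------------------------------------------------------
# Sampled metric axioms (seeded batches; functions broadcast over rows)


def _positive_pairs(rng, n, count=1000):
    return rng.uniform(0.05, 10.0, (count, n)), rng.uniform(0.05, 10.0, (count, n))


@pytest.mark.parametrize("n", [1, 2, 9, 55])
@pytest.mark.parametrize("name", ALL_NAMES)
def test_symmetry_and_nonnegativity(name, n, rng):
    metric = kb.get_metric(name)
    x, y = _positive_pairs(rng, n, count=250)
    d_xy = np.asarray(metric(x, y), dtype=float)
    d_yx = np.asarray(metric(y, x), dtype=float)
    np.testing.assert_allclose(d_xy, d_yx, atol=1e-12)
    assert np.all(d_xy >= 0)


@pytest.mark.parametrize("name", ALL_NAMES)
def test_identity_at_zero(name, rng):
    metric = kb.get_metric(name)
    x = rng.uniform(0.05, 10.0, (200, 9))
    np.testing.assert_allclose(np.asarray(metric(x, x), dtype=float), 0.0, atol=1e-12)


def test_raw_bhattacharyya_self_distance_is_neg_log_sum(rng):
    # On unnormalized input the printed formula gives d(x, x) = -ln(sum x_i)
    x = rng.uniform(0.05, 10.0, (50, 9))
    np.testing.assert_allclose(
        kb.bhattacharyya(x, x), -np.log(x.sum(axis=1)), atol=1e-10
    )


@pytest.mark.parametrize(
    "name", ["manhattan", "euclidean", "chebyshev", "soergel", "sobolev"]
)
def test_triangle_inequality_sampled(name, rng):
    metric = kb.get_metric(name)
    x, y = _positive_pairs(rng, 9, count=1000)
    z = rng.uniform(0.05, 10.0, (1000, 9))
    d_xz = np.asarray(metric(x, z), dtype=float)
    d_xy = np.asarray(metric(x, y), dtype=float)
    d_yz = np.asarray(metric(y, z), dtype=float)
    assert np.all(d_xz <= d_xy + d_yz + 1e-9)


def test_bounds(rng):
    x, y = _positive_pairs(rng, 9, count=500)
    assert np.all(np.asarray(kb.bray_curtis(x, y)) <= 1.0)
    assert np.all(np.asarray(kb.soergel(x, y)) <= 1.0)
    assert np.all(np.asarray(kb.canberra(x, y)) <= 9.0)
    assert np.all(np.asarray(kb.clark(x, y)) <= math.sqrt(9) + 1e-12)
    xn = rng.normal(size=(500, 9))
    yn = rng.normal(size=(500, 9))
    # each hassanat per-dimension term lies in [0, 1), so totals in [0, n)
    assert np.all(np.asarray(kb.hassanat(xn, yn)) < 9.0)
    fx = kb.simplex_project(rng.uniform(0, 1, (500, 9)))
    fy = kb.simplex_project(rng.uniform(0, 1, (500, 9)))
    d = np.asarray(kb.fisher(fx, fy))
    assert np.all((d >= 0) & (d <= math.pi / 2 + 1e-12))


def test_hamming_counts_integer_positions(rng):
    x = rng.integers(0, 3, (300, 12)).astype(float)
    y = x.copy()
    flip = rng.random((300, 12)) < 0.25
    y[flip] += 1.0
    np.testing.assert_array_equal(np.asarray(kb.hamming(x, y)), flip.sum(axis=1))


def test_chebyshev_below_manhattan(rng):
    x, y = rng.normal(size=(500, 7)), rng.normal(size=(500, 7))
    assert np.all(np.asarray(kb.chebyshev(x, y)) <= np.asarray(kb.manhattan(x, y)) + 1e-12)


# ---------------------------------------------------------------------------
# Structural oracles


@pytest.mark.parametrize("n", [2, 9, 55])
def test_sobolev_parseval_limit(n, rng):
    # degree 0 with the full spectral range reduces to sqrt(N) * Euclidean
    x = rng.normal(size=(100, n))
    y = rng.normal(size=(100, n))
    lhs = np.asarray(kb.sobolev(x, y, k=0, dialect="full"))
    rhs = math.sqrt(n) * np.asarray(kb.euclidean(x, y))
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_fisher_equals_sphere_embedding_arc(rng):
    # the sqrt map embeds the simplex on the unit sphere; the geodesic is
    # the great-circle arc between the embedded points
    x = rng.dirichlet(np.ones(6), size=500)
    y = rng.dirichlet(np.ones(6), size=500)
    sx, sy = np.sqrt(x), np.sqrt(y)
    np.testing.assert_allclose(np.linalg.norm(sx, axis=1), 1.0, atol=1e-12)
    arc = np.arccos(np.clip((sx * sy).sum(axis=1), 0.0, 1.0))
    np.testing.assert_allclose(np.asarray(kb.fisher(x, y)), arc, atol=1e-12)
    # chord-based arc length as an independent numerical route
    chord = np.linalg.norm(sx - sy, axis=1)
    np.testing.assert_allclose(
        np.asarray(kb.fisher(x, y)), 2 * np.arcsin(chord / 2), atol=1e-7
    )


def test_registry_fisher_projects_raw_features():
    metric = kb.get_metric("fisher")
    raw = metric((1.0, 2.0, 3.0), (3.0, 2.0, 1.0))
    manual = kb.fisher(kb.simplex_project((1.0, 2.0, 3.0)), kb.simplex_project((3.0, 2.0, 1.0)))
    assert raw == pytest.approx(manual, abs=1e-12)


def test_registry_flags():
    assert kb.get_metric("soergel").requires_nonnegative
    assert kb.get_metric("bhattacharyya").requires_nonnegative
    assert not kb.get_metric("euclidean").requires_nonnegative
    assert kb.get_metric("manhattan").is_true_metric
    assert not kb.get_metric("bray_curtis").is_true_metric
    assert not kb.get_metric("minkowski", p=0.5).is_true_metric
    assert not kb.get_metric("sobolev", dialect="literal").is_true_metric


# ---------------------------------------------------------------------------
# Hypothesis properties


finite_floats = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


@settings(derandomize=True, max_examples=100)
@given(st.lists(finite_floats, min_size=1, max_size=12), st.data())
def test_sobolev_zero_iff_equal_and_symmetric(values, data):
    x = np.array(values)
    y = np.array(data.draw(st.lists(finite_floats, min_size=len(values), max_size=len(values))))
    assert kb.sobolev(x, x) == pytest.approx(0.0, abs=1e-9)
    assert kb.sobolev(x, y) == pytest.approx(kb.sobolev(y, x), abs=1e-9)
    if not np.allclose(x, y):
        assert kb.sobolev(x, y) > 0


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=20))
def test_simplex_project_lands_on_simplex(values):
    x = np.array(values)
    if np.ptp(x) == 0 and (x <= 0).all():
        with pytest.raises((DegenerateInputError,)):
            kb.simplex_project(x)
        return
    p = kb.simplex_project(x)
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
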