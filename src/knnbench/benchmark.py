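"""Ranking and clustering of distance-measure performance profiles.

A benchmark run produces a score tensor S[d, p, e, k] — the score of
distance measure d under performance measure p in experiment (dataset) e
with neighbourhood size k.  This module turns such tensors into the
benchmark's summary artifacts:

* best-over-k final scores ``S[d, p, e] = max_k S[d, p, e, k]``;
* tie-aware rankings of the measures per (experiment, performance) pair;
* two consensus orders: the arithmetic mean of ranks, and a weighted
  rank aggregation by cross-entropy Monte Carlo search minimising the
  summed Kendall distance to the input rankings (rho = 0.1 elite
  fraction by default);
* k-means clustering of the measures' best-score profiles, with a 2-D
  PCA projection for plotting.

A reference 12×16 matrix of published best scores for the four cancer
benchmark datasets (brain MRI, breast cytology, lung, prostate) is
packaged for ranking and clustering checks
(:func:`load_reference_best_scores`).
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .exceptions import (
    AlignmentError,
    DomainError,
    IncompleteTensorError,
    ParameterError,
)

__all__ = [
    "ScoreTensor",
    "Ranking",
    "ConsensusRanking",
    "AggregationConfig",
    "ClusterResult",
    "best_over_k",
    "rank_with_ties",
    "average_rank",
    "kendall_distance",
    "ce_rank_aggregate",
    "cluster_profiles",
    "pca_project",
    "load_reference_best_scores",
    "rankings_from_best_scores",
    "plot_profiles",
]

_TENSOR_COLUMNS = ("metric", "performance", "experiment", "k", "score")


@dataclass
class ScoreTensor:
    """Long-format container for S[d, p, e, k] scores in [0, 1].

    Backed by a DataFrame with columns metric, performance, experiment,
    k, score.  The tensor is expected to be complete over the declared
    metric × performance × experiment × k grid; :meth:`validate_complete`
    enforces this and lists any gaps.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TENSOR_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ParameterError(f"score tensor frame lacks columns {missing}")
        self.frame = self.frame.loc[:, list(_TENSOR_COLUMNS)].copy()
        self.frame["k"] = self.frame["k"].astype(int)
        self.frame["score"] = self.frame["score"].astype(float)
        if ((self.frame["score"] < 0) | (self.frame["score"] > 1)).any():
            raise DomainError("scores must lie in [0, 1]")

    @property
    def metrics(self) -> tuple:
        return tuple(pd.unique(self.frame["metric"]))

    @property
    def performances(self) -> tuple:
        return tuple(pd.unique(self.frame["performance"]))

    @property
    def experiments(self) -> tuple:
        return tuple(pd.unique(self.frame["experiment"]))

    @property
    def k_values(self) -> tuple:
        return tuple(sorted(pd.unique(self.frame["k"])))

    def experiment_k_values(self, experiment) -> tuple:
        """The k grid of one experiment (grids may differ between datasets)."""
        sub = self.frame[self.frame["experiment"] == experiment]
        if sub.empty:
            raise IncompleteTensorError(f"no scores for experiment {experiment!r}")
        return tuple(sorted(pd.unique(sub["k"])))

    def validate_complete(self) -> None:
        """Require every (metric, performance, k) cell within each experiment's grid."""
        index = pd.MultiIndex.from_frame(self.frame[["metric", "performance", "experiment", "k"]])
        gaps: list = []
        for e in self.experiments:
            expected = pd.MultiIndex.from_product(
                [self.metrics, self.performances, [e], self.experiment_k_values(e)]
            )
            gaps.extend(expected.difference(index))
        if gaps:
            shown = ", ".join(map(str, gaps[:10]))
            raise IncompleteTensorError(
                f"score tensor is missing {len(gaps)} cells, e.g. {shown}"
            )

    def best_scores(self) -> pd.DataFrame:
        """Best-over-k final scores: rows = metrics, columns = (experiment, performance)."""
        self.validate_complete()
        table = (
            self.frame.groupby(["metric", "experiment", "performance"], sort=False)["score"]
            .max()
            .unstack(["experiment", "performance"])
        )
        return table.loc[list(self.metrics)]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScoreTensor":
        return cls(pd.read_csv(path, sep="\t"))


def best_over_k(tensor: ScoreTensor, metric, performance, experiment) -> float:
    """Final score of one (metric, performance, experiment) cell: max over k."""
    sub = tensor.frame[
        (tensor.frame["metric"] == metric)
        & (tensor.frame["performance"] == performance)
        & (tensor.frame["experiment"] == experiment)
    ]
    have = set(sub["k"])
    expected = tensor.experiment_k_values(experiment) if not sub.empty else tensor.k_values
    missing = [k for k in expected if k not in have]
    if missing or sub.empty:
        raise IncompleteTensorError(
            f"missing k values {missing or list(tensor.k_values)} for "
            f"({metric!r}, {performance!r}, {experiment!r})"
        )
    return float(sub["score"].max())


# --------------------------------------------------------------------------
# Rankings

_POLICIES = {"average": "average", "min": "min", "ordinal": "ordinal"}


@dataclass(frozen=True)
class Ranking:
    """Tie-aware ranks per item; rank 1 is best (highest score)."""

    item_ranks: Mapping
    policy: str = "average"

    def items(self) -> tuple:
        return tuple(self.item_ranks)

    def as_order(self) -> list:
        """Items sorted best-first, ties broken by item identity (stringified)."""
        return sorted(self.item_ranks, key=lambda i: (self.item_ranks[i], str(i)))


def rank_with_ties(final_scores: Mapping, policy: str = "average") -> Ranking:
    """Rank items by descending score with the chosen tie policy.

    ``average`` assigns tied items their fractional mean rank, ``min``
    competition ranks, ``ordinal`` strict 1..m ranks (ties broken by
    position in the mapping's iteration order).
    """
    if policy not in _POLICIES:
        raise ParameterError(f"unknown tie policy {policy!r}")
    if not final_scores:
        raise ParameterError("rank_with_ties needs at least one item")
    items = list(final_scores)
    scores = np.array([float(final_scores[i]) for i in items])
    if np.isnan(scores).any():
        raise DomainError("NaN score cannot be ranked")
    ranks = rankdata(-scores, method=_POLICIES[policy])
    return Ranking(dict(zip(items, (float(r) for r in ranks))), policy=policy)


def average_rank(rankings: Sequence[Ranking]) -> dict:
    """Arithmetic mean of each item's rank over a sequence of rankings."""
    if not rankings:
        raise ParameterError("average_rank needs at least one ranking")
    base = set(rankings[0].item_ranks)
    for r in rankings[1:]:
        if set(r.item_ranks) != base:
            raise AlignmentError("rankings cover different item sets")
    return {
        item: float(np.mean([r.item_ranks[item] for r in rankings])) for item in base
    }


def kendall_distance(a: Sequence, b: Sequence) -> int:
    """Number of item pairs ordered differently by the two (tie-free) lists."""
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise AlignmentError("kendall_distance inputs must not contain duplicates")
    if set(a) != set(b):
        raise AlignmentError("kendall_distance inputs must share one item set")
    pos_b = {item: i for i, item in enumerate(b)}
    seq = [pos_b[item] for item in a]
    return sum(
        1 for i, j in itertools.combinations(range(len(seq)), 2) if seq[i] > seq[j]
    )


# --------------------------------------------------------------------------
# Cross-entropy Monte Carlo rank aggregation


@dataclass(frozen=True)
class AggregationConfig:
    """Hyperparameters of the cross-entropy Monte Carlo consensus search.

    ``rho`` is the elite fraction; ``sample_size`` the candidate orders
    drawn per iteration (None → 200·m for m items); ``smoothing`` the
    weight of the elite empirical frequencies in the probability-matrix
    update; the search stops when the best objective has not improved for
    ``convergence_window`` iterations.  ``weights`` optionally weight the
    input lists in the objective.
    """

    rho: float = 0.1
    sample_size: int | None = None
    smoothing: float = 0.7
    max_iterations: int = 100
    convergence_window: int = 7
    seed: int = 0
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ParameterError("rho must lie in (0, 1)")
        if not 0.0 < self.smoothing <= 1.0:
            raise ParameterError("smoothing must lie in (0, 1]")
        if self.sample_size is not None and self.rho * self.sample_size < 1:
            raise ParameterError("rho * sample_size must be at least 1")
        if self.max_iterations < 1 or self.convergence_window < 1:
            raise ParameterError("max_iterations and convergence_window must be >= 1")


@dataclass(frozen=True)
class ConsensusRanking:
    order: tuple
    objective: float


def _sample_orders(P: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n orders (rows of item indices) position-by-position from P.

    P[i, j] is the probability of placing item i at position j; at each
    position the remaining items are renormalised.
    """
    m = P.shape[0]
    orders = np.empty((n, m), dtype=np.int64)
    remaining = np.ones((n, m), dtype=bool)
    for j in range(m):
        probs = np.where(remaining, P[:, j][None, :], 0.0)
        totals = probs.sum(axis=1, keepdims=True)
        flat = totals.ravel() == 0.0
        if flat.any():  # degenerate column: fall back to uniform over remaining
            probs[flat] = remaining[flat].astype(float)
            totals = probs.sum(axis=1, keepdims=True)
        probs /= totals
        cum = probs.cumsum(axis=1)
        u = rng.random((n, 1))
        choice = (u > cum).sum(axis=1)
        choice = np.minimum(choice, m - 1)
        orders[:, j] = choice
        remaining[np.arange(n), choice] = False
    return orders


def ce_rank_aggregate(
    rankings: Sequence[Sequence],
    config: AggregationConfig | None = None,
    extra_candidates: Sequence[Sequence] = (),
) -> ConsensusRanking:
    """Consensus order minimising the weighted sum of Kendall distances.

    Cross-entropy Monte Carlo search: an m×m position-probability matrix
    (initialised uniform) is sampled for candidate orders; the elite
    ``ceil(rho * sample_size)`` candidates by objective re-fit the matrix
    with exponential smoothing.  The input lists themselves (and any
    ``extra_candidates``) are evaluated up front, so the returned
    objective never exceeds that of any input.  Seeded and reproducible.
    """
    if not rankings:
        raise ParameterError("ce_rank_aggregate needs at least one input list")
    config = config or AggregationConfig()
    items = list(rankings[0])
    item_set = set(items)
    if len(item_set) != len(items):
        raise AlignmentError("input lists must not contain duplicates")
    for r in rankings[1:]:
        if set(r) != item_set:
            raise AlignmentError("input lists cover different item sets")
    m = len(items)
    index = {item: i for i, item in enumerate(items)}
    n_lists = len(rankings)
    weights = np.ones(n_lists) if config.weights is None else np.asarray(config.weights, float)
    if len(weights) != n_lists:
        raise ParameterError("weights length must equal the number of input lists")

    # Pairwise order signs of each input list over all item pairs.
    pairs_i, pairs_j = map(np.asarray, zip(*itertools.combinations(range(m), 2)))
    positions = np.array([[list(map(index.__getitem__, r)).index(i) for i in range(m)]
                          for r in rankings])
    # positions[l, item] = rank position of item in list l
    ref_signs = np.sign(positions[:, pairs_i] - positions[:, pairs_j])  # (L, P)

    def objectives(orders: np.ndarray) -> np.ndarray:
        # orders: (n, m) item indices best-first -> candidate positions
        n = orders.shape[0]
        pos = np.empty_like(orders)
        np.put_along_axis(pos, orders, np.broadcast_to(np.arange(m), (n, m)).copy(), axis=1)
        cand = np.sign(pos[:, pairs_i] - pos[:, pairs_j])  # (n, P)
        mism = cand[:, None, :] != ref_signs[None, :, :]  # (n, L, P)
        return mism.sum(axis=2) @ weights

    rng = np.random.default_rng(config.seed)
    sample_size = config.sample_size or 200 * m
    elite_n = max(1, math.ceil(config.rho * sample_size))

    seed_orders = [tuple(r) for r in rankings] + [tuple(c) for c in extra_candidates]
    for cand in seed_orders:
        if set(cand) != item_set:
            raise AlignmentError("candidate covers a different item set")
    seed_idx = np.array([[index[i] for i in cand] for cand in seed_orders])
    seed_obj = objectives(seed_idx)
    best_at = int(np.argmin(seed_obj))
    best_order = seed_idx[best_at].copy()
    best_obj = float(seed_obj[best_at])

    P = np.full((m, m), 1.0 / m)
    stall = 0
    for _ in range(config.max_iterations):
        orders = _sample_orders(P, sample_size, rng)
        obj = objectives(orders)
        elite = orders[np.argsort(obj, kind="stable")[:elite_n]]
        freq = np.zeros((m, m))
        np.add.at(freq, (elite.ravel(), np.tile(np.arange(m), elite_n)), 1.0)
        P = (1.0 - config.smoothing) * P + config.smoothing * freq / elite_n
        it_best = float(obj.min())
        if it_best < best_obj:
            best_obj = it_best
            best_order = orders[int(np.argmin(obj))].copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.convergence_window:
                break
        if best_obj == 0.0:
            break
    return ConsensusRanking(
        order=tuple(items[i] for i in best_order), objective=best_obj
    )


# --------------------------------------------------------------------------
# Clustering and projection of performance profiles


@dataclass(frozen=True)
class ClusterResult:
    """k-means partition of items; cluster indices are 1-based."""

    assignment: Mapping
    centers: np.ndarray
    inertia: float

    def clusters(self) -> list[frozenset]:
        """The partition as a list of item sets, largest first."""
        groups: dict[int, set] = {}
        for item, c in self.assignment.items():
            groups.setdefault(c, set()).add(item)
        return sorted(
            (frozenset(g) for g in groups.values()), key=lambda g: (-len(g), sorted(map(str, g)))
        )


def _profile_matrix(profiles: Mapping) -> tuple[list, np.ndarray]:
    items = list(profiles)
    if not items:
        raise ParameterError("empty profile mapping")
    X = np.array([np.asarray(profiles[i], dtype=float).ravel() for i in items])
    if np.unique([len(np.ravel(profiles[i])) for i in items]).size != 1:
        raise ParameterError("profile vectors must share one length")
    return items, X


def cluster_profiles(
    profiles: Mapping,
    k: int,
    restarts: int = 50,
    seed: int = 0,
    standardize: bool = False,
) -> ClusterResult:
    """k-means (squared Euclidean) over item profile vectors.

    Runs ``restarts`` seeded k-means++ initialisations and keeps the
    lowest-inertia solution.  Profiles are used raw by default;
    ``standardize=True`` z-scores each profile coordinate first.
    """
    items, X = _profile_matrix(profiles)
    if not 1 <= k <= len(items):
        raise ParameterError(f"k={k} invalid for {len(items)} items")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(X)
    return ClusterResult(
        assignment={item: int(c) + 1 for item, c in zip(items, labels)},
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def pca_project(profiles: Mapping, dims: int = 2) -> dict:
    """Centered principal-component projection of profiles (plotting aid)."""
    items, X = _profile_matrix(profiles)
    if len(items) < dims:
        raise ParameterError(f"need at least {dims} items for a {dims}-D projection")
    coords = PCA(n_components=dims, random_state=0).fit_transform(X)
    return {item: coords[i] for i, item in enumerate(items)}


def plot_profiles(profiles: Mapping, assignment: Mapping | None = None, path=None):
    """Scatter the 2-D PCA projection, coloured by cluster; save if path given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = pca_project(profiles, dims=2)
    fig, ax = plt.subplots(figsize=(6, 5))
    for item, (x, y) in coords.items():
        c = assignment.get(item, 1) if assignment else 1
        ax.scatter(x, y, color=f"C{(c - 1) % 10}")
        ax.annotate(str(item), (x, y), fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("distance-measure performance profiles")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# --------------------------------------------------------------------------
# Reference fixture and ranking pipeline helpers


def load_reference_best_scores() -> pd.DataFrame:
    """Published best kNN scores of the 12 measures on the 4 cancer datasets.

    Returns a 12×16 DataFrame: rows are metric names, columns a
    (experiment, performance) MultiIndex over {brain, breast, lung,
    prostate} × {precision, recall, f1, accuracy}.
    """
    ref = importlib.resources.files("knnbench.data") / "reference_best_scores.tsv"
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    table = frame.set_index(["metric", "experiment", "performance"])["score"].unstack(
        ["experiment", "performance"]
    )
    return table.loc[pd.unique(frame["metric"])]


def rankings_from_best_scores(
    best: pd.DataFrame, policy: str = "average"
) -> list[Ranking]:
    """One tie-aware ranking per (experiment, performance) column of a best-score table."""
    return [rank_with_ties(best[col].to_dict(), policy=policy) for col in best.columns]
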