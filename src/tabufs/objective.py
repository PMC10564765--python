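"""The composite objective the search maximizes, with subset-level caching.

A candidate subset S of the m available features is scored by

    f(S) = beta * Rat(S) + (1 - beta) * (1 - |S| / m)

where Rat(S) is the resubstitution rate: the fraction of *training* cases
correctly classified by a model fit on the training set restricted to S.
beta (default 0.99) trades classifying capacity against parsimony.  By
convention f(empty set) = 0 exactly — Rat is never computed on an empty
subset.

Because the tabu search revisits subsets heavily and classifier fits
dominate runtime, evaluations are memoized in an :class:`EvaluationCache`
keyed by an order-independent bitmask of the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable

from . import classifiers

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import Dataset


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered set of feature indices drawn from the universe 0..m-1."""

    members: tuple[int, ...]
    m: int

    def __post_init__(self) -> None:
        members = tuple(sorted(set(int(j) for j in self.members)))
        object.__setattr__(self, "members", members)
        if members and not (0 <= members[0] and members[-1] < self.m):
            raise ValueError(f"members must lie in 0..{self.m - 1}")

    @classmethod
    def of(cls, members: Iterable[int], m: int) -> "FeatureSubset":
        return cls(tuple(members), m)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def key(self) -> int:
        """Canonical order-independent bitmask of the subset."""
        return subset_key(self.members)

    def names(self, feature_names: list[str]) -> list[str]:
        return [feature_names[j] for j in self.members]


def subset_key(members: Iterable[int]) -> int:
    key = 0
    for j in members:
        key |= 1 << j
    return key


@dataclass(frozen=True)
class ObjectiveConfig:
    """Objective weights and the classifier used to compute Rat."""

    beta: float = 0.99
    classifier: str = "da"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class EvaluationCache:
    """Exact memo of (rat, f) per subset key; no eviction below the cap."""

    max_entries: int | None = None
    hits: int = 0
    misses: int = 0
    _store: dict[int, tuple[float, float]] = field(default_factory=dict)

    def get_or_compute(
        self, key: int, compute: Callable[[], tuple[float, float]]
    ) -> tuple[float, float]:
        found = self._store.get(key)
        if found is not None:
            self.hits += 1
            return found
        self.misses += 1
        value = compute()
        if self.max_entries is None or len(self._store) < self.max_entries:
            self._store[key] = value
        return value

    def __len__(self) -> int:
        return len(self._store)

    def clear(self) -> None:
        self._store.clear()
        self.hits = 0
        self.misses = 0


def rat(ds: "Dataset", subset: FeatureSubset | Iterable[int], cfg: ObjectiveConfig) -> float:
    """Resubstitution rate of ``cfg.classifier`` fit on ``ds[:, subset]``.

    The model is trained and scored on the same cases; this is optimistic by
    design and is exactly the quantity the search optimizes.
    """
    members = tuple(getattr(subset, "members", subset))
    if len(members) == 0:
        raise ValueError("empty feature subset")
    if cfg.classifier == "da":
        # hot path: the search evaluates this millions of times
        return float(classifiers.resubstitution_rate_da(ds, members))
    model = classifiers.fit(cfg.classifier, ds, members)
    pred = classifiers.predict(model, ds)
    return float((pred == ds.labels).mean())


def objective_f(rat_value: float, subset_size: int, m: int, beta: float) -> float:
    """Composite score beta*rat + (1-beta)*(1 - |S|/m); exactly 0 for |S|=0."""
    if not 0 <= subset_size <= m:
        raise ValueError("subset_size must lie in [0, m]")
    if subset_size == 0:
        return 0.0
    return beta * rat_value + (1.0 - beta) * (1.0 - subset_size / m)


def evaluate(
    ds: "Dataset",
    subset: FeatureSubset | Iterable[int],
    cfg: ObjectiveConfig,
    cache: EvaluationCache | None = None,
) -> tuple[float, float]:
    """Cached (rat, f) for a subset; identical whether computed or served."""
    members = getattr(subset, "members", None)
    if members is None:
        members = tuple(sorted(subset))
    if len(members) == 0:
        return float("nan"), 0.0
    if cache is None:
        r = rat(ds, members, cfg)
        return r, objective_f(r, len(members), ds.m, cfg.beta)

    def compute() -> tuple[float, float]:
        r = rat(ds, members, cfg)
        return r, objective_f(r, len(members), ds.m, cfg.beta)

    return cache.get_or_compute(subset_key(members), compute)


def evaluate_many(
    ds: "Dataset",
    subsets: list[tuple[int, ...]],
    cfg: ObjectiveConfig,
    cache: EvaluationCache | None = None,
) -> list[tuple[float, float]]:
    """Cached (rat, f) for many subsets; one neighborhood in one call.

    Semantically identical to calling :func:`evaluate` per subset.  For the
    DA classifier the uncached subsets are fit in vectorized batches grouped
    by cardinality, which is what makes full-neighborhood enumeration
    affordable inside the search.
    """
    results: list[tuple[float, float] | None] = [None] * len(subsets)
    pending: dict[int, list[int]] = {}  # key -> positions awaiting its value
    for i, members in enumerate(subsets):
        if not members:
            results[i] = (float("nan"), 0.0)
            continue
        key = subset_key(members)
        if cache is not None:
            found = cache._store.get(key)
            if found is not None:
                cache.hits += 1
                results[i] = found
                continue
            if key in pending:
                cache.hits += 1
                pending[key].append(i)
                continue
        pending.setdefault(key, []).append(i)

    if pending:
        order = list(pending)
        first_pos = {key: positions[0] for key, positions in pending.items()}
        if cfg.classifier == "da":
            by_size: dict[int, list[int]] = {}
            for key in order:
                by_size.setdefault(len(subsets[first_pos[key]]), []).append(key)
            rat_of: dict[int, float] = {}
            for size, keys in by_size.items():
                batch = [subsets[first_pos[key]] for key in keys]
                rates = classifiers.resubstitution_rate_da_batch(ds, batch)
                rat_of.update(zip(keys, (float(r) for r in rates)))
        else:
            rat_of = {key: rat(ds, subsets[first_pos[key]], cfg) for key in order}
        for key in order:
            members = subsets[first_pos[key]]
            value = (rat_of[key], objective_f(rat_of[key], len(members), ds.m, cfg.beta))
            if cache is not None:
                cache.misses += 1
                if cache.max_entries is None or len(cache._store) < cache.max_entries:
                    cache._store[key] = value
            for i in pending[key]:
                results[i] = value
    return results
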