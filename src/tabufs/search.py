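"""Multistart tabu search over feature subsets.

The method repeats two phases until the incumbent stops improving:

1. *Constructive* — greedy randomized construction.  Starting from the
   empty subset (f = 0 by convention, so initially every feature is a
   candidate), it repeatedly evaluates the gain g(j) = f(S + {j}) of each
   unselected feature, keeps the improving ones (g(j) >= f(S)), restricts
   them to a candidate list of near-best gains controlled by ``alpha``
   (1 = pure greedy, 0 = uniform over all improving features), and adds a
   uniform-random member.  Construction stops when no feature improves f.

2. *TabuSearch* — steepest local search over the add/remove/swap
   neighborhood that accepts non-improving moves.  Reversing a recent move
   is forbidden ("tabu") for ``tenure`` iterations: a feature that left S
   may not re-enter while iter <= VectorOut(j) + tenure, and a feature that
   entered may not leave while iter <= VectorIn(j) + tenure; a swap is tabu
   if either end is.  A tabu move is still considered when it beats the
   best value found in this run (the aspiration criterion).  The best
   considered neighbor is executed each iteration, ties broken uniformly at
   random; the run ends after ``max_iter_ts`` consecutive iterations
   without improving the run best f*.

The multistart driver keeps the best subset over all starts and stops after
``max_iter_ms`` consecutive starts without improving it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .objective import (
    EvaluationCache,
    FeatureSubset,
    ObjectiveConfig,
    evaluate,
    evaluate_many,
)

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import Dataset

__all__ = [
    "SearchParams",
    "TabuMemory",
    "Move",
    "SearchResult",
    "greedy_gains",
    "rcl_select",
    "constructive",
    "is_entry_tabu",
    "is_exit_tabu",
    "tabu_search",
    "multistart_tabu",
]


@dataclass(frozen=True)
class SearchParams:
    """Tuning knobs of the search.

    ``tenure`` and ``max_iter_ts`` default to None, meaning "scale with the
    number of features m": tenure = ceil(m/2) and max_iter_ts = 10*m.
    Defaults follow the tuned values alpha=0.99, tenure=m/2,
    max_iter_ts=10*m, max_iter_ms=10.
    """

    alpha: float = 0.99
    tenure: int | None = None
    max_iter_ts: int | None = None
    max_iter_ms: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tenure is not None and self.tenure < 0:
            raise ValueError("tenure must be >= 0")
        if self.max_iter_ts is not None and self.max_iter_ts < 1:
            raise ValueError("max_iter_ts must be >= 1")
        if self.max_iter_ms < 1:
            raise ValueError("max_iter_ms must be >= 1")

    def resolved_tenure(self, m: int) -> int:
        return self.tenure if self.tenure is not None else math.ceil(m / 2)

    def resolved_max_iter_ts(self, m: int) -> int:
        return self.max_iter_ts if self.max_iter_ts is not None else 10 * m


@dataclass
class TabuMemory:
    """Per-feature iteration stamps of the last entry into / exit from S."""

    vector_in: np.ndarray
    vector_out: np.ndarray
    iter: int = 0

    @classmethod
    def fresh(cls, m: int, tenure: int) -> "TabuMemory":
        # stamps start at -(tenure+1) so no move is tabu at iter 1
        init = -(tenure + 1)
        return cls(
            vector_in=np.full(m, init, dtype=int),
            vector_out=np.full(m, init, dtype=int),
        )


@dataclass(frozen=True)
class Move:
    """One neighborhood move: add j_in, remove j_out, or swap j_out -> j_in."""

    move_type: str  # "add" | "remove" | "swap"
    j_in: int | None = None
    j_out: int | None = None


@dataclass(frozen=True)
class TabuStep:
    """One executed tabu-search iteration, for trace audits."""

    iteration: int
    move: Move
    f: float
    f_star: float
    move_was_tabu: bool
    aspired: bool


@dataclass(frozen=True)
class StartRecord:
    """One multistart iteration: the f its tabu run reached and the running best."""

    start: int
    f: float
    best_f: float


@dataclass
class SearchResult:
    best_subset: FeatureSubset
    best_f: float
    best_rat: float
    trace: list[StartRecord]
    iterations_run: int
    iter_best: int
    evaluations: int


def is_entry_tabu(mem: TabuMemory, j: int, tenure: int) -> bool:
    """Entry of a feature j (currently outside S) is tabu while it has
    recently left: iter <= VectorOut(j) + tenure."""
    return mem.iter <= mem.vector_out[j] + tenure


def is_exit_tabu(mem: TabuMemory, j: int, tenure: int) -> bool:
    """Exit of a feature j (currently in S) is tabu while it has recently
    entered: iter <= VectorIn(j) + tenure."""
    return mem.iter <= mem.vector_in[j] + tenure


def greedy_gains(
    ds: "Dataset",
    subset: FeatureSubset | Iterable[int],
    cfg: ObjectiveConfig,
    cache: EvaluationCache | None = None,
) -> dict[int, float]:
    """g(j) = f(S + {j}) for every candidate feature j outside S."""
    members = set(getattr(subset, "members", subset))
    if len(members) >= ds.m:
        raise ValueError("no candidate features: subset already spans the universe")
    candidates = [j for j in range(ds.m) if j not in members]
    trials = [tuple(sorted(members | {j})) for j in candidates]
    values = evaluate_many(ds, trials, cfg, cache)
    return {j: f_val for j, (_, f_val) in zip(candidates, values)}


def rcl_select(
    gains: dict[int, float],
    current_f: float,
    alpha: float,
    rng: np.random.Generator,
) -> int | None:
    """Pick the next feature from the restricted candidate list, or None.

    Improving candidates L' = {j : g(j) >= current_f}; among them the RCL is
    L = {j : g(j) >= gmin + alpha*(gmax - gmin)} with gmin/gmax over L'.
    Returns a uniform-random member of L, or None when L' is empty.
    """
    if not gains:
        raise ValueError("gains must be nonempty")
    improving = sorted(j for j, g in gains.items() if g >= current_f)
    if not improving:
        return None
    values = [gains[j] for j in improving]
    gmin, gmax = min(values), max(values)
    threshold = gmin + alpha * (gmax - gmin)
    rcl = [j for j in improving if gains[j] >= threshold]
    return rcl[int(rng.integers(len(rcl)))]


def constructive(
    ds: "Dataset",
    cfg: ObjectiveConfig,
    params: SearchParams,
    rng: np.random.Generator,
    cache: EvaluationCache | None = None,
    audit: list | None = None,
) -> FeatureSubset:
    """Greedy randomized construction of a starting subset.

    Every accepted addition satisfies g(j*) >= f(S) at the time of addition;
    with ``audit`` a list, each step appends (f_before, j_star, g(j_star)).
    """
    members: set[int] = set()
    f_cur = 0.0  # f(empty set) by convention
    while len(members) < ds.m:
        gains = greedy_gains(ds, members, cfg, cache)
        j_star = rcl_select(gains, f_cur, params.alpha, rng)
        if j_star is None:
            break
        if audit is not None:
            audit.append((f_cur, j_star, gains[j_star]))
        members.add(j_star)
        f_cur = gains[j_star]
    return FeatureSubset.of(members, ds.m)


def _enumerate_moves(members: set[int], m: int) -> Iterable[Move]:
    outside = [j for j in range(m) if j not in members]
    inside = sorted(members)
    for j in outside:
        yield Move("add", j_in=j)
    for j in inside:
        yield Move("remove", j_out=j)
    for j_out in inside:
        for j_in in outside:
            yield Move("swap", j_in=j_in, j_out=j_out)


def tabu_search(
    ds: "Dataset",
    cfg: ObjectiveConfig,
    start: FeatureSubset,
    params: SearchParams,
    rng: np.random.Generator,
    cache: EvaluationCache | None = None,
    audit: list | None = None,
) -> tuple[FeatureSubset, float, float, list[TabuStep]]:
    """Tabu search from ``start``; returns (S*, f*, rat*, executed-move trace).

    With ``audit`` a list, each iteration appends a dict holding the
    iteration number, the memory stamps before the move, f* before the move,
    the executed step, and every (move, f) pair rejected as tabu.
    """
    if cache is None:
        cache = EvaluationCache()
    m = ds.m
    tenure = params.resolved_tenure(m)
    max_no_improve = params.resolved_max_iter_ts(m)

    members = set(start.members)
    rat_cur, f_cur = evaluate(ds, sorted(members), cfg, cache)
    star_members = set(members)
    f_star, rat_star = f_cur, rat_cur

    mem = TabuMemory.fresh(m, tenure)
    trace: list[TabuStep] = []
    no_improve = 0
    while no_improve < max_no_improve:
        mem.iter += 1
        moves: list[tuple[Move, bool, tuple[int, ...]]] = []
        for move in _enumerate_moves(members, m):
            if move.move_type == "add":
                tabu = is_entry_tabu(mem, move.j_in, tenure)
                new_members = tuple(sorted(members | {move.j_in}))
            elif move.move_type == "remove":
                tabu = is_exit_tabu(mem, move.j_out, tenure)
                new_members = tuple(sorted(members - {move.j_out}))
            else:
                tabu = is_entry_tabu(mem, move.j_in, tenure) or is_exit_tabu(
                    mem, move.j_out, tenure
                )
                new_members = tuple(sorted((members - {move.j_out}) | {move.j_in}))
            moves.append((move, tabu, new_members))
        values = evaluate_many(ds, [nm for _, _, nm in moves], cfg, cache)

        best_f = -math.inf
        best: list[tuple[Move, float, float, bool]] = []  # move, f, rat, was_tabu
        rejected: list[tuple[Move, float]] = []
        for (move, tabu, _), (r_val, f_val) in zip(moves, values):
            if (not tabu) or f_val > f_star:  # aspiration overrides tabu status
                if f_val > best_f:
                    best_f = f_val
                    best = [(move, f_val, r_val, tabu)]
                elif f_val == best_f:
                    best.append((move, f_val, r_val, tabu))
            elif audit is not None:
                rejected.append((move, f_val))
        if not best:
            warnings.warn("tabu search stalled: no considered neighbor", stacklevel=2)
            break
        if audit is not None:
            audit.append(
                {
                    "iteration": mem.iter,
                    "vector_in": mem.vector_in.copy(),
                    "vector_out": mem.vector_out.copy(),
                    "f_star_before": f_star,
                    "rejected_tabu": rejected,
                }
            )
        move, f_cur, rat_cur, was_tabu = best[int(rng.integers(len(best)))]
        if move.j_in is not None:
            members.add(move.j_in)
            mem.vector_in[move.j_in] = mem.iter
        if move.j_out is not None:
            members.discard(move.j_out)
            mem.vector_out[move.j_out] = mem.iter
        if f_cur > f_star:
            f_star, rat_star = f_cur, rat_cur
            star_members = set(members)
            no_improve = 0
        else:
            no_improve += 1
        trace.append(
            TabuStep(mem.iter, move, f_cur, f_star, was_tabu, was_tabu)
        )
        if audit is not None:
            audit[-1]["executed"] = trace[-1]
    return FeatureSubset.of(star_members, m), f_star, rat_star, trace


def multistart_tabu(
    ds: "Dataset",
    cfg: ObjectiveConfig | None = None,
    params: SearchParams | None = None,
    rng: np.random.Generator | None = None,
    cache: EvaluationCache | None = None,
) -> SearchResult:
    """Repeat constructive + tabu search, keeping the best subset overall.

    Stops after ``params.max_iter_ms`` consecutive starts that fail to
    improve the best objective value.  Fully reproducible from
    ``params.seed`` when no explicit ``rng`` is supplied.  ``evaluations``
    counts classifier fits (cache misses) performed during this call.
    """
    cfg = cfg or ObjectiveConfig()
    params = params or SearchParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if cache is None:
        cache = EvaluationCache()
    misses0 = cache.misses

    best_members: FeatureSubset | None = None
    best_f = -math.inf
    best_rat = float("nan")
    iter_best = 0
    trace: list[StartRecord] = []
    start_idx = 0
    no_improve = 0
    while no_improve < params.max_iter_ms:
        start_idx += 1
        s0 = constructive(ds, cfg, params, rng, cache)
        s_loc, f_loc, rat_loc, _ = tabu_search(ds, cfg, s0, params, rng, cache)
        if f_loc > best_f:
            best_members, best_f, best_rat = s_loc, f_loc, rat_loc
            iter_best = start_idx
            no_improve = 0
        else:
            no_improve += 1
        trace.append(StartRecord(start_idx, f_loc, best_f))
    assert best_members is not None
    return SearchResult(
        best_subset=best_members,
        best_f=best_f,
        best_rat=best_rat,
        trace=trace,
        iterations_run=start_idx,
        iter_best=iter_best,
        evaluations=cache.misses - misses0,
    )
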