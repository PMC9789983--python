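"""Structure learning: score-based search, constraint-based tests, hybrids.

Nine learners spanning the three classical families:

========================  =================================================
score-based               hill climbing (``hc``), hill climbing with random
                          restarts (``hc_restarts``), Tabu search (``tabu``)
constraint-based          PC-stable (``pc_stable``), grow-shrink (``gs``),
                          IAMB (``iamb``), interleaved IAMB (``inter_iamb``)
hybrid                    MMHC (``mmhc``), skeleton-restricted Tabu
                          (``tabu_restricted``)
========================  =================================================

All learners consume a complete binary DataFrame whose column order is the
canonical variable order, and return a :class:`LearnedStructure` holding an
acyclic DAG.  Search is deterministic: it starts from the empty graph,
candidate moves are enumerated in canonical edge order, ties between
equal-scoring moves go to the earliest candidate, and randomness (restart
perturbations, bootstrap callers) flows only through explicit seeds.

Constraint-based learners use the G² conditional-independence test and
complete their partially directed output to a DAG (v-structures first, then
a deterministic consistent extension), because downstream parameter
learning and reporting need a DAG, not an equivalence class.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .graph import DAG
from .scoring import ScoreCache, as_binary_matrix

__all__ = [
    "LearnedStructure",
    "hill_climb",
    "hill_climb_restarts",
    "tabu_search",
    "g2_test",
    "pc_stable",
    "grow_shrink",
    "iamb",
    "inter_iamb",
    "mmhc",
    "tabu_restricted",
    "algorithm_menu",
]

_TOL = 1e-9


@dataclass
class LearnedStructure:
    """Result of one structure-learning run."""

    algorithm: str
    dag: DAG
    score: float
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# score-based local search
# ---------------------------------------------------------------------------


def _has_path(children: dict[int, set[int]], src: int, dst: int) -> bool:
    """Directed reachability src -> dst (used as the acyclicity guard)."""
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _graph_key(parents: dict[int, frozenset[int]]) -> frozenset[tuple[int, int]]:
    return frozenset((u, v) for v, ps in parents.items() for u in ps)


def _local_search(
    cache: ScoreCache,
    start_parents: dict[int, frozenset[int]] | None = None,
    allowed: set[frozenset[int]] | None = None,
    tabu_len: int = 0,
    max_iter: int = 500,
    max_stall: int = 15,
) -> tuple[dict[int, frozenset[int]], float, dict]:
    """Greedy / tabu single-edge search over DAGs.

    With ``tabu_len == 0`` this is plain hill climbing: only strictly
    improving moves are accepted and the search stops at a local optimum.
    With ``tabu_len >= 1``, at a local optimum the best move whose resulting
    graph is not among the last ``tabu_len`` visited structures is accepted
    even if it worsens the score, and the best structure ever seen is
    returned; the walk stops after ``max_stall`` consecutive iterations
    without improving the best score.
    """
    d = len(cache.columns)
    parents = {i: frozenset() for i in range(d)}
    if start_parents:
        parents.update({i: frozenset(ps) for i, ps in start_parents.items()})
    children = {i: set() for i in range(d)}
    for v, ps in parents.items():
        for u in ps:
            children[u].add(v)

    current = cache.graph(parents)
    best_parents, best_score = dict(parents), current
    tabu: deque[frozenset] = deque(maxlen=max(tabu_len, 1))
    tabu_set: set[frozenset] = set()

    def _push_tabu(key):
        if tabu_len:
            if len(tabu) == tabu.maxlen:
                tabu_set.discard(tabu[0])
            tabu.append(key)
            tabu_set.add(key)

    _push_tabu(_graph_key(parents))
    iterations = moves_evaluated = 0
    stall = 0

    for _ in range(max_iter):
        iterations += 1
        best_move = None
        best_delta = -np.inf
        for u in range(d):
            for v in range(d):
                if u == v:
                    continue
                pv = parents[v]
                if u not in pv:
                    if allowed is not None and frozenset((u, v)) not in allowed:
                        continue
                    if _has_path(children, v, u):
                        continue
                    moves_evaluated += 1
                    delta = cache.family(v, pv | {u}) - cache.family(v, pv)
                    move = ("add", u, v, delta)
                    if delta > best_delta + _TOL and not self_tabu(move, parents, tabu_set, tabu_len):
                        best_delta, best_move = delta, move
                else:
                    moves_evaluated += 1
                    d_del = cache.family(v, pv - {u}) - cache.family(v, pv)
                    move = ("del", u, v, d_del)
                    if d_del > best_delta + _TOL and not self_tabu(move, parents, tabu_set, tabu_len):
                        best_delta, best_move = d_del, move
                    # reversal u->v  =>  v->u
                    children[u].discard(v)
                    makes_cycle = _has_path(children, u, v)
                    children[u].add(v)
                    if not makes_cycle and (
                        allowed is None or frozenset((u, v)) in allowed
                    ):
                        moves_evaluated += 1
                        pu = parents[u]
                        d_rev = d_del + cache.family(u, pu | {v}) - cache.family(u, pu)
                        move = ("rev", u, v, d_rev)
                        if d_rev > best_delta + _TOL and not self_tabu(
                            move, parents, tabu_set, tabu_len
                        ):
                            best_delta, best_move = d_rev, move

        if best_move is None:
            break
        if tabu_len == 0 and best_delta <= _TOL:
            break

        kind, u, v, delta = best_move
        if kind == "add":
            parents[v] = parents[v] | {u}
            children[u].add(v)
        elif kind == "del":
            parents[v] = parents[v] - {u}
            children[u].discard(v)
        else:
            parents[v] = parents[v] - {u}
            children[u].discard(v)
            parents[u] = parents[u] | {v}
            children[v].add(u)
        current += delta
        _push_tabu(_graph_key(parents))

        if current > best_score + _TOL:
            best_score = current
            best_parents = dict(parents)
            stall = 0
        else:
            stall += 1
            if tabu_len and stall >= max_stall:
                break

    diag = {"iterations": iterations, "moves_evaluated": moves_evaluated}
    return best_parents, best_score, diag


def self_tabu(move, parents, tabu_set, tabu_len) -> bool:
    """True when applying ``move`` would revisit a tabu structure."""
    if not tabu_len:
        return False
    kind, u, v, _ = move
    edges = set(_graph_key(parents))
    if kind == "add":
        edges.add((u, v))
    elif kind == "del":
        edges.discard((u, v))
    else:
        edges.discard((u, v))
        edges.add((v, u))
    return frozenset(edges) in tabu_set


def _to_dag(columns: list[str], parents: dict[int, frozenset[int]]) -> DAG:
    edges = [(columns[u], columns[v]) for v, ps in parents.items() for u in ps]
    return DAG(tuple(columns), edges)


def hill_climb(
    dataset: pd.DataFrame,
    score: str = "aic",
    max_iter: int = 500,
    seed: int | None = None,
) -> LearnedStructure:
    """Greedy single-edge hill climbing from the empty graph.

    Accepted moves strictly increase the score; the result is a local
    optimum (its score is never below the empty graph's).  ``seed`` is
    accepted for interface uniformity but unused: plain hill climbing is
    fully deterministic.
    """
    cache = ScoreCache(dataset, score)
    parents, best, diag = _local_search(cache, max_iter=max_iter)
    return LearnedStructure("hc", _to_dag(cache.columns, parents), best, diag)


def hill_climb_restarts(
    dataset: pd.DataFrame,
    score: str = "aic",
    n_restarts: int = 5,
    n_perturb: int = 4,
    max_iter: int = 500,
    seed: int = 0,
) -> LearnedStructure:
    """Hill climbing with seeded random restarts.

    After the deterministic first climb, each restart perturbs the incumbent
    with random edge additions/deletions and climbs again; the best-scoring
    structure across all climbs is returned.
    """
    cache = ScoreCache(dataset, score)
    rng = np.random.default_rng(seed)
    d = len(cache.columns)
    parents, best, diag = _local_search(cache, max_iter=max_iter)
    for _ in range(n_restarts):
        pert = {i: set(ps) for i, ps in parents.items()}
        children = {i: {v for v, ps in pert.items() if i in ps} for i in range(d)}
        for _ in range(n_perturb):
            u, v = rng.choice(d, size=2, replace=False)
            if u in pert[v]:
                pert[v].discard(u)
                children[u].discard(v)
            elif not _has_path(children, v, u):
                pert[v].add(u)
                children[u].add(v)
        cand, cand_score, d2 = _local_search(
            cache, start_parents={i: frozenset(ps) for i, ps in pert.items()}, max_iter=max_iter
        )
        diag["iterations"] += d2["iterations"]
        diag["moves_evaluated"] += d2["moves_evaluated"]
        if cand_score > best + _TOL:
            parents, best = cand, cand_score
    return LearnedStructure("hc_restarts", _to_dag(cache.columns, parents), best, diag)


def tabu_search(
    dataset: pd.DataFrame,
    score: str = "aic",
    tabu_len: int = 10,
    max_iter: int = 500,
    max_stall: int = 15,
    seed: int | None = None,
    _allowed: set[frozenset[int]] | None = None,
    _name: str = "tabu",
) -> LearnedStructure:
    """Tabu search: hill climbing that escapes local optima.

    At a local optimum the best non-tabu (possibly worsening) move is taken,
    with the last ``tabu_len`` visited structures forbidden; the best
    structure encountered anywhere along the walk is returned, so the
    result can never score below the plain hill-climbing optimum reached on
    the way.
    """
    if tabu_len < 1:
        raise ValueError("tabu_len must be >= 1")
    cache = ScoreCache(dataset, score)
    parents, best, diag = _local_search(
        cache, allowed=_allowed, tabu_len=tabu_len, max_iter=max_iter, max_stall=max_stall
    )
    return LearnedStructure(_name, _to_dag(cache.columns, parents), best, diag)


# ---------------------------------------------------------------------------
# conditional-independence testing
# ---------------------------------------------------------------------------


def _col_index(dataset: pd.DataFrame, col) -> int:
    if isinstance(col, (int, np.integer)):
        return int(col)
    return list(dataset.columns).index(col)


def g2_test(dataset: pd.DataFrame, x, y, conditioning_set=()) -> tuple[float, int, float]:
    """G² test of X ⟂ Y | Z on binary data.

    Returns ``(statistic, dof, p_value)``.  The statistic is
    ``2 * sum O log(O/E)`` over the per-stratum 2x2 tables; nominal degrees
    of freedom are ``2**|Z|``, reduced by one for every stratum that is
    empty or has a zero margin (such strata contribute nothing to the
    statistic).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    X = as_binary_matrix(dataset)
    xi, yi = _col_index(dataset, x), _col_index(dataset, y)
    zi = tuple(_col_index(dataset, z) for z in conditioning_set)
    code = np.zeros(len(X), dtype=np.int64)
    for z in zi:
        code = (code << 1) | X[:, z]
    idx = ((code << 1) | X[:, xi]) << 1 | X[:, yi]
    counts = np.bincount(idx, minlength=2 ** (len(zi) + 2)).reshape(-1, 2, 2)

    stat = 0.0
    dof = 0
    for table in counts:
        n = table.sum()
        rows = table.sum(axis=1)
        colsums = table.sum(axis=0)
        if n == 0 or (rows == 0).any() or (colsums == 0).any():
            continue
        dof += 1
        expected = np.outer(rows, colsums) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = table * np.log(table / expected)
        stat += 2.0 * float(np.where(table > 0, terms, 0.0).sum())
    p = float(chi2.sf(stat, dof)) if dof > 0 else 1.0
    return stat, dof, p


# ---------------------------------------------------------------------------
# constraint-based learning
# ---------------------------------------------------------------------------


def _skeleton(dataset: pd.DataFrame, alpha: float, max_cond: int):
    """PC-stable adjacency search.

    Returns (adjacency sets, separating sets, number of tests).  Edge
    removals within one level use the adjacency sets frozen at the start of
    the level, which is what makes the result order-independent.
    """
    d = dataset.shape[1]
    adj = {i: set(range(d)) - {i} for i in range(d)}
    sepset: dict[tuple[int, int], frozenset[int]] = {}
    n_tests = 0
    for level in range(max_cond + 1):
        frozen = {i: sorted(adj[i]) for i in range(d)}
        if all(len(frozen[i]) - 1 < level for i in range(d)):
            break
        for i in range(d):
            for j in list(sorted(adj[i])):
                if j < i or j not in adj[i]:
                    continue
                removed = False
                for base in ([k for k in frozen[i] if k != j], [k for k in frozen[j] if k != i]):
                    if len(base) < level:
                        continue
                    for S in combinations(base, level):
                        n_tests += 1
                        _, _, p = g2_test(dataset, i, j, S)
                        if p > alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepset[(i, j)] = sepset[(j, i)] = frozenset(S)
                            removed = True
                            break
                    if removed:
                        break
    return adj, sepset, n_tests


def _orient_v_structures(d, adj, sepset):
    """Collider orientation, processed in canonical order.

    An orientation is skipped when it conflicts with an earlier one or
    would close a directed cycle, so the returned edge set is always
    acyclic (finite-sample tests can suggest contradictory colliders).
    """
    directed: set[tuple[int, int]] = set()
    children = {i: set() for i in range(d)}

    def try_orient(a, b):
        if (b, a) in directed or (a, b) in directed:
            return
        if _has_path(children, b, a):
            return
        directed.add((a, b))
        children[a].add(b)

    for k in range(d):
        nbrs = sorted(adj[k])
        for i, j in combinations(nbrs, 2):
            if j in adj[i] or (i, j) not in sepset:
                continue
            if k not in sepset[(i, j)]:
                try_orient(i, k)
                try_orient(j, k)
    return directed


def _extend_to_dag(d, adj, directed) -> set[tuple[int, int]]:
    """Complete a partially directed graph to a DAG (Dor–Tarsi).

    Repeatedly finds a potential sink and orients its undirected edges
    inward; when no such node exists (the PDAG admits no consistent
    extension), remaining undirected edges are oriented along the canonical
    node order, skipping any orientation that would close a cycle.
    """
    undirected = {
        frozenset((i, j))
        for i in range(d)
        for j in adj[i]
        if i < j and (i, j) not in directed and (j, i) not in directed
    }
    result = set(directed)
    remaining = set(range(d))
    rem_dir = set(directed)
    rem_und = set(undirected)

    def adjacent(a, b):
        return (
            frozenset((a, b)) in rem_und or (a, b) in rem_dir or (b, a) in rem_dir
        )

    while remaining:
        sink = None
        for x in sorted(remaining):
            if any((x, y) in rem_dir for y in remaining):
                continue
            und_nbrs = [y for y in remaining if frozenset((x, y)) in rem_und]
            all_nbrs = und_nbrs + [y for y in remaining if (y, x) in rem_dir]
            if all(adjacent(y, z) for y in und_nbrs for z in all_nbrs if z != y):
                sink = x
                break
        if sink is None:
            break
        for y in [y for y in remaining if frozenset((sink, y)) in rem_und]:
            result.add((y, sink))
            rem_und.discard(frozenset((sink, y)))
        rem_dir = {(u, v) for (u, v) in rem_dir if u != sink and v != sink}
        rem_und = {e for e in rem_und if sink not in e}
        remaining.discard(sink)

    if rem_und:  # inconsistent PDAG: canonical fallback
        children = {i: set() for i in range(d)}
        for u, v in result:
            children[u].add(v)
        for e in sorted(rem_und, key=sorted):
            i, j = sorted(e)
            if not _has_path(children, j, i):
                result.add((i, j))
                children[i].add(j)
            else:
                result.add((j, i))
                children[j].add(i)
    return result


def _finish_constraint(dataset, adj, sepset, name, n_tests, extra=None) -> LearnedStructure:
    from .scoring import aic_score

    d = dataset.shape[1]
    directed = _orient_v_structures(d, adj, sepset)
    edges = _extend_to_dag(d, adj, directed)
    cols = list(dataset.columns)
    dag = DAG(tuple(cols), [(cols[u], cols[v]) for u, v in edges])
    diag = {"n_tests": n_tests}
    if extra:
        diag.update(extra)
    return LearnedStructure(name, dag, aic_score(dataset, dag), diag)


def pc_stable(dataset: pd.DataFrame, alpha: float = 0.05, max_cond: int = 3) -> LearnedStructure:
    """PC-stable: order-independent skeleton, v-structures, DAG extension."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    adj, sepset, n_tests = _skeleton(dataset, alpha, max_cond)
    return _finish_constraint(dataset, adj, sepset, "pc_stable", n_tests)


# -- Markov-blanket discovery ------------------------------------------------


def _blanket_gs(dataset, t, alpha):
    d = dataset.shape[1]
    mb: list[int] = []
    changed = True
    while changed:
        changed = False
        for x in range(d):
            if x == t or x in mb:
                continue
            if g2_test(dataset, t, x, tuple(mb))[2] <= alpha:
                mb.append(x)
                changed = True
    _shrink(dataset, t, mb, alpha)
    return set(mb)


def _shrink(dataset, t, mb: list[int], alpha):
    changed = True
    while changed:
        changed = False
        for x in list(mb):
            rest = tuple(y for y in mb if y != x)
            if g2_test(dataset, t, x, rest)[2] > alpha:
                mb.remove(x)
                changed = True


def _blanket_iamb(dataset, t, alpha, interleaved=False):
    d = dataset.shape[1]
    mb: list[int] = []
    while True:
        best_x, best_stat = None, 0.0
        for x in range(d):
            if x == t or x in mb:
                continue
            stat, _, p = g2_test(dataset, t, x, tuple(mb))
            if p <= alpha and stat > best_stat:
                best_x, best_stat = x, stat
        if best_x is None:
            break
        mb.append(best_x)
        if interleaved:
            _shrink(dataset, t, mb, alpha)
    _shrink(dataset, t, mb, alpha)
    return set(mb)


def _mb_based(dataset, alpha, max_cond, name, blanket_fn) -> LearnedStructure:
    d = dataset.shape[1]
    blankets = {t: blanket_fn(dataset, t, alpha) for t in range(d)}
    # symmetry correction (AND rule)
    adj = {i: {j for j in blankets[i] if i in blankets[j]} for i in range(d)}
    # refine blanket members to true neighbours, recording separating sets
    sepset: dict[tuple[int, int], frozenset[int]] = {}
    for i in range(d):
        for j in sorted(adj[i]):
            if j < i:
                continue
            base = blankets[i] - {j}
            if len(blankets[j] - {i}) < len(base):
                base = blankets[j] - {i}
            separated = False
            for size in range(min(len(base), max_cond) + 1):
                for S in combinations(sorted(base), size):
                    if g2_test(dataset, i, j, S)[2] > alpha:
                        sepset[(i, j)] = sepset[(j, i)] = frozenset(S)
                        separated = True
                        break
                if separated:
                    break
            if separated:
                adj[i].discard(j)
                adj[j].discard(i)
    # separating sets for never-linked pairs (needed for collider detection)
    for i in range(d):
        for j in range(i + 1, d):
            if j in adj[i] or (i, j) in sepset:
                continue
            base = sorted(blankets[i] - {j})
            found = False
            for size in range(min(len(base), max_cond) + 1):
                for S in combinations(base, size):
                    if g2_test(dataset, i, j, S)[2] > alpha:
                        sepset[(i, j)] = sepset[(j, i)] = frozenset(S)
                        found = True
                        break
                if found:
                    break
    return _finish_constraint(
        dataset, adj, sepset, name, n_tests=-1, extra={"blanket_sizes": {i: len(b) for i, b in blankets.items()}}
    )


def grow_shrink(dataset: pd.DataFrame, alpha: float = 0.05, max_cond: int = 3) -> LearnedStructure:
    """Grow-shrink Markov-blanket learning completed to a DAG."""
    return _mb_based(dataset, alpha, max_cond, "gs", _blanket_gs)


def iamb(dataset: pd.DataFrame, alpha: float = 0.05, max_cond: int = 3) -> LearnedStructure:
    """Incremental-association Markov-blanket learning completed to a DAG."""
    return _mb_based(dataset, alpha, max_cond, "iamb", _blanket_iamb)


def inter_iamb(dataset: pd.DataFrame, alpha: float = 0.05, max_cond: int = 3) -> LearnedStructure:
    """IAMB with shrinking interleaved into the growth phase."""
    return _mb_based(
        dataset, alpha, max_cond, "inter_iamb", lambda ds, t, a: _blanket_iamb(ds, t, a, True)
    )


# ---------------------------------------------------------------------------
# hybrid learning
# ---------------------------------------------------------------------------


def _restriction(dataset, alpha, max_cond) -> tuple[set[frozenset[int]], int]:
    adj, _, n_tests = _skeleton(dataset, alpha, max_cond)
    pairs = {frozenset((i, j)) for i in adj for j in adj[i]}
    return pairs, n_tests


def mmhc(
    dataset: pd.DataFrame, alpha: float = 0.05, score: str = "aic", max_cond: int = 3
) -> LearnedStructure:
    """Hybrid: constraint-based neighbourhood discovery, then restricted hill climb.

    No edge outside the discovered neighbourhoods can appear in the output.
    """
    allowed, n_tests = _restriction(dataset, alpha, max_cond)
    cache = ScoreCache(dataset, score)
    parents, best, diag = _local_search(cache, allowed=allowed)
    diag["n_tests"] = n_tests
    return LearnedStructure("mmhc", _to_dag(cache.columns, parents), best, diag)


def tabu_restricted(
    dataset: pd.DataFrame,
    alpha: float = 0.05,
    score: str = "aic",
    tabu_len: int = 10,
    max_cond: int = 3,
) -> LearnedStructure:
    """Hybrid: Tabu search restricted to the constraint-discovered skeleton."""
    allowed, n_tests = _restriction(dataset, alpha, max_cond)
    result = tabu_search(dataset, score, tabu_len=tabu_len, _allowed=allowed, _name="tabu_restricted")
    result.diagnostics["n_tests"] = n_tests
    return result


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def algorithm_menu() -> dict:
    """Registry of the nine structure learners.

    Each entry maps a name to a callable ``learner(dataset, seed=0) ->
    LearnedStructure``; the seed matters only for learners with a random
    component (restarts).
    """
    return {
        "hc": lambda ds, seed=0: hill_climb(ds, seed=seed),
        "hc_restarts": lambda ds, seed=0: hill_climb_restarts(ds, seed=seed),
        "tabu": lambda ds, seed=0: tabu_search(ds, seed=seed),
        "pc_stable": lambda ds, seed=0: pc_stable(ds),
        "gs": lambda ds, seed=0: grow_shrink(ds),
        "iamb": lambda ds, seed=0: iamb(ds),
        "inter_iamb": lambda ds, seed=0: inter_iamb(ds),
        "mmhc": lambda ds, seed=0: mmhc(ds),
        "tabu_restricted": lambda ds, seed=0: tabu_restricted(ds),
    }
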