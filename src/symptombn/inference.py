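"""Parameter learning and exact probabilistic queries.

Parameter learning is closed-form for discrete data: each CPT entry is the
(optionally Laplace-smoothed) conditional frequency of the child given one
parent configuration.  Queries are answered exactly by variable
elimination; with eleven binary nodes the full joint (2048 states) is also
cheap to enumerate, which provides both an independent oracle and a fast
vectorised path for predicting every symptom of every patient from the
other ten.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .graph import CPT, DAG, DiscreteBayesianNetwork, topological_order
from .scoring import as_binary_matrix, family_counts

__all__ = [
    "QueryResult",
    "fit_cpts",
    "enumerate_joint",
    "query",
    "predict_from_others",
    "predict_proba_all",
]

logger = logging.getLogger(__name__)

_ENUM_GUARD = 20


@dataclass(frozen=True)
class QueryResult:
    target: str
    evidence: dict
    probability: float


def fit_cpts(
    dataset: pd.DataFrame, dag: DAG, smoothing_alpha: float = 0.0
) -> DiscreteBayesianNetwork:
    """Estimate one CPT per node from complete binary data.

    Each entry is ``(n(child=1, pa) + alpha) / (n(pa) + 2 alpha)``;
    ``alpha = 0`` gives maximum likelihood (empirical conditional
    frequencies), ``alpha = 1`` Laplace smoothing.  A parent configuration
    never observed in the data gets 0.5 under maximum likelihood and is
    recorded in the returned network's ``diagnostics['unseen_configs']``.
    """
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be >= 0")
    cols = list(dataset.columns)
    if set(cols) != set(dag.nodes):
        raise ValueError("dataset columns do not match DAG nodes")
    X = as_binary_matrix(dataset)
    cpts = {}
    unseen = []
    for node in dag.nodes:
        parents = dag.parents(node)
        counts = family_counts(X, cols.index(node), tuple(cols.index(p) for p in parents))
        totals = counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            table = (counts[:, 1] + smoothing_alpha) / (totals + 2 * smoothing_alpha)
        for r in np.where(totals == 0)[0]:
            if smoothing_alpha == 0:
                table[r] = 0.5
            unseen.append((node, int(r)))
        cpts[node] = CPT(node, parents, table)
    net = DiscreteBayesianNetwork(dag, cpts)
    net.diagnostics["unseen_configs"] = unseen
    return net


# ---------------------------------------------------------------------------
# joint enumeration (brute-force path)
# ---------------------------------------------------------------------------


def enumerate_joint(network: DiscreteBayesianNetwork) -> np.ndarray:
    """The full joint distribution as a tensor.

    Axis ``i`` (size 2, indexed absent/present) corresponds to
    ``network.nodes[i]``; the entries sum to one.  Guarded at 20 nodes —
    beyond that use :func:`query`.
    """
    n = len(network.nodes)
    if n > _ENUM_GUARD:
        raise ValueError(f"{n} nodes exceeds the enumeration guard ({_ENUM_GUARD}); use query()")
    pos = {node: i for i, node in enumerate(network.nodes)}
    joint = np.ones((2,) * n)
    for node in network.nodes:
        cpt = network.cpts[node]
        k = len(cpt.parents)
        arr = np.empty((2,) * k + (2,))
        arr[..., 1] = cpt.table.reshape((2,) * k)
        arr[..., 0] = 1.0 - arr[..., 1]
        axes = [pos[p] for p in cpt.parents] + [pos[node]]
        order = np.argsort(axes)
        arr = np.transpose(arr, order)
        shape = [2 if i in axes else 1 for i in range(n)]
        joint = joint * arr.reshape(shape)
    return joint


# ---------------------------------------------------------------------------
# variable elimination
# ---------------------------------------------------------------------------


def _factor_multiply(f1, f2):
    vars1, a1 = f1
    vars2, a2 = f2
    union = sorted(set(vars1) | set(vars2))
    pos = {v: i for i, v in enumerate(union)}

    def expand(vars_, arr):
        order = np.argsort([pos[v] for v in vars_])
        arr = np.transpose(arr, order)
        shape = [2 if v in vars_ else 1 for v in union]
        return arr.reshape(shape)

    return tuple(union), expand(vars1, a1) * expand(vars2, a2)


def _check_evidence(network: DiscreteBayesianNetwork, evidence: Mapping[str, int]) -> dict:
    ev = {}
    for node, val in evidence.items():
        if node not in network.nodes:
            raise ValueError(f"evidence node {node!r} not in network")
        if node in ev:
            raise ValueError(f"evidence assigns {node!r} twice")
        if int(val) not in (0, 1):
            raise ValueError(f"evidence value for {node!r} must be 0 or 1")
        ev[node] = int(val)
    return ev


def query(
    network: DiscreteBayesianNetwork, target: str, evidence: Mapping[str, int] | None = None
) -> QueryResult:
    """P(target = present | evidence) by variable elimination.

    Non-evidence, non-target variables are summed out in reverse
    topological order (a deterministic choice; at this scale ordering only
    matters for reproducibility).  Evidence with probability zero raises
    ``ValueError`` naming the impossible configuration.
    """
    evidence = _check_evidence(network, evidence or {})
    if target not in network.nodes:
        raise ValueError(f"unknown target {target!r}")
    if target in evidence:
        raise ValueError(f"target {target!r} is part of the evidence")
    pos = {node: i for i, node in enumerate(network.nodes)}

    factors = []
    for node in network.nodes:
        cpt = network.cpts[node]
        k = len(cpt.parents)
        arr = np.empty((2,) * k + (2,))
        arr[..., 1] = cpt.table.reshape((2,) * k)
        arr[..., 0] = 1.0 - arr[..., 1]
        fvars = tuple(pos[p] for p in cpt.parents) + (pos[node],)
        # reduce by evidence
        for ax in range(len(fvars) - 1, -1, -1):
            name = network.nodes[fvars[ax]]
            if name in evidence:
                arr = np.take(arr, evidence[name], axis=ax)
                fvars = fvars[:ax] + fvars[ax + 1 :]
        factors.append((fvars, arr))

    elim = [
        pos[node]
        for node in reversed(topological_order(network.dag))
        if node != target and node not in evidence
    ]
    for v in elim:
        group = [f for f in factors if v in f[0]]
        factors = [f for f in factors if v not in f[0]]
        if not group:
            continue
        prod = group[0]
        for f in group[1:]:
            prod = _factor_multiply(prod, f)
        fvars, arr = prod
        ax = fvars.index(v)
        factors.append((fvars[:ax] + fvars[ax + 1 :], arr.sum(axis=ax)))

    prod = ((), np.ones(()))
    for f in factors:
        prod = _factor_multiply(prod, f)
    fvars, arr = prod
    assert fvars == (pos[target],)
    total = float(arr.sum())
    if total <= 0.0:
        raise ValueError(f"evidence has probability zero: {evidence}")
    return QueryResult(target, dict(evidence), float(arr[1] / total))


def predict_from_others(
    network: DiscreteBayesianNetwork, row: Mapping[str, int], target: str
) -> float:
    """P(target present | observed values of all other network nodes).

    If the observed configuration has probability zero under the network
    (possible with unsmoothed CPTs), the target's marginal probability is
    returned instead and a warning is logged, so a single degenerate row
    cannot abort a whole evaluation.
    """
    evidence = {node: int(row[node]) for node in network.nodes if node != target}
    try:
        return query(network, target, evidence).probability
    except ValueError as exc:
        if "probability zero" not in str(exc):
            raise
        logger.warning(
            "zero-probability evidence for target %r; falling back to the marginal", target
        )
        return query(network, target, {}).probability


def predict_proba_all(network: DiscreteBayesianNetwork, dataset: pd.DataFrame) -> np.ndarray:
    """Predict every node of every row from the other nodes' observed values.

    Returns an ``(n_rows, n_nodes)`` array whose column ``j`` holds
    ``P(node_j = present | other nodes as observed)``.  Computed from the
    enumerated joint (exactly equal to variable elimination, verified in
    tests); rows whose evidence configuration has probability zero fall
    back to the node's marginal.
    """
    nodes = network.nodes
    X = as_binary_matrix(dataset[list(nodes)])
    joint = enumerate_joint(network)
    n = len(nodes)
    out = np.empty((len(X), n))
    for t in range(n):
        num = np.take(joint, 1, axis=t)  # P(others, target=1)
        den = joint.sum(axis=t)  # P(others)
        marginal = float(num.sum())
        flat_num = num.reshape(-1)
        flat_den = den.reshape(-1)
        others = [i for i in range(n) if i != t]
        code = np.zeros(len(X), dtype=np.int64)
        for i in others:
            code = (code << 1) | X[:, i]
        d_vals = flat_den[code]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = flat_num[code] / d_vals
        out[:, t] = np.where(d_vals > 0, p, marginal)
    return out
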