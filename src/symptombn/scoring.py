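"""Decomposable network scores for binary data.

All scores are sums over nodes of a family score (the node with its parent
set), which is what makes local search efficient: a single-edge move changes
only the affected families.  Conventions here are higher-is-better:

* ``loglik``  — maximised multinomial log-likelihood, no penalty;
* ``aic``     — log-likelihood minus the number of free parameters
  (``2**|parents|`` per binary node), so the best-scoring model is the one
  with the lowest estimated prediction error;
* ``bic``     — log-likelihood minus ``log(n)/2`` per free parameter.

The textbook ``-2 loglik + 2 p`` form of AIC is ``-2 *`` the value used
here; model rankings are identical (reversed sign).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import DAG

__all__ = ["family_counts", "family_loglik", "loglik_score", "aic_score", "bic_score", "ScoreCache"]

_KINDS = ("loglik", "aic", "bic")


def as_binary_matrix(dataset: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = dataset.to_numpy() if isinstance(dataset, pd.DataFrame) else np.asarray(dataset)
    X = X.astype(np.int8, copy=False)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("dataset must be binary 0/1 with no missing cells")
    return X


def family_counts(X: np.ndarray, child: int, parents: tuple[int, ...]) -> np.ndarray:
    """Counts n(parent configuration, child value), shape (2**|parents|, 2).

    Parent configurations are indexed with the first parent most
    significant, matching the CPT row convention.
    """
    k = len(parents)
    if k:
        code = np.zeros(len(X), dtype=np.int64)
        for p in parents:
            code = (code << 1) | X[:, p]
    else:
        code = np.zeros(len(X), dtype=np.int64)
    idx = code * 2 + X[:, child]
    return np.bincount(idx, minlength=2 ** (k + 1)).reshape(-1, 2)


def _counts_loglik(counts: np.ndarray) -> float:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * (np.log(counts) - np.log(totals))
    return float(np.where(counts > 0, terms, 0.0).sum())


def family_loglik(dataset, child, parents) -> float:
    """Maximised log-likelihood contribution of one (child | parents) family.

    ``sum over configs c and values v of n(v, c) * log(n(v, c) / n(c))``,
    with ``0 log 0 = 0``.  Accepts column names (DataFrame input) or
    integer column indices.
    """
    if isinstance(dataset, pd.DataFrame):
        cols = list(dataset.columns)
        child = cols.index(child) if not isinstance(child, (int, np.integer)) else child
        parents = tuple(
            cols.index(p) if not isinstance(p, (int, np.integer)) else p for p in parents
        )
    X = as_binary_matrix(dataset)
    return _counts_loglik(family_counts(X, int(child), tuple(int(p) for p in parents)))


def _graph_score(dataset: pd.DataFrame, dag: DAG, kind: str) -> float:
    X = as_binary_matrix(dataset)
    cols = list(dataset.columns)
    total = 0.0
    n = len(X)
    for node in dag.nodes:
        parents = tuple(cols.index(p) for p in dag.parents(node))
        ll = _counts_loglik(family_counts(X, cols.index(node), parents))
        total += ll - _penalty(kind, len(parents), n)
    return total


def _penalty(kind: str, n_parents: int, n: int) -> float:
    if kind == "loglik":
        return 0.0
    if kind == "aic":
        return float(2**n_parents)
    if kind == "bic":
        return 0.5 * np.log(n) * 2**n_parents
    raise ValueError(f"unknown score kind {kind!r}; expected one of {_KINDS}")


def loglik_score(dataset: pd.DataFrame, dag: DAG) -> float:
    return _graph_score(dataset, dag, "loglik")


def aic_score(dataset: pd.DataFrame, dag: DAG) -> float:
    """AIC of a DAG on complete binary data (higher is better)."""
    return _graph_score(dataset, dag, "aic")


def bic_score(dataset: pd.DataFrame, dag: DAG) -> float:
    return _graph_score(dataset, dag, "bic")


class ScoreCache:
    """Memoised family scores over one dataset, used by the structure search.

    A family is identified by (child index, sorted parent index tuple); the
    cached value already includes the penalty of the chosen score kind.
    """

    def __init__(self, dataset: pd.DataFrame, kind: str = "aic"):
        if kind not in _KINDS:
            raise ValueError(f"unknown score kind {kind!r}; expected one of {_KINDS}")
        self.X = as_binary_matrix(dataset)
        self.n = len(self.X)
        self.kind = kind
        self.columns = list(dataset.columns)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self.evaluations = 0

    def family(self, child: int, parents: frozenset[int] | tuple[int, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        val = self._cache.get(key)
        if val is None:
            self.evaluations += 1
            ll = _counts_loglik(family_counts(self.X, child, key[1]))
            val = ll - _penalty(self.kind, len(key[1]), self.n)
            self._cache[key] = val
        return val

    def graph(self, parent_sets: dict[int, frozenset[int]]) -> float:
        return sum(self.family(c, ps) for c, ps in parent_sets.items())
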