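"""Score imputation and dichotomization.

Raw symptom data are patient-by-symptom tables of 0--10 numeric-rating-scale
scores with occasional missing cells.  Preparation follows the clinical
convention: missing scores are filled in by k-nearest-neighbour imputation
(k = 5) on the raw scores, then every score is dichotomized at the
clinically relevant cut-off (>= 4 means the symptom is present).

The imputation conventions are fixed and deterministic so results reproduce
exactly:

* distance between two rows = sqrt(mean of squared differences over the
  columns observed in both rows); rows sharing no observed column are
  ineligible;
* a neighbour must itself observe the column being imputed;
* the k nearest eligible neighbours contribute; distance ties are broken by
  row position;
* the imputed value is the arithmetic mean of the neighbours' scores,
  rounded half up to an integer and clamped to 0--10.

Both steps are also available as scikit-learn transformers
(:class:`KNNScoreImputer`, :class:`SymptomDichotomizer`) so they compose in
a :class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "knn_impute",
    "dichotomize",
    "prevalence",
    "KNNScoreImputer",
    "SymptomDichotomizer",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _impute_into(target: np.ndarray, donors: np.ndarray, k: int, exclude_self: bool) -> np.ndarray:
    """Fill NaNs in ``target`` rows using ``donors`` as the neighbour pool."""
    out = target.copy()
    n_donor = donors.shape[0]
    donor_obs = ~np.isnan(donors)
    for i in range(target.shape[0]):
        row = target[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"row {i} has no observed cells; cannot impute")
        obs_i = ~miss
        # squared differences over columns observed in both rows
        shared = donor_obs & obs_i
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, donors - row, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.where(shared, diff, 0.0).__pow__(2).sum(axis=1) / n_shared)
        dist = np.where(n_shared > 0, dist, np.inf)
        if exclude_self and i < n_donor:
            dist[i] = np.inf
        for j in np.where(miss)[0]:
            eligible = np.where(donor_obs[:, j] & np.isfinite(dist))[0]
            if eligible.size < k:
                raise ValueError(
                    f"column {j}: only {eligible.size} eligible neighbours, need k={k}"
                )
            # stable sort on distance -> ties broken by row position
            order = eligible[np.argsort(dist[eligible], kind="stable")]
            neigh = order[:k]
            out[i, j] = min(10, max(0, _round_half_up(float(np.mean(donors[neigh, j])))))
    return out


def knn_impute(dataset: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Replace missing scores by the rounded mean of the k nearest rows.

    Observed cells are never altered; a complete dataset is returned
    unchanged (imputation is the identity on complete data).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = dataset.to_numpy(dtype=float)
    filled = _impute_into(values, values, k, exclude_self=True)
    return pd.DataFrame(filled, index=dataset.index, columns=dataset.columns)


def dichotomize(dataset: pd.DataFrame, threshold: int = 4) -> pd.DataFrame:
    """Presence/absence at the clinically relevant cut-off (score >= threshold)."""
    if not 1 <= int(threshold) <= 10:
        raise ValueError("threshold must be an integer in 1-10")
    values = dataset.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("dataset has missing cells; run knn_impute first")
    return pd.DataFrame(
        (values >= threshold).astype(np.int8), index=dataset.index, columns=dataset.columns
    )


def prevalence(binary: pd.DataFrame) -> pd.Series:
    """Per-symptom proportion of patients with the symptom present."""
    if len(binary) == 0:
        raise ValueError("empty dataset")
    return binary.sum(axis=0) / len(binary)


class KNNScoreImputer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping :func:`knn_impute`.

    ``fit`` stores the donor rows; ``transform`` fills missing cells in new
    data using those donors.  ``fit_transform(X)`` performs within-dataset
    imputation (each row's own copy in the donor pool is excluded), which is
    the usual single-dataset usage.

    Parameters
    ----------
    k : int, default 5
        Number of nearest neighbours averaged per missing cell.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None):
        X = self._as_frame(X)
        self.donors_ = X.to_numpy(dtype=float)
        self.columns_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "donors_")
        X = self._as_frame(X)
        same = X.shape == tuple(self.donors_.shape) and np.array_equal(
            X.to_numpy(dtype=float), self.donors_, equal_nan=True
        )
        filled = _impute_into(
            X.to_numpy(dtype=float), self.donors_, self.k, exclude_self=same
        )
        return pd.DataFrame(filled, index=X.index, columns=X.columns)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))


class SymptomDichotomizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping :func:`dichotomize` (stateless)."""

    def __init__(self, threshold: int = 4):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = KNNScoreImputer._as_frame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return dichotomize(KNNScoreImputer._as_frame(X), self.threshold)
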