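"""Scikit-learn estimator interface to the Bayesian network model.

:class:`BayesianSymptomNetwork` bundles structure learning and parameter
learning behind the usual ``fit`` / ``predict_proba`` contract, so the
model composes with :mod:`sklearn.pipeline` and model-selection utilities.
``predict_proba(X)`` returns, for every row and every variable, the exact
conditional probability that the variable is present given the observed
values of all other variables — the prediction task the network is
evaluated on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .graph import DAG
from .inference import fit_cpts, predict_proba_all
from .scoring import aic_score
from .structure import algorithm_menu

__all__ = ["BayesianSymptomNetwork"]


class BayesianSymptomNetwork(BaseEstimator):
    """Discrete Bayesian network over binary symptom indicators.

    Parameters
    ----------
    algorithm : str, default "tabu"
        Structure learner; one of the nine names in
        :func:`symptombn.structure.algorithm_menu`. Ignored when ``dag`` is
        given.
    dag : DAG or None
        Fix the structure and perform parameter learning only.
    smoothing_alpha : float, default 1.0
        Additive smoothing for CPT estimation. The default keeps held-out
        predictions finite when a parent configuration is absent from the
        training fold; use 0 for plain empirical conditional frequencies.
    random_state : int, default 0
        Seed passed to the structure learner (only learners with restarts
        use it).

    Attributes
    ----------
    columns_ : list of str
        Variable names in canonical (column) order.
    dag_ : DAG
        The learned or fixed structure.
    network_ : DiscreteBayesianNetwork
        Structure plus fitted CPTs.
    score_ : float
        AIC (higher is better) of ``dag_`` on the training data.
    """

    def __init__(
        self,
        algorithm: str = "tabu",
        dag: DAG | None = None,
        smoothing_alpha: float = 1.0,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.dag = dag
        self.smoothing_alpha = smoothing_alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._as_frame(X)
        self.columns_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        if self.dag is not None:
            if set(self.dag.nodes) != set(self.columns_):
                raise ValueError("fixed DAG nodes do not match the data columns")
            self.dag_ = self.dag
        else:
            menu = algorithm_menu()
            if self.algorithm not in menu:
                raise ValueError(
                    f"unknown algorithm {self.algorithm!r}; choose from {sorted(menu)}"
                )
            self.dag_ = menu[self.algorithm](X, seed=self.random_state).dag
        self.network_ = fit_cpts(X, self.dag_, self.smoothing_alpha)
        self.score_ = aic_score(X, self.dag_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """P(variable present | all other variables), per row and variable."""
        check_is_fitted(self, "network_")
        X = self._as_frame(X)
        return predict_proba_all(self.network_, X[self.columns_])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(np.int8)

    def score(self, X, y=None) -> float:
        """Mean per-row joint log-likelihood of ``X`` under the fitted network."""
        check_is_fitted(self, "network_")
        X = self._as_frame(X)
        from .inference import enumerate_joint
        from .scoring import as_binary_matrix

        joint = enumerate_joint(self.network_)
        M = as_binary_matrix(X[self.columns_])
        code = np.zeros(len(M), dtype=np.int64)
        for i in range(M.shape[1]):
            code = (code << 1) | M[:, i]
        probs = joint.reshape(-1)[code]
        with np.errstate(divide="ignore"):
            return float(np.mean(np.log(probs)))

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        cols = getattr(self, "columns_", None) or [f"x{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=cols)
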