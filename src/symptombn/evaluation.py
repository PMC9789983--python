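"""Model selection and validation: cross-validated AIC, AUC, calibration.

The evaluation design mirrors a fourfold cross-validation study: the
learning algorithm is chosen by mean AIC across folds, the chosen model's
discrimination is summarised per symptom as the mean (and SD) of the
Mann-Whitney AUC over folds (>= 0.65 counted as satisfactory), and its
calibration is assessed by pooling held-out predictions, grouping each
symptom's patients into deciles of predicted probability and comparing the
decile's mean prediction with the observed frequency (a gap of more than 10
percentage points counts as inaccurate).  Edge-direction stability is
assessed by relearning the structure on bootstrap resamples and tallying
per-edge direction frequencies against a majority threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .inference import fit_cpts, predict_proba_all
from .scoring import aic_score, as_binary_matrix
from .structure import LearnedStructure, algorithm_menu

__all__ = [
    "kfold_split",
    "cv_algorithm_selection",
    "auc_roc",
    "cv_predictions",
    "symptom_auc_cv",
    "calibration",
    "calibration_from_predictions",
    "CalibrationResult",
    "EdgeDirectionVote",
    "bootstrap_edge_directions",
    "operating_thresholds",
]

AUC_SATISFACTORY = 0.65
CALIBRATION_TOLERANCE = 0.10


def _resolve_learner(learner):
    if callable(learner):
        return learner
    menu = algorithm_menu()
    if learner not in menu:
        raise ValueError(f"unknown learner {learner!r}; choose from {sorted(menu)}")
    return menu[learner]


def kfold_split(n_rows: int, k: int = 4, seed: int = 0) -> np.ndarray:
    """Fold index per row: seeded shuffle, then contiguous near-equal chunks."""
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    folds = np.empty(n_rows, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def cv_algorithm_selection(
    dataset: pd.DataFrame,
    registry: dict | None = None,
    k: int = 4,
    seed: int = 0,
    heldout: bool = False,
) -> pd.DataFrame:
    """Rank structure learners by mean AIC across cross-validation folds.

    Per fold each learner fits a structure on the training portion and the
    structure's AIC is computed on the same training data (the default), or
    — with ``heldout=True`` — the per-row held-out log-likelihood of the
    fold's fitted network is used instead.  Returns a DataFrame with one
    row per algorithm, fold columns, a ``mean`` column, sorted best first;
    the winner's name is in ``result.attrs['winner']``.  An algorithm that
    fails on any fold is excluded with a warning.
    """
    registry = registry or algorithm_menu()
    folds = kfold_split(len(dataset), k, seed)
    rows = {}
    for name, learner in registry.items():
        scores = []
        try:
            for f in range(k):
                train = dataset.iloc[folds != f]
                learned = learner(train, seed=seed)
                if heldout:
                    net = fit_cpts(train, learned.dag, smoothing_alpha=1.0)
                    test = dataset.iloc[folds == f]
                    scores.append(_mean_row_loglik(net, test))
                else:
                    scores.append(aic_score(train, learned.dag))
        except Exception as exc:  # noqa: BLE001 - a learner failure must not abort the ranking
            warnings.warn(f"algorithm {name!r} failed and is excluded: {exc}")
            continue
        rows[name] = scores
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"fold{f}" for f in range(k)]
    )
    table["mean"] = table.mean(axis=1)
    table = table.sort_values("mean", ascending=False, kind="stable")
    table.attrs["winner"] = table.index[0] if len(table) else None
    table.attrs["criterion"] = "heldout_loglik" if heldout else "train_aic"
    return table


def _mean_row_loglik(network, dataset) -> float:
    from .inference import enumerate_joint

    joint = enumerate_joint(network)
    M = as_binary_matrix(dataset[list(network.nodes)])
    code = np.zeros(len(M), dtype=np.int64)
    for i in range(M.shape[1]):
        code = (code << 1) | M[:, i]
    return float(np.mean(np.log(joint.reshape(-1)[code])))


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


def auc_roc(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute 1/2.

    Returns NaN with a warning when the labels contain a single class.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("AUC undefined: labels contain a single class")
        return float("nan")
    ranks = rankdata(predicted)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def cv_predictions(
    dataset: pd.DataFrame,
    learner="tabu",
    k: int = 4,
    seed: int = 0,
    smoothing_alpha: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out predictions for every row and symptom across k folds.

    Per fold: learn a structure and fit (smoothed) CPTs on the training
    rows, then predict each held-out row's symptoms from its other ten.
    Returns ``(predictions, fold_of_row)`` with predictions aligned to the
    input row order.
    """
    learner = _resolve_learner(learner)
    folds = kfold_split(len(dataset), k, seed)
    pred = np.full(dataset.shape, np.nan)
    for f in range(k):
        train = dataset.iloc[folds != f]
        learned = learner(train, seed=seed)
        net = fit_cpts(train, learned.dag, smoothing_alpha=smoothing_alpha)
        test_mask = folds == f
        pred[test_mask] = predict_proba_all(net, dataset.iloc[test_mask])
    return pred, folds


def symptom_auc_cv(
    dataset: pd.DataFrame,
    learner="tabu",
    k: int = 4,
    seed: int = 0,
    smoothing_alpha: float = 1.0,
) -> pd.DataFrame:
    """Per-symptom cross-validated AUC summary.

    One row per symptom with the mean and sample SD of the per-fold AUCs
    and a ``satisfactory`` flag (mean >= 0.65).
    """
    pred, folds = cv_predictions(dataset, learner, k, seed, smoothing_alpha)
    y = as_binary_matrix(dataset)
    rows = []
    for j, name in enumerate(dataset.columns):
        per_fold = []
        for f in range(k):
            m = folds == f
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_fold.append(auc_roc(pred[m, j], y[m, j]))
        per_fold = np.asarray(per_fold)
        valid = per_fold[~np.isnan(per_fold)]
        mean = float(valid.mean()) if valid.size else float("nan")
        sd = float(valid.std(ddof=1)) if valid.size > 1 else float("nan")
        rows.append(
            {
                "symptom": name,
                "mean_auc": mean,
                "sd_auc": sd,
                "n_folds": int(valid.size),
                "satisfactory": bool(mean >= AUC_SATISFACTORY) if valid.size else False,
            }
        )
    return pd.DataFrame(rows).set_index("symptom")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Decile calibration tables (one DataFrame per symptom) plus the
    overall accurate/total count across all symptoms."""

    tables: dict[str, pd.DataFrame]
    n_accurate: int
    n_total: int
    constant_prediction: list[str]


def calibration_from_predictions(
    predicted: np.ndarray, observed: pd.DataFrame, n_bins: int = 10
) -> CalibrationResult:
    """Group each symptom's rows into deciles of predicted probability.

    Rows are stably sorted by prediction (row order breaks ties) and split
    into ``n_bins`` near-equal bins; a bin is accurate when the absolute
    difference between its mean predicted probability and observed
    frequency is at most 0.10.
    """
    y = as_binary_matrix(observed)
    n = len(y)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} rows, got {n}")
    predicted = np.asarray(predicted, dtype=float)
    tables = {}
    constant = []
    n_acc = n_tot = 0
    for j, name in enumerate(observed.columns):
        p = predicted[:, j]
        if np.all(p == p[0]):
            constant.append(name)
        order = np.argsort(p, kind="stable")
        recs = []
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            mean_p = float(p[chunk].mean())
            obs = float(y[chunk, j].mean())
            acc = abs(mean_p - obs) <= CALIBRATION_TOLERANCE
            recs.append(
                {
                    "decile": b + 1,
                    "n": len(chunk),
                    "mean_predicted": mean_p,
                    "observed": obs,
                    "accurate": acc,
                }
            )
            n_acc += acc
            n_tot += 1
        tables[name] = pd.DataFrame(recs).set_index("decile")
    return CalibrationResult(tables, int(n_acc), int(n_tot), constant)


def calibration(
    dataset: pd.DataFrame,
    learner="tabu",
    k: int = 4,
    seed: int = 0,
    smoothing_alpha: float = 1.0,
    n_bins: int = 10,
) -> CalibrationResult:
    """Cross-validated decile calibration (held-out predictions pooled over folds)."""
    pred, _ = cv_predictions(dataset, learner, k, seed, smoothing_alpha)
    return calibration_from_predictions(pred, dataset, n_bins)


# ---------------------------------------------------------------------------
# edge-direction stability
# ---------------------------------------------------------------------------


@dataclass
class EdgeDirectionVote:
    """Bootstrap direction tally for one undirected adjacency.

    ``edge`` is the canonical (lower, higher) node pair; the fractions are
    the share of bootstrap networks containing each direction; ``resolved``
    is the winning directed edge, or None below the majority threshold.
    """

    edge: tuple[str, str]
    forward_fraction: float
    reverse_fraction: float
    resolved: tuple[str, str] | None


def bootstrap_edge_directions(
    dataset: pd.DataFrame,
    learner="tabu",
    n_boot: int = 10_000,
    majority: float = 0.51,
    seed: int = 0,
) -> list[EdgeDirectionVote]:
    """Tally per-edge direction frequencies over bootstrap resamples.

    Rows are resampled with replacement, the structure relearned per
    replicate, and an adjacency's direction is resolved when one direction
    appears in at least ``majority`` of the replicates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.5 < majority <= 1.0:
        raise ValueError("majority must lie in (0.5, 1]")
    learner = _resolve_learner(learner)
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    cols = list(dataset.columns)
    pos = {c: i for i, c in enumerate(cols)}
    for b in range(n_boot):
        idx = rng.integers(0, len(dataset), size=len(dataset))
        learned: LearnedStructure = learner(dataset.iloc[idx], seed=int(rng.integers(2**31)))
        for u, v in learned.dag.edges:
            counts[(u, v)] = counts.get((u, v), 0) + 1
    pairs = sorted(
        {tuple(sorted(e, key=pos.get)) for e in counts}, key=lambda e: (pos[e[0]], pos[e[1]])
    )
    votes = []
    for a, b in pairs:
        fwd = counts.get((a, b), 0) / n_boot
        rev = counts.get((b, a), 0) / n_boot
        if fwd >= majority:
            resolved = (a, b)
        elif rev >= majority:
            resolved = (b, a)
        else:
            resolved = None
        votes.append(EdgeDirectionVote((a, b), fwd, rev, resolved))
    return votes


# ---------------------------------------------------------------------------
# operating thresholds
# ---------------------------------------------------------------------------


def operating_thresholds(
    predicted: np.ndarray,
    labels: np.ndarray,
    min_sensitivity: float = 0.9,
    min_specificity: float = 0.9,
) -> dict:
    """Two probability cut-offs from the empirical ROC.

    A row is flagged positive when its predicted probability is at least
    the cut-off.  Returns the lowest cut-off whose specificity meets
    ``min_specificity`` (the limited-time setting: few false positives) and
    the highest cut-off whose sensitivity meets ``min_sensitivity`` (the
    sufficient-time setting: few false negatives); an unattainable
    constraint is reported as None.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    out = {"high_specificity": None, "high_sensitivity": None}
    for t in np.unique(predicted):
        flag = predicted >= t
        sens = float(flag[labels == 1].sum() / n1)
        spec = float((~flag)[labels == 0].sum() / n0)
        if out["high_specificity"] is None and spec >= min_specificity:
            out["high_specificity"] = {"threshold": float(t), "sensitivity": sens, "specificity": spec}
        if sens >= min_sensitivity:
            out["high_sensitivity"] = {"threshold": float(t), "sensitivity": sens, "specificity": spec}
    return out
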