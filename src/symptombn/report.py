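"""Human-readable reports and the end-to-end pipeline.

Probabilities live as proportions everywhere else in the package;
rendering as percentages (one decimal, ties rounded half away from zero)
happens only here.
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, preprocessing, synthetic
from .graph import DiscreteBayesianNetwork
from .inference import fit_cpts, query
from .structure import algorithm_menu

__all__ = ["format_percent", "cpt_report", "flowchart", "run_pipeline"]


def format_percent(p: float) -> float:
    """Proportion -> percentage with one decimal, half away from zero."""
    return float(Decimal(repr(float(p) * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cpt_report(network: DiscreteBayesianNetwork) -> pd.DataFrame:
    """One row per node per parent configuration, formatted as percentages.

    Parent nodes are labelled main symptoms and the child the simultaneous
    symptom, mirroring the convention that volunteered symptoms predict the
    ones worth asking about.
    """
    rows = []
    for node in network.nodes:
        cpt = network.cpts[node]
        k = len(cpt.parents)
        for r in range(2**k - 1, -1, -1):  # (+,..,+) first
            bits = [(r >> (k - 1 - i)) & 1 for i in range(k)]
            rows.append(
                {
                    "main_symptoms": "; ".join(
                        f"{p}{'+' if b else '-'}" for p, b in zip(cpt.parents, bits)
                    ),
                    "simultaneous_symptom": node,
                    "probability_pct": format_percent(float(cpt.table[r])),
                }
            )
    return pd.DataFrame(rows)


def flowchart(network: DiscreteBayesianNetwork, start: str | None = None) -> dict:
    """Flow-chart data: a start symptom and, per child, the probability of
    the child given the start symptom present and given it absent.

    The default start is the node with the most children (ties broken by
    canonical order) — the natural hub to open a consultation with.
    """
    if start is None:
        start = max(network.nodes, key=lambda n: len(network.dag.children(n)))
    elif start not in network.nodes:
        raise ValueError(f"unknown start node {start!r}")
    children = network.dag.children(start)
    chart = {"start": start, "children": [], "note": None}
    if not children:
        chart["note"] = f"{start!r} has no children; nothing to predict from it"
        return chart
    for child in children:
        chart["children"].append(
            {
                "symptom": child,
                "p_if_present_pct": format_percent(query(network, child, {start: 1}).probability),
                "p_if_absent_pct": format_percent(query(network, child, {start: 0}).probability),
            }
        )
    return chart


_DEFAULT_CONFIG = {
    "seed": 0,
    "input": None,  # CSV of 0-10 scores; None -> synthetic generation
    "synthetic": {},  # GeneratorConfig overrides
    "k_neighbors": 5,
    "threshold": 4,
    "cv_folds": 4,
    "algorithm": "tabu",  # or "auto" -> cross-validated AIC winner
    "bootstrap_replicates": 0,
    "plots": True,
    "output_dir": "symptombn_out",
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis and write the artifact bundle.

    Stages: load or generate scores -> impute -> dichotomize ->
    cross-validated algorithm ranking -> learn on the full data -> fit CPTs
    -> CPT report, flow-chart, AUC table, calibration tables (and plots),
    optional bootstrap edge directions.  Returns a manifest of written
    files; reruns with the same config are deterministic.
    """
    cfg = {**_DEFAULT_CONFIG, **(config or {})}
    out = Path(cfg["output_dir"])
    seed = int(cfg["seed"])
    log: list[str] = [f"config_hash={_config_hash(cfg)}", f"seed={seed}"]

    if cfg["input"] is not None:
        path = Path(cfg["input"])
        if not path.exists():
            raise FileNotFoundError(f"stage load: input CSV not found: {path}")
        scores = pd.read_csv(path)
    else:
        gen = synthetic.GeneratorConfig(seed=seed, **cfg["synthetic"])
        scores = synthetic.generate_dataset(gen)
    log.append(f"rows={len(scores)} columns={scores.shape[1]}")

    out.mkdir(parents=True, exist_ok=True)
    n_missing = int(scores.isna().sum().sum())
    log.append(f"missing_cells={n_missing}")
    if n_missing:
        scores = preprocessing.knn_impute(scores, k=int(cfg["k_neighbors"]))
        log.append(f"imputed_cells={n_missing} (k={cfg['k_neighbors']})")
    binary = preprocessing.dichotomize(scores, threshold=int(cfg["threshold"]))
    binary.to_csv(out / "binary.csv", index=False)

    ranking = evaluation.cv_algorithm_selection(binary, k=int(cfg["cv_folds"]), seed=seed)
    ranking.to_csv(out / "aic_ranking.csv")
    winner = ranking.attrs["winner"]
    algorithm = winner if cfg["algorithm"] == "auto" else cfg["algorithm"]
    log.append(f"cv_winner={winner} algorithm_used={algorithm}")

    learned = algorithm_menu()[algorithm](binary, seed=seed)
    network = fit_cpts(binary, learned.dag, smoothing_alpha=0.0)
    (out / "network.json").write_text(network.to_json())
    (out / "dag.dot").write_text(learned.dag.to_dot())
    cpt_report(network).to_csv(out / "cpt_report.csv", index=False)
    (out / "flowchart.json").write_text(json.dumps(flowchart(network), indent=2))

    auc = evaluation.symptom_auc_cv(binary, algorithm, k=int(cfg["cv_folds"]), seed=seed)
    auc.to_csv(out / "auc_table.csv")
    calib = evaluation.calibration(binary, algorithm, k=int(cfg["cv_folds"]), seed=seed)
    calib_dir = out / "calibration"
    calib_dir.mkdir(exist_ok=True)
    for symptom, table in calib.tables.items():
        slug = symptom.replace(" ", "_")
        table.to_csv(calib_dir / f"{slug}.csv")
        if cfg["plots"]:
            _calibration_plot(symptom, table, calib_dir / f"{slug}.png")
    log.append(f"calibration_accurate={calib.n_accurate}/{calib.n_total}")
    if calib.constant_prediction:
        log.append(f"warning: constant predictions for {calib.constant_prediction}")

    if int(cfg["bootstrap_replicates"]) > 0:
        votes = evaluation.bootstrap_edge_directions(
            binary, algorithm, n_boot=int(cfg["bootstrap_replicates"]), seed=seed
        )
        pd.DataFrame(
            [
                {
                    "edge": f"{a}--{b}",
                    "forward_fraction": v.forward_fraction,
                    "reverse_fraction": v.reverse_fraction,
                    "resolved": "->".join(v.resolved) if v.resolved else "unresolved",
                }
                for v in votes
                for a, b in [v.edge]
            ]
        ).to_csv(out / "edge_directions.csv", index=False)

    (out / "log.txt").write_text("\n".join(log) + "\n")
    manifest = {p.name: str(p) for p in sorted(out.iterdir())}
    return manifest


def _calibration_plot(symptom: str, table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], color="black", lw=1, label="ideal")
    ax.plot(table["mean_predicted"], table["observed"], "o-", ms=4, label="model")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed frequency")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title(symptom)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
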