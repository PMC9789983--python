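"""Synthetic symptom data with the statistical structure the analysis assumes.

The reference network encodes eleven dichotomized symptoms with the parent
sets and conditional probabilities of a published palliative-care symptom
network; ancestral sampling from it yields presence/absence matrices whose
marginal and conditional frequencies converge to the generating tables.
``expand_to_nrs`` turns presence/absence into 0--10 numeric-rating-scale
scores using disjoint ranges on either side of the clinical cut-off (>= 4),
so dichotomizing the expanded scores recovers the binary data exactly, and
``inject_missing`` reproduces the sparse item non-response pattern of the
emulated survey (26 of 532 questionnaires with 1--3 missing scores, 36
missing cells in total), completely at random.

Datasets are plain pandas DataFrames: binary data as int8 0/1, score data
as float with NaN marking missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import CPT, DAG, DiscreteBayesianNetwork, parent_config_index, topological_order
from .labels import SYMPTOMS, canonical_index

__all__ = [
    "GeneratorConfig",
    "reference_network",
    "sample_binary",
    "expand_to_nrs",
    "inject_missing",
    "generate_dataset",
]


# Reference parameterisation: child -> (parents as printed, P(child present)
# for parent configurations (+,+), (+,-), (-,+), (-,-); a root lists the
# single marginal).
_REFERENCE_TABLES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "pain": (("fatigue", "sleeping problems"), (0.544, 0.376, 0.400, 0.138)),
    "sleeping problems": (("fatigue", "anxiety"), (0.635, 0.414, 0.563, 0.183)),
    "dry mouth": (("fatigue", "sleeping problems"), (0.627, 0.478, 0.450, 0.228)),
    "dysphagia": (("dry mouth", "nausea"), (0.542, 0.330, 0.313, 0.058)),
    "lack of appetite": (("fatigue", "dysphagia"), (0.800, 0.564, 0.810, 0.244)),
    "constipation": (("dysphagia", "lack of appetite"), (0.787, 0.500, 0.568, 0.339)),
    "nausea": (("fatigue", "depressed mood"), (0.301, 0.095, 0.040, 0.013)),
    "shortness of breath": (("fatigue", "dry mouth"), (0.361, 0.160, 0.059, 0.022)),
    "fatigue": ((), (0.647,)),
    "anxiety": (("fatigue",), (0.331, 0.086)),
    "depressed mood": (("anxiety", "dry mouth"), (0.789, 0.764, 0.229, 0.089)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults for the synthetic survey generator.

    The defaults emulate the survey the analysis was designed for: 532
    returned questionnaires, presence meaning a numeric score of 4--10 and
    absence 0--3, and 36 missing cells spread over 26 questionnaires as
    18 rows with one, 6 with two and 2 with three missing scores.
    """

    n_patients: int = 532
    seed: int = 0
    nrs_present_range: tuple[int, int] = (4, 10)
    nrs_absent_range: tuple[int, int] = (0, 3)
    missing_rows: int = 26
    missing_cells_total: int = 36
    missing_composition: tuple[int, int, int] | None = field(default=None)
    dichotomize_threshold: int = 4

    def __post_init__(self):
        lo_a, hi_a = self.nrs_absent_range
        lo_p, hi_p = self.nrs_present_range
        if not (0 <= lo_a <= hi_a <= 10 and 0 <= lo_p <= hi_p <= 10):
            raise ValueError("NRS ranges must lie within 0-10")
        if not (hi_a < self.dichotomize_threshold <= lo_p):
            raise ValueError(
                "NRS ranges overlap the dichotomization threshold: absent must stay "
                f"below {self.dichotomize_threshold}, present at or above it"
            )
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        comp = self.resolved_composition()
        if sum(comp) != self.missing_rows or sum((i + 1) * c for i, c in enumerate(comp)) != self.missing_cells_total:
            raise ValueError(
                f"missing composition {comp} inconsistent with missing_rows="
                f"{self.missing_rows}, missing_cells_total={self.missing_cells_total}"
            )

    def resolved_composition(self) -> tuple[int, int, int]:
        """Rows with exactly 1, 2 and 3 missing cells.

        The study-scale default (26 rows, 36 cells) uses 18/6/2. For other
        counts, if no composition is given, a deterministic rule minimises
        the number of three-cell rows.
        """
        if self.missing_composition is not None:
            return self.missing_composition
        if (self.missing_rows, self.missing_cells_total) == (26, 36):
            return (18, 6, 2)
        extra = self.missing_cells_total - self.missing_rows
        if extra < 0 or extra > 2 * self.missing_rows:
            raise ValueError("missing_cells_total not achievable with 1-3 cells per row")
        c3 = max(0, extra - self.missing_rows)
        c2 = extra - 2 * c3
        c1 = self.missing_rows - c2 - c3
        return (c1, c2, c3)


def _canonical_cpt(child: str, parents: tuple[str, ...], probs: tuple[float, ...]) -> CPT:
    """Build a CPT with parents re-sorted into canonical symptom order."""
    k = len(parents)
    stated = np.empty(2**k)
    # probs are listed (+..+) first, descending by the stated-order config bits
    for pos, idx in enumerate(range(2**k - 1, -1, -1)):
        stated[idx] = probs[pos]
    order = sorted(range(k), key=lambda i: canonical_index(parents[i]))
    new_parents = tuple(parents[i] for i in order)
    table = np.empty(2**k)
    for idx in range(2**k):
        bits_new = [(idx >> (k - 1 - j)) & 1 for j in range(k)]
        stated_bits = [bits_new[order.index(i)] for i in range(k)]
        table[idx] = stated[parent_config_index(stated_bits)]
    return CPT(child, new_parents, table)


def reference_network() -> DiscreteBayesianNetwork:
    """The eleven-symptom reference Bayesian network.

    Fatigue is the single root (marginal presence 0.647) and a direct parent
    of seven other symptoms; the DAG has 19 edges in total.
    """
    edges = []
    cpts = {}
    for child, (parents, probs) in _REFERENCE_TABLES.items():
        cpts[child] = _canonical_cpt(child, parents, probs)
        edges.extend((p, child) for p in parents)
    dag = DAG(SYMPTOMS, edges)
    return DiscreteBayesianNetwork(dag, cpts)


def sample_binary(network: DiscreteBayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` presence/absence rows by ancestral sampling.

    Nodes are visited in topological order and each is sampled from its CPT
    given the already-sampled parent values; fully reproducible for a fixed
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in topological_order(network.dag):
        cpt = network.cpts[node]
        if cpt.parents:
            code = np.zeros(n, dtype=np.int64)
            for p in cpt.parents:
                code = (code << 1) | cols[p]
            probs = cpt.table[code]
        else:
            probs = np.full(n, cpt.table[0])
        cols[node] = (rng.random(n) < probs).astype(np.int8)
    return pd.DataFrame({node: cols[node] for node in network.nodes})


def expand_to_nrs(
    binary: pd.DataFrame, config: GeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Expand presence/absence to integer 0--10 scores.

    Present cells draw uniformly from ``config.nrs_present_range``, absent
    cells from ``config.nrs_absent_range``; because the two ranges sit on
    opposite sides of the dichotomization threshold, thresholding the output
    recovers the input exactly.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    values = binary.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("expand_to_nrs expects a 0/1 presence matrix")
    lo_p, hi_p = config.nrs_present_range
    lo_a, hi_a = config.nrs_absent_range
    present = rng.integers(lo_p, hi_p + 1, size=values.shape)
    absent = rng.integers(lo_a, hi_a + 1, size=values.shape)
    scores = np.where(values == 1, present, absent).astype(float)
    return pd.DataFrame(scores, index=binary.index, columns=binary.columns)


def inject_missing(
    dataset: pd.DataFrame, config: GeneratorConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Blank cells completely at random following the configured pattern.

    Exactly ``missing_rows`` distinct rows are affected, each losing 1--3
    cells per the resolved composition, ``missing_cells_total`` cells in all.
    """
    config = config or GeneratorConfig()
    if dataset.isna().any().any():
        raise ValueError("inject_missing expects a complete dataset")
    if config.missing_rows == 0:
        return dataset.copy()
    n, d = dataset.shape
    if n < config.missing_rows:
        raise ValueError(f"dataset has {n} rows, fewer than missing_rows={config.missing_rows}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = rng.choice(n, size=config.missing_rows, replace=False)
    counts = np.repeat([1, 2, 3], config.resolved_composition())
    rng.shuffle(counts)
    out = dataset.copy().astype(float)
    for row, c in zip(rows, counts):
        cols = rng.choice(d, size=c, replace=False)
        out.iloc[row, cols] = np.nan
    return out


def generate_dataset(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Full generator: ancestral sample -> NRS scores -> injected missingness.

    Sub-seeds for the three stages are derived from ``config.seed`` so a
    single integer reproduces the whole dataset.
    """
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    binary = sample_binary(reference_network(), config.n_patients, seeds[0])
    scores = expand_to_nrs(binary, config, seeds[1])
    return inject_missing(scores, config, seeds[2])
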