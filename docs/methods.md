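# Methods

## Model

The package models eleven dichotomized symptom indicators (present =
score ≥ 4 on a 0–10 numeric rating scale) as a discrete Bayesian network:
a directed acyclic graph (DAG) plus one conditional probability table
(CPT) per node. Variables are binary throughout; CPTs store only
P(child = present | parent configuration), with the absent probability
taken by complement, so normalisation is exact by construction. Parent
configurations are indexed by reading parent values as binary digits with
the first parent most significant.

The canonical variable order is the symptom-diary listing order (pain,
sleeping problems, dry mouth, dysphagia, lack of appetite, constipation,
nausea, shortness of breath, fatigue, anxiety, depressed mood). Every
tie-break in the package — topological sorting, search move enumeration,
DAG extension, report row order — refers to this order, which is what
makes reruns bit-identical.

## Reference network and synthetic data

`reference_network()` encodes a published eleven-symptom network: 19
edges, fatigue the only root (marginal presence 0.647) and a direct parent
of seven symptoms. Its CPT entries are transcribed as proportions from the
published conditional-probability table. One published inconsistency is
worth noting: the running text gives 79.8% for depressed mood given
anxiety with dry mouth where the table prints 78.9; the table is treated
as authoritative and 0.789 is used.

The generator emulates the survey the analysis was designed around:

* **n = 532 patients** (the returned-questionnaire count), sampled
  ancestrally: nodes visited in topological order, each drawn from its CPT
  given already-sampled parents.
* **Score expansion**: present cells draw uniformly from 4–10, absent
  cells from 0–3. The two ranges sit on opposite sides of the clinical
  cut-off, so dichotomization inverts the expansion exactly; real 0–10
  score distributions are not uniform, but no published raw-score
  distribution exists to calibrate against, and the disjoint-uniform
  choice makes the imputation round-trip deterministic in expectation.
* **Missingness**: 26 rows with 1–3 missing cells, 36 cells total,
  completely at random (the survey reports only counts, not a mechanism).
  The default composition is 18 rows × 1 + 6 × 2 + 2 × 3; for other
  row/cell counts a deterministic rule minimises the number of three-cell
  rows. Rows and columns are chosen uniformly under the seed.

What passing tests on these data do **not** show: robustness to
informative missingness, to non-uniform score distributions near the
cut-off, or to dependencies outside the model family (the synthetic joint
distribution is exactly representable by the generating DAG, which is why
synthetic AUCs run higher than AUCs on real survey data).

## Preprocessing conventions

k-nearest-neighbour imputation (k = 5 by default) is specified only
loosely in the applied literature, so the package fixes conventions:

* distance between rows = √(mean of squared differences over the columns
  observed in both rows); rows sharing no observed column are ineligible;
* a neighbour must itself observe the column being imputed;
* distance ties break by row position;
* the imputed value is the neighbour mean, rounded half up to an integer
  and clamped to 0–10.

Imputation happens on raw 0–10 scores *before* dichotomization. Observed
cells are never altered and complete data pass through unchanged.

## Scores and structure search

Scores are decomposable and higher-is-better: log-likelihood, AIC
(log L − #parameters, one parameter per CPT row), and BIC
(log L − (log n)/2 per parameter). The textbook −2 log L + 2p form of AIC
is −2 × the value used here; rankings are identical.

Score-based search starts from the empty graph and applies single-edge
additions, deletions and reversals, with reachability checks guarding
acyclicity. Hill climbing accepts only strictly improving moves; Tabu
search (list length 10 by default) accepts the best non-tabu move at a
local optimum, returns the best structure ever visited, and stops after 15
non-improving iterations. Random restarts perturb the incumbent with
seeded random edge flips. Ties between equal-scoring moves go to the
earliest candidate in canonical edge order, so results are reproducible;
seeds affect only restart perturbations.

A practical property of AIC worth knowing: its penalty of one
log-likelihood unit per parameter is weak relative to max-selection over
~100 candidate moves, so on large samples the AIC search typically keeps
all true adjacencies *plus* a few noise edges whose chance G² exceeded the
penalty (the denser graph genuinely scores higher AIC). The BIC-scored
search recovers the generating Markov equivalence class exactly at
n = 50,000. The test suite checks both behaviours.

Constraint-based learning uses the G² conditional-independence test
(degrees of freedom reduced for strata with zero margins) at α = 0.05 by
default, with conditioning sets capped at size 3 — at eleven nodes and
survey-scale n, larger sets leave strata too sparse to test. PC-stable
freezes adjacency sets per level, making the skeleton order-independent.
Markov-blanket learners (grow–shrink, IAMB, interleaved IAMB) symmetrise
blankets with the AND rule and refine them to neighbourhoods by subset
search. All constraint-based outputs are completed to a DAG: v-structures
are oriented first (conflicting or cycle-closing colliders are skipped in
canonical order), then a Dor–Tarsi consistent extension orients the rest;
if the partially directed graph admits no consistent extension, remaining
edges are oriented along the canonical order with a cycle guard. A DAG
rather than an equivalence class is returned because parameter learning
and reporting need one; the chosen member is deterministic.

Hybrid learners restrict the score search to the constraint-discovered
skeleton (MMHC-style with hill climbing, and a skeleton-restricted Tabu).

## Parameter learning and inference

CPT entries are (n(child = 1, pa) + α) / (n(pa) + 2α). Within
cross-validated evaluation α defaults to 1 (Laplace), so held-out rows
with parent configurations unseen in the training fold get finite,
non-degenerate predictions; for reporting on full data α defaults to 0
(empirical conditional frequencies), with never-observed configurations
set to 0.5 and flagged in diagnostics.

Queries are exact. Variable elimination sums out non-evidence, non-target
variables in reverse topological order — at eleven binary nodes any order
is fast, determinism is the point — and is verified in tests against
brute-force enumeration of the 2048-state joint (guarded at 20 nodes).
Batch prediction of every symptom from the other ten uses the enumerated
joint directly (numerator/denominator lookup per row), which is
mathematically identical to per-row elimination and is tested as such.
Evidence with probability zero raises for single queries; during
evaluation it falls back to the target's marginal with a logged warning so
one degenerate row cannot abort a fold.

## Evaluation choices

* **Folds**: seeded shuffle, then contiguous near-equal chunks; k = 4. Not
  stratified.
* **Algorithm selection**: AIC per fold is computed on the training
  portion by default; a `heldout=True` switch scores mean held-out per-row
  log-likelihood instead. Both are legitimate readings of "per-fold AIC";
  neither is asserted as canonical.
* **AUC**: Mann–Whitney rank form, ties at 1/2; SD across folds is the
  sample SD (ddof = 1). Undefined (single-class) folds are dropped with a
  warning. The satisfactory threshold is 0.65.
* **Calibration**: held-out predictions pooled across folds; per symptom,
  rows are stably sorted by predicted probability (row order breaks ties)
  and split into ten near-equal bins, so bin sizes differ by at most one
  and bin means are non-decreasing. The 10% rule is read as 10 percentage
  points of absolute probability. Constant-prediction symptoms keep ten
  bins by stable row order and are flagged.
* **Edge directions**: rows resampled with replacement, structure
  relearned per replicate, per-direction fractions tallied; a direction
  wins at the 0.51 majority by default. The reference workflow uses 10,000
  replicates; tests use 20–100 to stay desk-scale.
* **Operating thresholds**: from the empirical ROC, the lowest cut-off
  meeting a specificity floor (limited-time setting) and the highest
  cut-off meeting a sensitivity floor (sufficient-time setting).

## Problem sizes in the test suite

The suite exercises convergence claims at the largest sizes that keep a
single-CPU run comfortable: CPT-recovery and MLE checks at 500,000
sampled rows; skeleton/equivalence-class recovery over ten seeds at 50,000
rows; true-model calibration at 50,000 rows; cross-validated evaluation at
500–3,000 rows; 1,000 randomised elimination-vs-enumeration queries.

## Known limitations

* Binary variables only; ordinal severity categories (mild/moderate/
  severe) and continuous or hybrid networks are out of scope.
* No prior-knowledge constraints (whitelists/blacklists) in structure
  learning.
* Single imputation; no propagation of imputation uncertainty.
* Synthetic validation bounds what can be claimed about real survey data
  (see above); external validation requires a second dataset.
* Edge directions from observational data identify only the Markov
  equivalence class; directions beyond v-structures are a deterministic
  convention, and the bootstrap vote quantifies their stability, not their
  causal truth.
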