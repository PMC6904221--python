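# Methods

This note records, in the package's own words, the methods implemented in
`phenostrat` and the numerical conventions they follow. Module names in
parentheses point at the implementation.

## Synthetic cohort generator (`synthetic_cohort`)

All downstream methods are exercised on a synthetic diabetes cohort with
planted ground truth. `generate_cohort(CohortConfig(...))` produces:

- **Patients.** `n_patients` patients with sex, birth date (by decade),
  diabetes type and onset date, assigned round-robin to `k_clusters`
  planted phenotype clusters so cluster sizes are balanced.
- **Diagnosis profiles.** Each cluster owns a disjoint set of profile
  ICD-10 codes drawn at elevated rates for its members, on top of a
  shared background code pool drawn at low rates for everyone. Every
  patient also carries a primary diabetes code (E10/E109/E11/E119),
  which the vectorizer later excludes.
- **Notes.** Per patient, dated notes are built from sentence templates
  around dictionary terms. Controlled fractions of mentions are negated
  ("no sign of X"), attributed to a relative ("the patient's mother had
  X"), or corrupted with a single-character substitution typo. The term
  pool is constructed so that (i) any two distinct terms are at
  Levenshtein distance ≥ 3 from each other and (ii) every term is at
  distance ≥ 2 from every template/cue word. This guarantees that exact
  matching is unambiguous and that a single-substitution typo has a
  unique dictionary term within edit distance 1 — the generator makes
  exact NER *possible*, and the truth inventory
  (`cohort.truth.mentions`) makes it *checkable*.
- **HbA1c series.** `hba1c_points_per_patient` measurements per patient
  in mmol/mol with Gaussian noise (SD 2 by default). A configurable
  fraction of patients receives a planted level shift
  (`hba1c_shift`, default 15 mmol/mol) at a recorded change-point index;
  the rest are flat. Baseline levels and slopes vary by patient so the
  mixed onset model has real between-patient structure.
- **Labs and prescriptions.** A panel of `n_lab_tests` numeric tests
  (some with planted cluster shifts, some pure noise, one deliberately
  log-normal) and ATC-coded prescriptions where each cluster has one
  enriched ATC level-3 class (`cohort.truth.cluster_atc`).
- **Truth object.** Cluster labels, profile codes per cluster, the full
  mention inventory with negation flags, change-point indices
  (`None` for flat patients), and the dysregulated patient set.

Generation is fully deterministic given `seed`; `write_cohort` writes
byte-stable TSV/JSONL files so file-based and in-memory pipeline runs
agree exactly.

## Dictionary NER (`dictionary_ner`)

Tagging is dictionary lookup, not statistical NER:

- **Normalization.** Notes are lowercased; tokens are alphanumeric runs.
  Sentences are split on `.`, `;`, `!`, `?`.
- **Matching.** Multi-word dictionary terms are matched
  longest-match-first over token n-grams, so "type 1 diabetes" wins over
  "diabetes". Each matched span yields the code(s) mapped to that term;
  duplicate (term, code) hits in one note collapse to one mention per
  date, but one term mapping to two codes yields two mentions.
- **Fuzzy matching.** A token with no exact hit is compared against the
  index by Levenshtein distance with `max_edits = 1` (configurable to
  0). Exact matches are always preferred; tokens of length ≤ 3 are never
  fuzzy-matched (too many accidental neighbours); distance computation
  is banded and caps early at `max_edits + 1`.
- **Negation and subject.** A mention is flagged negated when a negation
  cue ("no", "not", "without", "denies", "no sign of", …) occurs within
  a 5-token window before the match *within the same sentence*; sentence
  boundaries reset the window. Family/subject cues ("mother", "father",
  "sister", …) in the window likewise suppress the mention from the
  event stream. Negated mentions are reported in the mention table but
  excluded from mined events.
- **Output.** `tag_corpus` returns the full mention table (with
  character offsets and flags) and the mined event stream
  (patient, date, code, `source = "notes"`), ready to concatenate with
  assigned diagnoses.

## BM25 phenotype vectors (`phenotype_vectors`)

Per-patient code lists are all dated code events (assigned + mined) with
the uncomplicated primary diabetes codes E10, E109, E11, E119 removed
*before* any corpus statistic is computed. For patient *p* and code *c*
with in-list frequency *f*:

```
score(c, p) = IDF(c) · f · (k1 + 1) / (f + k1 · (1 − b + b · |p| / |p_ave|))
IDF(c)      = ln( (N − n(c) + 0.5) / (n(c) + 0.5) )
```

with `b = 0.75`, `k1 = 1.2`, natural logarithm, `N` the number of
patients with a non-empty code list, `n(c)` the number of patients
carrying *c*, `|p|` the patient's code-list length and `|p_ave|` the
corpus mean length. Consequences worth stating explicitly:

- IDF is **zero** when exactly half the corpus carries the code and
  **negative** for codes carried by more than half — ubiquitous codes
  actively push patients together rather than apart. This is deliberate
  and is asserted in tests.
- The term-frequency factor saturates at `IDF · (k1 + 1)` as `f → ∞`.
- Patients whose entire code list was excluded end up with empty vectors
  and are reported separately rather than silently dropped.

The vectorized implementation (sparse matrix algebra) is tested for
`< 1e-10` agreement with a naive per-entry loop over random corpora.

## Patient network and MCL clustering (`patient_clustering`)

Cosine similarity is computed between BM25 vectors; zero vectors have
undefined cosine and become isolated nodes. Pairs with similarity
`s ≥ 0.5` (inclusive) get an edge with weight rescaled affinely to
`w = 10 + 180 · (s − 0.5)`, i.e. [0.5, 1.0] → [10, 100].

The Markov Cluster algorithm is implemented in-package on the weighted
adjacency matrix (self-loops added): alternate expansion (matrix square)
and inflation (element-wise power, default 1.2) with column
re-normalization and pruning until the matrix is idempotent to
tolerance; clusters are read off the attractor rows and merged with a
union–find so overlapping attractor sets yield one cluster. Cluster
labels are canonicalized by decreasing size (ties broken by smallest
member id), so labels are deterministic. Partitions expose `retained(n)`
(clusters with > n members, reporting threshold 11 ≙ "> 10 patients")
and `analysis(n)` (clusters with ≥ n members, default 50) views.

## Stability via Variation of Information (`cluster_stability`)

For partitions P, Q over the same node set,

```
VI(P, Q) = H(P) + H(Q) − 2 I(P, Q)
```

in nats, computed from the contingency table over the *common* nodes
(perturbation can orphan nodes); disjoint node sets raise. VI is a
metric: identity, symmetry and the triangle inequality are tested, plus
agreement with a brute-force `Counter`-based oracle on random partitions.

Perturbations at level α:

- **dilute** — delete a uniformly random fraction α of edges;
- **shuffle** — degree-preserving double-edge swaps applied to a
  fraction α of edges, keeping the weight multiset.

`stability_curve` re-runs MCL on each perturbed network over a grid of α
with `replicates` repeats and reports mean VI per α, together with
reference lines: the expected VI between the reference partition and a
copy with 10% / 20% of nodes reassigned to uniformly random clusters
(averaged over Monte Carlo draws). A stable clustering stays well below
the 10% line over moderate dilution.

## Symptom grouping (`symptom_grouping`)

For each analysis cluster (≥ 50 patients), the symptom profile is the
fraction of its patients carrying at least one code in each of the 13
ICD-10 chapter-XVIII blocks (R00–R09, …, R95–R99). Clusters are grouped
by hierarchical clustering of these 13-dimensional profiles using
Euclidean distance and **classical Ward linkage (ward.D)**, cut at `k`
groups; a Newick string of the dendrogram is also produced.

A subtle implementation point: SciPy's `linkage(..., method="ward")`
implements **ward.D2** — it runs the Lance–Williams recurrence on the
*squares* of its input distances, whether it is given observations or a
condensed distance matrix. Classical ward.D (the recurrence on the
unsquared distances, as in R's `hclust(d, "ward.D")`) is obtained here
by feeding `sqrt(pdist(x))` to SciPy and squaring the resulting merge
heights. Both variants were validated against R's `hclust`: merge
heights match to machine precision and `cutree` partitions agree exactly
for ward.D and ward.D2 alike. `ward_groups(..., method="ward.d2")`
exposes the SciPy-native variant for comparison.

## Enrichment statistics (`enrichment_stats`)

- **Stratified binomial code enrichment.** Patients are stratified by
  sex × birth decade. For code *c* in cluster *k*, the background
  carrier rate is estimated *per stratum* from the whole cohort; the
  null distribution of the cluster's carrier count is the
  Poisson-binomial over its members' stratum rates (computed by exact
  convolution of the per-stratum binomials). The reported p-value is the
  upper tail at the observed count; Benjamini–Hochberg controls FDR
  across all (cluster, code) tests with ≥ `min_support` carriers. With a
  single stratum this reduces exactly to a plain binomial test, which is
  asserted; a planted sex-confounded code is shown to be de-confounded
  by the stratification.
- **Metadata contrasts.** Numeric patient metadata are compared cluster
  vs rest with two-sided Wilcoxon rank-sum tests; constant columns yield
  NaN, non-numeric columns are ignored.
- **Prescription enrichment.** ATC codes are truncated to level 3
  (4 characters); malformed codes are dropped with a warning. Each
  (cluster, ATC class) is tested cluster vs rest with a two-sided Fisher
  exact test on carrier counts, BH-corrected, with an
  enriched/depleted direction flag.

## Comorbidity statistics (`comorbidity_networks`)

Patients are reduced to code carrier sets (repeat events count once).
For each code pair with ≥ `min_carriers` carriers each:

- **Co-occurrence.** Two-sided Fisher exact test on the 2×2 carrier
  table, Bonferroni-corrected over all tested pairs, plus a comorbidity
  score `CS = log2(observed / expected)` where
  `expected = n_A · n_B / N`.
- **Directionality.** On patients carrying both codes, first-occurrence
  dates define a lag; ties (same date) are excluded. The direction test
  is an exact two-sided binomial sign test on the number of A-before-B
  orderings at p = 0.5, BH-corrected; a pair is "directional" when
  significant, with the mean signed lag reported.
- **Lag ANOVA.** For a significant pair, per-cluster lag distributions
  are compared with one-way ANOVA (`f_oneway`); degenerate cases
  (one group, constant lags) yield NaN or 1.0 as appropriate.
- `top_pairs_by_unique_codes` greedily selects top-scoring pairs under a
  unique-code budget for compact network rendering.

## Glycemic dysregulation (`dysregulation`)

**HbA1c preprocessing.** Measurements are bounded to the assay range
[15, 184] mmol/mol (inclusive); same-day values are averaged; series are
split wherever the gap between consecutive measurements exceeds 365 days
(exactly 365 does not split); a segment is valid when it has ≥ 5 points
spanning ≥ 90 days. Patients without a valid segment contribute `False`
to the series-based criteria.

**Change-point detection.** Bayesian online change-point detection with
a Normal-Gamma conjugate model (Student-t predictive), constant hazard
1/20, `kappa0 = 0.01`. The run-length posterior matrix R is aligned to
calendar positions via `cp[c] = max_t R[t, t − c]`; a change point is
flagged at positions where this posterior exceeds 0.5 **and** the
difference in segment means across the candidate is ≥ 5 mmol/mol (the
magnitude gate, which suppresses statistically crisp but clinically
trivial shifts). Measured on the generator's envelope (shift 15
mmol/mol = 7.5× the noise SD, 10 points): detection within ±2 positions
in 100/100 replicates, 0/100 false flags on flat noise; a 3 mmol/mol
shift is correctly gated out even when its posterior is high.

**Onset level.** A linear mixed model on all patients' valid HbA1c
segments — fixed intercept + slope in years since onset, random
intercept (and slope when estimable) per patient — yields each patient's
model-based HbA1c at onset (fixed + random intercept). Criterion: onset
level ≥ 53 mmol/mol. Recovery on simulated trajectories: MAE < 2
mmol/mol against planted intercepts.

**Severity.** Strictly more than half of a patient's valid measurements
above 48 mmol/mol.

**Score.** Five booleans — dysregulation code (`sdcL03`), hyperglycemia
code (R73 or E89), change point flagged, onset level ≥ 53, majority
above threshold — summed to a 0–5 score; missing criteria count as
`False`; `score ≥ 3` defines the dysregulated class. All 32 flag
combinations are covered by a truth-table test.

**Lab contrasts.** Lab panels are normalized per test (log-transform
first when a normality test prefers the log scale, then z-score);
cluster differences are assessed jointly with MANOVA (Pillai's trace)
and per-test with two-sample Kolmogorov–Smirnov contrasts.

## Pipeline and CLI (`pipeline`, `cli`)

`RunConfig` is a pydantic v2 model with `extra="forbid"` at every level,
so typos in YAML configs fail loudly. A run takes either `simulate:`
(generator parameters) or `inputs:` (paths to notes/diagnoses/patients/
labs/prescriptions/dictionaries) — exactly one — plus a stage list, and
writes each stage's TSV outputs and a `manifest.json` recording status,
row counts and parameters per stage. Runs are byte-deterministic given
the seed, and a file-based run on a written cohort reproduces the
simulated run's partition byte for byte. The `phenostrat` CLI (click)
exposes each stage and `run`.

## Numerical conventions and limitations

- All logarithms in BM25 and VI are natural logs.
- Randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global seeding.
- Exact tests (Fisher, binomial) are validated against direct
  hypergeometric/binomial enumeration with `math.comb` on all 2×2
  tables with total ≤ 30, using the conventional two-sided rule
  (sum of outcome probabilities ≤ observed × (1 + 1e−7)).
- The MCL implementation is dense; it is comfortable at the cohort
  sizes used here (≤ a few thousand patients) but is not tuned for
  very large sparse networks.
- The BOCPD detector's operating characteristics are reported for the
  generator's noise envelope; much lower signal-to-noise regimes would
  need longer series or a re-derived threshold, which is why the
  magnitude gate and posterior threshold are explicit `BocpdConfig`
  fields rather than constants.
- The mixed onset model falls back from random-slopes to
  random-intercepts when the slope variance is not estimable.
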