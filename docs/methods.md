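# Methods

## Scope and model

`herbnet` analyses a multi-herb formula as a layered bipartite system:
herbs contain compounds; compounds that survive a pharmacokinetic screen
("actives") connect to protein targets; targets connect to diseases and to
pathways. All graphs are **simple undirected bipartite graphs** — repeated
evidence for an edge is stored as an evidence-tag set, never as a
multi-edge — and degree (number of distinct neighbors) is the only topology
statistic, because that is the statistic this style of analysis interprets.

Identifiers are opaque normalized strings (trim, case-fold, collapse internal
whitespace). No synonym dictionary is applied: two spellings that differ
beyond whitespace/case are different compounds. A compound listed under
several herbs becomes a single node whose `herb_ids` is the union of its
memberships; per-herb statistics count it once per herb.

## Drug-likeness (DL)

DL of a compound with descriptor vector A against a reference profile B is
the continuous Tanimoto coefficient f(A,B) = A·B / (|A|² + |B|² − A·B).
Raw molecular descriptors mix incommensurate scales, and the coefficient is
not scale-invariant, so a scaling convention is required and is part of this
package's definition of the score: each descriptor is min–max scaled to
[0, 1] using the **reference library's** (min, max); B is the column mean of
the scaled library; queries are scaled with the same ranges and clipped to
[0, 1]. Under this convention f ∈ [0, 1] for all inputs, f(A,A) = 1, and the
score is invariant to affine rescaling of any raw descriptor column (tested).
Constant library columns scale to 0 and are flagged. A query that scales to
the zero vector has an undefined score (0/0 against a zero profile direction)
and raises a domain error by default; `on_missing="skip"` yields NaN instead.

The canonical 6,511-drug reference library behind the published 0.18
threshold is not distributable and its descriptor set is unpublished, so the
profile is always built from a user-supplied (or generated) library, and
0.18 is a configurable threshold, not a derivable constant. Tables that
already carry DL values bypass scoring entirely (pass-through), which is how
the bundled fixture of printed OB/DL values is screened.

## ADME screen

Retained ⟺ OB ≥ `ob_min` **and** DL ≥ `dl_min`, inclusive comparisons,
defaults 40.0 (percent) and 0.18. Two OB cutoffs circulate for this style of
screen (40% and 50%); the default is 40% because the published active set
(e.g. kaempferol at OB 41.88%) only satisfies that one, and the stricter
variant is one flag away. The screen is a pure partition of its input:
retained ∪ rejected = input, each rejected record carries every failed
criterion, and raising either threshold can only shrink the retained set.

## Target fishing

Dual-classifier predictions carry an SVM and a random-forest score per
compound–target pair; a pair is kept when **both** are strictly above their
cutoffs (defaults 0.8 and 0.7 — "larger than" read literally; an inclusive
mode exists). Curated sources are consumed as exported edge-list files, never
live queries, for reproducibility. All sources merge by set union — one edge
per (compound, target), evidence = contributing source tags — which is
idempotent and order-independent; no attempt is made to resolve
"conflicts" between a curated edge and a low prediction score, since union
semantics treat any one source as sufficient evidence.

Disease annotation uses a declared vocabulary (default: the eight disease
classes of the target–disease analysis — obesity, cardiovascular disease,
diabetes, fatty liver, gastrointestinal disease, osteoarthritis,
inflammation, cancer); labels outside it are errors, and the vocabulary is
user-extensible.

## Networks

`build_bipartite` takes edges of one kind; nodes are exactly the edge
endpoints (isolated nodes only by explicit injection — by default a screened
active with no surviving target edge is absent from the C-T network).
Handshake (Σ left degrees = Σ right degrees = |edges|) and
order-independence are tested invariants. The phrase "targets with at least
k interactions with compounds of the different herbs" is ambiguous between
degree ≥ k and "compounds from ≥ k herbs"; both are implemented
(`nodes_with_min_degree` and `targets_hit_by_min_herbs`) and neither is
asserted as canonical. `per_herb_disease_counts` counts a target for
(herb h, disease d) iff it is annotated to d and adjacent to ≥ 1 compound of
h, and also reports each disease's distinct-target total.

## Enrichment

Over-representation only: p = P(X ≥ k), X ~ Hypergeom(N, K, n), computed via
`scipy.stats.hypergeom.sf` (log-space internally; verified against exact
combinatorial enumeration for every configuration with N ≤ 12 to 1e−12).
The default universe is the union of all annotation members, overridable;
queries are silently restricted to the universe (logged). Following the
original analysis style the default filter is raw p ≤ 0.05; BH-adjusted
filtering (`statsmodels.stats.multitest`, verified against a hand step-up) is
available and adjusted values are always reported. The BH family is the set
of terms with overlap ≥ 1 (terms with k = 0 are untestable here and their
p = 1 would only dilute the correction). Term grouping: pairwise Cohen's
kappa on hit-set indicators over the query, single-linkage components at
kappa ≥ 0.4 (the conventional default for this grouping style;
configurable), each group led by its smallest raw p, ties broken by term id.
The degenerate kappa case (chance agreement 1) is defined as 1 for identical
indicators, else 0.

## Synthetic studies

`generate_study(StudyConfig)` draws one seeded `numpy` Generator through all
sub-generators; identical (config, seed) gives byte-identical serialized
output. Defaults are the study-scale conditions: 541 compounds split
225/48/85/87/80/16 over six herbs, active fraction 51/541, 111 targets,
8 descriptors, a 6,511-row reference library, one hub compound of degree 70,
non-hub actives with 1 + Poisson(11.12) targets — so the expected edge count
is 50 × 12.12 + 70 = 676 — eight diseases at the per-disease rates of the
published target–disease network, and 24 pathways (2 planted) over a
500-target annotation universe. The default cross-herb overlap rate is 0,
matching the printed per-herb partition whose counts sum exactly to 541;
overlap > 0 is supported and tested.

Planting uses wide margins so ground truth is recoverable by construction,
not by luck: actives draw OB = 41 + Exp(18) (capped at 110, matching the
printed OB range) and descriptors ~ N(centroid, 0.2 σ), putting DL near 1;
inactives fail OB (U(5, 38)), DL (descriptors at 0.5–5% of the library
range, DL ≲ 0.13), or both; true prediction edges score U(0.82, 0.99) /
U(0.72, 0.99), decoys below both cutoffs. Planted pathways take 75% of
their members from the hit-target set. What passing recovery tests therefore
shows is that the pipeline is a faithful implementation of its own
definitions — exact recovery under strong separation — **not** that the
screen separates real chemistry, where OB/DL distributions overlap the
thresholds and prediction scores are noisy near the cutoffs. No valid
molecular structures are simulated; only the statistical shapes the pipeline
consumes.

## Pipeline and numerical choices

The file pipeline (`run_pipeline` / `herbnet run-all`) is a thin
orchestration of the library stages with a pydantic-validated YAML/JSON
config (unknown and duplicate keys rejected; all problems reported at once;
relative paths resolved against the config file). Every output is tabular
text; the manifest records config, seed, per-stage counts and SHA-256 of
every file, and re-runs on identical inputs are byte-identical. A stage
failure aborts with the stage name and leaves a manifest marked incomplete.

Degree tables and all emitted lists use deterministic orderings
((−degree, id) or lexicographic) so ties never depend on hash order.
Acceptance-style checks run at the default study scale (20 seeds, ~2 s
total); the enrichment null-calibration check compares the observed
rejection rate at p ≤ 0.05 against the exact attainable level of the
discrete test (for the K = 40, n = 50, N = 400 configuration used, that
level is ≈ 0.037, not 0.05 — comparing against 0.05 itself would mistake
discreteness for miscalibration).

## Known limitations

- No chemical-structure handling (SMILES/SDF) or descriptor computation;
  descriptors arrive as numeric columns.
- No oral-bioavailability prediction: OB is a required input column.
- No re-implementation of the upstream target-prediction classifiers or of
  database clients; their outputs are consumed as files.
- The published 24-pathway enrichment list depends on external database
  versions and is out of scope; enrichment correctness is established by
  oracle, power and calibration tests instead.
- Supplementary-table loaders use heuristic column matching and are
  exercised only when the user supplies the files.
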