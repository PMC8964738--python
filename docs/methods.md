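# Methods

## Problem setting

Pooled CRISPR knockout (CRISPRn) and activation (CRISPRa) screens in
EGFR-mutant NSCLC cell lines under EGFR tyrosine-kinase-inhibitor
treatment yield per-gene comparison statistics for three arm pairs:
control vs treated (CvT), control vs plasmid (CvP), treated vs plasmid
(TvP). `paretohits` consumes these per-gene tables (it does not process
guide-level counts; MAGeCK/CRISPRCleanR/BAGEL-style upstream analysis and
QC are out of scope), scores them with desirability curves, joins them
with knowledge-graph, literature, clinical, tractability and essentiality
evidence into one gene × feature matrix, and ranks genes by Pareto
non-domination under a user-chosen preference. TvP tables are ingested
but unused by the default aggregation.

## Desirability model

Partial desirabilities map each statistic to [0, 1]; the overall score is
their weighted geometric mean (equal weights by default), so any zero
component annihilates the product — an explicit veto semantics.

Numerical choices where the rule family leaves freedom:

- **Boundary inclusivity.** FDR exactly 0.1 scores 1; LFC exactly at the
  mean + 3·sd boundary scores 1. Ties take the favorable branch so that
  a gene sitting on a published cut-off is not silently discarded.
- **p-value curve shape.** Between p = 0.1 (floor 0.01) and p = 10⁻⁴
  (saturation at 1) the curve is d = 0.01 + 0.99·t^s with t the
  fractional position on the −log₁₀ axis and shape s ≥ 1 (default 2).
  The exponent is a configuration knob: larger s concentrates
  desirability near the saturation point.
- **Effect-size step.** The LFC rule is a hard 0.01/1 step by default; a
  logistic variant (`d_lfc_smooth`, steepness 10 per LFC unit) exists for
  callers who prefer a soft boundary.
- **Boundary spread.** The LFC boundary uses the sample (n−1) standard
  deviation. With a degenerate sd of 0 the boundary equals the mean.
- **Hit thresholds.** Overall desirability > 0.7 and positive-selection
  FDR < 0.1, both strict. The positive-selection FDR used in the
  assembled pipeline is the CvT FDR masked to genes with positive LFC
  (non-positively-selected genes are assigned 1, i.e. never hits).
- **Sensitivity mode** drops the essentiality veto (its rationale —
  slow-dying essential knockouts inflating CvT enrichment — is specific
  to resistance calls) and mirrors the LFC rule at mean − 3·sd; the
  d_essentiality column is NaN there.

The seven consistency features are, per technology, the number of
conditions / distinct cell lines / distinct treatments in which a gene is
a hit, plus `full_screen` = distinct cell lines hit in either technology.
The 3 + 3 + 1 split is this package's concretization of
condition/cell-line/treatment consistency.

## Graph features

Degree and unique-neighbor counts are computed on the full typed graph
(degree counts incident triples across all relations; parallel edges of
different relations count separately). PageRank and betweenness are
computed on the undirected PPI subgraph induced by the "interacts"
relation, mirroring the intuition that interaction-level centrality is
the mechanistically relevant one. PageRank is a power iteration with
damping 0.85, L1 tolerance 1e-9, and a 200-iteration cap that raises on
non-convergence; isolated nodes shed their mass uniformly. Betweenness is
exact Brandes (networkx), unnormalized pair counts with endpoints
excluded; a normalized option exists.

RESCAL embeddings factor the stacked per-relation adjacency tensor
X_k ≈ A R_k Aᵀ by alternating least squares: R_k updates solve the
ridge-regularized Kronecker system exactly; the A update is the standard
simultaneous left/right least-squares step. Because that A step is an
approximation to a bilinear subproblem it is not theoretically monotone,
so a safeguard rejects any update that would increase the penalized loss
(falling back to an R-only refresh, then to early stop) — the recorded
loss sequence is non-increasing by construction. Defaults: rank 32
(16 in the assembled pipeline's small graphs), λ = 0.01, seeded
uniform(−1, 1) initialization, deterministic per seed. Anchor relevance
is the exact L2 distance from each gene's embedding row to the anchor
rows (EGFR, NSCLC); no approximate nearest-neighbor search is used at
desk scale. Because embedding geometry depends on rank, regularization
and schedule, distances are meaningful ordinally (planted-structure
recovery), not as absolute values.

## Literature, clinical, tractability, essentiality

- **Literature.** Corpora arrive as documents with pre-extracted mention
  sets (no NER is performed). Co-mention counts are document
  intersections; the normalized frequency divides by the gene's total
  document count, directly compensating the large per-gene variation in
  publication volume; genes never mentioned score 0 by convention. The
  year filter (2000–2019 typical) is a configurable method, not
  hard-coded.
- **Clinical.** Responder = RECIST CR/PR **and** PFS > 6 months (strict).
  Per-trial enrichment is log₂((prev_nr + ε)/(prev_r + ε)) with
  prevalences the altered fraction of each group and ε = 0.01 by default;
  positive values mean enrichment in non-responders. Scores stay
  trial-specific — panels differ across trials, so no cross-trial
  aggregation is performed — and the raw 2×2 counts are always emitted
  alongside so alternative statistics can be recomputed. Trials lacking
  either group report a missing score.
- **Tractability.** Ordinal buckets (1 = most druggable) are reversed to
  scores via (max_bucket + 1) − bucket, default max 10, an involution.
- **Essentiality.** A gene is essential when its dependent-cell-line
  fraction is ≥ 0.9 (boundary inclusive); the assembled feature is the
  favorable indicator `nonessential`.

## Pareto engine

Dominance respects per-objective directions by sign-flipping minimized
columns. Front extraction is a vectorized linear-scan peel (each
candidate checked against current survivors in one broadcast); levels
come from iterated peeling. At the scale of screens (thousands of genes,
~10 objectives) this O(n²·k) scheme is fast and is verified against an
independent full dominance-matrix oracle in the test suite. Exactly-tied
vectors are mutually non-dominating and share a level. Ranking output is
deterministic: level ascending, then optional user sort-within columns
(direction-corrected, best first), then gene id.

Genes missing any selected objective are excluded with a logged warning
and listed with reasons in the provenance block — dominance is undefined
on missing coordinates. An opt-in `impute_worst` switch instead fills
missing entries with the worst observed value of that objective, keeping
the gene rankable but never advantaged.

The shipped default preference maximizes ten objectives: `full_screen`,
`RNASeq_LFC`, `clinical_ES1..3`, `lit_EGFR`, `lit_NSCLC`, `pagerank`,
`betweenness`, `RNASeq_pval`. `RNASeq_pval` is stored as −log₁₀ p so
"maximize" is uniformly higher-is-better. Directions and the objective
set are user-overridable; no claim is made that these defaults are
bit-compatible with any other tool's.

## Synthetic benchmark

The generators emulate the statistical shape of each input with planted
ground truth, one independent seeded substream per generator:

- **Screen**: nulls LFC ~ N(0, 1), p ~ U(0, 1), FDR by
  Benjamini–Hochberg; planted genes sit 4 (+U(0, 0.2)) null standard
  deviations above the null mean — safely past the 3·sd hit boundary but
  configurable to probe it — with p = 10⁻⁶ and no essentiality flag.
- **RNA-seq**: planted profiles are deliberately heterogeneous — effect
  size rises across the planted set (LFC 4 → 6) while significance falls
  (p 10⁻⁹ → 10⁻⁵) — so the planted drivers form a genuine mutually
  non-dominated trade-off set. A homogeneous "uniformly best" planting
  would let one planted gene dominate another, making "all planted genes
  on the front" false ground truth.
- **Knowledge graph**: Erdős–Rényi background per relation (p = 0.02)
  over gene plus entity nodes, with a dense (p = 0.8) planted cluster
  containing the anchors EGFR/NSCLC and the planted genes; always
  includes an "interacts" relation.
- **Corpus**: each document has a focal gene — drawn from the planted
  set with probability 0.3, else uniformly — and acquires the anchor
  terms at 0.6 (planted focal) vs 0.05 (null) probability. Exact
  co-mention counts are tallied during generation into a ground-truth
  sidecar; downstream checks read the sidecar rather than re-deriving.
- **Cohort**: per trial 40 responders / 60 non-responders whose RECIST
  and PFS values recover the intended labels by construction; planted
  genes are altered at base + 0.25 prevalence in non-responders vs base
  0.05 elsewhere.

Defaults are 500 genes with 5 planted drivers across 2 cell lines × 2
treatments × 2 technologies. What passing the planted-recovery benchmark
shows: the pipeline's rules and the ranking engine compose correctly and
recover a known multi-evidence signal. What it does not show: performance
on real screens — real guide-level noise, realistic knowledge-graph
degree distributions, publication-volume skew, and panel heterogeneity
are deliberately not modeled.

## Known limitations

- Fronts widen with objective count; with ten objectives a few-hundred-
  gene level 1 is normal, and within-front ordering is the user's
  responsibility (`sort_within`).
- RESCAL embeddings (hence anchor distances) are reproducible only per
  seed/rank/regularization; cross-configuration distances are not
  comparable.
- The clinical enrichment score is a descriptive prevalence ratio, not a
  test statistic; use the emitted 2×2 counts for inference.
- Hit calling consumes upstream essentiality flags; no BAGEL-style
  essentiality inference is performed.
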