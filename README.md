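# paretohits

Multi-objective re-ranking of CRISPR-screen resistance hits.

Pooled CRISPR screens against EGFR-inhibitor-treated NSCLC cell lines
routinely return thousands of statistically significant candidate
resistance genes — far more than can be validated. Triaging them is a
multi-evidence judgement call: screen consistency, literature support,
clinical alteration enrichment, network context, druggability, and
essentiality all matter, and no single score combines them without
imposing arbitrary weights. `paretohits` formalizes the triage as a
multi-objective optimization and is aimed at functional-genomics and
target-discovery scientists who need a reproducible, preference-driven
short list.

## The model

**Desirability scoring of screen statistics.** For each screen condition
(cell line × treatment × CRISPRn/CRISPRa), per-gene statistics of the
control-vs-treated (CvT) and control-vs-plasmid (CvP) comparisons are
mapped to the unit interval by partial-desirability rules and combined by
a geometric mean, *D* = (∏ dᵢ^{wᵢ})^{1/Σwᵢ}:

- d_FDR — step: 0 if FDR > 0.1, else 1;
- d_p — 0.01 for p > 0.1, rising as a power curve on the −log₁₀ axis to 1
  at p ≤ 10⁻⁴;
- d_LFC — step at the distribution-derived boundary mean(LFC) + 3·sd:
  1 at or above, 0.01 below (mirrored for sensitivity screens);
- d_ess — veto (0) for genes essential in both CvP and CvT or with
  negative CvT log fold-change.

A gene is a **hit** when *D* > 0.7 and its positive-selection FDR < 0.1.
Hit patterns across conditions collapse into seven consistency features
(per-technology condition/cell-line/treatment counts plus the
cross-technology `full_screen` cell-line count).

**Hybrid features.** A typed knowledge graph contributes degree, unique
neighbors, PageRank and betweenness (on the "interacts" PPI subgraph),
and RESCAL bilinear embeddings X_k ≈ A R_k Aᵀ from which exact L2
distances to the EGFR and NSCLC anchor nodes are taken. A literature
corpus contributes co-mention counts and normalized frequencies with
those anchors plus a gene co-occurrence matrix. A clinical cohort
contributes per-trial enrichment log₂((prev_non-resp + ε)/(prev_resp + ε))
of alterations in non-responders (responder = RECIST CR/PR and PFS > 6
months). Tractability buckets are reversed (bucket 1 → score 10) and
genes dependent in ≥ 90% of cell lines are flagged essential.

**Pareto ranking.** Given objectives F(x) = [f₁(x), …, f_k(x)]ᵀ with
per-objective directions, gene x₁ dominates x₂ iff x₁ is not worse on
every objective and strictly better on at least one. Level 1 is the set
of non-dominated genes (the Pareto front); peeling fronts assigns every
gene a level. A `Preference` — an ordered list of (feature, direction)
pairs — is fully user-composable; the shipped default uses ten
objectives (screen consistency, RNA-seq effect and significance, three
trial enrichments, two literature metrics, two PPI centralities), all
maximized.

## Worked example

`examples/04_pareto_ranking.py` ranks six genes on a screen-consistency
vs literature-support trade-off:

```
NF1 dominates MET: True
       pareto_level  screen_consistency  literature_support
gene
WWTR1             1                 1.0                 9.0
PTEN              1                 2.0                 8.0
NF1               1                 3.0                 5.0
SRC               2                 1.0                 2.0
MET               2                 3.0                 1.0
GENEX             3                 0.0                 0.0
```

WWTR1, PTEN and NF1 form the front: each trades screen consistency
against literature support and none can improve one objective without
losing the other. MET ties NF1 on consistency but is strictly worse on
literature, so it falls to level 2. `examples/05_end_to_end.py` runs the
whole pipeline on a synthetic benchmark (200 genes, 4 planted resistance
drivers) and recovers all four planted genes at level 1 among a 28-gene
front. The other examples exercise each feature module in isolation.

A CLI mirrors the three pipeline stages:

```
paretohits simulate --out fixtures/ --seed 7
paretohits features --screens fixtures/screens --graph fixtures/kg.tsv \
    --corpus fixtures/corpus.jsonl --cohort fixtures/cohort.tsv \
    --rnaseq fixtures/rnaseq.tsv --out features.tsv
paretohits rank --features features.tsv \
    --preference fixtures/default_preference.yaml --out ranked.tsv
```

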