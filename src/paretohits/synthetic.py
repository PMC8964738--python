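"""Seeded generators for every input the pipeline consumes.

Each generator plants a known signal so downstream stages can be checked
against ground truth: resistance genes with large positive log fold-changes
and tiny p-values in the screen, a dense knowledge-graph cluster around the
EGFR and NSCLC anchor nodes, elevated literature co-mentions with the
anchor terms, and an alteration-prevalence gap toward non-responders in the
clinical cohort. One master seed spawns independent per-generator
substreams so any module's input can be regenerated in isolation. Every
generator writes (or returns) a ground-truth sidecar that downstream
checks read instead of re-deriving the truth.

The generators emulate the statistical shape of the real inputs, not their
scale: guide-level count distributions, realistic knowledge-graph degree
distributions, and publication-volume skew are out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import ClinicalCohort, Corpus, Document, Patient
from .feature_table import FeatureTable
from .kg import KnowledgeGraph, graph_feature_table
from .screen import (
    Condition,
    DesirabilityResult,
    HitMatrix,
    ScreenComparisonTable,
    build_hit_matrix,
    consistency_features,
    overall_desirability,
)

ANCHOR_GENE = "EGFR"
ANCHOR_DISEASE = "NSCLC"

DEFAULT_CONDITIONS = [
    Condition("PC-9", "gefitinib", "KO"),
    Condition("PC-9", "osimertinib", "KO"),
    Condition("HCC827", "gefitinib", "KO"),
    Condition("HCC827", "osimertinib", "KO"),
    Condition("PC-9", "gefitinib", "activation"),
    Condition("PC-9", "osimertinib", "activation"),
    Condition("HCC827", "gefitinib", "activation"),
    Condition("HCC827", "osimertinib", "activation"),
]


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults: 500 genes with 5 planted resistance drivers whose screen
    effect sits 4 standard deviations above the null mean (safely past the
    mean + 3 sd hit boundary), screened across 2 cell lines x 2 treatments
    x 2 technologies; a 150-node, 3-relation knowledge graph with a dense
    planted cluster around the anchors; a 400-document corpus; and three
    trials with a 0.25 alteration-prevalence gap toward non-responders.
    """

    n_genes: int = 500
    n_planted: int = 5
    conditions: list[Condition] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_CONDITIONS)
    )
    planted_effect_sd_multiple: float = 4.0
    planted_pvalue: float = 1e-6
    null_essential_rate: float = 0.05
    # knowledge graph
    kg_n_background_nodes: int = 150
    kg_relations: tuple[str, ...] = ("interacts", "associates", "regulates")
    kg_background_edge_prob: float = 0.02
    kg_cluster_edge_prob: float = 0.8
    # literature corpus
    corpus_size: int = 400
    corpus_base_rate: float = 0.05
    corpus_planted_rate: float = 0.6
    corpus_planted_focal_share: float = 0.3
    # clinical cohort
    trials: tuple[str, ...] = ("TRIAL1", "TRIAL2", "TRIAL3")
    n_responders: int = 40
    n_nonresponders: int = 60
    base_alteration_prev: float = 0.05
    planted_prevalence_gap: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted >= self.n_genes:
            raise ValueError("n_planted must be < n_genes")
        for field in ("n_genes", "n_planted", "corpus_size", "n_responders",
                      "n_nonresponders", "kg_n_background_nodes"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def planted_genes(self) -> list[str]:
        return self.genes[: self.n_planted]

def _stream_rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    """Independent, seed-derived substream for one generator."""
    streams = {"screen": 1, "kg": 2, "corpus": 3, "cohort": 4, "rnaseq": 5,
               "tractability": 6}
    return np.random.default_rng([spec.seed, streams[stream]])


# ---------------------------------------------------------------------------
# screen


def generate_screen(spec: SyntheticSpec) -> list[ScreenComparisonTable]:
    """CvT and CvP comparison tables for every condition.

    Null genes: LFC ~ Normal(0, 1), p ~ Uniform(0, 1), FDR by
    Benjamini-Hochberg. Planted genes: LFC at ``planted_effect_sd_multiple``
    null standard deviations above the null mean, p = 1e-6, never essential.
    """
    rng = _stream_rng(spec, "screen")
    genes = spec.genes
    planted = set(spec.planted_genes)
    tables: list[ScreenComparisonTable] = []
    for cond in spec.conditions:
        for comparison in ("CvT", "CvP"):
            lfc = rng.normal(0.0, 1.0, size=spec.n_genes)
            pvals = rng.uniform(0.0, 1.0, size=spec.n_genes)
            essential = rng.uniform(size=spec.n_genes) < spec.null_essential_rate
            null_mask = np.array([g not in planted for g in genes])
            null_mean = lfc[null_mask].mean()
            null_sd = lfc[null_mask].std(ddof=1)
            for i, g in enumerate(genes):
                if g in planted:
                    jitter = rng.uniform(0.0, 0.2)
                    lfc[i] = null_mean + (
                        spec.planted_effect_sd_multiple + jitter
                    ) * null_sd
                    pvals[i] = spec.planted_pvalue
                    essential[i] = False
            pvals = np.clip(pvals, 1e-12, 1.0)
            fdr = stats.false_discovery_control(pvals, method="bh")
            rows = pd.DataFrame(
                {
                    "gene": genes,
                    "lfc": lfc,
                    "pvalue": pvals,
                    "fdr": fdr,
                    "essential_flag": essential,
                }
            )
            tables.append(
                ScreenComparisonTable(condition=cond, comparison=comparison,
                                      rows=rows)
            )
    return tables


def generate_rnaseq(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene differential-expression table (lfc, pvalue).

    Planted genes get large positive fold-changes and tiny p-values; nulls
    are centered at zero with uniform p-values. The planted profiles are
    heterogeneous — effect size increases across the planted set while
    significance decreases — so the planted drivers form a genuine
    trade-off set rather than a single uniformly-best gene: no planted
    gene dominates another, which is the ground truth the end-to-end
    benchmark asserts.
    """
    rng = _stream_rng(spec, "rnaseq")
    genes = spec.genes
    planted = {g: j for j, g in enumerate(spec.planted_genes)}
    P = spec.n_planted
    lfc = rng.normal(0.0, 1.0, size=spec.n_genes)
    pvals = rng.uniform(0.0, 1.0, size=spec.n_genes)
    for i, g in enumerate(genes):
        if g in planted:
            j = planted[g]
            frac = j / (P - 1) if P > 1 else 0.0
            lfc[i] = 4.0 + 2.0 * frac           # graded effect size
            pvals[i] = 10 ** (-(9.0 - 4.0 * frac))  # graded significance
    return pd.DataFrame(
        {"lfc": lfc, "pvalue": np.clip(pvals, 1e-12, 1.0)},
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# knowledge graph


def generate_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, dict]:
    """Erdős–Rényi background plus a dense planted cluster around the anchors.

    Nodes are the screen's genes plus ``kg_n_background_nodes`` non-gene
    entities plus the two anchors (EGFR typed as gene, NSCLC as disease).
    Every relation type gets independent ER edges at the background
    probability; within the planted cluster (planted genes + anchors) every
    ordered pair is connected per relation with the cluster probability.
    Returns the graph and a ground-truth sidecar.
    """
    rng = _stream_rng(spec, "kg")
    gene_nodes = [g for g in spec.genes]
    other_nodes = [f"ENT{i}" for i in range(spec.kg_n_background_nodes)]
    nodes = gene_nodes + other_nodes + [ANCHOR_GENE, ANCHOR_DISEASE]
    node_types = {n: "gene" for n in gene_nodes}
    node_types.update({n: "entity" for n in other_nodes})
    node_types[ANCHOR_GENE] = "gene"
    node_types[ANCHOR_DISEASE] = "disease"
    cluster = set(spec.planted_genes) | {ANCHOR_GENE, ANCHOR_DISEASE}
    edges: list[tuple[str, str, str]] = []
    n = len(nodes)
    for rel in spec.kg_relations:
        # background ER edges over ordered pairs
        m = rng.binomial(n * (n - 1), spec.kg_background_edge_prob)
        src = rng.integers(0, n, size=m)
        dst = rng.integers(0, n, size=m)
        for s, t in zip(src, dst):
            if s != t:
                edges.append((nodes[s], rel, nodes[t]))
        for a in sorted(cluster):
            for b in sorted(cluster):
                if a != b and rng.uniform() < spec.kg_cluster_edge_prob:
                    edges.append((a, rel, b))
    graph = KnowledgeGraph(edges=edges, node_types=node_types)
    truth = {
        "planted_cluster": sorted(cluster),
        "anchors": [ANCHOR_GENE, ANCHOR_DISEASE],
        "background_edge_prob": spec.kg_background_edge_prob,
        "cluster_edge_prob": spec.kg_cluster_edge_prob,
    }
    return graph, truth


# ---------------------------------------------------------------------------
# corpus


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, dict]:
    """Documents co-mentioning planted genes with the anchors at a high rate.

    Each document mentions one focal gene — drawn from the planted set with
    probability ``corpus_planted_focal_share`` (resistance drivers attract
    disproportionate literature attention), otherwise uniformly from all
    genes. Anchor terms are added with the planted rate for planted genes
    and the base rate for nulls. The sidecar records the exact co-mention
    counts tallied during generation.
    """
    rng = _stream_rng(spec, "corpus")
    genes = spec.genes
    planted = set(spec.planted_genes)
    counts = {g: {ANCHOR_GENE: 0, ANCHOR_DISEASE: 0} for g in genes}
    docs = []
    for i in range(spec.corpus_size):
        if rng.uniform() < spec.corpus_planted_focal_share:
            focal = spec.planted_genes[int(rng.integers(0, spec.n_planted))]
        else:
            focal = genes[int(rng.integers(0, spec.n_genes))]
        rate = spec.corpus_planted_rate if focal in planted else spec.corpus_base_rate
        mentions = {focal}
        # a few co-mentioned secondary genes
        for _ in range(int(rng.integers(0, 3))):
            mentions.add(genes[int(rng.integers(0, spec.n_genes))])
        for term in (ANCHOR_GENE, ANCHOR_DISEASE):
            if rng.uniform() < rate:
                mentions.add(term)
        for g in mentions & set(genes):
            for term in (ANCHOR_GENE, ANCHOR_DISEASE):
                if term in mentions:
                    counts[g][term] += 1
        year = int(rng.integers(2000, 2020))
        docs.append(Document(doc_id=f"doc{i}", year=year,
                             mentions=frozenset(mentions)))
    truth = {"comention_counts": counts,
             "base_rate": spec.corpus_base_rate,
             "planted_rate": spec.corpus_planted_rate}
    return Corpus(docs), truth


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(spec: SyntheticSpec) -> tuple[ClinicalCohort, dict]:
    """Per-trial patients with a planted alteration-prevalence gap.

    Responders are CR/PR with PFS uniform in (7, 30) months; non-responders
    are SD/PD or early progressors, so the RECIST + PFS responder rule
    recovers the intended labels by construction. Planted genes are altered
    with probability base + gap in non-responders vs base in responders;
    null genes with the base prevalence in both groups.
    """
    rng = _stream_rng(spec, "cohort")
    planted = set(spec.planted_genes)
    patients = []
    intended: dict[str, str] = {}
    for trial in spec.trials:
        for j in range(spec.n_responders + spec.n_nonresponders):
            pid = f"{trial}_P{j:03d}"
            responder = j < spec.n_responders
            if responder:
                recist = str(rng.choice(["CR", "PR"]))
                pfs = float(rng.uniform(7.0, 30.0))
            else:
                if rng.uniform() < 0.5:
                    recist = str(rng.choice(["SD", "PD"]))
                    pfs = float(rng.uniform(0.0, 30.0))
                else:  # early progressor despite radiographic response
                    recist = str(rng.choice(["CR", "PR"]))
                    pfs = float(rng.uniform(0.0, 6.0))
            alts = set()
            for g in spec.genes:
                if g in planted:
                    prev = (spec.base_alteration_prev
                            if responder
                            else spec.base_alteration_prev
                            + spec.planted_prevalence_gap)
                else:
                    prev = spec.base_alteration_prev
                if rng.uniform() < prev:
                    alts.add(g)
            intended[pid] = "responder" if responder else "non_responder"
            patients.append(
                Patient(patient_id=pid, trial=trial, recist=recist,
                        pfs_months=pfs, alterations=frozenset(alts))
            )
    truth = {"intended_labels": intended,
             "planted_prevalence_gap": spec.planted_prevalence_gap}
    return ClinicalCohort(patients), truth


# ---------------------------------------------------------------------------
# tractability / essentiality


def generate_tractability(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene tractability buckets; planted genes are highly druggable."""
    rng = _stream_rng(spec, "tractability")
    planted = set(spec.planted_genes)
    rows = {}
    for g in spec.genes:
        if g in planted:
            buckets = rng.integers(1, 4, size=3)
        else:
            buckets = rng.integers(1, 11, size=3)
        rows[g] = {"bucket_ab": int(buckets[0]), "bucket_sm": int(buckets[1]),
                   "bucket_other": int(buckets[2])}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return df


def generate_essentiality(spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene DepMap-style dependent-cell-line fractions.

    Planted genes are non-essential (low dependency); null genes span the
    whole range so the 90% flag threshold is exercised.
    """
    rng = _stream_rng(spec, "tractability")
    planted = set(spec.planted_genes)
    frac = rng.uniform(0.0, 1.0, size=spec.n_genes)
    for i, g in enumerate(spec.genes):
        if g in planted:
            frac[i] = rng.uniform(0.0, 0.5)
    df = pd.DataFrame({"dependent_fraction": frac},
                      index=pd.Index(spec.genes, name="gene"))
    return df


# ---------------------------------------------------------------------------
# assembly


def screen_feature_table(tables: list[ScreenComparisonTable]) -> pd.DataFrame:
    """Run desirability scoring and hit calling; emit the 7 consistency features."""
    by_cond: dict[str, dict[str, ScreenComparisonTable]] = {}
    for t in tables:
        comp = "CvT" if t.comparison in ("CvT", "TvC") else t.comparison
        by_cond.setdefault(t.condition.label, {})[comp] = t
    results: list[DesirabilityResult] = []
    pos_fdr: dict[str, pd.Series] = {}
    for label, comps in by_cond.items():
        if "CvT" not in comps or "CvP" not in comps:
            raise ValueError(f"condition {label!r} lacks a CvT or CvP table")
        res = overall_desirability(comps["CvT"], comps["CvP"], mode="resistance")
        results.append(res)
        cvt = comps["CvT"].indexed()
        # positive-selection FDR: the CvT FDR on positively selected genes
        pos = cvt["fdr"].where(cvt["lfc"] > 0, 1.0)
        pos_fdr[label] = pos
    hits: HitMatrix = build_hit_matrix(results, pos_fdr)
    return consistency_features(hits).astype(float)


def assemble_feature_table(
    screen_tables: list[ScreenComparisonTable],
    graph: KnowledgeGraph,
    corpus: Corpus,
    cohort: ClinicalCohort,
    rnaseq: pd.DataFrame | None = None,
    tractability: pd.DataFrame | None = None,
    essentiality: pd.DataFrame | None = None,
    genes: Iterable[str] | None = None,
    kg_rank: int = 16,
    kg_iterations: int = 30,
    seed: int = 0,
) -> FeatureTable:
    """Run every feature module and join the columns into one FeatureTable.

    All inputs must share the screen's gene universe (graph genes are the
    subset present as graph nodes; absent genes get zero centralities and
    missing distances handled by kg_features).
    """
    from .evidence import (
        clinical_feature_table,
        literature_feature_table,
    )

    if genes is None:
        genes = sorted(
            set.intersection(
                *[set(t.rows["gene"]) for t in screen_tables]
            )
        )
    genes = list(genes)
    if not genes:
        raise ValueError("gene universes of the screen tables do not overlap")

    blocks: list[tuple[pd.DataFrame, str]] = []
    crispr = screen_feature_table(screen_tables).reindex(genes)
    blocks.append((crispr, "crispr"))
    graph_genes = [g for g in genes if g in set(graph.nodes)]
    gfeat = graph_feature_table(graph, graph_genes, rank=kg_rank,
                                iterations=kg_iterations, seed=seed)
    blocks.append((gfeat.reindex(genes), "graph"))
    blocks.append((literature_feature_table(corpus, genes), "literature"))
    blocks.append((clinical_feature_table(cohort, genes), "clinical"))
    if rnaseq is not None:
        rna = pd.DataFrame(index=pd.Index(genes, name="gene"))
        rna["RNASeq_LFC"] = rnaseq["lfc"].reindex(genes)
        # stored as -log10 p so that larger means more significant
        rna["RNASeq_pval"] = -np.log10(rnaseq["pvalue"].reindex(genes))
        blocks.append((rna, "preclinical"))
    if tractability is not None:
        from .evidence import reverse_tractability

        tr = pd.DataFrame(index=pd.Index(genes, name="gene"))
        for col in ("bucket_ab", "bucket_sm", "bucket_other"):
            tr[col.replace("bucket", "tractability")] = [
                float(reverse_tractability(int(b))) if pd.notna(b) else np.nan
                for b in tractability[col].reindex(genes)
            ]
        blocks.append((tr, "tractability"))
    if essentiality is not None:
        from .evidence import essentiality_flag

        es = pd.DataFrame(index=pd.Index(genes, name="gene"))
        es["nonessential"] = [
            (1.0 if essentiality_flag(float(f)) == "nonessential" else 0.0)
            if pd.notna(f) else np.nan
            for f in essentiality["dependent_fraction"].reindex(genes)
        ]
        blocks.append((es, "essentiality"))

    df = pd.concat([b for b, _ in blocks], axis=1)
    meta = {}
    for block, category in blocks:
        for col in block.columns:
            meta[col] = {"category": category, "description": ""}
    return FeatureTable(df=df, feature_meta=meta)


def simulate_all(spec: SyntheticSpec) -> dict:
    """Generate every pipeline input plus ground-truth sidecars."""
    screens = generate_screen(spec)
    graph, kg_truth = generate_kg(spec)
    corpus, corpus_truth = generate_corpus(spec)
    cohort, cohort_truth = generate_cohort(spec)
    rnaseq = generate_rnaseq(spec)
    tractability = generate_tractability(spec)
    essentiality = generate_essentiality(spec)
    return {
        "screens": screens,
        "graph": graph,
        "corpus": corpus,
        "cohort": cohort,
        "rnaseq": rnaseq,
        "tractability": tractability,
        "essentiality": essentiality,
        "truth": {
            "planted_genes": spec.planted_genes,
            "kg": kg_truth,
            "corpus": corpus_truth,
            "cohort": cohort_truth,
            "seed": spec.seed,
        },
    }


def write_fixture_dir(spec: SyntheticSpec, outdir: str | Path,
                      force: bool = False) -> None:
    """Write all fixture files plus sidecars and a manifest to a directory."""
    from . import __version__
    from .evidence import write_cohort, write_corpus
    from .kg import write_graph
    from .screen import write_comparison_table

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is non-empty (use force to overwrite)")
    (outdir / "screens").mkdir(parents=True, exist_ok=True)
    data = simulate_all(spec)
    for t in data["screens"]:
        name = f"{t.condition.label.replace('|', '_')}_{t.comparison}.tsv"
        write_comparison_table(t, outdir / "screens" / name)
    write_graph(data["graph"], outdir / "kg.tsv", outdir / "kg_nodes.tsv")
    write_corpus(data["corpus"], outdir / "corpus.jsonl")
    write_cohort(data["cohort"], outdir / "cohort.tsv")
    for key in ("rnaseq", "tractability", "essentiality"):
        df = data[key].copy()
        df.insert(0, "gene", df.index)
        df.to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(data["truth"], indent=2))
    manifest = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "n_planted": spec.n_planted,
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
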