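"""Literature, clinical, tractability, and essentiality evidence features.

Literature support is abstracted as a corpus of documents with pre-extracted
entity mention sets: co-mention counts of a gene with key terms (EGFR,
NSCLC), per-gene normalized frequencies, and a gene co-occurrence matrix.
Clinical evidence is a per-trial enrichment of genetic alterations in
non-responders versus responders (responder = RECIST CR/PR and PFS > 6
months). Tractability buckets are reversed so the most druggable bucket
scores highest; a gene is flagged essential when at least 90% of assayed
cell lines depend on it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

RECIST_CLASSES = ("CR", "PR", "SD", "PD")
RESPONDER_PFS_MONTHS = 6.0
ESSENTIALITY_THRESHOLD = 0.9
DEFAULT_MAX_BUCKET = 10
DEFAULT_PSEUDOCOUNT = 0.01


@dataclasses.dataclass
class Document:
    doc_id: str
    year: int
    mentions: frozenset[str]


@dataclasses.dataclass
class Corpus:
    """Documents with entity mention sets (genes and key terms)."""

    documents: list[Document]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_ids in corpus")

    def __len__(self) -> int:
        return len(self.documents)

    def filter_years(self, start: int, end: int) -> "Corpus":
        return Corpus([d for d in self.documents if start <= d.year <= end])


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus: one {doc_id, year, mentions: [...]} per line."""
    docs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(
                Document(
                    doc_id=str(rec["doc_id"]),
                    year=int(rec["year"]),
                    mentions=frozenset(rec["mentions"]),
                )
            )
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in corpus.documents:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "year": d.year,
                     "mentions": sorted(d.mentions)}
                )
                + "\n"
            )


def comention_count(corpus: Corpus, gene: str, term: str) -> int:
    """Number of documents mentioning both ``gene`` and ``term``."""
    return sum(1 for d in corpus.documents
               if gene in d.mentions and term in d.mentions)


def normalized_comention(corpus: Corpus, gene: str, term: str) -> float:
    """Co-mention count divided by the gene's total document count.

    Normalizes away the huge differences in per-gene publication volume;
    0 by convention for genes never mentioned.
    """
    total = sum(1 for d in corpus.documents if gene in d.mentions)
    if total == 0:
        return 0.0
    return comention_count(corpus, gene, term) / total


def cooccurrence_matrix(corpus: Corpus, genes: list[str]) -> pd.DataFrame:
    """Symmetric gene x gene document co-mention counts; diagonal = per-gene count."""
    if not genes:
        raise ValueError("genes list must be non-empty")
    n = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    M = np.zeros((n, n), dtype=int)
    for d in corpus.documents:
        present = sorted(m for m in d.mentions if m in gi)
        for a in present:
            ia = gi[a]
            M[ia, ia] += 1
            for b in present:
                if b > a:
                    M[ia, gi[b]] += 1
                    M[gi[b], ia] += 1
    return pd.DataFrame(M, index=genes, columns=genes)


def literature_feature_table(corpus: Corpus, genes: Iterable[str],
                             terms: Iterable[str] = ("EGFR", "NSCLC")
                             ) -> pd.DataFrame:
    """Per-gene co-mention counts and normalized frequencies per key term."""
    genes = list(genes)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for term in terms:
        out[f"lit_{term}"] = [
            float(comention_count(corpus, g, term)) for g in genes
        ]
        out[f"lit_{term}_norm"] = [
            normalized_comention(corpus, g, term) for g in genes
        ]
    return out


# ---------------------------------------------------------------------------
# clinical cohort


@dataclasses.dataclass
class Patient:
    patient_id: str
    trial: str
    recist: Literal["CR", "PR", "SD", "PD"]
    pfs_months: float
    alterations: frozenset[str]


@dataclasses.dataclass
class ClinicalCohort:
    patients: list[Patient]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.patients:
            key = (p.trial, p.patient_id)
            if key in seen:
                raise ValueError(f"duplicate patient {p.patient_id!r} in {p.trial!r}")
            seen.add(key)
            if p.pfs_months < 0:
                raise ValueError("pfs_months must be >= 0")
            if p.recist not in RECIST_CLASSES:
                raise ValueError(f"unknown RECIST class {p.recist!r}")

    @property
    def trials(self) -> list[str]:
        return sorted({p.trial for p in self.patients})


def read_cohort(path: str | Path) -> ClinicalCohort:
    """Read a cohort TSV: patient_id, trial, recist, pfs_months, altered_genes."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patients = []
    for _, r in df.iterrows():
        alts = frozenset(
            g for g in str(r["altered_genes"]).split(";") if g
        )
        patients.append(
            Patient(
                patient_id=r["patient_id"], trial=r["trial"],
                recist=r["recist"], pfs_months=float(r["pfs_months"]),
                alterations=alts,
            )
        )
    return ClinicalCohort(patients)


def write_cohort(cohort: ClinicalCohort, path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id, "trial": p.trial, "recist": p.recist,
            "pfs_months": p.pfs_months,
            "altered_genes": ";".join(sorted(p.alterations)),
        }
        for p in cohort.patients
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_responder(recist: str, pfs_months: float) -> str:
    """Responder iff RECIST CR or PR AND progression-free survival > 6 months."""
    if recist not in RECIST_CLASSES:
        raise ValueError(f"unknown RECIST class {recist!r}")
    if pfs_months < 0:
        raise ValueError("pfs_months must be >= 0")
    if recist in ("CR", "PR") and pfs_months > RESPONDER_PFS_MONTHS:
        return "responder"
    return "non_responder"


def clinical_enrichment(cohort: ClinicalCohort, gene: str,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT
                        ) -> dict[str, dict]:
    """Per-trial enrichment of a gene's alterations in non-responders.

    score = log2((prev_nonresp + eps) / (prev_resp + eps)) with prev the
    altered fraction of each response group; positive scores mean the
    alteration is enriched among non-responders (a resistance signal).
    Trials lacking a responder or non-responder get score None (missing).
    The raw 2x2 counts are always returned alongside the score.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out: dict[str, dict] = {}
    for trial in cohort.trials:
        pts = [p for p in cohort.patients if p.trial == trial]
        resp = [p for p in pts
                if classify_responder(p.recist, p.pfs_months) == "responder"]
        nonresp = [p for p in pts
                   if classify_responder(p.recist, p.pfs_months) == "non_responder"]
        alt_resp = sum(1 for p in resp if gene in p.alterations)
        alt_nonresp = sum(1 for p in nonresp if gene in p.alterations)
        counts = {
            "n_responders": len(resp), "n_nonresponders": len(nonresp),
            "altered_responders": alt_resp, "altered_nonresponders": alt_nonresp,
        }
        if not resp or not nonresp:
            out[trial] = {"score": None, **counts}
            continue
        prev_r = alt_resp / len(resp)
        prev_n = alt_nonresp / len(nonresp)
        num = prev_n + pseudocount
        den = prev_r + pseudocount
        if num == 0 and den == 0:
            score = 0.0
        elif den == 0:
            score = math.inf
        elif num == 0:
            score = -math.inf
        else:
            score = math.log2(num / den)
        out[trial] = {"score": score, **counts}
    return out


def clinical_feature_table(cohort: ClinicalCohort, genes: Iterable[str],
                           pseudocount: float = DEFAULT_PSEUDOCOUNT
                           ) -> pd.DataFrame:
    """Per-gene, per-trial enrichment scores as columns clinical_ES1..ESk.

    Trials are numbered in sorted-name order; missing scores become NaN.
    """
    genes = list(genes)
    trials = ClinicalCohort(cohort.patients).trials
    cols = {f"clinical_ES{i + 1}": [] for i in range(len(trials))}
    for g in genes:
        enr = clinical_enrichment(cohort, g, pseudocount=pseudocount)
        for i, trial in enumerate(trials):
            s = enr[trial]["score"]
            cols[f"clinical_ES{i + 1}"].append(np.nan if s is None else s)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# tractability and essentiality


def reverse_tractability(bucket: int, max_bucket: int = DEFAULT_MAX_BUCKET) -> int:
    """Reverse an ordinal tractability bucket so bucket 1 scores max_bucket.

    Bucket 1 (most druggable) maps to 10 under the default 10-bucket scheme.
    """
    if not 1 <= bucket <= max_bucket:
        raise ValueError(f"bucket must lie in [1, {max_bucket}], got {bucket}")
    return (max_bucket + 1) - bucket


def essentiality_flag(dependent_fraction: float) -> str:
    """'essential' when >= 90% of assayed cell lines depend on the gene."""
    if not 0.0 <= dependent_fraction <= 1.0:
        raise ValueError("dependent_fraction must lie in [0, 1]")
    return ("essential" if dependent_fraction >= ESSENTIALITY_THRESHOLD
            else "nonessential")


def tractability_feature_table(path: str | Path) -> pd.DataFrame:
    """Read per-gene bucket TSV (gene, bucket_ab, bucket_sm, bucket_other)
    and return reversed scores (tractability_ab/sm/other)."""
    df = pd.read_csv(path, sep="\t").set_index("gene")
    out = pd.DataFrame(index=df.index)
    for col in ("bucket_ab", "bucket_sm", "bucket_other"):
        out[col.replace("bucket", "tractability")] = [
            float(reverse_tractability(int(b))) for b in df[col]
        ]
    return out


def essentiality_feature_table(path: str | Path) -> pd.DataFrame:
    """Read per-gene dependency fractions and emit a binary nonessential flag.

    The feature is 1 for nonessential genes (favorable for a drug target)
    and 0 for essential genes.
    """
    df = pd.read_csv(path, sep="\t").set_index("gene")
    out = pd.DataFrame(index=df.index)
    out["nonessential"] = [
        1.0 if essentiality_flag(float(f)) == "nonessential" else 0.0
        for f in df["dependent_fraction"]
    ]
    return out
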