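"""Gene-by-feature matrix, preference configurations, and ranked output.

The feature table is the decision-variable space of the multi-objective
ranking problem: one row per gene, one numeric column per line of evidence
(CRISPR consistency, graph centrality, literature support, clinical
enrichment, tractability, essentiality). A preference selects an ordered
subset of those columns together with an optimization direction for each,
and is the objective vector the Pareto engine optimizes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = frozenset(
    {"crispr", "graph", "literature", "clinical", "preclinical",
     "tractability", "essentiality"}
)

Direction = Literal["maximize", "minimize"]


@dataclasses.dataclass
class FeatureTable:
    """A gene x feature matrix with per-feature metadata.

    Parameters
    ----------
    df
        DataFrame indexed by unique gene identifiers; every column numeric
        (float), NaN marking missing values.
    feature_meta
        Optional mapping feature name -> {"category": ..., "description": ...}.
    """

    df: pd.DataFrame
    feature_meta: dict[str, dict[str, str]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.df.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifier(s): {dupes}")
        if any(g == "" or pd.isna(g) for g in idx):
            raise ValueError("empty gene identifier")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        self.df = self.df.astype(float)
        for name, meta in self.feature_meta.items():
            cat = meta.get("category")
            if cat is not None and cat not in FEATURE_CATEGORIES:
                raise ValueError(f"unknown feature category {cat!r} for {name!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def features(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)


@dataclasses.dataclass
class Preference:
    """An ordered set of (feature, direction) objectives."""

    objectives: list[tuple[str, Direction]]
    name: str = "preference"

    def __post_init__(self) -> None:
        if not self.objectives:
            raise ValueError("preference must contain at least one objective")
        feats = [f for f, _ in self.objectives]
        if len(set(feats)) != len(feats):
            raise ValueError("a feature appears more than once in the preference")
        for f, d in self.objectives:
            if d not in ("maximize", "minimize"):
                raise ValueError(
                    f"unknown direction {d!r} for objective {f!r}; "
                    "expected 'maximize' or 'minimize'"
                )

    @property
    def feature_names(self) -> list[str]:
        return [f for f, _ in self.objectives]

    @property
    def directions(self) -> list[Direction]:
        return [d for _, d in self.objectives]

    def validate_against(self, table: FeatureTable) -> None:
        """Reject objectives absent from the target table before ranking."""
        missing = [f for f in self.feature_names if f not in table.df.columns]
        if missing:
            raise ValueError(
                f"preference {self.name!r} references feature(s) absent from the "
                f"table: {missing}; available: {sorted(table.df.columns)}"
            )


# The ten objectives of the shipped default preference: overall screen
# consistency, RNA-seq effect size and significance, three trial-specific
# clinical enrichment scores, literature co-mentions with the two anchor
# terms, and the two PPI centralities. All treated as higher-is-better
# under the resistance framing (RNASeq_pval is stored as -log10 p).
DEFAULT_OBJECTIVES = [
    "full_screen", "RNASeq_LFC", "clinical_ES1", "clinical_ES2",
    "clinical_ES3", "lit_EGFR", "lit_NSCLC", "pagerank", "betweenness",
    "RNASeq_pval",
]


def default_preference() -> Preference:
    """The shipped default: all ten standard objectives, maximized."""
    return Preference(
        objectives=[(f, "maximize") for f in DEFAULT_OBJECTIVES],
        name="default",
    )


@dataclasses.dataclass
class RankedOutput:
    """Per-gene Pareto level plus the objective values used to produce it."""

    ranking: pd.DataFrame  # index gene; columns: pareto_level + objective columns
    preference: Preference
    excluded: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if "pareto_level" not in self.ranking.columns:
            raise ValueError("ranking must carry a pareto_level column")
        lv = self.ranking["pareto_level"]
        if len(lv) and (lv < 1).any():
            raise ValueError("pareto_level must be >= 1")

    def level(self, n: int) -> list[str]:
        """Genes occupying Pareto level ``n``."""
        return list(self.ranking.index[self.ranking["pareto_level"] == n])

    def write(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        path = Path(path)
        out = self.ranking.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)
        if provenance_path is not None:
            prov = {
                "preference": {
                    "name": self.preference.name,
                    "objectives": [
                        {"feature": f, "direction": d}
                        for f, d in self.preference.objectives
                    ],
                },
                "excluded_genes": self.excluded,
                "n_ranked": int(len(self.ranking)),
            }
            Path(provenance_path).write_text(json.dumps(prov, indent=2))


def read_feature_table(
    path: str | Path, dialect: Literal["csv", "tsv"] = "tsv"
) -> FeatureTable:
    """Read a gene x feature table from TSV (canonical) or CSV.

    First column is the gene identifier; empty cells become NaN (missing).
    Duplicate genes or non-numeric cells are hard errors naming the culprit.
    """
    sep = "\t" if dialect == "tsv" else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: no columns")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene {dup.iloc[0]!r}")
    data = {}
    for col in raw.columns[1:]:
        vals = []
        for i, cell in enumerate(raw[col]):
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, "
                    f"row {i + 2}"
                ) from None
        data[col] = vals
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return FeatureTable(df=df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a TSV with the gene column first; missing values as empty cells."""
    out = table.df.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_preference(path: str | Path) -> Preference:
    """Read a preference from YAML or JSON.

    Expected shape::

        name: my_pref
        objectives:
          - {feature: pagerank, direction: maximize}
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict) or "objectives" not in doc:
        raise ValueError(f"{path}: expected mapping with an 'objectives' list")
    objs = doc["objectives"]
    if not isinstance(objs, list) or not objs:
        raise ValueError(f"{path}: 'objectives' must be a non-empty list")
    parsed: list[tuple[str, Direction]] = []
    for o in objs:
        if not isinstance(o, dict) or "feature" not in o or "direction" not in o:
            raise ValueError(f"{path}: each objective needs 'feature' and 'direction'")
        parsed.append((str(o["feature"]), o["direction"]))
    return Preference(objectives=parsed, name=str(doc.get("name", Path(path).stem)))


def write_preference(pref: Preference, path: str | Path) -> None:
    doc = {
        "name": pref.name,
        "objectives": [{"feature": f, "direction": d} for f, d in pref.objectives],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
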