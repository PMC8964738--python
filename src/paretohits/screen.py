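"""Desirability scoring and hit calling for pooled CRISPR screen comparisons.

Each screen condition (cell line x treatment x technology) yields pairwise
comparisons between arms — control vs treated (CvT), control vs plasmid
(CvP), treated vs plasmid (TvP). Per-gene statistics from those comparisons
(log2 fold-change, p-value, FDR, an upstream essentiality call) are mapped
onto the [0, 1] desirability scale by four partial-desirability rules and
aggregated by a weighted geometric mean into a single overall score. Genes
passing the overall-desirability and positive-FDR thresholds are hits; hit
patterns across conditions are summarized into seven consistency features.

The partial rules (resistance direction):

* FDR step: 0 above the 0.1 cut-off, 1 at or below it.
* p-value curve: floor 0.01 above p = 0.1, saturating at 1 for p <= 1e-4,
  a power curve on the -log10 axis in between.
* Effect size step: 1 at or above the distribution-derived boundary
  (mean LFC + 3 sd), 0.01 below.
* Essentiality veto: 0 for genes essential in both CvP and CvT, or with
  negative CvT LFC; such enrichments are artifacts of slow-dying essential
  knockouts, not resistance.

Sensitivity scoring uses the FDR and p-value rules plus the mirrored
effect-size rule (1 at or below mean - 3 sd).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Mode = Literal["resistance", "sensitivity"]
Technology = Literal["KO", "activation"]

#: Partial-desirability and hit-calling thresholds.
FDR_CUTOFF = 0.1
PVALUE_FLOOR_CUTOFF = 0.1
PVALUE_SATURATION = 1e-4
LFC_SD_MULTIPLE = 3.0
HIT_DESI_THRESHOLD = 0.7
HIT_POSFDR_THRESHOLD = 0.1


@dataclasses.dataclass(frozen=True)
class Condition:
    cell_line: str
    treatment: str
    technology: Technology

    @property
    def label(self) -> str:
        return f"{self.cell_line}|{self.treatment}|{self.technology}"


@dataclasses.dataclass
class ScreenComparisonTable:
    """Per-gene statistics for one comparison arm of one screen condition.

    ``rows`` carries columns gene, lfc, pvalue, fdr, essential_flag.
    """

    condition: Condition
    comparison: Literal["TvC", "CvT", "CvP", "TvP"]
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "lfc", "pvalue", "fdr", "essential_flag"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"comparison table missing columns {sorted(missing)}")
        if self.rows["gene"].duplicated().any():
            dup = self.rows.loc[self.rows["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene {dup!r} in comparison table")
        for col in ("pvalue", "fdr"):
            v = self.rows[col].to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any() or np.isnan(v).any():
                raise ValueError(f"{col} values must lie in [0, 1]")
        if not np.isfinite(self.rows["lfc"].to_numpy(dtype=float)).all():
            raise ValueError("lfc values must be finite")

    def indexed(self) -> pd.DataFrame:
        return self.rows.set_index("gene")


def read_comparison_table(path, dialect: str = "tsv") -> ScreenComparisonTable:
    """Read a comparison TSV with in-file condition metadata columns.

    Expected columns: gene, lfc, pvalue, fdr, essential_flag, cell_line,
    treatment, technology, comparison (metadata constant per file).
    """
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    meta_cols = ["cell_line", "treatment", "technology", "comparison"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    for c in meta_cols:
        if df[c].nunique() != 1:
            raise ValueError(f"{path}: metadata column {c!r} is not constant")
    cond = Condition(
        cell_line=str(df["cell_line"].iloc[0]),
        treatment=str(df["treatment"].iloc[0]),
        technology=str(df["technology"].iloc[0]),
    )
    comparison = str(df["comparison"].iloc[0])
    rows = df.drop(columns=meta_cols).copy()
    rows["essential_flag"] = rows["essential_flag"].astype(bool)
    return ScreenComparisonTable(condition=cond, comparison=comparison, rows=rows)


def write_comparison_table(table: ScreenComparisonTable, path) -> None:
    out = table.rows.copy()
    out["cell_line"] = table.condition.cell_line
    out["treatment"] = table.condition.treatment
    out["technology"] = table.condition.technology
    out["comparison"] = table.comparison
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# partial desirabilities


def d_fdr(fdr: float) -> float:
    """FDR step rule: 0 above the 0.1 cut-off, 1 at or below it."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError(f"fdr must lie in [0, 1], got {fdr}")
    return 0.0 if fdr > FDR_CUTOFF else 1.0


def d_pvalue(p: float, shape: float = 2.0) -> float:
    """p-value curve: 0.01 floor above 0.1, 1 at or below 1e-4.

    In between, a power interpolation on the -log10 axis:
    d = 0.01 + 0.99 * t**shape with t the fractional position between
    log10(0.1) and log10(1e-4). ``shape`` >= 1 controls how "rapidly" the
    curve rises toward 1.
    """
    if p <= 0 or p > 1:
        raise ValueError(f"p-value must lie in (0, 1], got {p}")
    if shape < 1:
        raise ValueError("shape exponent must be >= 1")
    if p > PVALUE_FLOOR_CUTOFF:
        return 0.01
    if p <= PVALUE_SATURATION:
        return 1.0
    span = np.log10(PVALUE_FLOOR_CUTOFF) - np.log10(PVALUE_SATURATION)
    t = (np.log10(PVALUE_FLOOR_CUTOFF) - np.log10(p)) / span
    return float(0.01 + 0.99 * t**shape)


def lfc_boundary(lfcs: Iterable[float], mode: Mode = "resistance") -> float:
    """Distribution-derived effect-size boundary: mean +/- 3 sample sd."""
    v = np.asarray(list(lfcs), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 LFC values to derive a boundary")
    if not np.isfinite(v).all():
        raise ValueError("LFC values must be finite")
    sd = float(np.std(v, ddof=1))
    mean = float(np.mean(v))
    if mode == "resistance":
        return mean + LFC_SD_MULTIPLE * sd
    if mode == "sensitivity":
        return mean - LFC_SD_MULTIPLE * sd
    raise ValueError(f"unknown mode {mode!r}")


def d_lfc(lfc: float, boundary: float, mode: Mode = "resistance") -> float:
    """Effect-size step: 1 on the favorable side of the boundary, else 0.01.

    Equality with the boundary takes the favorable branch.
    """
    if not (np.isfinite(lfc) and np.isfinite(boundary)):
        raise ValueError("lfc and boundary must be finite")
    if mode == "resistance":
        return 1.0 if lfc >= boundary else 0.01
    if mode == "sensitivity":
        return 1.0 if lfc <= boundary else 0.01
    raise ValueError(f"unknown mode {mode!r}")


def d_lfc_smooth(lfc: float, boundary: float, mode: Mode = "resistance",
                 steepness: float = 10.0) -> float:
    """Logistic variant of the effect-size rule (optional smoothing)."""
    sgn = 1.0 if mode == "resistance" else -1.0
    z = sgn * steepness * (lfc - boundary)
    return float(0.01 + 0.99 / (1.0 + np.exp(-z)))


def d_essentiality(gene: str, cvp_essential: bool, cvt_essential: bool,
                   cvt_lfc: float) -> float:
    """Essentiality veto: 0 if essential in both CvP and CvT, or CvT LFC < 0."""
    if (cvp_essential and cvt_essential) or cvt_lfc < 0:
        return 0.0
    return 1.0


def aggregate_desirability(components: Iterable[float],
                           weights: Iterable[float] | None = None) -> float:
    """Weighted geometric mean of partial desirabilities: (prod d_i^w_i)^(1/sum w).

    Any zero component annihilates the aggregate.
    """
    d = np.asarray(list(components), dtype=float)
    if d.size == 0:
        raise ValueError("no components to aggregate")
    if ((d < 0) | (d > 1)).any():
        raise ValueError("components must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(d)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != d.shape:
            raise ValueError("weights and components length mismatch")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    if (d == 0).any():
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


@dataclasses.dataclass
class DesirabilityResult:
    """Per-gene partial and overall desirabilities for one condition."""

    condition: Condition
    mode: Mode
    table: pd.DataFrame  # index gene; d_fdr, d_pvalue, d_lfc, d_essentiality, overall

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)


def overall_desirability(cvt: ScreenComparisonTable,
                         cvp: ScreenComparisonTable | None = None,
                         mode: Mode = "resistance",
                         shape: float = 2.0) -> DesirabilityResult:
    """Score every gene of a condition by aggregating the partial rules.

    The effect-size boundary is derived from the CvT LFC distribution. In
    resistance mode the essentiality veto consumes the CvP and CvT
    essentiality flags (so ``cvp`` is required); sensitivity mode uses only
    the FDR, p-value, and mirrored effect-size rules. Gene universes are
    inner-joined with a warning when they differ.
    """
    cvt_idx = cvt.indexed()
    if mode == "resistance":
        if cvp is None:
            raise ValueError("resistance mode requires the CvP comparison")
        cvp_idx = cvp.indexed()
        common = cvt_idx.index.intersection(cvp_idx.index)
        if len(common) == 0:
            raise ValueError("CvT and CvP share no genes")
        if len(common) < len(cvt_idx) or len(common) < len(cvp_idx):
            logger.warning(
                "CvT and CvP gene universes differ; inner join keeps %d genes",
                len(common),
            )
        cvt_idx = cvt_idx.loc[common]
        cvp_idx = cvp_idx.loc[common]
    boundary = lfc_boundary(cvt_idx["lfc"], mode=mode)
    rows = {}
    for gene, r in cvt_idx.iterrows():
        dd = {
            "d_fdr": d_fdr(float(r["fdr"])),
            "d_pvalue": d_pvalue(float(r["pvalue"]), shape=shape),
            "d_lfc": d_lfc(float(r["lfc"]), boundary, mode=mode),
        }
        if mode == "resistance":
            dd["d_essentiality"] = d_essentiality(
                gene,
                bool(cvp_idx.loc[gene, "essential_flag"]),
                bool(r["essential_flag"]),
                float(r["lfc"]),
            )
            comps = [dd["d_fdr"], dd["d_pvalue"], dd["d_lfc"], dd["d_essentiality"]]
        else:
            dd["d_essentiality"] = np.nan
            comps = [dd["d_fdr"], dd["d_pvalue"], dd["d_lfc"]]
        dd["overall"] = aggregate_desirability(comps)
        rows[gene] = dd
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return DesirabilityResult(condition=cvt.condition, mode=mode, table=table)


# ---------------------------------------------------------------------------
# hit calling and consistency features


def call_hit(overall_desi: float, pos_fdr: float) -> bool:
    """Hit iff overall desirability > 0.7 AND positive-selection FDR < 0.1."""
    if not (0.0 <= overall_desi <= 1.0 and 0.0 <= pos_fdr <= 1.0):
        raise ValueError("inputs must lie in [0, 1]")
    return overall_desi > HIT_DESI_THRESHOLD and pos_fdr < HIT_POSFDR_THRESHOLD


@dataclasses.dataclass
class HitMatrix:
    """Boolean gene x condition hit calls with per-column condition metadata."""

    calls: pd.DataFrame  # bool; columns are condition labels
    conditions: dict[str, Condition]  # label -> Condition

    def __post_init__(self) -> None:
        if self.calls.columns.has_duplicates:
            raise ValueError("duplicate condition labels")
        missing = set(self.calls.columns) - set(self.conditions)
        if missing:
            raise ValueError(
                f"columns missing condition annotation: {sorted(missing)}"
            )
        self.calls = self.calls.astype(bool)


def build_hit_matrix(results: Iterable[DesirabilityResult],
                     pos_fdr: dict[str, pd.Series]) -> HitMatrix:
    """Assemble a HitMatrix from per-condition desirabilities and posFDR.

    ``pos_fdr`` maps condition labels to per-gene positive-selection FDR
    (in practice the CvT FDR restricted to positively selected genes).
    """
    cols = {}
    conditions = {}
    for res in results:
        label = res.condition.label
        fdr = pos_fdr[label]
        common = res.table.index.intersection(fdr.index)
        calls = pd.Series(False, index=res.table.index)
        calls.loc[common] = [
            call_hit(res.table.loc[g, "overall"], float(fdr.loc[g])) for g in common
        ]
        cols[label] = calls
        conditions[label] = res.condition
    return HitMatrix(calls=pd.DataFrame(cols).fillna(False), conditions=conditions)


CONSISTENCY_FEATURES = [
    "KO_n_conditions_hit", "KO_n_cell_lines_hit", "KO_n_treatments_hit",
    "activation_n_conditions_hit", "activation_n_cell_lines_hit",
    "activation_n_treatments_hit", "full_screen",
]


def consistency_features(hits: HitMatrix) -> pd.DataFrame:
    """The seven consistency features summarizing hit stability.

    Per technology (KO, activation): number of conditions hit, number of
    distinct cell lines hit, number of distinct treatments hit; plus
    ``full_screen`` — the number of distinct cell lines where the gene is a
    hit in either technology.
    """
    out = pd.DataFrame(0, index=hits.calls.index, columns=CONSISTENCY_FEATURES)
    by_tech: dict[str, list[str]] = {"KO": [], "activation": []}
    for label, cond in hits.conditions.items():
        if cond.technology not in by_tech:
            raise ValueError(
                f"condition {label!r} has unknown technology {cond.technology!r}"
            )
        by_tech[cond.technology].append(label)
    for gene in hits.calls.index:
        row = hits.calls.loc[gene]
        all_cell_lines: set[str] = set()
        for tech, labels in by_tech.items():
            hit_labels = [lb for lb in labels if row[lb]]
            cls = {hits.conditions[lb].cell_line for lb in hit_labels}
            trts = {hits.conditions[lb].treatment for lb in hit_labels}
            out.loc[gene, f"{tech}_n_conditions_hit"] = len(hit_labels)
            out.loc[gene, f"{tech}_n_cell_lines_hit"] = len(cls)
            out.loc[gene, f"{tech}_n_treatments_hit"] = len(trts)
            all_cell_lines |= cls
        out.loc[gene, "full_screen"] = len(all_cell_lines)
    out.index.name = "gene"
    return out
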