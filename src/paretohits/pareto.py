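"""Pareto dominance, front extraction, level assignment, and ranking.

A gene's objective vector x1 dominates x2 when x1 is at least as good on
every objective (respecting each objective's direction) and strictly
better on at least one. The set of mutually non-dominated vectors is the
Pareto front (level 1); peeling fronts iteratively assigns every gene a
Pareto level. Ranking a feature table under a preference returns genes
ordered by level, with a deterministic within-level order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, Preference, RankedOutput

logger = logging.getLogger(__name__)


def _oriented(values: np.ndarray, pref: Preference) -> np.ndarray:
    """Flip minimized columns so that larger is always better."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != len(pref.objectives):
        raise ValueError(
            f"objective matrix has {v.shape[1] if v.ndim == 2 else '?'} columns; "
            f"preference has {len(pref.objectives)} objectives"
        )
    signs = np.array([1.0 if d == "maximize" else -1.0 for d in pref.directions])
    return v * signs


def dominates(a, b, pref: Preference) -> bool:
    """True iff vector ``a`` Pareto-dominates ``b`` under the preference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (len(pref.objectives),) or b.shape != (len(pref.objectives),):
        raise ValueError("vector length must equal the preference's objective count")
    oa = _oriented(a[None, :], pref)[0]
    ob = _oriented(b[None, :], pref)[0]
    return bool(np.all(oa >= ob) and np.any(oa > ob))


def _front_mask(oriented: np.ndarray) -> np.ndarray:
    """Non-dominated mask by vectorized linear-scan peeling.

    Each candidate is compared against the current survivor set in one
    broadcast; a candidate dominated by any survivor is dropped. Single
    objective reduces to the argmax set.
    """
    n, k = oriented.shape
    if n == 0:
        return np.zeros(0, dtype=bool)
    if k == 1:
        return oriented[:, 0] == oriented[:, 0].max()
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        others = oriented[mask]
        ge = (others >= oriented[i]).all(axis=1)
        gt = (others > oriented[i]).any(axis=1)
        if (ge & gt).any():
            mask[i] = False
    return mask


def pareto_front(values, pref: Preference, genes: list[str] | None = None
                 ) -> set[str] | np.ndarray:
    """The maximal non-dominated subset of the given objective vectors.

    With ``genes`` supplied, returns the set of gene ids on the front;
    otherwise the boolean membership mask over rows.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    oriented = _oriented(v, pref)
    mask = _front_mask(oriented)
    if genes is None:
        return mask
    return {g for g, m in zip(genes, mask) if m}


def pareto_levels(values, pref: Preference) -> np.ndarray:
    """Assign every vector a Pareto level by iterative front peeling."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    oriented = _oriented(v, pref)
    n = oriented.shape[0]
    levels = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    level = 0
    while remaining.size:
        level += 1
        mask = _front_mask(oriented[remaining])
        levels[remaining[mask]] = level
        remaining = remaining[~mask]
    return levels


def rank(table: FeatureTable, pref: Preference,
         sort_within: list[str] | None = None,
         impute_worst: bool = False) -> RankedOutput:
    """Rank a feature table under a preference.

    Genes missing any selected objective are excluded with a logged warning
    (dominance is undefined on missing coordinates); ``impute_worst=True``
    instead fills each gene's missing objectives with the worst observed
    value of that objective. Output is ordered by Pareto level, then by the
    ``sort_within`` features (direction-corrected, best first), then gene id.
    """
    pref.validate_against(table)
    sub = table.df[pref.feature_names].copy()
    excluded: dict[str, str] = {}
    if impute_worst:
        for (feat, direction) in pref.objectives:
            col = sub[feat]
            if col.isna().all():
                raise ValueError(f"objective {feat!r} has no observed values")
            worst = col.min() if direction == "maximize" else col.max()
            sub[feat] = col.fillna(worst)
    incomplete = sub.isna().any(axis=1)
    for g in sub.index[incomplete]:
        miss = [c for c in sub.columns if pd.isna(sub.loc[g, c])]
        excluded[g] = f"missing objective(s): {', '.join(miss)}"
    if excluded:
        logger.warning("excluded %d gene(s) with missing objectives", len(excluded))
    sub = sub[~incomplete]
    if sub.empty:
        raise ValueError("no gene has complete values for all selected objectives")
    levels = pareto_levels(sub.to_numpy(), pref)
    out = sub.copy()
    out.insert(0, "pareto_level", levels)

    sort_cols = ["pareto_level"]
    ascending = [True]
    if sort_within:
        dir_map = dict(pref.objectives)
        for feat in sort_within:
            if feat not in out.columns:
                if feat in table.df.columns:
                    out[feat] = table.df[feat].reindex(out.index)
                else:
                    raise ValueError(f"sort_within feature {feat!r} unknown")
            sort_cols.append(feat)
            # best-first: descending for maximize, ascending for minimize
            ascending.append(dir_map.get(feat, "maximize") == "minimize")
    out = out.reset_index(names="gene").sort_values(
        sort_cols + ["gene"], ascending=ascending + [True], kind="mergesort"
    ).set_index("gene")
    return RankedOutput(ranking=out, preference=pref, excluded=excluded)
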