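"""GO-term enrichment and the module-vs-DET enrichment z-score.

Two layers of enrichment are used by the pipeline.  First, classical
hypergeometric over-representation of a gene set against an annotation
universe, BH-corrected and filtered at a strict FDR (default 1e-4).
Second, a continuity-corrected binomial z-score comparing a GO term's
frequency inside one module group of size n against its frequency B/N
among all N differential transcripts:

    z = (x - 0.5 - B * n / N) / sqrt(n * (B / N) * (1 - B / N) * c)

with x the term's count inside the group and c a variance factor
(default 1; an alternative reading of the score doubles the variance, see
``variance_factor``).  A term counts as enriched in a group when its FDR
passes the filter and z > 2.  Module combinations are enumerated as unions,
and each term is credited to the single group where its z is highest.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    gene_set: Iterable[str],
    term_map: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_set`` in each term.

    Terms are intersected with the universe; terms with zero overlap with
    the gene set are excluded from testing.  Columns: term, x (overlap),
    term_size (successes in universe), set_size (draws), universe_size,
    p, fdr.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty universe")
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")

    N_u, n_draw = len(universe), len(gene_set)
    rows = []
    for term, genes in term_map.items():
        K = len(genes & universe)
        x = len(genes & gene_set)
        if x == 0:
            continue
        p = float(hypergeom.sf(x - 1, N_u, K, n_draw))
        rows.append((term, x, K, n_draw, N_u, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "x", "term_size", "set_size", "universe_size", "p"])
    df["fdr"] = bh_adjust(df["p"]) if len(df) else []
    return df


def filter_terms(records: pd.DataFrame, fdr_max: float = 1e-4) -> pd.DataFrame:
    """Keep records with fdr strictly below ``fdr_max`` (input order kept)."""
    return records.loc[records["fdr"] < fdr_max].reset_index(drop=True)


def module_term_zscore(x: float, B: float, n: float, N: float, variance_factor: float = 1.0) -> float:
    """Continuity-corrected z for a term seen x times in a module group of
    size n versus B times among the N differential transcripts."""
    if not (0 < B < N):
        raise ValueError("need 0 < B < N for a defined variance")
    if n > N or x > min(n, B):
        raise ValueError("inconsistent counts: need x <= min(n, B) and n <= N")
    q = B / N
    return (x - 0.5 - q * n) / math.sqrt(n * q * (1 - q) * variance_factor)


def enumerate_module_groups(
    module_sets: Mapping[int, set[str]], selected: Sequence[int]
) -> dict[str, set[str]]:
    """All non-empty subsets of the selected modules, named "[i;j;...]",
    each mapped to the union of its modules' transcripts."""
    if len(set(selected)) != len(selected):
        raise ValueError("duplicate module ids")
    if not (1 <= len(selected) <= 6):
        raise ValueError("select between 1 and 6 modules")
    groups: dict[str, set[str]] = {}
    ordered = sorted(selected)
    for r in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, r):
            name = "[" + ";".join(str(i) for i in combo) + "]"
            union: set[str] = set()
            for i in combo:
                union |= module_sets[i]
            groups[name] = union
    return groups


def module_group_enrichment(
    group_sets: Mapping[str, set[str]],
    det_set: set[str],
    term_map: Mapping[str, set[str]],
    fdr_max: float = 1e-4,
    z_min: float = 2.0,
    variance_factor: float = 1.0,
) -> pd.DataFrame:
    """Score every (group, term) pair against the DET universe.

    The universe is the DET list itself (N = number of DETs, B = the term's
    count among DETs), so both the hypergeometric FDR and the z-score ask
    whether a group concentrates the term beyond its DET-wide frequency.
    Returns one row per tested pair with an ``enriched`` flag
    (fdr < fdr_max and z > z_min).
    """
    N = len(det_set)
    frames = []
    for name, genes in group_sets.items():
        genes = set(genes) & det_set
        if not genes:
            continue
        rec = hypergeom_enrich(genes, term_map, det_set)
        if not len(rec):
            continue
        rec.insert(0, "group", name)
        rec["group_size"] = len(genes)
        zs = []
        for _, row in rec.iterrows():
            B = row["term_size"]
            if 0 < B < N:
                zs.append(module_term_zscore(row["x"], B, len(genes), N, variance_factor))
            else:
                zs.append(float("nan"))
        rec["z"] = zs
        frames.append(rec)
    if not frames:
        return pd.DataFrame(
            columns=["group", "term", "x", "term_size", "set_size", "universe_size",
                     "p", "fdr", "group_size", "z", "enriched"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["enriched"] = (out["fdr"] < fdr_max) & (out["z"] > z_min)
    return out


def best_predictor_assignment(records: pd.DataFrame) -> tuple[dict[str, str], pd.Series]:
    """Credit each enriched term to the single group with the highest z.

    Ties break toward the smaller group, then the lexicographically smaller
    group name.  Returns (term -> group, per-group term counts).
    """
    enriched = records.loc[records["enriched"]]
    assignment: dict[str, str] = {}
    for term, sub in enriched.groupby("term"):
        best = sub.sort_values(
            ["z", "group_size", "group"], ascending=[False, True, True], kind="mergesort"
        ).iloc[0]
        assignment[term] = best["group"]
    counts = pd.Series(assignment, dtype=object).value_counts() if assignment else pd.Series(dtype=int)
    return assignment, counts


def rollup_processes(
    terms: Iterable[str], category_map: Mapping[str, str]
) -> tuple[pd.DataFrame, int]:
    """Roll enriched terms up into process categories.

    Returns a (category, count, percentage) table over classified terms —
    percentages sum to 100 — plus the count of unclassified terms.
    """
    terms = list(terms)
    cats = [category_map[t] for t in terms if t in category_map]
    unassigned = len(terms) - len(cats)
    if not cats:
        return pd.DataFrame(columns=["category", "count", "percentage"]), unassigned
    counts = pd.Series(cats).value_counts()
    df = counts.rename_axis("category").reset_index(name="count")
    df["percentage"] = 100.0 * df["count"] / df["count"].sum()
    return df, unassigned
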