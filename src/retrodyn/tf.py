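"""Transcription-factor target-set over-representation among DETs.

Each TF's precomputed target set is tested for over-representation in the
differential (target) gene list against a background list with a one-tailed
Fisher exact test; the F-score is -ln(p).  A continuity-corrected binomial
z-score compares the hit rate in the target list to the background rate:

    z = (hits_t - 0.5 - n_t * p0) / sqrt(n_t * p0 * (1 - p0))

with p0 the background hit rate.  TFs passing the F-score floor are sorted
into five nested groups by |z| (cuts 35 / 25 / 15 / 10 / 2), each group
accumulating the TFs of all stricter cuts.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

DEFAULT_Z_CUTS = (35.0, 25.0, 15.0, 10.0, 2.0)


def f_score_to_p(f_score: float) -> float:
    """Invert F = -ln(p); exp(-20) reproduces the conventional cut's p-value."""
    return math.exp(-f_score)


def tf_overrepresentation(
    target_set: Iterable[str],
    background_set: Iterable[str],
    tf_targets: Mapping[str, set[str]],
    variance_factor: float = 1.0,
) -> pd.DataFrame:
    """Fisher F-score and binomial z-score per TF.

    The 2x2 table crosses (target vs background gene) with (TF target vs
    not); the Fisher p is the one-tailed enrichment probability, i.e. the
    hypergeometric upper tail of the observed target-list hit count.
    Rows where the background rate p0 is degenerate (0 or 1) carry
    ``z_valid = False`` and are excluded from grouping.
    """
    target = set(target_set)
    background = set(background_set)
    if not target or not background:
        raise ValueError("target and background sets must be non-empty")
    if target & background:
        raise ValueError("target and background sets must be disjoint")

    n_t, n_b = len(target), len(background)
    pop = n_t + n_b
    rows = []
    for tf, genes in tf_targets.items():
        hits_t = len(genes & target)
        hits_b = len(genes & background)
        total_hits = hits_t + hits_b
        p = float(hypergeom.sf(hits_t - 1, pop, total_hits, n_t))
        p = min(p, 1.0)
        f = -math.log(p) if p > 0 else math.inf
        p0 = hits_b / n_b
        z_valid = 0.0 < p0 < 1.0
        if z_valid:
            z = (hits_t - 0.5 - n_t * p0) / math.sqrt(n_t * p0 * (1.0 - p0) * variance_factor)
        else:
            z = float("nan")
        rows.append((tf, hits_t, n_t, hits_b, n_b, p, f, z, z_valid))
    return pd.DataFrame(
        rows,
        columns=[
            "tf", "hits_target", "n_target", "hits_bg", "n_bg",
            "fisher_p", "f_score", "z_score", "z_valid",
        ],
    )


def filter_and_group_tfs(
    records: pd.DataFrame,
    f_min: float = 20.0,
    z_cuts: Sequence[float] = DEFAULT_Z_CUTS,
) -> dict[int, list[str]]:
    """Five nested TF groups: group g holds TFs with f_score > f_min
    (strict) and |z| above the g-th cut.  Cuts must be strictly decreasing,
    which makes the nesting structural."""
    cuts = list(z_cuts)
    if any(nxt >= prev for prev, nxt in zip(cuts, cuts[1:])):
        raise ValueError("z_cuts must be strictly decreasing")
    usable = records.loc[records["z_valid"] & (records["f_score"] > f_min)]
    groups: dict[int, list[str]] = {}
    for gi, cut in enumerate(cuts, start=1):
        members = usable.loc[usable["z_score"].abs() > cut, "tf"]
        groups[gi] = sorted(members)
    return groups
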