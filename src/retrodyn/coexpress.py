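"""Signed weighted co-expression networks, TOM clustering and eigengenes.

Differential transcripts are clustered from a signed adjacency
a_ij = ((1 + cor_ij) / 2)^beta, transformed into the topological overlap
measure and hierarchically clustered (average linkage on 1 - TOM) with a
static tree cut; clusters below the minimum size fall into the unassigned
class (label 0).  This approximates the dynamic hybrid tree cut of the
reference workflow with a simpler, deterministic rule.  Each module is
summarized by its eigengene — the first principal component of its
standardized expression, oriented to correlate positively with the module
mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ModulePartition:
    """Transcript -> module labels; 0 is the unassigned (grey) class.

    Modules are numbered 1..m by decreasing size.
    """

    labels: pd.Series
    module_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.module_sizes:
            counts = self.labels.value_counts()
            self.module_sizes = {int(k): int(v) for k, v in counts.items() if k != 0}

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def members(self, module: int) -> set[str]:
        return set(self.labels.index[self.labels == module])

    def module_sets(self) -> dict[int, set[str]]:
        return {m: self.members(m) for m in self.module_sizes}

    def unassigned_fraction(self) -> float:
        """Percentage of transcripts left in the unassigned class."""
        return 100.0 * float((self.labels == 0).sum()) / len(self.labels)


@dataclass
class SoftThresholdResult:
    beta: int
    fit_r2: dict[int, float]
    warning: bool  # no candidate met the scale-free fit target


def signed_adjacency(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """a_ij = ((1 + cor_ij) / 2)^beta with unit diagonal; zero-variance
    transcripts get correlation 0 against everything."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(const, 1.0, sd * np.sqrt(X.shape[1]))
    Z = Xc / denom[:, None]
    cor = Z @ Z.T
    cor[const, :] = 0.0
    cor[:, const] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return ((1.0 + cor) / 2.0) ** beta


def _scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) against log10 k over connectivity bins, signed so
    a positive slope (non-scale-free) reports a non-qualifying value."""
    k = adj.sum(axis=0) - 1.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 4:
        raise ValueError("fewer than 4 non-empty connectivity bins")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    r2 = float(r**2)
    return r2 if slope < 0 else -r2


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates: list[int] | None = None,
    fit_target: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Smallest candidate beta whose scale-free fit R^2 (with negative
    slope) reaches ``fit_target``; otherwise the best-fitting candidate with
    a warning flag."""
    if len(expr) < 20:
        raise ValueError("need >= 20 transcripts to assess scale-free fit")
    candidates = list(candidates) if candidates else list(range(1, 31))
    r2s: dict[int, float] = {}
    for beta in candidates:
        adj = signed_adjacency(expr, beta)
        r2s[beta] = _scale_free_r2(adj, n_bins=n_bins)
        if r2s[beta] >= fit_target:
            return SoftThresholdResult(beta=beta, fit_r2=r2s, warning=False)
    best = max(r2s, key=lambda b: r2s[b])
    return SoftThresholdResult(beta=best, fit_r2=r2s, warning=True)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with l_ij the shared-neighbour weight sum and unit diagonal."""
    A = np.asarray(adj, dtype=float)
    k = A.sum(axis=0) - 1.0
    # (A @ A)_ij counts u = i and u = j with the unit diagonal: subtract 2 a_ij
    L = A @ A - 2.0 * A
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    tom = num / np.maximum(den, 1e-12)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    transcript_ids: list[str],
    min_module_size: int = 20,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters below ``min_module_size`` are folded into the unassigned
    class; surviving modules are renumbered by decreasing size (ties by
    first appearance).
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = [int(c) for c in sizes.index if sizes[c] >= min_module_size]
    first_pos = {c: int(np.argmax(raw == c)) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_pos[c]))
    remap = {c: i + 1 for i, c in enumerate(keep)}
    labels = np.array([remap.get(int(c), 0) for c in raw])
    series = pd.Series(labels, index=pd.Index(transcript_ids, name="transcript"), name="module")
    return ModulePartition(labels=series)


def module_eigengenes(
    expr: pd.DataFrame, partition: ModulePartition, groups: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame | None]:
    """First-PC eigengene of every module.

    Expression is standardized per transcript; the eigengene is the leading
    right singular vector over samples, unit norm, sign-fixed so its
    correlation with the module's mean standardized profile is >= 0.
    Returns (eigengenes modules x samples, explained-variance fractions,
    per-group eigengene means if ``groups`` maps samples to time labels).
    """
    eig_rows, var_rows, names = [], [], []
    for module in sorted(partition.module_sizes):
        members = sorted(partition.members(module))
        sub = expr.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        if (sd == 0).all():
            eig_rows.append(np.zeros(expr.shape[1]))
            var_rows.append(0.0)
            names.append(module)
            continue
        sd[sd == 0] = 1.0
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
        if np.dot(v, Z.mean(axis=0)) < 0:
            v = -v
        eig_rows.append(v)
        var_rows.append(float(s[0] ** 2 / np.sum(s**2)))
        names.append(module)
    eig = pd.DataFrame(eig_rows, index=pd.Index(names, name="module"), columns=expr.columns)
    var = pd.Series(var_rows, index=eig.index, name="explained_variance")
    profiles = None
    if groups is not None:
        profiles = eig.T.groupby(groups.loc[eig.columns]).mean().T
        profiles = profiles[list(dict.fromkeys(groups))]
    return eig, var, profiles
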