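"""Time-course differential expression via a simplified NB-GLM LRT.

Counts y_gj are modelled as negative binomial with mean q_{g,time(j)} * s_j
and a per-transcript dispersion alpha (Var = mu + alpha * mu^2).  Size
factors s_j come from the median-of-ratios rule.  The full model fits one
mean per time group, the reduced model one shared mean.  The likelihood
ratio statistic divided by its degrees of freedom (groups - 1) is referred
to an F distribution with (groups - 1, samples - groups) degrees of
freedom — the moment-matched small-sample reference that accounts for the
dispersion being estimated rather than known (the asymptotic chi-square
reference is anticonservative at 8 samples per group) — and BH-corrected
across transcripts.

This is a deliberately simplified test, not a DESeq2 clone: dispersions are
per-transcript Cox-Reid-adjusted profile maximum likelihood estimates
(floored at 1e-8, method-of-moments fallback on failure) with no trend
shrinkage, no outlier handling and no independent filtering.  All-zero
transcripts are dropped before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import f as f_dist, ncf
from sklearn.decomposition import PCA

from .go import bh_adjust

_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 50.0


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median over reference transcripts of
    count / geometric-mean-across-samples; transcripts with a zero anywhere
    are excluded from the reference.  ``pseudo_reference=True`` relaxes that
    by adding a pseudocount of 1 before forming the reference.
    """
    values = counts.to_numpy(dtype=float)
    if pseudo_reference:
        values = values + 1.0
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no transcript is positive in every sample; re-run with "
            "pseudo_reference=True to use a pseudo-reference"
        )
    ref = values[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# vectorized NB fitting


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; y, mu are (G, S), alpha is (G,)."""
    r = 1.0 / alpha[:, None]
    mu = np.maximum(mu, 1e-12)
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)),
        axis=1,
    )


def _fit_means(
    y: np.ndarray, sf: np.ndarray, groups: list[np.ndarray], alpha: np.ndarray, n_iter: int = 30
) -> np.ndarray:
    """MLE of per-group means q given dispersion, by a fixed-point iteration
    on the score equation.  Returns the fitted q as (G, n_groups)."""
    G = y.shape[0]
    q = np.empty((G, len(groups)))
    a = alpha[:, None]
    for gi, cols in enumerate(groups):
        yg = y[:, cols]
        sg = sf[cols][None, :]
        qg = yg.sum(axis=1) / sg.sum()
        qg = np.maximum(qg, 1e-8)
        ysum = yg.sum(axis=1)
        for _ in range(n_iter):
            denom = np.sum((yg + 1.0 / a) * (a * sg) / (1.0 + a * sg * qg[:, None]), axis=1)
            qg_new = ysum / np.maximum(denom, 1e-300)
            qg = np.maximum(qg_new, 1e-8)
        q[:, gi] = qg
    return q


def _cr_penalty(mu: np.ndarray, sf_cols: list[np.ndarray], alpha: np.ndarray) -> np.ndarray:
    """Cox-Reid adjustment 0.5 * log det(X'WX); diagonal for a group-means
    design, with GLM weights w = mu / (1 + alpha * mu)."""
    w = mu / (1.0 + alpha[:, None] * mu)
    pen = np.zeros(mu.shape[0])
    for cols in sf_cols:
        pen += 0.5 * np.log(np.maximum(w[:, cols].sum(axis=1), 1e-300))
    return pen


def _profile_objective(
    y: np.ndarray, sf: np.ndarray, groups: list[np.ndarray], log_alpha: np.ndarray
) -> np.ndarray:
    """Negative CR-adjusted profile log-likelihood of the full model at the
    given per-transcript log dispersion."""
    alpha = np.exp(log_alpha)
    q = _fit_means(y, sf, groups, alpha)
    mu = np.empty_like(y, dtype=float)
    for gi, cols in enumerate(groups):
        mu[:, cols] = q[:, [gi]] * sf[cols][None, :]
    return -(_nb_loglik(y, mu, alpha) - _cr_penalty(mu, groups, alpha))


def _estimate_dispersion(
    y: np.ndarray, sf: np.ndarray, groups: list[np.ndarray], n_iter: int = 45
) -> np.ndarray:
    """Golden-section search on log alpha, vectorized over transcripts."""
    G = y.shape[0]
    lo = np.full(G, np.log(_ALPHA_FLOOR))
    hi = np.full(G, np.log(_ALPHA_CEIL))
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc = _profile_objective(y, sf, groups, c)
    fd = _profile_objective(y, sf, groups, d)
    for _ in range(n_iter):
        left = fc < fd  # minimum lies in [lo, d]
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        d_new = np.where(left, c, lo + invphi * (hi - lo))
        c_new = np.where(left, hi - invphi * (hi - lo), d)
        # exactly one point per transcript is fresh; evaluate it once
        x_eval = np.where(left, c_new, d_new)
        fx = _profile_objective(y, sf, groups, x_eval)
        fc, fd = np.where(left, fx, fd), np.where(left, fc, fx)
        c, d = c_new, d_new
    return np.exp((lo + hi) / 2.0)


def _mom_dispersion(y: np.ndarray, sf: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion from within-group normalized counts."""
    norm = y / sf[None, :]
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for cols in groups:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m**2
    alpha = np.where(den > 0, num / np.maximum(den, 1e-300), _ALPHA_FLOOR)
    return np.clip(alpha, _ALPHA_FLOOR, _ALPHA_CEIL)


@dataclass
class DEResult:
    """LRT table plus bookkeeping from the fit."""

    table: pd.DataFrame           # lrt_stat, df, p, fdr, is_det, mean_<group>..., dispersion
    dropped_all_zero: list[str]   # transcripts excluded before testing
    n_mom_fallback: int


def nb_lrt(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    sf: pd.Series | None = None,
    det_fdr_threshold: float = 0.05,
) -> DEResult:
    """Likelihood-ratio test of time-group means against a shared mean."""
    times = meta.loc[counts.columns, "time"]
    group_labels = list(dict.fromkeys(times))
    if len(group_labels) < 2:
        raise ValueError("need at least 2 time groups")
    groups = [np.flatnonzero((times == g).to_numpy()) for g in group_labels]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 samples per group")
    if sf is None:
        sf = size_factors(counts)
    sfv = sf.loc[counts.columns].to_numpy(dtype=float)

    nz = counts.sum(axis=1) > 0
    dropped = list(counts.index[~nz])
    y = counts.loc[nz].to_numpy(dtype=float)
    ids = counts.index[nz]
    G, S = y.shape
    all_cols = [np.arange(S)]

    alpha = _estimate_dispersion(y, sfv, groups)
    bad = ~np.isfinite(alpha)
    n_fallback = int(bad.sum())
    if n_fallback:
        alpha[bad] = _mom_dispersion(y, sfv, groups)[bad]

    q_full = _fit_means(y, sfv, groups, alpha)
    mu_full = np.empty_like(y)
    for gi, cols in enumerate(groups):
        mu_full[:, cols] = q_full[:, [gi]] * sfv[cols][None, :]
    q_red = _fit_means(y, sfv, all_cols, alpha)
    mu_red = q_red[:, [0]] * sfv[None, :]

    ll_full = _nb_loglik(y, mu_full, alpha)
    ll_red = _nb_loglik(y, mu_red, alpha)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    df = len(groups) - 1
    df_resid = S - len(groups)
    p = f_dist.sf(lrt / df, df, df_resid)
    fdr = bh_adjust(p)

    table = pd.DataFrame(
        {
            "lrt_stat": lrt,
            "df": df,
            "p": p,
            "fdr": fdr,
            "is_det": fdr < det_fdr_threshold,
            "dispersion": alpha,
        },
        index=pd.Index(ids, name="transcript"),
    )
    for gi, g in enumerate(group_labels):
        table[f"mean_{g}"] = q_full[:, gi]
    return DEResult(table=table, dropped_all_zero=dropped, n_mom_fallback=n_fallback)


# ---------------------------------------------------------------------------
# transforms, QC, power


def vst(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Variance-mitigating transform log2(count / sf + 1).

    A monotone stand-in for a full variance-stabilizing transformation —
    adequate for PCA QC and correlation-based clustering, not byte-
    equivalent to any reference tool.
    """
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / sf.loc[counts.columns] + 1.0)


def pca_embedding(expr: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a transcripts x samples expression matrix.

    Transcript means are centred out; returns per-sample scores and the
    explained-variance fractions (non-increasing).
    """
    X = expr.to_numpy(dtype=float).T  # samples x transcripts
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=expr.columns, columns=cols), pca.explained_variance_ratio_


def _anova_power(n: int, effect_f: float, alpha: float, k_groups: int) -> float:
    df1 = k_groups - 1
    df2 = k_groups * n - k_groups
    if df2 < 1:
        return 0.0
    lam = effect_f**2 * k_groups * n
    crit = f_dist.isf(alpha, df1, df2)
    return float(ncf.sf(crit, df1, df2, lam))


def power_sample_size(
    effect_f: float, alpha: float = 0.05, power: float = 0.8, k_groups: int = 3
) -> int:
    """Smallest per-group n with one-way ANOVA power >= target.

    Power uses the noncentral F distribution with df1 = k - 1,
    df2 = k(n - 1) and noncentrality f^2 * k * n.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if k_groups < 2 or effect_f <= 0:
        raise ValueError("need k_groups >= 2 and effect_f > 0")
    n = 2
    if _anova_power(n, effect_f, alpha, k_groups) >= power:
        return n
    hi = 4
    while _anova_power(hi, effect_f, alpha, k_groups) < power:
        hi *= 2
        if hi > 10**6:
            raise ValueError("requested power unreachable within n <= 1e6")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if _anova_power(mid, effect_f, alpha, k_groups) >= power:
            hi = mid
        else:
            lo = mid
    return hi
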