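"""TOM construction, soft-threshold choice, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from retrodyn import coexpress


def _block_expression(sizes, n_samples=24, noise=0.3, seed=0):
    """Blocks of transcripts sharing a latent profile (high within-block
    correlation, mutually decorrelated profiles); returns (DataFrame,
    truth labels)."""
    rng = np.random.default_rng(seed)
    bases, _ = np.linalg.qr(rng.normal(size=(n_samples, len(sizes))))
    rows, labels = [], []
    for bi, size in enumerate(sizes):
        base = bases[:, bi] * np.sqrt(n_samples)
        for _ in range(size):
            rows.append(base + noise * rng.normal(size=n_samples))
            labels.append(bi)
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.array(labels)


class TestAdjacencyTom:
    def test_tom_matches_direct_formula_on_4x4(self):
        expr, _ = _block_expression([2, 2], n_samples=10, noise=0.3, seed=1)
        adj = coexpress.signed_adjacency(expr, beta=6)
        tom = coexpress.tom_similarity(adj)
        n = adj.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
                k_i = adj[i].sum() - 1
                k_j = adj[j].sum() - 1
                expected = (l_ij + adj[i, j]) / (min(k_i, k_j) + 1 - adj[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_transcripts_have_maximal_overlap(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 20))
        X[1] = X[0]
        expr = pd.DataFrame(X)
        tom = coexpress.tom_similarity(coexpress.signed_adjacency(expr, 6))
        row = tom[0].copy()
        row[0] = -1
        assert np.argmax(row) == 1

    def test_uncorrelated_noise_gives_half_power_adjacency(self):
        expr = pd.DataFrame(np.eye(4))  # orthogonal-ish rows
        adj = coexpress.signed_adjacency(expr, beta=2)
        assert np.allclose(np.diag(adj), 1.0)
        tom = coexpress.tom_similarity(adj)
        assert np.allclose(tom, tom.T)
        assert ((tom >= 0) & (tom <= 1)).all()

    def test_constant_transcript_is_neutral(self):
        X = np.vstack([np.ones(10), np.random.default_rng(3).normal(size=(3, 10))])
        adj = coexpress.signed_adjacency(pd.DataFrame(X), beta=4)
        # correlation forced to 0 -> adjacency (1/2)^beta off-diagonal
        assert np.allclose(adj[0, 1:], 0.5**4)


class TestSoftThreshold:
    @staticmethod
    def _direct_r2(adj, n_bins=10):
        """Independent re-derivation: regression of log10 p(k) on log10 k
        over equal-width connectivity bins, sign-penalized for positive
        slopes."""
        k = adj.sum(axis=0) - 1.0
        edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
        xs, ys = [], []
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            mask = (k >= lo) & (k < hi) if b < n_bins - 1 else (k >= lo)
            if mask.sum() == 0 or k[mask].mean() <= 0:
                continue
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum() / len(k)))
        slope = np.polyfit(xs, ys, 1)[0]
        r2 = np.corrcoef(xs, ys)[0, 1] ** 2
        return r2 if slope < 0 else -r2

    def test_blocks_return_low_beta_and_r2_matches_direct_computation(self):
        expr, _ = _block_expression([30, 25, 20], seed=4)
        res = coexpress.pick_soft_threshold(expr, candidates=list(range(1, 11)))
        assert res.beta <= 10
        for beta, r2 in res.fit_r2.items():
            adj = coexpress.signed_adjacency(expr, beta)
            assert r2 == pytest.approx(self._direct_r2(adj), abs=1e-9)

    def test_iid_noise_sets_warning(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(60, 24)))
        res = coexpress.pick_soft_threshold(expr, candidates=[2, 4, 6], fit_target=0.95)
        assert res.warning

    def test_single_candidate_returned_regardless(self):
        expr, _ = _block_expression([20, 20], seed=6)
        res = coexpress.pick_soft_threshold(expr, candidates=[7])
        assert res.beta == 7

    def test_too_few_transcripts_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(7).normal(size=(5, 10)))
        with pytest.raises(ValueError):
            coexpress.pick_soft_threshold(expr)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        expr, truth = _block_expression([50, 40, 30], seed=8)
        adj = coexpress.signed_adjacency(expr, beta=12)
        tom = coexpress.tom_similarity(adj)
        part = coexpress.detect_modules(tom, list(expr.index))
        assert part.n_modules == 3
        ari = adjusted_rand_score(truth, part.labels.to_numpy())
        assert ari >= 0.8

    def test_pure_noise_leaves_everything_unassigned(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(100, 24)))
        tom = coexpress.tom_similarity(coexpress.signed_adjacency(expr, 20))
        part = coexpress.detect_modules(tom, list(expr.index))
        assert part.n_modules == 0
        assert part.unassigned_fraction() == 100.0

    def test_smaller_min_size_never_unassigns_more(self):
        expr, _ = _block_expression([30, 15, 8], seed=10)
        tom = coexpress.tom_similarity(coexpress.signed_adjacency(expr, 12))
        assigned = []
        for min_size in (25, 12, 6):
            part = coexpress.detect_modules(tom, list(expr.index), min_module_size=min_size)
            assigned.append(int((part.labels > 0).sum()))
        assert assigned == sorted(assigned)

    def test_partition_stable_under_transcript_permutation(self):
        expr, _ = _block_expression([40, 30], seed=11)
        perm = np.random.default_rng(12).permutation(len(expr))
        tom1 = coexpress.tom_similarity(coexpress.signed_adjacency(expr, 12))
        p1 = coexpress.detect_modules(tom1, list(expr.index))
        expr2 = expr.iloc[perm]
        tom2 = coexpress.tom_similarity(coexpress.signed_adjacency(expr2, 12))
        p2 = coexpress.detect_modules(tom2, list(expr2.index))
        joined = pd.concat([p1.labels.rename("a"), p2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_tiny_min_module_size_rejected(self):
        with pytest.raises(ValueError):
            coexpress.detect_modules(np.eye(10), [str(i) for i in range(10)], min_module_size=2)


class TestEigengenes:
    def test_shared_profile_recovered_with_positive_orientation(self):
        profile = np.array([1.0, 2, 3, 4, 5, 6])
        expr = pd.DataFrame(
            [profile * s + o for s, o in [(1, 0), (2, 1), (0.5, -1), (3, 2)]],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series([1, 1, 1, 1], index=expr.index)
        part = coexpress.ModulePartition(labels=labels)
        eig, var, _ = coexpress.module_eigengenes(expr, part)
        v = eig.loc[1].to_numpy()
        std_profile = (profile - profile.mean()) / profile.std()
        cos = v @ std_profile / (np.linalg.norm(v) * np.linalg.norm(std_profile))
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert var.loc[1] == pytest.approx(1.0, abs=1e-9)

    def test_eigengene_explains_most_variance(self, small_study):
        from retrodyn import de as de_mod

        sf = de_mod.size_factors(small_study.counts)
        expr = de_mod.vst(small_study.counts, sf)
        members = [t for t, m in small_study.truth.module_labels.items() if m == "M_up24h"]
        labels = pd.Series(1, index=pd.Index(members))
        part = coexpress.ModulePartition(labels=labels)
        eig, var, _ = coexpress.module_eigengenes(expr.loc[members], part)
        assert 0.3 < var.loc[1] <= 1.0
        assert np.linalg.norm(eig.loc[1]) == pytest.approx(1.0, abs=1e-9)

    def test_transient_module_profile_peaks_at_45min(self, default_run):
        """The planted transient module's eigengene group means must peak in
        the middle time group."""
        res = default_run
        truth = res.truth
        # find the detected module dominated by the planted transient module
        best_mod, best_frac = None, 0.0
        for m, members in res.partition.module_sets().items():
            frac = np.mean([truth.module_labels[t] == "M_transient" for t in members])
            if frac > best_frac:
                best_mod, best_frac = m, frac
        assert best_frac > 0.8
        eig = res.eigengenes.loc[best_mod]
        groups = pd.Series([s.rsplit("_", 1)[0] for s in eig.index], index=eig.index)
        means = eig.groupby(groups).mean()
        assert means["45min"] == max(means["0min"], means["45min"], means["24h"])
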