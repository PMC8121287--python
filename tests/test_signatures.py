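import numpy as np
import pandas as pd
import pytest

import cnsig
from cnsig.signatures import cophenetic_coefficient, kl_nmf


def planted_catalog(m=20, n=30, k=2, seed=0, scale=200):
    """Catalog V = W0 @ H0 with well-separated nonnegative factors."""
    rng = np.random.default_rng(seed)
    W0 = rng.dirichlet(np.full(m, 0.3), size=k).T  # m x k, columns sum to 1
    # sparse mixing weights give near-pure samples, pinning the factor cone
    H0 = rng.dirichlet(np.full(k, 0.3), size=n).T * rng.uniform(scale / 2, scale, n)
    # make columns distinct by disjoint dominant blocks
    W0[: m // 2, 0] *= 5
    W0[m // 2 :, 1] *= 5
    W0 /= W0.sum(axis=0)
    V = W0 @ H0
    catalog = pd.DataFrame(V.T, index=[f"S{j}" for j in range(n)],
                           columns=[f"c{i}" for i in range(m)])
    return catalog, W0, H0


class TestRunNMF:
    def test_rank1_catalog_reconstructs_exactly(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(1, 5, size=15)
        v = rng.uniform(1, 5, size=12)
        V = np.outer(u, v)
        catalog = pd.DataFrame(V.T)
        res = cnsig.run_nmf(catalog, k=2, n_runs=3, seed=0, tol=1e-12)
        recon = res.W.to_numpy() @ res.H.to_numpy()
        assert np.linalg.norm(V - recon) <= 1e-6 * np.linalg.norm(V)

    def test_same_seed_is_bitwise_deterministic(self):
        catalog, _, _ = planted_catalog()
        a = cnsig.run_nmf(catalog, k=2, n_runs=3, seed=5)
        b = cnsig.run_nmf(catalog, k=2, n_runs=3, seed=5)
        assert (a.W.to_numpy() == b.W.to_numpy()).all()
        assert (a.H.to_numpy() == b.H.to_numpy()).all()
        assert a.objectives == b.objectives

    def test_consensus_is_symmetric_with_unit_diagonal(self):
        catalog, _, _ = planted_catalog()
        res = cnsig.run_nmf(catalog, k=2, n_runs=5, seed=2)
        C = res.consensus.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert C.min() >= 0 and C.max() <= 1

    def test_kl_objective_is_nonincreasing(self):
        # Poisson noise keeps the optimum away from machine precision,
        # where float round-off would mask the descent property
        catalog, W0, H0 = planted_catalog(seed=3)
        rng = np.random.default_rng(0)
        V = rng.poisson(W0 @ H0).astype(float) + 1e-6
        _, _, history = kl_nmf(V, k=2, rng=np.random.default_rng(0),
                               max_iter=500, tol=0.0, check_every=1)
        diffs = np.diff(history)
        assert (diffs <= 1e-8 * np.abs(history[:-1])).all()

    def test_rank_out_of_range_and_zero_rows_error(self):
        catalog, _, _ = planted_catalog(n=10)
        with pytest.raises(ValueError, match="rank"):
            cnsig.run_nmf(catalog, k=1, n_runs=2, seed=0)
        catalog.iloc[0] = 0
        with pytest.raises(ValueError, match="S0"):
            cnsig.run_nmf(catalog, k=2, n_runs=2, seed=0)


class TestSurveyRanks:
    def test_duplicated_blocks_give_perfect_consensus_at_k2(self):
        # two blocks of identical samples: clustering is unambiguous
        a = np.full(12, 10.0)
        a[:6] = 0.5
        b = np.full(12, 0.5)
        b[:6] = 10.0
        rows = [a] * 8 + [b] * 8
        catalog = pd.DataFrame(rows, index=[f"S{j}" for j in range(16)])
        res = cnsig.survey_ranks(catalog, [2], n_runs=5, seed=0)
        C = res.consensus[2].to_numpy()
        block = C[:8, :8]
        off = C[:8, 8:]
        assert np.allclose(block, 1.0) and np.allclose(off, 0.0)
        assert res.table["cophenetic"].iloc[0] == pytest.approx(1.0)

    def test_single_rank_survey_has_one_entry(self):
        catalog, _, _ = planted_catalog()
        res = cnsig.survey_ranks(catalog, [3], n_runs=2, seed=1)
        assert len(res.table) == 1
        assert (res.table["cophenetic"] <= 1).all() and (res.table["cophenetic"] >= 0).all()

    def test_planted_rank_is_more_stable_than_next(self):
        # 3 well-separated planted signatures: cophenetic(3) > cophenetic(4)
        rng = np.random.default_rng(8)
        k, m, n = 3, 24, 45
        W0 = np.zeros((m, k))
        for j in range(k):
            W0[j * 8 : (j + 1) * 8, j] = rng.uniform(1, 2, size=8)
        W0 /= W0.sum(axis=0)
        H0 = rng.dirichlet(np.full(k, 0.2), size=n).T * 300
        noise = rng.poisson(W0 @ H0).astype(float)
        catalog = pd.DataFrame(noise.T + 1e-6)
        res = cnsig.survey_ranks(catalog, [3, 4], n_runs=10, seed=4)
        coph = dict(zip(res.table["rank"], res.table["cophenetic"]))
        assert coph[3] > coph[4]


class TestExtractSignatures:
    def test_planted_factors_recovered(self):
        catalog, W0, H0 = planted_catalog(seed=7)
        sigs, rel, absolute, _ = cnsig.extract_signatures(catalog, 2, n_runs=5, seed=0,
                                                          tol=1e-9)
        sim = cnsig.cosine_similarity_matrix(
            sigs, cnsig.SignatureSet(matrix=pd.DataFrame(W0, index=catalog.columns))
        )
        assert sim.max(axis=0).min() >= 0.99

    def test_absolute_exposures_sum_to_catalog_totals_when_exact(self):
        catalog, _, _ = planted_catalog(seed=9)
        _, rel, absolute, _ = cnsig.extract_signatures(catalog, 2, n_runs=4, seed=1,
                                                       tol=1e-10)
        np.testing.assert_allclose(
            absolute.sum(axis=1), catalog.sum(axis=1), rtol=1e-3
        )
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_column_scaling_preserves_reconstruction(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, size=(10, 3))
        H = rng.uniform(0, 2, size=(3, 8))
        scale = W.sum(axis=0)
        W2, H2 = W / scale, H * scale[:, None]
        np.testing.assert_allclose(W @ H, W2 @ H2, atol=1e-12)

    def test_ss_ordering_is_deterministic(self, toy_build, scheme):
        cfg = cnsig.SimConfig(genome=toy_build, n_samples=25, seed=3,
                              focal_amp_rate=30, tandem_dup_rate=30,
                              chromothripsis_rate=2)
        profiles, _ = cnsig.simulate_cohort(cfg)
        catalog = cnsig.tally_cn_catalog(profiles, toy_build, scheme)
        a = cnsig.extract_signatures(catalog, 2, n_runs=3, seed=5, scheme=scheme)
        b = cnsig.extract_signatures(catalog, 2, n_runs=3, seed=5, scheme=scheme)
        assert (a[0].matrix.to_numpy() == b[0].matrix.to_numpy()).all()
        # shorter-segment-mass signature comes first
        feat = scheme.feature_of()
        ss_rows = feat[feat == "SS"].index
        def mean_bin(col):
            w = a[0].matrix.loc[ss_rows, col]
            return (np.arange(len(w)) * w / w.sum()).sum()
        bins = [mean_bin(c) for c in a[0].matrix.columns]
        med_bins = [
            np.searchsorted(np.cumsum(a[0].matrix.loc[ss_rows, c] /
                                      a[0].matrix.loc[ss_rows, c].sum()), 0.5)
            for c in a[0].matrix.columns
        ]
        assert med_bins == sorted(med_bins)

    def test_matches_sklearn_kl_nmf_objective(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        catalog, _, _ = planted_catalog(m=16, n=24, seed=5)
        res = cnsig.run_nmf(catalog, k=2, n_runs=5, seed=0)
        V = catalog.to_numpy(float).T
        model = sklearn.NMF(n_components=2, solver="mu",
                            beta_loss="kullback-leibler", init="random",
                            random_state=0, max_iter=2000, tol=1e-9)
        Wsk = model.fit_transform(V)
        from cnsig.signatures import _kl_divergence
        ours = min(res.objectives)
        theirs = _kl_divergence(V, Wsk @ model.components_)
        assert ours <= theirs * 1.05 + 1e-6


class TestNormalization:
    def make_sigs(self):
        matrix = pd.DataFrame(
            {"SigA": [2.0, 2.0, 0.0, 0.0, 1.0], "SigB": [1.0, 3.0, 0.0, 0.0, 4.0]},
            index=["f1a", "f1b", "f2a", "f2b", "f3a"],
        )
        features = pd.Series(["F1", "F1", "F2", "F2", "F3"], index=matrix.index)
        return cnsig.SignatureSet(matrix=matrix, features=features)

    def test_within_feature_rows_sum_to_one_per_block(self):
        sigs = self.make_sigs()
        out = cnsig.normalize_profile_matrix(sigs, "within-feature-row")
        assert out.matrix.loc[["f1a", "f1b"], "SigA"].tolist() == [0.5, 0.5]
        # all-zero block stays zero, no NaN
        assert out.matrix.loc[["f2a", "f2b"]].to_numpy().sum() == 0
        assert not out.matrix.isna().any().any()

    def test_whole_signature_columns_sum_to_one(self):
        out = cnsig.normalize_profile_matrix(self.make_sigs(), "whole-signature")
        np.testing.assert_allclose(out.matrix.sum(axis=0), 1.0)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            cnsig.normalize_profile_matrix(self.make_sigs(), "per-row")


class TestCosineSimilarity:
    def test_closed_forms(self):
        A = cnsig.SignatureSet(matrix=pd.DataFrame(
            {"a": [1.0, 1.0, 0.0], "one": [1.0, 0.0, 0.0], "zero": [0.0, 0.0, 0.0]}))
        sim = cnsig.cosine_similarity_matrix(A, A)
        assert sim.loc["a", "a"] == pytest.approx(1.0)
        assert sim.loc["one", "a"] == pytest.approx(1 / np.sqrt(2))
        assert sim.loc["zero", "a"] == 0.0
        orth = cnsig.SignatureSet(matrix=pd.DataFrame(
            {"x": [1.0, 0.0, 0.0], "y": [0.0, 1.0, 0.0]}))
        assert cnsig.cosine_similarity_matrix(orth, orth).loc["x", "y"] == pytest.approx(0.0)

    def test_component_mismatch_is_error(self):
        A = cnsig.SignatureSet(matrix=pd.DataFrame({"a": [1.0]}, index=["c1"]))
        B = cnsig.SignatureSet(matrix=pd.DataFrame({"b": [1.0]}, index=["c2"]))
        with pytest.raises(ValueError, match="component"):
            cnsig.cosine_similarity_matrix(A, B)


class TestConsensusClustering:
    def test_block_diagonal_consensus_recovers_blocks(self):
        n = 10
        C = np.zeros((n, n))
        C[:4, :4] = 1.0
        C[4:, 4:] = 1.0
        consensus = pd.DataFrame(C, index=[f"S{i}" for i in range(n)],
                                 columns=[f"S{i}" for i in range(n)])
        rel = pd.DataFrame(
            {"Sig1": [1.0] * 4 + [0.0] * 6, "Sig2": [0.0] * 4 + [1.0] * 6},
            index=consensus.index,
        )
        groups, enriched = cnsig.consensus_cluster_samples(consensus, 2, rel)
        assert groups.iloc[:4].nunique() == 1 and groups.iloc[4:].nunique() == 1
        assert groups.iloc[0] != groups.iloc[5]
        assert enriched[groups.iloc[0]] == "Sig1"
        assert enriched[groups.iloc[5]] == "Sig2"

    def test_k_equal_n_gives_singletons(self):
        n = 5
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 1, size=(n, n))
        C = (M + M.T) / 2
        np.fill_diagonal(C, 1.0)
        consensus = pd.DataFrame(C)
        rel = pd.DataFrame({"Sig1": np.ones(n)})
        groups, _ = cnsig.consensus_cluster_samples(consensus, n, rel)
        assert groups.nunique() == n

    def test_k_beyond_n_errors(self):
        consensus = pd.DataFrame(np.eye(3))
        rel = pd.DataFrame({"Sig1": np.ones(3)})
        with pytest.raises(ValueError):
            cnsig.consensus_cluster_samples(consensus, 4, rel)
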