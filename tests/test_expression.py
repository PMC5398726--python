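"""Expression transforms, DE/overlap statistics, proximity grouping,
and RNA-protein correlation."""

import numpy as np
import pandas as pd
import pytest

from venomkit import synthetic
from venomkit.errors import ValidationError
from venomkit.expression import (
    de_threshold_filter,
    log_transform,
    mean_center_rows,
    overlap_stats,
    proximity_groups,
    quantile_normalize,
    remove_batch_means,
    rna_protein_correlation,
    sample_correlation_clusters,
    sample_pca,
)


def random_matrix(rng, n_genes=30, n_samples=6):
    return pd.DataFrame(
        rng.gamma(2.0, 50.0, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestLogTransform:
    def test_closed_forms(self):
        m = pd.DataFrame([[0.0, 1.0, 3.0]])
        assert log_transform(m).values.tolist() == [[0.0, 1.0, 2.0]]

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng)
        back = np.power(2.0, log_transform(m)) - 1.0
        assert np.allclose(back, m, atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_transform(pd.DataFrame([[-1.0]]))


class TestBatchCorrection:
    def meta(self, batches):
        return pd.DataFrame(
            {"condition": "x", "batch": batches},
            index=[f"s{j}" for j in range(len(batches))],
        )

    def test_single_batch_identity(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, n_samples=4)
        out = remove_batch_means(m, self.meta(["A"] * 4))
        assert np.allclose(out, m)

    def test_two_batch_arithmetic(self):
        m = pd.DataFrame([[4.0, 6.0, 6.0, 8.0]], columns=["s0", "s1", "s2", "s3"])
        out = remove_batch_means(m, self.meta(["A", "A", "B", "B"]))
        # batch means 5 and 7, grand mean 6 -> +1 / -1
        assert out.values.tolist() == [[5.0, 7.0, 5.0, 7.0]]

    def test_planted_offsets_removed(self):
        design = synthetic.SyntheticDesign.small(
            seed=3, noiseless=True, n_de_up=0, n_de_down=0
        )
        m, meta, truth = synthetic.make_expression(design)
        logm = log_transform(m)
        in_a, in_b = meta["batch"] == "A", meta["batch"] == "B"
        # the planted offset is visible before correction (where no gene was
        # clipped at zero counts, i.e. its signal stayed positive)
        clean = (truth["base_log2"] + truth["batch_offset_log2"] > 0).to_numpy()
        raw = (
            logm.loc[:, meta.index[in_b]].mean(axis=1)
            - logm.loc[:, meta.index[in_a]].mean(axis=1)
        )
        assert np.allclose(
            raw[clean], truth["batch_offset_log2"].to_numpy()[clean], atol=1e-9
        )
        corrected = remove_batch_means(logm, meta)
        resid = (
            corrected.loc[:, meta.index[in_b]].mean(axis=1)
            - corrected.loc[:, meta.index[in_a]].mean(axis=1)
        )
        assert float(resid.abs().max()) < 1e-9

    def test_empty_metadata_rejected(self):
        m = pd.DataFrame([[1.0]], columns=["s0"])
        with pytest.raises(ValidationError):
            remove_batch_means(m, pd.DataFrame({"batch": []}))


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(m), m)

    def test_hand_computed_reference(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_rank_order_preserved_and_columns_identical(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_genes=50, n_samples=7)
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.values, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-9)
        for c in m.columns:
            assert (
                m[c].rank(method="average").tolist()
                == out[c].rank(method="average").tolist()
            )

    def test_ties_get_mean_reference_value(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[0] == out["a"].iloc[1]


class TestSampleStructure:
    def test_duplicate_sample_correlates_fully(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=40)})
        corr, _ = sample_correlation_clusters(m, k=2, random_state=0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_rank_reversal_gives_minus_one(self):
        x = np.arange(20.0)
        m = pd.DataFrame({"a": x, "b": x[::-1]})
        corr, _ = sample_correlation_clusters(m, k=1)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(9)
        program = rng.normal(0, 3, size=100)
        cols = {}
        for j in range(4):
            cols[f"on{j}"] = program + rng.normal(0, 0.3, 100)
        for j in range(4):
            cols[f"off{j}"] = -program + rng.normal(0, 0.3, 100)
        m = pd.DataFrame(cols)
        _, labels = sample_correlation_clusters(m, k=2, random_state=0)
        on = set(labels[[c for c in m if c.startswith("on")]])
        off = set(labels[[c for c in m if c.startswith("off")]])
        assert len(on) == 1 and len(off) == 1 and on != off

    def test_k_exceeding_samples_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValidationError):
            sample_correlation_clusters(m, k=3)

    def test_pca_two_samples_one_axis(self):
        m = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [2.0, 3.0, 1.0]})
        coords, var = sample_pca(m, n_components=2)
        assert var[0] == pytest.approx(1.0)

    def test_pca_gradient_ordering(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=200)
        direction = rng.normal(size=200)
        m = pd.DataFrame(
            {f"s{t}": base + t * direction + rng.normal(0, 0.05, 200) for t in range(6)}
        )
        coords, var = sample_pca(m, n_components=2)
        pc1 = coords["PC1"].to_numpy()
        assert (np.all(np.diff(pc1) > 0) or np.all(np.diff(pc1) < 0))
        assert var.sum() <= 1.0 + 1e-12

    def test_pca_degenerate_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            sample_pca(m)


class TestDEAndOverlap:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])

    def test_threshold_cases(self):
        t = self.table(
            [("up", 1.5, 0.04), ("weak", 0.9, 0.04), ("down", -1.2, 0.01),
             ("insig", 2.0, 0.06)]
        )
        up, down = de_threshold_filter(t)
        assert up == {"up"}
        assert down == {"down"}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        t = self.table(
            [(f"g{i}", float(rng.normal(0, 2)), float(rng.uniform())) for i in range(300)]
        )
        up, down = de_threshold_filter(t)
        exp_up = {
            r.gene_id for r in t.itertuples() if r.fdr < 0.05 and r.log2fc > 1
        }
        exp_down = {
            r.gene_id for r in t.itertuples() if r.fdr < 0.05 and r.log2fc < -1
        }
        assert (up, down) == (exp_up, exp_down)
        assert not up & down

    def test_identical_sets_fully_shared(self):
        s = overlap_stats({"a", "b"}, {"a", "b"})
        assert s.pct_shared == 100

    @pytest.mark.parametrize(
        "n_shared,n_a,n_b,pct", [(135, 75, 0, 64), (65, 23, 0, 74)]
    )
    def test_published_venn_percentages(self, n_shared, n_a, n_b, pct):
        shared = {f"s{i}" for i in range(n_shared)}
        a = shared | {f"a{i}" for i in range(n_a)}
        b = shared | {f"b{i}" for i in range(n_b)}
        s = overlap_stats(a, b)
        assert s.shared == n_shared
        assert s.total_union == n_shared + n_a + n_b
        assert s.pct_shared == pct
        assert s.shared + s.a_only + s.b_only == s.total_union

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError):
            overlap_stats(set(), set())


class TestMeanCenter:
    def test_rows_centered(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        out = mean_center_rows(m)
        assert out.values.tolist() == [[-1.0, 0.0, 1.0], [0.0, 0.0, 0.0]]
        rng = np.random.default_rng(7)
        r = mean_center_rows(random_matrix(rng))
        assert float(r.mean(axis=1).abs().max()) < 1e-12


def positions_frame(entries):
    return pd.DataFrame(
        entries, columns=["gene_id", "scaffold_id", "ordinal_index"]
    )


class TestProximityGroups:
    def test_distinct_scaffolds_no_groups(self):
        pos = positions_frame(
            [("a", "s1", 0), ("b", "s2", 0), ("c", "s3", 0)]
        )
        groups, summary = proximity_groups({"a", "b", "c"}, pos)
        assert groups == []
        assert summary.fraction_clustered == 0.0

    def test_hand_traced_chaining(self):
        pos = positions_frame([("a", "s1", 5), ("b", "s1", 12), ("c", "s1", 40)])
        groups, summary = proximity_groups({"a", "b", "c"}, pos, window=10)
        assert [set(g.gene_ids) for g in groups] == [{"a", "b"}]
        assert summary.mean_group_size == 2
        assert summary.fraction_clustered == pytest.approx(2 / 3)

    def test_missing_position_reported(self):
        pos = positions_frame([("a", "s1", 0)])
        with pytest.raises(ValidationError, match="zz"):
            proximity_groups({"a", "zz"}, pos)

    def test_matches_graph_closure_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            scaffolds = rng.choice(["s1", "s2", "s3"], size=n)
            # unique (scaffold, index) pairs
            idx, used = [], set()
            for s in scaffolds:
                i = int(rng.integers(0, 60))
                while (s, i) in used:
                    i = int(rng.integers(0, 60))
                used.add((s, i))
                idx.append(i)
            pos = positions_frame(list(zip(genes, scaffolds, idx)))
            window = int(rng.integers(1, 15))
            groups, summary = proximity_groups(genes, pos, window=window)

            g = nx.Graph()
            g.add_nodes_from(genes)
            for i in range(n):
                for j in range(i + 1, n):
                    if scaffolds[i] == scaffolds[j] and abs(idx[i] - idx[j]) <= window:
                        g.add_edge(genes[i], genes[j])
            expected = sorted(
                sorted(c) for c in nx.connected_components(g) if len(c) >= 2
            )
            assert sorted(sorted(grp.gene_ids) for grp in groups) == expected
            assert summary.n_clustered == sum(len(c) for c in expected)

    def test_input_order_invariance(self):
        pos = positions_frame(
            [(f"g{i}", "s1", i * 3) for i in range(10)]
        )
        a = proximity_groups([f"g{i}" for i in range(10)], pos, window=5)
        b = proximity_groups([f"g{i}" for i in reversed(range(10))], pos, window=5)
        assert a[1] == b[1]


class TestRnaProteinCorrelation:
    def test_perfect_and_inverted(self):
        expr = {f"g{i}": float(i) for i in range(10)}
        gene_map = {f"p{i}": f"g{i}" for i in range(10)}
        ab = {f"p{i}": float(i + 1) for i in range(10)}
        assert rna_protein_correlation(expr, ab, gene_map, top_n=10) == pytest.approx(1.0)
        inv = {f"p{i}": float(10 - i) for i in range(10)}
        assert rna_protein_correlation(expr, inv, gene_map, top_n=10) == pytest.approx(-1.0)

    def test_planted_rank_correlation_recovered(self):
        # bivariate normal copula with rho chosen to plant a Spearman
        # correlation near 0.34 among the n = 100 retained pairs
        target = 0.34
        rho = 2 * np.sin(np.pi * target / 6)
        estimates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cov = [[1, rho], [rho, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=100)
            expr = {f"g{i}": float(xy[i, 0]) for i in range(100)}
            ab = {f"p{i}": float(np.exp(xy[i, 1])) for i in range(100)}
            gene_map = {f"p{i}": f"g{i}" for i in range(100)}
            estimates.append(rna_protein_correlation(expr, ab, gene_map, top_n=100))
        assert abs(np.mean(estimates) - target) < 0.15

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            rna_protein_correlation(
                {"g1": 1.0, "g2": 2.0}, {"p1": 1.0, "p2": 2.0},
                {"p1": "g1", "p2": "g2"}, top_n=2
            )
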