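"""QC rule, normalization, marker ranking, signatures, mapping, EMT axis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thymoquant.expr import (
    QCThresholds,
    build_signatures,
    emt_axis,
    exclude_low_quality_clusters,
    map_subsets,
    normalize_log1p,
    qc_flag_cells,
    rank_markers,
    scaled_frequency_change,
    score_signature,
)
from thymoquant.expr.markers import _rank_sum_z
from thymoquant.expr.signatures import score_signature_set


class TestQC:
    @pytest.mark.parametrize(
        "low_counts,low_genes,high_mito",
        list(itertools.product([False, True], repeat=3)),
    )
    def test_all_eight_indicator_combinations(self, low_counts, low_genes, high_mito):
        """Flag fires iff ≥2 of the three indicators fire (thresholds
        1,000 genes and 0.2 mito)."""
        n = 40
        obs = pd.DataFrame(
            {
                "total_counts": np.full(n, 8000.0),
                "n_genes": np.full(n, 3000),
                "mito_fraction": np.full(n, 0.05),
            }
        )
        # target cell 0; baseline cells keep percentile structure stable
        if low_counts:
            obs.loc[0, "total_counts"] = 10.0
        if low_genes:
            obs.loc[0, "n_genes"] = 1000  # boundary: ≤ 1,000 fires
        if high_mito:
            obs.loc[0, "mito_fraction"] = 0.2  # boundary: ≥ 0.2 fires
        flags = qc_flag_cells(obs)
        n_ind = int(low_counts) + int(low_genes) + int(high_mito)
        assert flags.loc[0, "n_indicators"] == n_ind
        assert bool(flags.loc[0, "low_quality"]) == (n_ind >= 2)

    def test_published_example_two_indicators(self):
        obs = pd.DataFrame(
            {
                "total_counts": [8000.0] * 30,
                "n_genes": [800] + [3000] * 29,
                "mito_fraction": [0.25] + [0.02] * 29,
            }
        )
        flags = qc_flag_cells(obs)
        assert flags.loc[0, "n_indicators"] == 2 and bool(flags.loc[0, "low_quality"])

    def test_single_indicator_not_flagged(self):
        obs = pd.DataFrame(
            {
                "total_counts": [8000.0] * 30,
                "n_genes": [3000] * 30,
                "mito_fraction": [0.3] + [0.02] * 29,
            }
        )
        flags = qc_flag_cells(obs)
        assert not flags.loc[0, "low_quality"]

    def test_cluster_exclusion_rules(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(60, 5))
        counts[:, 4] = 0
        counts[40:, 4] = 5  # cluster 'c' expresses the contaminant
        obs = pd.DataFrame(
            {
                "cluster": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
                "low_quality": [True] * 18 + [False] * 42,
            }
        )
        table = exclude_low_quality_clusters(
            counts, ["g0", "g1", "g2", "g3", "Ptprc"], obs, ["Ptprc"]
        )
        decisions = table.set_index("cluster").keep
        assert not decisions["a"]  # 90% flagged
        assert decisions["b"]
        assert not decisions["c"]  # 100% contaminant

    def test_unknown_contaminant_warns(self):
        counts = np.ones((4, 2))
        obs = pd.DataFrame({"cluster": ["a"] * 4, "low_quality": [False] * 4})
        with pytest.warns(UserWarning, match="NotAGene"):
            exclude_low_quality_clusters(counts, ["g0", "g1"], obs, ["NotAGene"])


class TestNormalize:
    def test_stated_formula(self):
        counts = np.zeros((1, 3))
        counts[0] = [100, 9900, 0]
        out = normalize_log1p(counts)
        assert out[0, 0] == pytest.approx(np.log(101.0))
        assert out[0, 2] == 0.0

    def test_conservation_identity(self, normalized_expr):
        back = (np.exp(normalized_expr) - 1).sum(axis=1)
        np.testing.assert_allclose(back, 10_000.0, rtol=1e-6)

    def test_zero_total_cell_listed(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_log1p(counts)


def _enumerate_rank_sum(values, n1):
    """Exhaustive permutation null of the rank-sum statistic (with ties)."""
    ranks = stats.rankdata(values)
    n = len(values)
    sums = [
        ranks[list(c)].sum() for c in itertools.combinations(range(n), n1)
    ]
    return np.mean(sums), np.std(sums)


class TestRankMarkers:
    def test_z_matches_exact_enumeration(self):
        """Tie-corrected z equals the exact permutation moments for tiny
        groups (the normal approximation uses the exact null mean/SD)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            vals = rng.integers(0, 4, size=10).astype(float)
            if len(np.unique(vals)) == 1:
                vals[0] += 1
            in_group = np.zeros(10, bool)
            in_group[:5] = True
            z = _rank_sum_z(vals.reshape(-1, 1), in_group)[0]
            mu, sd = _enumerate_rank_sum(vals, 5)
            r1 = stats.rankdata(vals)[:5].sum()
            z_exact = (r1 - mu) / sd
            assert z == pytest.approx(z_exact, abs=1e-9)

    def test_scanpy_cross_check(self, normalized_expr, expr_adata):
        """Independent oracle: scanpy's tie-corrected Wilcoxon ranking."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        sub = slice(0, 300)
        X = normalized_expr[sub, :400]
        labels = expr_adata.obs.subset.to_numpy()[sub]
        mine = rank_markers(X, labels, gene_names=[f"g{i}" for i in range(400)])
        a2 = ad.AnnData(
            X=X.copy(),
            obs=pd.DataFrame({"subset": pd.Categorical(labels)},
                             index=[f"c{i}" for i in range(X.shape[0])]),
        )
        a2.var_names = [f"g{i}" for i in range(400)]
        sc.tl.rank_genes_groups(a2, "subset", method="wilcoxon",
                                tie_correct=True, n_genes=400)
        grp = a2.obs.subset.cat.categories[0]
        sdf = sc.get.rank_genes_groups_df(a2, group=grp).set_index("names")
        ours = mine[mine.subset == grp].set_index("gene").loc[sdf.index]
        np.testing.assert_allclose(ours.z, sdf.scores, atol=1e-5)

    def test_null_permutation_fdr_rate(self):
        """Label permutations of one population: essentially nothing passes
        FDR ≤ 0.05."""
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(80, 150)).astype(float)
        hits = []
        for rep in range(20):
            labels = np.array(["a"] * 40 + ["b"] * 40)
            rng.shuffle(labels)
            mk = rank_markers(X, labels)
            hits.append((mk.q <= 0.05).mean())
        assert np.mean(hits) < 0.01

    def test_planted_marker_top_z(self, normalized_expr, expr_adata):
        mk = rank_markers(
            normalized_expr,
            expr_adata.obs.subset.to_numpy(),
            gene_names=list(expr_adata.var_names),
        )
        truth = expr_adata.uns["marker_truth"]
        for subset, genes in truth.items():
            top = (
                mk[mk.subset == subset]
                .sort_values("z", ascending=False)
                .head(len(genes))
                .gene
            )
            assert len(set(top) & set(genes)) >= 0.8 * len(genes)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="two distinct"):
            rank_markers(np.ones((4, 3)), ["a"] * 4)


class TestSignatures:
    def _markers(self):
        return pd.DataFrame(
            {
                "subset": ["s"] * 5,
                "gene": ["g4", "g1", "g2", "g3", "g5"],
                "z": [3.0, 5.0, 5.0, 4.0, -6.0],
                "p": [1e-3] * 5,
                "q": [0.01, 0.01, 0.01, 0.01, 0.2],
            }
        )

    def test_build_rules_order_truncation_ties(self):
        sigs = build_signatures(self._markers(), n=3)
        # descending z, tie between g1/g2 broken by name, q ≤ 0.05 only
        assert sigs["s"] == ["g1", "g2", "g3"]
        sigs_all = build_signatures(self._markers(), n=20)
        assert sigs_all["s"] == ["g1", "g2", "g3", "g4"]

    def test_empty_signature_warns(self):
        mk = self._markers()
        mk["q"] = 0.5
        with pytest.warns(UserWarning, match="no FDR-passing"):
            sigs = build_signatures(mk)
        assert sigs["s"] == []

    def test_score_zero_for_uniform_expression(self):
        X = np.full((10, 50), 3.0)
        genes = [f"g{i}" for i in range(50)]
        s = score_signature(X, genes, ["g0", "g1"], ctrl_per_gene=5, seed=0)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_score_equals_bruteforce_fixed_reference(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 40))
        genes = [f"g{i}" for i in range(40)]
        sig = ["g3", "g7"]
        ref = ["g10", "g11", "g12"]
        s = score_signature(X, genes, sig, reference=ref)
        brute = X[:, [3, 7]].mean(axis=1) - X[:, [10, 11, 12]].mean(axis=1)
        np.testing.assert_allclose(s, brute, atol=1e-9)

    def test_shifted_signature_recovers_delta(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.05, size=(200, 300))
        genes = [f"g{i}" for i in range(300)]
        delta = 1.5
        X[:100, :10] += delta  # first 100 cells over-express the signature
        s = score_signature(X, genes, genes[:10], seed=4)
        assert np.mean(s[:100]) == pytest.approx(delta, abs=0.1)
        assert abs(np.mean(s[100:])) < 0.1

    def test_seed_determinism_and_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 60))
        genes = [f"g{i}" for i in range(60)]
        sig = ["g5", "g10", "g15"]
        s1 = score_signature(X, genes, sig, seed=9)
        s2 = score_signature(X, genes, sig, seed=9)
        s3 = score_signature(X, genes, list(reversed(sig)), seed=9)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_allclose(s1, s3, atol=1e-12)

    def test_missing_genes_warn_empty_raises(self):
        X = np.ones((5, 4))
        genes = ["a", "b", "c", "d"]
        with pytest.warns(UserWarning, match="not found"):
            score_signature(X, genes, ["a", "zz"], ctrl_per_gene=1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            score_signature(X, genes, ["zz"], seed=0)


class TestMapping:
    def test_argmax_and_tie_rules(self):
        scores = pd.DataFrame(
            {"s1": [0.9, 0.5, 0.2], "s2": [0.1, 0.5, 0.8]}
        )
        out = map_subsets(scores)
        assert list(out.assignment) == ["s1", "unassigned", "s2"]
        assert out.margin.iloc[1] == 0.0
        assert out.margin.iloc[0] == pytest.approx(0.8)

    def test_accuracy_monotone_in_effect_size(self):
        from thymoquant.synth import ExprSimSpec, make_expression, make_pseudobulk_spots

        accs = []
        for lfc in (0.2, 1.5):
            adata = make_expression(
                ExprSimSpec(seed=21, marker_log_fold_change=lfc, n_cells=600)
            )
            mk = rank_markers(
                normalize_log1p(adata.X),
                adata.obs.subset.to_numpy(),
                gene_names=list(adata.var_names),
            )
            sigs = {k: v for k, v in build_signatures(mk, n=20).items() if v}
            spots = make_pseudobulk_spots(adata, seed=22)
            snorm = normalize_log1p(spots.X)
            scores = score_signature_set(snorm, spots.var_names, sigs, seed=23)
            out = map_subsets(scores)
            accs.append(
                (out.assignment.to_numpy() == spots.obs.subset.to_numpy()).mean()
            )
        assert accs[1] >= accs[0]


class TestFrequencyChange:
    def test_equal_frequencies_all_zero(self):
        f = pd.DataFrame({"young": [0.5, 0.5], "aged": [0.5, 0.5]}, index=["a", "b"])
        out = scaled_frequency_change(f)
        np.testing.assert_array_equal(out.to_numpy(), 0.0)

    def test_single_absorbing_subset(self):
        f = pd.DataFrame(
            {"young": [0.6, 0.4, 0.0], "aged": [0.3, 0.4, 0.3]},
            index=["a", "b", "c"],
        )
        out = scaled_frequency_change(f)
        assert out["a"] == pytest.approx(-1.0)
        assert out["c"] == pytest.approx(1.0)

    def test_three_subset_hand_computation(self):
        f = pd.DataFrame(
            {"young": [0.5, 0.3, 0.2], "aged": [0.4, 0.25, 0.35]},
            index=["a", "b", "c"],
        )
        out = scaled_frequency_change(f)
        # deltas: -0.10, -0.05, +0.15; max |delta| = 0.15
        np.testing.assert_allclose(
            out.to_numpy(), [-0.1 / 0.15, -0.05 / 0.15, 1.0], atol=1e-12
        )

    def test_unnormalized_rejected(self):
        f = pd.DataFrame({"young": [0.5, 0.4], "aged": [0.5, 0.5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="sum"):
            scaled_frequency_change(f)


class TestEMT:
    def test_ordering_by_anchor(self):
        X = np.array([[1.0, 0.0], [3.0, 0.0], [2.0, 0.0]])
        out = emt_axis(X, ["Cdh1", "Vim"], ["Cdh1"], ["Vim"])
        assert list(out["rank"]) == [2, 0, 1]

    def test_pure_epithelial_cell(self):
        X = np.zeros((1, 4))
        X[0, [0, 2]] = 2.0  # Cdh1 and epithelial gene only
        out = emt_axis(X, ["Cdh1", "Vim", "Epcam", "Fn1"], ["Epcam"], ["Fn1"])
        assert out.e_score.iloc[0] > 0
        assert out.m_score.iloc[0] == 0
        assert out.quadrant.iloc[0] == "E+M-"

    def test_partial_emt_quadrant(self):
        """Anchor-low/Vim-high cells land in the low-E/high-M quadrant."""
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(0.05, 0.02, size=(50, 5)))
        X[:25, 0] = 2.0   # epithelial cells: Cdh1 high
        X[:25, 2] = 1.5
        X[25:, 0] = 0.0   # partial-EMT: anchor silent, Vim high
        X[25:, 1] = 2.0
        X[25:, 2] = 0.0
        out = emt_axis(
            X, ["Cdh1", "Vim", "Epcam", "Krt8", "Fn1"], ["Epcam", "Krt8"], ["Vim", "Fn1"],
            anchor_threshold=0.5, vim_threshold=0.5,
        )
        assert (out.quadrant.iloc[25:] == "E-M+").all()
        assert (out.quadrant.iloc[:25] == "E+M-").all()

    def test_missing_anchor_rejected(self):
        with pytest.raises(KeyError, match="Cdh1"):
            emt_axis(np.ones((2, 1)), ["Vim"], [], [])
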