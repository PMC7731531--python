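"""Feature engineering: closed-form examples, brute-force oracles, and
order-invariance properties."""

import numpy as np
import pandas as pd
import pytest

from smtransfer.features import (
    DETable,
    ExpressionMatrix,
    FeatureTable,
    GeneCoordinates,
    HomologyTable,
    ParalogTable,
    bh_adjust,
    cluster_module_features,
    coexpression_class_features,
    de_breadth,
    duplication_features,
    evolutionary_summaries,
    expression_summaries,
    genomic_cluster_counts,
    harmonize_shared_features,
    impute_missing,
    select_top_modules,
)


# ---------------------------------------------------------------------- expression


class TestExpressionSummaries:
    def test_three_value_closed_form(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 3.0, 5.0]], index=["g1"], columns=["a", "b", "c"]),
            groups=pd.Series({"a": "dev", "b": "dev", "c": "dev"}),
        )
        ft = expression_summaries(expr)
        assert ft.values.loc["g1", "expr_dev_median"] == 3.0
        assert ft.values.loc["g1", "expr_dev_max"] == 5.0
        assert ft.values.loc["g1", "expr_dev_mad"] == 2.0

    def test_constant_row_zero_mad(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame([[2.0, 2.0, 2.0]], index=["g1"], columns=["a", "b", "c"]),
            groups=pd.Series({"a": "dev", "b": "dev", "c": "dev"}),
        )
        assert expression_summaries(expr).values.loc["g1", "expr_all_mad"] == 0.0

    def test_matches_sort_based_oracle(self, rng):
        values = pd.DataFrame(
            rng.random((10, 6)), index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=values.columns)
        ft = expression_summaries(ExpressionMatrix(values=values, groups=groups))
        for gene in values.index:
            for group, cols in (("x", values.columns[:3]), ("y", values.columns[3:]),
                                ("all", values.columns)):
                row = sorted(values.loc[gene, cols])
                n = len(row)
                med = (row[n // 2] if n % 2 else (row[n // 2 - 1] + row[n // 2]) / 2)
                mad = sorted(abs(v - med) for v in row)
                mad = mad[n // 2] if n % 2 else (mad[n // 2 - 1] + mad[n // 2]) / 2
                assert ft.values.loc[gene, f"expr_{group}_median"] == pytest.approx(med)
                assert ft.values.loc[gene, f"expr_{group}_max"] == pytest.approx(row[-1])
                assert ft.values.loc[gene, f"expr_{group}_mad"] == pytest.approx(mad)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(
                values=pd.DataFrame([[-1.0]], index=["g"], columns=["s"]),
                groups=pd.Series({"s": "dev"}),
            )


# ---------------------------------------------------------------------- BH / DE


def bh_oracle(p):
    """Definitional step-up BH: adj_i = min over rank >= rank(i) of p_j*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBHAdjust:
    def test_closed_form_m3(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_definitional_oracle(self, rng):
        p = rng.random(100)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_bounds_and_rank_monotonicity(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDEBreadth:
    def test_direct_rule(self):
        table = pd.DataFrame(
            {
                "gene": ["g1"] * 3,
                "contrast": ["c1", "c2", "c3"],
                "group": ["dev"] * 3,
                "logFC": [1.5, -2.0, 0.5],
                "p": [0.01, 0.2, 0.001],
            }
        )
        ft = de_breadth(DETable(table, p_adjusted=True))
        assert ft.values.loc["g1", "de_dev_n_up"] == 1
        assert ft.values.loc["g1", "de_dev_n_down"] == 0

    def test_all_p_one_gives_zero(self):
        table = pd.DataFrame(
            {"gene": ["g1", "g1"], "contrast": ["c1", "c2"], "group": ["dev"] * 2,
             "logFC": [5.0, -5.0], "p": [1.0, 1.0]}
        )
        ft = de_breadth(DETable(table, p_adjusted=True))
        assert ft.values.loc["g1"].sum() == 0

    def test_matches_double_loop_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        contrasts = [f"c{j}" for j in range(20)]
        groups = {c: ("dev" if j < 10 else "stress") for j, c in enumerate(contrasts)}
        rows = [
            {"gene": g, "contrast": c, "group": groups[c],
             "logFC": rng.normal(0, 2), "p": rng.random()}
            for g in genes for c in contrasts
        ]
        table = pd.DataFrame(rows)
        ft = de_breadth(DETable(table, p_adjusted=False))
        # oracle: per-contrast BH, then double loop
        adj = {}
        for c in contrasts:
            sub = table[table["contrast"] == c]
            for gene, a in zip(sub["gene"], bh_oracle(sub["p"].to_numpy())):
                adj[(gene, c)] = a
        for g in genes:
            for grp_name, members in (
                ("dev", contrasts[:10]), ("stress", contrasts[10:]), ("all", contrasts)
            ):
                n_up = n_down = 0
                for c in members:
                    row = table[(table["gene"] == g) & (table["contrast"] == c)].iloc[0]
                    if row["logFC"] > 1 and adj[(g, c)] < 0.05:
                        n_up += 1
                    if row["logFC"] < -1 and adj[(g, c)] < 0.05:
                        n_down += 1
                assert ft.values.loc[g, f"de_{grp_name}_n_up"] == n_up
                assert ft.values.loc[g, f"de_{grp_name}_n_down"] == n_down


# ---------------------------------------------------------------------- co-expression


def _expr(values, groups=None):
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{j}" for j in range(values.shape[1])]
    if groups is None:
        groups = pd.Series("all0", index=values.columns)
    return ExpressionMatrix(values=values, groups=groups)


class TestCoexpressionClassFeatures:
    def test_identical_profile_max_pcc_one(self, rng):
        base = rng.random(6) * 10
        values = np.vstack([base, base, rng.random(6) * 10])
        expr = _expr(values)
        labels = pd.Series({"g1": "SM", "g2": "GM"})
        ft = coexpression_class_features(expr, labels, method="pearson", per_group=False)
        assert ft.values.loc["g0", "coexp_pearson_all_SM_max"] == pytest.approx(1.0)

    def test_sole_class_member_missing_after_self_exclusion(self, rng):
        expr = _expr(rng.random((3, 5)))
        labels = pd.Series({"g0": "SM", "g1": "GM", "g2": "GM"})
        ft = coexpression_class_features(expr, labels, method="pearson", per_group=False)
        assert np.isnan(ft.values.loc["g0", "coexp_pearson_all_SM_max"])
        assert np.isnan(ft.values.loc["g0", "coexp_pearson_all_SM_median"])

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_pairwise_loop_oracle(self, rng, method):
        import scipy.stats

        x = rng.random((20, 8))
        expr = _expr(x)
        labels = pd.Series(
            {f"g{i}": ("SM" if i < 6 else "GM") for i in range(15)}
        )
        ft = coexpression_class_features(expr, labels, method=method, per_group=False)
        for i in range(20):
            for cls, members in (("SM", range(6)), ("GM", range(6, 15))):
                vals = []
                for j in members:
                    if i == j:
                        continue
                    if method == "pearson":
                        r = scipy.stats.pearsonr(x[i], x[j])[0]
                    else:
                        r = scipy.stats.spearmanr(x[i], x[j])[0]
                    vals.append(r)
                assert ft.values.loc[f"g{i}", f"coexp_{method}_all_{cls}_median"] == pytest.approx(
                    np.median(vals), abs=1e-10
                )
                assert ft.values.loc[f"g{i}", f"coexp_{method}_all_{cls}_max"] == pytest.approx(
                    max(vals), abs=1e-10
                )

    def test_pearson_equals_matrix_product_on_standardized(self, rng):
        x = rng.random((15, 10))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        prod = z @ z.T / x.shape[1]
        expr = _expr(x)
        labels = pd.Series({f"g{i}": "SM" for i in range(5)})
        ft = coexpression_class_features(expr, labels, method="pearson",
                                         classes=("SM",), per_group=False)
        for i in range(5, 15):
            expected = max(prod[i, j] for j in range(5))
            assert ft.values.loc[f"g{i}", "coexp_pearson_all_SM_max"] == pytest.approx(
                expected, abs=1e-10
            )

    def test_partial_correlation_bounded_and_symmetric_input_ok(self, rng):
        expr = _expr(rng.random((10, 12)))
        labels = pd.Series({f"g{i}": "SM" for i in range(4)})
        ft = coexpression_class_features(expr, labels, method="partial",
                                         classes=("SM",), per_group=False)
        vals = ft.values["coexp_partial_all_SM_max"].dropna()
        assert ((vals >= -1.000001) & (vals <= 1.000001)).all()

    def test_too_few_samples_rejected(self, rng):
        expr = _expr(rng.random((4, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            coexpression_class_features(expr, pd.Series({"g0": "SM"}))


class TestClusterModules:
    def test_planted_two_block_recovery_kmeans(self, rng):
        block1 = rng.normal(2, 0.2, size=(10, 6))
        block2 = rng.normal(8, 0.2, size=(10, 6))
        expr = _expr(np.vstack([block1, block2]))
        ft = cluster_module_features(expr, "kmeans", k=2, seed=0)
        assign = ft.values.to_numpy().argmax(axis=1)
        # label-invariant: both blocks pure, different modules
        assert len(set(assign[:10])) == 1 and len(set(assign[10:])) == 1
        assert assign[0] != assign[10]

    def test_k1_single_all_ones_column(self, rng):
        expr = _expr(rng.random((6, 5)))
        ft = cluster_module_features(expr, "hier_ward", k=1, seed=0)
        assert ft.values.shape[1] == 1
        assert (ft.values.iloc[:, 0] == 1.0).all()

    def test_hier_average_matches_manual_dendrogram_cut(self):
        # 5 one-dimensional points: {0, 1} and {10, 11, 12.5} merge first;
        # cutting at k=2 must recover those two groups
        x = np.array([[0.0], [1.0], [10.0], [11.0], [12.5]])
        expr = _expr(np.repeat(x, 3, axis=1))
        ft = cluster_module_features(expr, "hier_average", k=2, seed=0)
        assign = ft.values.to_numpy().argmax(axis=1)
        assert assign[0] == assign[1]
        assert assign[2] == assign[3] == assign[4]
        assert assign[0] != assign[2]

    def test_each_gene_exactly_one_module(self, rng):
        expr = _expr(rng.random((12, 5)))
        for method in ("kmeans", "cmeans", "hier_complete"):
            ft = cluster_module_features(expr, method, k=3, seed=1)
            assert (ft.values.sum(axis=1) == 1.0).all()

    def test_k_out_of_range_rejected(self, rng):
        expr = _expr(rng.random((4, 5)))
        with pytest.raises(ValueError, match="out of range"):
            cluster_module_features(expr, "kmeans", k=5, seed=0)


class TestSelectTopModules:
    def make_modules(self, rng, n_genes=40, n_modules=12):
        genes = [f"g{i}" for i in range(n_genes)]
        values = pd.DataFrame(
            (rng.random((n_genes, n_modules)) < 0.3).astype(float),
            index=genes, columns=[f"m{j}" for j in range(n_modules)],
        )
        meta = pd.DataFrame(
            {"category": "coexpression", "kind": "binary", "shared": False},
            index=values.columns,
        )
        return FeatureTable(values=values, meta=meta)

    def test_perfectly_separating_module_ranked_first(self, rng):
        modules = self.make_modules(rng)
        labels = pd.Series(
            ["SM"] * 15 + ["GM"] * 25, index=modules.values.index
        )
        modules.values["m0"] = (labels == "SM").astype(float)  # pure SM module
        top = select_top_modules(modules, labels, n=3, mode="fisher_score")
        assert "m0" in top.feature_names

    def test_n_at_least_total_returns_input(self, rng):
        modules = self.make_modules(rng)
        labels = pd.Series(["SM"] * 20 + ["GM"] * 20, index=modules.values.index)
        top = select_top_modules(modules, labels, n=100)
        assert top.feature_names == modules.feature_names

    def test_fisher_mode_matches_enrichment_oracle(self, rng):
        import scipy.stats

        modules = self.make_modules(rng, n_genes=60, n_modules=10)
        labels = pd.Series(["SM"] * 20 + ["GM"] * 40, index=modules.values.index)
        top = select_top_modules(modules, labels, n=4, mode="fisher_score")
        pvals = {}
        for col in modules.feature_names:
            member = modules.values[col] > 0
            is_sm = labels == "SM"
            table = [
                [(member & is_sm).sum(), (member & ~is_sm).sum()],
                [(~member & is_sm).sum(), (~member & ~is_sm).sum()],
            ]
            pvals[col] = scipy.stats.fisher_exact(table)[1]
        expected = sorted(sorted(pvals, key=lambda c: (pvals[c], modules.feature_names.index(c)))[:4],
                          key=modules.feature_names.index)
        assert top.feature_names == expected


# ---------------------------------------------------------------------- genomic / duplication


def make_coords(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneCoordinates.from_frame(df)


class TestGenomicClusterCounts:
    def test_adjacent_pair_within_window(self):
        coords = make_coords([("gA", "1", 1000, 2000), ("gB", "1", 7000, 8000)])
        labels = pd.Series({"gA": "SM", "gB": "GM"})
        ft = genomic_cluster_counts(coords, labels)
        assert ft.values.loc["gA", "cluster_n_GM"] == 1
        assert ft.values.loc["gB", "cluster_n_SM"] == 1
        assert ft.values.loc["gA", "cluster_n_SM"] == 0

    def test_far_apart_not_counted(self):
        coords = make_coords([("gA", "1", 1000, 2000), ("gB", "1", 52000, 53000)])
        labels = pd.Series({"gA": "SM", "gB": "GM"})
        ft = genomic_cluster_counts(coords, labels)
        assert ft.values.to_numpy().sum() == 0

    def test_matches_all_pairs_brute_force(self, rng):
        n = 200
        rows = []
        for i in range(n):
            chrom = str(rng.integers(1, 4))
            start = int(rng.integers(1, 500_000))
            rows.append((f"g{i}", chrom, start, start + int(rng.integers(100, 5000))))
        coords = make_coords(rows)
        labels = pd.Series(
            {f"g{i}": rng.choice(["SM", "GM", "DF"]) for i in range(n)}
        )
        ft = genomic_cluster_counts(coords, labels, window_bp=10_000, window_genes=10)
        t = coords.table
        for gi in t.index:
            exp_sm = exp_gm = 0
            for gj in t.index:
                if gi == gj or t.loc[gi, "chrom"] != t.loc[gj, "chrom"]:
                    continue
                if abs(t.loc[gi, "rank"] - t.loc[gj, "rank"]) > 10:
                    continue
                gap = max(
                    0,
                    max(t.loc[gi, "start"], t.loc[gj, "start"])
                    - min(t.loc[gi, "end"], t.loc[gj, "end"]),
                )
                if gap > 10_000:
                    continue
                if labels[gj] == "SM":
                    exp_sm += 1
                elif labels[gj] == "GM":
                    exp_gm += 1
            assert ft.values.loc[gi, "cluster_n_SM"] == exp_sm, gi
            assert ft.values.loc[gi, "cluster_n_GM"] == exp_gm, gi


class TestDuplicationFeatures:
    coords = None

    def setup_method(self):
        rows = [(f"g{i}", "1", 1000 * (i + 1), 1000 * (i + 1) + 500) for i in range(40)]
        self.coords = make_coords(rows)

    def test_rank_distance_one_tandem(self):
        pairs = ParalogTable(pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]}))
        ft = duplication_features(pairs, self.coords)
        assert ft.values.loc["g0", "dup_tandem"] == 1.0
        assert ft.values.loc["g1", "dup_tandem"] == 1.0

    def test_rank_distance_seven_proximal_not_tandem(self):
        pairs = ParalogTable(pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g7"]}))
        ft = duplication_features(pairs, self.coords)
        assert ft.values.loc["g0", "dup_proximal"] == 1.0
        assert ft.values.loc["g0", "dup_tandem"] == 0.0

    def test_rank_distance_thirty_neither(self):
        pairs = ParalogTable(pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g30"]}))
        ft = duplication_features(pairs, self.coords)
        assert ft.values.loc["g0", "dup_tandem"] == 0.0
        assert ft.values.loc["g0", "dup_proximal"] == 0.0

    def test_upstream_flags_passed_through(self):
        pairs = ParalogTable(
            pd.DataFrame(
                {"gene_a": ["g0"], "gene_b": ["g30"], "syntenic": [True], "dispersed": [False]}
            )
        )
        ft = duplication_features(pairs, self.coords)
        assert ft.values.loc["g0", "dup_syntenic"] == 1.0
        assert ft.values.loc["g30", "dup_dispersed"] == 0.0

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pairs"):
            ParalogTable(pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g0"]}))

    def test_unknown_gene_rejected(self):
        pairs = ParalogTable(pd.DataFrame({"gene_a": ["g0"], "gene_b": ["nope"]}))
        with pytest.raises(ValueError, match="unknown gene"):
            duplication_features(pairs, self.coords)


class TestEvolutionarySummaries:
    def test_median_max_closed_form(self):
        hom = HomologyTable(
            pairs=pd.DataFrame(
                {"gene": ["g1", "g1"], "species": ["spX", "spX"], "dn_ds": [0.1, 0.3]}
            ),
            orthogroup=pd.Series({"g1": "OG1"}),
        )
        ft = evolutionary_summaries(hom, focal_species="focal")
        assert ft.values.loc["g1", "homolog_spX_dnds_median"] == pytest.approx(0.2)
        assert ft.values.loc["g1", "homolog_spX_dnds_max"] == pytest.approx(0.3)
        assert ft.values.loc["g1", "homolog_spX_presence"] == 1.0

    def test_absent_homolog_missing_features(self):
        hom = HomologyTable(
            pairs=pd.DataFrame({"gene": ["g1"], "species": ["spX"], "dn_ds": [0.1]}),
            orthogroup=pd.Series({"g1": "OG1", "g2": "OG1"}),
        )
        ft = evolutionary_summaries(hom, focal_species="focal")
        assert ft.values.loc["g2", "homolog_spX_presence"] == 0.0
        assert np.isnan(ft.values.loc["g2", "homolog_spX_dnds_max"])

    def test_family_size_matches_brute_force(self, rng):
        genes = [f"g{i}" for i in range(30)]
        og = pd.Series({g: f"OG{rng.integers(0, 6)}" for g in genes})
        hom = HomologyTable(
            pairs=pd.DataFrame({"gene": genes, "species": "spX", "dn_ds": rng.random(30)}),
            orthogroup=og,
        )
        ft = evolutionary_summaries(hom, focal_species="focal")
        for g in genes:
            expected = sum(1 for other in genes if og[other] == og[g])
            assert ft.values.loc[g, "family_size"] == expected

    def test_negative_dnds_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            HomologyTable(
                pairs=pd.DataFrame({"gene": ["g1"], "species": ["spX"], "dn_ds": [-0.1]}),
                orthogroup=pd.Series({"g1": "OG1"}),
            )


# ---------------------------------------------------------------------- harmonize


def make_table(values: pd.DataFrame, kinds: dict, shared=True) -> FeatureTable:
    meta = pd.DataFrame(
        {"category": "synthetic", "kind": pd.Series(kinds), "shared": shared}
    )
    meta.index.name = "feature"
    return FeatureTable(values=values, meta=meta.loc[values.columns])


class TestHarmonize:
    def test_zscore_closed_form(self):
        a = make_table(pd.DataFrame({"f": [1.0, 2.0, 3.0]}), {"f": "continuous"})
        b = make_table(pd.DataFrame({"f": [4.0, 5.0, 6.0]}), {"f": "continuous"})
        ha, hb = harmonize_shared_features(a, b, ["f"])
        np.testing.assert_allclose(ha.values["f"], [-1.224744871, 0.0, 1.224744871])
        np.testing.assert_allclose(hb.values["f"], [-1.224744871, 0.0, 1.224744871])

    def test_binary_passthrough(self):
        a = make_table(pd.DataFrame({"b": [0.0, 1.0, 1.0]}), {"b": "binary"})
        b = make_table(pd.DataFrame({"b": [1.0, 0.0, 0.0]}), {"b": "binary"})
        ha, hb = harmonize_shared_features(a, b, ["b"])
        np.testing.assert_allclose(ha.values["b"], [0.0, 1.0, 1.0])

    def test_constant_column_zeroed_with_warning(self, caplog):
        a = make_table(pd.DataFrame({"f": [5.0, 5.0, 5.0]}), {"f": "continuous"})
        b = make_table(pd.DataFrame({"f": [1.0, 2.0, 3.0]}), {"f": "continuous"})
        import logging

        with caplog.at_level(logging.WARNING, logger="smtransfer.features"):
            ha, _ = harmonize_shared_features(a, b, ["f"])
        assert (ha.values["f"] == 0.0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_missing_shared_name_rejected(self):
        a = make_table(pd.DataFrame({"f": [1.0, 2.0]}), {"f": "continuous"})
        b = make_table(pd.DataFrame({"g": [1.0, 2.0]}), {"g": "continuous"})
        with pytest.raises(KeyError, match="missing"):
            harmonize_shared_features(a, b, ["f"])

    def test_kind_mismatch_rejected(self):
        a = make_table(pd.DataFrame({"f": [1.0, 0.0]}), {"f": "binary"})
        b = make_table(pd.DataFrame({"f": [1.0, 2.0]}), {"f": "continuous"})
        with pytest.raises(ValueError, match="kind mismatch"):
            harmonize_shared_features(a, b, ["f"])

    def test_mean_zero_sd_one_property(self, small_world):
        src, tgt = small_world.source.features, small_world.target.features
        ha, hb = harmonize_shared_features(src, tgt, small_world.shared_features)
        for h in (ha, hb):
            cont = [n for n in h.feature_names if h.meta.loc[n, "kind"] == "continuous"]
            x = h.values[cont].to_numpy()
            nonconst = x.std(axis=0) > 0
            assert np.abs(x.mean(axis=0)[nonconst]).max() < 1e-9
            assert np.abs(x.std(axis=0)[nonconst] - 1).max() < 1e-9
        assert h.values.attrs.get("harmonized") is True

    def test_identical_column_order(self, small_world):
        ha, hb = harmonize_shared_features(
            small_world.source.features, small_world.target.features,
            small_world.shared_features,
        )
        assert ha.feature_names == hb.feature_names == small_world.shared_features


def test_row_order_invariance_of_summaries(rng):
    """Derived continuous features must not depend on gene-row order."""
    values = pd.DataFrame(
        rng.random((8, 6)), index=[f"g{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(6)],
    )
    groups = pd.Series("dev", index=values.columns)
    ft1 = expression_summaries(ExpressionMatrix(values=values, groups=groups))
    shuffled = values.sample(frac=1.0, random_state=1)
    ft2 = expression_summaries(ExpressionMatrix(values=shuffled, groups=groups))
    pd.testing.assert_frame_equal(ft1.values, ft2.values.loc[ft1.values.index])


def test_impute_missing_binary_zero_continuous_median():
    values = pd.DataFrame(
        {"b": [1.0, np.nan, 0.0, 1.0], "c": [1.0, 2.0, np.nan, 10.0]},
        index=list("wxyz"),
    )
    table = make_table(values, {"b": "binary", "c": "continuous"})
    out = impute_missing(table, train_genes=pd.Index(["w", "x"]))
    assert out.values.loc["x", "b"] == 0.0
    assert out.values.loc["y", "c"] == 1.5  # median of training rows only
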