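"""Coexpression network core: oracles, hand examples, recovery."""

import numpy as np
import pandas as pd
import pytest

from gliasig import enrichment, netcore
from gliasig.netcore import NetworkParams, UNASSIGNED


def expr_frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestOutlierRemoval:
    def test_anticorrelated_sample_removed_at_hand_zk(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 50)
        cols = np.column_stack([profile] * 5 + [-profile])
        expr = expr_frame(cols)
        kept, zk = netcore.remove_outlier_samples(expr)
        # k = (4,4,4,4,4,0) -> Z.K of the outlier = -2.0412
        assert zk.iloc[-1] == pytest.approx(-5 / np.sqrt(6), abs=1e-9)
        assert zk.iloc[-1] < -2
        assert kept == list(expr.columns[:5])

    def test_identical_profiles_all_kept(self):
        profile = np.arange(10.0)
        expr = expr_frame(np.column_stack([profile] * 4))
        kept, zk = netcore.remove_outlier_samples(expr)
        assert kept == list(expr.columns)
        assert zk.to_numpy() == pytest.approx(0.0)

    def test_infinite_cutoff_keeps_all(self):
        rng = np.random.default_rng(1)
        expr = expr_frame(rng.normal(size=(30, 6)))
        kept, _ = netcore.remove_outlier_samples(expr, zk_cutoff=-np.inf)
        assert kept == list(expr.columns)

    def test_constant_sample_named_in_error(self):
        expr = expr_frame(np.column_stack([np.arange(5.0),
                                           np.ones(5), np.arange(5.0) ** 2]))
        with pytest.raises(ValueError, match="s1"):
            netcore.remove_outlier_samples(expr)


class TestAdjacency:
    def test_identical_genes_full_adjacency(self):
        expr = expr_frame([[1, 2, 3], [2, 4, 6]])
        adj = netcore.adjacency(expr, NetworkParams(power=1))
        assert adj.iat[0, 1] == pytest.approx(1.0)

    def test_orthogonal_genes_zero_adjacency(self):
        expr = expr_frame([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        adj = netcore.adjacency(expr, NetworkParams(power=1))
        assert adj.iat[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_power_six_on_half_correlation(self):
        # two genes engineered to correlate exactly 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        a = np.array([1.0, 0.0, -1.0])
        b = np.array([0.0, 1.0, -1.0])
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.5)
        adj = netcore.adjacency(expr_frame([a, b]), NetworkParams(power=6))
        assert adj.iat[0, 1] == pytest.approx(0.5 ** 6)

    def test_constant_gene_named_in_error(self):
        expr = expr_frame([[1, 2, 3], [5, 5, 5]], genes=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            netcore.adjacency(expr, NetworkParams())


def tom_oracle(a):
    """Triple-loop topological overlap, straight from the definition."""
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    def test_three_gene_hand_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = netcore.tom_similarity(pd.DataFrame(a))
        assert tom.iat[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))

    def test_identity_adjacency_maps_to_identity(self):
        tom = netcore.tom_similarity(pd.DataFrame(np.eye(4)))
        assert tom.to_numpy() == pytest.approx(np.eye(4))

    @pytest.mark.parametrize("n,seed", [(4, 0), (4, 1), (5, 2), (6, 3),
                                        (6, 4), (5, 5)])
    def test_matches_triple_loop_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = netcore.tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.abs(tom - tom_oracle(a)).max() < 1e-12


def block_tom(sizes, within=0.9, between=0.05):
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    genes = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(t, index=genes, columns=genes)


class TestCutModules:
    def test_two_perfect_blocks_found(self):
        tom = block_tom([30, 30])
        assignment = netcore.cut_modules(tom, NetworkParams(cut_height=0.5,
                                                            min_module_size=30))
        sizes = assignment.value_counts()
        assert set(sizes.index) == {"M1", "M2"}
        assert (sizes == 30).all()

    def test_min_size_filter_unassigns_small_blocks(self):
        tom = block_tom([30, 30])
        assignment = netcore.cut_modules(tom, NetworkParams(cut_height=0.5,
                                                            min_module_size=31))
        assert (assignment == UNASSIGNED).all()

    def test_perfect_pair_is_one_module(self):
        tom = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        assignment = netcore.cut_modules(tom, NetworkParams(cut_height=0.5,
                                                            min_module_size=2))
        assert (assignment == "M1").all()


class TestEigengene:
    def test_single_gene_module(self):
        rng = np.random.default_rng(0)
        expr = expr_frame(rng.normal(size=(1, 8)))
        assignment = pd.Series(["M1"], index=expr.index)
        me, varexp = netcore.module_eigengene(expr, assignment, "M1")
        assert varexp == pytest.approx(1.0)
        z = (expr.iloc[0] - expr.iloc[0].mean()) / expr.iloc[0].std(ddof=1)
        assert np.corrcoef(me, z)[0, 1] == pytest.approx(1.0)

    def test_two_correlated_genes_full_variance(self):
        expr = expr_frame([[1, 2, 3, 4], [10, 20, 30, 40]])
        assignment = pd.Series(["M1", "M1"], index=expr.index)
        me, varexp = netcore.module_eigengene(expr, assignment, "M1")
        assert varexp == pytest.approx(1.0)
        kme_tab = netcore.kme(expr, pd.DataFrame({"M1": me}).T)
        assert kme_tab["M1"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_variance_explained_is_maximal_over_projections(self):
        rng = np.random.default_rng(2)
        expr = expr_frame(rng.normal(size=(20, 10)))
        assignment = pd.Series(["M1"] * 20, index=expr.index)
        _, varexp = netcore.module_eigengene(expr, assignment, "M1")
        z = ((expr.sub(expr.mean(axis=1), axis=0))
             .div(expr.std(axis=1, ddof=1), axis=0)).to_numpy()
        total = (z ** 2).sum()
        for _ in range(1000):
            v = rng.normal(size=10)
            v /= np.linalg.norm(v)
            assert ((z @ v) ** 2).sum() / total <= varexp + 1e-12

    def test_me_unit_norm(self, benchmark_network):
        mes = benchmark_network["eigengenes"]
        norms = np.linalg.norm(mes.to_numpy(), axis=1)
        assert norms == pytest.approx(1.0, abs=1e-9)


class TestKme:
    def test_hand_pearson_example(self):
        expr = expr_frame([[1, 2, 3]])
        me = pd.DataFrame({"M1": pd.Series([3, 1, 2], index=expr.columns)}).T
        assert netcore.kme(expr, me).iat[0, 0] == pytest.approx(-0.5)

    def test_gene_equal_to_negative_me(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=6)
        expr = expr_frame([v, -v])
        me = pd.DataFrame({"M1": pd.Series(v, index=expr.columns)}).T
        tab = netcore.kme(expr, me)
        assert tab["M1"].to_numpy() == pytest.approx([1.0, -1.0])


class TestMergeModules:
    @staticmethod
    def latent_module_expr(rho, n_samples=40, genes_per_module=5, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=n_samples)
        w = rng.normal(size=n_samples)
        u = (u - u.mean()) / u.std()
        w = w - w.mean() - u * (u @ (w - w.mean())) / (u @ u)
        w /= w.std()
        v = rho * u + np.sqrt(1 - rho ** 2) * w
        rows = [u * (1 + 0.1 * i) for i in range(genes_per_module)] + \
               [v * (1 + 0.1 * i) for i in range(genes_per_module)]
        expr = expr_frame(rows)
        assignment = pd.Series(["M1"] * genes_per_module +
                               ["M2"] * genes_per_module, index=expr.index)
        return expr, assignment

    def test_same_latent_factor_modules_merge(self):
        expr, assignment = self.latent_module_expr(rho=0.95)
        merged = netcore.merge_modules(expr, assignment, NetworkParams())
        assert merged.nunique() == 1

    def test_correlation_at_threshold_not_merged(self):
        expr, assignment = self.latent_module_expr(rho=0.85)
        mes = netcore.eigengene_matrix(expr, assignment)
        r = np.corrcoef(mes.to_numpy())[0, 1]
        params = NetworkParams(merge_r_threshold=r)  # strict > means no merge
        merged = netcore.merge_modules(expr, assignment, params)
        assert merged.nunique() == 2
        params_low = NetworkParams(merge_r_threshold=r - 1e-9)
        assert netcore.merge_modules(expr, assignment, params_low).nunique() == 1

    def test_independent_modules_unchanged(self):
        expr, assignment = self.latent_module_expr(rho=0.0)
        merged = netcore.merge_modules(expr, assignment, NetworkParams())
        assert merged.equals(assignment)


class TestHubGenes:
    def make_kme(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        tab = pd.DataFrame({"M1": values}, index=genes)
        assignment = pd.Series("M1", index=genes)
        return tab, assignment

    def test_threshold_semantics(self):
        tab, assignment = self.make_kme([0.95, 0.81, 0.79])
        hubs = netcore.hub_genes(tab, assignment, "M1",
                                 NetworkParams(hub_kme_threshold=0.8))
        assert hubs == ["g0", "g1"]

    def test_unreachable_threshold_empty(self):
        tab, assignment = self.make_kme([0.95, 0.81])
        params = NetworkParams(hub_kme_threshold=1.01)
        assert netcore.hub_genes(tab, assignment, "M1", params) == []

    def test_unknown_module_rejected(self):
        tab, assignment = self.make_kme([0.9])
        with pytest.raises(ValueError):
            netcore.hub_genes(tab, assignment, "M9", NetworkParams())


class TestEigengeneAnova:
    @staticmethod
    def anova_input(groups):
        vals, labels = [], []
        for name, arr in groups.items():
            vals.extend(arr)
            labels.extend([name] * len(arr))
        idx = [f"s{i}" for i in range(len(vals))]
        me = pd.Series(vals, index=idx, dtype=float)
        meta = pd.DataFrame({"grp": labels}, index=idx)
        return me, meta

    def test_equal_group_means_give_f_zero(self):
        me, meta = self.anova_input({"a": [1, 2, 3], "b": [1, 2, 3],
                                     "c": [1, 2, 3]})
        res = netcore.eigengene_anova(me, meta, None, "grp")
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_f_statistic(self):
        me, meta = self.anova_input({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        res = netcore.eigengene_anova(me, meta, None, "grp")
        assert res.f_statistic == pytest.approx(16.0)
        from scipy import stats
        assert res.p_value == pytest.approx(stats.f.sf(16.0, 2, 3))
        assert res.p_value == pytest.approx(0.025, abs=0.003)

    def test_degenerate_identical_groups_flagged(self):
        me, meta = self.anova_input({"a": [1, 1], "b": [1, 1]})
        res = netcore.eigengene_anova(me, meta, None, "grp")
        assert res.degenerate and res.p_value == 1.0


class TestSoftPower:
    def test_single_candidate_returned(self, benchmark_network):
        expr = benchmark_network["expr"]
        report = netcore.pick_soft_power(expr, candidate_powers=(6,))
        assert report.chosen == 6

    def test_white_noise_falls_back_to_max_with_warning(self):
        # at low powers white noise cannot reach the scale-free target, so
        # the chooser returns the largest candidate and sets the flag
        rng = np.random.default_rng(7)
        expr = expr_frame(rng.normal(size=(200, 15)))
        params = NetworkParams(scale_free_r2_target=0.95)
        report = netcore.pick_soft_power(expr, candidate_powers=(1, 2, 3),
                                         params=params)
        assert report.chosen == 3
        assert report.warning

    def test_modular_data_reaches_target(self, benchmark_network):
        report = benchmark_network["power_report"]
        assert not report.warning
        chosen_fit = report.fits.set_index("power").loc[report.chosen, "r2"]
        assert chosen_fit >= 0.8
        # reproducibility with the same input
        again = netcore.pick_soft_power(benchmark_network["expr"])
        assert again.chosen == report.chosen


class TestEndToEndRecovery:
    def test_exactly_one_module_captures_planted_set(self, benchmark,
                                                     benchmark_network):
        assignment = benchmark_network["assignment"]
        planted = benchmark["planted"]
        universe = set(assignment.index)
        enriched = []
        for m in sorted(set(assignment) - {UNASSIGNED}):
            genes = set(assignment.index[assignment == m])
            p = enrichment.hypergeom_overlap(genes, planted & universe,
                                             universe)
            if p < 1e-6:
                enriched.append(m)
        assert len(enriched) == 1
        me = benchmark_network["eigengenes"].loc[enriched[0]]
        meta = benchmark_network["meta"]
        wt = meta.index[meta["genotype"] == "WT"]
        stage_means = me[wt].groupby(meta.loc[wt, "stage"]).mean()
        assert stage_means["E12.5"] < stage_means["E13.5"] < stage_means["E14.5"]

    def test_hub_genes_enriched_for_planted_set(self, benchmark,
                                                benchmark_network):
        assignment = benchmark_network["assignment"]
        planted = benchmark["planted"]
        universe = set(assignment.index)
        sizes = assignment[assignment != UNASSIGNED].value_counts()
        module = sizes.index[0]
        hubs = netcore.hub_genes(benchmark_network["kme"], assignment, module,
                                 benchmark_network["params"])
        assert len(hubs) >= 3
        p = enrichment.hypergeom_overlap(set(hubs), planted & universe,
                                         universe)
        assert p < 0.01

    def test_eigengene_anova_reproduces_genotype_pattern(self, benchmark,
                                                         benchmark_network):
        # knockout suppresses the module eigengene at E14.5 (Tukey p < 0.01)
        # while rescue restores it (vs WT not significant)
        assignment = benchmark_network["assignment"]
        sizes = assignment[assignment != UNASSIGNED].value_counts()
        module = sizes.index[0]
        meta = benchmark_network["meta"]
        e14 = meta.index[meta["stage"] == "E14.5"]
        res = netcore.eigengene_anova(
            benchmark_network["eigengenes"][e14], meta.loc[e14], module,
            "genotype")
        tk = res.tukey.set_index(["group_a", "group_b"])["p_adj"]

        def pair_p(a, b):
            return tk.get((a, b), tk.get((b, a)))

        assert pair_p("WT", "cKO") < 0.01
        assert pair_p("WT", "rescue") > 0.05
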