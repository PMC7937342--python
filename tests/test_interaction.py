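import numpy as np
import pandas as pd
import pytest

from ripseq import interaction as inter
from ripseq import simulate as sim
from ripseq.io_formats import RunConfig


def toy_composition_matrix():
    """100-gene two-sample matrix, 10 genes 8-fold up in B: library-size
    normalization alone would misstate the unchanged genes."""
    rng = np.random.default_rng(20240631)
    base = rng.integers(50, 2000, size=100)
    b = base.copy()
    b[:10] = b[:10] * 8
    return pd.DataFrame({"A": base, "B": b}, index=[f"g{i}" for i in range(100)])


class TestCpmFilter:
    def test_all_zero_gene_discarded(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 200]}, index=["z", "ok"])
        assert list(inter.cpm_filter(counts, ["s1", "s2"])) == ["ok"]

    def test_cpm_exactly_one_in_one_replicate_retained(self):
        # gene "edge": 1 count in 1e6 library = exactly 1 CPM in s1 only
        counts = pd.DataFrame(
            {"s1": [1, 999_999], "s2": [0, 1_000_000]}, index=["edge", "big"]
        )
        kept = inter.cpm_filter(counts, ["s1", "s2"])
        assert "edge" in kept

    def test_hand_computed_toy_matrix(self):
        lib = 10_000
        counts = pd.DataFrame({
            "s1": [0, 0, 5, 100, 9795, 0, 20, 30, 25, 25],
            "s2": [0, 1, 0, 200, 9699, 0, 30, 20, 25, 25],
        }, index=[f"g{i}" for i in range(10)])
        assert counts.sum().tolist() == [lib, lib]
        # CPM = count x 100 here; threshold 1 CPM = 0.01 counts
        kept = set(inter.cpm_filter(counts, ["s1", "s2"]))
        assert kept == {"g1", "g2", "g3", "g4", "g6", "g7", "g8", "g9"}

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]})
        with pytest.raises(inter.DataError):
            inter.cpm_filter(counts, ["s1", "s2"])


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 30, 40], "B": [10, 20, 30, 40]})
        assert inter.tmm_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 30, 40], "B": [20, 40, 60, 80]})
        assert inter.tmm_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_composition_bias_matches_published_algorithm(self):
        """Factors on the toy composition-bias matrix agree to 1e-6 with an
        independent implementation of the published trimmed-mean-of-M-values
        algorithm (edgeR 4.0.16 calcNormFactors, frozen oracle values)."""
        f = inter.tmm_factors(toy_composition_matrix())
        assert f["A"] == pytest.approx(1.305241388356, abs=1e-6)
        assert f["B"] == pytest.approx(0.766141810183, abs=1e-6)

    def test_factor_direction_compensates_composition(self):
        f = inter.tmm_factors(toy_composition_matrix())
        # B's library is inflated by the 10 up genes: its factor drops below 1
        assert f["B"] < 1.0 < f["A"]
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(inter.DataError):
            inter.tmm_factors(counts)


class TestCommonDispersion:
    def test_recovers_known_dispersion(self):
        rng = np.random.default_rng(5)
        phi = 0.1225  # BCV 0.35
        mu = rng.lognormal(4, 1, size=3000)
        lam = rng.gamma(1 / phi, phi * mu[:, None] * np.ones(8))
        y = pd.DataFrame(rng.poisson(lam), columns=[f"s{i}" for i in range(8)])
        groups = [[f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]]
        est = inter.estimate_common_dispersion(y, groups)
        assert est == pytest.approx(phi, rel=0.10)

    def test_poisson_data_floors_at_zero(self):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(4, 1, size=2000)
        y = pd.DataFrame(rng.poisson(mu[:, None] * np.ones(6)),
                         columns=[f"s{i}" for i in range(6)])
        groups = [[f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]]
        assert inter.estimate_common_dispersion(y, groups) < 0.01


class TestReferenceDe:
    def test_null_simulation_calibrated(self):
        cfg = sim.CountSimConfig(seed=7, class_sizes={})
        counts, design, _ = sim.simulate_counts(cfg)
        comp = inter.reference_de(counts, inter.standard_contrasts(design)["blue"],
                                  "blue")
        fdrs = np.array([g.fdr for g in comp.genes])
        assert np.mean(fdrs < 0.05) <= 0.05

    def test_planted_fourfold_mostly_detected(self):
        """Genes planted at 4-fold with BCV 0.3 and n=4 are detected at a
        rate consistent with the closed-form power envelope (>=75%)."""
        cfg = sim.CountSimConfig(seed=8, bcv=0.3)
        counts, design, truth = sim.simulate_counts(cfg)
        comp = inter.reference_de(counts, inter.standard_contrasts(design)["red"],
                                  "red")
        calls = inter.de_filter(comp)
        planted = truth.loc[truth["class"] == "wasp_up", "gene_id"]
        assert np.mean([g in calls["up"] for g in planted]) >= 0.75

    def test_all_equal_counts_not_de(self):
        counts = pd.DataFrame(
            np.full((50, 8), 100), columns=[f"s{i}" for i in range(8)],
            index=[f"g{i}" for i in range(50)],
        )
        comp = inter.reference_de(
            counts, ([f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]),
            "blue", dispersion=0.1,
        )
        for g in comp.genes:
            assert g.log2fc == pytest.approx(0.0, abs=1e-9) and g.fdr > 0.9

    def test_single_replicate_side_refused(self):
        counts = pd.DataFrame({"a": [10] * 5, "b": [12] * 5, "c": [11] * 5})
        with pytest.raises(inter.DataError, match="allow_no_replication"):
            inter.reference_de(counts, (["a"], ["b", "c"]), "blue")


def _comp(name, up=(), down=()):
    genes = [inter.DEGene(g, 1.0, 0.01) for g in up] + \
            [inter.DEGene(g, -1.0, 0.01) for g in down]
    return inter.DEComparison(name=name, genes=genes)


class TestVennPartition:
    def test_gene_up_only_in_red(self):
        p = inter.venn_partition(_comp("blue"), _comp("red", up=["g1"]),
                                 _comp("green"))
        assert p.regions["up"] == {"g1": "red_only"}

    def test_direction_stratified_double_membership(self):
        """A gene down in green and up in red occupies both partitions —
        the restored-gene reading of the three-set diagram."""
        p = inter.venn_partition(
            _comp("blue"), _comp("red", up=["g1"]), _comp("green", down=["g1"]))
        assert p.regions["up"]["g1"] == "red_only"
        assert p.regions["down"]["g1"] == "green_only"

    def test_duplicate_gene_ids_rejected(self):
        genes = [inter.DEGene("g1", 1.0, 0.01), inter.DEGene("g1", 2.0, 0.01)]
        with pytest.raises(inter.DataError, match="duplicate"):
            inter.DEComparison(name="blue", genes=genes)

    def test_sub_threshold_genes_excluded(self):
        genes = [inter.DEGene("weak", 0.40, 0.001), inter.DEGene("lax", 2.0, 0.20),
                 inter.DEGene("ok", 0.58, 0.049)]
        p = inter.venn_partition(inter.DEComparison("blue", genes),
                                 _comp("red"), _comp("green"))
        assert p.regions["up"] == {"ok": "blue_only"}

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_set_algebra_oracle(self, seed):
        """Regions are disjoint, exhaustive, and identical to brute-force
        set operations on randomized 300-gene instances."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(300)]
        sets = {}
        comps = {}
        for name in inter.CONTRAST_NAMES:
            up = set(rng.choice(genes, size=rng.integers(0, 80), replace=False))
            down = set(rng.choice(
                [g for g in genes if g not in up],
                size=rng.integers(0, 80), replace=False))
            sets[name] = {"up": up, "down": down}
            comps[name] = inter.DEComparison(name, [
                inter.DEGene(g, 1.0, 0.01) for g in sorted(up)
            ] + [inter.DEGene(g, -1.0, 0.01) for g in sorted(down)])
        p = inter.venn_partition(comps["blue"], comps["red"], comps["green"])
        for direction in ("up", "down"):
            b, r, g = (sets[n][direction] for n in inter.CONTRAST_NAMES)
            expected = {
                "blue_only": b - r - g, "red_only": r - b - g,
                "green_only": g - b - r, "blue_red": (b & r) - g,
                "blue_green": (b & g) - r, "red_green": (r & g) - b,
                "blue_red_green": b & r & g,
            }
            for region, members in expected.items():
                assert p.genes_in(direction, region) == members
            # partition property: disjoint and exhaustive
            assert set(p.regions[direction]) == b | r | g


class TestPatternClassifiers:
    @staticmethod
    def _expr_from_treatment_means(means, design, sd=0.05, seed=0):
        """Expression matrix with per-treatment means (genes x 4) plus noise."""
        rng = np.random.default_rng(seed)
        labels = inter.design_treatments(design)
        cols = {}
        order = [inter.TREATMENT_CONTROL, inter.TREATMENT_SPIROPLASMA,
                 inter.TREATMENT_WASP, inter.TREATMENT_BOTH]
        for sample in design.sample_id:
            t = order.index(labels[sample])
            cols[sample] = means[:, t] * (1 + rng.normal(0, sd, means.shape[0]))
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(means.shape[0])])

    def test_group_c_planted_gene(self):
        design = sim.make_design()
        means = np.array([[100.0, 95.0, 105.0, 400.0]])
        expr = self._expr_from_treatment_means(means, design)
        p = inter.venn_partition(_comp("blue"), _comp("red"),
                                 _comp("green", up=["g0"]))
        [a] = inter.classify_groups(p, expr, design)
        assert a.group == "C" and "peak:S+wasp" in a.evidence

    def test_red_only_flat_gene_unclassified(self):
        design = sim.make_design()
        expr = self._expr_from_treatment_means(
            np.array([[100.0, 100.0, 100.0, 100.0]]), design)
        p = inter.venn_partition(_comp("blue"), _comp("red", up=["g0"]),
                                 _comp("green"))
        [a] = inter.classify_groups(p, expr, design)
        assert a.group == "unclassified"

    def test_restored_up_gene_is_group_b(self):
        """Down in red, up in green, S+wasp back at control level."""
        design = sim.make_design()
        means = np.array([[200.0, 210.0, 40.0, 205.0]])
        expr = self._expr_from_treatment_means(means, design)
        p = inter.venn_partition(_comp("blue"), _comp("red", down=["g0"]),
                                 _comp("green", up=["g0"]))
        [a] = inter.classify_groups(p, expr, design)
        assert a.group == "B"

    def test_restored_down_gene_is_group_a(self):
        design = sim.make_design()
        means = np.array([[100.0, 102.0, 410.0, 95.0]])
        expr = self._expr_from_treatment_means(means, design)
        p = inter.venn_partition(_comp("blue"), _comp("red", up=["g0"]),
                                 _comp("green", down=["g0"]))
        [a] = inter.classify_groups(p, expr, design)
        assert a.group == "A"

    def test_b_like_annotation_for_blue_green_up(self):
        design = sim.make_design()
        means = np.array([[200.0, 420.0, 40.0, 205.0]])
        expr = self._expr_from_treatment_means(means, design)
        p = inter.venn_partition(_comp("blue", up=["g0"]), _comp("red"),
                                 _comp("green", up=["g0"]))
        [a] = inter.classify_groups(p, expr, design)
        assert a.group == "unclassified" and "B-like" in a.evidence

    def test_male_gonad_ordering_flagged(self):
        design = sim.make_design()
        means = np.array([
            [400.0, 8.0, 160.0, 8.0],    # the ordering pattern
            [100.0, 100.0, 100.0, 100.0],  # flat
            [160.0, 8.0, 400.0, 8.0],    # ordering violated (wasp highest)
        ])
        expr = self._expr_from_treatment_means(means, design)
        flagged = inter.male_gonad_pattern(expr, design)
        assert flagged == {"g0"}

    def test_per_sample_rescaling_absorbed_by_tmm_cpm(self):
        """Tripling one sample's sequencing depth is absorbed by
        normalization: CPM cancels the depth exactly and only TMM's
        depth-dependent precision weights move (sub-percent), so group
        classification is unchanged."""
        cfg = sim.CountSimConfig(seed=12)
        counts, design, _ = sim.simulate_counts(cfg)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        before = inter.tmm_cpm(counts)
        after = inter.tmm_cpm(scaled)
        assert np.allclose(before.values, after.values, rtol=0.01)
        contrasts = inter.standard_contrasts(design)
        comps = {n: inter.reference_de(counts, contrasts[n], n)
                 for n in inter.CONTRAST_NAMES}
        p = inter.venn_partition(comps["blue"], comps["red"], comps["green"])
        assert inter.classify_groups(p, before, design) == \
               inter.classify_groups(p, after, design)


class TestClusterView:
    def test_separates_planted_patterns(self):
        """Average-linkage on z-means groups restored-up, restored-down and
        boosted genes into distinct clusters."""
        design = sim.make_design()
        means = np.array([
            [100.0, 102.0, 410.0, 95.0],   # wasp-raised, restored
            [110.0, 100.0, 430.0, 100.0],
            [200.0, 210.0, 40.0, 205.0],   # wasp-lowered, restored
            [190.0, 200.0, 45.0, 210.0],
            [100.0, 95.0, 105.0, 400.0],   # boosted under S+wasp
            [90.0, 100.0, 95.0, 380.0],
        ])
        expr = TestPatternClassifiers._expr_from_treatment_means(means, design)
        view = inter.cluster_view(expr, design, list(expr.index), n_clusters=3)
        clusters = view["cluster"]
        assert clusters["g0"] == clusters["g1"]
        assert clusters["g2"] == clusters["g3"]
        assert clusters["g4"] == clusters["g5"]
        assert len({clusters["g0"], clusters["g2"], clusters["g4"]}) == 3

    def test_single_gene_degenerate(self):
        design = sim.make_design()
        expr = TestPatternClassifiers._expr_from_treatment_means(
            np.array([[1.0, 2.0, 3.0, 4.0]]), design)
        view = inter.cluster_view(expr, design, ["g0"])
        assert view.loc["g0", "cluster"] == 1


class TestAggregateIdenticalGenes:
    def test_rip3_5_additivity(self):
        counts = pd.DataFrame(
            {"s1": [2, 1, 0, 7], "s2": [3, 0, 1, 9]},
            index=["RIP3", "RIP4", "RIP5", "RIP1"],
        )
        merged = inter.aggregate_identical_genes(counts, {"RIP3-5": ["RIP3", "RIP4", "RIP5"]})
        assert merged.loc["RIP3-5"].tolist() == [3, 4]
        assert merged.loc["RIP1"].tolist() == [7, 9]
        assert merged.values.sum() == counts.values.sum()

    def test_empty_group_list_is_identity(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        assert inter.aggregate_identical_genes(counts, {}).equals(counts)

    def test_overlapping_groups_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2, 3]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="multiple groups"):
            inter.aggregate_identical_genes(
                counts, {"x": ["a", "b"], "y": ["b", "c"]})


class TestDeFilterMonotone:
    def test_relaxing_thresholds_never_removes_genes(self):
        rng = np.random.default_rng(3)
        genes = [inter.DEGene(f"g{i}", float(rng.normal(0, 2)),
                              float(rng.uniform(0, 1))) for i in range(200)]
        comp = inter.DEComparison("blue", genes)
        strict = inter.de_filter(comp, lfc_min=1.0, fdr_max=0.01)
        lax = inter.de_filter(comp, lfc_min=0.58, fdr_max=0.05)
        assert strict["up"] <= lax["up"] and strict["down"] <= lax["down"]
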