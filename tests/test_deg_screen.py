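import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhfsig import deg_screen
from rhfsig.deg_screen import (apply_deg_filter, human_de_filter, nb_wald_test,
                               normalize_rpm, ventricle_specific_sets)
from tests.conftest import condition_samples


class TestNormalizeRpm:
    def test_definition(self):
        counts = pd.DataFrame({"s": [10, 999_990]}, index=["g1", "g2"])
        rpm = normalize_rpm(counts)
        assert rpm.loc["g1", "s"] == pytest.approx(10.0)

    def test_uniform_counts_share_rpm_equally(self):
        counts = pd.DataFrame(np.full((8, 3), 7), columns=list("abc"))
        rpm = normalize_rpm(counts)
        assert np.allclose(rpm.to_numpy(), 1e6 / 8)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 6)))
        assert np.allclose(normalize_rpm(counts).sum(axis=0), 1e6)

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            normalize_rpm(counts)


class TestNbWaldTest:
    def test_duplicated_groups_give_null_results(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(40, 4)),
                              columns=["a1", "a2", "b1", "b2"])
        dup = counts.copy()
        dup.columns = ["c1", "c2", "c3", "c4"]
        both = pd.concat([counts, dup], axis=1)
        table = nb_wald_test(both, ["a1", "a2", "b1", "b2"],
                             ["c1", "c2", "c3", "c4"])
        assert np.allclose(table["log2fc"], 0.0)
        assert (table["p_value"] > 0.99).all()

    def test_all_zero_gene_gets_p_one(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(10, 6)))
        counts.iloc[3] = 0
        table = nb_wald_test(counts, list(counts.columns[:3]),
                             list(counts.columns[3:]))
        assert table.iloc[3]["p_value"] == 1.0
        assert table.iloc[3]["log2fc"] == 0.0

    def test_single_sample_group_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(5, 3)))
        with pytest.raises(ValueError):
            nb_wald_test(counts, [counts.columns[0]], list(counts.columns[1:]))

    def test_large_counts_agree_with_log_count_z_test(self):
        # dispersion-free (Poisson) counts in the large-sample regime: the
        # NB Wald p should track a Gaussian z-test on the log ratio of group
        # means with the known Poisson variance
        rng = np.random.default_rng(12)
        n, ns = 300, 20
        mu = rng.uniform(500, 1500, n)
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(n, 2 * ns)),
                              columns=[f"s{i}" for i in range(2 * ns)])
        table = nb_wald_test(counts, [f"s{i}" for i in range(ns)],
                             [f"s{i}" for i in range(ns, 2 * ns)])
        arr = counts.to_numpy(dtype=float)
        ma, mb = arr[:, :ns].mean(axis=1), arr[:, ns:].mean(axis=1)
        z = (np.log(ma) - np.log(mb)) / np.sqrt(1 / (ns * ma) + 1 / (ns * mb))
        p_ref = 2 * stats.norm.sf(np.abs(z))
        rel = np.abs(table["p_value"].to_numpy() - p_ref) / p_ref
        assert np.median(rel) < 0.10

    def test_planted_fourfold_gene_detected_reliably(self):
        # 6 vs 6 samples, moderate dispersion (alpha = 0.05): a 4-fold gene
        # should reach p <= 0.01 in at least 90% of simulations
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            mu = rng.uniform(200, 2000, 60)
            fold = np.ones((60, 12))
            fold[0, :6] = 4.0
            lam = rng.gamma(shape=1 / 0.05, scale=0.05 * mu[:, None] * fold)
            counts = pd.DataFrame(rng.poisson(lam),
                                  columns=[f"s{i}" for i in range(12)])
            table = nb_wald_test(counts, [f"s{i}" for i in range(6)],
                                 [f"s{i}" for i in range(6, 12)])
            hits += table.iloc[0]["p_value"] <= 0.01
        assert hits / n_sim >= 0.90

    def test_agrees_with_deseq2_oracle(self, small_rat_cohort):
        """Independent cross-check of the NB Wald engine against DESeq2."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, sheet, _ = small_rat_cohort
        dis = condition_samples(sheet, "PAB-H", "RV")
        ctl = condition_samples(sheet, "Sham-H", "RV")
        sub = counts[dis + ctl].iloc[:400]
        table = nb_wald_test(sub, dis, ctl)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meta = pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6},
                                index=dis + ctl)
            dds = DeseqDataSet(counts=sub.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
            ds.summary()
        ref = ds.results_df
        mask = ref["pvalue"].notna()
        rho = stats.spearmanr(table["p_value"][mask], ref["pvalue"][mask]).statistic
        assert rho > 0.95
        sig = mask & (ref["pvalue"] < 0.01) & (table["p_value"] < 0.01)
        signs_agree = (np.sign(table["log2fc"][sig])
                       == np.sign(ref["log2FoldChange"][sig]))
        assert signs_agree.all()


class TestDegFilter:
    @pytest.mark.parametrize(
        "log2fc, mean_disease, p, expected",
        [
            (1.2, 60.0, 0.005, True),    # all three satisfied
            (1.2, 50.0, 0.005, False),   # mean boundary is strict (> 50)
            (1.0, 60.0, 0.005, True),    # two-fold boundary is inclusive
            (0.99, 60.0, 0.005, False),
            (1.2, 60.0, 0.01, True),     # alpha boundary is inclusive
            (1.2, 60.0, 0.011, False),
            (-1.5, 60.0, 0.001, True),   # down-regulation counts too
        ],
    )
    def test_boundary_rules(self, log2fc, mean_disease, p, expected):
        table = pd.DataFrame({"log2fc": [log2fc],
                              "mean_rpm_disease": [mean_disease],
                              "p_value": [p], "padj": [p]}, index=["g"])
        assert (("g" in apply_deg_filter(table)) is expected)

    def test_relaxing_any_threshold_gives_superset(self, rng):
        table = pd.DataFrame({
            "log2fc": rng.normal(0, 1.5, 300),
            "mean_rpm_disease": rng.uniform(0, 200, 300),
            "p_value": rng.uniform(0, 0.1, 300),
        }, index=[f"g{i}" for i in range(300)])
        table["padj"] = table["p_value"]
        base = apply_deg_filter(table)
        assert base <= apply_deg_filter(table, fc_threshold=1.5)
        assert base <= apply_deg_filter(table, min_mean_disease=20)
        assert base <= apply_deg_filter(table, alpha=0.05)


class TestVentricleSpecificSets:
    def test_set_algebra_example(self):
        mapping = {
            ("PAB", "compensated", "RV"): {"a", "b", "c"},
            ("PAB", "compensated", "LV"): {"c"},
            ("PAB", "decompensated", "RV"): {"b", "d"},
        }
        sets = ventricle_specific_sets(mapping, "PAB")
        assert sets.compensated_specific == {"a", "b"}
        assert sets.shared == {"b"}
        assert sets.union == {"a", "b", "d"}

    def test_banding_venn_arithmetic(self):
        # 121 RV-specific compensated + 160 decompensated sharing 57 -> 224;
        # 10 + 117 disjoint -> 127
        shared = {f"s{i}" for i in range(57)}
        comp = shared | {f"c{i}" for i in range(121 - 57)}
        decomp = shared | {f"d{i}" for i in range(160 - 57)}
        pab = ventricle_specific_sets(
            {("PAB", "compensated", "RV"): comp,
             ("PAB", "compensated", "LV"): set(),
             ("PAB", "decompensated", "RV"): decomp}, "PAB")
        assert pab.sizes() == {"compensated_specific": 121, "decompensated": 160,
                               "shared": 57, "union": 224}
        aob = ventricle_specific_sets(
            {("AOB", "compensated", "LV"): {f"a{i}" for i in range(10)},
             ("AOB", "compensated", "RV"): set(),
             ("AOB", "decompensated", "LV"): {f"b{i}" for i in range(117)}},
            "AOB")
        assert aob.sizes()["union"] == 127

    def test_union_identity_holds(self, rng):
        for _ in range(20):
            comp = set(rng.choice(100, size=rng.integers(0, 40), replace=False))
            decomp = set(rng.choice(100, size=rng.integers(0, 40), replace=False))
            sets = ventricle_specific_sets(
                {("PAB", "compensated", "RV"): comp,
                 ("PAB", "compensated", "LV"): set(),
                 ("PAB", "decompensated", "RV"): decomp}, "PAB")
            assert len(sets.union) == (len(sets.compensated_specific)
                                       + len(sets.decompensated)
                                       - len(sets.shared))

    def test_missing_condition_rejected(self):
        with pytest.raises(KeyError):
            ventricle_specific_sets({("PAB", "compensated", "RV"): set()}, "PAB")


class TestHumanDeFilter:
    @pytest.mark.parametrize(
        "mean_count, padj, log2fc, expected",
        [
            (6.0, 0.01, 0.7, True),
            (6.0, 0.01, 0.585, False),   # |log2fc| boundary strict
            (5.0, 0.01, 0.7, False),     # count boundary strict
            (6.0, 0.05, 0.7, False),     # adjusted-p boundary strict
            (6.0, 0.01, -0.7, True),
        ],
    )
    def test_boundaries(self, mean_count, padj, log2fc, expected):
        table = pd.DataFrame({"mean_count": [mean_count], "padj": [padj],
                              "log2fc": [log2fc]}, index=["g"])
        assert (("g" in human_de_filter(table)) is expected)

    def test_empty_table(self):
        table = pd.DataFrame(columns=["mean_count", "padj", "log2fc"])
        assert human_de_filter(table) == set()
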