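import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhfsig import deg_screen, esc_rank, synthdata
from rhfsig.synthdata import (HumanSimConfig, RatSimConfig,
                              simulate_annotation_resources,
                              simulate_human_cohort, simulate_proteome,
                              simulate_rat_cohort, simulate_singlecell)
from tests.conftest import condition_samples


class TestRatSimulator:
    def test_identical_seed_gives_byte_identical_counts(self):
        cfg = RatSimConfig(n_genes=200, library_size=1e5, seed=1)
        c1, s1, t1 = simulate_rat_cohort(cfg)
        c2, s2, t2 = simulate_rat_cohort(RatSimConfig(n_genes=200,
                                                      library_size=1e5, seed=1))
        assert c1.to_csv() == c2.to_csv()
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_fold_change_recovered_in_expectation(self):
        # one template, +2 log2 in RV PAB groups, vanishing dispersion and a
        # large library: the empirical PAB/sham mean ratio approaches 4
        cfg = RatSimConfig(n_genes=200, n_per_group=6, library_size=5e6,
                           baseline_logmean_scale=0.3,
                           dispersion_a0=1e-13, dispersion_a1=0.0,
                           planted_clusters=[({("PAB-H", "RV"): 2.0,
                                               ("PAB-F", "RV"): 2.0}, 1)],
                           seed=5)
        counts, sheet, truth = simulate_rat_cohort(cfg)
        gene = truth.index[truth["role"] == "planted-DE"][0]
        rpm = deg_screen.normalize_rpm(counts)
        pab = rpm.loc[gene, condition_samples(sheet, "PAB-H", "RV")].mean()
        sham = rpm.loc[gene, condition_samples(sheet, "Sham-H", "RV")].mean()
        assert pab / sham == pytest.approx(4.0, rel=0.1)

    def test_zero_effect_cohort_rarely_passes_full_filter(self):
        # all effects zero: the joint three-part filter can select at most
        # the nominal p-threshold fraction
        cfg = RatSimConfig(n_genes=3000, library_size=1e6,
                           planted_clusters=[], seed=9)
        counts, sheet, _ = simulate_rat_cohort(cfg)
        table = deg_screen.nb_wald_test(
            counts, condition_samples(sheet, "PAB-H", "RV"),
            condition_samples(sheet, "Sham-H", "RV"))
        selected = deg_screen.apply_deg_filter(table)
        nominal = 0.01
        three_se = 3 * np.sqrt(nominal * (1 - nominal) / len(table))
        assert len(selected) / len(table) <= nominal + three_se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            RatSimConfig(n_genes=0)
        with pytest.raises(ValueError):
            RatSimConfig(library_size=-1)
        with pytest.raises(ValueError):
            RatSimConfig(n_per_group=1)
        with pytest.raises(ValueError):
            RatSimConfig(planted_clusters=[({("NOPE", "RV"): 1.0}, 5)])

    def test_sample_sheet_covers_design(self, small_rat_cohort):
        counts, sheet, _ = small_rat_cohort
        assert set(sheet["sample_id"]) == set(counts.columns)
        assert sheet.groupby(["group", "ventricle"]).size().eq(6).all()


class TestHumanSimulator:
    def test_zero_clinical_noise_gives_identical_parameter_ranks(self):
        cfg = HumanSimConfig(n_patients=20, n_genes=50, ci_noise=0.0,
                             ntprobnp_lognoise=0.0, tapse_spap_noise=0.0,
                             n_planted_pos=0, n_planted_neg=0, seed=3)
        _, clinical, _ = simulate_human_cohort(cfg)
        ranking = esc_rank.severity_rank(clinical)
        per_param = ranking.per_parameter
        pd.testing.assert_series_equal(per_param["CI"], per_param["NTproBNP"],
                                       check_names=False)
        pd.testing.assert_series_equal(per_param["CI"], per_param["TAPSE_sPAP"],
                                       check_names=False)

    def test_planted_negative_gene_detected_by_screen(self):
        cfg = HumanSimConfig(n_genes=60, n_planted_pos=0, n_planted_neg=5,
                             effect_slope=6.0, planted_baseline=(300.0, 400.0),
                             seed=4)
        counts, clinical, truth = simulate_human_cohort(cfg)
        ranking = esc_rank.severity_rank(clinical)
        norm = counts / deg_screen.size_factors(counts)
        screen = esc_rank.correlation_screen(norm, ranking)
        planted = truth.index[truth["role"] == "planted-neg-corr"]
        assert (screen.loc[planted, "r"] < -0.3).all()
        assert screen.loc[planted, "selected"].all()

    def test_determinism(self):
        cfg = HumanSimConfig(n_genes=40, seed=1, n_planted_pos=5, n_planted_neg=5)
        _, c1, _ = simulate_human_cohort(cfg)
        _, c2, _ = simulate_human_cohort(HumanSimConfig(n_genes=40, seed=1,
                                                        n_planted_pos=5,
                                                        n_planted_neg=5))
        pd.testing.assert_frame_equal(c1, c2)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            HumanSimConfig(n_patients=2)


class TestAnnotationResources:
    def test_below_minimum_set_present_but_excluded_from_ora(self):
        from rhfsig.enrichment import ora
        collection, _, _ = simulate_annotation_resources(200, seed=0)
        small = [n for n, s in collection.items() if len(s) < 5]
        assert small, "collection must span sizes below the ORA minimum"
        universe = {f"g{i:05d}" for i in range(200)}
        records = ora(set(list(universe)[:20]), collection, universe)
        assert not set(records.index) & set(small)

    def test_full_ortholog_fraction_is_bijection(self):
        _, orthologs, _ = simulate_annotation_resources(50, seed=0,
                                                        ortholog_fraction=1.0)
        assert len(orthologs) == 50
        assert orthologs["rat_gene"].is_unique
        assert orthologs["human_gene"].is_unique

    def test_edge_score_filter_retains_expected_fraction(self):
        _, _, edges = simulate_annotation_resources(300, seed=1, n_edges=4000)
        frac = (edges["score"] > 0.4).mean()
        # scores are uniform on [0, 1]
        assert frac == pytest.approx(0.6, abs=3 * np.sqrt(0.6 * 0.4 / len(edges)))


class TestProteomeSimulator:
    def test_no_missingness_keeps_every_protein(self):
        from rhfsig.proteome import filter_valid_values
        m, groups, _ = simulate_proteome(100, missing_rate=0.0, seed=0)
        assert filter_valid_values(m, groups).shape[0] == 100

    def test_half_missing_retention_matches_binomial_tail(self):
        from rhfsig.proteome import filter_valid_values
        n = 3000
        m, groups, _ = simulate_proteome(n, missing_rate=0.5, seed=2,
                                         n_planted=0)
        kept = filter_valid_values(m, groups).shape[0] / n
        p6 = stats.binom.sf(5, 8, 0.5)          # P(>=6 of 8 valid)
        expected = 1 - (1 - p6) ** 3            # in at least one of 3 groups
        assert kept == pytest.approx(expected,
                                     abs=3 * np.sqrt(expected * (1 - expected) / n))

    def test_planted_shift_is_called_as_dep(self):
        from rhfsig.proteome import call_deps, preprocess_proteome
        m, groups, truth = simulate_proteome(80, missing_rate=0.0, seed=3,
                                             n_planted=5, planted_shift=1.0,
                                             noise_sd=0.15)
        pre = preprocess_proteome(m)
        deps = call_deps(pre, groups["PAB"], groups["Sham"])
        planted = set(truth.index[truth["role"] == "planted-DE"])
        assert planted <= deps["up"]

    def test_invalid_missing_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_proteome(10, missing_rate=1.0)


class TestSingleCellSimulator:
    def test_single_group_pseudobulk_equals_column_sum(self):
        from rhfsig.pseudobulk import aggregate_pseudobulk
        cells, meta, _ = simulate_singlecell(n_cells=30, celltypes=["CM"],
                                             n_samples=1, conditions=["NF"],
                                             seed=0, n_genes=50)
        pb = aggregate_pseudobulk(cells, meta)
        assert pb.shape[0] == 1
        np.testing.assert_array_equal(pb.iloc[0].to_numpy(),
                                      cells.sum(axis=0).to_numpy())

    def test_seed_determinism(self):
        a = simulate_singlecell(60, ["CM", "FB"], 2, ["NF", "HCM"], seed=5,
                                n_genes=40)
        b = simulate_singlecell(60, ["CM", "FB"], 2, ["NF", "HCM"], seed=5,
                                n_genes=40)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_empty_celltype_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_singlecell(10, [], 1, ["NF"])


def test_child_seeds_use_fixed_offsets():
    assert synthdata.child_seed(3, "rat") != synthdata.child_seed(3, "human")
    assert synthdata.child_seed(3, "rat") == 3 + synthdata.SEED_OFFSETS["rat"]
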