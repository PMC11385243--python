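import numpy as np
import pytest

from mthet.calling import VariantCall, classify_zygosity
from mthet.somatic import SomaticVariantSet
from mthet.stats import (
    burden_by_locus,
    compare_burdens,
    compare_groups,
    compare_hf_distributions,
    hf_threshold_summary,
    mann_whitney,
    per_cell_totals,
    score_shape,
    substitution_spectrum,
)


def call(pos, hf=0.1, ref="A", alt="G"):
    return VariantCall(pos, ref, alt, int(hf * 2000), 2000 - int(hf * 2000), 2000,
                       hf, classify_zygosity(hf))


def sset(cell, variants, sample="s1"):
    return SomaticVariantSet(sample=sample, cell=cell, variants=variants)


class TestHFThresholdSummary:
    def test_partition_arithmetic(self):
        hfs = [0.01] * 3 + [0.5] * 7
        s = hf_threshold_summary(hfs, floor=0.02)
        assert s["n_below"] == 3 and s["n_retained"] == 7
        assert s["pct_below"] == pytest.approx(30.0)
        assert s["pct_retained"] == pytest.approx(70.0)

    def test_empty(self):
        assert hf_threshold_summary([])["n_total"] == 0


class TestSpectrum:
    def test_counts_and_percentages(self):
        variants = [call(1, ref="T", alt="C"), call(2, ref="T", alt="C"), call(3, ref="A", alt="G")]
        sp = substitution_spectrum(variants).set_index("substitution")
        assert sp.loc["T>C", "count"] == 2
        assert sp.loc["T>C", "percent"] == pytest.approx(200 / 3)
        assert sp.loc["A>G", "percent"] == pytest.approx(100 / 3)
        assert sp["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_empty_input_gives_zero_table(self):
        sp = substitution_spectrum([])
        assert len(sp) == 12 and sp["count"].sum() == 0

    def test_matches_truth_of_error_free_sets(self, pipeline_small):
        pooled = [v for s in pipeline_small.somatic.values() for v in s.variants]
        sp = substitution_spectrum(pipeline_small.somatic).set_index("substitution")
        from collections import Counter

        expected = Counter(f"{v.ref}>{v.alt}" for v in pooled)
        for sub, row in sp.iterrows():
            assert row["count"] == expected.get(sub, 0)
        assert sp["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_complementary_classes_not_collapsed(self):
        sp = substitution_spectrum([call(1, ref="T", alt="C")]).set_index("substitution")
        assert sp.loc["T>C", "count"] == 1 and sp.loc["A>G", "count"] == 0


class TestBurden:
    def test_dloop_normalisation(self, locus_map):
        s = sset("c1", [call(100), call(200)])  # two D-loop variants
        b = burden_by_locus([s], locus_map).set_index("locus_class")
        assert b.loc["D-loop", "count"] == 2
        assert b.loc["D-loop", "normalized"] == pytest.approx(2 / 1124)
        assert b.loc["rRNA", "count"] == 0

    def test_zero_variant_cell_has_all_zero_rows(self, locus_map):
        b = burden_by_locus([sset("c1", [])], locus_map)
        assert len(b) == 4 and (b["count"] == 0).all()

    def test_linearity(self, locus_map):
        vs = [call(100), call(3400), call(700)]
        b1 = burden_by_locus([sset("c1", vs)], locus_map)
        b2 = burden_by_locus([sset("c1", vs + [call(p.position + 1, ref="A", alt="G") for p in vs])], locus_map)
        # doubling every variant doubles normalized counts exactly
        assert np.allclose(2 * b1["normalized"], b2["normalized"])

    def test_totals_sum_over_classes(self, pipeline_small, locus_map):
        b = burden_by_locus(pipeline_small.somatic, locus_map)
        tot = per_cell_totals(b)
        for r in tot.itertuples():
            n = sum(
                s.n for s in pipeline_small.somatic.values() if s.cell == r.cell
            )
            # totals may undercount by intergenic variants only
            assert 0 <= n - r.count <= 3

    def test_uniform_placement_gives_flat_normalized_burden(self, locus_map, masks):
        rng = np.random.default_rng(6)
        unmasked = [p for p in range(1, 16570) if p not in masks]
        pos = rng.choice(unmasked, size=5000, replace=False)
        s = sset("c1", [call(int(p)) for p in pos])
        b = burden_by_locus([s], locus_map).set_index("locus_class")
        rates = b["normalized"]
        rel = rates / rates.mean()
        # Poisson sampling error on the smallest class (D-loop, ~340 hits) ~5%
        assert np.all(np.abs(rel - 1) < 0.2)


class TestCompareGroups:
    CTRL = [24.5, 23.5, 26.4, 27.1, 29.9]
    T1 = [28.4, 34.2, 29.5, 32.2, 30.1]
    T2 = [26.1, 28.3, 24.3, 26.2, 27.8]

    def test_identical_groups_anova_null(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "a")
        anova = res[0]
        assert anova.statistic == pytest.approx(0.0)
        assert anova.pvalue == pytest.approx(1.0)

    def test_matches_R_multcomp_reference(self):
        """Frozen oracle: R aov + multcomp::glht Dunnett contrasts."""
        res = compare_groups({"ctrl": self.CTRL, "t1": self.T1, "t2": self.T2}, "ctrl")
        anova, d1, d2 = res
        assert anova.statistic == pytest.approx(7.137828, abs=1e-4)
        assert anova.pvalue == pytest.approx(0.0090733, abs=1e-5)
        assert d1.statistic == pytest.approx(3.36301400, abs=1e-4)
        assert d2.statistic == pytest.approx(0.19008340, abs=1e-4)
        assert d1.pvalue == pytest.approx(0.01045594, abs=1e-3)
        assert d2.pvalue == pytest.approx(0.97392838, abs=1e-3)
        assert d1.reference == "ctrl" and d1.groups == ("ctrl", "t1")

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_groups(
                {"a": [1.0, 2.0, 3.1], "b": [2.0, 3.0, 1.2], "c": [5.0]}, "a"
            )
        assert all("c" not in r.groups for r in res)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            compare_groups({"a": [1.0, 2.0], "b": [2.0, 3.0]}, "zzz")


class TestCompareBurdens:
    def test_dloop_enriched_simulation_is_detected(self, reference):
        from mthet import run_sample
        from mthet.simulate import SimSampleConfig, simulate_sample

        cfg = SimSampleConfig(seed=55, n_cells=6, dloop_enrichment=15.0)
        sim = simulate_sample(cfg, reference=reference)
        res = run_sample(sim.cells, sim.consensus, reference)
        b = burden_by_locus(res.somatic)
        tests = compare_burdens(b, "locus_class", "D-loop")
        dunnett = [t for t in tests if t.name.startswith("Dunnett")]
        assert len(dunnett) == 3
        assert all(t.pvalue < 0.05 for t in dunnett)
        assert tests[0].pvalue < 0.05  # ANOVA

    def test_by_sample_uses_per_cell_totals(self, pipeline_small):
        b = burden_by_locus(pipeline_small.somatic)
        b["sample"] = "s1"
        b2 = b.copy()
        b2["sample"] = "s2"
        import pandas as pd

        tests = compare_burdens(pd.concat([b, b2]), "sample", "s1", value="count")
        # identical groups: no between-sample signal
        assert tests[0].pvalue == pytest.approx(1.0)


class TestCompareHF:
    def test_identical_groups_mann_whitney_p_one(self):
        r = mann_whitney([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r.pvalue == pytest.approx(1.0)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(12)
        ns = rng.beta(2.0, 6.0, size=200) + 0.05
        s = rng.beta(2.0, 6.0, size=200)
        assert mann_whitney(ns, s, names=("NS", "S")).pvalue < 0.05

    def test_grouped_by_sample(self, pipeline_small):
        sets = [
            SomaticVariantSet(sample=f"s{i % 2}", cell=s.cell, variants=s.variants)
            for i, s in enumerate(pipeline_small.somatic.values())
        ]
        res = compare_hf_distributions(sets, "sample", "s0")
        assert res[0].name == "ANOVA[hf]"
        assert 0 <= res[0].pvalue <= 1

    def test_grouped_by_locus_class(self, pipeline_small, locus_map):
        res = compare_hf_distributions(
            pipeline_small.somatic, "locus_class", "D-loop", locus_map
        )
        assert any(r.name.startswith("Dunnett") for r in res)


class TestScoreShape:
    def test_counts_with_few_scores(self):
        s = score_shape([0.6, 0.7, 0.2], threshold=0.5)
        assert s.n_pathogenic == 2
        assert s.pathogenic_fraction == pytest.approx(2 / 3)
        assert s.kurtosis_excess is None  # below the Shapiro-Wilk minimum

    def test_degenerate_identical_scores(self):
        s = score_shape([0.4] * 20, threshold=0.5)
        assert s.kurtosis_excess is None and s.shapiro_pvalue is None
        assert s.pathogenic_fraction == 0.0

    def test_threshold_is_strict(self):
        s = score_shape([0.5] * 10 + [0.51], threshold=0.5)
        assert s.n_pathogenic == 1

    def test_normal_sample_baselines(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5000)
        s = score_shape((x - x.min()) / (x.max() - x.min()), threshold=0.5)
        assert abs(s.kurtosis_excess) < 0.25
        assert s.kurtosis_pearson == pytest.approx(s.kurtosis_excess + 3.0)
        assert s.shapiro_pvalue is not None
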