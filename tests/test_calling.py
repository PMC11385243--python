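import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthet.calling import (
    AlleleCountTable,
    UndefinedHFError,
    VariantCall,
    call_variants,
    calls_to_frame,
    classify_zygosity,
    compute_hf,
    coverage_qc,
    read_calls_tsv,
    read_calls_vcf,
    write_calls_tsv,
    write_calls_vcf,
)
from mthet.reference import MT_LENGTH
from mthet.simulate import TrueVariant, generate_counts


def uniform_table(reference, depth=2000, sample="cell"):
    counts = np.zeros((MT_LENGTH, 4), dtype=np.int64)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref_idx = np.array([idx[b] for b in reference.sequence])
    counts[np.arange(MT_LENGTH), ref_idx] = depth
    return AlleleCountTable.from_arrays(counts, sample=sample)


def with_alt(table, reference, position, alt, alt_depth):
    df = table.df.copy()
    ref = reference.base(position)
    df.loc[position, ref] -= alt_depth
    df.loc[position, alt] += alt_depth
    return AlleleCountTable(df, sample=table.sample)


class TestComputeHF:
    @pytest.mark.parametrize(
        "alt, ref, expected", [(50, 150, 0.25), (0, 1000, 0.0), (1000, 0, 1.0)]
    )
    def test_arithmetic(self, alt, ref, expected):
        assert compute_hf(alt, ref) == expected

    def test_zero_total_raises(self):
        with pytest.raises(UndefinedHFError):
            compute_hf(0, 0)


class TestZygosity:
    @pytest.mark.parametrize(
        "hf, expected",
        [
            (0.99, "homoplasmic"),
            (0.981, "homoplasmic"),
            (0.98, "heteroplasmic"),  # strict: not > 0.98
            (0.50, "heteroplasmic"),
            (0.021, "heteroplasmic"),
            (0.02, "sub-threshold"),  # strict: not > 0.02
            (0.0, "sub-threshold"),
            (1.0, "homoplasmic"),
        ],
    )
    def test_boundaries(self, hf, expected):
        assert classify_zygosity(hf) == expected

    @pytest.mark.parametrize("hf", [-0.1, 1.1])
    def test_domain(self, hf):
        with pytest.raises(ValueError):
            classify_zygosity(hf)

    @settings(derandomize=True, max_examples=300)
    @given(hf=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_is_total(self, hf):
        z = classify_zygosity(hf)
        assert z in ("homoplasmic", "heteroplasmic", "sub-threshold")
        if hf > 0.98:
            assert z == "homoplasmic"
        elif hf > 0.02:
            assert z == "heteroplasmic"
        else:
            assert z == "sub-threshold"


class TestAlleleCountTable:
    def test_rejects_count_depth_mismatch(self):
        df = pd.DataFrame(
            {"A": [1], "C": [0], "G": [0], "T": [0], "depth": [2]},
            index=pd.RangeIndex(1, 2),
        )
        with pytest.raises(ValueError, match="sum to depth"):
            AlleleCountTable(df, sample="x")

    def test_zero_fills_missing_positions(self):
        df = pd.DataFrame(
            {"A": [5], "C": [0], "G": [0], "T": [0], "depth": [5]},
            index=pd.Index([42], name="pos"),
        )
        t = AlleleCountTable(df, sample="x")
        assert len(t.df) == MT_LENGTH
        assert t.df.loc[42, "A"] == 5
        assert t.df.loc[43, "depth"] == 0

    def test_tsv_round_trip(self, reference, tmp_path):
        t = uniform_table(reference, depth=7)
        p = tmp_path / "c.tsv"
        t.to_tsv(p, reference=reference)
        back = AlleleCountTable.from_tsv(p)
        pd.testing.assert_frame_equal(back.df, t.df)


class TestCallVariants:
    def test_single_heteroplasmic_call(self, reference):
        t = with_alt(uniform_table(reference), reference, 5000, _alt(reference, 5000), 100)
        calls = call_variants(t, reference)
        assert len(calls) == 1
        c = calls[0]
        assert c.position == 5000
        assert c.hf == pytest.approx(100 / 2000)
        assert c.zygosity == "heteroplasmic"
        assert not c.low_confidence

    def test_sub_threshold_flagged_not_dropped(self, reference):
        t = with_alt(uniform_table(reference), reference, 5000, _alt(reference, 5000), 10)
        calls = call_variants(t, reference, error_rate=0.001)
        assert len(calls) == 1
        assert calls[0].hf == pytest.approx(0.005)
        assert calls[0].zygosity == "sub-threshold"

    def test_multiallelic_site_emits_one_call_per_alt(self, reference):
        ref = reference.base(5000)
        alts = [b for b in "ACGT" if b != ref][:2]
        t = uniform_table(reference)
        t = with_alt(t, reference, 5000, alts[0], 100)
        t = with_alt(t, reference, 5000, alts[1], 60)
        calls = call_variants(t, reference)
        assert [c.alt for c in calls] == sorted(alts)

    def test_low_depth_site_flagged_low_confidence(self, reference):
        t = uniform_table(reference, depth=2000)
        df = t.df.copy()
        ref = reference.base(7000)
        alt = _alt(reference, 7000)
        df.loc[7000, ref] = 80
        df.loc[7000, alt] = 20
        df.loc[7000, "depth"] = 100
        calls = call_variants(AlleleCountTable(df, sample="x"), reference, min_site_depth=500)
        (c,) = [c for c in calls if c.position == 7000]
        assert c.low_confidence

    def test_recovers_simulated_truth_exactly_without_error(self, reference):
        rng = np.random.default_rng(5)
        pos = rng.choice(np.arange(1000, 16000), size=5, replace=False)
        truth = []
        for p, h in zip(pos, [0.1, 0.2, 0.3, 0.5, 0.9]):
            r = reference.base(int(p))
            truth.append(TrueVariant(int(p), r, _alt(reference, int(p)), h, "somatic"))
        t = generate_counts(truth, 2000, 0.0, reference, seed=11)
        calls = call_variants(t, reference)
        assert {(c.position, c.alt) for c in calls} == {(v.position, v.alt) for v in truth}

    def test_idempotent(self, reference):
        t = with_alt(uniform_table(reference), reference, 5000, _alt(reference, 5000), 100)
        assert call_variants(t, reference) == call_variants(t, reference)

    def test_hf_estimator_calibration(self, reference):
        # binomial concentration: called HF within 3 sd of truth for >= 99%
        rng = np.random.default_rng(17)
        pos = rng.choice(np.arange(1000, 16000), size=300, replace=False)
        h, depth = 0.2, 2000
        truth = [
            TrueVariant(int(p), reference.base(int(p)), _alt(reference, int(p)), h, "somatic")
            for p in pos
        ]
        t = generate_counts(truth, depth, 0.0, reference, seed=23)
        calls = {c.position: c.hf for c in call_variants(t, reference)}
        tol = 3 * np.sqrt(h * (1 - h) / depth)
        ok = sum(abs(calls[v.position] - h) <= tol for v in truth if v.position in calls)
        assert ok / len(truth) >= 0.99


class TestCoverageQC:
    def test_uniform_depth_passes(self, reference):
        r = coverage_qc(uniform_table(reference, depth=2000))
        assert r.passed and r.covered_fraction == 1.0

    def test_200_uncovered_positions_fail(self, reference):
        t = uniform_table(reference, depth=2000)
        df = t.df.copy()
        df.iloc[:200] = 0
        r = coverage_qc(AlleleCountTable(df, sample="x"))
        assert r.n_covered == MT_LENGTH - 200
        assert r.covered_fraction == pytest.approx(16369 / 16569)
        assert not r.passed

    def test_simulated_low_coverage_cell_fails(self, reference):
        from mthet.simulate import SimSampleConfig, simulate_sample

        cfg = SimSampleConfig(seed=9, n_cells=2, n_qc_fail_cells=1, somatic_rate=5.0)
        sim = simulate_sample(cfg, reference=reference)
        (bad,) = sim.qc_fail_expected
        assert not coverage_qc(sim.cells[bad]).passed
        assert coverage_qc(sim.cells["cell01"]).passed


class TestCallIO:
    def _calls(self, reference):
        t = with_alt(uniform_table(reference), reference, 5000, _alt(reference, 5000), 100)
        return call_variants(t, reference)

    def test_tsv_round_trip(self, reference, tmp_path):
        calls = self._calls(reference)
        p = tmp_path / "calls.tsv"
        write_calls_tsv(calls, p)
        assert read_calls_tsv(p) == calls

    def test_vcf_round_trip(self, reference, tmp_path):
        calls = self._calls(reference)
        p = tmp_path / "calls.vcf"
        write_calls_vcf(calls, reference, "cell01", p)
        back = read_calls_vcf(p)
        assert len(back) == len(calls)
        for a, b in zip(back, calls):
            assert (a.position, a.ref, a.alt, a.alt_depth, a.ref_depth) == (
                b.position,
                b.ref,
                b.alt,
                b.alt_depth,
                b.ref_depth,
            )
            assert a.hf == pytest.approx(b.hf)


def _alt(reference, position):
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[reference.base(position)]
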