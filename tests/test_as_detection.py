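"""Exact binomial tests, CNV-adjusted nulls, BH correction and AS calling."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asbind.as_detection import (
    NullSpec,
    NullVerdict,
    bh_adjust,
    binomial_p_values,
    call_as_snps,
    resolve_null,
    two_sided_binomial_p,
)
from asbind.variant_io import (
    CNVRegion,
    DuplicatedHaplotype,
    GenomicInterval,
    HetSNP,
)


def _snp(pos, snp_id="rs1"):
    return HetSNP(snp_id, "chr1", pos, "A", "G", "K562")


class TestTwoSidedBinomialP:
    def test_mode_observed_gives_one(self):
        assert two_sided_binomial_p(16, 16, 0.5) == 1.0

    def test_symmetric_null_equals_doubled_tail(self):
        # exact rational: 2 * sum_{k=20..24} C(24,k) / 2^24
        expected = float(2 * Fraction(10626 + 2024 + 276 + 24 + 1, 2**24))
        assert two_sided_binomial_p(20, 4, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_asymmetric_null_match_is_insignificant(self):
        # 16:8 = 2:1 sits exactly on the adjusted null 2/3
        assert two_sided_binomial_p(16, 8, 2 / 3) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("null_p", [1 / 3, 0.5, 2 / 3])
    @pytest.mark.parametrize("n", [5, 12, 25])
    def test_matches_scipy_binomtest(self, n, null_p):
        for g1 in range(1, n):
            ref = stats.binomtest(g1, n, null_p).pvalue
            assert two_sided_binomial_p(g1, n - g1, null_p) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("null_p", [1 / 3, 0.5, 2 / 3])
    def test_relabeling_invariance(self, null_p):
        for g1, g2 in [(3, 17), (10, 10), (1, 5), (22, 7)]:
            assert two_sided_binomial_p(g1, g2, null_p) == pytest.approx(
                two_sided_binomial_p(g2, g1, 1 - null_p), rel=1e-12
            )

    def test_monotone_in_imbalance_at_symmetric_null(self):
        n = 40
        pvals = [two_sided_binomial_p(n // 2 + d, n // 2 - d, 0.5) for d in range(0, 20)]
        assert all(b <= a + 1e-15 for a, b in zip(pvals, pvals[1:]))

    def test_vectorised_path_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(1, 30, size=200)
        g2 = rng.integers(1, 30, size=200)
        null_p = rng.choice([1 / 3, 0.5, 2 / 3], size=200)
        vec = binomial_p_values(g1, g2, null_p)
        for i in range(200):
            assert vec[i] == pytest.approx(
                two_sided_binomial_p(int(g1[i]), int(g2[i]), float(null_p[i])), rel=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sided_binomial_p(5, 5, 0.0)
        with pytest.raises(ValueError):
            two_sided_binomial_p(-1, 5, 0.5)


class TestPValueProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        g1=st.integers(1, 60),
        g2=st.integers(1, 60),
        null_p=st.sampled_from([1 / 3, 0.5, 2 / 3]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_bounds_and_relabeling_invariance(self, g1, g2, null_p):
        """p in (0, 1] and invariant under swapping alleles with 1 - null_p."""
        p = two_sided_binomial_p(g1, g2, null_p)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(two_sided_binomial_p(g2, g1, 1 - null_p), rel=1e-9)


class TestResolveNull:
    def test_outside_cnv_is_diploid(self):
        spec = resolve_null(_snp(100), [])
        assert spec.verdict is NullVerdict.TESTABLE and spec.null_p == 0.5

    def test_two_copy_cnv_keeps_diploid_null(self):
        cnv = CNVRegion(GenomicInterval("chr1", 0, 1000), 2)
        assert resolve_null(_snp(100), [cnv]).null_p == 0.5

    @pytest.mark.parametrize(
        "hap,expected",
        [(DuplicatedHaplotype.G1, 2 / 3), (DuplicatedHaplotype.G2, 1 / 3)],
    )
    def test_resolved_three_copy_adjusts_null(self, hap, expected):
        cnv = CNVRegion(GenomicInterval("chr1", 0, 1000), 3, hap)
        spec = resolve_null(_snp(100), [cnv])
        assert spec.null_p == pytest.approx(expected)

    def test_unresolved_three_copy_excluded(self):
        cnv = CNVRegion(GenomicInterval("chr1", 0, 1000), 3)
        assert resolve_null(_snp(100), [cnv]).verdict is NullVerdict.EXCLUDED_UNRESOLVED_CNV

    def test_four_copies_excluded(self):
        cnv = CNVRegion(GenomicInterval("chr1", 0, 1000), 4)
        assert resolve_null(_snp(100), [cnv]).verdict is NullVerdict.EXCLUDED_HIGH_COPY

    def test_ungenotyped_cnv_excluded(self):
        cnv = CNVRegion(GenomicInterval("chr1", 0, 1000), None)
        assert resolve_null(_snp(100), [cnv]).verdict is NullVerdict.EXCLUDED_UNGENOTYPED_CNV

    def test_conflicting_overlap_errors(self):
        cnvs = [
            CNVRegion(GenomicInterval("chr1", 0, 1000), 2),
            CNVRegion(GenomicInterval("chr1", 50, 500), 3, DuplicatedHaplotype.G1),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            resolve_null(_snp(100), cnvs)

    def test_half_open_boundary(self):
        cnv = CNVRegion(GenomicInterval("chr1", 0, 100), 4)
        assert resolve_null(_snp(100), [cnv]).verdict is NullVerdict.TESTABLE


class TestBHAdjust:
    def test_all_ones(self):
        assert list(bh_adjust([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computed(self):
        # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 -> min over j>=i = 0.04 each
        assert list(bh_adjust([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4)

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallASSNPs:
    def _nullspecs(self, snp_ids, null_p=0.5):
        return {s: NullSpec(s, NullVerdict.TESTABLE, null_p) for s in snp_ids}

    def test_zero_allele_records_discarded(self):
        counts = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2"],
                "dataset_id": ["TF1", "TF1"],
                "g1_count": [0, 10],
                "g2_count": [25, 10],
            }
        )
        results, as_ids, discarded = call_as_snps(counts, self._nullspecs(["rs1", "rs2"]))
        assert discarded["zero_allele"] == 1
        assert list(results["snp_id"]) == ["rs2"]

    def test_untestable_snps_dropped(self):
        counts = pd.DataFrame(
            {"snp_id": ["rs1"], "dataset_id": ["TF1"], "g1_count": [30], "g2_count": [2]}
        )
        specs = {"rs1": NullSpec("rs1", NullVerdict.EXCLUDED_HIGH_COPY)}
        results, as_ids, discarded = call_as_snps(counts, specs)
        assert discarded["not_testable"] == 1 and len(results) == 0 and not as_ids

    def test_planted_strong_as_snp_is_called(self):
        # theta = 0.9 at depth 50 in 3 datasets: exact-test power >> 0.99
        rng = np.random.default_rng(42)
        g1 = rng.binomial(50, 0.9, size=3)
        counts = pd.DataFrame(
            {
                "snp_id": ["rs9"] * 3 + ["rs_null"] * 3,
                "dataset_id": ["TF1", "TF2", "TF3"] * 2,
                "g1_count": list(g1) + [25, 24, 26],
                "g2_count": list(50 - g1) + [25, 26, 24],
            }
        )
        results, as_ids, _ = call_as_snps(counts, self._nullspecs(["rs9", "rs_null"]))
        assert "rs9" in as_ids and "rs_null" not in as_ids

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            call_as_snps(pd.DataFrame(columns=["snp_id", "dataset_id", "g1_count", "g2_count"]), {}, alpha=0.0)

    def test_bh_family_modes_differ_only_in_grouping(self, small_bundle):
        from asbind.as_detection import resolve_nulls

        specs = resolve_nulls(small_bundle.snps, small_bundle.cnvs)
        per_ds, _, _ = call_as_snps(small_bundle.counts, specs, bh_family="per_dataset")
        glob, _, _ = call_as_snps(small_bundle.counts, specs, bh_family="global")
        # identical tests, identical p-values; only q-values may differ
        assert np.allclose(per_ds["p_value"], glob["p_value"])
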