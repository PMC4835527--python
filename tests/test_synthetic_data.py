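"""Generator correctness: determinism, AF structure, null calibration, CNVs."""

import numpy as np
import pandas as pd
import pytest

from asbind.as_detection import binomial_p_values
from asbind.synthetic_data import (
    CNVConfig,
    EffectModel,
    MaskConfig,
    SimulationConfig,
    emit_fixture_bundle,
    generate_bundle,
    generate_cnv_and_mask_regions,
    generate_het_snps,
    simulate_allelic_counts,
)
from asbind.variant_io import CNVRegion, DuplicatedHaplotype, GenomicInterval


def _null_config(**kwargs):
    defaults = dict(
        seed=5,
        n_snps=1000,
        frac_as=0.0,
        cnv=CNVConfig(n_regions=0),
        mask=MaskConfig(n_gap=0, n_blacklist=0),
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        cfg = SimulationConfig(seed=3, n_snps=300)
        a, b = generate_bundle(cfg), generate_bundle(cfg)
        assert [s.snp_id for s in a.snps] == [s.snp_id for s in b.snps]
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_same_seed_identical_checksums(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_snps=200)
        m1 = emit_fixture_bundle(tmp_path / "a", cfg)
        m2 = emit_fixture_bundle(tmp_path / "b", cfg)
        assert list(m1["sha256"]) == list(m2["sha256"])

    def test_different_seed_differs(self):
        a = generate_bundle(SimulationConfig(seed=1, n_snps=300))
        b = generate_bundle(SimulationConfig(seed=2, n_snps=300))
        assert not a.counts.equals(b.counts)


class TestHetSNPGeneration:
    def test_positions_unique_per_chromosome(self):
        snps, _, _ = generate_het_snps(SimulationConfig(seed=0, n_snps=2000))
        seen = {}
        for s in snps:
            assert (s.chrom, s.pos) not in seen
            seen[(s.chrom, s.pos)] = True

    def test_frac_rare_zero_means_all_common(self):
        _, freq, truth = generate_het_snps(_null_config(frac_rare=0.0))
        assert all(af >= 0.01 for af in freq.values())
        assert not truth["is_rare"].any()

    def test_rare_fraction_within_binomial_noise(self):
        # 14 % of heterozygous SNPs have AF < 1 %
        n = 10_000
        _, _, truth = generate_het_snps(_null_config(n_snps=n, frac_rare=0.14))
        sd = np.sqrt(0.14 * 0.86 / n)
        assert abs(truth["is_rare"].mean() - 0.14) < 3 * sd

    def test_absent_af_only_for_rare(self):
        _, freq, truth = generate_het_snps(SimulationConfig(seed=2, n_snps=3000))
        absent = truth[truth["af_absent"]]
        assert len(absent) > 0
        assert absent["is_rare"].all()
        assert not set(absent["snp_id"]) & set(freq)

    def test_too_many_snps_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_het_snps(SimulationConfig(seed=0, n_snps=300, chrom_sizes={"chr1": 100}))


class TestRegionGeneration:
    def test_zero_regions(self):
        cnvs, gaps, blacklist = generate_cnv_and_mask_regions(_null_config())
        assert cnvs == [] and gaps == [] and blacklist == []

    def test_regions_disjoint_and_in_bounds(self):
        cfg = SimulationConfig(seed=4, cnv=CNVConfig(n_regions=6, region_length=200_000))
        cnvs, gaps, blacklist = generate_cnv_and_mask_regions(cfg)
        ivs = [c.interval for c in cnvs] + gaps + blacklist
        for iv in ivs:
            assert 0 <= iv.start < iv.end <= cfg.chrom_sizes[iv.chrom]
        for a in ivs:
            for b in ivs:
                if a is not b and a.chrom == b.chrom:
                    assert a.end <= b.start or b.end <= a.start

    def test_capacity_error(self):
        cfg = SimulationConfig(
            seed=0,
            n_snps=10,
            chrom_sizes={"chr1": 1_000_000},
            cnv=CNVConfig(n_regions=50, region_length=100_000),
        )
        with pytest.raises(ValueError, match="could not place"):
            generate_cnv_and_mask_regions(cfg)


class TestAllelicCounts:
    def test_null_calibration_is_conservative(self):
        """With no AS signal and no CNVs, exact-test type-I error stays at
        or below nominal (discreteness makes it conservative)."""
        cfg = _null_config(n_snps=2500, n_datasets=4, seed=17)
        bundle = generate_bundle(cfg)
        c = bundle.counts
        c = c[(c["g1_count"] > 0) & (c["g2_count"] > 0)]
        p = binomial_p_values(c["g1_count"].to_numpy(), c["g2_count"].to_numpy(), 0.5)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert rate <= 0.05 + 3 * se

    def test_non_as_snp_in_resolved_cnv_sits_at_one_third(self):
        """Balanced SNPs inside a resolved 3-copy region (duplicated G2)
        average g1/(g1+g2) = 1/3 across many datasets."""
        cfg = _null_config(
            n_snps=50,
            chrom_sizes={"chr1": 10_000},
            n_datasets=1000,
            seed=23,
        )
        snps, _, truth = generate_het_snps(cfg)
        cnvs = [CNVRegion(GenomicInterval("chr1", 0, 10_000), 3, DuplicatedHaplotype.G2)]
        counts, truth = simulate_allelic_counts(snps, truth, cnvs, cfg)
        assert np.allclose(truth["theta_eff"], 1 / 3)
        total = counts["g1_count"] + counts["g2_count"]
        frac = counts["g1_count"].sum() / total.sum()
        assert frac == pytest.approx(1 / 3, abs=0.01)

    def test_rare_effects_stochastically_larger(self):
        cfg = SimulationConfig(
            seed=31, n_snps=5000, frac_as=0.5, frac_rare=0.3,
            cnv=CNVConfig(n_regions=0), mask=MaskConfig(n_gap=0, n_blacklist=0),
        )
        bundle = generate_bundle(cfg)
        t = bundle.truth
        shift = (t["true_theta"] - 0.5).abs()
        rare_shift = shift[t["is_as"] & t["is_rare"]].mean()
        common_shift = shift[t["is_as"] & ~t["is_rare"]].mean()
        assert rare_shift > common_shift

    def test_extreme_theta_gives_monoallelic_counts(self):
        cfg = _null_config(
            n_snps=20, chrom_sizes={"chr1": 1000}, n_datasets=5, seed=2,
            frac_as=1.0, common_effect=EffectModel(0.5, 0.5), rare_effect=EffectModel(0.5, 0.5),
        )
        snps, _, truth = generate_het_snps(cfg)
        counts, truth = simulate_allelic_counts(snps, truth, [], cfg)
        # theta clipped within 1e-6 of 0 or 1: counts essentially monoallelic
        merged = counts.merge(truth[["snp_id", "true_theta"]], on="snp_id")
        hi = merged[merged["true_theta"] > 0.5]
        assert (hi["g2_count"] == 0).mean() > 0.99

    def test_reference_bias_shifts_counts(self):
        cfg = _null_config(seed=6, n_snps=2000, ref_bias=1.2)
        bundle = generate_bundle(cfg)
        frac = bundle.counts["g1_count"].sum() / (
            bundle.counts["g1_count"] + bundle.counts["g2_count"]
        ).sum()
        assert frac == pytest.approx(0.6, abs=0.02)


class TestCatalogGeneration:
    def test_planted_links_cross_threshold(self, small_bundle):
        assert all(p.r2 > 0.8 or p.r2 <= 0.8 for p in small_bundle.proxies)
        planted = [p for p in small_bundle.proxies if p.r2 > 0.8]
        as_ids = set(small_bundle.truth.loc[small_bundle.truth["is_as"], "snp_id"])
        assert planted and all(p.proxy_snp_id in as_ids for p in planted)

    def test_decoys_link_non_as(self, small_bundle):
        decoys = [p for p in small_bundle.proxies if p.r2 <= 0.8]
        as_ids = set(small_bundle.truth.loc[small_bundle.truth["is_as"], "snp_id"])
        assert decoys and not any(p.proxy_snp_id in as_ids for p in decoys)
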