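"""Clone mixtures, sample-type karyotype models and count simulation."""

import numpy as np
import pytest
from scipy import stats

from pgscreen.reference import HG19_CHROM_LENGTHS, build_reference
from pgscreen.simulate import (
    CloneKaryotype,
    CloneMix,
    CohortParams,
    DEFAULT_GC_BIAS,
    EmbryoSpec,
    SegmentCN,
    effective_karyotype_ecb,
    effective_karyotype_re,
    effective_karyotype_te,
    euploid_karyotype,
    simulate_cohort,
    simulate_counts,
    simulate_negative_control,
    simulate_trio,
)

CHROMS = [c for c, _ in HG19_CHROM_LENGTHS]


def _spec(clones, sex="XX", te_cells=4, w=0.5):
    return EmbryoSpec(
        embryo_id="e", mix=CloneMix(clones, sex=sex), te_cells=te_cells,
        ecb_apoptosis_weight=w,
    )


def _trisomy(chrom, sex="XX"):
    k = euploid_karyotype(sex, CHROMS)
    k.copy_number[chrom] = 3
    return k


def _monosomy(chrom, sex="XX"):
    k = euploid_karyotype(sex, CHROMS)
    k.copy_number[chrom] = 1
    return k


class TestValidation:
    def test_fraction_sum(self):
        with pytest.raises(ValueError):
            CloneMix([(CloneKaryotype(), 0.6), (CloneKaryotype(), 0.6)])

    def test_nonpositive_fraction(self):
        with pytest.raises(ValueError):
            CloneMix([(CloneKaryotype(), 1.2), (CloneKaryotype(), -0.2)])

    def test_overlapping_segments(self):
        with pytest.raises(ValueError):
            CloneKaryotype(segments=[
                SegmentCN("chr1", 0, 60_000_000, 3),
                SegmentCN("chr1", 50_000_000, 120_000_000, 1),
            ])

    def test_te_cells_range(self):
        with pytest.raises(ValueError):
            _spec([(euploid_karyotype("XX", CHROMS), 1.0)], te_cells=6)

    def test_negative_copy(self):
        with pytest.raises(ValueError):
            CloneKaryotype(copy_number={"chr1": -1})


class TestTrophectoderm:
    def test_euploid_any_draw(self):
        spec = _spec([(euploid_karyotype("XX", CHROMS), 1.0)])
        ek = effective_karyotype_te(spec, seed=0)
        assert all(ek.chromosome_copy(c) == 2.0 for c in CHROMS[:22])

    def test_binomial_distribution_of_cell_draws(self):
        """4 cells from a 50:50 trisomy-16 mosaic: chr16 mean copy follows
        2 + Binomial(4, 0.5)/4."""
        spec = _spec([(euploid_karyotype("XX", CHROMS), 0.5), (_trisomy("chr16"), 0.5)])
        rng = np.random.default_rng(123)
        n = 4000
        values = np.array([
            effective_karyotype_te(spec, rng).chromosome_copy("chr16")
            for _ in range(n)
        ])
        support = np.array([2.0, 2.25, 2.5, 2.75, 3.0])
        assert set(np.round(values, 10)).issubset(set(support))
        expected = stats.binom.pmf(np.arange(5), 4, 0.5)
        for v, p in zip(support, expected):
            freq = np.mean(values == v)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se + 1e-12

    def test_all_euploid_draw_probability(self):
        """90:10 monosomy-7 mosaic, 3 cells: P(all euploid) = 0.9^3 = 0.729."""
        spec = _spec(
            [(euploid_karyotype("XX", CHROMS), 0.9), (_monosomy("chr7"), 0.1)],
            te_cells=3,
        )
        rng = np.random.default_rng(7)
        n = 5000
        hits = np.mean([
            effective_karyotype_te(spec, rng).chromosome_copy("chr7") == 2.0
            for _ in range(n)
        ])
        p = 0.729
        assert abs(hits - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_mean_converges_to_re(self):
        """Averaging TE draws converges to the RE mix average (LLN)."""
        spec = _spec([(euploid_karyotype("XX", CHROMS), 0.7), (_trisomy("chr21"), 0.3)])
        rng = np.random.default_rng(5)
        n = 10_000
        mean = np.mean([
            effective_karyotype_te(spec, rng).chromosome_copy("chr21")
            for _ in range(n)
        ])
        assert abs(mean - effective_karyotype_re(spec).chromosome_copy("chr21")) < 0.02


class TestRemainingEmbryo:
    def test_weighted_mean(self):
        spec = _spec([(euploid_karyotype("XX", CHROMS), 0.5), (_trisomy("chr16"), 0.5)])
        assert effective_karyotype_re(spec).chromosome_copy("chr16") == 2.5

    def test_x0(self):
        spec = _spec([(euploid_karyotype("X0", CHROMS), 1.0)], sex="X0")
        ek = effective_karyotype_re(spec)
        assert ek.chromosome_copy("chrX") == 1.0
        assert ek.chromosome_copy("chrY") == 0.0

    def test_monosomy_mixture(self):
        spec = _spec([(euploid_karyotype("XX", CHROMS), 0.7), (_monosomy("chr21"), 0.3)])
        assert effective_karyotype_re(spec).chromosome_copy("chr21") == pytest.approx(1.7)


class TestEcb:
    def test_w_zero_reduces_to_re(self):
        spec = _spec(
            [(euploid_karyotype("XX", CHROMS), 0.6), (_trisomy("chr4"), 0.4)], w=0.0
        )
        re_ek = effective_karyotype_re(spec)
        ecb_ek = effective_karyotype_ecb(spec)
        for c in CHROMS:
            assert ecb_ek.chromosome_copy(c) == re_ek.chromosome_copy(c)

    def test_apoptosis_weighting_arithmetic(self):
        """50:50 trisomy-16 with w=1: abnormal weight 2/3, chr16 = 8/3."""
        spec = _spec([(euploid_karyotype("XX", CHROMS), 0.5), (_trisomy("chr16"), 0.5)], w=1.0)
        assert effective_karyotype_ecb(spec).chromosome_copy("chr16") == pytest.approx(8 / 3)

    def test_euploid_unaffected(self):
        spec = _spec([(euploid_karyotype("XX", CHROMS), 1.0)], w=3.0)
        assert all(
            effective_karyotype_ecb(spec).chromosome_copy(c) == 2.0
            for c in CHROMS[:22]
        )


class TestCounts:
    def test_multinomial_conservation(self, toy_ref):
        k = euploid_karyotype("XX", [c for c, _ in toy_ref.chromosomes])
        t = simulate_counts(k, toy_ref, total_reads=100_000, dispersion=0.0, seed=0)
        assert t.counts.sum() == 100_000

    def test_mean_recovery_uniform(self):
        """Equal-width euploid bins, no bias: empirical means match the
        uniform expectation within 3 multinomial standard errors."""
        ref = build_reference([("A", 20_000_000)], 2_000_000, seed=2)
        n_rep, reads = 200, 10_000
        acc = np.zeros(ref.n_bins)
        rng = np.random.default_rng(9)
        for _ in range(n_rep):
            acc += simulate_counts(
                np.full(ref.n_bins, 2.0), ref, total_reads=reads, seed=rng
            ).counts
        p = 1.0 / ref.n_bins
        se = np.sqrt(reads * p * (1 - p) / n_rep)
        assert np.all(np.abs(acc / n_rep - reads * p) < 3 * se + 1e-9)

    def test_dosage_ratio_expectation(self, hg19_ref):
        """Trisomic bins carry 1.5x and monosomic bins 0.5x the disomic
        read density (the +/-50% dosage rule)."""
        k = euploid_karyotype("XX", CHROMS)
        k.copy_number["chr16"] = 3
        k.copy_number["chr9"] = 1
        t = simulate_counts(k, hg19_ref, total_reads=2_000_000, dispersion=0.0, seed=4)
        rate = t.counts / hg19_ref.widths
        sl16 = hg19_ref.chrom_slices["chr16"]
        sl9 = hg19_ref.chrom_slices["chr9"]
        disomic = hg19_ref.autosomal_mask.copy()
        disomic[sl16] = disomic[sl9] = False
        base = rate[disomic].mean()
        assert rate[sl16].mean() / base == pytest.approx(1.5, abs=0.05)
        assert rate[sl9].mean() / base == pytest.approx(0.5, abs=0.05)

    def test_gc_bias_shapes_counts(self, hg19_ref):
        k = euploid_karyotype("XX", CHROMS)
        t = simulate_counts(
            k, hg19_ref, total_reads=2_000_000, gc_bias=DEFAULT_GC_BIAS,
            dispersion=0.0, seed=5,
        )
        mask = hg19_ref.autosomal_mask
        gc = hg19_ref.gc[mask]
        rate = t.counts[mask] / hg19_ref.widths[mask]
        near = rate[np.abs(gc - 0.45) < 0.03].mean()
        far = rate[np.abs(gc - 0.45) > 0.12].mean()
        # bias curve: g = 1 at gc 0.45 vs g <= 0.94 beyond 0.12 away
        assert near > 1.03 * far
        assert np.corrcoef(DEFAULT_GC_BIAS.curve(gc), rate)[0, 1] > 0.4

    def test_bad_args(self, toy_ref):
        k = euploid_karyotype("XX", [c for c, _ in toy_ref.chromosomes])
        with pytest.raises(ValueError):
            simulate_counts(k, toy_ref, total_reads=0)
        with pytest.raises(ValueError):
            simulate_counts(k, toy_ref, total_reads=100, dispersion=-1.0)


class TestNegativeControl:
    def test_deterministic(self, toy_ref):
        a = simulate_negative_control(toy_ref, seed=3)
        b = simulate_negative_control(toy_ref, seed=3)
        assert (a.counts == b.counts).all()
        assert a.sample_type == "NC"

    def test_single_bin(self):
        ref = build_reference([("A", 1_000_000)], 2_000_000, seed=0)
        t = simulate_negative_control(ref, total_reads=500, dispersion=0.0, seed=1)
        assert t.counts[0] == 500


class TestCohort:
    def test_all_normal_cohort(self):
        params = CohortParams(p_aneuploid=0.0, p_mosaic=0.0)
        specs = simulate_cohort(10, params, seed=0)
        for s in specs:
            assert len(s.mix.clones) == 1
            assert not s.mix.clone_is_abnormal(s.mix.clones[0][0])

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            CohortParams(p_aneuploid=1.5)
        with pytest.raises(ValueError):
            CohortParams(sex_probs={"XX": 0.5, "XY": 0.6})

    def test_sex_frequencies(self):
        """Default sex mix emulates the 22:17:1 XX:XY:X0 cohort."""
        specs = simulate_cohort(2000, CohortParams(), seed=1)
        sexes = [s.mix.sex for s in specs]
        for sex, p in [("XX", 22 / 40), ("XY", 17 / 40), ("X0", 1 / 40)]:
            freq = np.mean([s == sex for s in sexes])
            assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / 2000)

    def test_failure_rate(self):
        """3 failures per 120 samples in expectation."""
        specs = simulate_cohort(2000, CohortParams(), seed=2)
        fails = sum(sum(s.failure_flags.values()) for s in specs)
        p = 3 / 120
        n = 3 * 2000
        assert abs(fails / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_reproducible(self):
        a = simulate_cohort(30, CohortParams(), seed=9)
        b = simulate_cohort(30, CohortParams(), seed=9)
        assert [s.to_dict() for s in a] == [s.to_dict() for s in b]

    def test_affected_chromosome_count_and_direction(self):
        params = CohortParams(p_aneuploid=1.0, p_mosaic=0.0, p_segmental=0.0)
        specs = simulate_cohort(200, params, seed=3)
        n_affected = []
        for s in specs:
            (k, _), = s.mix.clones
            affected = {c: cn for c, cn in k.copy_number.items()
                        if cn != 2 and c not in ("chrX", "chrY")}
            n_affected.append(len(affected))
            assert set(affected.values()) <= {1, 3}
        assert set(n_affected) == {1, 2, 3}

    def test_segmental_events_at_least_50mb(self):
        params = CohortParams(p_aneuploid=1.0, p_mosaic=0.0, p_segmental=1.0)
        specs = simulate_cohort(100, params, seed=4)
        segs = [seg for s in specs for (k, _) in s.mix.clones for seg in k.segments]
        assert segs, "expected segmental events"
        assert all(seg.end - seg.start >= 50_000_000 for seg in segs)

    def test_embryo_spec_round_trip(self):
        spec = simulate_cohort(1, CohortParams(p_aneuploid=1.0), seed=5)[0]
        assert EmbryoSpec.from_dict(spec.to_dict()).to_dict() == spec.to_dict()


class TestTrio:
    def test_failure_flag_produces_low_yield_sample(self, toy_ref):
        spec = _spec([(euploid_karyotype("XX", [c for c, _ in toy_ref.chromosomes]), 1.0)])
        spec.failure_flags["TE"] = True
        params = CohortParams(total_reads=100_000, p_sample_failure=0.0)
        trio = simulate_trio(spec, toy_ref, params, seed=0)
        assert trio["TE"].total_reads < 0.05 * trio["RE"].total_reads
        assert trio["TE"].sample_type == "TE"

    def test_deterministic(self, toy_ref):
        spec = _spec([(euploid_karyotype("XY", [c for c, _ in toy_ref.chromosomes]), 1.0)], sex="XY")
        params = CohortParams(total_reads=50_000)
        a = simulate_trio(spec, toy_ref, params, seed=11)
        b = simulate_trio(spec, toy_ref, params, seed=11)
        for st in ("ECB", "TE", "RE"):
            assert (a[st].counts == b[st].counts).all()
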