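"""Binomial tail tests, Bonferroni control, filter chain, VCF output."""

import math
from math import comb

import numpy as np
import pytest

from sscall.caller import test_position as binom_pvalue
from sscall.caller import (
    CallerConfig,
    bonferroni_adjust,
    call_variants,
    compute_vaf,
    strand_bias_test,
    write_vcf,
)
from sscall.errormodel import build_error_profile
from sscall.regions import PositionMask
from sscall.simulate import SpikeIn, simulate_sscs_pileup


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Exact upper-tail by direct pmf summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def hypergeom_fisher_oracle(a, b, c, d) -> float:
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


@pytest.fixture(scope="module")
def profile(small_panel, small_reference):
    rng = np.random.default_rng(2024)
    controls = [
        simulate_sscs_pileup(small_panel, small_reference, 2000, 1e-4, rng)
        for _ in range(60)
    ]
    return build_error_profile(controls)


class TestTestPosition:
    def test_zero_alt_is_one(self):
        assert binom_pvalue(0, 100, 0.001) == 1.0

    def test_worked_example_against_oracle(self):
        """3 alt molecules among 165 at background 1e-3."""
        expected = binom_tail_oracle(3, 165, 0.001)
        assert expected == pytest.approx(6.513e-4, rel=1e-3)
        assert binom_pvalue(3, 165, 0.001) == pytest.approx(expected, rel=1e-10)

    def test_exhaustive_small_grid(self):
        """Agrees with direct pmf summation for all n<=50, k<=n."""
        for eps in (1e-4, 0.01, 0.3, 0.9):
            for n in (1, 2, 7, 23, 50):
                for k in range(0, n + 1):
                    assert binom_pvalue(k, n, eps) == pytest.approx(
                        binom_tail_oracle(k, n, eps), abs=1e-12
                    )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binom_pvalue(1, 0, 0.1)
        with pytest.raises(ValueError):
            binom_pvalue(5, 4, 0.1)
        with pytest.raises(ValueError):
            binom_pvalue(1, 10, 1.5)


class TestBonferroni:
    def test_multiplies(self):
        assert bonferroni_adjust([0.001], 10) == [0.01]

    def test_clips_at_one(self):
        assert bonferroni_adjust([0.5], 1000) == [1.0]

    def test_order_preserving(self, rng):
        ps = sorted(rng.random(50))
        adj = bonferroni_adjust(list(ps), 200)
        assert adj == sorted(adj)

    def test_m_below_one_errors(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1], 0)


class TestStrandBias:
    def test_balanced_table_no_bias(self):
        assert strand_bias_test(5, 5, 100, 100) == pytest.approx(1.0)

    def test_fully_biased_fails_floor(self):
        # 13:0 strand split at coverage 1000/1000; two-sided exact p ~ 2.4e-4
        p = strand_bias_test(13, 0, 1000, 1000)
        assert p == pytest.approx(hypergeom_fisher_oracle(13, 987, 0, 1000), rel=1e-6)
        assert p < 0.001

    def test_symmetric_under_strand_swap(self, rng):
        for _ in range(20):
            af, ar = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            cf, cr = int(rng.integers(30, 200)), int(rng.integers(30, 200))
            assert strand_bias_test(af, ar, cf, cr) == pytest.approx(
                strand_bias_test(ar, af, cr, cf), rel=1e-9
            )

    @pytest.mark.parametrize(
        "table", [(3, 1, 20, 25), (0, 5, 50, 40), (10, 2, 30, 30), (4, 4, 8, 8)]
    )
    def test_matches_hypergeometric_oracle(self, table):
        af, ar, cf, cr = table
        assert strand_bias_test(af, ar, cf, cr) == pytest.approx(
            hypergeom_fisher_oracle(af, cf - af, ar, cr - ar), rel=1e-6
        )

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            strand_bias_test(5, 1, 3, 10)


class TestComputeVaf:
    def test_worked_example_prints_1_8_percent(self):
        """3 supporting molecules at coverage 165 → 1.8% at one decimal."""
        vaf = compute_vaf(3, 165)
        assert f"{vaf:.1%}" == "1.8%"

    @pytest.mark.parametrize("alt,cov,expected", [(0, 100, 0.0), (100, 100, 1.0)])
    def test_edges(self, alt, cov, expected):
        assert compute_vaf(alt, cov) == expected

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            compute_vaf(0, 0)


class TestCallVariants:
    def _spike(self, small_panel, small_reference, vaf, rng, coverage=2000):
        chrom, pos = list(small_panel.positions())[10]
        ref = small_reference[chrom][pos]
        alt = "A" if ref != "A" else "C"
        spike = SpikeIn(chrom, pos, ref, alt, vaf)
        pileup = simulate_sscs_pileup(
            small_panel, small_reference, coverage, 1e-4, rng, [spike]
        )
        return pileup, spike

    def test_spike_in_called(self, small_panel, small_reference, profile):
        """0.5% VAF at coverage 2000 against a 60-normal profile is called."""
        rng = np.random.default_rng(8)
        pileup, spike = self._spike(small_panel, small_reference, 0.005, rng)
        calls, universe = call_variants(pileup, profile)
        passed = [c for c in calls if c.passed]
        assert any(c.pos == spike.pos and c.alt == spike.alt for c in passed)
        assert universe.m >= len(calls)

    def test_mutation_free_sample_mostly_clean(self, small_panel, small_reference, profile):
        """Null samples rarely produce PASS calls (family-wise alpha=0.05)."""
        rng = np.random.default_rng(99)
        n_dirty = 0
        for _ in range(50):
            pileup = simulate_sscs_pileup(small_panel, small_reference, 2000, 1e-4, rng)
            calls, _ = call_variants(pileup, profile)
            n_dirty += any(c.passed for c in calls)
        assert n_dirty <= 5  # 0.05 * 50 + generous slack

    def test_single_strand_filtered(self, small_panel, small_reference, profile):
        rng = np.random.default_rng(17)
        pileup, spike = self._spike(small_panel, small_reference, 0.0, rng)
        site = (spike.chrom, spike.pos)
        cnts = pileup.counts[site]
        # plant 20 alt molecules all on the forward strand
        cnts[spike.alt] = [20, 0]
        cnts[spike.ref][0] -= 20
        calls, _ = call_variants(pileup, profile)
        hit = [c for c in calls if c.pos == spike.pos and c.alt == spike.alt]
        assert hit and "single_strand" in hit[0].filters or "strand_bias" in hit[0].filters
        assert not hit[0].passed

    def test_low_coverage_position_not_tested(self, small_panel, small_reference, profile):
        rng = np.random.default_rng(18)
        pileup, spike = self._spike(small_panel, small_reference, 0.05, rng, coverage=50)
        calls, universe = call_variants(pileup, profile)
        assert calls == []
        assert universe.m == 0
        assert universe.n_low_coverage == small_panel.n_positions()

    def test_snp_mask_excludes_position(self, small_panel, small_reference, profile):
        rng = np.random.default_rng(19)
        pileup, spike = self._spike(small_panel, small_reference, 0.05, rng)
        mask = PositionMask.from_sites([(spike.chrom, spike.pos)])
        calls, universe = call_variants(
            pileup, profile, CallerConfig(snp_mask=mask)
        )
        assert not any(c.pos == spike.pos for c in calls)
        calls2, universe2 = call_variants(pileup, profile)
        assert universe2.m == universe.m + 3

    def test_short_indel_filtered_long_indel_tested(
        self, small_panel, small_reference, profile
    ):
        rng = np.random.default_rng(20)
        pileup, _ = self._spike(small_panel, small_reference, 0.0, rng)
        chrom, pos = list(small_panel.positions())[20]
        # 2 bp deletion: excluded; 3 bp deletion: tested and callable
        pileup.indel_events[(chrom, pos, "del:2")] = [10, 10]
        pileup.indel_events[(chrom, pos, "del:3")] = [10, 10]
        calls, _ = call_variants(pileup, profile)
        short = [c for c in calls if c.alt == "del:2"]
        long = [c for c in calls if c.alt == "del:3"]
        assert short and short[0].filters == {"indel_too_short"}
        assert long and long[0].passed

    def test_pass_vaf_consistency_and_determinism(
        self, small_panel, small_reference, profile
    ):
        rng = np.random.default_rng(21)
        pileup, _ = self._spike(small_panel, small_reference, 0.01, rng)
        calls1, u1 = call_variants(pileup, profile)
        calls2, u2 = call_variants(pileup, profile)
        assert calls1 == calls2 and u1 == u2
        for c in calls1:
            assert c.vaf == (c.alt_f + c.alt_r) / c.coverage
            assert c.p_adj >= c.p_raw

    def test_relaxing_filters_is_monotone(self, small_panel, small_reference, profile):
        """Removing a filter never decreases the number of PASS calls."""
        rng = np.random.default_rng(22)
        pileup, spike = self._spike(small_panel, small_reference, 0.0, rng)
        cnts = pileup.counts[(spike.chrom, spike.pos)]
        cnts[spike.alt] = [20, 0]
        cnts[spike.ref][0] -= 20
        strict, _ = call_variants(pileup, profile, CallerConfig())
        relaxed, _ = call_variants(
            pileup,
            profile,
            CallerConfig(require_both_strands=False, strand_bias_p_floor=1e-12,
                         min_indel_length=1),
        )
        assert sum(c.passed for c in relaxed) >= sum(c.passed for c in strict)

    def test_panel_mismatch_errors(self, panel, reference, profile):
        rng = np.random.default_rng(23)
        pileup = simulate_sscs_pileup(panel, reference, 200, 1e-4, rng)
        with pytest.raises(ValueError, match="different panels"):
            call_variants(pileup, profile)


class TestVcfOutput:
    def test_vcf_parses_and_round_trips_fields(
        self, small_panel, small_reference, profile, tmp_path
    ):
        import pysam

        rng = np.random.default_rng(31)
        chrom, pos = list(small_panel.positions())[10]
        ref = small_reference[chrom][pos]
        alt = "A" if ref != "A" else "C"
        pileup = simulate_sscs_pileup(
            small_panel, small_reference, 2000, 1e-4, rng,
            [SpikeIn(chrom, pos, ref, alt, 0.01)],
        )
        pileup.indel_events[(chrom, pos, "del:4")] = [15, 15]
        calls, _ = call_variants(pileup, profile)
        assert calls
        path = str(tmp_path / "calls.vcf")
        write_vcf(calls, path, {"chrS": 400})
        recs = list(pysam.VariantFile(path))
        assert len(recs) == len(calls)
        by_pos = {(r.chrom, r.pos - 1, r.alts[0]) for r in recs}
        for c in calls:
            alt_field = c.alt if ":" not in c.alt else (
                "<DEL>" if c.alt.startswith("del") else "<INS>"
            )
            assert (c.chrom, c.pos, alt_field) in by_pos
        snv = next(r for r in recs if r.alts[0] in "ACGT")
        assert snv.info["COV"] > 0 and 0 <= snv.info["VAF"] <= 1


def test_null_family_wise_error_rate(small_panel, small_reference, profile):
    """Under the null the per-sample P(any false PASS) stays near alpha.

    200 mutation-free samples drawn at the profile's true error rate; with a
    conservative upper bound plus Bonferroni, the false-sample fraction must
    not exceed alpha plus 3-sigma binomial slack.
    """
    rng = np.random.default_rng(404)
    alpha = 0.05
    n_samples, n_bad = 200, 0
    for _ in range(n_samples):
        pileup = simulate_sscs_pileup(small_panel, small_reference, 500, 1e-4, rng)
        calls, _ = call_variants(
            pileup, profile, CallerConfig(alpha=alpha, min_sscs_coverage=100)
        )
        n_bad += any(c.passed for c in calls)
    slack = 3 * math.sqrt(alpha * (1 - alpha) / n_samples)
    assert n_bad / n_samples <= alpha + slack
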