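"""Somatic filter cascade: reason accumulation, missing evidence,
monotonicity, AF spectrum."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetseq.filtering import af_spectrum, filter_cohort, population_filter, quality_filter
from tetseq.models import FilterConfig, FilterReason, VariantCall


def call(**kw) -> VariantCall:
    base = dict(
        sample_id="S1", chrom="chr1", pos=kw.pop("pos", 100),
        ref="C", alt="T", depth=200, alt_reads=20,
        strand_counts=(90, 90, 10, 10), sb_phred=10.0, sb_odds_ratio=1.0,
        mean_mismatches=1.0, snr=20.0, msi_flag=False, pop_af=None,
    )
    base.update(kw)
    return VariantCall(**base)


CFG = FilterConfig()


class TestReasons:
    def test_clean_somatic_like_call_passes(self):
        assert quality_filter(call(), CFG).passed

    def test_all_reasons_accumulated_not_short_circuited(self):
        bad = call(depth=10, alt_reads=10, sb_phred=100.0, sb_odds_ratio=5.0,
                   mean_mismatches=4.0, snr=1.0, msi_flag=True,
                   strand_counts=(0, 0, 10, 0))
        decision = quality_filter(bad, CFG)
        assert decision.reasons == {
            FilterReason.LOW_DEPTH, FilterReason.GERMLINE_AF,
            FilterReason.STRAND_BIAS_PHRED, FilterReason.STRAND_BIAS_OR,
            FilterReason.MISMATCHES, FilterReason.LOW_SNR, FilterReason.MSI,
        }

    def test_each_reason_reproducible_in_isolation(self):
        """Any single reason can be reproduced by a config in which every
        other threshold is maximally permissive."""
        permissive = dict(min_depth=1, min_af=1e-9, max_af=1 - 1e-9,
                          max_sb_phred=1e9, max_sb_or=1e9,
                          max_mean_mismatches=1e9, min_snr=1e-9,
                          max_pop_af=1.0, exclude_msi=False)
        singles = {
            FilterReason.LOW_DEPTH: (
                {"depth": 19, "alt_reads": 2}, {"min_depth": 20}),
            FilterReason.LOW_AF: (
                {"depth": 1000, "alt_reads": 30}, {"min_af": 0.04}),
            FilterReason.GERMLINE_AF: (
                {"depth": 100, "alt_reads": 50}, {"max_af": 0.45}),
            FilterReason.STRAND_BIAS_PHRED: (
                {"sb_phred": 100.0}, {"max_sb_phred": 60}),
            FilterReason.STRAND_BIAS_OR: (
                {"sb_odds_ratio": 5.0}, {"max_sb_or": 3}),
            FilterReason.MISMATCHES: (
                {"mean_mismatches": 4.0}, {"max_mean_mismatches": 3}),
            FilterReason.LOW_SNR: ({"snr": 1.0}, {"min_snr": 4}),
            FilterReason.MSI: ({"msi_flag": True}, {"exclude_msi": True}),
        }
        for reason, (call_kw, override) in singles.items():
            bad = call(**call_kw)
            assert reason in quality_filter(bad, CFG).reasons
            config = FilterConfig(**{**permissive, **override})
            assert quality_filter(bad, config).reasons == {reason}, reason

    def test_zero_depth_is_low_depth_with_af_zero(self):
        decision = quality_filter(call(depth=0, alt_reads=0), CFG)
        assert FilterReason.LOW_DEPTH in decision.reasons
        assert FilterReason.GERMLINE_AF not in decision.reasons

    def test_missing_optional_evidence_does_not_fire(self):
        clean = call(sb_phred=None, sb_odds_ratio=None, mean_mismatches=None,
                     snr=None, pop_af=None)
        assert quality_filter(clean, CFG).passed

    def test_strict_mode_rejects_missing_evidence(self):
        strict = FilterConfig(strict_missing=True)
        decision = quality_filter(call(snr=None), strict)
        assert FilterReason.LOW_SNR in decision.reasons

    def test_population_filter_contract(self):
        assert population_filter(call(pop_af=0.063), CFG) is FilterReason.POP_AF
        assert population_filter(call(pop_af=0.00009), CFG) is None
        assert population_filter(call(pop_af=None), CFG) is None


class TestCohortFilter:
    def test_empty_input(self):
        result = filter_cohort([])
        assert result.passed == [] and result.decisions == []
        assert sum(result.tally.values()) == 0

    def test_internal_control_af_range_passes(self):
        # clean calls across the reported 4-22% driver-control AF range
        calls = [call(pos=i, depth=500, alt_reads=int(500 * af))
                 for i, af in enumerate(np.linspace(0.04, 0.22, 10), start=1)]
        result = filter_cohort(calls)
        assert result.n_passed == len(calls)

    def test_germline_af_rejections(self):
        het = call(depth=200, alt_reads=100)
        hom = call(depth=200, alt_reads=200)
        result = filter_cohort([het, hom])
        assert result.n_passed == 0
        assert all(FilterReason.GERMLINE_AF in d.reasons for d in result.decisions)

    def test_simulated_germline_vs_somatic_separation(self):
        """Deep coverage separates binomially sampled heterozygous
        germline AFs (around 0.5) from purity-diluted somatic AFs
        (around 0.1) through the AF window alone."""
        rng = np.random.default_rng(42)
        depth = 1000
        calls, labels = [], []
        for i in range(100):
            calls.append(call(pos=i + 1, depth=depth,
                              alt_reads=int(rng.binomial(depth, 0.5))))
            labels.append("germline")
        for i in range(10):
            calls.append(call(pos=1000 + i, depth=depth,
                              alt_reads=int(rng.binomial(depth, 0.10))))
            labels.append("somatic")
        result = filter_cohort(calls)
        somatic_pass = sum(1 for l, d in zip(labels, result.decisions)
                           if l == "somatic" and d.passed)
        germline_rej = sum(1 for l, d in zip(labels, result.decisions)
                           if l == "germline" and not d.passed)
        assert somatic_pass == 10
        assert germline_rej >= 99

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 300), st.floats(0.0, 1.0)),
            max_size=25,
        ),
        st.floats(0.01, 0.2),
        st.floats(0.3, 0.9),
    )
    def test_monotonicity_in_af_window(self, specs, min_af, max_af):
        calls = [
            call(pos=i + 1, depth=d, alt_reads=int(round(d * af)))
            for i, (d, af) in enumerate(specs)
        ]
        narrow = FilterConfig(min_af=min_af, max_af=max_af)
        wide = FilterConfig(min_af=min_af / 2,
                            max_af=min(0.99, max_af + 0.05))
        passed_narrow = {c.pos for c in filter_cohort(calls, narrow).passed}
        passed_wide = {c.pos for c in filter_cohort(calls, wide).passed}
        assert passed_narrow <= passed_wide
        deeper = FilterConfig(min_af=min_af, max_af=max_af,
                              min_depth=CFG.min_depth * 2)
        assert {c.pos for c in filter_cohort(calls, deeper).passed} <= passed_narrow


class TestAfSpectrum:
    def test_bimodal_germline_modes(self):
        rng = np.random.default_rng(7)
        calls = [call(pos=i + 1, depth=200,
                      alt_reads=int(rng.binomial(200, 0.5)))
                 for i in range(200)]
        calls += [call(pos=1000 + i, depth=200,
                       alt_reads=int(rng.binomial(200, 0.995)))
                  for i in range(100)]
        spectrum = af_spectrum(calls)
        assert any(abs(m - 0.5) <= 0.02 for m in spectrum.modes)
        assert any(m >= 0.97 for m in spectrum.modes)

    def test_single_mode_at_somatic_af(self):
        calls = [call(pos=i + 1, depth=100, alt_reads=10) for i in range(20)]
        spectrum = af_spectrum(calls)
        assert spectrum.modes == [pytest.approx(0.11)]
        assert spectrum.n_in_somatic_window == 20

    def test_empty(self):
        spectrum = af_spectrum([])
        assert spectrum.counts.sum() == 0 and spectrum.modes == []
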