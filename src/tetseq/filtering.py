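"""Tumor-only somatic filter cascade.

Without a matched normal, germline variants are removed by their allele
fraction (heterozygous ~50%, homozygous ~100%, so anything at AF >= 45% is
excluded), known population variants by annotated population frequency
(>= 0.01%), and sequencing artifacts by strand-bias, mismatch, signal-to-
noise and microsatellite evidence. Somatic mutations, diluted by the
non-tumoral thymocyte and stromal fraction of the sample, survive in the
4-45% AF window provided the locus has at least 20 reads.

Every applicable reason is recorded for every call — the cascade is
conjunctive and never short-circuits, so tallies are order-independent.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import FilterConfig, FilterDecision, FilterReason, VariantCall


def population_filter(call: VariantCall, config: FilterConfig) -> Optional[FilterReason]:
    """POP_AF fires iff the annotated population allele frequency reaches
    ``max_pop_af`` (inclusive). Absent annotation never fires (unless the
    config is strict about missing evidence)."""
    if call.pop_af is None:
        return FilterReason.POP_AF if config.strict_missing else None
    return FilterReason.POP_AF if call.pop_af >= config.max_pop_af else None


def quality_filter(call: VariantCall, config: FilterConfig) -> FilterDecision:
    """Evidence-threshold verdict for one call (population filter aside).

    Inequality directions follow the published wording literally:
    depth "at least 20" (fail when < 20), AF "at least 4%" (fail when
    < 0.04), germline exclusion at AF >= 0.45, strand-bias Phred score
    > 60, strand-bias odds ratio > 3, mean mismatches >= 3, signal-to-
    noise < 4, and any flagged microsatellite locus.
    """
    reasons: set[FilterReason] = set()
    af = call.af  # 0.0 at zero depth
    if call.depth < config.min_depth:
        reasons.add(FilterReason.LOW_DEPTH)
    if af < config.min_af:
        reasons.add(FilterReason.LOW_AF)
    if af >= config.max_af:
        reasons.add(FilterReason.GERMLINE_AF)

    def _breach(value: Optional[float], fires, reason: FilterReason) -> None:
        if value is None:
            if config.strict_missing:
                reasons.add(reason)
        elif fires(value):
            reasons.add(reason)

    _breach(call.sb_phred, lambda v: v > config.max_sb_phred,
            FilterReason.STRAND_BIAS_PHRED)
    _breach(call.sb_odds_ratio, lambda v: v > config.max_sb_or,
            FilterReason.STRAND_BIAS_OR)
    _breach(call.mean_mismatches, lambda v: v >= config.max_mean_mismatches,
            FilterReason.MISMATCHES)
    _breach(call.snr, lambda v: v < config.min_snr, FilterReason.LOW_SNR)
    if config.exclude_msi and call.msi_flag:
        reasons.add(FilterReason.MSI)
    return FilterDecision(call=call, reasons=frozenset(reasons))


@dataclass
class CohortFilterResult:
    passed: list[VariantCall]
    decisions: list[FilterDecision]
    tally: Counter

    @property
    def n_passed(self) -> int:
        return len(self.passed)


def filter_cohort(
    calls: Sequence[VariantCall], config: Optional[FilterConfig] = None
) -> CohortFilterResult:
    """Run the full cascade over every call, order-preserving.

    The tally counts every fired reason over all calls (one call can
    contribute several reasons)."""
    if config is None:
        config = FilterConfig()
    decisions: list[FilterDecision] = []
    passed: list[VariantCall] = []
    tally: Counter = Counter()
    for call in calls:
        decision = quality_filter(call, config)
        pop = population_filter(call, config)
        if pop is not None:
            decision = FilterDecision(call=call, reasons=decision.reasons | {pop})
        decisions.append(decision)
        for reason in decision.reasons:
            tally[reason] += 1
        if decision.passed:
            passed.append(call)
    return CohortFilterResult(passed=passed, decisions=decisions, tally=tally)


@dataclass
class AFSpectrum:
    """Binned allele-fraction histogram with local modes.

    The bimodal germline structure (modes near 0.5 and 1.0) plus the
    purity-diluted somatic mass at low AF is the pattern this summarizes.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    modes: list[float] = field(default_factory=list)  # bin centers of local maxima
    n_in_somatic_window: int = 0


def af_spectrum(
    calls: Sequence[VariantCall],
    decisions: Optional[Sequence[FilterDecision]] = None,
    bin_width: float = 0.02,
    config: Optional[FilterConfig] = None,
) -> AFSpectrum:
    """Histogram of observed allele fractions (default 2% bins).

    Local modes are non-empty bins strictly greater than both neighbours
    (plateau ties keep the leftmost bin). ``n_in_somatic_window`` counts
    calls inside [min_af, max_af) — of passing calls only, when decisions
    are supplied."""
    if config is None:
        config = FilterConfig()
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    afs = np.array([c.af for c in calls])
    if afs.size == 0:
        return AFSpectrum(edges, np.zeros(len(edges) - 1, dtype=int))
    counts, _ = np.histogram(np.clip(afs, 0, 1 - 1e-12), bins=edges)
    padded = np.concatenate([[-1], counts, [-1]])
    modes = [
        float((edges[i] + edges[i + 1]) / 2)
        for i in range(len(counts))
        if counts[i] > 0
        and padded[i] < padded[i + 1] >= padded[i + 2]
        and (padded[i + 1] > padded[i + 2] or padded[i] < padded[i + 1])
    ]
    if decisions is not None:
        pool = [d.call.af for d in decisions if d.passed]
    else:
        pool = list(afs)
    window = sum(1 for a in pool if config.min_af <= a < config.max_af)
    return AFSpectrum(edges, counts, modes, window)
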