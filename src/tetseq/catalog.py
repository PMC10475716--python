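"""Meta-analysis over pooled mutation catalogs.

Recurrence, per-sample burden, substitution spectra and pairwise
co-occurrence / mutual-exclusivity testing over presence/absence of
non-synonymous coding mutations per gene. A "mutated sample" for
recurrence and association carries at least one non-synonymous coding
mutation in the gene; set ``coding_only=False`` to count every record.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import MutationRecord, NONSYNONYMOUS_CLASSES
from .stats import fisher_exact_2x2, odds_ratio_estimates

log = logging.getLogger(__name__)

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class Catalog:
    """Pooled mutation records plus the sample universe.

    ``samples`` may contain samples with zero records (they still count in
    denominators and contribute zero burden).
    """

    records: list[MutationRecord]
    samples: set[tuple[str, str, str]] = field(default_factory=set)  # (sample, study, histotype)

    def __post_init__(self) -> None:
        known = {(s, st) for s, st, _ in self.samples}
        for r in self.records:
            if (r.sample_id, r.study_id) not in known:
                self.samples.add((r.sample_id, r.study_id, r.histotype))
                known.add((r.sample_id, r.study_id))

    @property
    def studies(self) -> set[str]:
        return {st for _, st, _ in self.samples} | {r.study_id for r in self.records}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_mutations(self) -> int:
        return len(self.records)

    def study_summary(self) -> pd.DataFrame:
        """Per-study sample and mutation totals (the pooled-report shape)."""
        n_rec = Counter(r.study_id for r in self.records)
        n_smp = Counter(st for _, st, _ in self.samples)
        rows = [
            {"study_id": st, "n_samples": n_smp.get(st, 0),
             "n_mutations": n_rec.get(st, 0)}
            for st in sorted(self.studies)
        ]
        return pd.DataFrame(rows)


def pool_studies(
    per_study_records: Sequence[Sequence[MutationRecord]],
    extra_samples: Iterable[tuple[str, str, str]] = (),
) -> Catalog:
    """Pool study record lists into one catalog.

    Duplicate (study, sample, chrom, pos, alt) rows are de-duplicated with
    a logged warning count. Pooling is order-invariant: records are sorted
    canonically.
    """
    seen = set()
    dupes = 0
    records: list[MutationRecord] = []
    for study_records in per_study_records:
        for r in study_records:
            key = (r.study_id, r.sample_id, r.chrom, r.pos, r.alt)
            if key in seen:
                dupes += 1
                continue
            seen.add(key)
            records.append(r)
    if dupes:
        log.warning("pool_studies: dropped %d duplicate records", dupes)
    records.sort(key=lambda r: (r.study_id, r.sample_id, r.chrom, r.pos, r.alt))
    return Catalog(records=records, samples=set(extra_samples))


@dataclass(frozen=True)
class GeneRecurrence:
    gene: str
    n_samples: int
    n_mutations: int


def recurrence(catalog: Catalog, coding_only: bool = True) -> list[GeneRecurrence]:
    """Per-gene recurrence sorted by distinct mutated samples, descending
    (ties broken lexicographically by gene)."""
    classes = NONSYNONYMOUS_CLASSES if coding_only else None
    per_gene_samples: dict[str, set] = defaultdict(set)
    per_gene_n: Counter = Counter()
    for r in catalog.records:
        if classes is not None and r.effect_class not in classes:
            continue
        per_gene_samples[r.gene].add((r.sample_id, r.study_id))
        per_gene_n[r.gene] += 1
    out = [
        GeneRecurrence(g, len(s), per_gene_n[g])
        for g, s in per_gene_samples.items()
    ]
    out.sort(key=lambda gr: (-gr.n_samples, gr.gene))
    return out


def recurrent_gene_set(
    catalog: Catalog, min_samples: int, coding_only: bool = True
) -> set[str]:
    """Genes mutated in at least ``min_samples`` distinct samples (use 6
    for the 'more than five patients' rule)."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    return {
        gr.gene for gr in recurrence(catalog, coding_only=coding_only)
        if gr.n_samples >= min_samples
    }


def substitution_spectrum(records: Sequence[MutationRecord]) -> dict[str, int]:
    """Counts over the six pyrimidine-reference substitution classes.

    Purine-reference SNVs are complement-collapsed; non-SNVs are excluded
    (counts sum to the number of SNVs)."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for r in records:
        if not r.is_snv:
            continue
        ref, alt = r.ref, r.alt
        if ref in "GA":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    return counts


@dataclass
class BurdenSummary:
    per_sample: pd.DataFrame  # sample_id, study_id, n_mutations, hypermutator
    median: float
    q1: float
    q3: float

    @property
    def hypermutators(self) -> list[str]:
        return list(self.per_sample.loc[self.per_sample.hypermutator, "sample_id"])


def burden_per_sample(catalog: Catalog) -> BurdenSummary:
    """Per-sample mutation counts with quartile summary.

    Samples listed in the catalog with zero records contribute a zero
    count. Samples with count > Q3 + 3*IQR are flagged as hypermutator
    outliers (the catalog's 936-mutation mismatch-repair case is the
    motivating example)."""
    counts = Counter((r.sample_id, r.study_id) for r in catalog.records)
    rows = [
        {"sample_id": s, "study_id": st,
         "n_mutations": counts.get((s, st), 0)}
        for s, st, _ in sorted(catalog.samples)
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "study_id", "n_mutations"])
    if df.empty:
        return BurdenSummary(df.assign(hypermutator=[]), np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(df.n_mutations, [25, 50, 75])
    iqr = q3 - q1
    df["hypermutator"] = df.n_mutations > q3 + 3 * iqr
    return BurdenSummary(df, float(med), float(q1), float(q3))


@dataclass
class PairAssociation:
    gene_a: str
    gene_b: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, a_only], [b_only, neither]]
    odds_ratio: float  # conditional-MLE convention
    odds_ratio_haldane: float
    p_value: float
    direction: str  # co-occurrent | mutually-exclusive | none
    significance: str  # significant | borderline | ns


def pairwise_association(
    catalog: Catalog,
    genes: Sequence[str],
    alpha1: float = 0.05,
    alpha2: float = 0.1,
    coding_only: bool = True,
) -> list[PairAssociation]:
    """Two-sided Fisher exact test of per-sample presence/absence for
    every unordered gene pair.

    No multiple-testing correction is applied: results carry raw p-values
    with significance labels at ``alpha1`` (significant) and ``alpha2``
    (borderline). A degenerate margin (a gene mutated in no sample or in
    every sample) yields p=1 and direction "none".
    """
    classes = NONSYNONYMOUS_CLASSES if coding_only else None
    presence: dict[str, set] = {g: set() for g in genes}
    for r in catalog.records:
        if r.gene in presence and (classes is None or r.effect_class in classes):
            presence[r.gene].add((r.sample_id, r.study_id))
    universe = {(s, st) for s, st, _ in catalog.samples}
    n = len(universe)
    out = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            a, b = presence[ga], presence[gb]
            both = len(a & b)
            a_only = len(a - b)
            b_only = len(b - a)
            neither = n - both - a_only - b_only
            table = ((both, a_only), (b_only, neither))
            degenerate = len(a) in (0, n) or len(b) in (0, n)
            if degenerate:
                out.append(PairAssociation(ga, gb, table, np.nan, np.nan,
                                           1.0, "none", "ns"))
                continue
            _, p = fisher_exact_2x2(table)
            ors = odds_ratio_estimates(table)
            hald = ors["haldane"]
            direction = ("co-occurrent" if hald > 1
                         else "mutually-exclusive" if hald < 1 else "none")
            sig = ("significant" if p < alpha1
                   else "borderline" if p < alpha2 else "ns")
            out.append(PairAssociation(ga, gb, table, ors["cmle"], hald,
                                       p, direction, sig))
    return out


def association_frame(associations: Sequence[PairAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": a.gene_a, "gene_b": a.gene_b,
                "both": a.table[0][0], "a_only": a.table[0][1],
                "b_only": a.table[1][0], "neither": a.table[1][1],
                "odds_ratio": a.odds_ratio,
                "odds_ratio_haldane": a.odds_ratio_haldane,
                "p_value": a.p_value, "direction": a.direction,
                "significance": a.significance,
            }
            for a in associations
        ]
    )
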