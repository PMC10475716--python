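"""Cohort-level statistics for a resequencing study.

Per-histotype coding-mutation detection rates, the 2xk exact association
test between histotype and detection, and GTF2I internal-control
summaries. Histotype groups can be merged through a grouping map (the
study convention merges the mixed B2-B3 class into B3); merging always
sums stored counts, and percentages are recomputed from counts, never
stored independently.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import CohortSample, VariantCall
from .stats import freeman_halton

log = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class HistotypeTable:
    """Per-histotype mutated/not-mutated counts with integer-percent
    detection frequencies (half-up rounding)."""

    table: pd.DataFrame  # histotype, n_mutated, n_not, frequency (nullable Int64)

    @property
    def histotypes(self) -> list[str]:
        return list(self.table.histotype)

    def counts_2xk(self, exclude: Sequence[str] = ()) -> np.ndarray:
        df = self.table[~self.table.histotype.isin(exclude)]
        return np.vstack([df.n_mutated.to_numpy(int), df.n_not.to_numpy(int)])


def _apply_grouping(
    df: pd.DataFrame, grouping: Optional[Mapping[str, str]]
) -> pd.DataFrame:
    if grouping:
        df = df.assign(histotype=df.histotype.map(lambda h: grouping.get(h, h)))
    out = df.groupby("histotype", sort=False, as_index=False)[
        ["n_mutated", "n_not"]
    ].sum()
    return out


def detection_table(
    samples_or_counts,
    grouping: Optional[Mapping[str, str]] = None,
    expected_total: Optional[int] = None,
) -> HistotypeTable:
    """Detection-rate table, from cohort samples or a precomputed counts
    frame (columns histotype, n_mutated, n_not).

    Frequencies are half-up-rounded integer percentages; an empty group
    has an absent frequency. When the column totals disagree with
    ``expected_total`` a reconciliation warning is logged (published
    per-histotype tables do not always sum to the stated cohort size).
    """
    if isinstance(samples_or_counts, pd.DataFrame):
        df = samples_or_counts[["histotype", "n_mutated", "n_not"]].copy()
    else:
        samples: Sequence[CohortSample] = list(samples_or_counts)
        rows = {}
        for s in samples:
            m, n = rows.get(s.histotype, (0, 0))
            if s.has_coding_mutation:
                m += 1
            else:
                n += 1
            rows[s.histotype] = (m, n)
        df = pd.DataFrame(
            [
                {"histotype": h, "n_mutated": m, "n_not": n}
                for h, (m, n) in rows.items()
            ]
        )
    df = _apply_grouping(df, grouping)
    total = int(df.n_mutated.sum() + df.n_not.sum())
    if expected_total is not None and total != expected_total:
        log.warning(
            "detection_table: counts sum to %d samples, expected %d — "
            "published tables and cohort size may disagree",
            total, expected_total,
        )
    freq = [
        round_half_up(100 * m / (m + n)) if (m + n) > 0 else pd.NA
        for m, n in zip(df.n_mutated, df.n_not)
    ]
    df["frequency"] = pd.array(freq, dtype="Int64")
    return HistotypeTable(table=df.reset_index(drop=True))


def histotype_association(
    table: HistotypeTable,
    exclude_nos: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Freeman–Halton exact p-value for histotype x detection.

    By default the NOS/unknown-histotype column is excluded (an unknown
    histotype is not a biological class); pass ``exclude_nos=False`` to
    keep it. Groups with zero samples are dropped.
    """
    exclude = ["NOS"] if exclude_nos else []
    counts = table.counts_2xk(exclude=exclude)
    counts = counts[:, counts.sum(axis=0) > 0]
    if counts.shape[1] < 2:
        log.warning("histotype_association: fewer than 2 non-empty groups; p=1")
        return 1.0
    if (counts.sum(axis=1) == 0).any():
        log.warning("histotype_association: zero margin; p=1")
        return 1.0
    return freeman_halton(counts, rng=rng)


@dataclass
class Gtf2iSummary:
    counts_by_histotype: dict[str, int]
    n_mutant: int
    af_min: Optional[float]
    af_max: Optional[float]
    stage_cross_tab: pd.DataFrame  # gtf2i_mutant x early/advanced stage
    metastasis_table: tuple[tuple[int, int], tuple[int, int]]  # gtf2i x metastatic


_EARLY_STAGES = {"I", "IIA", "IIB"}


def gtf2i_summary(
    samples: Sequence[CohortSample],
    calls: Sequence[VariantCall] = (),
    gene: str = "GTF2I",
    gene_loci: Optional[Sequence[tuple[str, int]]] = None,
) -> Gtf2iSummary:
    """Internal-control summary for the recurrent-driver gene.

    Per-histotype mutant counts come from the cohort annotations; the AF
    range comes from the calls at the gene's loci (``gene_loci`` as
    (chrom, pos) pairs; when omitted, all provided calls are treated as
    calls in the gene). Also cross-tabulates mutation status against
    early (I/II) vs advanced (III/IV) stage and against metastasis at
    diagnosis."""
    counts: dict[str, int] = {}
    for s in samples:
        if s.gtf2i_mutant:
            counts[s.histotype] = counts.get(s.histotype, 0) + 1
    gene_calls = [
        c for c in calls
        if gene_loci is None or (c.chrom, c.pos) in set(gene_loci)
    ]
    afs = [c.af for c in gene_calls]
    rows = []
    for mutant in (True, False):
        sub = [s for s in samples if s.gtf2i_mutant == mutant]
        rows.append(
            {
                "gtf2i_mutant": mutant,
                "stage_I_II": sum(1 for s in sub if s.stage in _EARLY_STAGES),
                "stage_III_IV": sum(
                    1 for s in sub if s.stage not in _EARLY_STAGES and s.stage != "unknown"
                ),
                "stage_unknown": sum(1 for s in sub if s.stage == "unknown"),
            }
        )
    meta = tuple(
        (
            sum(1 for s in samples if s.gtf2i_mutant == m and s.metastatic_at_diagnosis),
            sum(1 for s in samples if s.gtf2i_mutant == m and not s.metastatic_at_diagnosis),
        )
        for m in (True, False)
    )
    return Gtf2iSummary(
        counts_by_histotype=dict(sorted(counts.items())),
        n_mutant=sum(counts.values()),
        af_min=min(afs) if afs else None,
        af_max=max(afs) if afs else None,
        stage_cross_tab=pd.DataFrame(rows),
        metastasis_table=meta,  # type: ignore[arg-type]
    )
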