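"""Core domain types shared across the pipeline.

Coordinates are 1-based closed everywhere inside the package (VCF
convention); conversion to 0-based half-open BED happens only at the
:mod:`tetseq.io_formats` boundary.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class EffectClass(str, enum.Enum):
    """Consequence vocabulary for a mutation relative to a transcript.

    ``silent`` and ``Synonymous Mutation`` are one class; MAF-style and
    annotator-style labels are normalized onto this vocabulary by the
    catalog reader.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    NONSTOP = "nonstop"
    SILENT = "silent"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    NONFRAMESHIFT_SUBSTITUTION = "nonframeshift_substitution"
    UTR5 = "utr5"
    UTR3 = "utr3"
    FLANK5 = "flank5"
    FLANK3 = "flank3"
    INTRON = "intron"
    INTERGENIC = "intergenic"
    NCRNA = "ncRNA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes counted in the "coding sequence" subtotal. Splice-site and
#: synonymous changes are included: this is the definition under which the
#: per-class tally of a thymoma panel study reconciles (coding subtotal 83
#: of 238 total).
CODING_CLASSES = frozenset(
    {
        EffectClass.MISSENSE,
        EffectClass.NONSENSE,
        EffectClass.NONSTOP,
        EffectClass.SILENT,
        EffectClass.SPLICE_SITE,
        EffectClass.FRAMESHIFT_INSERTION,
        EffectClass.FRAMESHIFT_DELETION,
        EffectClass.INFRAME_INSERTION,
        EffectClass.INFRAME_DELETION,
        EffectClass.NONFRAMESHIFT_SUBSTITUTION,
    }
)

#: Coding classes with a non-synonymous effect on the protein — the set
#: that defines a "mutated sample" for recurrence and co-occurrence.
NONSYNONYMOUS_CLASSES = frozenset(CODING_CLASSES - {EffectClass.SILENT})

#: WHO histotype vocabulary (thymomas A..B3, thymic carcinoma TC, and
#: not-otherwise-specified).
HISTOTYPES = ("A", "AB", "B1", "B2", "B2-B3", "B3", "TC", "NOS")

STAGES = ("I", "IIA", "IIB", "III", "IVA", "unknown")


class FilterReason(str, enum.Enum):
    """Machine-readable reason codes for the somatic filter cascade."""

    POP_AF = "POP_AF"
    LOW_DEPTH = "LOW_DEPTH"
    LOW_AF = "LOW_AF"
    GERMLINE_AF = "GERMLINE_AF"
    STRAND_BIAS_PHRED = "STRAND_BIAS_PHRED"
    STRAND_BIAS_OR = "STRAND_BIAS_OR"
    MISMATCHES = "MISMATCHES"
    LOW_SNR = "LOW_SNR"
    MSI = "MSI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class VariantCall:
    """One caller record (one ALT allele) with its quality evidence.

    ``strand_counts`` is (ref-forward, ref-reverse, alt-forward,
    alt-reverse). Optional evidence (``sb_phred`` .. ``pop_af``) may be
    ``None`` when the caller did not annotate it; the filter treats absent
    evidence as non-firing unless run in strict mode.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int
    strand_counts: tuple[int, int, int, int] = (0, 0, 0, 0)
    sb_phred: Optional[float] = None
    sb_odds_ratio: Optional[float] = None
    mean_mismatches: Optional[float] = None
    snr: Optional[float] = None
    msi_flag: bool = False
    pop_af: Optional[float] = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} > depth {self.depth} at {self.chrom}:{self.pos}"
            )
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def af(self) -> float:
        """Allele fraction; 0.0 at zero depth."""
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class MutationRecord:
    """One mutation observation in one sample (a catalog row)."""

    sample_id: str
    study_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: EffectClass
    protein_change: Optional[str] = None
    histotype: str = "NOS"

    def __post_init__(self) -> None:
        if self.histotype not in HISTOTYPES:
            raise ValueError(
                f"unknown histotype {self.histotype!r}; accepted: {HISTOTYPES}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _check_intervals(intervals: Sequence[tuple[int, int]], label: str) -> None:
    prev_end = None
    for start, end in intervals:
        if end < start:
            raise ValueError(f"{label}: interval end {end} < start {start}")
        if prev_end is not None and start <= prev_end:
            raise ValueError(f"{label}: intervals overlap or are unsorted")
        prev_end = end


@dataclass
class GeneModel:
    """Stranded transcript skeleton used for consequence classification.

    All intervals are 1-based closed genomic coordinates, sorted by start
    regardless of strand. For minus-strand genes the first codon of the
    protein sits at the *highest* CDS coordinate. ``ncrna`` models carry
    their exons in ``cds_exons`` but are never translated.
    """

    gene: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    splice_window: int = 2
    ncrna: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for label, ivs in (
            ("cds_exons", self.cds_exons),
            ("utr5", self.utr5),
            ("utr3", self.utr3),
        ):
            _check_intervals(sorted(ivs), f"{self.gene}.{label}")
        self.cds_exons = sorted(self.cds_exons)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Transcript exons: union of CDS and UTR intervals, merged."""
        ivs = sorted(self.cds_exons + self.utr5 + self.utr3)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    @property
    def span(self) -> tuple[int, int]:
        ex = self.exons
        return (ex[0][0], ex[-1][1])


@dataclass
class FilterConfig:
    """Thresholds of the tumor-only somatic filter cascade.

    Defaults encode the published cascade: >=20 reads of coverage, >=4%
    allele fraction, germline exclusion at AF >=45%, Phred-scaled
    strand-bias score >60, strand-bias odds ratio >3, mean mismatches per
    alt read >=3, signal-to-noise <4, population allele frequency >=0.01%,
    and exclusion of microsatellite loci. Inclusive/exclusive directions
    follow the published wording literally.
    """

    min_depth: int = 20
    min_af: float = 0.04
    max_af: float = 0.45
    max_sb_phred: float = 60.0
    max_sb_or: float = 3.0
    max_mean_mismatches: float = 3.0
    min_snr: float = 4.0
    max_pop_af: float = 1e-4
    exclude_msi: bool = True
    strict_missing: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_af < self.max_af < 1):
            raise ValueError("require 0 < min_af < max_af < 1")
        for name in ("min_depth", "max_sb_phred", "max_sb_or",
                     "max_mean_mismatches", "min_snr", "max_pop_af"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterDecision:
    """Per-call verdict; ``passed`` iff no reason fired. Reasons are
    accumulated exhaustively, never short-circuited."""

    call: VariantCall
    reasons: frozenset[FilterReason]

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass
class CohortSample:
    """One patient/sample row of a resequencing cohort table."""

    sample_id: str
    histotype: str
    stage: str = "unknown"
    myasthenia_class: str = ""
    has_coding_mutation: bool = False
    gtf2i_mutant: bool = False
    metastatic_at_diagnosis: bool = False

    def __post_init__(self) -> None:
        if self.histotype not in HISTOTYPES:
            raise ValueError(f"unknown histotype {self.histotype!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; accepted: {STAGES}")
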