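"""Variant-consequence classification against transcript models, plus
predicted-impact flags (M-CAP thresholding and driver-list membership).

Classification precedence: splice site (intronic bases within the model's
splice window of an exon boundary) > coding classes (codon effect for
SNVs; length mod 3 for indels; equal-length multi-base changes are
non-frameshift substitutions) > UTR > intron > flank > intergenic.
Noncoding-RNA models yield the ncRNA class. Minus-strand genes are
translated on the reverse complement of the spliced genomic sequence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .models import EffectClass, GeneModel, MutationRecord, CODING_CLASSES

#: M-CAP scores strictly above this value predict damage to protein
#: structure or function.
MCAP_THRESHOLD = 0.025

#: Most-severe-first order used when several transcripts overlap a locus.
SEVERITY_ORDER = (
    EffectClass.SPLICE_SITE,
    EffectClass.NONSENSE,
    EffectClass.FRAMESHIFT_INSERTION,
    EffectClass.FRAMESHIFT_DELETION,
    EffectClass.NONSTOP,
    EffectClass.MISSENSE,
    EffectClass.INFRAME_INSERTION,
    EffectClass.INFRAME_DELETION,
    EffectClass.NONFRAMESHIFT_SUBSTITUTION,
    EffectClass.SILENT,
    EffectClass.UTR5,
    EffectClass.UTR3,
    EffectClass.NCRNA,
    EffectClass.INTRON,
    EffectClass.FLANK5,
    EffectClass.FLANK3,
    EffectClass.INTERGENIC,
)
_SEVERITY_RANK = {e: i for i, e in enumerate(SEVERITY_ORDER)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(Exception):
    """Reference/model disagreement or undefined classification."""


class DictReference:
    """In-memory reference: mapping of chrom -> sequence string, queried
    with 1-based closed coordinates."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def seq(self, chrom: str, start: int, end: int) -> str:
        s = self._seqs[chrom]
        if start < 1 or end > len(s):
            raise IndexError(f"{chrom}:{start}-{end} outside reference")
        return s[start - 1:end]


class FastaReference:
    """Reference backed by an indexed FASTA (pyfaidx)."""

    def __init__(self, path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    def seq(self, chrom: str, start: int, end: int) -> str:
        return str(self._fa[chrom][start - 1:end]).upper()


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _spliced_cds(model: GeneModel, reference) -> str:
    fwd = "".join(
        reference.seq(model.chrom, s, e) for s, e in model.cds_exons
    )
    if model.strand == "-":
        return fwd.translate(_COMPLEMENT)[::-1]
    return fwd


def _cds_offset(model: GeneModel, pos: int) -> int:
    """0-based position within the spliced, strand-oriented CDS."""
    fwd = 0
    for s, e in model.cds_exons:
        if s <= pos <= e:
            fwd += pos - s
            break
        fwd += e - s + 1
    if model.strand == "-":
        return model.cds_length - 1 - fwd
    return fwd


def classify_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_model: GeneModel,
    reference=None,
    flank_window: int = 1000,
) -> tuple[EffectClass, Optional[str]]:
    """Classify one variant against one transcript model.

    Returns ``(effect_class, protein_change)``; the protein change (one-
    letter, HGVS-like, e.g. ``L424H`` or ``E37*``) is filled for coding
    SNVs when a reference is available. ``reference`` must expose
    ``seq(chrom, start, end)`` with 1-based closed coordinates; without
    one, coding SNVs cannot be resolved to the codon level and raise.
    A reference base disagreeing with the model's sequence raises
    :class:`AnnotationError` naming the locus.
    """
    ref = ref.upper()
    alt = alt.upper()
    model = gene_model
    if chrom != model.chrom:
        return EffectClass.INTERGENIC, None
    affected = range(pos, pos + max(len(ref), 1))

    if reference is not None and len(ref) >= 1:
        seen = reference.seq(chrom, pos, pos + len(ref) - 1)
        if seen != ref:
            raise AnnotationError(
                f"reference mismatch at {chrom}:{pos}: variant ref {ref!r}, "
                f"reference has {seen!r}"
            )

    exons = model.exons
    span_start, span_end = model.span

    if model.ncrna:
        if any(_in_intervals(p, exons) for p in affected):
            return EffectClass.NCRNA, None
        if span_start <= pos <= span_end:
            return EffectClass.INTRON, None
        return _flank_or_intergenic(model, pos, span_start, span_end, flank_window)

    # splice: any affected intronic base within splice_window of an exon edge
    for p in affected:
        if span_start <= p <= span_end and not _in_intervals(p, exons):
            for s, e in exons:
                if 0 < s - p <= model.splice_window or 0 < p - e <= model.splice_window:
                    return EffectClass.SPLICE_SITE, None

    in_cds = any(_in_intervals(p, model.cds_exons) for p in affected)
    if in_cds:
        if len(ref) == len(alt):
            if len(ref) == 1:
                return _classify_coding_snv(model, pos, ref, alt, reference)
            return EffectClass.NONFRAMESHIFT_SUBSTITUTION, None
        delta = len(alt) - len(ref)
        if delta > 0:
            return (
                EffectClass.INFRAME_INSERTION
                if delta % 3 == 0
                else EffectClass.FRAMESHIFT_INSERTION
            ), None
        return (
            EffectClass.INFRAME_DELETION
            if (-delta) % 3 == 0
            else EffectClass.FRAMESHIFT_DELETION
        ), None

    if any(_in_intervals(p, model.utr5) for p in affected):
        return EffectClass.UTR5, None
    if any(_in_intervals(p, model.utr3) for p in affected):
        return EffectClass.UTR3, None
    if span_start <= pos <= span_end:
        return EffectClass.INTRON, None
    return _flank_or_intergenic(model, pos, span_start, span_end, flank_window)


def _flank_or_intergenic(
    model: GeneModel, pos: int, span_start: int, span_end: int, flank_window: int
) -> tuple[EffectClass, None]:
    upstream = span_start - flank_window <= pos < span_start
    downstream = span_end < pos <= span_end + flank_window
    if upstream:
        return (EffectClass.FLANK5 if model.strand == "+" else EffectClass.FLANK3), None
    if downstream:
        return (EffectClass.FLANK3 if model.strand == "+" else EffectClass.FLANK5), None
    return EffectClass.INTERGENIC, None


def _classify_coding_snv(
    model: GeneModel, pos: int, ref: str, alt: str, reference
) -> tuple[EffectClass, str]:
    if model.cds_length % 3 != 0:
        raise AnnotationError(
            f"{model.gene}: CDS length {model.cds_length} not divisible by 3; "
            "coding classification undefined"
        )
    if reference is None:
        raise AnnotationError(
            f"{model.gene}: cannot resolve codon at {model.chrom}:{pos} "
            "without a reference sequence"
        )
    cds = _spliced_cds(model, reference)
    offset = _cds_offset(model, pos)
    codon_idx, within = divmod(offset, 3)
    codon = list(cds[codon_idx * 3: codon_idx * 3 + 3])
    alt_base = alt if model.strand == "+" else alt.translate(_COMPLEMENT)
    codon_alt = codon.copy()
    codon_alt[within] = alt_base
    ref_aa = str(Seq("".join(codon)).translate())
    alt_aa = str(Seq("".join(codon_alt)).translate())
    change = f"{ref_aa}{codon_idx + 1}{alt_aa}"
    if ref_aa == alt_aa:
        return EffectClass.SILENT, change
    if alt_aa == "*":
        return EffectClass.NONSENSE, change
    if ref_aa == "*":
        return EffectClass.NONSTOP, change
    return EffectClass.MISSENSE, change


def classify_most_severe(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: Sequence[GeneModel],
    reference=None,
    flank_window: int = 1000,
) -> tuple[EffectClass, Optional[str], Optional[str]]:
    """Classify against several transcripts, keeping the most severe
    consequence; returns (effect, protein_change, gene)."""
    best: tuple[int, EffectClass, Optional[str], Optional[str]] = (
        len(SEVERITY_ORDER),
        EffectClass.INTERGENIC,
        None,
        None,
    )
    for model in gene_models:
        effect, change = classify_consequence(
            chrom, pos, ref, alt, model, reference, flank_window
        )
        rank = _SEVERITY_RANK[effect]
        if rank < best[0]:
            best = (rank, effect, change, model.gene)
    return best[1], best[2], best[3]


@dataclass
class ImpactCall:
    """Predicted-impact flags for one mutation."""

    variant: MutationRecord
    mcap_score: Optional[float]
    mcap_significant: bool
    driver_flag: bool
    role_context: str = "unannotated"


def impact_flags(
    record: MutationRecord,
    mcap_table: Mapping[tuple[str, str], float],
    driver_table,
    annotations: Optional[Mapping[str, object]] = None,
) -> ImpactCall:
    """M-CAP threshold (strictly > 0.025) and driver-list membership.

    The two flags are independent: a known driver below the score
    threshold keeps ``driver_flag`` without ``mcap_significant`` (the
    recurrent GTF2I L424H driver is the canonical example). Lookup keys
    are (gene, protein_change)."""
    key = (record.gene, record.protein_change or "")
    score = mcap_table.get(key)
    driver = key in set(driver_table)
    role = "unannotated"
    if annotations and record.gene in annotations:
        role = getattr(annotations[record.gene], "role", "unannotated")
        role = getattr(role, "value", str(role))
    return ImpactCall(
        variant=record,
        mcap_score=score,
        mcap_significant=score is not None and score > MCAP_THRESHOLD,
        driver_flag=driver,
        role_context=role,
    )


@dataclass
class EffectTally:
    counts: dict[EffectClass, int]
    total: int
    coding_subtotal: int


def effect_tally(items) -> EffectTally:
    """Tally effect classes (accepts records or bare classes).

    ``coding_subtotal`` counts the coding-sequence classes: missense,
    nonsense, nonstop, synonymous, splice site, the four indel classes and
    non-frameshift substitutions. The grand total covers every class, so
    the two reconcile with a published per-class table's 238/83 split."""
    counts = {e: 0 for e in EffectClass}
    for item in items:
        effect = item.effect_class if isinstance(item, MutationRecord) else EffectClass(item)
        counts[effect] += 1
    total = sum(counts.values())
    coding = sum(counts[e] for e in CODING_CLASSES)
    return EffectTally(counts=counts, total=total, coding_subtotal=coding)
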