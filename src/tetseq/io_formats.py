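"""Readers and writers for every external format the pipeline touches.

Strict coordinate conventions: everything inside the package is 1-based
closed (VCF style); BED output is converted to 0-based half-open at this
boundary and nowhere else.

VCF evidence-tag names are configurable through :class:`TagMap`; defaults
follow the VarDict tumor-only caller's INFO vocabulary (DP, VD, AF,
REFBIAS/VARBIAS, SBF, ODDRATIO, NM, SN, MSI).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .models import (
    CohortSample,
    EffectClass,
    FilterDecision,
    FilterReason,
    GeneModel,
    HISTOTYPES,
    MutationRecord,
    VariantCall,
)

log = logging.getLogger(__name__)


class ConfigurationError(Exception):
    """A required tag/column/setting is missing or inconsistent."""


class ParseError(Exception):
    """Malformed input file."""


class VocabularyError(ValueError):
    """A label falls outside a closed vocabulary."""


# ---------------------------------------------------------------------------
# label normalization


def _norm(label: str) -> str:
    return "_".join(str(label).strip().lower().replace("'", "").split())


_EFFECT_SYNONYMS: dict[str, EffectClass] = {}


def _register_effect(effect: EffectClass, *labels: str) -> None:
    for lab in (effect.value, *labels):
        _EFFECT_SYNONYMS[_norm(lab)] = effect


_register_effect(EffectClass.MISSENSE, "Missense_Mutation", "Missense Mutation")
_register_effect(EffectClass.NONSENSE, "Nonsense_Mutation", "Nonsense Mutation",
                 "stop_gained", "stopgain")
_register_effect(EffectClass.NONSTOP, "Nonstop_Mutation", "Nonstop Mutation",
                 "stop_lost", "stoploss")
_register_effect(EffectClass.SILENT, "Silent", "Synonymous_Mutation",
                 "Synonymous Mutation", "synonymous", "synonymous_variant")
_register_effect(EffectClass.SPLICE_SITE, "Splice_Site", "Splice Site",
                 "splicing", "splice site mutation")
_register_effect(EffectClass.FRAMESHIFT_INSERTION, "Frame_Shift_Ins",
                 "Frame Shift Insertions", "frameshift insertion",
                 "frameshift_ins")
_register_effect(EffectClass.FRAMESHIFT_DELETION, "Frame_Shift_Del",
                 "Frame Shift Deletions", "frameshift deletion",
                 "frameshift_del")
_register_effect(EffectClass.INFRAME_INSERTION, "In_Frame_Ins",
                 "In Frame Insertions", "nonframeshift insertion")
_register_effect(EffectClass.INFRAME_DELETION, "In_Frame_Del",
                 "In Frame Deletions", "nonframeshift deletion")
_register_effect(EffectClass.NONFRAMESHIFT_SUBSTITUTION,
                 "Non frameshift Substitution", "nonframeshift substitution",
                 "non_frameshift_substitution", "mnv")
_register_effect(EffectClass.UTR5, "5'UTR", "5' Untranslated Regions",
                 "5_prime_utr", "five_prime_utr", "5utr")
_register_effect(EffectClass.UTR3, "3'UTR", "3' Untranslated Regions",
                 "3_prime_utr", "three_prime_utr", "3utr")
_register_effect(EffectClass.FLANK5, "5'Flank", "upstream")
_register_effect(EffectClass.FLANK3, "3'Flank", "downstream")
_register_effect(EffectClass.INTRON, "Intron", "intronic")
_register_effect(EffectClass.INTERGENIC, "IGR", "intergenic_region")
_register_effect(EffectClass.NCRNA, "RNA", "Noncoding RNA", "lincRNA",
                 "ncrna_exonic", "non-coding rna")

_HISTOTYPE_SYNONYMS: dict[str, str] = {_norm(h): h for h in HISTOTYPES}
_HISTOTYPE_SYNONYMS.update(
    {
        _norm("B2/B3"): "B2-B3",
        _norm("B2B3"): "B2-B3",
        _norm("thymic carcinoma"): "TC",
        _norm("C"): "TC",
        _norm("unknown"): "NOS",
        _norm("unspecified"): "NOS",
        _norm("not otherwise specified"): "NOS",
        _norm("NA"): "NOS",
        "": "NOS",
    }
)


def normalize_effect(label: str) -> EffectClass:
    """Map a MAF-style or annotator-style effect label onto the closed
    vocabulary, failing loudly on unknown labels."""
    key = _norm(label)
    if key not in _EFFECT_SYNONYMS:
        accepted = sorted({e.value for e in EffectClass})
        raise VocabularyError(
            f"unmappable effect label {label!r}; accepted classes: {accepted}"
        )
    return _EFFECT_SYNONYMS[key]


def normalize_histotype(label: str) -> str:
    key = _norm(label)
    if key not in _HISTOTYPE_SYNONYMS:
        raise VocabularyError(
            f"unmappable histotype {label!r}; accepted: {HISTOTYPES}"
        )
    return _HISTOTYPE_SYNONYMS[key]


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class TagMap:
    """INFO-tag names holding the caller's evidence fields."""

    depth: str = "DP"
    alt_reads: str = "VD"
    af: str = "AF"
    ref_bias: str = "REFBIAS"
    var_bias: str = "VARBIAS"
    sb_phred: str = "SBF"
    sb_odds_ratio: str = "ODDRATIO"
    mean_mismatches: str = "NM"
    snr: str = "SN"
    msi: str = "MSI"
    pop_af: str = "POP_AF"


_INFO_DEFS = [
    ("depth", "1", "Integer", "Total read depth at the locus"),
    ("alt_reads", "A", "Integer", "Reads supporting the ALT allele"),
    ("af", "A", "Float", "ALT allele fraction"),
    ("ref_bias", "1", "String", "REF strand counts forward:reverse"),
    ("var_bias", "A", "String", "ALT strand counts forward:reverse"),
    ("sb_phred", "A", "Float", "Phred-scaled strand-bias exact-test score"),
    ("sb_odds_ratio", "A", "Float", "Strand-bias odds ratio"),
    ("mean_mismatches", "A", "Float", "Mean mismatches per ALT-supporting read"),
    ("snr", "A", "Float", "Signal-to-noise ratio"),
    ("msi", "0", "Flag", "Locus reported as microsatellite"),
    ("pop_af", "A", "Float", "Max population allele frequency"),
]

_MANDATORY_TAGS = ("depth", "alt_reads")


def _per_allele(value, i: int):
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else value[0]
    return value


def read_vcf(path, sample_id: str, tags: TagMap = TagMap()) -> list[VariantCall]:
    """Read caller output into :class:`VariantCall` records.

    Multi-allelic records are split: one output call per ALT allele,
    sharing chrom/pos. Positions stay 1-based. A missing mandatory tag
    raises :class:`ConfigurationError` naming the tag.
    """
    calls: list[VariantCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            info = dict(rec.info)
            for attr in _MANDATORY_TAGS:
                tag = getattr(tags, attr)
                if tag not in info:
                    raise ConfigurationError(
                        f"VCF record {rec.chrom}:{rec.pos} lacks mandatory INFO "
                        f"tag {tag!r} (maps to {attr!r})"
                    )
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                depth = int(info[tags.depth])
                alt_reads = int(_per_allele(info[tags.alt_reads], i))
                rb = info.get(tags.ref_bias, "0:0")
                vb = _per_allele(info.get(tags.var_bias, "0:0"), i)
                rf, rr = (int(x) for x in str(rb).split(":"))
                af_, ar = (int(x) for x in str(vb).split(":"))

                def _opt(attr: str) -> Optional[float]:
                    tag = getattr(tags, attr)
                    if tag not in info:
                        return None
                    return float(_per_allele(info[tag], i))

                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        alt_reads=alt_reads,
                        strand_counts=(rf, rr, af_, ar),
                        sb_phred=_opt("sb_phred"),
                        sb_odds_ratio=_opt("sb_odds_ratio"),
                        mean_mismatches=_opt("mean_mismatches"),
                        snr=_opt("snr"),
                        msi_flag=bool(info.get(tags.msi, False)),
                        pop_af=_opt("pop_af"),
                    )
                )
    return calls


def write_vcf(
    calls: Sequence[VariantCall],
    path,
    tags: TagMap = TagMap(),
    decisions: Optional[Sequence[FilterDecision]] = None,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write calls to an uncompressed VCF, one record per call.

    When ``decisions`` is given (aligned with ``calls``), the FILTER
    column carries the reason codes, or PASS.
    """
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for c in calls:
        contigs.setdefault(c.chrom, 0)
        contigs[c.chrom] = max(contigs[c.chrom], c.pos + len(c.ref) + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for attr, number, vtype, desc in _INFO_DEFS:
        header.info.add(getattr(tags, attr), number, vtype, desc)
    for reason in FilterReason:
        header.filters.add(reason.value, None, None, f"Failed: {reason.value}")
    if decisions is not None and len(decisions) != len(calls):
        raise ValueError("decisions must align one-to-one with calls")

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, call in enumerate(calls):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            rf, rr, af_, ar = call.strand_counts
            rec.info[tags.depth] = call.depth
            rec.info[tags.alt_reads] = (call.alt_reads,)
            rec.info[tags.af] = (call.af,)
            rec.info[tags.ref_bias] = f"{rf}:{rr}"
            rec.info[tags.var_bias] = (f"{af_}:{ar}",)
            for attr in ("sb_phred", "sb_odds_ratio", "mean_mismatches",
                         "snr", "pop_af"):
                value = getattr(call, attr)
                if value is not None:
                    rec.info[getattr(tags, attr)] = (float(value),)
            if call.msi_flag:
                rec.info[tags.msi] = True
            if decisions is not None:
                d = decisions[i]
                if d.passed:
                    rec.filter.add("PASS")
                else:
                    for reason in sorted(r.value for r in d.reasons):
                        rec.filter.add(reason)
            out.write(rec)


# ---------------------------------------------------------------------------
# BED


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of 1-based closed intervals; overlapping or bookended
    intervals are merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e < s:
            raise ValueError(f"interval end {e} < start {s}")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_bed(
    regions: Sequence[tuple[str, int, int, str]],
    path,
    merge: bool = False,
) -> None:
    """Write 1-based closed regions as 0-based half-open BED, sorted by
    chrom then start. With ``merge``, overlapping/adjacent intervals on the
    same chrom are unioned (names comma-joined)."""
    for chrom, start, end, _ in regions:
        if end < start:
            raise ValueError(f"region end {end} < start {start} on {chrom}")
    rows = sorted(regions, key=lambda r: (r[0], r[1], r[2]))
    if merge:
        merged: list[list] = []
        for chrom, start, end, name in rows:
            if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
                merged[-1][2] = max(merged[-1][2], end)
                if name not in merged[-1][3]:
                    merged[-1][3].append(name)
            else:
                merged.append([chrom, start, end, [name]])
        rows = [(c, s, e, ",".join(n)) for c, s, e, n in merged]
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# catalog tables

_CATALOG_COLUMNS = {
    "sample_id": "sample_id",
    "study_id": "study_id",
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "effect": "effect",
    "protein_change": "protein_change",
    "histotype": "histotype",
}


def read_catalog(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[MutationRecord]:
    """Read a delimited mutation catalog into records.

    ``column_map`` maps internal field names to the file's header names.
    Effect and histotype labels are validated against the closed
    vocabularies through the synonym maps.
    """
    cols = dict(_CATALOG_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"catalog file {path} is empty")
        return []
    if df.empty:
        warnings.warn(f"catalog file {path} has no rows")
        return []
    missing = [v for k, v in cols.items()
               if v not in df.columns and k not in ("protein_change", "histotype", "study_id")]
    if missing:
        raise ConfigurationError(f"catalog {path} lacks columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(row)
        pc = r.get(cols["protein_change"])
        records.append(
            MutationRecord(
                sample_id=str(r[cols["sample_id"]]),
                study_id=str(r.get(cols["study_id"], "study")),
                gene=str(r[cols["gene"]]),
                chrom=str(r[cols["chrom"]]),
                pos=int(r[cols["pos"]]),
                ref=str(r[cols["ref"]]).upper(),
                alt=str(r[cols["alt"]]).upper(),
                effect_class=normalize_effect(r[cols["effect"]]),
                protein_change=None if pd.isna(pc) else str(pc),
                histotype=normalize_histotype(r.get(cols["histotype"], "NOS")),
            )
        )
    return records


def write_catalog(
    records: Sequence[MutationRecord],
    path,
    contexts: Optional[Mapping[tuple, str]] = None,
) -> None:
    """Write records as the catalog TSV. ``contexts`` optionally adds a
    trinucleotide ``context`` column keyed by (sample_id, chrom, pos)."""
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "study_id": r.study_id,
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "effect": r.effect_class.value,
            "protein_change": r.protein_change or "",
            "histotype": r.histotype,
        }
        if contexts is not None:
            row["context"] = contexts.get((r.sample_id, r.chrom, r.pos), "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_context_column(path) -> dict[tuple, str]:
    """Trinucleotide contexts from a catalog TSV's ``context`` column,
    keyed by (sample_id, chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "context" not in df.columns:
        return {}
    return {
        (str(r.sample_id), str(r.chrom), int(r.pos)): str(r.context)
        for r in df.itertuples(index=False)
        if isinstance(r.context, str) and len(r.context) == 3
    }


# ---------------------------------------------------------------------------
# gene models

_FEATURES = {"cds", "utr5", "utr3", "ncrna"}


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read the simplified transcript table: one row per interval with
    columns gene, chrom, strand, feature (cds|utr5|utr3|ncrna), start,
    end, and optional splice_window."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"gene", "chrom", "strand", "feature", "start", "end"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(
            f"gene-model table {path} lacks columns {sorted(needed - set(df.columns))}"
        )
    models: dict[str, GeneModel] = {}
    for gene, grp in df.groupby("gene", sort=True):
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        sw = int(grp["splice_window"].iloc[0]) if "splice_window" in grp else 2
        cds, u5, u3 = [], [], []
        ncrna = False
        for row in grp.itertuples(index=False):
            feat = str(row.feature).lower()
            if feat not in _FEATURES:
                raise VocabularyError(
                    f"unknown feature {row.feature!r} for gene {gene}; "
                    f"accepted: {sorted(_FEATURES)}"
                )
            iv = (int(row.start), int(row.end))
            if feat == "cds":
                cds.append(iv)
            elif feat == "utr5":
                u5.append(iv)
            elif feat == "utr3":
                u3.append(iv)
            else:
                cds.append(iv)
                ncrna = True
        models[str(gene)] = GeneModel(
            gene=str(gene), chrom=str(chrom), strand=str(strand),
            cds_exons=cds, utr5=u5, utr3=u3, splice_window=sw, ncrna=ncrna,
        )
    return models


def write_gene_models(models: Mapping[str, GeneModel], path) -> None:
    rows = []
    for m in models.values():
        feats = [("ncrna" if m.ncrna else "cds", iv) for iv in m.cds_exons]
        feats += [("utr5", iv) for iv in m.utr5] + [("utr3", iv) for iv in m.utr3]
        for feat, (s, e) in feats:
            rows.append(
                dict(gene=m.gene, chrom=m.chrom, strand=m.strand,
                     feature=feat, start=s, end=e, splice_window=m.splice_window)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort tables

_BOOL_COLS = ("has_coding_mutation", "gtf2i_mutant", "metastatic_at_diagnosis")


def read_cohort(path) -> list[CohortSample]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    samples = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        kwargs = {
            "sample_id": str(r["sample_id"]),
            "histotype": normalize_histotype(r.get("histotype", "NOS")),
            "stage": r.get("stage") or "unknown",
            "myasthenia_class": r.get("myasthenia_class", ""),
        }
        for col in _BOOL_COLS:
            kwargs[col] = str(r.get(col, "")).strip().lower() in ("true", "1", "yes")
        samples.append(CohortSample(**kwargs))
    return samples


def write_cohort(samples: Sequence[CohortSample], path) -> None:
    rows = [
        {f.name: getattr(s, f.name) for f in dc_fields(CohortSample)}
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
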