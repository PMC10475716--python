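"""Sequencing-panel design from a recurrence catalog.

Inclusion rules: a gene enters the panel when mutated in more than five
patients (>=6), or when it is a known proto-oncogene / tumor suppressor
mutated in two or more patients. An exclusion list overrides inclusion
with a recorded reason (the shipped default excludes TTN for gene-length
bias, MUC4 for a known alternative-alignment artifact region, MUC16 as a
mucin-family gene, and UNC93B1 whose recurrence is driven by a frequent
polymorphism). Tumor suppressors get their full coding sequence; oncogenes
get hotspot regions, extended when catalog mutations fall outside them.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalog import GeneRecurrence
from .io_formats import merge_intervals
from .models import GeneModel, MutationRecord


class GeneRole(str, enum.Enum):
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    BOTH = "both"
    UNANNOTATED = "unannotated"


class PanelRule(str, enum.Enum):
    RECURRENCE_GT5 = "recurrence_gt5"
    ONCO_TSG_GE2 = "onco_tsg_ge2"
    MANUAL_ADDITION = "manual_addition"
    EXCLUDED_LENGTH_BIAS = "excluded_length_bias"
    EXCLUDED_GENE_FAMILY = "excluded_gene_family"
    EXCLUDED_ARTIFACT_REGION = "excluded_artifact_region"
    EXCLUDED_POLYMORPHISM = "excluded_polymorphism"
    EXCLUDED_BELOW_THRESHOLD = "excluded_below_threshold"


INCLUSION_RULES = frozenset(
    {PanelRule.RECURRENCE_GT5, PanelRule.ONCO_TSG_GE2, PanelRule.MANUAL_ADDITION}
)

#: Default exclusion reasons for the four literature-recurrent genes the
#: published panel dropped. Driven by config, not hard-coded in the rules.
DEFAULT_EXCLUSIONS: dict[str, PanelRule] = {
    "TTN": PanelRule.EXCLUDED_LENGTH_BIAS,
    "MUC4": PanelRule.EXCLUDED_ARTIFACT_REGION,
    "MUC16": PanelRule.EXCLUDED_GENE_FAMILY,
    "UNC93B1": PanelRule.EXCLUDED_POLYMORPHISM,
}


@dataclass
class GeneAnnotation:
    """Curated per-gene facts driving the design rules."""

    gene: str
    role: GeneRole = GeneRole.UNANNOTATED
    hotspots: list[tuple[int, int]] = field(default_factory=list)  # genomic, 1-based closed
    gene_length_bp: int = 0
    known_artifact_region: bool = False
    polymorphism_notes: list[tuple[int, float]] = field(default_factory=list)


class RegionMode(str, enum.Enum):
    FULL_CDS = "full_cds"
    HOTSPOTS = "hotspots"
    HOTSPOTS_EXTENDED = "hotspots_extended"


@dataclass
class PanelDecision:
    gene: str
    included: bool
    rule_fired: PanelRule
    region_mode: Optional[RegionMode] = None
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.included != (self.rule_fired in INCLUSION_RULES):
            raise ValueError(
                f"{self.gene}: included={self.included} inconsistent with "
                f"rule {self.rule_fired}"
            )


def select_genes(
    recurrence: Sequence[GeneRecurrence],
    annotations: Mapping[str, GeneAnnotation],
    manual_additions: Sequence[str] = (),
    exclusions: Optional[Mapping[str, PanelRule]] = None,
    min_recurrent: int = 6,
    min_onco_tsg: int = 2,
) -> list[PanelDecision]:
    """Apply the inclusion/exclusion rules to a coding-only recurrence
    table. Output is sorted by gene, so decisions are independent of input
    order. Each gene carries exactly the one rule that fired."""
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS
    overlap = set(manual_additions) & set(exclusions)
    if overlap:
        raise ValueError(
            f"genes in both manual_additions and exclusions: {sorted(overlap)}"
        )
    decisions: dict[str, PanelDecision] = {}
    for gr in recurrence:
        ann = annotations.get(gr.gene, GeneAnnotation(gr.gene))
        if gr.gene in exclusions:
            rule = exclusions[gr.gene]
            if rule in INCLUSION_RULES:
                raise ValueError(f"{gr.gene}: exclusion reason {rule} is an inclusion rule")
            decisions[gr.gene] = PanelDecision(gr.gene, False, rule, None, gr.n_samples)
            continue
        if gr.n_samples >= min_recurrent:
            rule = PanelRule.RECURRENCE_GT5
        elif ann.role != GeneRole.UNANNOTATED and gr.n_samples >= min_onco_tsg:
            rule = PanelRule.ONCO_TSG_GE2
        else:
            decisions[gr.gene] = PanelDecision(
                gr.gene, False, PanelRule.EXCLUDED_BELOW_THRESHOLD, None, gr.n_samples
            )
            continue
        decisions[gr.gene] = PanelDecision(
            gr.gene, True, rule, _region_mode(ann), gr.n_samples
        )
    for gene in manual_additions:
        ann = annotations.get(gene, GeneAnnotation(gene))
        prior = decisions.get(gene)
        if prior is None or not prior.included:
            decisions[gene] = PanelDecision(
                gene, True, PanelRule.MANUAL_ADDITION, _region_mode(ann),
                prior.n_samples if prior else 0,
            )
    return [decisions[g] for g in sorted(decisions)]


def _region_mode(ann: GeneAnnotation) -> RegionMode:
    # Oncogenes are sequenced at hotspots; everything else (tumor
    # suppressors, dual-role and unannotated genes) gets the full CDS.
    if ann.role == GeneRole.ONCOGENE and ann.hotspots:
        return RegionMode.HOTSPOTS
    return RegionMode.FULL_CDS


def build_regions(
    decisions: Sequence[PanelDecision],
    gene_models: Mapping[str, GeneModel],
    annotations: Mapping[str, GeneAnnotation],
    observed_mutations: Sequence[MutationRecord] = (),
    flank: int = 10,
) -> list[tuple[str, int, int, str]]:
    """Panel intervals (1-based closed) for the included genes.

    Full-CDS genes contribute every CDS exon padded by ``flank`` bp (to
    capture splice sites). Hotspot genes contribute their hotspot
    intervals; any observed catalog mutation in the gene outside the
    hotspots extends the region set (mode ``hotspots_extended``), the rule
    motivated by an oncogene mutation observed away from the canonical
    hotspot codons. Intervals are merged per gene, so the output is
    disjoint per gene and the total panel length is monotone in the gene
    set."""
    observed_by_gene: dict[str, list[MutationRecord]] = {}
    for m in observed_mutations:
        observed_by_gene.setdefault(m.gene, []).append(m)
    regions: list[tuple[str, int, int, str]] = []
    missing = [d.gene for d in decisions if d.included and d.gene not in gene_models]
    if missing:
        raise KeyError(f"included genes without a gene model: {sorted(missing)}")
    for d in decisions:
        if not d.included:
            continue
        model = gene_models[d.gene]
        if d.region_mode == RegionMode.FULL_CDS or not annotations.get(d.gene) or (
            d.region_mode in (RegionMode.HOTSPOTS, RegionMode.HOTSPOTS_EXTENDED)
            and not annotations[d.gene].hotspots
        ):
            ivs = [(max(1, s - flank), e + flank) for s, e in model.cds_exons]
            label = RegionMode.FULL_CDS
        else:
            hotspots = list(annotations[d.gene].hotspots)
            ivs = [(max(1, s - flank), e + flank) for s, e in hotspots]
            label = RegionMode.HOTSPOTS
            for m in observed_by_gene.get(d.gene, []):
                if not any(s <= m.pos <= e for s, e in hotspots):
                    ivs.append((max(1, m.pos - flank), m.pos + len(m.ref) - 1 + flank))
                    label = RegionMode.HOTSPOTS_EXTENDED
            d.region_mode = label
        for s, e in merge_intervals(ivs):
            regions.append((model.chrom, s, e, f"{d.gene}|{label.value}"))
    regions.sort(key=lambda r: (r[0], r[1], r[2]))
    return regions


def panel_summary(decisions: Sequence[PanelDecision]) -> dict[str, int]:
    """Counts of decisions by fired rule, plus included/excluded totals."""
    out: dict[str, int] = {rule.value: 0 for rule in PanelRule}
    for d in decisions:
        out[d.rule_fired.value] += 1
    out["included_total"] = sum(1 for d in decisions if d.included)
    out["excluded_total"] = sum(1 for d in decisions if not d.included)
    return out
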