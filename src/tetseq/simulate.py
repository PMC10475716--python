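"""Synthetic tumor-only cohorts with complete truth labels.

The generator emulates the statistical structure the analysis assumes:

* germline variants with bimodal allele fractions — heterozygous (true AF
  0.5) and homozygous (true AF 1.0) polymorphisms, most of them carrying a
  population-frequency annotation;
* clonal heterozygous somatic mutations whose true AF is purity/2, with
  tumor purity drawn per histotype (tumor-cell-rich type A high, thymocyte-
  rich B1/B2 low) — the dilution that pushes somatic AFs into the 4-25%
  window;
* a recurrent driver ("GTF2I-like") injected preferentially into A/AB
  samples at the diluted AF;
* somatic substitution channels drawn from a mixture of reference
  signatures, with the trinucleotide context emitted alongside;
* sequencing artifacts that breach exactly one evidence threshold each, so
  filter reason codes are individually testable.

Observed alt-read counts are Binomial(depth, true AF) with negative-
binomial depth. Every emitted call carries a truth label.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats, resources
from .models import (
    CODING_CLASSES,
    CohortSample,
    EffectClass,
    FilterConfig,
    FilterDecision,
    MutationRecord,
    VariantCall,
)
from .signatures import CHANNELS, decode_channel, revcomp

_BASES = "ACGT"
_CODING = {e.value for e in CODING_CLASSES}

#: Synthetic target space: gene -> (chrom, start, end). The driver gene
#: keeps its real locus so the recurrent-driver call lands at the expected
#: coordinate; the rest is invented plumbing.
DEFAULT_GENE_SPACE: dict[str, tuple[str, int, int]] = {
    "GTF2I": ("chr7", 74100000, 74175000),
    "TP53": ("chr17", 7571000, 7591000),
    "HRAS": ("chr11", 532000, 537000),
    "BCOR": ("chrX", 39910000, 40036000),
    "ATM": ("chr11", 108093000, 108240000),
    "BRD4": ("chr19", 15348000, 15391000),
    "BRCA1": ("chr17", 41196000, 41278000),
    "NF1": ("chr17", 29420000, 29710000),
    "CDKN2A": ("chr9", 21967000, 21995000),
    "BAP1": ("chr3", 52435000, 52444000),
    "CYLD": ("chr16", 50775000, 50835000),
    "KIT": ("chr4", 55524000, 55606000),
}

DRIVER_GENE = "GTF2I"
DRIVER_LOCUS = ("chr7", 74146970)
DRIVER_REF, DRIVER_ALT = "T", "A"
DRIVER_PROTEIN_CHANGE = "L424H"


def _beta_params(mean: float, concentration: float = 20.0) -> tuple[float, float]:
    return mean * concentration, (1 - mean) * concentration


@dataclass
class SimulationConfig:
    """Study-shaped generator settings.

    Defaults mirror the resequencing study where it states them: 67
    samples with its histotype mix, mean target coverage ~1248 reads,
    driver prevalence concentrated in A/AB histotypes; per-histotype
    purity means encode the thymocyte-dilution narrative (A tumor-cell-
    rich ~0.6; B1/B2 thymocyte-rich ~0.15)."""

    n_samples: int = 67
    histotype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "A": 12 / 67, "AB": 12 / 67, "B1": 5 / 67, "B2": 21 / 67,
            "B2-B3": 5 / 67, "B3": 8 / 67, "NOS": 4 / 67,
        }
    )
    purity_mean_by_histotype: dict[str, float] = field(
        default_factory=lambda: {
            "A": 0.60, "AB": 0.40, "B1": 0.15, "B2": 0.15,
            "B2-B3": 0.20, "B3": 0.30, "NOS": 0.30,
        }
    )
    purity_concentration: float = 40.0
    n_germline_per_sample: int = 200
    het_hom_ratio: float = 2.0
    pop_af_annotated_fraction: float = 0.9
    somatic_rate: float = 4.0  # Poisson mean per sample
    depth_mean: float = 1248.0
    depth_dispersion: float = 8.0
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {
            "1": 0.35, "4": 0.15, "15": 0.20, "18": 0.10, "29": 0.10, "30": 0.10,
        }
    )
    #: Per-sample exposures are Dirichlet(concentration * signature_mix):
    #: tumors differ in which mutational processes dominate them, and that
    #: between-sample variation is what makes the mixture identifiable.
    signature_exposure_concentration: float = 2.0
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "strand_bias_phred": 0.5, "strand_bias_or": 0.5,
            "high_mismatch": 0.5, "low_snr": 0.5, "msi": 0.25,
        }
    )
    gtf2i_rate_by_histotype: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "AB": 0.42, "B2": 0.10, "NOS": 0.25}
    )
    subclonal_fraction: float = 0.0
    effect_distribution: Optional[dict[EffectClass, float]] = None
    gene_space: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_SPACE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("histotype_mix", "signature_mix"):
            total = sum(getattr(self, name).values())
            if not np.isclose(total, 1.0, atol=1e-6):
                setattr(
                    self, name,
                    {k: v / total for k, v in getattr(self, name).items()},
                )
        if any(v < 0 for v in self.artifact_rates.values()):
            raise ValueError("artifact rates must be non-negative")


@dataclass(frozen=True)
class TruthLabel:
    sample_id: str
    chrom: str
    pos: int
    origin: str  # germline_het | germline_hom | somatic | artifact
    true_af: float
    signature_channel: Optional[str] = None


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    samples: list[CohortSample]
    calls: list[VariantCall]
    truth: list[TruthLabel]
    catalog_records: list[MutationRecord]
    contexts: dict[tuple, str]
    purities: dict[str, float]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])


def _effect_distribution(config: SimulationConfig) -> tuple[list[EffectClass], np.ndarray]:
    if config.effect_distribution is not None:
        items = list(config.effect_distribution.items())
    else:
        df = resources.load_effect_class_counts()
        items = [(e, n) for e, n in zip(df.effect, df.n) if n > 0]
    classes = [EffectClass(e) for e, _ in items]
    weights = np.array([float(w) for _, w in items])
    return classes, weights / weights.sum()


def _draw_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    return max(1, int(rng.negative_binomial(r, p)))


def _clean_evidence(rng: np.random.Generator) -> dict:
    return {
        "sb_phred": float(rng.uniform(0, 40)),
        "sb_odds_ratio": float(rng.uniform(0.5, 2.5)),
        "mean_mismatches": float(rng.uniform(0.2, 2.0)),
        "snr": float(rng.uniform(6, 40)),
        "msi_flag": False,
    }


_ARTIFACT_BREACH = {
    "strand_bias_phred": ("sb_phred", lambda rng: float(rng.uniform(61, 250))),
    "strand_bias_or": ("sb_odds_ratio", lambda rng: float(rng.uniform(3.5, 12))),
    "high_mismatch": ("mean_mismatches", lambda rng: float(rng.uniform(3.0, 8))),
    "low_snr": ("snr", lambda rng: float(rng.uniform(0.2, 3.9))),
    "msi": ("msi_flag", lambda rng: True),
}


def _random_locus(
    config: SimulationConfig, rng: np.random.Generator, used: set
) -> tuple[str, str, int]:
    genes = sorted(config.gene_space)
    for _ in range(1000):
        gene = genes[rng.integers(len(genes))]
        chrom, start, end = config.gene_space[gene]
        pos = int(rng.integers(start, end + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return gene, chrom, pos
    raise RuntimeError("could not place a unique locus")


def simulate_sample(
    config: SimulationConfig,
    histotype: str,
    rng: np.random.Generator,
    sample_id: str = "S1",
    purity: Optional[float] = None,
) -> tuple[list[VariantCall], list[TruthLabel], list[MutationRecord], dict]:
    """One sample's calls, truth labels, somatic catalog records and
    context map. ``purity`` overrides the per-histotype Beta draw."""
    if purity is None:
        mean = config.purity_mean_by_histotype.get(histotype, 0.3)
        a, b = _beta_params(mean, config.purity_concentration)
        purity = float(rng.beta(a, b))
    if not (0 < purity <= 1):
        raise ValueError(f"purity {purity} outside (0, 1]")

    calls: list[VariantCall] = []
    truth: list[TruthLabel] = []
    records: list[MutationRecord] = []
    contexts: dict[tuple, str] = {}
    used: set = set()

    sig_ids = sorted(config.signature_mix)
    base_weights = np.array([config.signature_mix[s] for s in sig_ids])
    if len(sig_ids) > 1:
        alpha = base_weights * config.signature_exposure_concentration
        sig_weights = rng.dirichlet(np.maximum(alpha, 1e-3))
    else:
        sig_weights = base_weights
    ref_sigs = resources.load_reference_signatures()
    channel_probs = {
        s: ref_sigs[s].to_numpy() / ref_sigs[s].sum() for s in sig_ids
    }
    eff_classes, eff_weights = _effect_distribution(config)

    def emit(chrom, pos, ref, alt, true_af, origin, channel=None,
             evidence=None, pop_af=None):
        depth = _draw_depth(config, rng)
        alt_reads = int(rng.binomial(depth, true_af))
        if alt_reads == 0:
            return None
        ev = evidence or _clean_evidence(rng)
        alt_fwd = int(rng.binomial(alt_reads, 0.5))
        ref_reads = depth - alt_reads
        ref_fwd = int(rng.binomial(ref_reads, 0.5))
        call = VariantCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            depth=depth, alt_reads=alt_reads,
            strand_counts=(ref_fwd, ref_reads - ref_fwd, alt_fwd,
                           alt_reads - alt_fwd),
            pop_af=pop_af, **ev,
        )
        calls.append(call)
        truth.append(TruthLabel(sample_id, chrom, pos, origin, true_af, channel))
        return call

    # germline polymorphisms: bimodal AF at 0.5 / 1.0
    p_het = config.het_hom_ratio / (config.het_hom_ratio + 1)
    for _ in range(config.n_germline_per_sample):
        gene, chrom, pos = _random_locus(config, rng, used)
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        het = rng.random() < p_het
        pop_af = (
            float(rng.uniform(0.001, 0.5))
            if rng.random() < config.pop_af_annotated_fraction
            else None
        )
        emit(chrom, pos, str(ref), str(alt),
             0.5 if het else 0.995,
             "germline_het" if het else "germline_hom",
             pop_af=pop_af)

    # clonal somatic mutations, signature-driven
    n_somatic = int(rng.poisson(config.somatic_rate))
    somatic_af = purity / 2
    for _ in range(n_somatic):
        gene, chrom, pos = _random_locus(config, rng, used)
        sig = sig_ids[int(rng.choice(len(sig_ids), p=sig_weights))]
        channel = CHANNELS[int(rng.choice(96, p=channel_probs[sig]))]
        context, ref, alt = decode_channel(channel)
        if rng.random() < 0.5:  # record on the purine strand half the time
            context, ref, alt = revcomp(context), revcomp(ref), revcomp(alt)
        true_af = somatic_af
        if config.subclonal_fraction and rng.random() < config.subclonal_fraction:
            true_af *= float(rng.uniform(0.3, 1.0))
        call = emit(chrom, pos, ref, alt, true_af, "somatic", channel=channel)
        if call is not None:
            effect = eff_classes[int(rng.choice(len(eff_classes), p=eff_weights))]
            records.append(
                MutationRecord(
                    sample_id=sample_id, study_id="simulated", gene=gene,
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    effect_class=effect, histotype=histotype,
                )
            )
            contexts[(sample_id, chrom, pos)] = context

    # recurrent driver call
    gtf2i = rng.random() < config.gtf2i_rate_by_histotype.get(histotype, 0.0)
    if gtf2i:
        chrom, pos = DRIVER_LOCUS
        used.add((chrom, pos))
        call = emit(chrom, pos, DRIVER_REF, DRIVER_ALT, somatic_af, "somatic")
        if call is not None:
            records.append(
                MutationRecord(
                    sample_id=sample_id, study_id="simulated", gene=DRIVER_GENE,
                    chrom=chrom, pos=pos, ref=DRIVER_REF, alt=DRIVER_ALT,
                    effect_class=EffectClass.MISSENSE,
                    protein_change=DRIVER_PROTEIN_CHANGE, histotype=histotype,
                )
            )
        else:
            gtf2i = False

    # artifacts: exactly one evidence field breached each
    for kind, rate in sorted(config.artifact_rates.items()):
        for _ in range(int(rng.poisson(rate))):
            gene, chrom, pos = _random_locus(config, rng, used)
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            ev = _clean_evidence(rng)
            fld, draw = _ARTIFACT_BREACH[kind]
            ev[fld] = draw(rng)
            # true AF inside the somatic window, so only the breached
            # evidence field separates the artifact from a real somatic call
            emit(chrom, pos, str(ref), str(alt),
                 float(rng.uniform(0.10, 0.30)), "artifact", evidence=ev)

    return calls, truth, records, {"purity": purity, "gtf2i": gtf2i,
                                   "contexts": contexts}


_EARLY = ("I", "IIA", "IIB")
_LATE = ("III", "IVA")


def simulate_cohort(
    config: Optional[SimulationConfig] = None,
    outdir: Optional[Path] = None,
) -> SimulatedCohort:
    """Simulate the full cohort; optionally write the file set every other
    module consumes (per-sample VCFs, cohort/truth/catalog TSVs)."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    histotypes = sorted(config.histotype_mix)
    mix = np.array([config.histotype_mix[h] for h in histotypes])

    samples: list[CohortSample] = []
    calls: list[VariantCall] = []
    truth: list[TruthLabel] = []
    records: list[MutationRecord] = []
    contexts: dict[tuple, str] = {}
    purities: dict[str, float] = {}

    for i in range(config.n_samples):
        sample_id = f"S{i + 1:03d}"
        histotype = histotypes[int(rng.choice(len(histotypes), p=mix))]
        s_calls, s_truth, s_records, meta = simulate_sample(
            config, histotype, rng, sample_id=sample_id
        )
        calls.extend(s_calls)
        truth.extend(s_truth)
        records.extend(s_records)
        contexts.update(meta["contexts"])
        purities[sample_id] = meta["purity"]
        gtf2i = meta["gtf2i"]
        if gtf2i:
            stage = str(rng.choice(_EARLY))
            metastatic = False
        else:
            stage = str(rng.choice(_EARLY + _LATE))
            metastatic = bool(rng.random() < 0.17) and stage in _LATE
        samples.append(
            CohortSample(
                sample_id=sample_id, histotype=histotype, stage=stage,
                has_coding_mutation=any(
                    r.effect_class.value in _CODING for r in s_records
                ),
                gtf2i_mutant=gtf2i,
                metastatic_at_diagnosis=metastatic,
            )
        )

    cohort = SimulatedCohort(config, samples, calls, truth, records,
                             contexts, purities)
    if outdir is not None:
        _write_cohort(cohort, Path(outdir))
    return cohort


def _write_cohort(cohort: SimulatedCohort, outdir: Path) -> None:
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[VariantCall]] = {}
    for c in cohort.calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    for s in cohort.samples:
        io_formats.write_vcf(
            sorted(by_sample.get(s.sample_id, []), key=lambda c: (c.chrom, c.pos)),
            vcf_dir / f"{s.sample_id}.vcf",
        )
    io_formats.write_cohort(cohort.samples, outdir / "cohort.tsv")
    cohort.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    io_formats.write_catalog(
        cohort.catalog_records, outdir / "catalog.tsv", contexts=cohort.contexts
    )


@dataclass
class FilterScore:
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame  # origin x (passed, rejected)
    n_detectable_somatic: int


def score_filter(
    decisions: Sequence[FilterDecision],
    truth: Sequence[TruthLabel],
    config: Optional[FilterConfig] = None,
) -> FilterScore:
    """Parameter-recovery scores for a filter run against truth labels.

    Sensitivity is over somatic truths whose true AF lies in the
    detectable window [min_af + 0.01, max_af - 0.05]; specificity is the
    rejected fraction of germline truths. Calls and truths must align by
    (sample, chrom, pos)."""
    if config is None:
        config = FilterConfig()
    truth_by_key = {(t.sample_id, t.chrom, t.pos): t for t in truth}
    if len(truth_by_key) != len(truth):
        raise ValueError("duplicate truth keys")
    lo, hi = config.min_af + 0.01, config.max_af - 0.05
    rows: dict[str, dict[str, int]] = {}
    sens_num = sens_den = spec_num = spec_den = 0
    for d in decisions:
        key = (d.call.sample_id, d.call.chrom, d.call.pos)
        t = truth_by_key.get(key)
        if t is None:
            raise ValueError(f"call without truth label: {key}")
        row = rows.setdefault(t.origin, {"passed": 0, "rejected": 0})
        row["passed" if d.passed else "rejected"] += 1
        if t.origin == "somatic" and lo <= t.true_af <= hi:
            sens_den += 1
            sens_num += int(d.passed)
        if t.origin in ("germline_het", "germline_hom"):
            spec_den += 1
            spec_num += int(not d.passed)
    return FilterScore(
        sensitivity=sens_num / sens_den if sens_den else float("nan"),
        specificity=spec_num / spec_den if spec_den else float("nan"),
        confusion=pd.DataFrame(rows).T.fillna(0).astype(int),
        n_detectable_somatic=sens_den,
    )
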