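"""Shared fixtures: small synthetic references and gene models."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tetseq.effects import DictReference
from tetseq.models import GeneModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


@pytest.fixture(scope="session")
def plus_gene() -> GeneModel:
    """Three-exon plus-strand coding gene on chrT (CDS 240 bp)."""
    return GeneModel(
        gene="GENEP",
        chrom="chrT",
        strand="+",
        utr5=[(101, 130)],
        cds_exons=[(131, 220), (301, 390), (451, 510)],
        utr3=[(511, 540)],
        splice_window=2,
    )


@pytest.fixture(scope="session")
def minus_gene() -> GeneModel:
    """Two-exon minus-strand coding gene on chrU (CDS 150 bp); its 5'UTR
    sits at the high genomic coordinates."""
    return GeneModel(
        gene="GENEM",
        chrom="chrU",
        strand="-",
        utr3=[(161, 200)],
        cds_exons=[(201, 260), (321, 410)],
        utr5=[(411, 440)],
        splice_window=2,
    )


@pytest.fixture(scope="session")
def reference(plus_gene, minus_gene) -> DictReference:
    """Deterministic random reference covering both fixture genes, with
    the plus gene's CDS forced to start ATG and to contain no premature
    stop codon (so whole-protein oracle translations are clean)."""
    rng = np.random.default_rng(20240001)
    seqs = {}
    for chrom in ("chrT", "chrU"):
        seqs[chrom] = list(_random_seq(rng, 2000))

    def _force_codons(model: GeneModel, seq: list[str]) -> None:
        # genomic positions of the spliced CDS in translation order
        pos_list = [p for s, e in model.cds_exons for p in range(s, e + 1)]
        if model.strand == "-":
            pos_list = pos_list[::-1]
        comp = dict(zip("ACGT", "TGCA"))
        n_codons = len(pos_list) // 3
        stops = {"TAA", "TAG", "TGA"}
        for ci in range(n_codons):
            triplet_pos = pos_list[ci * 3: ci * 3 + 3]
            codon = "".join(
                seq[p - 1] if model.strand == "+" else comp[seq[p - 1]]
                for p in triplet_pos
            )
            want = None
            if ci == 0:
                want = "ATG"
            elif ci == n_codons - 1:
                want = "TAA"
            elif codon in stops:
                want = "CTG"  # swap internal stops for leucine
            if want:
                for p, base in zip(triplet_pos, want):
                    seq[p - 1] = base if model.strand == "+" else comp[base]

    _force_codons(plus_gene, seqs["chrT"])
    _force_codons(minus_gene, seqs["chrU"])
    return DictReference({c: "".join(s) for c, s in seqs.items()})
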