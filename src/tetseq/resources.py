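"""Loaders for tables shipped with the package.

Study constants (the published literature-review totals, per-class mutation
tally, per-histotype detection counts, GTF2I histology breakdown) are
packaged so cohort-level summaries can be recomputed from the printed
numbers without the unpublished per-sample data.

The reference signature matrix is a deterministic *synthetic* stand-in for
the COSMIC v2 catalogue: 30 probability profiles over the 96 pyrimidine-
centred trinucleotide channels whose qualitative channel preferences mirror
the correspondingly numbered COSMIC v2 signatures (see
``scripts/build_reference_signatures.py``). It is suitable for planted-
signature simulation and recovery, not for attributing real tumor data.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .models import EffectClass


def _path(name: str):
    return resources.files("tetseq.data").joinpath(name)


@lru_cache(maxsize=None)
def _read_cached(name: str, **kwargs) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, sep="\t", **kwargs)


def load_literature_studies() -> pd.DataFrame:
    """The nine published sequencing reports pooled by the meta-analysis:
    study id, year, technology, number of tumors and of mutations."""
    return _read_cached("literature_study_counts.tsv").copy()


def load_effect_class_counts() -> pd.DataFrame:
    """Published per-class mutation tally of the 67-thymoma resequencing
    cohort (columns: effect, n)."""
    df = _read_cached("study_effect_class_counts.tsv").copy()
    df["effect"] = df["effect"].map(EffectClass)
    return df


def load_detection_by_histotype() -> pd.DataFrame:
    """Published per-histotype coding-mutation detection counts
    (columns: histotype, n_mutated, n_not)."""
    return _read_cached("study_detection_by_histotype.tsv").copy()


def load_gtf2i_by_histotype() -> pd.DataFrame:
    """Published GTF2I-mutant counts per histotype (columns: histotype, n)."""
    return _read_cached("study_gtf2i_by_histotype.tsv").copy()


def load_reference_signatures() -> pd.DataFrame:
    """Synthetic stand-in reference signature matrix, 96 channels x 30
    signatures; rows indexed by channel (``A[C>A]A`` ... ``T[T>G]T``),
    columns ``"1"`` ... ``"30"``, each column summing to 1."""
    df = _read_cached("reference_signatures_synthetic.tsv", index_col=0).copy()
    df.columns = [str(c) for c in df.columns]
    return df / df.sum(axis=0)
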