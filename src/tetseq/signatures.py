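"""Mutational-signature analysis over 96 trinucleotide channels.

A single-base substitution is binned by its pyrimidine-centred class
(C>A, C>G, C>T, T>A, T>C, T>G) and the two flanking reference bases;
purine-reference mutations are reverse-complemented into the pyrimidine
channel. The 96 channels are ordered lexicographically by their string
form, ``A[C>A]A`` ... ``T[T>G]T`` (the conventional catalogue order).

De novo signatures come from a non-negative matrix factorization with
multiplicative updates under the KL (generalized Kullback-Leibler)
divergence, restarted from seeded random initializations and matched to
the packaged reference catalogue by cosine similarity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import MutationRecord

log = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 96 channels in lexicographic string order.
CHANNELS: tuple[str, ...] = tuple(
    sorted(
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    )
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(context: str, alt: str) -> Optional[str]:
    """Channel for a SNV given its plus-strand trinucleotide ``context``
    (5' base, ref, 3' base) and ``alt``; ``None`` when the context is
    ambiguous (non-ACGT) or ref equals alt."""
    context = context.upper()
    alt = alt.upper()
    if len(context) != 3 or any(b not in _BASES for b in context + alt):
        return None
    ref = context[1]
    if ref == alt:
        return None
    if ref in "GA":  # collapse onto the pyrimidine strand
        context = revcomp(context)
        alt = alt.translate(_COMPLEMENT)
        ref = context[1]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def decode_channel(channel: str) -> tuple[str, str, str]:
    """Inverse of :func:`channel_of` on the pyrimidine strand:
    returns (context, ref, alt)."""
    five, rest = channel[0], channel[2:5]
    three = channel[-1]
    ref, alt = rest.split(">")
    return f"{five}{ref}{three}", ref, alt


# context providers -----------------------------------------------------------

ContextProvider = Callable[[MutationRecord], Optional[str]]


def contexts_from_mapping(mapping: Mapping[tuple, str]) -> ContextProvider:
    """Provider backed by a mapping keyed (sample_id, chrom, pos), with a
    (chrom, pos) fallback — the shape produced by a catalog ``context``
    column."""

    def provider(rec: MutationRecord) -> Optional[str]:
        return mapping.get((rec.sample_id, rec.chrom, rec.pos)) or mapping.get(
            (rec.chrom, rec.pos)
        )

    return provider


def contexts_from_reference(reference) -> ContextProvider:
    """Provider reading +/-1 bp around each SNV from a reference with a
    ``seq(chrom, start, end)`` accessor (1-based closed), e.g.
    :class:`tetseq.effects.DictReference`."""

    def provider(rec: MutationRecord) -> Optional[str]:
        try:
            ctx = reference.seq(rec.chrom, rec.pos - 1, rec.pos + 1)
        except (KeyError, IndexError, ValueError):
            return None
        return ctx if len(ctx) == 3 else None

    return provider


@dataclass
class ContextMatrix:
    """Per-sample counts over the 96 channels."""

    samples: list[str]
    counts: np.ndarray  # (n_samples, 96) non-negative ints
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.samples), 96):
            raise ValueError("counts must be n_samples x 96")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=CHANNELS)


def context_matrix(
    records: Sequence[MutationRecord], context_provider: ContextProvider
) -> ContextMatrix:
    """Build the samples x 96 substitution matrix from SNV records.

    Non-SNVs, records without a retrievable context, and contexts whose
    central base disagrees with the record's ref are skipped and counted
    in ``n_skipped``.
    """
    samples = sorted({r.sample_id for r in records})
    idx = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), 96))
    skipped = 0
    for rec in records:
        if not rec.is_snv:
            skipped += 1
            continue
        ctx = context_provider(rec)
        if ctx is None or len(ctx) != 3 or ctx[1].upper() != rec.ref:
            skipped += 1
            continue
        ch = channel_of(ctx, rec.alt)
        if ch is None:
            skipped += 1
            continue
        counts[idx[rec.sample_id], _CHANNEL_INDEX[ch]] += 1
    if skipped:
        log.info("context_matrix: skipped %d records without usable context", skipped)
    return ContextMatrix(samples=samples, counts=counts, n_skipped=skipped)


# NMF -------------------------------------------------------------------------


@dataclass
class SignatureSet:
    """De novo signatures (k x 96 probability rows) with per-sample
    exposures and, after matching, reference-catalogue assignments."""

    k: int
    signatures: np.ndarray  # (k, 96), rows sum to 1
    exposures: np.ndarray  # (n_samples, k)
    samples: list[str]
    reconstruction_error: float
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    cosmic_matches: list[tuple[str, float]] = field(default_factory=list)

    def signatures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures,
            index=[f"S{i + 1}" for i in range(self.k)],
            columns=CHANNELS,
        )


def _kl_loss(V: np.ndarray, WH: np.ndarray) -> float:
    eps = 1e-12
    mask = V > 0
    return float(
        np.sum(V[mask] * np.log(V[mask] / (WH[mask] + eps))) - V.sum() + WH.sum()
    )


def _kl_nmf_once(
    V: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One seeded multiplicative-update run of V ~ W @ H under KL.

    The loss curve is tracked; multiplicative updates guarantee it is
    non-increasing (asserted by the property tests).
    """
    n, m = V.shape
    eps = 1e-12
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.5, 1.5, size=(n, k)) * scale
    H = rng.uniform(0.5, 1.5, size=(k, m)) * scale
    losses = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        loss = _kl_loss(V, W @ H + eps)
        losses.append(loss)
        if prev - loss < tol * max(1.0, abs(prev)) and it > 10:
            break
        prev = loss
    return W, H, np.asarray(losses)


def extract_signatures(
    matrix: ContextMatrix,
    k: int,
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> SignatureSet:
    """Factorize the context matrix into ``k`` signatures.

    Best-of-``n_restarts`` KL-divergence multiplicative-update NMF; each
    restart is seeded from ``seed`` so the result is deterministic.
    Signatures are normalized to probability rows; exposures absorb the
    scale. Signatures are ordered by total exposure, descending.
    """
    V = np.asarray(matrix.counts, dtype=float)
    n = V.shape[0]
    if not (1 <= k < min(n, 96) or (k == 1 and n >= 1)):
        raise ValueError(f"k={k} out of range for {n} samples x 96 channels")
    if V.sum() <= 0:
        raise ValueError("context matrix is empty")
    best: Optional[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        W, H, losses = _kl_nmf_once(V, k, rng, max_iter, tol)
        loss = losses[-1]
        if best is None or loss < best[3]:
            best = (W, H, losses, float(loss))
    W, H, losses, loss = best
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    S = H / row_sums[:, None]
    E = W * row_sums[None, :]
    order = np.argsort(-E.sum(axis=0))
    return SignatureSet(
        k=k,
        signatures=S[order],
        exposures=E[:, order],
        samples=list(matrix.samples),
        reconstruction_error=loss,
        loss_curve=losses,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_cosmic(
    signature_set: SignatureSet,
    cosmic: pd.DataFrame,
    assign_threshold: float = 0.80,
) -> SignatureSet:
    """Assign each de novo signature its argmax-cosine reference
    signature (ties broken by lowest reference index). ``cosmic`` must be
    a 96 x n frame indexed by channel in the package channel order.

    Matches below ``assign_threshold`` keep their best id but are reported
    with their (low) similarity; callers decide whether to treat them as
    unassigned.
    """
    if list(cosmic.index) != list(CHANNELS):
        raise ValueError("reference matrix channel order mismatch")
    ids = list(cosmic.columns)
    ref = cosmic.to_numpy().T  # (n_refs, 96)
    matches = []
    for sig in signature_set.signatures:
        sims = np.array([cosine_similarity(sig, r) for r in ref])
        best = int(np.argmax(sims))  # argmax takes the first (lowest) index on ties
        matches.append((str(ids[best]), float(sims[best])))
    signature_set.cosmic_matches = matches
    return signature_set
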