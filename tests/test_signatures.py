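"""96-channel machinery, KL-NMF extraction, reference matching."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetseq import resources
from tetseq.models import EffectClass, MutationRecord
from tetseq.signatures import (
    CHANNELS,
    ContextMatrix,
    channel_of,
    context_matrix,
    contexts_from_mapping,
    cosine_similarity,
    decode_channel,
    extract_signatures,
    match_cosmic,
    revcomp,
)


def rec(sample="s1", pos=1, ref="C", alt="T"):
    return MutationRecord(sample, "st", "G", "chr1", pos, ref, alt,
                          EffectClass.MISSENSE, None, "A")


class TestChannels:
    def test_channel_order_is_lexicographic(self):
        assert CHANNELS[0] == "A[C>A]A"
        assert CHANNELS[-1] == "T[T>G]T"
        assert list(CHANNELS) == sorted(CHANNELS)
        assert len(set(CHANNELS)) == 96

    def test_purine_collapsing(self):
        # T[G>A]C on the plus strand is G[C>T]A on the pyrimidine strand
        assert channel_of("TGC", "A") == "G[C>T]A"

    def test_collapsing_is_involutive(self):
        for channel in CHANNELS:
            context, ref, alt = decode_channel(channel)
            flipped_ctx, flipped_alt = revcomp(context), revcomp(alt)
            assert channel_of(flipped_ctx, flipped_alt) == channel
            assert channel_of(context, alt) == channel

    def test_ambiguous_context_rejected(self):
        assert channel_of("ANA", "T") is None
        assert channel_of("ACA", "C") is None


class TestContextMatrix:
    def test_counts_and_row_sums(self):
        records = [rec(pos=i + 1) for i in range(10)]
        contexts = {("s1", "chr1", i + 1): "ACG" for i in range(10)}
        matrix = context_matrix(records, contexts_from_mapping(contexts))
        assert matrix.counts.sum() == 10
        frame = matrix.to_frame()
        assert frame.loc["s1", "A[C>T]G"] == 10

    def test_non_snv_and_missing_context_skipped(self):
        records = [
            rec(pos=1),
            MutationRecord("s1", "st", "G", "chr1", 2, "CT", "C",
                           EffectClass.FRAMESHIFT_DELETION, None, "A"),
            rec(pos=3),
        ]
        contexts = {("s1", "chr1", 1): "TCA"}
        matrix = context_matrix(records, contexts_from_mapping(contexts))
        assert matrix.counts.sum() == 1
        assert matrix.n_skipped == 2

    def test_mismatching_central_base_skipped(self):
        matrix = context_matrix([rec(pos=1, ref="C")],
                                contexts_from_mapping({("s1", "chr1", 1): "ATA"}))
        assert matrix.n_skipped == 1

    def test_npcpg_generator_only_fills_cpg_channels(self):
        rng = np.random.default_rng(0)
        records, contexts = [], {}
        for i in range(50):
            five = "ACGT"[rng.integers(4)]
            records.append(rec(pos=i + 1))
            contexts[("s1", "chr1", i + 1)] = f"{five}CG"
        matrix = context_matrix(records, contexts_from_mapping(contexts))
        frame = matrix.to_frame()
        nonzero = frame.columns[(frame.to_numpy()[0] > 0)]
        assert set(nonzero) <= {f"{b}[C>T]G" for b in "ACGT"}


class TestExtraction:
    def _planted_matrix(self, sig_ids, n_samples=30, n_mut=150, seed=0):
        ref = resources.load_reference_signatures()
        rng = np.random.default_rng(seed)
        counts = np.zeros((n_samples, 96))
        exposures = rng.dirichlet(np.ones(len(sig_ids)) * 0.8, size=n_samples)
        for i in range(n_samples):
            mix = sum(w * ref[s].to_numpy() for w, s in zip(exposures[i], sig_ids))
            counts[i] = rng.multinomial(n_mut, mix / mix.sum())
        return ContextMatrix([f"s{i}" for i in range(n_samples)], counts), exposures

    def test_rank_one_recovery(self):
        matrix, _ = self._planted_matrix(["1"], seed=1)
        sigset = extract_signatures(matrix, k=1, n_restarts=5, seed=2)
        truth = resources.load_reference_signatures()["1"].to_numpy()
        assert cosine_similarity(sigset.signatures[0], truth) >= 0.99

    def test_two_signature_recovery_with_exposures(self):
        matrix, exposures = self._planted_matrix(["1", "4"], seed=3)
        sigset = extract_signatures(matrix, k=2, n_restarts=10, seed=4)
        sigset = match_cosmic(sigset, resources.load_reference_signatures())
        ids = {m for m, _ in sigset.cosmic_matches}
        assert ids == {"1", "4"}
        assert all(c >= 0.90 for _, c in sigset.cosmic_matches)
        # exposures correlate with the planted ones
        order = [int(m) == 4 for m, _ in sigset.cosmic_matches]
        est_sig4 = sigset.exposures[:, order.index(True)]
        corr = np.corrcoef(est_sig4, exposures[:, 1])[0, 1]
        assert corr >= 0.9

    def test_seed_determinism_bit_identical(self):
        matrix, _ = self._planted_matrix(["1", "4"], seed=5)
        a = extract_signatures(matrix, k=2, n_restarts=3, seed=6)
        b = extract_signatures(matrix, k=2, n_restarts=3, seed=6)
        assert np.array_equal(a.signatures, b.signatures)
        assert np.array_equal(a.exposures, b.exposures)

    def test_loss_non_increasing_and_rows_normalized(self):
        matrix, _ = self._planted_matrix(["1", "15"], seed=7)
        sigset = extract_signatures(matrix, k=2, n_restarts=2, seed=8)
        assert np.all(np.diff(sigset.loss_curve) <= 1e-6)
        assert np.allclose(sigset.signatures.sum(axis=1), 1.0, atol=1e-9)

    def test_reconstruction_conserves_totals(self):
        matrix, _ = self._planted_matrix(["1", "4"], seed=9)
        sigset = extract_signatures(matrix, k=2, n_restarts=5, seed=10)
        recon = sigset.exposures @ sigset.signatures
        assert recon.sum() == pytest.approx(matrix.counts.sum(), rel=0.05)

    def test_k_out_of_range_rejected(self):
        matrix, _ = self._planted_matrix(["1"], n_samples=5)
        with pytest.raises(ValueError):
            extract_signatures(matrix, k=5)

    def test_sklearn_kl_nmf_cross_check(self):
        """Independent implementation: sklearn's multiplicative-update
        KL NMF should land on an equivalent factorization."""
        from sklearn.decomposition import NMF

        matrix, _ = self._planted_matrix(["1", "4"], seed=11)
        ours = extract_signatures(matrix, k=2, n_restarts=10, seed=12)
        model = NMF(n_components=2, beta_loss="kullback-leibler", solver="mu",
                    init="random", random_state=0, max_iter=2000, tol=1e-9)
        W = model.fit_transform(matrix.counts)
        H = model.components_
        theirs = H / H.sum(axis=1, keepdims=True)
        for sig in ours.signatures:
            assert max(cosine_similarity(sig, t) for t in theirs) >= 0.95


class TestMatching:
    def test_identity_match(self):
        ref = resources.load_reference_signatures()
        sigset = extract_signatures(
            ContextMatrix(["s1", "s2"],
                          np.vstack([ref["1"].to_numpy() * 500] * 2)),
            k=1, n_restarts=3, seed=0,
        )
        sigset = match_cosmic(sigset, ref)
        match_id, cosine = sigset.cosmic_matches[0]
        assert match_id == "1"
        assert cosine >= 0.999

    def test_channel_order_mismatch_rejected(self):
        ref = resources.load_reference_signatures().iloc[::-1]
        sigset = extract_signatures(
            ContextMatrix(["s1", "s2"], np.ones((2, 96))), k=1,
            n_restarts=2, seed=0,
        )
        with pytest.raises(ValueError, match="channel order"):
            match_cosmic(sigset, ref)

    def test_uniform_signature_has_deterministic_argmax(self):
        ref = resources.load_reference_signatures()
        uniform = np.full(96, 1 / 96)
        sims = [cosine_similarity(uniform, ref[c].to_numpy()) for c in ref.columns]
        assert max(sims) < 1.0
        sigset = extract_signatures(
            ContextMatrix(["s1", "s2"], np.ones((2, 96)) * 10), k=1,
            n_restarts=2, seed=1,
        )
        a = match_cosmic(sigset, ref).cosmic_matches
        b = match_cosmic(sigset, ref).cosmic_matches
        assert a == b
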