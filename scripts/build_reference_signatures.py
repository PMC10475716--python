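"""Generate the packaged synthetic reference-signature matrix.

Writes ``src/tetseq/data/reference_signatures_synthetic.tsv``: 30
probability profiles over the 96 pyrimidine-centred trinucleotide
channels. The profiles are a deterministic synthetic stand-in for the
COSMIC v2 catalogue — each numbered profile encodes the qualitative
channel preferences the correspondingly numbered COSMIC v2 signature is
known for (e.g. 1: C>T at NpCpG from 5-methylcytosine deamination; 2/13:
APOBEC C>T / C>G at TpC; 4/29: tobacco C>A; 6/15/26: mismatch-repair
classes), with seeded Dirichlet background so every profile has full
support. Numeric values are NOT the published catalogue values.

Run from the repository root:  python scripts/build_reference_signatures.py
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from tetseq.signatures import CHANNELS  # noqa: E402

SEED = 2024_0001
BACKGROUND_MASS = 0.12

# (substitution, 5' bases or None=any, 3' bases or None=any, weight)
PROFILES: dict[int, list[tuple[str, str | None, str | None, float]]] = {
    1: [("C>T", None, "G", 10.0), ("C>T", None, None, 0.6)],
    2: [("C>T", "T", None, 10.0)],
    3: [(s, None, None, 1.0) for s in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")],
    4: [("C>A", None, None, 6.0), ("C>G", None, None, 0.8), ("T>A", None, None, 0.5)],
    5: [("T>C", None, None, 3.0), ("C>T", None, None, 2.0),
        ("C>A", None, None, 1.0), ("T>G", None, None, 0.8)],
    6: [("C>T", "G", None, 8.0), ("T>C", None, None, 0.8)],
    7: [("C>T", "T", "C", 8.0), ("C>T", "C", "C", 5.0)],
    8: [("C>A", None, None, 3.0), ("C>T", None, None, 0.8)],
    9: [("T>C", "A", None, 6.0), ("T>A", None, None, 0.8)],
    10: [("C>A", "T", "T", 10.0), ("C>T", "T", "G", 6.0)],
    11: [("C>T", None, "C", 6.0), ("C>T", None, "T", 4.0)],
    12: [("T>C", None, None, 4.0), ("C>T", None, None, 0.6)],
    13: [("C>G", "T", None, 10.0)],
    14: [("C>A", None, "T", 4.0), ("C>T", "A", None, 4.0)],
    15: [("C>T", None, "T", 8.0), ("C>A", None, None, 0.7)],
    16: [("T>C", "A", "A", 8.0), ("T>C", "A", None, 3.0)],
    17: [("T>G", "C", "T", 10.0), ("T>C", None, None, 0.5)],
    18: [("C>A", None, "A", 7.0), ("C>A", "G", None, 3.0)],
    19: [("C>T", None, None, 2.5), ("T>C", None, None, 2.5)],
    20: [("C>T", "G", "G", 5.0), ("C>A", None, None, 2.0)],
    21: [("T>C", None, "G", 7.0)],
    22: [("T>A", "C", "G", 12.0)],
    23: [("C>T", "A", "G", 8.0)],
    24: [("C>A", "G", None, 7.0), ("C>T", None, None, 0.5)],
    25: [("T>A", None, "T", 5.0), ("T>C", None, None, 1.0)],
    26: [("T>C", None, "T", 6.0), ("C>T", None, None, 0.8)],
    27: [("T>A", None, "A", 8.0), ("T>G", None, None, 1.0)],
    28: [("T>G", None, "T", 8.0)],
    29: [("C>A", None, "C", 7.0), ("C>G", "T", None, 2.0)],
    30: [("C>T", None, None, 3.0), ("T>C", None, None, 0.5)],
}


def build_matrix() -> np.ndarray:
    rng = np.random.default_rng(SEED)
    mat = np.zeros((96, 30))
    for sig_id, motifs in PROFILES.items():
        vec = np.zeros(96)
        for i, ch in enumerate(CHANNELS):
            five, sub, three = ch[0], ch[2:5], ch[-1]
            for msub, mfive, mthree, w in motifs:
                if sub != msub:
                    continue
                if mfive is not None and five not in mfive:
                    continue
                if mthree is not None and three not in mthree:
                    continue
                vec[i] += w
        vec = vec / vec.sum() * (1 - BACKGROUND_MASS)
        vec += rng.dirichlet(np.full(96, 0.5)) * BACKGROUND_MASS
        mat[:, sig_id - 1] = vec / vec.sum()
    return mat


def main() -> None:
    mat = build_matrix()
    out = Path(__file__).resolve().parents[1] / "src" / "tetseq" / "data" / (
        "reference_signatures_synthetic.tsv"
    )
    with open(out, "w") as fh:
        fh.write("channel\t" + "\t".join(str(i) for i in range(1, 31)) + "\n")
        for i, ch in enumerate(CHANNELS):
            fh.write(ch + "\t" + "\t".join(f"{x:.6f}" for x in mat[i]) + "\n")
    print(f"wrote {out} ({out.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
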