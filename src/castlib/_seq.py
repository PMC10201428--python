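"""Low-level DNA utilities shared across modules.

Sequences are plain Python strings over ACGT (IUPAC codes where noted).
Hot paths encode sequences as ``uint8`` arrays with A,C,G,T -> 0,1,2,3.
"""
from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgt", "TGCAYRSWMKVHDBNtgca")

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_ALPHABET):
    _ENC[ord(_b)] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def complement(seq: str) -> str:
    """Base-wise complement (no reversal)."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-ACGT character in sequence: {seq!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def decode_rows(mat: np.ndarray) -> list[str]:
    """Decode a (n, L) uint8 matrix into n strings."""
    flat = _DEC[mat].tobytes().decode("ascii")
    L = mat.shape[1]
    return [flat[i : i + L] for i in range(0, len(flat), L)]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


def add_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply uniform per-base substitution errors to an encoded read matrix.

    Errors replace a base with one of the three alternatives, each equally
    likely.  Returns a copy; the input is untouched.
    """
    if rate <= 0:
        return mat
    out = mat.copy()
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, mat.shape, dtype=np.uint8)
    out[mask] = (mat[mask] + shift[mask]) % 4
    return out


def mutate_string(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    return decode(add_errors(encode(seq)[None, :], rate, rng)[0])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
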