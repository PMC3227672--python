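"""Low-level DNA helpers shared by the simulator and the deconvolver."""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 byte array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance of two equal-length encoded sequences."""
    return int(np.count_nonzero(a != b))


def sliding_hamming(read: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Hamming distance of ``anchor`` against every offset of ``read``.

    Returns an array of length ``len(read) - len(anchor) + 1`` (empty if the
    anchor is longer than the read).
    """
    n, k = len(read), len(anchor)
    if k > n:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(read, k)
    return np.count_nonzero(windows != anchor, axis=1)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return decode(_BASES[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seqs: np.ndarray, error_rate: float) -> np.ndarray:
    """Apply i.i.d. per-base substitution errors to encoded reads (2-D array).

    Each error substitutes one of the three other bases uniformly.
    """
    if error_rate <= 0:
        return seqs
    out = seqs.copy()
    hit = rng.random(out.shape) < error_rate
    idx = np.nonzero(hit)
    if idx[0].size:
        # map each base to a uniformly chosen different base
        shift = rng.integers(1, 4, size=idx[0].size)
        base_idx = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(base_idx + shift) % 4]
    return out
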