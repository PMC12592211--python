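"""Vectorized 2-bit DNA encoding and rolling k-mer codes.

Bases are coded A=0, C=1, G=2, T=3; N and anything else is 4 (invalid).
A k-mer code packs bases big-endian into a uint64 (k <= 31), so the code of
the lexicographically smaller of a k-mer and its reverse complement is also
the numerically smaller code.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _LUT[ord(b)] = i
    _LUT[ord(b.lower())] = i

_DECODE = np.array(list("ACGTN"))

MAX_K = 31
#: sentinel for an invalid/out-of-range k-mer code
INVALID = np.uint64(2**64 - 1)


def dtype_for(k: int):
    """Narrowest unsigned dtype holding a 2k-bit code (uint32 for k <= 15)."""
    return np.uint32 if k <= 15 else np.uint64


def invalid_for(k: int):
    """All-ones sentinel in the dtype used for k-mers of size k."""
    return np.uint32(2**32 - 1) if k <= 15 else INVALID


def seq_to_codes(seq: str) -> np.ndarray:
    """String -> uint8 base codes (N and unknown -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(_DECODE[np.asarray(codes, dtype=np.uint8)])


def encode_kmer(kmer: str) -> int:
    codes = seq_to_codes(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT bases")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmer(code: int, k: int) -> str:
    bases = []
    for shift in range(2 * (k - 1), -2, -2):
        bases.append("ACGT"[(code >> shift) & 3])
    return "".join(bases)


def revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def rolling_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes at every start position of a base-code array.

    Returns ``(codes, valid)`` of length ``len(codes) - k + 1`` (empty when
    shorter than k); a window containing any invalid base is masked out and
    its code set to :data:`INVALID`.
    """
    if k < 1 or k > MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    dtype = dtype_for(k)
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=dtype), np.empty(0, dtype=bool))
    out = np.zeros(n, dtype=dtype)
    for i in range(k):
        out <<= dtype(2)
        out |= codes[i:i + n].astype(dtype)
    valid = _window_all_valid(codes, k)
    out[~valid] = invalid_for(k)
    return out, valid


def rolling_rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement k-mer codes aligned to the same start positions."""
    dtype = dtype_for(k)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=dtype)
    out = np.zeros(n, dtype=dtype)
    comp = (np.uint8(3) - codes).astype(dtype)  # invalid bases wrap; masked below
    for i in range(k):
        out |= comp[i:i + n] << dtype(2 * i)
    out[~_window_all_valid(codes, k)] = invalid_for(k)
    return out


def _window_all_valid(codes: np.ndarray, k: int) -> np.ndarray:
    invalid = (codes > 3).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    return (csum[k:] - csum[:-k]) == 0


def canonical_rolling(codes: np.ndarray, k: int,
                      canonical: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of forward and reverse complement) rolling k-mer codes."""
    fwd, valid = rolling_codes(codes, k)
    if not canonical:
        return fwd, valid
    rc = rolling_rc_codes(codes, k)
    return np.minimum(fwd, rc), valid
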