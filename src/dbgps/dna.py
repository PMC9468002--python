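"""Low-level base/array/k-mer-code utilities.

Sequences are handled in two forms: Python strings over the alphabet ACGT,
and numpy ``uint8`` arrays with A=0, C=1, G=2, T=3.  k-mers are packed into
``uint64`` codes, two bits per base, first base in the most significant
position, so lexicographic order of sequences equals numeric order of codes
and a prefix of bases corresponds to a contiguous code range.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

# byte value of 'A','C','G','T' -> 0..3; everything else maps to 255
_CHAR_TO_VAL = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CHAR_TO_VAL[ord(_b)] = _i
    _CHAR_TO_VAL[ord(_b.lower())] = _i

_VAL_TO_CHAR = np.frombuffer(BASES.encode(), dtype=np.uint8)


def seq_to_arr(seq: str) -> np.ndarray:
    """Convert an ACGT string to a uint8 array of 2-bit base values."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = _CHAR_TO_VAL[raw]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def arr_to_seq(arr: np.ndarray) -> str:
    """Convert a uint8 base-value array back to an ACGT string."""
    return _VAL_TO_CHAR[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def revcomp(seq: str) -> str:
    return arr_to_seq(revcomp_arr(seq_to_arr(seq)))


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Codes of every length-k window of ``arr`` (empty if the array is shorter).

    Runs k vectorised passes, so it is fast for large concatenated inputs.
    """
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    code = np.zeros(n, dtype=np.uint64)
    a = arr.astype(np.uint64)
    for j in range(k):
        code <<= np.uint64(2)
        code |= a[j : j + n]
    return code


def code_of(seq_or_arr, k: int | None = None) -> int:
    """Pack one sequence (string or array) into an integer code."""
    arr = seq_to_arr(seq_or_arr) if isinstance(seq_or_arr, str) else seq_or_arr
    if k is not None and arr.size != k:
        raise ValueError(f"expected {k} bases, got {arr.size}")
    code = 0
    for v in arr:
        code = (code << 2) | int(v)
    return code


def code_to_seq(code: int, k: int) -> str:
    vals = [(code >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    return "".join(BASES[v] for v in vals)


def revcomp_code(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out
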