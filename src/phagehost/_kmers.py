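"""Low-level k-mer machinery shared by the signal modules.

Sequences are encoded as int8 arrays (A=0, C=1, G=2, T=3, N=-1) so that
k-mer extraction, reverse complementation and seed lookup can run as
vectorised numpy operations.  A k-mer "code" packs k bases into an int64,
two bits per base, most significant bits first; any window touching an N
is flagged invalid and never enters an index.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"

_ENCODE_LUT = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_ENCODE_LUT[ord("N")] = -1
_ENCODE_LUT[ord("n")] = -1


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an int8 array (N -> -1)."""
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise InvalidAlphabetError(f"non-ASCII character in sequence: {exc}") from None
    arr = _ENCODE_LUT[raw]
    if (arr == -2).any():
        bad = chr(raw[int(np.argmax(arr == -2))])
        raise InvalidAlphabetError(f"invalid nucleotide {bad!r}; expected A/C/G/T/N")
    return arr


def decode(arr: np.ndarray) -> str:
    out = np.full(arr.size, ord("N"), dtype=np.uint8)
    ok = arr >= 0
    out[ok] = np.frombuffer(b"ACGT", dtype=np.uint8)[arr[ok]]
    return out.tobytes().decode("ascii")


def complement(arr: np.ndarray) -> np.ndarray:
    """Complement an encoded array; N (-1) stays N."""
    return np.where(arr < 0, np.int8(-1), (3 - arr).astype(np.int8))


def revcomp(arr: np.ndarray) -> np.ndarray:
    return complement(arr)[::-1]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid) for every length-k window of ``arr``.

    ``codes`` is int64 of length len(arr)-k+1; ``valid`` is False for
    windows containing an N.  Windows are empty when the array is shorter
    than k.
    """
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    clean = np.where(arr < 0, 0, arr).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | clean[j : j + n]
    bad = (arr < 0).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse-complement of packed k-mer codes."""
    res = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        res = (res << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return res


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


@lru_cache(maxsize=None)
def canonical_map(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Map every k-mer code to its canonical bin.

    Returns (representatives, index_map): ``representatives`` lists the
    canonical codes in ascending (lexicographic) order; ``index_map`` has
    length 4**k and sends any code to its bin index.  The canonical
    representative of a word is the lexicographic minimum of the word and
    its reverse complement.
    """
    codes = np.arange(4**k, dtype=np.int64)
    canon = np.minimum(codes, revcomp_codes(codes, k))
    reps = np.unique(canon)
    index_map = np.searchsorted(reps, canon)
    return reps, index_map


class KmerIndex:
    """Sorted-array index of the k-mer codes of one sequence.

    Supports bulk lookup of query codes, returning (query position,
    target position) pairs for every exact occurrence.
    """

    def __init__(self, arr: np.ndarray, k: int):
        self.k = k
        self.length = arr.size
        codes, valid = kmer_codes(arr, k)
        pos = np.flatnonzero(valid)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order].astype(np.int64)

    def lookup(self, query_codes: np.ndarray, query_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) pairs where codes match exactly."""
        if query_codes.size == 0 or self._codes.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._codes, query_codes, side="left")
        hi = np.searchsorted(self._codes, query_codes, side="right")
        cnt = hi - lo
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qp = np.repeat(query_pos, cnt)
        starts = np.cumsum(cnt) - cnt
        idx = np.repeat(lo - starts, cnt) + np.arange(total)
        return qp, self._pos[idx]

    def positions(self, code: int) -> np.ndarray:
        """Sorted target positions of a single k-mer code."""
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        return np.sort(self._pos[lo:hi])
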