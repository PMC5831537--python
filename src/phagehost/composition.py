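"""Oligonucleotide composition profiles and profile distances.

Phages tend to ameliorate their nucleotide composition towards that of
their host, so similarity between composition profiles is a (weak but
homology-free) host signal.  Profiles here are canonical k-mer frequency
vectors for k = 1..8 — forward and reverse-complement words are counted
in a single bin, making profiles strand-invariant — plus two special
cases: GC content (k = 1, two values) and in-frame codon usage over
coding regions (64 values).  For odd k the vector has 4^k/2 components;
for even k it has 2^k + (4^k - 2^k)/2, the extra 2^k being words that are
their own reverse complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import canonical_map, decode_kmer, encode, kmer_codes
from .scoretable import ScoreTable
from .sequence import SequenceRecord, find_orfs

__all__ = [
    "ProfileVector",
    "kmer_dim",
    "kmer_labels",
    "canonical_kmer_profile",
    "gc_profile",
    "codon_profile",
    "profile_distance",
    "composition_scores",
    "NoCodingRegionsError",
]

METRICS = ("euclidean", "manhattan", "cosine", "pearson")


class NoCodingRegionsError(ValueError):
    """Raised when a codon profile is requested but no coding regions exist."""


@dataclass
class ProfileVector:
    """A normalised composition vector with its kind and dimension."""

    kind: str  # "kmer:<k>", "codon" or "gc"
    values: np.ndarray
    dim: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.dim,):
            raise ValueError("profile dimension mismatch")


def kmer_dim(k: int) -> int:
    """Number of canonical k-mer bins: 4^k/2 for odd k, 2^k + (4^k-2^k)/2
    for even k (palindromic words are their own bin)."""
    if k % 2:
        return 4**k // 2
    return 2**k + (4**k - 2**k) // 2


def kmer_labels(k: int) -> list[str]:
    """Canonical representatives in lexicographic order (profile columns)."""
    reps, _ = canonical_map(k)
    return [decode_kmer(int(c), k) for c in reps]


def _seq_of(x: SequenceRecord | str) -> str:
    return x.seq if isinstance(x, SequenceRecord) else x


def canonical_kmer_profile(seq: SequenceRecord | str, k: int) -> ProfileVector:
    """Relative frequencies of canonical k-mers; windows with N skipped."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in 1..8, got {k}")
    s = _seq_of(seq)
    if len(s) < k:
        raise ValueError(f"sequence shorter than k={k}")
    arr = encode(s)
    codes, valid = kmer_codes(arr, k)
    reps, index_map = canonical_map(k)
    counts = np.bincount(index_map[codes[valid]], minlength=reps.size).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable k-mer windows (all contain N)")
    return ProfileVector(kind=f"kmer:{k}", values=counts / total, dim=reps.size)


def gc_profile(seq: SequenceRecord | str) -> ProfileVector:
    """Two-component (AT, GC) frequency vector, N positions excluded."""
    arr = encode(_seq_of(seq))
    at = int(np.count_nonzero((arr == 0) | (arr == 3)))
    gc = int(np.count_nonzero((arr == 1) | (arr == 2)))
    if at + gc == 0:
        raise ValueError("no countable bases (all N)")
    total = at + gc
    return ProfileVector(kind="gc", values=np.array([at / total, gc / total]), dim=2)


def codon_profile(rec: SequenceRecord, min_codons: int = 60) -> ProfileVector:
    """In-frame codon usage pooled over coding regions (64 values).

    Uses annotated CDS when present, internally called ORFs otherwise.
    All 64 codons, including stops, are counted.
    """
    if rec.cds:
        regions = rec.cds
    else:
        regions = [(o.start, o.end, o.strand) for o in find_orfs(rec, min_codons)]
    if not regions:
        raise NoCodingRegionsError(f"record {rec.id!r}: no CDS and no callable ORFs")
    arr = encode(rec.seq)
    counts = np.zeros(64, dtype=float)
    for start, end, strand in regions:
        sub = arr[start:end]
        if strand == -1:
            sub = np.where(sub < 0, -1, 3 - sub)[::-1]
        n = sub.size - sub.size % 3
        tri = sub[:n].reshape(-1, 3)
        ok = (tri >= 0).all(axis=1)
        codes = tri[ok, 0] * 16 + tri[ok, 1] * 4 + tri[ok, 2]
        counts += np.bincount(codes, minlength=64)
    total = counts.sum()
    if total == 0:
        raise NoCodingRegionsError(f"record {rec.id!r}: coding regions contain no countable codons")
    return ProfileVector(kind="codon", values=counts / total, dim=64)


def profile_distance(p: ProfileVector, q: ProfileVector, metric: str = "euclidean") -> float:
    """Distance (euclidean/manhattan/cosine) or Pearson correlation
    between two profiles of the same kind and dimension."""
    if p.kind != q.kind or p.dim != q.dim:
        raise ValueError(f"profile mismatch: {p.kind}/{p.dim} vs {q.kind}/{q.dim}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    a, b = p.values, q.values
    if metric == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(a - b)))
    if metric == "cosine":
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(1.0 - np.dot(a, b) / denom)
    return float(np.corrcoef(a, b)[0, 1])


def _profile(rec: SequenceRecord, kind: str, k: int) -> ProfileVector:
    if kind == "kmer":
        return canonical_kmer_profile(rec, k)
    if kind == "gc":
        return gc_profile(rec)
    if kind == "codon":
        return codon_profile(rec)
    raise ValueError(f"kind must be 'kmer', 'codon' or 'gc', got {kind!r}")


def composition_scores(
    phages: list[SequenceRecord],
    hosts: list[SequenceRecord],
    kind: str = "kmer",
    k: int = 4,
    metric: str = "euclidean",
) -> ScoreTable:
    """Pairwise profile distances/correlations as a ScoreTable.

    Distances are lower-is-better; the Pearson variant is
    higher-is-better.  Records whose profile cannot be computed (e.g. no
    coding regions for the codon profile) are dropped with a warning.
    """
    def gather(records):
        out = {}
        for rec in records:
            try:
                out[rec.id] = _profile(rec, kind, k)
            except (ValueError, NoCodingRegionsError) as exc:
                warnings.warn(f"dropping {rec.id!r} from composition table: {exc}")
        return out

    pprof, hprof = gather(phages), gather(hosts)
    pmat = np.array([pprof[p].values for p in pprof]) if pprof else np.empty((0, 0))
    hmat = np.array([hprof[h].values for h in hprof]) if hprof else np.empty((0, 0))
    pids, hids = list(pprof), list(hprof)
    table = np.zeros((len(pids), len(hids)))
    for i in range(len(pids)):
        if metric == "euclidean":
            table[i] = np.sqrt(np.sum((hmat - pmat[i]) ** 2, axis=1))
        elif metric == "manhattan":
            table[i] = np.sum(np.abs(hmat - pmat[i]), axis=1)
        else:
            for j in range(len(hids)):
                table[i, j] = profile_distance(pprof[pids[i]], hprof[hids[j]], metric)
    name = f"{kind}{k if kind == 'kmer' else ''}_{metric}"
    return ScoreTable(
        scores=pd.DataFrame(table, index=pids, columns=hids),
        higher_is_better=(metric == "pearson"),
        name=name,
    )


def profiles_to_tsv(records: list[SequenceRecord], path, kind: str = "kmer", k: int = 4) -> None:
    """One row per genome, one column per canonical word (lexicographic)."""
    if kind == "kmer":
        cols = kmer_labels(k)
    elif kind == "codon":
        cols = [decode_kmer(c, 3) for c in range(64)]
    else:
        cols = ["AT", "GC"]
    rows = {rec.id: _profile(rec, kind, k).values for rec in records}
    pd.DataFrame.from_dict(rows, orient="index", columns=cols).to_csv(path, sep="\t")
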