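"""Longest exact match between phage and host genomes.

Integrated prophages, CRISPR spacers, shared genes and attachment-site
cores all leave verbatim sequence shared between a phage and its host.
The signal here is the length of the longest identical stretch, found in
two steps: all shared 15-mers are located via a seed index, then seeds on
the same diagonal whose intervals overlap or abut are merged and the
merged runs extended base-by-base to maximal identical stretches.  Pairs
sharing no 15-mer score 0: matches shorter than the seed length cannot be
reported, which is deliberate — such short identities are hard to tell
from random matches.

By default the phage forward strand is compared against both host
strands; ``both_strands=False`` restricts to forward-only.  N never
matches anything, including another N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import KmerIndex, encode, kmer_codes, revcomp_codes
from .scoretable import ScoreTable
from .sequence import SequenceRecord

__all__ = [
    "ExactMatch",
    "SeedIndex",
    "build_seed_index",
    "longest_exact_match",
    "exact_match_scores",
    "match_length_histogram",
    "DEFAULT_SEED_LEN",
]

DEFAULT_SEED_LEN = 15


@dataclass(frozen=True)
class ExactMatch:
    """A maximal identical stretch between a phage and a host.

    ``phage_pos``/``host_pos`` are 0-based starts on the forward strands;
    for strand -1 the phage substring equals the reverse complement of
    the host substring.
    """

    phage_id: str
    host_id: str
    length: int
    phage_pos: int
    host_pos: int
    strand: int


class SeedIndex:
    """Per-host k-mer indexes over the forward strands of host records.

    Hosts are added one record at a time, so building streams over the
    host set without an all-pairs scan.
    """

    def __init__(self, seed_len: int = DEFAULT_SEED_LEN):
        if seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        self.seed_len = seed_len
        self._hosts: dict[str, tuple[np.ndarray, KmerIndex]] = {}

    def add_host(self, host: SequenceRecord) -> None:
        if host.id in self._hosts:
            raise ValueError(f"duplicate host id {host.id!r}")
        arr = encode(host.seq)
        self._hosts[host.id] = (arr, KmerIndex(arr, self.seed_len))

    @property
    def host_ids(self) -> list[str]:
        return list(self._hosts)

    def host_array(self, host_id: str) -> np.ndarray:
        return self._hosts[host_id][0]

    def host_index(self, host_id: str) -> KmerIndex:
        return self._hosts[host_id][1]

    def seed_positions(self, host_id: str, word: str) -> np.ndarray:
        """Positions of one exact seed word in a host (forward strand)."""
        arr = encode(word)
        if arr.size != self.seed_len or (arr < 0).any():
            raise ValueError(f"word must be {self.seed_len} bp over ACGT")
        codes, _ = kmer_codes(arr, self.seed_len)
        return self._hosts[host_id][1].positions(int(codes[0]))


def build_seed_index(hosts: list[SequenceRecord], seed_len: int = DEFAULT_SEED_LEN) -> SeedIndex:
    index = SeedIndex(seed_len)
    for host in hosts:
        index.add_host(host)
    return index


def _merge_runs(qpos: np.ndarray, key: np.ndarray, seed_len: int) -> list[tuple[int, int, int]]:
    """Merge seed hits on a shared diagonal key into runs.

    Returns (key, run_start, run_end) phage intervals where seeds with the
    same key overlap or abut.
    """
    if qpos.size == 0:
        return []
    order = np.lexsort((qpos, key))
    key, qpos = key[order], qpos[order]
    runs = []
    cur_key, start, end = int(key[0]), int(qpos[0]), int(qpos[0]) + seed_len
    for i in range(1, qpos.size):
        k, q = int(key[i]), int(qpos[i])
        if k == cur_key and q <= end:
            end = max(end, q + seed_len)
        else:
            runs.append((cur_key, start, end))
            cur_key, start, end = k, q, q + seed_len
    runs.append((cur_key, start, end))
    return runs


def _extend_forward(parr, harr, diag, s, e):
    """Maximally extend an identical run on a forward-strand diagonal."""
    hs = s - diag
    while s > 0 and hs > 0 and parr[s - 1] >= 0 and parr[s - 1] == harr[hs - 1]:
        s -= 1
        hs -= 1
    he = e - diag
    while e < parr.size and he < harr.size and parr[e] >= 0 and parr[e] == harr[he]:
        e += 1
        he += 1
    return s, e, s - diag


def _extend_reverse(parr, harr, anti, s, e):
    """Extend on a reverse-strand anti-diagonal.

    Phage base q pairs with host base (anti - q), complemented.
    """
    while s > 0 and anti - (s - 1) < harr.size:
        hb = harr[anti - (s - 1)]
        if parr[s - 1] >= 0 and hb >= 0 and parr[s - 1] == 3 - hb:
            s -= 1
        else:
            break
    while e < parr.size and anti - e >= 0:
        hb = harr[anti - e]
        if parr[e] >= 0 and hb >= 0 and parr[e] == 3 - hb:
            e += 1
        else:
            break
    return s, e, anti - (e - 1)


def longest_exact_match(
    phage: SequenceRecord,
    host: SequenceRecord | str,
    index: SeedIndex,
    both_strands: bool = True,
) -> ExactMatch | None:
    """The longest identical substring shared by a phage and one host.

    Seeds on the same diagonal (constant phage_pos - host_pos per strand)
    are merged when overlapping or abutting, then extended base-by-base.
    Returns None when no seed-length word is shared.
    """
    host_id = host.id if isinstance(host, SequenceRecord) else host
    harr = index.host_array(host_id)
    kidx = index.host_index(host_id)
    parr = encode(phage.seq)
    k = index.seed_len
    codes, valid = kmer_codes(parr, k)
    qpos_all = np.flatnonzero(valid)
    fcodes = codes[qpos_all]

    best: ExactMatch | None = None

    qp, hp = kidx.lookup(fcodes, qpos_all)
    for diag, s, e in _merge_runs(qp, qp - hp, k):
        s, e, hs = _extend_forward(parr, harr, diag, s, e)
        if best is None or e - s > best.length:
            best = ExactMatch(phage.id, host_id, e - s, s, hs, 1)

    if both_strands:
        # A phage window whose reverse complement occurs forward in the host
        # is a reverse-strand match; contiguity follows anti-diagonals
        # (constant phage_pos + host_end).
        rcodes = revcomp_codes(fcodes, k)
        qp, hp = kidx.lookup(rcodes, qpos_all)
        for anti, s, e in _merge_runs(qp, qp + hp + (k - 1), k):
            s, e, hs = _extend_reverse(parr, harr, anti, s, e)
            if best is None or e - s > best.length:
                best = ExactMatch(phage.id, host_id, e - s, s, hs, -1)

    return best


def exact_match_scores(
    phages: list[SequenceRecord],
    hosts: list[SequenceRecord],
    seed_len: int = DEFAULT_SEED_LEN,
    both_strands: bool = True,
) -> ScoreTable:
    """Longest-exact-match length per pair (0 where no seed is shared).

    Ties are preserved by the raw lengths: several hosts can share a
    phage's row maximum, e.g. when related hosts carry the same prophage.
    """
    index = build_seed_index(hosts, seed_len)
    hids = [h.id for h in hosts]
    rows = {}
    for phage in phages:
        row = []
        for hid in hids:
            m = longest_exact_match(phage, hid, index, both_strands)
            row.append(0 if m is None else m.length)
        rows[phage.id] = row
    return ScoreTable(
        scores=pd.DataFrame.from_dict(rows, orient="index", columns=hids),
        higher_is_better=True,
        name="exact_match",
    )


def matches_to_tsv(matches: list[ExactMatch], path) -> None:
    pd.DataFrame(
        [
            (m.phage_id, m.host_id, m.length, m.phage_pos, m.host_pos, m.strand)
            for m in matches
        ],
        columns=["phage_id", "host_id", "length", "phage_start", "host_start", "strand"],
    ).to_csv(path, sep="\t", index=False)


def match_length_histogram(
    table: ScoreTable, truth: dict[str, str], bin_edges: list[int] | np.ndarray
) -> pd.DataFrame:
    """Counts of longest-match lengths per bin, split correct/incorrect.

    For each phage, every host attaining the row maximum contributes one
    count (hosts tied at the maximum are all included).
    """
    edges = np.asarray(bin_edges)
    correct = np.zeros(edges.size - 1, dtype=int)
    incorrect = np.zeros(edges.size - 1, dtype=int)
    for pid in table.phage_ids:
        row = table.scores.loc[pid]
        top = table.top_hosts(pid)
        if not top:
            continue
        length = float(row[list(top)[0]])
        b = int(np.searchsorted(edges, length, side="right")) - 1
        if not 0 <= b < edges.size - 1:
            continue
        for hid in top:
            if truth.get(pid) == hid:
                correct[b] += 1
            else:
                incorrect[b] += 1
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "correct": correct, "incorrect": incorrect}
    )
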