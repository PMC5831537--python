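"""CRISPR array detection, spacer extraction and spacer-to-phage matching.

Bacteria store short fragments (spacers, typically 25-75 bp) of invading
phage genomes between near-identical repeats in CRISPR arrays.  A spacer
aligning to a phage genome is therefore direct evidence of a past
infection.  Two score variants are produced: the best percent identity of
any qualifying spacer hit, and the number of distinct spacers from one
host hitting the phage — multiple spacers from the same array (a known
consequence of primed acquisition, which tolerates up to ~13 mismatches
in the priming spacer) make a prediction more specific.

The array finder is a deliberately simple repeat-spacer detector: exact
anchor words recurring at spacer-like intervals seed candidate arrays,
repeats are grown column-by-column around the anchors, and candidates
must show >= 3 repeat copies, repeat length 21-48 bp, spacer lengths
18-72 bp and >= 90% per-column agreement.  Externally produced spacer
sets can be imported from FASTA to bypass detection entirely.

Spacer alignment mirrors a short-query nucleotide search (word size 7,
match +1, mismatch -1, both strands, no low-complexity masking).  Gap
penalties of 10 (open) and 2 (extend) exceed what the score floor below
can absorb, so qualifying alignments are gap-free and are evaluated
exactly as ungapped full-width comparisons: a hit must cover at least
spacer_length - 2 bases and reach score >= spacer_length -
2*max_mismatch.  Mismatch counts are substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import KmerIndex, decode, encode, kmer_codes, revcomp
from .scoretable import ScoreTable
from .sequence import SequenceRecord

__all__ = [
    "CrisprParams",
    "CrisprArray",
    "Spacer",
    "SpacerHit",
    "detect_crispr_arrays",
    "extract_spacers",
    "host_spacers",
    "match_spacers",
    "crispr_best_hit_scores",
    "crispr_spacer_count_scores",
    "read_spacer_fasta",
    "write_spacer_fasta",
]


@dataclass(frozen=True)
class CrisprParams:
    repeat_len_min: int = 21
    repeat_len_max: int = 48
    spacer_len_min: int = 18
    spacer_len_max: int = 72
    min_copies: int = 3
    min_repeat_identity: float = 0.90
    anchor_len: int = 16


@dataclass
class CrisprArray:
    """A detected repeat-spacer array.

    ``units`` pairs each repeat interval with the spacer interval that
    follows it (None after the terminal repeat); intervals are 0-based
    half-open on the host forward strand.
    """

    host_id: str
    repeat_seq: str
    units: list[tuple[tuple[int, int], tuple[int, int] | None]]
    n_spacers: int


@dataclass(frozen=True)
class Spacer:
    host_id: str
    array_index: int
    ordinal: int
    seq: str
    start: int = -1
    end: int = -1

    @property
    def label(self) -> str:
        return f"{self.host_id}|{self.array_index}|{self.ordinal}"


@dataclass
class SpacerHit:
    """One spacer-to-phage alignment (ungapped; see module docstring)."""

    spacer: Spacer
    phage_id: str
    start: int
    end: int
    strand: int
    aligned_len: int
    mismatches: int
    gaps: int
    percent_identity: float
    is_best: bool = False

    @property
    def score(self) -> int:
        return self.aligned_len - 2 * self.mismatches


def _chains(positions: np.ndarray, lo: int, hi: int) -> list[list[int]]:
    """Split anchor positions into maximal chains with gaps in [lo, hi]."""
    chains: list[list[int]] = []
    cur = [int(positions[0])]
    for p in positions[1:]:
        p = int(p)
        if lo <= p - cur[-1] <= hi:
            cur.append(p)
        else:
            chains.append(cur)
            cur = [p]
    chains.append(cur)
    return chains


def _column_ok(arr: np.ndarray, positions: list[int], offset: int, min_ident: float) -> bool:
    bases = []
    for p in positions:
        q = p + offset
        if q < 0 or q >= arr.size or arr[q] < 0:
            return False
        bases.append(int(arr[q]))
    counts = np.bincount(bases, minlength=4)
    return counts.max() / len(bases) >= min_ident


def detect_crispr_arrays(host: SequenceRecord, params: CrisprParams = CrisprParams()) -> list[CrisprArray]:
    """Find repeat-spacer arrays in one host genome.

    Empty list when nothing qualifies; i.i.d. random sequence essentially
    never produces three identical anchor words at spacer-like intervals,
    so the detector is specific by construction.
    """
    arr = encode(host.seq)
    k = params.anchor_len
    if arr.size < params.min_copies * (params.repeat_len_min + params.spacer_len_min):
        return []
    codes, valid = kmer_codes(arr, k)
    pos_all = np.flatnonzero(valid)
    codes = codes[pos_all]
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], pos_all[order]
    # candidate anchors = codes occurring >= min_copies times, visited in
    # order of first genomic occurrence for determinism
    bounds = np.flatnonzero(np.diff(sc)) + 1
    groups = np.split(sp, bounds)
    cands = sorted(
        (np.sort(g) for g in groups if g.size >= params.min_copies),
        key=lambda g: int(g[0]),
    )
    gap_lo = params.repeat_len_min + params.spacer_len_min
    gap_hi = params.repeat_len_max + params.spacer_len_max
    arrays: list[CrisprArray] = []
    claimed: list[tuple[int, int]] = []
    for g in cands:
        for chain in _chains(g, gap_lo, gap_hi):
            if len(chain) < params.min_copies:
                continue
            if any(s <= chain[0] < e for s, e in claimed):
                continue
            # grow the repeat around the anchors while columns stay conserved
            dl = 0
            while (
                dl + 1 + k <= params.repeat_len_max
                and chain[0] - (dl + 1) >= 0
                and _column_ok(arr, chain, -(dl + 1), params.min_repeat_identity)
            ):
                dl += 1
            dr = 0
            while (
                dl + k + dr + 1 <= params.repeat_len_max
                and _column_ok(arr, chain, k + dr, params.min_repeat_identity)
            ):
                dr += 1
            rlen = dl + k + dr
            if rlen < params.repeat_len_min:
                continue
            starts = [p - dl for p in chain]
            gaps = [starts[i + 1] - (starts[i] + rlen) for i in range(len(starts) - 1)]
            if not all(params.spacer_len_min <= gap <= params.spacer_len_max for gap in gaps):
                continue
            units: list[tuple[tuple[int, int], tuple[int, int] | None]] = []
            for i, s in enumerate(starts):
                rep = (s, s + rlen)
                spc = (s + rlen, starts[i + 1]) if i + 1 < len(starts) else None
                units.append((rep, spc))
            consensus = _consensus(arr, starts, rlen)
            arrays.append(
                CrisprArray(host.id, consensus, units, n_spacers=len(starts) - 1)
            )
            claimed.append((starts[0], starts[-1] + rlen))
    arrays.sort(key=lambda a: a.units[0][0][0])
    return arrays


def _consensus(arr: np.ndarray, starts: list[int], rlen: int) -> str:
    cols = np.stack([arr[s : s + rlen] for s in starts])
    out = np.empty(rlen, dtype=np.int8)
    for j in range(rlen):
        col = cols[:, j]
        col = col[col >= 0]
        out[j] = np.argmax(np.bincount(col, minlength=4)) if col.size else -1
    return decode(out)


def extract_spacers(array: CrisprArray, host: SequenceRecord, array_index: int = 0) -> list[Spacer]:
    """Verbatim spacer substrings of the host, in array order."""
    out = []
    ordinal = 0
    for _, spc in array.units:
        if spc is None:
            continue
        s, e = spc
        out.append(Spacer(host.id, array_index, ordinal, host.seq[s:e], s, e))
        ordinal += 1
    return out


def host_spacers(host: SequenceRecord, params: CrisprParams = CrisprParams()) -> list[Spacer]:
    spacers = []
    for i, array in enumerate(detect_crispr_arrays(host, params)):
        spacers.extend(extract_spacers(array, host, array_index=i))
    return spacers


@dataclass(frozen=True)
class SpacerMatchParams:
    word_size: int = 7
    max_mismatch: int = 13  # widest budget reported; scorers filter further
    coverage_slack: int = 2  # hits must cover >= spacer length - this


def match_spacers(
    spacers: list[Spacer],
    phage: SequenceRecord,
    params: SpacerMatchParams = SpacerMatchParams(),
) -> list[SpacerHit]:
    """Align spacers to one phage genome on both strands.

    Every near-full-length ungapped placement reaching the score floor
    (see module docstring) is returned; the best-scoring hit per spacer is
    flagged.
    """
    if not spacers:
        raise ValueError("no spacers supplied")
    parr = encode(phage.seq)
    kidx = KmerIndex(parr, params.word_size)
    hits: list[SpacerHit] = []
    for spacer in spacers:
        sarr = encode(spacer.seq)
        L = sarr.size
        floor = L - 2 * params.max_mismatch
        best_i = -1
        best_key = None
        for strand, qarr in ((1, sarr), (-1, revcomp(sarr))):
            codes, valid = kmer_codes(qarr, params.word_size)
            qpos = np.flatnonzero(valid)
            qp, pp = kidx.lookup(codes[qpos], qpos)
            if qp.size == 0:
                continue
            for off in np.unique(pp - qp):
                off = int(off)
                qs = max(0, -off)
                qe = min(L, parr.size - off)
                aligned = qe - qs
                if aligned < L - params.coverage_slack:
                    continue
                a = qarr[qs:qe]
                b = parr[off + qs : off + qe]
                mism = int(np.count_nonzero((a != b) | (a < 0) | (b < 0)))
                score = aligned - 2 * mism
                if score < floor:
                    continue
                if strand == 1:
                    start, end = off + qs, off + qe
                else:
                    # qarr is the reverse complement; map back to forward axis
                    start, end = off + qs, off + qe
                pct = 100.0 * (aligned - mism) / aligned
                hits.append(
                    SpacerHit(spacer, phage.id, start, end, strand, aligned, mism, 0, pct)
                )
                key = (score, -mism, -start)
                if best_key is None or key > best_key:
                    best_key, best_i = key, len(hits) - 1
        if best_i >= 0:
            hits[best_i].is_best = True
    return hits


def _gather_spacers(
    hosts: list[SequenceRecord] | None,
    spacers: list[Spacer] | None,
    params: CrisprParams,
) -> dict[str, list[Spacer]]:
    by_host: dict[str, list[Spacer]] = {}
    if spacers is not None:
        for sp in spacers:
            by_host.setdefault(sp.host_id, []).append(sp)
        if hosts is not None:
            for h in hosts:
                by_host.setdefault(h.id, [])
    elif hosts is not None:
        for h in hosts:
            by_host[h.id] = host_spacers(h, params)
    else:
        raise ValueError("provide hosts or spacers")
    return by_host


def _all_hits(
    phages: list[SequenceRecord],
    by_host: dict[str, list[Spacer]],
    match_params: SpacerMatchParams,
) -> dict[tuple[str, str], list[SpacerHit]]:
    out: dict[tuple[str, str], list[SpacerHit]] = {}
    flat = [sp for sps in by_host.values() for sp in sps]
    if not flat:
        return out
    for phage in phages:
        for hit in match_spacers(flat, phage, match_params):
            out.setdefault((phage.id, hit.spacer.host_id), []).append(hit)
    return out


def crispr_best_hit_scores(
    phages: list[SequenceRecord],
    hosts: list[SequenceRecord] | None = None,
    max_mismatch: int = 2,
    spacers: list[Spacer] | None = None,
    params: CrisprParams = CrisprParams(),
    match_params: SpacerMatchParams | None = None,
) -> ScoreTable:
    """Best spacer percent identity per phage-host pair.

    A pair scores only when some spacer hits near-full-length with at
    most ``max_mismatch`` substitutions; everything else — including
    hosts with no detected arrays — is no-evidence, not zero.
    """
    match_params = match_params or SpacerMatchParams(max_mismatch=max(max_mismatch, 13))
    by_host = _gather_spacers(hosts, spacers, params)
    hits = _all_hits(phages, by_host, match_params)
    hids = list(by_host)
    table = pd.DataFrame(np.nan, index=[p.id for p in phages], columns=hids)
    for (pid, hid), pair_hits in hits.items():
        good = [h.percent_identity for h in pair_hits if h.mismatches <= max_mismatch]
        if good:
            table.loc[pid, hid] = max(good)
    return ScoreTable(scores=table, higher_is_better=True, name="crispr_best_identity")


def crispr_spacer_count_scores(
    phages: list[SequenceRecord],
    hosts: list[SequenceRecord] | None = None,
    max_mismatch: int = 2,
    min_spacers: int = 1,
    spacers: list[Spacer] | None = None,
    params: CrisprParams = CrisprParams(),
    match_params: SpacerMatchParams | None = None,
) -> ScoreTable:
    """Number of distinct host spacers hitting each phage.

    Identical spacer sequences within one host count once.  Pairs with
    fewer than ``min_spacers`` matching spacers are no-evidence;
    ``min_spacers=2`` gives the stricter multi-spacer variant.
    """
    match_params = match_params or SpacerMatchParams(max_mismatch=max(max_mismatch, 13))
    by_host = _gather_spacers(hosts, spacers, params)
    hits = _all_hits(phages, by_host, match_params)
    hids = list(by_host)
    table = pd.DataFrame(np.nan, index=[p.id for p in phages], columns=hids)
    for (pid, hid), pair_hits in hits.items():
        seqs = {
            h.spacer.seq
            for h in pair_hits
            if h.mismatches <= max_mismatch
        }
        if len(seqs) >= min_spacers:
            table.loc[pid, hid] = len(seqs)
    return ScoreTable(scores=table, higher_is_better=True, name="crispr_spacer_count")


def write_spacer_fasta(spacers: list[Spacer], path) -> None:
    with open(path, "w") as fh:
        for sp in spacers:
            fh.write(f">{sp.label}\n{sp.seq}\n")


def read_spacer_fasta(path) -> list[Spacer]:
    """Import spacers; ids of the form host|array|ordinal keep their
    provenance, anything else becomes host=<id>, array 0, running ordinal."""
    from .sequence import read_fasta

    out = []
    for i, rec in enumerate(read_fasta(path)):
        parts = rec.id.split("|")
        if len(parts) == 3 and parts[1].isdigit() and parts[2].isdigit():
            out.append(Spacer(parts[0], int(parts[1]), int(parts[2]), rec.seq))
        else:
            out.append(Spacer(parts[0], 0, i, rec.seq))
    return out


def hits_to_tsv(hits: list[SpacerHit], path) -> None:
    pd.DataFrame(
        [
            (
                h.spacer.label,
                h.phage_id,
                h.strand,
                h.start,
                h.end,
                h.aligned_len,
                h.mismatches,
                h.gaps,
                round(h.percent_identity, 3),
            )
            for h in hits
        ],
        columns=[
            "spacer_id",
            "phage_id",
            "strand",
            "start",
            "end",
            "aligned_len",
            "mismatches",
            "gaps",
            "pct_identity",
        ],
    ).to_csv(path, sep="\t", index=False)
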