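"""Nucleotide and translated homology between phage and host genomes.

Genes acquired from a host during past infections leave detectable
homology.  Two summaries are produced per phage-host pair, matching the
two classic search modes: the overall aligned length of nucleotide hits
(union of phage intervals covered by qualifying local alignments) and
the number of phage ORFs with a qualifying hit against the host's
proteins.  The internal scorer is a deliberately simple seeded ungapped
extender — word seeds, X-drop extension, fixed score thresholds — and an
adapter for 12-column tabular alignment files lets externally computed
hits drive the identical summaries.

In score tables, a pair with no qualifying alignment at all is
no-evidence rather than a numeric zero: a phage without hits makes no
prediction instead of trivially tying every candidate host.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from ._kmers import KmerIndex, encode, kmer_codes, revcomp
from .scoretable import ScoreTable
from .sequence import SequenceRecord, orf_peptides

__all__ = [
    "AlignmentSummary",
    "NucleotideParams",
    "ProteinParams",
    "ProteomeIndex",
    "nucleotide_homology",
    "nucleotide_alignments",
    "translated_homology",
    "homology_scores",
    "read_tabular_hits",
    "write_tabular_hits",
    "TabularFormatError",
]


@dataclass
class AlignmentSummary:
    phage_id: str
    host_id: str
    total_aligned_len: int = 0
    n_matching_proteins: int = 0
    best_bitlike_score: float = 0.0


@dataclass(frozen=True)
class NucleotideParams:
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20
    min_score: int = 28


@dataclass(frozen=True)
class ProteinParams:
    word_size: int = 4
    xdrop: int = 20
    min_score: int = 50


@dataclass(frozen=True)
class LocalAlignment:
    """An ungapped local alignment on the phage forward axis."""

    qstart: int
    qend: int
    sstart: int  # subject forward-axis start
    send: int
    strand: int
    score: int
    mismatches: int


class TabularFormatError(ValueError):
    """Raised for rows violating the 12-column tabular layout."""


def _extend(q: list, s: list, q0: int, q1: int, s0: int, score0: int,
            match: int, mismatch: int, xdrop: int) -> tuple[int, int, int]:
    """Ungapped X-drop extension of a seeded identical run.

    Plain-list indexing: this inner loop runs for every seed hit.
    """
    nq, ns = len(q), len(s)
    best = score0
    run, best_e = score0, q1
    i, j = q1, s0 + (q1 - q0)
    while i < nq and j < ns:
        a = q[i]
        run += match if (a == s[j] and a >= 0) else mismatch
        if run > best:
            best, best_e = run, i + 1
        elif run <= best - xdrop:
            break
        i += 1
        j += 1
    run, best_s = best, q0
    i, j = q0 - 1, s0 - 1
    while i >= 0 and j >= 0:
        a = q[i]
        run += match if (a == s[j] and a >= 0) else mismatch
        if run > best:
            best, best_s = run, i
        elif run <= best - xdrop:
            break
        i -= 1
        j -= 1
    return best_s, best_e, best


def _strand_alignments(qarr: np.ndarray, sarr: np.ndarray, params: NucleotideParams):
    """(qstart, qend, sstart_local, score, mismatches) on one subject strand."""
    kidx = KmerIndex(sarr, params.word_size)
    codes, valid = kmer_codes(qarr, params.word_size)
    qpos = np.flatnonzero(valid)
    qp, sp = kidx.lookup(codes[qpos], qpos)
    if qp.size == 0:
        return []
    diag = qp - sp
    order = np.lexsort((qp, diag))
    qp, sp, diag = qp[order], sp[order], diag[order]
    qlist, slist = qarr.tolist(), sarr.tolist()
    covered: dict[int, int] = {}  # diagonal -> q end already claimed
    out = []
    k = params.word_size
    for i in range(qp.size):
        d = int(diag[i])
        q = int(qp[i])
        if covered.get(d, -1) > q:
            continue
        qs, qe, score = _extend(
            qlist, slist, q, q + k, int(sp[i]), k * params.match,
            params.match, params.mismatch, params.xdrop,
        )
        covered[d] = qe
        if score >= params.min_score:
            a = qarr[qs:qe]
            b = sarr[qs - d : qe - d]
            mism = int(np.count_nonzero((a != b) | (a < 0)))
            out.append((qs, qe, qs - d, score, mism))
    return out


def nucleotide_alignments(
    phage: SequenceRecord, host: SequenceRecord, params: NucleotideParams = NucleotideParams()
) -> list[LocalAlignment]:
    """All qualifying ungapped local alignments, both host strands."""
    qarr = encode(phage.seq)
    sarr = encode(host.seq)
    out = []
    for qs, qe, ss, score, mism in _strand_alignments(qarr, sarr, params):
        out.append(LocalAlignment(qs, qe, ss, ss + (qe - qs), 1, score, mism))
    rc = revcomp(sarr)
    n = sarr.size
    for qs, qe, ss, score, mism in _strand_alignments(qarr, rc, params):
        # map subject coords back to the forward axis
        out.append(LocalAlignment(qs, qe, n - (ss + (qe - qs)), n - ss, -1, score, mism))
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cs, ce = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def nucleotide_homology(
    phage: SequenceRecord, host: SequenceRecord, params: NucleotideParams = NucleotideParams()
) -> AlignmentSummary:
    """Union length of phage intervals covered by qualifying alignments."""
    hits = nucleotide_alignments(phage, host, params)
    return AlignmentSummary(
        phage_id=phage.id,
        host_id=host.id,
        total_aligned_len=_union_length([(h.qstart, h.qend) for h in hits]),
        best_bitlike_score=float(max((h.score for h in hits), default=0)),
    )


_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_BASE = len(_AA_ALPHABET) + 1  # 0 is the sentinel between proteins


@lru_cache(maxsize=1)
def _blosum() -> tuple[np.ndarray, np.ndarray]:
    """(encode LUT over ASCII, padded BLOSUM62 matrix with sentinel row)."""
    mat = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ALPHABET)
    scores = np.full((n + 1, n + 1), -1000, dtype=np.int64)  # index 0 = sentinel
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            scores[i + 1, j + 1] = int(mat[a][b])
    lut = np.zeros(256, dtype=np.int64)  # unknown chars -> sentinel 0
    for i, a in enumerate(_AA_ALPHABET):
        lut[ord(a)] = i + 1
    return lut, scores


def _encode_aa(pep: str) -> np.ndarray:
    lut, _ = _blosum()
    return lut[np.frombuffer(pep.encode("ascii"), dtype=np.uint8)]


def _aa_word_codes(arr: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-_AA_BASE word codes over an encoded peptide array; windows
    containing the sentinel (0) are invalid."""
    n = arr.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(w):
        codes = codes * _AA_BASE + arr[j : j + n]
    bad = (arr == 0).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[w:] - cs[:-w]) == 0
    pos = np.flatnonzero(valid)
    return codes[pos], pos


class ProteomeIndex:
    """Word index over one host's proteome for translated searches.

    Proteins are concatenated with sentinel separators so extensions can
    never cross a protein boundary (the sentinel scores -1000).
    """

    def __init__(self, host_id: str, proteins: list[tuple[str, str]], word_size: int = 4):
        if not proteins:
            raise ValueError("empty host protein set")
        self.host_id = host_id
        self.word_size = word_size
        parts = []
        for _, pep in proteins:
            parts.append(_encode_aa(pep))
            parts.append(np.zeros(1, dtype=np.int64))
        self.cat = np.concatenate(parts)
        codes, pos = _aa_word_codes(self.cat, word_size)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup(self, query_codes: np.ndarray, query_pos: np.ndarray):
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


def _extend_aa(q: list, s: list, q0: int, q1: int, s0: int,
               scores: list, xdrop: int) -> int:
    """Best ungapped X-drop score around an exact word seed (list-based)."""
    seed = 0
    for t in range(q1 - q0):
        seed += scores[q[q0 + t]][s[s0 + t]]
    best = seed
    run = seed
    i, j = q1, s0 + (q1 - q0)
    nq, ns = len(q), len(s)
    while i < nq and j < ns:
        run += scores[q[i]][s[j]]
        if run > best:
            best = run
        elif run <= best - xdrop:
            break
        i += 1
        j += 1
    run = best
    i, j = q0 - 1, s0 - 1
    while i >= 0 and j >= 0:
        run += scores[q[i]][s[j]]
        if run > best:
            best = run
        elif run <= best - xdrop:
            break
        i -= 1
        j -= 1
    return best


def translated_homology(
    phage: SequenceRecord,
    host_proteins: list[tuple[str, str]] | ProteomeIndex,
    params: ProteinParams = ProteinParams(),
    min_codons: int = 60,
) -> AlignmentSummary:
    """Count phage ORFs with a qualifying hit among the host's proteins.

    Each phage ORF (annotated CDS translation, or called ORFs otherwise)
    is compared against the host proteome by exact amino-acid word
    seeding plus ungapped BLOSUM62 X-drop extension; an ORF matches when
    its best alignment score reaches ``params.min_score``.
    """
    if isinstance(host_proteins, ProteomeIndex):
        index = host_proteins
    else:
        index = ProteomeIndex("" if not host_proteins else host_proteins[0][0].split("|")[0],
                              host_proteins, params.word_size)
    _, score_mat = _blosum()
    score_list = score_mat.tolist()
    cat_list = index.cat.tolist()
    w = params.word_size
    n_match = 0
    best_overall = 0.0
    for _, pep in orf_peptides(phage, min_codons):
        if len(pep) < w:
            continue
        qarr = _encode_aa(pep)
        qcodes, qpos = _aa_word_codes(qarr, w)
        qp, sp = index.lookup(qcodes, qpos)
        best = 0
        if qp.size:
            qlist = qarr.tolist()
            order = np.lexsort((qp, qp - sp))
            seen: dict[int, int] = {}
            for t in order:
                q, s = int(qp[t]), int(sp[t])
                d = q - s
                if seen.get(d, -1) > q:
                    continue
                score = _extend_aa(qlist, cat_list, q, q + w, s, score_list, params.xdrop)
                seen[d] = q + w
                if score > best:
                    best = score
        if best >= params.min_score:
            n_match += 1
        best_overall = max(best_overall, float(best))
    return AlignmentSummary(
        phage_id=phage.id,
        host_id=index.host_id,
        n_matching_proteins=n_match,
        best_bitlike_score=best_overall,
    )


def homology_scores(
    phages: list[SequenceRecord],
    hosts: list[SequenceRecord],
    mode: str = "nucleotide",
    nuc_params: NucleotideParams = NucleotideParams(),
    prot_params: ProteinParams = ProteinParams(),
    min_codons: int = 60,
) -> ScoreTable:
    """Full phage x host homology table (higher = better).

    Cells are aligned length (nucleotide) or matching-ORF count
    (translated); pairs with no qualifying alignment are no-evidence.
    """
    if mode not in ("nucleotide", "translated"):
        raise ValueError("mode must be 'nucleotide' or 'translated'")
    hids = [h.id for h in hosts]
    rows = {}
    if mode == "nucleotide":
        for phage in phages:
            row = []
            for host in hosts:
                v = nucleotide_homology(phage, host, nuc_params).total_aligned_len
                row.append(float(v) if v > 0 else np.nan)
            rows[phage.id] = row
        name = "homology_nucleotide"
    else:
        indexes = {}
        for h in hosts:
            prots = orf_peptides(h, min_codons)
            indexes[h.id] = ProteomeIndex(h.id, prots, prot_params.word_size) if prots else None
        for phage in phages:
            row = []
            for host in hosts:
                idx = indexes[host.id]
                if idx is None:
                    row.append(np.nan)
                    continue
                v = translated_homology(phage, idx, prot_params, min_codons).n_matching_proteins
                row.append(float(v) if v > 0 else np.nan)
            rows[phage.id] = row
        name = "homology_translated"
    return ScoreTable(
        scores=pd.DataFrame.from_dict(rows, orient="index", columns=hids),
        higher_is_better=True,
        name=name,
    )


_TABULAR_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _genome_of(seq_id: str) -> str:
    return seq_id.split("|")[0]


def read_tabular_hits(path, mode: str = "nucleotide") -> list[AlignmentSummary]:
    """Summarise a 12-column tabular alignment file.

    Nucleotide mode: query/subject ids are genome ids; per (phage, host)
    the 1-based inclusive query intervals are collapsed to their union
    length.  Translated mode: ids are ``genome|orf`` / ``genome|protein``
    and the summary counts distinct query ORFs with any hit.
    """
    if mode not in ("nucleotide", "translated"):
        raise ValueError("mode must be 'nucleotide' or 'translated'")
    groups: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TabularFormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise TabularFormatError(f"{path}: line {lineno}: {exc}") from None
            pair = (_genome_of(fields[0]), _genome_of(fields[1]))
            g = groups.setdefault(pair, {"intervals": [], "orfs": set(), "best": 0.0})
            lo, hi = min(qstart, qend), max(qstart, qend)
            g["intervals"].append((lo - 1, hi))  # 1-based inclusive -> half-open
            g["orfs"].add(fields[0])
            g["best"] = max(g["best"], bitscore)
    out = []
    for (pid, hid), g in sorted(groups.items()):
        out.append(
            AlignmentSummary(
                phage_id=pid,
                host_id=hid,
                total_aligned_len=_union_length(g["intervals"]) if mode == "nucleotide" else 0,
                n_matching_proteins=len(g["orfs"]) if mode == "translated" else 0,
                best_bitlike_score=g["best"],
            )
        )
    return out


def write_tabular_hits(
    phage: SequenceRecord, host: SequenceRecord, hits: list[LocalAlignment], path
) -> None:
    """Export internal nucleotide alignments in the 12-column layout."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.qend - h.qstart
            pident = 100.0 * (length - h.mismatches) / length if length else 0.0
            sstart, send = (h.sstart + 1, h.send) if h.strand == 1 else (h.send, h.sstart + 1)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            phage.id, host.id, f"{pident:.2f}", length, h.mismatches, 0,
                            h.qstart + 1, h.qend, sstart, send, 0.0, float(h.score),
                        ],
                    )
                )
                + "\n"
            )


def summaries_to_scoretable(
    summaries: list[AlignmentSummary],
    mode: str = "nucleotide",
    phage_ids: list[str] | None = None,
    host_ids: list[str] | None = None,
) -> ScoreTable:
    """Assemble summaries into a ScoreTable (pairs without hits are
    no-evidence)."""
    pids = phage_ids or sorted({s.phage_id for s in summaries})
    hids = host_ids or sorted({s.host_id for s in summaries})
    table = pd.DataFrame(np.nan, index=pids, columns=hids)
    for s in summaries:
        if s.phage_id in table.index and s.host_id in table.columns:
            value = s.total_aligned_len if mode == "nucleotide" else s.n_matching_proteins
            if value > 0:
                table.loc[s.phage_id, s.host_id] = float(value)
    name = "homology_nucleotide" if mode == "nucleotide" else "homology_translated"
    return ScoreTable(scores=table, higher_is_better=True, name=name)
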