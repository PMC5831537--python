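"""Synthetic phage-host benchmark with planted ground truth.

Generates a self-contained benchmark in which every host signal is
planted by an explicit mechanism, so each signal module can be tested
against known truth without any external data:

* hosts are drawn from per-host dinucleotide (first-order Markov)
  backgrounds, making composition signals learnable;
* each phage gets exactly one true host and one planting mode:
  ``prophage`` copies a long phage segment verbatim into the host,
  ``shared_gene`` plants one gene in the host and a diverged copy in the
  phage, ``spacer_donor`` inserts a CRISPR array into the host whose
  spacers are phage substrings, ``composition_only`` ameliorates the
  phage's composition towards the host's dinucleotide model, and
  ``abundance_only`` leaves sequences unrelated and couples only the
  abundance profiles;
* abundance profiles are sparse log-normals; a phage is zeroed wherever
  its host is absent, and only ``abundance_only`` phages are additionally
  coupled to their host's abundance values, keeping each planted
  mechanism recoverable by exactly one signal;
* hosts are grouped into a balanced toy taxonomy (genera of 2 species,
  families of 4, ...) so rank-nesting invariants hold exactly.

Everything is deterministic under the master seed; rebuilding a bundle
with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._kmers import BASES, decode, encode
from .sequence import SequenceRecord, write_fasta, read_fasta
from .taxonomy import Lineage, load_lineage_table, save_lineage_table

__all__ = [
    "FixtureConfig",
    "Bundle",
    "MODES",
    "make_hosts",
    "make_phage",
    "simulate_abundance",
    "build_benchmark",
    "save_bundle",
    "load_bundle",
]

MODES = ("prophage", "shared_gene", "spacer_donor", "composition_only", "abundance_only")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FixtureConfig:
    """Benchmark dimensions and per-mechanism planting strengths.

    Defaults are sized so the full benchmark (generation plus every
    signal) runs in a few minutes on one CPU while keeping each planted
    mechanism clearly recoverable.
    """

    n_hosts: int = 20
    host_len: int = 40_000
    n_phages: int = 40
    phage_len: int = 15_000
    host_bias: float = 1.0  # 0 = all hosts share a uniform background
    amelioration: float = 1.0  # weight of host dinucleotide model in composition_only phages
    prophage_fraction: float = 0.8  # fraction of the phage copied into the host
    shared_gene_len: int = 900
    shared_gene_divergence: float = 0.05
    n_spacers: int = 3
    spacer_len: int = 32
    spacer_mismatches: tuple[int, ...] = (0, 1, 2)  # per planted spacer, cycled
    crispr_repeat_len: int = 28
    n_samples: int = 40
    presence: float = 0.75  # per-sample probability a host is present
    coupling: float = 0.9  # abundance coupling for abundance_only phages
    phage_dropout: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("host_bias", "amelioration", "prophage_fraction",
                     "shared_gene_divergence", "presence", "coupling", "phage_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_hosts", "host_len", "n_phages", "phage_len", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Bundle:
    """An in-memory benchmark: records, truth, taxonomy and abundances."""

    hosts: list[SequenceRecord]
    phages: list[SequenceRecord]
    truth: dict[str, str]  # phage id -> true host id
    modes: dict[str, str]  # phage id -> planting mode
    lineages: dict[str, Lineage]
    phage_abundance: pd.DataFrame
    host_abundance: pd.DataFrame
    manifest: dict


def _markov_matrix(bias: float, rng: np.random.Generator) -> np.ndarray:
    """Per-host dinucleotide transition matrix: uniform background mixed
    with a host-specific Dirichlet draw, weighted by the bias strength."""
    hostly = rng.dirichlet(np.ones(4), size=4)
    return (1.0 - bias) * np.full((4, 4), 0.25) + bias * hostly


def _markov_seq(T: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    cum[:, 3] = 1.0 + 1e-12
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    state = int(rng.integers(4))
    rows = [tuple(cum[s]) for s in range(4)]
    for i in range(length):
        row = rows[state]
        x = u[i]
        state = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = state
    return out


def _uniform_seq(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.int8))


def _estimate_transitions(seq: str) -> np.ndarray:
    """Dinucleotide transition matrix observed in a sequence (+1 smoothing)."""
    arr = encode(seq)
    a, b = arr[:-1], arr[1:]
    ok = (a >= 0) & (b >= 0)
    counts = np.ones((4, 4))
    np.add.at(counts, (a[ok], b[ok]), 1)
    return counts / counts.sum(axis=1, keepdims=True)


def _host_lineage(i: int) -> Lineage:
    return Lineage(
        species=f"Species_{i}",
        genus=f"Genus_{i // 2}",
        family=f"Family_{i // 4}",
        order=f"Order_{i // 8}",
        class_=f"Class_{i // 16}",
        phylum=f"Phylum_{i // 32}",
    )


def make_hosts(
    config: FixtureConfig, rng: np.random.Generator
) -> tuple[list[SequenceRecord], dict[str, Lineage]]:
    """Host genomes from per-host dinucleotide backgrounds plus a
    balanced-tree toy taxonomy (2 species/genus, 2 genera/family, ...)."""
    hosts, lineages = [], {}
    for i in range(config.n_hosts):
        T = _markov_matrix(config.host_bias, rng)
        seq = decode(_markov_seq(T, config.host_len, rng))
        hid = f"host{i:03d}"
        hosts.append(SequenceRecord(id=hid, seq=seq))
        lineages[hid] = _host_lineage(i)
    return hosts, lineages


def _random_gene(length: int, rng: np.random.Generator) -> str:
    """An ORF-shaped gene: start codon, stop-free body, terminal stop."""
    if length % 3 or length < 9:
        raise ValueError("gene length must be a multiple of 3, >= 9")
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        c = "".join(BASES[b] for b in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = encode(seq).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        arr[i] = (arr[i] + int(rng.integers(1, 4))) % 4
    return decode(arr)


def _mutate_n(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    arr = encode(seq).copy()
    pos = rng.choice(arr.size, size=n_subs, replace=False) if n_subs else []
    for i in pos:
        arr[i] = (arr[i] + int(rng.integers(1, 4))) % 4
    return decode(arr)


def _splice(seq: str, pos: int, insert: str) -> str:
    """Replace a slice of ``seq`` with ``insert`` (length preserved)."""
    return seq[:pos] + insert + seq[pos + len(insert):]


def _free_position(
    host_len: int, insert_len: int, reserved: list[tuple[int, int]] | None,
    rng: np.random.Generator,
) -> int:
    """A start position whose span avoids previously planted intervals.

    Hosts carry material from several phages; overwriting an earlier
    plant would corrupt its ground truth.  Rejection-samples, falling
    back to an arbitrary position only if the host is too crowded.
    """
    for _ in range(200):
        pos = int(rng.integers(0, host_len - insert_len + 1))
        if not reserved or all(pos + insert_len <= s or pos >= e for s, e in reserved):
            return pos
    return int(rng.integers(0, host_len - insert_len + 1))


def make_phage(
    host: SequenceRecord,
    config: FixtureConfig,
    mode: str,
    rng: np.random.Generator,
    phage_id: str,
    reserved: list[tuple[int, int]] | None = None,
) -> tuple[SequenceRecord, str]:
    """Build one phage for ``host`` under a planting mode.

    Returns the phage record and the (possibly modified) host sequence:
    prophage, shared_gene and spacer_donor plant material into the host.
    ``reserved`` lists host intervals already planted by earlier phages;
    new material avoids them and extends the list in place.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    L = config.phage_len
    host_seq = host.seq
    if reserved is None:
        reserved = []

    if mode == "composition_only":
        T_host = _estimate_transitions(host.seq)
        T = (1.0 - config.amelioration) * np.full((4, 4), 0.25) + config.amelioration * T_host
        phage_seq = decode(_markov_seq(T, L, rng))
    else:
        phage_seq = _uniform_seq(L, rng)

    if mode == "prophage":
        seg_len = max(1, int(round(config.prophage_fraction * L)))
        ppos = int(rng.integers(0, L - seg_len + 1))
        hpos = _free_position(len(host_seq), seg_len, reserved, rng)
        host_seq = _splice(host_seq, hpos, phage_seq[ppos : ppos + seg_len])
        reserved.append((hpos, hpos + seg_len))
    elif mode == "shared_gene":
        gene = _random_gene(config.shared_gene_len, rng)
        ppos = int(rng.integers(0, L - len(gene) + 1))
        hpos = _free_position(len(host_seq), len(gene), reserved, rng)
        phage_seq = _splice(phage_seq, ppos, _mutate(gene, config.shared_gene_divergence, rng))
        host_seq = _splice(host_seq, hpos, gene)
        reserved.append((hpos, hpos + len(gene)))
    elif mode == "spacer_donor":
        repeat = _uniform_seq(config.crispr_repeat_len, rng)
        step = L // (config.n_spacers + 1)
        pieces = [repeat]
        for j in range(config.n_spacers):
            start = j * step + int(rng.integers(0, max(1, step - config.spacer_len)))
            spacer = phage_seq[start : start + config.spacer_len]
            n_mm = config.spacer_mismatches[j % len(config.spacer_mismatches)]
            pieces.append(_mutate_n(spacer, n_mm, rng))
            pieces.append(repeat)
        array = "".join(pieces)
        hpos = _free_position(len(host_seq), len(array), reserved, rng)
        host_seq = _splice(host_seq, hpos, array)
        reserved.append((hpos, hpos + len(array)))

    return SequenceRecord(id=phage_id, seq=phage_seq), host_seq


def simulate_abundance(
    truth: dict[str, str],
    modes: dict[str, str],
    hosts: list[str],
    config: FixtureConfig,
    rng: np.random.Generator,
    coupling_override: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coupled sparse abundance matrices.

    Host log-abundances are standard normal with Bernoulli presence; a
    phage's log-abundance is ``c * host + (1 - c) * noise`` with c the
    coupling (``config.coupling`` for abundance_only phages, 0 otherwise,
    unless overridden), zeroed wherever the host is absent and further
    thinned by the phage dropout rate.
    """
    samples = [f"s{j:03d}" for j in range(config.n_samples)]
    host_ln = rng.normal(0.0, 1.0, size=(len(hosts), config.n_samples))
    host_present = rng.random((len(hosts), config.n_samples)) < config.presence
    host_ab = np.where(host_present, np.exp(host_ln), 0.0)
    host_df = pd.DataFrame(host_ab, index=hosts, columns=samples)

    host_row = {h: i for i, h in enumerate(hosts)}
    pids = list(truth)
    phage_ab = np.zeros((len(pids), config.n_samples))
    for i, pid in enumerate(pids):
        hi = host_row[truth[pid]]
        if coupling_override is not None:
            c = coupling_override
        else:
            c = config.coupling if modes.get(pid) == "abundance_only" else 0.0
        eps = rng.normal(0.0, 1.0, size=config.n_samples)
        ln = c * host_ln[hi] + (1.0 - c) * eps
        keep = host_present[hi] & (rng.random(config.n_samples) >= config.phage_dropout)
        phage_ab[i] = np.where(keep, np.exp(ln), 0.0)
    return pd.DataFrame(phage_ab, index=pids, columns=samples), host_df


def build_benchmark(config: FixtureConfig | None = None) -> Bundle:
    """Deterministically build the full benchmark bundle in memory.

    Phages are assigned to hosts round-robin and to planting modes in
    rotation, so every mechanism is represented evenly.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    hosts, lineages = make_hosts(config, rng)
    truth: dict[str, str] = {}
    modes: dict[str, str] = {}
    phages: list[SequenceRecord] = []
    host_seqs = {h.id: h.seq for h in hosts}
    reserved: dict[str, list[tuple[int, int]]] = {h.id: [] for h in hosts}
    for i in range(config.n_phages):
        host = hosts[i % config.n_hosts]
        host.seq = host_seqs[host.id]  # current (possibly already edited) sequence
        mode = MODES[i % len(MODES)]
        pid = f"phage{i:03d}"
        phage, new_host_seq = make_phage(host, config, mode, rng, pid, reserved[host.id])
        host_seqs[host.id] = new_host_seq
        phages.append(phage)
        truth[pid] = host.id
        modes[pid] = mode
    for h in hosts:
        h.seq = host_seqs[h.id]
    phage_ab, host_ab = simulate_abundance(
        truth, modes, [h.id for h in hosts], config, rng
    )
    manifest = {
        "config": asdict(config),
        "phages": [{"id": p, "host": truth[p], "mode": modes[p]} for p in truth],
    }
    return Bundle(
        hosts=hosts,
        phages=phages,
        truth=truth,
        modes=modes,
        lineages=lineages,
        phage_abundance=phage_ab,
        host_abundance=host_ab,
        manifest=manifest,
    )


def save_bundle(bundle: Bundle, outdir: str | os.PathLike) -> None:
    """Write the bundle as FASTA/TSV/JSON files readable by every module."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.hosts, out / "hosts.fasta")
    write_fasta(bundle.phages, out / "phages.fasta")
    save_lineage_table(bundle.lineages, out / "lineages.tsv")
    pd.DataFrame(
        [(p, bundle.truth[p], bundle.modes[p]) for p in bundle.truth],
        columns=["phage", "host", "mode"],
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    from .abundance import write_abundance_tsv

    write_abundance_tsv(bundle.phage_abundance, out / "abundance_phage.tsv")
    write_abundance_tsv(bundle.host_abundance, out / "abundance_host.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_bundle(indir: str | os.PathLike) -> Bundle:
    """Read a saved bundle back into memory."""
    from .abundance import read_abundance_tsv

    ind = Path(indir)
    with open(ind / "manifest.json") as fh:
        manifest = json.load(fh)
    truth_df = pd.read_csv(ind / "truth.tsv", sep="\t", dtype=str)
    truth = dict(zip(truth_df["phage"], truth_df["host"]))
    modes = dict(zip(truth_df["phage"], truth_df["mode"]))
    return Bundle(
        hosts=read_fasta(ind / "hosts.fasta"),
        phages=read_fasta(ind / "phages.fasta"),
        truth=truth,
        modes=modes,
        lineages=load_lineage_table(ind / "lineages.tsv"),
        phage_abundance=read_abundance_tsv(ind / "abundance_phage.tsv"),
        host_abundance=read_abundance_tsv(ind / "abundance_host.tsv"),
        manifest=manifest,
    )
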