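"""Shared fixtures and independent oracles for the test suite.

The session-scoped ``default_bundle``/``default_report`` fixtures build
the full synthetic benchmark once (default FixtureConfig, fixed seed)
and run every signal over it; the end-to-end tests all read from these.
Oracle helpers here are deliberately independent of the implementation
paths they check (diagonal-scan longest common substring, hand-rolled
Pearson, codon-table translation).
"""

from __future__ import annotations

import numpy as np
import pytest

from phagehost.benchmark import run_benchmark
from phagehost.simulate import FixtureConfig, build_benchmark

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# --- independent oracles -------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def lcs_length(a: str, b: str) -> int:
    """Longest common substring by per-diagonal run scanning (O(nm))."""
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    best = 0
    for d in range(-(len(b) - 1), len(a)):
        if d >= 0:
            x, y = A[d:], B[: len(A) - d]
        else:
            x, y = A[: len(B) + d], B[-d:]
        n = min(len(x), len(y))
        if n <= best:
            continue
        eq = x[:n] == y[:n]
        if eq.any():
            idx = np.flatnonzero(~eq)
            runs = np.diff(np.r_[-1, idx, n]) - 1
            best = max(best, int(runs.max()))
    return best


def lcs_length_both_strands(a: str, b: str) -> int:
    return max(lcs_length(a, b), lcs_length(a, naive_revcomp(b)))


_CODON_TABLE = {}


def _build_codon_table():
    # independent of Biopython: standard code spelled out
    aas = (
        "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLL"
        "EDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
    )
    order = "ACGT"
    idx = 0
    for b1 in order:
        for b2 in order:
            for b3 in order:
                _CODON_TABLE[b1 + b2 + b3] = None
                idx += 1
    # fill from a canonical listing instead (simpler to verify by eye)
    listing = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
    _CODON_TABLE.update(listing)


_build_codon_table()


def table_translate(seq: str) -> str:
    """Codon-dict translation oracle (stops '*', N-codons 'X')."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X") or "X")
    return "".join(out)


def naive_pearson(x, y) -> float:
    """Direct covariance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return float(cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))


# --- session fixtures ----------------------------------------------------


@pytest.fixture(scope="session")
def default_bundle():
    """The full synthetic benchmark at the default configuration."""
    return build_benchmark(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    """All signals run once over the default benchmark."""
    return run_benchmark(default_bundle)


@pytest.fixture(scope="session")
def tiny_bundle():
    """A miniature bundle for cheap I/O and CLI tests."""
    return build_benchmark(
        FixtureConfig(
            n_hosts=5, host_len=4000, n_phages=5, phage_len=1500,
            shared_gene_len=300, n_samples=20, seed=3,
        )
    )
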