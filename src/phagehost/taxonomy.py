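"""Host lineages and rank-level agreement.

Predictions are scored at six taxonomic ranks (species, genus, family,
order, class, phylum).  Lineages come from a flat TSV table rather than
live taxonomy queries so benchmarks are fully self-contained; names are
matched case-insensitively as exact strings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

RANKS = ("species", "genus", "family", "order", "class", "phylum")


class LineageTableError(ValueError):
    """Raised for malformed lineage tables (bad header, duplicate taxa)."""


@dataclass(frozen=True)
class Lineage:
    species: str | None = None
    genus: str | None = None
    family: str | None = None
    order: str | None = None
    class_: str | None = None
    phylum: str | None = None

    def name_at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)


def load_lineage_table(path: str | os.PathLike) -> dict[str, Lineage]:
    """Load a TSV with header ``taxon<TAB>species<TAB>...<TAB>phylum``.

    Empty cells become absent ranks; duplicate taxon rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["taxon", *RANKS]
    if list(df.columns) != expected:
        raise LineageTableError(
            f"lineage table header must be {expected}, got {list(df.columns)}"
        )
    if df["taxon"].duplicated().any():
        dup = df["taxon"][df["taxon"].duplicated()].iloc[0]
        raise LineageTableError(f"duplicate taxon row {dup!r}")
    out: dict[str, Lineage] = {}
    for rec in df.to_dict("records"):
        out[rec["taxon"]] = Lineage(
            **{("class_" if r == "class" else r): (rec[r] or None) for r in RANKS}
        )
    return out


def save_lineage_table(lineages: dict[str, Lineage], path: str | os.PathLike) -> None:
    rows = []
    for taxon in lineages:
        lin = lineages[taxon]
        rows.append([taxon] + [(lin.name_at(r) or "") for r in RANKS])
    pd.DataFrame(rows, columns=["taxon", *RANKS]).to_csv(path, sep="\t", index=False)


def ranks_shared(predicted: Lineage, truth: Lineage) -> set[str]:
    """Ranks at which both lineages carry the same (case-folded) name."""
    shared = set()
    for rank in RANKS:
        a, b = predicted.name_at(rank), truth.name_at(rank)
        if a is not None and b is not None and a.casefold() == b.casefold():
            shared.add(rank)
    return shared
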