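"""Polarized single-nucleotide differences (SNDs).

Given a column-aligned triple (target, query, outgroup) this module emits
one record per site where target != query and the outgroup matches exactly
one of them: the lineage the outgroup does *not* match carries the derived
allele. Sites where the outgroup matches neither or carries a fourth
allele are discarded — no parsimony rescue, so every emitted polarization
is forced. A substitution is weak-to-strong (W->S) when the ancestral base
is A/T and the derived base is G/C, the signature amplified by GC-biased
gene conversion near (neo-)telomeres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

VALID_BASES = frozenset("ACGT")
WEAK = frozenset("AT")
STRONG = frozenset("GC")
LINEAGES = ("target", "query")


@dataclass(frozen=True)
class SNDRecord:
    """One polarized single-nucleotide difference on target coordinates."""

    chrom: str
    pos: int  # 0-based, target genome
    target_base: str
    query_base: str
    outgroup_base: str
    derived_lineage: str  # "target" or "query"
    ws: bool  # weak-to-strong (AT -> GC) substitution

    @property
    def ancestral_base(self) -> str:
        return self.query_base if self.derived_lineage == "target" else self.target_base

    @property
    def derived_base(self) -> str:
        return self.target_base if self.derived_lineage == "target" else self.query_base


def classify_ws(ancestral: str, derived: str) -> bool:
    """True iff the substitution replaces a weak (A/T) base with a strong (G/C) one."""
    return ancestral in WEAK and derived in STRONG


def polarize_snds(
    target_seq: str,
    query_seq: str,
    outgroup_seq: str,
    chrom: str = "chr1",
    offset: int = 0,
) -> list[SNDRecord]:
    """Call and polarize SNDs from three equal-length aligned sequences.

    Any column containing a non-ACGT character (gap, N, ambiguity code) in
    any of the three sequences is skipped. ``offset`` shifts reported
    positions, for alignments that cover a slice of the chromosome.
    """
    if not (len(target_seq) == len(query_seq) == len(outgroup_seq)):
        raise ValueError(
            "aligned sequences must have equal lengths, got "
            f"{len(target_seq)}/{len(query_seq)}/{len(outgroup_seq)}"
        )
    records: list[SNDRecord] = []
    for i, (t, q, o) in enumerate(
        zip(target_seq.upper(), query_seq.upper(), outgroup_seq.upper())
    ):
        if t == q:
            continue
        if t not in VALID_BASES or q not in VALID_BASES or o not in VALID_BASES:
            continue
        if o == t:
            derived, anc, der = "query", t, q
        elif o == q:
            derived, anc, der = "target", q, t
        else:
            continue  # outgroup matches neither: unpolarizable
        records.append(
            SNDRecord(chrom, offset + i, t, q, o, derived, classify_ws(anc, der))
        )
    return records


# ---------------------------------------------------------------------------
# SND table I/O (TSV)
# ---------------------------------------------------------------------------

_COLUMNS = ["chrom", "pos", "target", "query", "outgroup", "derived_lineage", "ws"]


def write_snd_table(path: str | os.PathLike, records: Iterable[SNDRecord]) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.pos, r.target_base, r.query_base, r.outgroup_base,
             r.derived_lineage, int(r.ws))
            for r in records
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_snd_table(path: str | os.PathLike) -> list[SNDRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "derived_lineage": str}
    )
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    records: list[SNDRecord] = []
    for row in df.itertuples(index=False):
        if row.derived_lineage not in LINEAGES:
            raise ValueError(
                f"{path}: unknown lineage token {row.derived_lineage!r}"
            )
        records.append(
            SNDRecord(
                row.chrom, int(row.pos), row.target, row.query, row.outgroup,
                row.derived_lineage, bool(int(row.ws)),
            )
        )
    return records
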