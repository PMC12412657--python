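"""File formats and coordinate conventions.

Everything internal is 0-based, half-open. The only places 1-based
coordinates appear are the VCF boundary (POS) and samtools-style region
strings ("chr1:1-100", 1-based inclusive), both converted on entry.

Readers/writers here cover the formats the pipeline touches: FASTA
(via Bio.SeqIO, wrapped at 60 columns on write), a VCF v4.2 subset with
GT:DP:GQ FORMAT fields (via pysam), BED3+label region files, synteny
block TSVs, and position-weight-matrix TSVs for splicing-factor motifs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1  # missing allele code in genotype tuples

REGION_LABELS = {
    "breakpoint_flank",
    "telomeric",
    "control",
    "fissioned",
    "other",
}


class FormatError(ValueError):
    """Malformed input file or record."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SyntenyBlock:
    """One collinear alignment block between two genomes (0-based half-open)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or min(self.ref_start, self.query_start) < 0:
            raise FormatError(
                f"invalid synteny block {self.ref_chrom}:{self.ref_start}-{self.ref_end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class VariantRecord:
    """One VCF record restricted to the fields the pipeline consumes.

    ``pos`` is 0-based internally; the VCF boundary converts. Genotypes are
    tuples of allele indices with :data:`MISSING` for uncalled alleles.
    ``alts`` keeps every ALT allele so multiallelic records stay visible to
    the documented filter instead of being dropped at parse time.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[int, int]]
    depths: list[int | None]
    quals: list[int | None]
    samples: list[str]
    var_id: str = "."

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def alt(self) -> str:
        return self.alts[0]


@dataclass
class PWMatrix:
    """Position score matrix for a splicing-factor motif.

    ``scores`` has shape (width, 4) in A, C, G, T order; a window's score is
    the sum of per-position weights; a hit passes iff score >= threshold.
    """

    factor: str
    scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4 or self.scores.shape[0] < 1:
            raise FormatError(f"PWM for {self.factor}: need shape (width>=1, 4)")
        if not np.isfinite(self.scores).all():
            raise FormatError(f"PWM for {self.factor}: non-finite weight")

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])

    def score_word(self, word: str) -> float:
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != width {self.width}")
        idx = [_BASE_INDEX[b] for b in word.upper()]
        return float(self.scores[np.arange(self.width), idx].sum())


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, uppercased sequence) pairs.

    Order is preserved. Duplicate record names and empty sequences are
    errors: both indicate a malformed input that downstream coordinate
    arithmetic would silently mangle.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA record name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as FASTA, wrapped at 60 columns."""
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Region strings and BED
# ---------------------------------------------------------------------------


def parse_region(text: str, label: str = "other") -> RegionSpec:
    """Parse a samtools-style region string ("chr1:1-100", 1-based inclusive).

    Returns a 0-based half-open :class:`RegionSpec`:
    start = start1 - 1, end = end1.
    """
    try:
        chrom, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError as exc:
        raise FormatError(f"cannot parse region string {text!r}") from exc
    if end1 < start1 or start1 < 1:
        raise FormatError(f"region {text!r}: end < start or start < 1")
    return RegionSpec(chrom, start1 - 1, end1, label)


def read_bed(path: str | os.PathLike) -> list[RegionSpec]:
    """Read BED3+label (label defaults to "other" when column 4 is absent)."""
    regions: list[RegionSpec] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line has <3 columns")
            try:
                regions.append(
                    RegionSpec(
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        parts[3] if len(parts) > 3 else "other",
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return regions


def write_bed(path: str | os.PathLike, regions: Iterable[RegionSpec]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | os.PathLike, samples: Sequence[str] | None = None) -> list[VariantRecord]:
    """Read a VCF (v4.x text) into :class:`VariantRecord` objects.

    ``samples`` restricts and orders the genotype columns; requesting a
    sample absent from the header raises naming the sample. Multiallelic
    records are retained (flagged via ``is_multiallelic``) — removal is the
    filter's job, so the audit trail stays complete.
    """
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if samples is None:
            samples = header_samples
        else:
            missing = [s for s in samples if s not in header_samples]
            if missing:
                raise FormatError(
                    f"sample(s) {missing} not in VCF header of {path}"
                )
        out: list[VariantRecord] = []
        for rec in vf:
            gts: list[tuple[int, int]] = []
            dps: list[int | None] = []
            gqs: list[int | None] = []
            for s in samples:
                sm = rec.samples[s]
                raw = sm.get("GT", (None, None))
                if raw is None or len(raw) == 0:
                    raw = (None, None)
                if len(raw) == 1:  # haploid entry; duplicate defensively
                    raw = (raw[0], raw[0])
                gts.append(tuple(MISSING if a is None else int(a) for a in raw))
                dp = sm.get("DP")
                gq = sm.get("GQ")
                dps.append(None if dp is None else int(dp))
                gqs.append(None if gq is None else int(gq))
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,  # pysam .pos is 1-based
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotypes=gts,
                    depths=dps,
                    quals=gqs,
                    samples=list(samples),
                    var_id=rec.id or ".",
                )
            )
    return out


def write_vcf(
    path: str | os.PathLike,
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    contigs: dict[str, int],
) -> None:
    """Write VariantRecords as VCF v4.2 with GT:DP:GQ FORMAT fields."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(
                contig=r.chrom,
                start=r.pos,
                stop=r.pos + len(r.ref),
                alleles=(r.ref, *r.alts),
            )
            for i, s in enumerate(samples):
                gt = tuple(None if a == MISSING else a for a in r.genotypes[i])
                rec.samples[s]["GT"] = gt
                if r.depths[i] is not None:
                    rec.samples[s]["DP"] = r.depths[i]
                if r.quals[i] is not None:
                    rec.samples[s]["GQ"] = r.quals[i]
            vf.write(rec)


# ---------------------------------------------------------------------------
# Synteny TSV
# ---------------------------------------------------------------------------

SYNTENY_COLUMNS = [
    "ref_chrom",
    "ref_start",
    "ref_end",
    "query_chrom",
    "query_start",
    "query_end",
    "strand",
]

DEFAULT_MIN_BLOCK_LEN = 8_000  # alignments shorter than 8 kb are discarded


def read_synteny_blocks(
    path: str | os.PathLike, min_len: int = DEFAULT_MIN_BLOCK_LEN
) -> list[SyntenyBlock]:
    """Read a 7-column synteny TSV, dropping blocks shorter than ``min_len``.

    The default 8-kb floor discards alignment noise; block length is
    measured on the reference (ref_end - ref_start).
    """
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[: len(SYNTENY_COLUMNS)] == SYNTENY_COLUMNS:
                continue  # header row
            if len(parts) < 7:
                raise FormatError(f"{path}:{ln}: synteny row has <7 columns")
            try:
                blk = SyntenyBlock(
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]), parts[6],
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            if blk.length >= min_len:
                blocks.append(blk)
    return blocks


def write_synteny_blocks(path: str | os.PathLike, blocks: Iterable[SyntenyBlock]) -> None:
    df = pd.DataFrame(
        [
            (b.ref_chrom, b.ref_start, b.ref_end, b.query_chrom,
             b.query_start, b.query_end, b.strand)
            for b in blocks
        ],
        columns=SYNTENY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWM TSV
# ---------------------------------------------------------------------------


def read_pwm(path: str | os.PathLike, factor: str, threshold: float) -> PWMatrix:
    """Read one PWM TSV with header row ``pos A C G T``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expect = ["pos", "A", "C", "G", "T"]
    if list(df.columns) != expect:
        raise FormatError(f"{path}: PWM header must be {expect}, got {list(df.columns)}")
    df = df.sort_values("pos")
    return PWMatrix(factor, df[["A", "C", "G", "T"]].to_numpy(float), threshold)


def write_pwm(path: str | os.PathLike, matrix: PWMatrix) -> None:
    df = pd.DataFrame(matrix.scores, columns=["A", "C", "G", "T"])
    df.insert(0, "pos", np.arange(1, matrix.width + 1))
    df.to_csv(path, sep="\t", index=False)


def load_packaged_ese_matrices() -> dict[str, PWMatrix]:
    """Load the SR-protein matrices shipped with the package.

    The matrices are synthetic stand-ins (see data/ese_matrices/README.md):
    consensus-anchored log-odds built for this package, not the original
    web-tool tables.
    """
    here = os.path.join(os.path.dirname(__file__), "data", "ese_matrices")
    thr = pd.read_csv(os.path.join(here, "thresholds.tsv"), sep="\t")
    out: dict[str, PWMatrix] = {}
    for _, row in thr.iterrows():
        factor = str(row["factor"])
        out[factor] = read_pwm(
            os.path.join(here, f"{factor.lower()}.tsv"), factor, float(row["threshold"])
        )
    return out
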