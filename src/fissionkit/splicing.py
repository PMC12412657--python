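"""Exonic splicing enhancer (ESE) scoring and exon-skipping consequences.

SR proteins (SRSF1/2/5/6) bind short exonic motifs that promote exon
inclusion; a point mutation that drops the best motif score below the
factor's decision threshold can cause the spliceosome to skip the exon.
Skipping an exon whose coding length is not a multiple of three shifts
the reading frame, usually introducing a premature termination codon
(PTC) that truncates every downstream protein domain.

Motifs are scored with position weight matrices: a window's score is the
sum of per-position weights and a hit passes iff score >= threshold.
Matrices are strand-specific — scanning the reverse complement is a
different computation, not a mirrored one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .formats import PWMatrix

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Exon:
    exon_id: int
    start: int  # genomic, 0-based half-open
    end: int
    seq: str  # transcript-orientation sequence, length == end - start

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError(
                f"exon {self.exon_id}: sequence length {len(self.seq)} != "
                f"coordinate span {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Ordered exons, a CDS start anchor, and domain-to-exon annotations."""

    exons: list[Exon]
    cds_start: tuple[int, int]  # (exon_id, offset within exon)
    strand: str = "+"
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> (first, last exon id)

    def __post_init__(self) -> None:
        ids = [e.exon_id for e in self.exons]
        if ids != sorted(ids) or len(set(ids)) != len(ids):
            raise ValueError("exons must be ordered with unique ids")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError("exons must be non-overlapping and ordered")
        if self.cds_start[0] not in set(ids):
            raise ValueError(f"CDS start exon {self.cds_start[0]} not in model")
        ex = self.exon(self.cds_start[0])
        if not (0 <= self.cds_start[1] < ex.length):
            raise ValueError("CDS start offset outside its exon")
        if len(self.cds_seq()) < 3:
            raise ValueError("CDS shorter than one codon")

    def exon(self, exon_id: int) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(f"no exon {exon_id}")

    def transcript_seq(self, skip: int | None = None) -> str:
        return "".join(e.seq for e in self.exons if e.exon_id != skip)

    def _tx_pos(self, exon_id: int, offset: int, skip: int | None = None) -> int:
        """Transcript coordinate of (exon, offset) in the chosen isoform."""
        pos = 0
        for e in self.exons:
            if e.exon_id == skip:
                continue
            if e.exon_id == exon_id:
                return pos + offset
            pos += e.length
        raise KeyError(f"exon {exon_id} absent from isoform (skip={skip})")

    def cds_seq(self, skip: int | None = None) -> str:
        tx = self.transcript_seq(skip)
        return tx[self._tx_pos(*self.cds_start, skip=skip):]

    def exon_at_tx_pos(self, pos: int, skip: int | None = None) -> int:
        """Original exon id containing a transcript coordinate of an isoform."""
        cur = 0
        for e in self.exons:
            if e.exon_id == skip:
                continue
            if cur <= pos < cur + e.length:
                return e.exon_id
            cur += e.length
        raise IndexError(f"transcript position {pos} beyond isoform end")

    def cds_overlap_of_exon(self, exon_id: int) -> int:
        """Number of coding bases the exon contributes to the full-length CDS."""
        cds_start_tx = self._tx_pos(*self.cds_start)
        cds = self.cds_seq()
        stop_at = _first_stop(cds)
        cds_end_tx = cds_start_tx + (stop_at + 3 if stop_at is not None else len(cds))
        exon_start_tx = self._tx_pos(exon_id, 0)
        exon_end_tx = exon_start_tx + self.exon(exon_id).length
        return max(0, min(exon_end_tx, cds_end_tx) - max(exon_start_tx, cds_start_tx))


@dataclass(frozen=True)
class ESEHit:
    factor: str
    position: int  # 0-based start of the matched window
    word: str
    score: float
    passes_threshold: bool


@dataclass(frozen=True)
class SkippingConsequence:
    skipped_exon_id: int
    frame_preserving: bool
    ptc: tuple[int, int] | None  # (original exon id, CDS coordinate of stop)
    truncated_domains: list[tuple[str, str]]  # (name, "lost"|"partially_truncated")
    inclusion_amplicon_bp: int | None = None
    exclusion_amplicon_bp: int | None = None


def _first_stop(cds: str) -> int | None:
    """CDS coordinate (0-based, multiple of 3) of the first in-frame stop."""
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return i
    return None


# ---------------------------------------------------------------------------
# ESE scanning
# ---------------------------------------------------------------------------


def scan_ese(
    seq: str,
    matrices: Mapping[str, PWMatrix],
    passing_only: bool = True,
) -> list[ESEHit]:
    """Score every window of each matrix's width along ``seq``.

    Returns passing hits by default; with ``passing_only=False`` every
    window's score is returned. Sequences shorter than a matrix's width
    yield no hits for that matrix.
    """
    seq = seq.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be ACGT-only")
    hits: list[ESEHit] = []
    for factor, m in matrices.items():
        for i in range(0, len(seq) - m.width + 1):
            word = seq[i : i + m.width]
            score = m.score_word(word)
            passes = score >= m.threshold
            if passes or not passing_only:
                hits.append(ESEHit(factor, i, word, score, passes))
    hits.sort(key=lambda h: (h.position, h.factor))
    return hits


def mutation_ese_impact(
    seq: str,
    pos: int,
    alt_base: str,
    matrices: Mapping[str, PWMatrix],
) -> dict[str, dict]:
    """Best motif score overlapping ``pos`` before vs after a point mutation.

    Classification per factor: "disrupted" when the wild type passes the
    threshold and the mutant does not; "created" for the reverse; else
    "neutral". The raw score change is reported alongside, since a fixed
    threshold is a coarse reading of "significantly reduced".
    """
    seq = seq.upper()
    alt_base = alt_base.upper()
    if not (0 <= pos < len(seq)):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    if seq[pos] == alt_base:
        raise ValueError(f"alt base equals reference base {alt_base!r} at {pos}")
    mut = seq[:pos] + alt_base + seq[pos + 1 :]
    out: dict[str, dict] = {}
    for factor, m in matrices.items():
        lo = max(0, pos - m.width + 1)
        hi = min(len(seq) - m.width, pos)
        if hi < lo:
            out[factor] = {
                "wt_best_score": None, "mut_best_score": None,
                "classification": "neutral", "delta": 0.0,
            }
            continue
        wt_best = max(m.score_word(seq[i : i + m.width]) for i in range(lo, hi + 1))
        mut_best = max(m.score_word(mut[i : i + m.width]) for i in range(lo, hi + 1))
        if wt_best >= m.threshold and mut_best < m.threshold:
            cls = "disrupted"
        elif wt_best < m.threshold and mut_best >= m.threshold:
            cls = "created"
        else:
            cls = "neutral"
        out[factor] = {
            "wt_best_score": wt_best,
            "mut_best_score": mut_best,
            "classification": cls,
            "delta": mut_best - wt_best,
        }
    return out


# ---------------------------------------------------------------------------
# Exon-skipping consequence
# ---------------------------------------------------------------------------


def skipping_consequence(
    model: TranscriptModel,
    skipped_exon_id: int,
    primers: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> SkippingConsequence:
    """Frame, PTC, domain and amplicon consequences of skipping one exon.

    The skipped exon must be internal and must not contain the CDS start.
    ``primers`` are (exon_id, offset) anchors: the forward anchor marks the
    amplicon start (inclusive) and the reverse anchor its end (exclusive),
    both in transcript coordinates of the respective isoform, so the
    inclusion-exclusion length difference always equals the skipped exon's
    length.
    """
    exon = model.exon(skipped_exon_id)
    if exon.exon_id in (model.exons[0].exon_id, model.exons[-1].exon_id):
        raise ValueError(f"exon {skipped_exon_id} is not internal")
    if skipped_exon_id == model.cds_start[0]:
        raise ValueError("unsupported: skipping the CDS-start exon")
    skipped_cds = model.cds_overlap_of_exon(skipped_exon_id)
    if skipped_cds == 0:
        raise ValueError(f"exon {skipped_exon_id} is non-coding; no consequence to call")
    frame_preserving = skipped_cds % 3 == 0

    cds_skip = model.cds_seq(skip=skipped_exon_id)
    cds_full = model.cds_seq()
    junction_cds = (
        model._tx_pos(skipped_exon_id, 0)
        - model._tx_pos(*model.cds_start)
    )  # CDS coordinate where the skipped exon began (same in both isoforms)

    ptc: tuple[int, int] | None = None
    stop_at = _first_stop(cds_skip)
    if stop_at is not None:
        full_stop = _first_stop(cds_full)
        if full_stop is None:
            full_stop = len(cds_full)
        is_premature = (
            not frame_preserving or stop_at + skipped_cds != full_stop
        )
        downstream_of_junction = stop_at + 3 > junction_cds
        if is_premature and downstream_of_junction:
            tx_pos = model._tx_pos(*model.cds_start, skip=skipped_exon_id) + stop_at
            ptc = (model.exon_at_tx_pos(tx_pos, skip=skipped_exon_id), stop_at)

    truncated: list[tuple[str, str]] = []
    if ptc is not None:
        ptc_exon = ptc[0]
        for name, (first, last) in model.domains.items():
            if first >= ptc_exon:
                truncated.append((name, "lost"))
            elif last >= ptc_exon:
                truncated.append((name, "partially_truncated"))

    inc = exc = None
    if primers is not None:
        (f_ex, f_off), (r_ex, r_off) = primers
        inc = model._tx_pos(r_ex, r_off) - model._tx_pos(f_ex, f_off)
        exc = model._tx_pos(r_ex, r_off, skip=skipped_exon_id) - model._tx_pos(
            f_ex, f_off, skip=skipped_exon_id
        )
    return SkippingConsequence(
        skipped_exon_id, frame_preserving, ptc, truncated, inc, exc
    )


def write_transcript_model(path, model: TranscriptModel) -> None:
    """TSV: one exon per row plus '#cds' / '#domain' metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"#cds\t{model.cds_start[0]}\t{model.cds_start[1]}\t{model.strand}\n")
        for name, (first, last) in model.domains.items():
            fh.write(f"#domain\t{name}\t{first}\t{last}\n")
        fh.write("exon_id\tstart\tend\tseq\n")
        for e in model.exons:
            fh.write(f"{e.exon_id}\t{e.start}\t{e.end}\t{e.seq}\n")


def read_transcript_model(path) -> TranscriptModel:
    cds: tuple[int, int] | None = None
    strand = "+"
    domains: dict[str, tuple[int, int]] = {}
    exons: list[Exon] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#cds\t"):
                _, ex, off, strand = line.split("\t")
                cds = (int(ex), int(off))
            elif line.startswith("#domain\t"):
                _, name, first, last = line.split("\t")
                domains[name] = (int(first), int(last))
            elif line.startswith("exon_id"):
                continue
            else:
                ex, s, e, seq = line.split("\t")
                exons.append(Exon(int(ex), int(s), int(e), seq))
    if cds is None:
        raise ValueError(f"{path}: missing '#cds' metadata line")
    return TranscriptModel(exons, cds, strand, domains)


def translate_cds(cds: str) -> str:
    """Translate a CDS, stopping at the first stop codon."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[: stop + 1]
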