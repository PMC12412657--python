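"""Telomeric-repeat scanning and interstitial telomeric sequence (ITS) calls.

Scans a genome for the vertebrate telomeric hexamer (TTAGGG)n in tiling
windows, counting non-overlapping exact matches of the unit and of its
reverse complement, then merges dense windows into arrays. An array
touching a chromosome end (within ``end_margin``) is a terminal telomere;
anything else is an ITS — the relic of an ancestral chromosome end or a
fission/fusion scar, and a fragile-site candidate. Matches that straddle a
window boundary are not counted (at the default 10-kb window this loses at
most one unit per boundary, negligible against the density threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import RegionSpec

TELOMERE_UNIT = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatScanWindow:
    region: RegionSpec
    fwd_count: int
    rev_count: int
    density: float  # motif-bases / window-bases, in [0, 1]


@dataclass(frozen=True)
class ITSCall:
    region: RegionSpec
    kind: str  # "terminal" or "interstitial"
    span_bp: int
    mean_density: float


def scan_telomeric_repeats(
    seq: str,
    chrom: str = "chr1",
    unit: str = TELOMERE_UNIT,
    window: int = 10_000,
) -> list[RepeatScanWindow]:
    """Per-window counts of non-overlapping exact unit matches, both strands."""
    unit = unit.upper()
    if len(unit) < 4 or any(b not in "ACGT" for b in unit):
        raise ValueError(f"repeat unit must be ACGT-only with length >= 4, got {unit!r}")
    seq = seq.upper()
    rc = revcomp(unit)
    out: list[RepeatScanWindow] = []
    for start in range(0, len(seq), window):
        chunk = seq[start : start + window]
        fwd = chunk.count(unit)  # str.count is non-overlapping
        rev = chunk.count(rc)
        out.append(
            RepeatScanWindow(
                RegionSpec(chrom, start, start + len(chunk), "other"),
                fwd,
                rev,
                len(unit) * (fwd + rev) / len(chunk),
            )
        )
    return out


def call_its(
    scan: list[RepeatScanWindow],
    chrom_length: int,
    min_density: float = 0.4,
    min_span: int = 1_000,
    end_margin: int = 100_000,
    merge_gap: int = 1,
) -> list[ITSCall]:
    """Merge dense windows into telomere-array calls, terminal vs interstitial.

    Windows with density >= ``min_density`` are merged when separated by at
    most ``merge_gap`` sub-threshold windows; merged runs spanning at least
    ``min_span`` bases are emitted. A run overlapping [0, end_margin) or
    (L - end_margin, L] is terminal.
    """
    starts = [w.region.start for w in scan]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("scan windows must be sorted by start position")
    dense = [i for i, w in enumerate(scan) if w.density >= min_density]
    calls: list[ITSCall] = []
    run: list[int] = []
    for i in dense:
        if run and i - run[-1] - 1 > merge_gap:
            calls.extend(_emit(scan, run, chrom_length, min_span, end_margin))
            run = []
        run.append(i)
    if run:
        calls.extend(_emit(scan, run, chrom_length, min_span, end_margin))
    return calls


def _emit(
    scan: list[RepeatScanWindow],
    run: list[int],
    chrom_length: int,
    min_span: int,
    end_margin: int,
) -> list[ITSCall]:
    start = scan[run[0]].region.start
    end = scan[run[-1]].region.end
    span = end - start
    if span < min_span:
        return []
    densities = [scan[i].density for i in run]
    terminal = start < end_margin or end > chrom_length - end_margin
    return [
        ITSCall(
            RegionSpec(scan[run[0]].region.chrom, start, end,
                       "telomeric" if terminal else "other"),
            "terminal" if terminal else "interstitial",
            span,
            sum(densities) / len(densities),
        )
    ]


def telomere_content_summary(
    scans: dict[str, list[RepeatScanWindow]], unit_len: int = len(TELOMERE_UNIT)
) -> dict:
    """Genome-wide motif-base totals and fraction of the genome."""
    total_hits = 0
    genome_len = 0
    per_chrom: dict[str, dict] = {}
    for chrom, windows in scans.items():
        hits = sum(w.fwd_count + w.rev_count for w in windows)
        length = sum(w.region.length for w in windows)
        per_chrom[chrom] = {
            "motif_bases": unit_len * hits,
            "length": length,
            "fraction": unit_len * hits / length if length else 0.0,
        }
        total_hits += hits
        genome_len += length
    return {
        "per_chrom": per_chrom,
        "motif_bases": unit_len * total_hits,
        "genome_length": genome_len,
        "fraction": unit_len * total_hits / genome_len if genome_len else 0.0,
    }
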