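"""Fission/fusion polarization from synteny-block tables.

A reference chromosome whose blocks partition cleanly between two query
chromosomes is a candidate split. The outgroup decides the polarity: if a
single outgroup chromosome covers the reference chromosome continuously
across the candidate breakpoint, the ancestral state was one chromosome
and the split is a fission in the query lineage; if the two reference
segments map to different outgroup chromosomes, the reference chromosome
is itself a fusion product. Inversions inside segments are irrelevant to
the call — only the query-chromosome identity of each block matters;
strand is carried but unused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import SyntenyBlock

DEFAULT_MIN_FRAC = 0.05
DEFAULT_MIN_BLOCKS = 2
DEFAULT_STRAY_TOLERANCE = 0.1  # max fraction of block-bases on the wrong side


@dataclass(frozen=True)
class RearrangementCall:
    ref_chrom: str
    query_chroms: tuple[str, ...]
    event: str  # fission_in_query | fusion | none | ambiguous
    breakpoint_ref: tuple[int, int] | None  # interval on ref, or None
    support: dict = field(default_factory=dict)


def _coverage_by_chrom(blocks: list[SyntenyBlock]) -> dict[str, int]:
    cov: dict[str, int] = {}
    for b in blocks:
        cov[b.query_chrom] = cov.get(b.query_chrom, 0) + b.length
    return cov


def localize_breakpoint(
    blocks: list[SyntenyBlock],
    stray_tolerance: float = DEFAULT_STRAY_TOLERANCE,
) -> tuple[tuple[int, int] | None, dict]:
    """Breakpoint interval between the two query-chromosome block sets.

    Blocks are majority-ordered along the reference; the interval is the
    gap between the rightmost block of the left-side query chromosome and
    the leftmost block of the right-side one. Blocks assigned to the wrong
    side ("strays") are tolerated up to ``stray_tolerance`` of block-bases
    per side and flagged; beyond that the split is ambiguous.
    """
    chroms = sorted(_coverage_by_chrom(blocks), key=lambda c: -_coverage_by_chrom(blocks)[c])
    if len(chroms) < 2:
        return None, {"reason": "fewer than two query chromosomes"}
    qa, qb = chroms[:2]
    sel = sorted(
        (b for b in blocks if b.query_chrom in (qa, qb)), key=lambda b: b.ref_start
    )
    # decide which chromosome owns the left side by length-weighted midpoint
    def _centroid(q: str) -> float:
        bs = [b for b in sel if b.query_chrom == q]
        return sum((b.ref_start + b.ref_end) / 2 * b.length for b in bs) / sum(
            b.length for b in bs
        )

    left, right = (qa, qb) if _centroid(qa) <= _centroid(qb) else (qb, qa)
    left_bases = sum(b.length for b in sel if b.query_chrom == left)
    right_bases = sum(b.length for b in sel if b.query_chrom == right)

    # optimal split point minimizing misassigned bases, swept over block order
    best_cut, best_cost = 0, float("inf")
    left_seen = 0
    right_seen = 0
    for k in range(len(sel) + 1):
        cost = (left_bases - left_seen) + right_seen  # left blocks after cut + right before
        if cost < best_cost:
            best_cost, best_cut = cost, k
        if k < len(sel):
            if sel[k].query_chrom == left:
                left_seen += sel[k].length
            else:
                right_seen += sel[k].length
    strays = [
        b
        for i, b in enumerate(sel)
        if (i < best_cut) != (b.query_chrom == left)
    ]
    stray_bases = sum(b.length for b in strays)
    if stray_bases > stray_tolerance * (left_bases + right_bases):
        return None, {"reason": "interleaved block assignments", "stray_bases": stray_bases}
    left_clean = [b for b in sel[:best_cut] if b.query_chrom == left]
    right_clean = [b for b in sel[best_cut:] if b.query_chrom == right]
    if not left_clean or not right_clean:
        return None, {"reason": "one side empty after majority ordering"}
    lo = max(b.ref_end for b in left_clean)
    hi = min(b.ref_start for b in right_clean)
    if hi < lo:  # strays can leave a negative gap; collapse to a point
        lo = hi = (lo + hi) // 2
    return (lo, hi), {
        "left": left,
        "right": right,
        "strays": len(strays),
        "stray_bases": stray_bases,
    }


def _split_candidate(
    blocks: list[SyntenyBlock], ref_len: int, min_frac: float, min_blocks: int
) -> list[str]:
    cov = _coverage_by_chrom(blocks)
    n_blocks: dict[str, int] = {}
    for b in blocks:
        n_blocks[b.query_chrom] = n_blocks.get(b.query_chrom, 0) + 1
    return sorted(
        (
            q
            for q in cov
            if cov[q] >= min_frac * ref_len and n_blocks[q] >= min_blocks
        ),
        key=lambda q: -cov[q],
    )


def call_rearrangements(
    ref_query_blocks: list[SyntenyBlock],
    ref_outgroup_blocks: list[SyntenyBlock],
    min_frac: float = DEFAULT_MIN_FRAC,
    min_blocks: int = DEFAULT_MIN_BLOCKS,
    stray_tolerance: float = DEFAULT_STRAY_TOLERANCE,
    ref_chrom_lengths: dict[str, int] | None = None,
) -> list[RearrangementCall]:
    """Classify each reference chromosome as fission/fusion/none/ambiguous.

    ``fission_in_query``: >= 2 supported query chromosomes and a single
    outgroup chromosome continuous across the breakpoint. ``fusion``: the
    reference chromosome's segments map to different outgroup chromosomes
    (the reference lineage fused two ancestral chromosomes) — detected from
    the outgroup table even when the query side is 1:1.
    """
    if not ref_query_blocks:
        raise ValueError("empty ref-query block table")
    lengths: dict[str, int] = dict(ref_chrom_lengths or {})
    for b in list(ref_query_blocks) + list(ref_outgroup_blocks):
        lengths[b.ref_chrom] = max(lengths.get(b.ref_chrom, 0), b.ref_end)

    by_ref_q: dict[str, list[SyntenyBlock]] = {}
    for b in ref_query_blocks:
        by_ref_q.setdefault(b.ref_chrom, []).append(b)
    by_ref_o: dict[str, list[SyntenyBlock]] = {}
    for b in ref_outgroup_blocks:
        by_ref_o.setdefault(b.ref_chrom, []).append(b)

    calls: list[RearrangementCall] = []
    for ref_chrom in sorted(by_ref_q):
        qblocks = by_ref_q[ref_chrom]
        oblocks = by_ref_o.get(ref_chrom, [])
        ref_len = lengths[ref_chrom]
        q_cand = _split_candidate(qblocks, ref_len, min_frac, min_blocks)
        o_cand = _split_candidate(oblocks, ref_len, min_frac, min_blocks) if oblocks else []
        support = {
            "query_coverage": {
                q: cov / ref_len for q, cov in _coverage_by_chrom(qblocks).items()
            },
            "outgroup_coverage": {
                q: cov / ref_len for q, cov in _coverage_by_chrom(oblocks).items()
            },
        }

        if len(q_cand) >= 2:
            bp, diag = localize_breakpoint(qblocks, stray_tolerance)
            support["breakpoint_diagnostics"] = diag
            if bp is None:
                calls.append(
                    RearrangementCall(ref_chrom, tuple(q_cand[:2]), "ambiguous", None, support)
                )
                continue
            # outgroup continuity across the breakpoint midpoint
            mid = (bp[0] + bp[1]) / 2
            event = "ambiguous"
            if oblocks:
                left_cov = _side_coverage(oblocks, 0, mid)
                right_cov = _side_coverage(oblocks, mid, ref_len)
                spanning = {
                    c
                    for c in left_cov
                    if c in right_cov
                    and left_cov[c] >= min_frac * mid
                    and right_cov[c] >= min_frac * (ref_len - mid)
                }
                if spanning:
                    event = "fission_in_query"
                elif len(o_cand) >= 2:
                    event = "fusion"
            calls.append(
                RearrangementCall(ref_chrom, tuple(q_cand[:2]), event, bp, support)
            )
        elif len(o_cand) >= 2:
            bp, diag = localize_breakpoint(oblocks, stray_tolerance)
            support["breakpoint_diagnostics"] = diag
            event = "fusion" if bp is not None else "ambiguous"
            calls.append(
                RearrangementCall(
                    ref_chrom, tuple(q_cand[:1]), event, bp, support
                )
            )
        else:
            calls.append(
                RearrangementCall(ref_chrom, tuple(q_cand[:1]), "none", None, support)
            )
    return calls


def _side_coverage(blocks: list[SyntenyBlock], lo: float, hi: float) -> dict[str, float]:
    cov: dict[str, float] = {}
    for b in blocks:
        ov = max(0.0, min(hi, b.ref_end) - max(lo, b.ref_start))
        if ov > 0:
            cov[b.query_chrom] = cov.get(b.query_chrom, 0.0) + ov
    return cov


def mirror_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Swap the reference and query sides of a block table."""
    return [
        SyntenyBlock(
            b.query_chrom, b.query_start, b.query_end,
            b.ref_chrom, b.ref_start, b.ref_end, b.strand,
        )
        for b in blocks
    ]
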