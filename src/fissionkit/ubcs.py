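"""Bias-clustered substitutions (BCS), the UBCS statistic, and fission dating.

A BCS is a weak-to-strong (AT->GC) substitution lying in at least one
300-bp window that contains >= 4 substitutions of the same lineage, of
which >= 80% are weak-to-strong. Such clusters are the footprint of
GC-biased gene conversion, which is strongly elevated near telomeres; a
chromosome arm that became a telomere only recently (a neo-telomere at a
fission breakpoint) has accumulated the signature for only part of its
history, which is what the dating formula exploits.

UBCS for a region is the *excess* of observed BCS over a permutation
expectation: ws labels are shuffled uniformly over the region's SND
positions (positions and ws count preserved), so the expectation
conditions on local SND density and isolates clustering-of-bias as the
signal. Sign convention: ubcs = observed - expected, positive = excess
clustering (recorded in output metadata).

Fission time: T = T_div * (1 - R1/R2), where R1 is the query/target UBCS
ratio in the breakpoint flank and R2 the query UBCS ratio between an
always-telomeric region and an interior control of identical width.

Window evaluation detail: candidate cluster windows are scanned at every
membership change-point (x in {p - w + 1} union {p + 1} over SND
positions p), which enumerates every distinct SND subset any width-w
interval can contain; this is exactly equivalent to sliding the window
over all integer offsets and is verified against a brute-force oracle.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .formats import RegionSpec
from .snd import SNDRecord

UBCS_SIGN_CONVENTION = "observed_minus_expected"

DEFAULT_CLUSTER_WINDOW = 300
DEFAULT_MIN_SUBS = 4
DEFAULT_MIN_WS_FRAC = 0.8
DEFAULT_WINDOW = 1_000_000
DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class BCSCall:
    """Per-SND clustered-bias call with one qualifying window when positive."""

    index: int
    is_bcs: bool
    supporting_window: tuple[int, int] | None = None


@dataclass(frozen=True)
class UBCSWindow:
    """Observed/expected BCS counts and their difference for one region."""

    region: RegionSpec
    lineage: str
    observed_bcs: int
    expected_bcs: float
    ubcs: float
    n_perm: int
    seed: int
    n_snds: int = 0


@dataclass(frozen=True)
class FissionTimeEstimate:
    """T = T_div * (1 - R1/R2); reported raw, flagged when outside [0, T_div]."""

    t_div: float
    r1: float
    r2: float
    t: float
    out_of_range: bool


# ---------------------------------------------------------------------------
# BCS detection
# ---------------------------------------------------------------------------


def _as_ratio(frac: float) -> tuple[int, int]:
    """Snap a fraction threshold to its intended small rational (0.8 -> 4/5).

    Comparing counts against the raw binary expansion of e.g. 0.8 would
    wrongly reject the exact 4-of-5 boundary the threshold is meant to keep.
    """
    from fractions import Fraction

    f = Fraction(frac).limit_denominator(10_000)
    return f.numerator, f.denominator


def _check_sorted(positions: np.ndarray) -> None:
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("SND positions must be sorted ascending")


def _candidate_ranges(
    positions: np.ndarray, window: int, min_subs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct index ranges [i, j) realizable as the content of a width-``window`` interval.

    Membership of [x, x+window) changes only at x = p - window + 1 (p enters)
    and x = p + 1 (p leaves); evaluating each change-point offset enumerates
    every distinct membership set. Ranges with < min_subs members are dropped.
    """
    if positions.size == 0:
        return np.empty(0, int), np.empty(0, int)
    offsets = np.unique(np.concatenate([positions - window + 1, positions + 1]))
    i = np.searchsorted(positions, offsets, side="left")
    j = np.searchsorted(positions, offsets + window, side="left")
    keep = (j - i) >= min_subs
    i, j = i[keep], j[keep]
    if i.size:
        pairs = np.unique(np.stack([i, j], axis=1), axis=0)
        i, j = pairs[:, 0], pairs[:, 1]
    return i, j


def _qualifying_ranges(
    ws: np.ndarray, i: np.ndarray, j: np.ndarray, min_ws_frac: float
) -> np.ndarray:
    """Boolean mask over candidate ranges: ws fraction >= min_ws_frac.

    The comparison is done in exact integer arithmetic when min_ws_frac is
    a ratio of small integers (the 0.8 default), avoiding float-edge bugs
    at the boundary.
    """
    cs = np.concatenate([[0], np.cumsum(ws.astype(np.int64))])
    ws_cnt = cs[j] - cs[i]
    cnt = j - i
    # exact rational comparison: ws_cnt / cnt >= num / den
    num, den = _as_ratio(min_ws_frac)
    return ws_cnt * den >= cnt * num


def _bcs_mask(
    positions: np.ndarray,
    ws: np.ndarray,
    window: int,
    min_subs: int,
    min_ws_frac: float,
) -> np.ndarray:
    """Boolean per-SND mask: ws and inside at least one qualifying window."""
    n = positions.size
    covered = np.zeros(n, bool)
    i, j = _candidate_ranges(positions, window, min_subs)
    if i.size:
        ok = _qualifying_ranges(ws, i, j, min_ws_frac)
        diff = np.zeros(n + 1, np.int64)
        np.add.at(diff, i[ok], 1)
        np.add.at(diff, j[ok], -1)
        covered = np.cumsum(diff[:-1]) > 0
    return covered & ws


def find_bcs(
    snds: list[SNDRecord],
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_subs: int = DEFAULT_MIN_SUBS,
    min_ws_frac: float = DEFAULT_MIN_WS_FRAC,
) -> list[BCSCall]:
    """Call bias-clustered substitutions among sorted single-lineage SNDs.

    Only ws substitutions inside qualifying windows are BCS; the non-ws
    substitutions sharing a window are not counted.
    """
    positions = np.array([r.pos for r in snds], dtype=np.int64)
    _check_sorted(positions)
    if len({r.chrom for r in snds}) > 1:
        raise ValueError("find_bcs expects SNDs from a single chromosome")
    ws = np.array([r.ws for r in snds], dtype=bool)
    i, j = _candidate_ranges(positions, cluster_window, min_subs)
    ok = _qualifying_ranges(ws, i, j, min_ws_frac) if i.size else np.empty(0, bool)
    mask = _bcs_mask(positions, ws, cluster_window, min_subs, min_ws_frac)

    support: dict[int, tuple[int, int]] = {}
    for ri, rj in zip(i[ok] if i.size else [], j[ok] if i.size else []):
        win = (int(positions[ri]), int(positions[ri]) + cluster_window)
        for k in range(ri, rj):
            if mask[k] and k not in support:
                support[k] = win
    return [
        BCSCall(k, bool(mask[k]), support.get(k))
        for k in range(len(snds))
    ]


def count_bcs(
    positions: np.ndarray,
    ws: np.ndarray,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_subs: int = DEFAULT_MIN_SUBS,
    min_ws_frac: float = DEFAULT_MIN_WS_FRAC,
) -> int:
    """Number of BCS among SNDs given as parallel position / ws arrays."""
    return int(_bcs_mask(positions, ws, cluster_window, min_subs, min_ws_frac).sum())


# ---------------------------------------------------------------------------
# UBCS: observed minus permutation expectation
# ---------------------------------------------------------------------------


def _expected_bcs(
    positions: np.ndarray,
    ws: np.ndarray,
    rng: np.random.Generator,
    n_perm: int,
    cluster_window: int,
    min_subs: int,
    min_ws_frac: float,
) -> float:
    """Mean BCS count over ws-label permutations (positions fixed).

    All permutations are evaluated in one vectorized pass: candidate index
    ranges depend only on positions, so per permutation only the ws prefix
    sums and the coverage sweep are recomputed.
    """
    n = positions.size
    if n == 0 or not ws.any() or ws.all():
        # no labels to shuffle, or shuffle is a no-op: expectation == observed
        return float(count_bcs(positions, ws, cluster_window, min_subs, min_ws_frac))
    i, j = _candidate_ranges(positions, cluster_window, min_subs)
    if i.size == 0:
        return 0.0
    # permuted label matrix via argsort of uniform noise
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    labels = np.broadcast_to(ws, (n_perm, n))
    labels = np.take_along_axis(labels, order, axis=1)

    cs = np.zeros((n_perm, n + 1), np.int64)
    np.cumsum(labels, axis=1, out=cs[:, 1:])
    ws_cnt = cs[:, j] - cs[:, i]
    cnt = (j - i)[None, :]
    num, den = _as_ratio(min_ws_frac)
    ok = ws_cnt * den >= cnt * num  # (n_perm, n_ranges)

    diff = np.zeros((n_perm, n + 1), np.int64)
    rows = np.repeat(np.arange(n_perm), ok.sum(axis=1))
    ii = i[None, :].repeat(n_perm, axis=0)[ok]
    jj = j[None, :].repeat(n_perm, axis=0)[ok]
    np.add.at(diff, (rows, ii), 1)
    np.add.at(diff, (rows, jj), -1)
    covered = np.cumsum(diff[:, :-1], axis=1) > 0
    return float((covered & labels).sum(axis=1).mean())


def _region_seed(seed: int, chrom: str, start: int) -> np.random.Generator:
    """Deterministic per-region stream; identical for identical (seed, chrom, start)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(chrom.encode()), int(start)])
    )


def _ubcs_one_region(
    snds: list[SNDRecord],
    lineage: str,
    region: RegionSpec,
    cluster_window: int,
    min_subs: int,
    min_ws_frac: float,
    n_perm: int,
    seed: int,
) -> UBCSWindow:
    sub = [
        r
        for r in snds
        if r.derived_lineage == lineage
        and r.chrom == region.chrom
        and region.contains(r.pos)
    ]
    sub.sort(key=lambda r: r.pos)
    positions = np.array([r.pos for r in sub], np.int64)
    ws = np.array([r.ws for r in sub], bool)
    observed = count_bcs(positions, ws, cluster_window, min_subs, min_ws_frac)
    rng = _region_seed(seed, region.chrom, region.start)
    expected = _expected_bcs(
        positions, ws, rng, n_perm, cluster_window, min_subs, min_ws_frac
    )
    return UBCSWindow(
        region=region,
        lineage=lineage,
        observed_bcs=observed,
        expected_bcs=expected,
        ubcs=observed - expected,
        n_perm=n_perm,
        seed=seed,
        n_snds=len(sub),
    )


def ubcs_by_window(
    snds: list[SNDRecord],
    lineage: str,
    window: int = DEFAULT_WINDOW,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_subs: int = DEFAULT_MIN_SUBS,
    min_ws_frac: float = DEFAULT_MIN_WS_FRAC,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> list[UBCSWindow]:
    """UBCS in tiling windows (1 Mb default) for one lineage.

    Windows tile each chromosome from 0 to its length (or to the last SND
    when lengths are not given). Deterministic given ``seed``: each window
    draws from a stream keyed by (seed, chrom, window start).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if window < cluster_window:
        raise ValueError(
            f"window ({window}) must be >= cluster_window ({cluster_window})"
        )
    chroms: dict[str, int] = {}
    for r in snds:
        if r.derived_lineage == lineage:
            chroms[r.chrom] = max(chroms.get(r.chrom, 0), r.pos + 1)
    if chrom_lengths:
        for c, ln in chrom_lengths.items():
            chroms[c] = ln
    out: list[UBCSWindow] = []
    for chrom in sorted(chroms):
        length = chroms[chrom]
        for start in range(0, length, window):
            region = RegionSpec(chrom, start, min(start + window, length), "other")
            out.append(
                _ubcs_one_region(
                    snds, lineage, region, cluster_window, min_subs,
                    min_ws_frac, n_perm, seed,
                )
            )
    return out


def ubcs_for_region(
    snds: list[SNDRecord],
    lineage: str,
    region: RegionSpec,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_subs: int = DEFAULT_MIN_SUBS,
    min_ws_frac: float = DEFAULT_MIN_WS_FRAC,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> UBCSWindow:
    """UBCS over one arbitrary region (permutations are region-local).

    Note the statistic is not additive across regions: the UBCS of a union
    of two disjoint regions need not equal the sum of their UBCS values,
    because each region's permutation null is conditioned locally.
    """
    result = _ubcs_one_region(
        snds, lineage, region, cluster_window, min_subs, min_ws_frac, n_perm, seed
    )
    if result.n_snds == 0:
        warnings.warn(
            f"region {region.chrom}:{region.start}-{region.end} contains no "
            f"{lineage}-derived SNDs; UBCS = 0",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# Fission dating
# ---------------------------------------------------------------------------


def date_fission_from_regions(
    snds: list[SNDRecord],
    regions: list[RegionSpec],
    t_div: float,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_subs: int = DEFAULT_MIN_SUBS,
    min_ws_frac: float = DEFAULT_MIN_WS_FRAC,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[FissionTimeEstimate, dict[str, UBCSWindow]]:
    """Full dating pass from an SND set and labelled regions.

    ``regions`` must contain labels "breakpoint_flank", "telomeric" and
    "control" (first of each label is used). Returns the estimate plus the
    four regional UBCS computations for auditing.
    """
    by_label = {}
    for r in regions:
        by_label.setdefault(r.label, r)
    missing = {"breakpoint_flank", "telomeric", "control"} - set(by_label)
    if missing:
        raise ValueError(f"regions missing required labels: {sorted(missing)}")
    kw = dict(cluster_window=cluster_window, min_subs=min_subs,
              min_ws_frac=min_ws_frac, n_perm=n_perm, seed=seed)
    parts = {
        "query_breakpoint": ubcs_for_region(snds, "query", by_label["breakpoint_flank"], **kw),
        "target_breakpoint": ubcs_for_region(snds, "target", by_label["breakpoint_flank"], **kw),
        "query_telomeric": ubcs_for_region(snds, "query", by_label["telomeric"], **kw),
        "query_control": ubcs_for_region(snds, "query", by_label["control"], **kw),
    }
    estimate = estimate_fission_time(
        t_div,
        parts["query_breakpoint"].ubcs,
        parts["target_breakpoint"].ubcs,
        parts["query_telomeric"].ubcs,
        parts["query_control"].ubcs,
    )
    return estimate, parts


def estimate_fission_time(
    t_div: float,
    ubcs_query_bp: float,
    ubcs_target_bp: float,
    ubcs_query_tel: float,
    ubcs_query_ctrl: float,
) -> FissionTimeEstimate:
    """Date the fission from four regional UBCS values.

    R1 = query/target UBCS at the breakpoint flank; R2 = query UBCS
    telomeric/control; T = T_div * (1 - R1/R2). T is reported even when it
    falls outside [0, T_div] (flagged) — clamping would hide model misfit.
    """
    if ubcs_target_bp == 0:
        raise ZeroDivisionError(
            "degenerate UBCS: target breakpoint-flank UBCS is zero (R1 undefined)"
        )
    if ubcs_query_ctrl == 0:
        raise ZeroDivisionError(
            "degenerate UBCS: query control-region UBCS is zero (R2 undefined)"
        )
    r1 = ubcs_query_bp / ubcs_target_bp
    r2 = ubcs_query_tel / ubcs_query_ctrl
    if r2 == 0:
        raise ZeroDivisionError(
            "degenerate UBCS: query telomeric UBCS is zero (R2 = 0)"
        )
    t = t_div * (1.0 - r1 / r2)
    return FissionTimeEstimate(
        t_div=t_div, r1=r1, r2=r2, t=t, out_of_range=not (0.0 <= t <= t_div)
    )
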