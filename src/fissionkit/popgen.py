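"""Windowed diversity/differentiation statistics, Da dating, and filters.

Statistics follow the field's standard definitions:

* within-population diversity at a biallelic site,
  pi = 2 j (n - j) / (n (n - 1)) for j derived alleles among n called
  chromosomes (the unbiased pairwise estimator);
* between-population divergence dxy = p_x (1 - p_y) + p_y (1 - p_x);
* FST via the Weir & Cockerham (1984) two-population variance components
  a (between populations), b (between individuals within populations) and
  c (within individuals), combined per window as the ratio of sums
  FST = sum(a) / sum(a + b + c) (the "weighted" convention);
* net divergence Da = Dxy - (pi_x + pi_y)/2, dated as T = Da / (2 mu)
  generations.

Window denominators use callable sites (monomorphic callable sites
contribute zero), matching all-sites genotyping output.

Variant filtering mirrors a standard short-read SNP pipeline: genotype-level
masking on GQ/DP first, then site-level removal of multiallelic sites,
sites near indels, high-missingness sites, low-MAF sites and
Hardy-Weinberg failures — each removed record carries its first failing
rule so the filter is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .formats import MISSING, RegionSpec, VariantRecord

# Soft-filter defaults of the SNP pipeline this mirrors (vcftools-style):
# --maf 0.05 --minDP 5 --maxDP 150 --minGQ 20 --hwe 0.001 --max-missing 0.95,
# plus removal of SNPs within 5 bp of indels; SV screen: length >= 50 bp,
# missing rate <= 0.05.
@dataclass(frozen=True)
class FilterConfig:
    maf: float = 0.05
    min_dp: int = 5
    max_dp: int = 150
    min_gq: int = 20
    hwe_alpha: float = 0.001
    max_missing: float = 0.95  # minimum fraction of genotypes CALLED (vcftools meaning)
    indel_proximity_bp: int = 5
    sv_min_len: int = 50
    sv_max_missing: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.maf <= 1 and 0 <= self.max_missing <= 1):
            raise ValueError("maf and max_missing must lie in [0, 1]")
        if min(self.min_dp, self.max_dp, self.min_gq, self.indel_proximity_bp,
               self.sv_min_len) < 0 or self.hwe_alpha < 0 or self.sv_max_missing < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for two populations at shared sites.

    ``gx``/``gy`` have shape (n_sites, n_samples, 2) with allele codes
    0 (ref), 1 (alt) and -1 (missing).
    """

    chrom: str
    positions: np.ndarray  # (n_sites,), 0-based
    gx: np.ndarray
    gy: np.ndarray
    samples_x: list[str] = field(default_factory=list)
    samples_y: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.gx = np.asarray(self.gx, dtype=np.int8)
        self.gy = np.asarray(self.gy, dtype=np.int8)
        if self.gx.shape[0] != self.positions.size or self.gy.shape[0] != self.positions.size:
            raise ValueError("genotype arrays and positions disagree on site count")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class WindowStat:
    """Per-window summary statistics (per-site units)."""

    region: RegionSpec
    pi_x: float
    pi_y: float
    dxy: float
    fst: float
    da: float
    n_sites: int
    n_callable: int
    ancestry_fraction: float | None = None
    region_class: str = "other"


@dataclass(frozen=True)
class DaTimeEstimate:
    da: float
    t_generations: float | None
    t_years: float | None
    defined: bool


@dataclass
class SVRecord:
    """A structural variant with per-species presence genotypes.

    Genotype codes per individual: 0 absent, 1 heterozygous, 2 homozygous
    present, None missing.
    """

    sv_id: str
    length: int
    genotypes: dict[str, list[int | None]]


@dataclass(frozen=True)
class AncestrySegment:
    """One local-ancestry call on one haplotype (0-based half-open)."""

    haplotype: str
    chrom: str
    start: int
    end: int
    ancestry: str  # "self" or "foreign" (the other species)


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------


def _pop_site_arrays(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (called chromosomes, alt alleles, called diploids, het diploids).

    pi/dxy count every called allele (half-called genotypes contribute one
    chromosome); the Weir-Cockerham components use fully-called diploids
    only, since they need heterozygote frequencies.
    """
    called = g != MISSING  # (sites, samples, 2)
    n_chr = called.sum(axis=(1, 2))
    j_alt = ((g == 1) & called).sum(axis=(1, 2))
    full = called.all(axis=2)  # fully-called diploids
    n_dip = full.sum(axis=1)
    het = full & (g[:, :, 0] != g[:, :, 1])
    n_het = het.sum(axis=1)
    return n_chr, j_alt, n_dip, n_het


def sitewise_stats(gx: np.ndarray, gy: np.ndarray) -> pd.DataFrame:
    """Vectorized per-site pi, dxy and Weir-Cockerham components.

    Sites with an all-missing population get NaN everywhere (skipped and
    counted by the caller); sites without enough individuals for the WC
    components (fewer than two called diploids overall, or n_bar == 1) get
    NaN components only.
    """
    ncx, jx, dx, hx = _pop_site_arrays(gx)
    ncy, jy, dy, hy = _pop_site_arrays(gy)

    with np.errstate(divide="ignore", invalid="ignore"):
        pi_x = np.where(ncx > 1, 2.0 * jx * (ncx - jx) / (ncx * np.maximum(ncx - 1, 1)), np.nan)
        pi_y = np.where(ncy > 1, 2.0 * jy * (ncy - jy) / (ncy * np.maximum(ncy - 1, 1)), np.nan)
        px = np.where(ncx > 0, jx / np.maximum(ncx, 1), np.nan)
        py = np.where(ncy > 0, jy / np.maximum(ncy, 1), np.nan)
        dxy = px * (1 - py) + py * (1 - px)

        # Weir & Cockerham (1984), r = 2 populations, diploid counts
        n1 = dx.astype(float)
        n2 = dy.astype(float)
        ok = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
        nbar = (n1 + n2) / 2.0
        nsum = n1 + n2
        nc = np.where(ok, nsum - (n1**2 + n2**2) / np.maximum(nsum, 1), np.nan)
        # allele frequencies among fully-called diploids
        p1 = _diploid_freq(gx)
        p2 = _diploid_freq(gy)
        h1 = np.where(n1 > 0, hx / np.maximum(n1, 1), np.nan)
        h2 = np.where(n2 > 0, hy / np.maximum(n2, 1), np.nan)
        pbar = (n1 * p1 + n2 * p2) / np.maximum(nsum, 1)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / np.maximum(nbar, 1e-300)
        hbar = (n1 * h1 + n2 * h2) / np.maximum(nsum, 1)

        inner = pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / np.maximum(nbar - 1, 1e-300))
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pbar * (1 - pbar) - s2 / 2.0 - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        bad = ~ok | (nc <= 0)
        a = np.where(bad, np.nan, a)
        b = np.where(bad, np.nan, b)
        c = np.where(bad, np.nan, c)

    return pd.DataFrame(
        {"pi_x": pi_x, "pi_y": pi_y, "dxy": dxy, "a": a, "b": b, "c": c}
    )


def _diploid_freq(g: np.ndarray) -> np.ndarray:
    full = (g != MISSING).all(axis=2)
    alt = ((g == 1) & full[:, :, None]).sum(axis=(1, 2)).astype(float)
    tot = 2.0 * full.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)


def site_stats(
    genotypes_x: np.ndarray, genotypes_y: np.ndarray
) -> tuple[float, float, float, tuple[float, float, float]]:
    """pi_x, pi_y, dxy and WC components (a, b, c) for one biallelic site.

    ``genotypes_*`` have shape (n_samples, 2) with codes 0/1/-1.
    """
    df = sitewise_stats(
        np.asarray(genotypes_x)[None, :, :], np.asarray(genotypes_y)[None, :, :]
    )
    row = df.iloc[0]
    return (
        float(row.pi_x),
        float(row.pi_y),
        float(row.dxy),
        (float(row.a), float(row.b), float(row.c)),
    )


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------


def _callable_in_window(
    start: int, end: int, callable_regions: list[RegionSpec] | None
) -> int:
    if callable_regions is None:
        return end - start
    total = 0
    for r in callable_regions:
        total += max(0, min(end, r.end) - max(start, r.start))
    return total


def window_stats(
    matrix: GenotypeMatrix,
    window_size: int = 20_000,
    step: int | None = None,
    chrom_length: int | None = None,
    callable_regions: list[RegionSpec] | None = None,
) -> list[WindowStat]:
    """Windowed pi, Dxy, Da and ratio-of-sums FST.

    Per-site values are summed and divided by the window's callable-site
    count (default: the full window), so monomorphic callable sites dilute
    the per-site averages as they should. Windows without callable sites
    are emitted with NaN statistics.
    """
    step = window_size if step is None else step
    if window_size < step:
        raise ValueError("window_size must be >= step")
    length = chrom_length if chrom_length is not None else (
        int(matrix.positions.max()) + 1 if matrix.n_sites else window_size
    )
    per_site = sitewise_stats(matrix.gx, matrix.gy)
    usable = ~(per_site.pi_x.isna() | per_site.pi_y.isna() | per_site.dxy.isna())

    out: list[WindowStat] = []
    for start in range(0, length, step):
        end = min(start + window_size, length)
        in_win = (matrix.positions >= start) & (matrix.positions < end)
        sel = in_win & usable.to_numpy()
        n_callable = _callable_in_window(start, end, callable_regions)
        region = RegionSpec(matrix.chrom, start, end, "other")
        if n_callable == 0:
            out.append(
                WindowStat(region, math.nan, math.nan, math.nan, math.nan,
                           math.nan, int(sel.sum()), 0)
            )
            continue
        sub = per_site[sel]
        pi_x = float(sub.pi_x.sum()) / n_callable
        pi_y = float(sub.pi_y.sum()) / n_callable
        dxy = float(sub.dxy.sum()) / n_callable
        asum = float(sub.a.sum(skipna=True))
        absum = float((sub.a + sub.b + sub.c).sum(skipna=True))
        fst = asum / absum if absum != 0 else math.nan
        out.append(
            WindowStat(
                region, pi_x, pi_y, dxy, fst,
                dxy - (pi_x + pi_y) / 2.0, int(sel.sum()), n_callable,
            )
        )
    return out


def classify_windows(
    windows: list[WindowStat], regions: list[RegionSpec]
) -> list[WindowStat]:
    """Assign region classes from labelled intervals (first overlap wins)."""
    out = []
    for w in windows:
        cls = "other"
        for r in regions:
            if r.chrom == w.region.chrom and (
                min(r.end, w.region.end) > max(r.start, w.region.start)
            ):
                cls = r.label
                break
        out.append(replace(w, region_class=cls))
    return out


# ---------------------------------------------------------------------------
# Da dating
# ---------------------------------------------------------------------------


def da_and_time(
    dxy: float, pi_x: float, pi_y: float, mu: float, gen_years: float = 1.0
) -> DaTimeEstimate:
    """Net divergence and the divergence time T = Da / (2 mu) generations.

    Da <= 0 (recent divergence or high diversity) leaves T undefined and
    flagged rather than clamped.
    """
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    da = dxy - (pi_x + pi_y) / 2.0
    if da > 0:
        t_gen = da / (2.0 * mu)
        return DaTimeEstimate(da, t_gen, t_gen * gen_years, True)
    return DaTimeEstimate(da, None, None, False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p: total probability of heterozygote
    counts (with the same allele counts) no more probable than observed."""
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative with n >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h) up to a constant: n! 2^h / (((nA-h)/2)! ((na-h)/2)! h!)
    logp = (
        hets * math.log(2.0)
        - gammaln((n_A - hets) / 2.0 + 1)
        - gammaln((n_a - hets) / 2.0 + 1)
        - gammaln(hets + 1.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------


def _mask_genotypes(rec: VariantRecord, cfg: FilterConfig) -> VariantRecord:
    gts = []
    for gt, dp, gq in zip(rec.genotypes, rec.depths, rec.quals):
        bad = False
        if gq is not None and gq < cfg.min_gq:
            bad = True
        if dp is not None and not (cfg.min_dp <= dp <= cfg.max_dp):
            bad = True
        gts.append((MISSING, MISSING) if bad else gt)
    return replace_record(rec, genotypes=gts)


def replace_record(rec: VariantRecord, **kw) -> VariantRecord:
    d = dict(
        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=rec.alts,
        genotypes=rec.genotypes, depths=rec.depths, quals=rec.quals,
        samples=rec.samples, var_id=rec.var_id,
    )
    d.update(kw)
    return VariantRecord(**d)


def filter_variants(
    records: Iterable[VariantRecord],
    config: FilterConfig | None = None,
    indel_positions: dict[str, Iterable[int]] | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Genotype masking then ordered site filters; auditable removals.

    Site rules in order, each removal tagged with its first failing rule:
    ``multiallelic``, ``near_indel`` (within ``indel_proximity_bp``),
    ``missing`` (called fraction < max_missing), ``maf``, ``hwe``.
    The filter is idempotent: kept records pass unchanged a second time.
    """
    cfg = config or FilterConfig()
    indels = {
        chrom: np.sort(np.asarray(list(pos), dtype=np.int64))
        for chrom, pos in (indel_positions or {}).items()
    }
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec in records:
        rec = _mask_genotypes(rec, cfg)
        if rec.is_multiallelic:
            removed.append((rec, "multiallelic"))
            continue
        near = indels.get(rec.chrom)
        if near is not None and near.size:
            k = np.searchsorted(near, rec.pos)
            dist = min(
                abs(rec.pos - near[k - 1]) if k > 0 else np.iinfo(np.int64).max,
                abs(near[k] - rec.pos) if k < near.size else np.iinfo(np.int64).max,
            )
            if dist <= cfg.indel_proximity_bp:
                removed.append((rec, "near_indel"))
                continue
        gts = np.array(rec.genotypes, dtype=int)
        called = (gts != MISSING).all(axis=1)
        if called.mean() < cfg.max_missing:
            removed.append((rec, "missing"))
            continue
        alleles = gts[called].ravel()
        if alleles.size == 0:
            removed.append((rec, "missing"))
            continue
        p = float((alleles == 1).mean())
        if min(p, 1 - p) < cfg.maf:
            removed.append((rec, "maf"))
            continue
        g = gts[called]
        n_het = int((g[:, 0] != g[:, 1]).sum())
        n_alt_hom = int(((g == 1).all(axis=1)).sum())
        n_ref_hom = int(((g == 0).all(axis=1)).sum())
        if hwe_exact_p(n_ref_hom, n_het, n_alt_hom) < cfg.hwe_alpha:
            removed.append((rec, "hwe"))
            continue
        kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# SV fixation screen
# ---------------------------------------------------------------------------


def sv_fixation_screen(
    svs: Iterable[SVRecord],
    focal_species: str,
    config: FilterConfig | None = None,
) -> list[str]:
    """IDs of SVs fixed (homozygous) in the focal species and absent elsewhere.

    Applies the length and missing-rate screens first (>= sv_min_len,
    missing rate <= sv_max_missing), then requires every called focal
    individual homozygous-present and every called non-focal individual
    absent.
    """
    cfg = config or FilterConfig()
    flagged: list[str] = []
    for sv in svs:
        if focal_species not in sv.genotypes:
            raise ValueError(f"unknown focal species {focal_species!r}")
        if sv.length < cfg.sv_min_len:
            continue
        all_gts = [g for gts in sv.genotypes.values() for g in gts]
        if not all_gts:
            continue
        missing_rate = sum(g is None for g in all_gts) / len(all_gts)
        if missing_rate > cfg.sv_max_missing:
            continue
        focal = [g for g in sv.genotypes[focal_species] if g is not None]
        others = [
            g
            for sp, gts in sv.genotypes.items()
            if sp != focal_species
            for g in gts
            if g is not None
        ]
        if focal and all(g == 2 for g in focal) and all(g == 0 for g in others):
            flagged.append(sv.sv_id)
    return flagged


# ---------------------------------------------------------------------------
# Selected-site density
# ---------------------------------------------------------------------------


def selected_site_density(
    positions: np.ndarray,
    scores: np.ndarray,
    threshold: float = 2.0,
    window: int = 100_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Counts of |normalized score| exceedances per tiling window.

    ``focal_density`` counts sites with score > threshold (selection in the
    focal population), ``other_density`` sites with score < -threshold.
    Densities are counts per window.
    """
    positions = np.asarray(positions, np.int64)
    scores = np.asarray(scores, float)
    length = chrom_length if chrom_length is not None else (
        int(positions.max()) + 1 if positions.size else window
    )
    starts = np.arange(0, length, window)
    idx = np.clip(positions // window, 0, starts.size - 1)
    focal = np.bincount(idx[scores > threshold], minlength=starts.size)
    other = np.bincount(idx[scores < -threshold], minlength=starts.size)
    return pd.DataFrame(
        {
            "start": starts,
            "end": np.minimum(starts + window, length),
            "focal_density": focal.astype(float),
            "other_density": other.astype(float),
        }
    )


# ---------------------------------------------------------------------------
# Rank-sum contrasts between region classes
# ---------------------------------------------------------------------------


def mann_whitney_p(x: Sequence[float], y: Sequence[float], exact_max_n: int = 12) -> float:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) p-value.

    Exact enumeration (ties handled via midranks) when both samples have
    <= ``exact_max_n`` observations; otherwise the normal approximation
    with tie and continuity corrections. The exact two-sided p is
    P(|T - E[T]| >= |t_obs - E[T]|) over all arrangements of the pooled
    values, computed with a generating-function DP rather than explicit
    enumeration.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size <= exact_max_n and y.size <= exact_max_n:
        return _mw_exact(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _mw_exact(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    r2 = np.rint(ranks * 2).astype(np.int64)  # doubled midranks are integers
    n, total = x.size, r2.sum()
    t_obs = r2[: x.size].sum()
    mu2 = n * total / (n + y.size)
    # dp[k] maps doubled-rank-sum -> number of k-subsets achieving it
    dp: list[dict[int, int]] = [dict() for _ in range(n + 1)]
    dp[0][0] = 1
    for r in r2:
        for k in range(min(n, len(r2)) - 1, -1, -1):
            if not dp[k]:
                continue
            tgt = dp[k + 1]
            for s, c in dp[k].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = dp[n]
    total_ways = sum(dist.values())
    d_obs = abs(t_obs - mu2)
    hits = sum(c for s, c in dist.items() if abs(s - mu2) >= d_obs - 1e-9)
    return min(1.0, hits / total_ways)


def region_contrast(
    windows: list[WindowStat],
    statistic: str = "fst",
    classes: Sequence[str] | None = None,
    exact_max_n: int = 12,
) -> dict:
    """Per-class summaries and pairwise rank-sum contrasts of a window statistic.

    Classes with fewer than two finite windows are summarized but excluded
    from pairwise comparisons (noted in the report).
    """
    values: dict[str, np.ndarray] = {}
    for w in windows:
        if classes is not None and w.region_class not in classes:
            continue
        v = getattr(w, statistic)
        if v is not None and math.isfinite(v):
            values.setdefault(w.region_class, [])
            values[w.region_class].append(float(v))
    report: dict = {"statistic": statistic, "classes": {}, "comparisons": [], "notes": []}
    for cls, vals in sorted(values.items()):
        arr = np.asarray(vals)
        report["classes"][cls] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
        }
    names = sorted(values)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if len(values[a]) < 2 or len(values[b]) < 2:
                report["notes"].append(
                    f"comparison {a} vs {b} omitted: a class has <2 windows"
                )
                continue
            p = mann_whitney_p(values[a], values[b], exact_max_n=exact_max_n)
            report["comparisons"].append({"a": a, "b": b, "p": p})
    return report


# ---------------------------------------------------------------------------
# Ancestry fractions and gene density
# ---------------------------------------------------------------------------


def ancestry_fraction_by_window(
    segments: Iterable[AncestrySegment],
    window: RegionSpec,
    n_haplotypes: int | None = None,
    foreign_label: str = "foreign",
) -> float:
    """Fraction of haplotype-bases in the window assigned foreign ancestry.

    Denominator is n_haplotypes * window length; n_haplotypes defaults to
    the number of distinct haplotype ids seen in the input. Overlapping
    segments on one haplotype are an error.
    """
    segs = [s for s in segments if s.chrom == window.chrom]
    by_hap: dict[str, list[AncestrySegment]] = {}
    for s in segs:
        by_hap.setdefault(s.haplotype, []).append(s)
    for hap, ss in by_hap.items():
        ss.sort(key=lambda s: s.start)
        for prev, cur in zip(ss, ss[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping ancestry segments on haplotype {hap!r} "
                    f"at {window.chrom}:{cur.start}"
                )
    n_hap = n_haplotypes if n_haplotypes is not None else len(by_hap)
    if n_hap == 0:
        return 0.0
    foreign_bases = sum(
        max(0, min(window.end, s.end) - max(window.start, s.start))
        for s in segs
        if s.ancestry == foreign_label
    )
    return foreign_bases / (n_hap * window.length)


def gene_density(
    gene_intervals: Iterable[RegionSpec],
    window: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
) -> dict:
    """Gene counts per tiling window, counted by start position.

    A gene spanning a window boundary is counted once, in the window
    containing its start. Returns per-chromosome window counts plus mean
    genes per window per chromosome and genome-wide.
    """
    genes = list(gene_intervals)
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end)
    counts: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        n_win = max(1, math.ceil(length / window))
        counts[chrom] = np.zeros(n_win, dtype=int)
    for g in genes:
        counts[g.chrom][g.start // window] += 1
    per_chrom_mean = {c: float(v.mean()) for c, v in counts.items()}
    all_counts = np.concatenate(list(counts.values())) if counts else np.zeros(1)
    return {
        "window": window,
        "counts": counts,
        "mean_per_chrom": per_chrom_mean,
        "mean_genome": float(all_counts.mean()),
        "total_genes": len(genes),
    }
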