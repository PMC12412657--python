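"""Independent reference implementations used only by the tests.

Each oracle takes the dumbest correct route — exhaustive enumeration,
explicit pairwise loops, full translation — and stays structurally
independent of the library code it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bcs_bruteforce(
    positions: np.ndarray,
    ws: np.ndarray,
    window: int = 300,
    min_subs: int = 4,
    frac_num: int = 4,
    frac_den: int = 5,
) -> np.ndarray:
    """Mark BCS by sliding a width-``window`` interval over EVERY integer offset."""
    positions = np.asarray(positions, np.int64)
    ws = np.asarray(ws, bool)
    marks = np.zeros(positions.size, bool)
    if positions.size == 0:
        return marks
    offsets = np.arange(positions.min() - window, positions.max() + 1)
    i = np.searchsorted(positions, offsets, side="left")
    j = np.searchsorted(positions, offsets + window, side="left")
    cs = np.concatenate([[0], np.cumsum(ws)])
    n = j - i
    wcnt = cs[j] - cs[i]
    good = (n >= min_subs) & (wcnt * frac_den >= n * frac_num)
    for a, b in zip(i[good], j[good]):
        marks[a:b] |= ws[a:b]
    return marks


def pairwise_pi(genotypes: np.ndarray) -> float:
    """Average pairwise difference over all pairs of called chromosomes."""
    alleles = [a for g in genotypes for a in g if a != -1]
    if len(alleles) < 2:
        return math.nan
    diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
    return diffs / math.comb(len(alleles), 2)


def pairwise_dxy(gx: np.ndarray, gy: np.ndarray) -> float:
    """Average difference over all cross-population chromosome pairs."""
    ax = [a for g in gx for a in g if a != -1]
    ay = [a for g in gy for a in g if a != -1]
    if not ax or not ay:
        return math.nan
    return sum(a != b for a in ax for b in ay) / (len(ax) * len(ay))


def anova_fst_components(gx: np.ndarray, gy: np.ndarray):
    """Weir-Cockerham a, b, c via the ANOVA mean-squares route.

    Uses only fully-called diploids, matching the library's convention.
    """
    pops = []
    for g in (np.asarray(gx), np.asarray(gy)):
        full = (g != -1).all(axis=1)
        pops.append(g[full].astype(float))
    n = [p.shape[0] for p in pops]
    if min(n) == 0 or sum(n) <= 2:
        return math.nan, math.nan, math.nan
    N, r = sum(n), 2
    ybar_ij = [p.mean(axis=1) for p in pops]
    ybar_i = [p.mean() for p in pops]
    grand = sum(p.sum() for p in pops) / (2 * N)
    SSG = sum(((p - ybar_ij[i][:, None]) ** 2).sum() for i, p in enumerate(pops))
    SSI = sum(2 * ((ybar_ij[i] - ybar_i[i]) ** 2).sum() for i in range(r))
    SSP = sum(2 * n[i] * (ybar_i[i] - grand) ** 2 for i in range(r))
    MSG = SSG / N
    MSI = SSI / (N - r)
    MSP = SSP / (r - 1)
    nc = (N - sum(x * x for x in n) / N) / (r - 1)
    return (MSP - MSI) / (2 * nc), (MSI - MSG) / 2, MSG


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by enumerating every genotype table with the same allele counts."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa

    def prob(aa: int, ab: int, bb: int) -> float:
        return math.exp(
            math.lgamma(n + 1)
            - math.lgamma(aa + 1) - math.lgamma(ab + 1) - math.lgamma(bb + 1)
            + ab * math.log(2)
            - (math.lgamma(2 * n + 1) - math.lgamma(n_A + 1)
               - math.lgamma(2 * n - n_A + 1))
        )

    configs = []
    for ab in range(min(n_A, 2 * n - n_A) + 1):
        if (n_A - ab) % 2:
            continue
        aa = (n_A - ab) // 2
        bb = n - aa - ab
        if bb < 0:
            continue
        configs.append((aa, ab, bb))
    probs = {c: prob(*c) for c in configs}
    p_obs = probs[(n_AA, n_Aa, n_aa)]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def mw_exact_bruteforce(x, y) -> float:
    """Two-sided rank-sum p by enumerating every assignment of pooled values."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n = len(x)
    mu = n * ranks.sum() / len(pooled)
    t_obs = ranks[:n].sum()
    d_obs = abs(t_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def naive_skip_translation(model, skip_exon: int):
    """(ptc_exon, cds_coord) from codon-by-codon translation of the skipped isoform."""
    tx = "".join(e.seq for e in model.exons if e.exon_id != skip_exon)
    offset = 0
    for e in model.exons:
        if e.exon_id == skip_exon:
            continue
        if e.exon_id == model.cds_start[0]:
            offset += model.cds_start[1]
            break
        offset += e.length
    cds = tx[offset:]
    for i in range(0, len(cds) - 2, 3):
        if cds[i : i + 3] in {"TAA", "TAG", "TGA"}:
            # locate the original exon containing transcript position offset+i
            pos = offset + i
            cur = 0
            for e in model.exons:
                if e.exon_id == skip_exon:
                    continue
                if cur <= pos < cur + e.length:
                    return e.exon_id, i
                cur += e.length
    return None


def count_unit_matches(seq: str, unit: str) -> int:
    """Non-overlapping exact matches by explicit stepping."""
    count = i = 0
    while True:
        j = seq.find(unit, i)
        if j < 0:
            return count
        count += 1
        i = j + len(unit)
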