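"""Synthetic-data generators with recorded ground truth.

Every generator is seed-deterministic and returns a :class:`TruthRecord`
holding the parameters and the derived expectations, so downstream modules
can be validated by parameter recovery rather than against opaque
fixtures.

Fission triple
--------------
``simulate_fission_triple`` plants lineage-polarized SNDs whose
weak-to-strong labels cluster with region-dependent intensity. Baseline
clusters occur everywhere at ``cluster_rate``; always-telomeric regions of
both lineages are amplified ``k_tel``-fold; the query breakpoint flank is
amplified ``k_tel * (1 - f)``-fold while the target flank stays at
baseline. This is a *formula-consistent* calibration: it makes
E[R1]/E[R2] = 1 - f by construction, so the dating formula
T = T_div * (1 - R1/R2) recovers T = f * T_div in expectation. It is a
validation target for the pipeline's implementation, not a mechanistic
model of GC-biased gene conversion through time (see docs/methods.md).

Divergent populations
---------------------
``simulate_divergent_populations`` draws independent sites of three kinds:
fixed interspecific differences (probability calibrated so E[Da] = 2 mu T
exactly), shared ancestral polymorphism (the same allele frequency in both
populations, which contributes equally to Dxy and to mean pi, leaving Da
untouched), and private polymorphism when the two diversity targets
differ (its Dxy overshoot is subtracted from the fixed-difference budget).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .formats import (
    MISSING,
    RegionSpec,
    SyntenyBlock,
    VariantRecord,
    write_bed,
    write_fasta,
    write_synteny_blocks,
    write_vcf,
)
from .snd import SNDRecord, classify_ws, write_snd_table
from .splicing import Exon, TranscriptModel
from .telomere import TELOMERE_UNIT

WEAK = ("A", "T")
STRONG = ("G", "C")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class TruthRecord:
    """Generator name, seed, parameters, and the expectations they imply."""

    generator: str
    seed: int
    parameters: dict
    expected: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant(seq: np.ndarray, start: int, insert: str) -> None:
    arr = np.frombuffer(insert.encode(), dtype="S1")
    seq[start : start + arr.size] = arr[: max(0, seq.size - start)]


# ---------------------------------------------------------------------------
# Telomeric genomes
# ---------------------------------------------------------------------------


def simulate_telomeric_genome(
    length: int,
    terminal_len: int = 30_000,
    its: tuple[int, int] | None = None,
    seed: int = 0,
    unit: str = TELOMERE_UNIT,
) -> tuple[str, TruthRecord]:
    """Random chromosome with terminal repeat arrays and an optional ITS.

    ``its`` is a (start, end) interval filled with the repeat unit.
    """
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, length)
    planted: list[tuple[int, int, str]] = []
    if terminal_len > 0:
        n = -(-terminal_len // len(unit))
        _plant(seq, 0, unit * n)
        start_right = max(0, length - terminal_len)
        _plant(seq, start_right, unit * n)
        planted.append((0, min(terminal_len, length), "terminal"))
        planted.append((start_right, length, "terminal"))
    if its is not None:
        s, e = its
        if not (0 <= s < e <= length):
            raise ValueError(f"ITS interval {its} outside chromosome of length {length}")
        _plant(seq, s, unit * (-(-(e - s) // len(unit))))
        planted.append((s, e, "interstitial"))
    truth = TruthRecord(
        "simulate_telomeric_genome",
        seed,
        {"length": length, "terminal_len": terminal_len, "its": its, "unit": unit},
        {"planted_arrays": planted},
    )
    return seq.tobytes().decode(), truth


# ---------------------------------------------------------------------------
# Fission triple
# ---------------------------------------------------------------------------


@dataclass
class FissionTriple:
    genomes: dict[str, str] | None  # target/query/outgroup -> sequence
    snds: list[SNDRecord]
    regions: list[RegionSpec]
    truth: TruthRecord


def _ws_bases(rng: np.random.Generator) -> tuple[str, str, str]:
    anc = WEAK[rng.integers(2)]
    der = STRONG[rng.integers(2)]
    return anc, der, anc  # (ancestral, derived, outgroup==ancestral)


def _non_ws_bases(rng: np.random.Generator) -> tuple[str, str, str]:
    while True:
        anc = "ACGT"[rng.integers(4)]
        der = "ACGT"[rng.integers(4)]
        if der != anc and not classify_ws(anc, der):
            return anc, der, anc


def _make_record(
    chrom: str, pos: int, lineage: str, ws: bool, rng: np.random.Generator
) -> SNDRecord:
    anc, der, out = (_ws_bases if ws else _non_ws_bases)(rng)
    t, q = (der, anc) if lineage == "target" else (anc, der)
    return SNDRecord(chrom, pos, t, q, out, lineage, ws)


def simulate_fission_triple(
    chrom_lengths: dict[str, int] | None = None,
    snd_rate: float = 3e-3,
    ws_base_frac: float = 0.1,
    cluster_rate: float = 3e-5,
    cluster_size: int = 6,
    cluster_span: int = 300,
    k_tel: float = 3.0,
    f: float = 0.4,
    t_div: float = 2.8e6,
    breakpoint: int = 16_000_000,
    region_width: int = 4_000_000,
    terminal_len: int = 30_000,
    its_len: int = 30_000,
    seed: int = 0,
    make_genomes: bool = True,
    out_dir: str | os.PathLike | None = None,
) -> FissionTriple:
    """Three diverged genomes with a planted centric fission and SND clusters.

    Regions on the fissioned chromosome: an always-telomeric region
    [0, region_width), an interior control of identical width separated
    from the telomere, and the breakpoint flank (region_width/2 each side
    of the breakpoint). Cluster intensities follow the formula-consistent
    calibration described in the module docstring.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("onset fraction f must lie in [0, 1]")
    if k_tel <= 1.0:
        raise ValueError("k_tel must exceed 1")
    chrom_lengths = dict(chrom_lengths or {"chr1": 24_000_000})
    chrom = next(iter(chrom_lengths))
    length = chrom_lengths[chrom]
    half = region_width // 2
    if not (region_width < breakpoint - half and breakpoint + half <= length):
        raise ValueError("breakpoint flank must fit inside the chromosome, clear of the telomeric region")
    rng = np.random.default_rng(seed)

    telomeric = RegionSpec(chrom, 0, region_width, "telomeric")
    gap = region_width // 2
    control = RegionSpec(chrom, region_width + gap, 2 * region_width + gap, "control")
    flank = RegionSpec(chrom, breakpoint - half, breakpoint + half, "breakpoint_flank")
    regions = [telomeric, control, flank]

    def _multiplier(lineage: str, pos_lo: int, pos_hi: int) -> float:
        if (pos_lo, pos_hi) == (telomeric.start, telomeric.end):
            return k_tel
        if (pos_lo, pos_hi) == (flank.start, flank.end):
            return k_tel * (1.0 - f) if lineage == "query" else 1.0
        return 1.0

    # Composition-matched planting: SND positions (background + dense cluster
    # seeds) and the total ws fraction are identically distributed in every
    # region; only the fraction of cluster seeds whose labels are coherently
    # ws varies with regional intensity. This isolates clustering-of-bias —
    # the one thing UBCS measures — so the permutation null behaves
    # identically across regions and regional UBCS ratios equal the planted
    # activation ratios.
    edges = sorted({0, length, telomeric.start, telomeric.end, control.start,
                    control.end, flank.start, flank.end})
    lam_pos = cluster_rate * k_tel  # position-cluster rate, region-independent
    if cluster_size * lam_pos > snd_rate:
        raise ValueError(
            "cluster SND mass exceeds background SND rate; the scattered-label "
            "compensation cannot hold the regional ws fraction constant"
        )
    snds: list[SNDRecord] = []
    for lineage in ("target", "query"):
        for lo, hi in zip(edges, edges[1:]):
            m = _multiplier(lineage, lo, hi)
            activation = m / k_tel
            # background ws fraction compensated so the expected total ws per
            # bp is region-independent; inactive cluster members stay at the
            # base fraction so they never mimic coherent ws clusters
            w_bg = (
                cluster_size * lam_pos * (1.0 - activation) * (1.0 - ws_base_frac)
                + snd_rate * ws_base_frac
            ) / snd_rate
            n_bg = rng.poisson(snd_rate * (hi - lo))
            pos_bg = rng.integers(lo, hi, size=n_bg)
            ws_bg = rng.random(n_bg) < w_bg
            for p, w in zip(pos_bg, ws_bg):
                snds.append(_make_record(chrom, int(p), lineage, bool(w), rng))
            n_cl = rng.poisson(lam_pos * (hi - lo))
            anchors = rng.integers(lo, max(lo + 1, hi - cluster_span), size=n_cl)
            for a in anchors:
                active = rng.random() < activation
                offs = rng.integers(0, cluster_span, size=cluster_size)
                for o in np.sort(offs):
                    w = True if active else bool(rng.random() < ws_base_frac)
                    snds.append(_make_record(chrom, int(a + o), lineage, w, rng))
    snds.sort(key=lambda r: (r.chrom, r.pos))

    genomes = None
    if make_genomes:
        base = _random_seq(rng, length)
        genomes = {}
        for name in ("target", "query", "outgroup"):
            g = base.copy()
            n_unit = -(-terminal_len // len(TELOMERE_UNIT))
            _plant(g, 0, TELOMERE_UNIT * n_unit)
            _plant(g, length - terminal_len, TELOMERE_UNIT * n_unit)
            its_start = breakpoint - its_len // 2
            _plant(g, its_start, TELOMERE_UNIT * (-(-its_len // len(TELOMERE_UNIT))))
            genomes[name] = g.tobytes().decode()

    truth = TruthRecord(
        "simulate_fission_triple",
        seed,
        {
            "chrom_lengths": chrom_lengths, "snd_rate": snd_rate,
            "ws_base_frac": ws_base_frac, "cluster_rate": cluster_rate,
            "cluster_size": cluster_size, "k_tel": k_tel, "f": f,
            "t_div": t_div, "breakpoint": breakpoint,
            "region_width": region_width, "terminal_len": terminal_len,
            "its_len": its_len,
        },
        {
            "fission_time": f * t_div,
            "r1": k_tel * (1.0 - f),
            "r2": k_tel,
            "its_interval": [breakpoint - its_len // 2,
                             breakpoint - its_len // 2 + its_len],
        },
    )
    triple = FissionTriple(genomes, snds, regions, truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        if genomes:
            write_fasta(
                os.path.join(out_dir, "triple.fa"),
                [(f"{chrom}_{n}", s) for n, s in genomes.items()],
            )
        write_snd_table(os.path.join(out_dir, "snds.tsv"), snds)
        write_bed(os.path.join(out_dir, "regions.bed"), regions)
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return triple


# ---------------------------------------------------------------------------
# Two diverged populations
# ---------------------------------------------------------------------------


@dataclass
class DivergentPopulations:
    records: list[VariantRecord]
    callable_regions: list[RegionSpec]
    samples_x: list[str]
    samples_y: list[str]
    chrom: str
    length: int
    truth: TruthRecord


def simulate_divergent_populations(
    L: int = 1_000_000,
    T_gen: float = 1e5,
    mu: float = 3.03e-9,
    pi_x: float = 1e-3,
    pi_y: float = 1e-3,
    n_x: int = 13,
    n_y: int = 14,
    seed: int = 0,
    chrom: str = "chr1",
    out_dir: str | os.PathLike | None = None,
) -> DivergentPopulations:
    """Two-population diploid genotypes with E[Da] = 2 mu T by construction."""
    if min(L, n_x, n_y) <= 0 or mu <= 0 or T_gen < 0 or min(pi_x, pi_y) < 0:
        raise ValueError("all parameters must be positive (T_gen, pi may be zero)")
    d = 2.0 * mu * T_gen
    pi_s = min(pi_x, pi_y)
    delta_x = pi_x - pi_s
    delta_y = pi_y - pi_s
    # private polymorphism (other population fixed ancestral) adds E[q] = 1/2
    # to dxy per site but only 1/6 via the (pi_x+pi_y)/2 term; subtract the
    # overshoot from the fixed-difference budget so E[Da] = 2 mu T holds.
    d_eff = d - delta_x - delta_y
    if d_eff < 0:
        raise ValueError(
            "infeasible parameters: private diversity excess exceeds the "
            "fixed-difference budget 2*mu*T_gen"
        )
    r_shared = 3.0 * pi_s
    r_px = 3.0 * delta_x
    r_py = 3.0 * delta_y
    if d_eff + r_shared + r_px + r_py > 1:
        raise ValueError("per-site event probability exceeds 1; lower rates")
    rng = np.random.default_rng(seed)

    u = rng.random(L)
    kinds = np.full(L, 0, np.int8)  # 0 monomorphic
    b0 = d_eff
    b1 = b0 + r_shared
    b2 = b1 + r_px
    b3 = b2 + r_py
    kinds[u < b0] = 1  # fixed difference
    kinds[(u >= b0) & (u < b1)] = 2  # shared polymorphism
    kinds[(u >= b1) & (u < b2)] = 3  # private in X
    kinds[(u >= b2) & (u < b3)] = 4  # private in Y

    samples_x = [f"X{i+1}" for i in range(n_x)]
    samples_y = [f"Y{i+1}" for i in range(n_y)]
    records: list[VariantRecord] = []
    for pos in np.flatnonzero(kinds):
        kind = kinds[pos]
        if kind == 1:
            hx = np.zeros(2 * n_x, np.int8)
            hy = np.ones(2 * n_y, np.int8)
        else:
            q = rng.random()
            hx = (rng.random(2 * n_x) < q).astype(np.int8) if kind in (2, 3) else np.zeros(2 * n_x, np.int8)
            hy = (rng.random(2 * n_y) < q).astype(np.int8) if kind in (2, 4) else np.zeros(2 * n_y, np.int8)
            if hx.sum() + hy.sum() == 0:
                continue  # polymorphism lost in sampling: site is monomorphic
        ref, alt = ("A", "G")
        gts = [tuple(hx[2 * i : 2 * i + 2]) for i in range(n_x)] + [
            tuple(hy[2 * i : 2 * i + 2]) for i in range(n_y)
        ]
        records.append(
            VariantRecord(
                chrom=chrom, pos=int(pos), ref=ref, alts=(alt,),
                genotypes=[(int(a), int(b)) for a, b in gts],
                depths=[30] * (n_x + n_y), quals=[99] * (n_x + n_y),
                samples=samples_x + samples_y,
            )
        )

    callable_regions = [RegionSpec(chrom, 0, L, "other")]
    truth = TruthRecord(
        "simulate_divergent_populations",
        seed,
        {"L": L, "T_gen": T_gen, "mu": mu, "pi_x": pi_x, "pi_y": pi_y,
         "n_x": n_x, "n_y": n_y},
        {"expected_da": d, "expected_dxy": d + (pi_x + pi_y) / 2.0,
         "expected_t_gen": T_gen},
    )
    result = DivergentPopulations(
        records, callable_regions, samples_x, samples_y, chrom, L, truth
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_vcf(
            os.path.join(out_dir, "populations.vcf"), records,
            samples_x + samples_y, {chrom: L},
        )
        write_bed(os.path.join(out_dir, "callable.bed"), callable_regions)
        for name, samples in (("samples_x.txt", samples_x), ("samples_y.txt", samples_y)):
            with open(os.path.join(out_dir, name), "w") as fh:
                fh.write("\n".join(samples) + "\n")
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return result


def genotype_matrix(pops: DivergentPopulations):
    """Assemble the GenotypeMatrix container from simulated records."""
    from .popgen import GenotypeMatrix

    n_x = len(pops.samples_x)
    positions = np.array([r.pos for r in pops.records], np.int64)
    gx = np.array([[g for g in r.genotypes[:n_x]] for r in pops.records], np.int8)
    gy = np.array([[g for g in r.genotypes[n_x:]] for r in pops.records], np.int8)
    if positions.size == 0:
        gx = np.zeros((0, n_x, 2), np.int8)
        gy = np.zeros((0, len(pops.samples_y), 2), np.int8)
    return GenotypeMatrix(pops.chrom, positions, gx, gy,
                          pops.samples_x, pops.samples_y)


# ---------------------------------------------------------------------------
# Rearranged genomes (synteny tables)
# ---------------------------------------------------------------------------


@dataclass
class RearrangedGenomes:
    ref_query: list[SyntenyBlock]
    ref_outgroup: list[SyntenyBlock]
    query_outgroup: list[SyntenyBlock]
    truth: TruthRecord


def _tile_blocks(
    rng: np.random.Generator,
    ref_chrom: str,
    length: int,
    query_name_at,
    min_block: int = 100_000,
    max_block: int = 500_000,
    max_gap: int = 20_000,
    inversion_prob: float = 0.0,
    force_edges: tuple[int, ...] = (),
) -> list[SyntenyBlock]:
    blocks: list[SyntenyBlock] = []
    pos = int(rng.integers(0, max_gap + 1))
    q_offsets: dict[str, int] = {}
    while pos < length - min_block:
        size = int(rng.integers(min_block, max_block + 1))
        end = min(pos + size, length)
        for edge in force_edges:  # never let a block straddle a true breakpoint
            if pos < edge < end:
                end = edge
        qc = query_name_at(pos, end)
        q0 = q_offsets.get(qc, 0)
        strand = "-" if rng.random() < inversion_prob else "+"
        blocks.append(SyntenyBlock(ref_chrom, pos, end, qc, q0, q0 + (end - pos), strand))
        q_offsets[qc] = q0 + (end - pos) + int(rng.integers(0, max_gap + 1))
        pos = end + int(rng.integers(0, max_gap + 1))
    return blocks


def simulate_rearranged_genomes(
    karyotype: dict[str, int] | None = None,
    event: str = "fission",
    event_chrom: str | None = None,
    breakpoint: int | None = None,
    inversion_prob: float = 0.05,
    stray_blocks: int = 0,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> RearrangedGenomes:
    """Synteny tables consistent with a fission/fusion/none event.

    ``fission``: the query lineage split ``event_chrom`` at ``breakpoint``
    (the outgroup matches the intact reference chromosome). ``fusion``: the
    reference chromosome is a fusion of two ancestral chromosomes that the
    outgroup retains separately (the query shares the fused state, the
    post-split case the tables can express). ``none``: strict 1:1.
    """
    if event not in {"fission", "fusion", "none"}:
        raise ValueError(f"unknown event {event!r}")
    karyotype = dict(
        karyotype
        if karyotype is not None
        else {"chr1": 20_000_000, "chr2": 15_000_000, "chr3": 10_000_000}
    )
    rng = np.random.default_rng(seed)
    if event_chrom is None:
        event_chrom = next(iter(karyotype))
    if breakpoint is None:
        breakpoint = karyotype[event_chrom] // 2

    ref_query: list[SyntenyBlock] = []
    ref_outgroup: list[SyntenyBlock] = []
    query_outgroup: list[SyntenyBlock] = []
    for i, (chrom, length) in enumerate(karyotype.items(), 1):
        is_event = chrom == event_chrom and event != "none"

        def q_name(lo: int, hi: int, i=i, is_event=is_event) -> str:
            if is_event and event == "fission":
                return f"q{i}" if (lo + hi) / 2 < breakpoint else f"q{i}b"
            return f"q{i}"

        def o_name(lo: int, hi: int, i=i, is_event=is_event) -> str:
            if is_event and event == "fusion":
                return f"o{i}" if (lo + hi) / 2 < breakpoint else f"o{i}b"
            return f"o{i}"

        edges = (breakpoint,) if is_event else ()
        ref_query.extend(
            _tile_blocks(rng, chrom, length, q_name,
                         inversion_prob=inversion_prob, force_edges=edges)
        )
        ref_outgroup.extend(
            _tile_blocks(rng, chrom, length, o_name,
                         inversion_prob=inversion_prob, force_edges=edges)
        )
        # query-outgroup table in query coordinates (ancestral = outgroup state)
        for b in _tile_blocks(rng, chrom, length, q_name, force_edges=edges):
            query_outgroup.append(
                SyntenyBlock(b.query_chrom, b.query_start, b.query_end,
                             o_name(b.ref_start, b.ref_end), b.ref_start,
                             b.ref_end, "+")
            )
    for _ in range(stray_blocks):
        donor = ref_query[int(rng.integers(len(ref_query)))]
        other = [b.query_chrom for b in ref_query if b.query_chrom != donor.query_chrom]
        if other:
            ref_query.append(
                SyntenyBlock(
                    donor.ref_chrom, donor.ref_start,
                    min(donor.ref_start + 10_000, donor.ref_end),
                    other[int(rng.integers(len(other)))], 0, 10_000, "+",
                )
            )

    truth = TruthRecord(
        "simulate_rearranged_genomes",
        seed,
        {"karyotype": karyotype, "event": event, "event_chrom": event_chrom,
         "breakpoint": breakpoint, "inversion_prob": inversion_prob,
         "stray_blocks": stray_blocks},
        {"expected_event": {"fission": "fission_in_query", "fusion": "fusion",
                            "none": "none"}[event]},
    )
    result = RearrangedGenomes(ref_query, ref_outgroup, query_outgroup, truth)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_synteny_blocks(os.path.join(out_dir, "ref_query.tsv"), ref_query)
        write_synteny_blocks(os.path.join(out_dir, "ref_outgroup.tsv"), ref_outgroup)
        write_synteny_blocks(os.path.join(out_dir, "query_outgroup.tsv"), query_outgroup)
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return result


# ---------------------------------------------------------------------------
# Transcript loci
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


def simulate_transcript_locus(
    n_exons: int = 10,
    exon_lengths: list[int] | None = None,
    cds_start: tuple[int, int] = (1, 0),
    domain_map: dict[str, tuple[int, int]] | None = None,
    skippable_exon: int | None = None,
    skippable_mod3: int | None = None,
    plant_ese: tuple[int, int, str] | None = None,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> tuple[TranscriptModel, TruthRecord]:
    """A coding-compatible toy transcript with controllable skipping outcome.

    The CDS is built from non-stop codons with a terminal TAA, so the only
    stop in the full-length frame is the last codon. ``skippable_mod3``
    forces the designated exon's length modulo 3 (0 = frame-preserving
    skip, 1/2 = frameshift). ``plant_ese`` = (exon_id, offset, word) writes
    a motif into an exon; the planted word must be stop-free in every
    frame to keep the CDS coding-compatible (the default enhancer word
    CAGCAGA is).
    """
    rng = np.random.default_rng(seed)
    if exon_lengths is None:
        exon_lengths = [int(rng.integers(81, 160)) for _ in range(n_exons)]
    if len(exon_lengths) != n_exons:
        raise ValueError("exon_lengths must have n_exons entries")
    exon_lengths = list(exon_lengths)
    if skippable_exon is not None and skippable_mod3 is not None:
        idx = skippable_exon - 1
        shift = (skippable_mod3 - exon_lengths[idx]) % 3
        exon_lengths[idx] += shift
    total = sum(exon_lengths)
    cds_offset_tx = sum(exon_lengths[: cds_start[0] - 1]) + cds_start[1]
    n_coding = total - cds_offset_tx
    n_codons = n_coding // 3
    codons = [ _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons) ]
    if n_codons >= 1:
        codons[-1] = "TAA"
    leader = "".join("ACGT"[i] for i in rng.integers(0, 4, cds_offset_tx))
    tail = "".join("ACGT"[i] for i in rng.integers(0, 4, n_coding - 3 * n_codons))
    tx = leader + "".join(codons) + tail

    if plant_ese is not None:
        ex_id, off, word = plant_ese
        if any(w in {"TAA", "TAG", "TGA"} for w in
               (word[i:i+3] for i in range(len(word) - 2))):
            raise ValueError("planted word contains a stop codon triplet")
        start_tx = sum(exon_lengths[: ex_id - 1]) + off
        if start_tx + len(word) > total:
            raise ValueError("planted word exceeds transcript")
        tx = tx[:start_tx] + word + tx[start_tx + len(word):]

    exons: list[Exon] = []
    g, t = 0, 0
    for i, ln in enumerate(exon_lengths, 1):
        exons.append(Exon(i, g, g + ln, tx[t : t + ln]))
        g += ln + int(rng.integers(200, 2000))  # intron
        t += ln
    model = TranscriptModel(exons, cds_start, "+", dict(domain_map or {}))
    truth = TruthRecord(
        "simulate_transcript_locus",
        seed,
        {"n_exons": n_exons, "exon_lengths": exon_lengths,
         "cds_start": list(cds_start), "skippable_exon": skippable_exon,
         "skippable_mod3": skippable_mod3, "plant_ese": list(plant_ese) if plant_ese else None},
        {"frame_preserving_skip": (
            None if skippable_exon is None
            else exon_lengths[skippable_exon - 1] % 3 == 0)},
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(os.path.join(out_dir, "exons.fa"),
                    [(f"exon{e.exon_id}", e.seq) for e in model.exons])
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return model, truth
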