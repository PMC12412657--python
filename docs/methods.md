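# Methods

This note documents the models implemented in fissionkit, the choices made
where the design was genuinely open, the synthetic-data generators and
their calibration, and the limits of what the test suite demonstrates.
No empirical number appears here that the tests or `scripts/acceptance.py`
do not themselves compute.

## SND polarization

Given column-aligned target/query/outgroup sequences, a site yields a
record only when target ≠ query and the outgroup matches exactly one of
them; the unmatched lineage carries the derived allele. Sites where the
outgroup matches neither, carries a fourth allele, or where any sequence
has a non-ACGT character are discarded — no parsimony rescue, so every
emitted polarization is forced by the data. A substitution is
weak-to-strong (W→S) iff the ancestral base is A/T and the derived base is
G/C. CpG context is not masked (no such filter is applied anywhere in the
pipeline; adding one is future work).

## BCS and UBCS

A **bias-clustered substitution** is a W→S SND lying in at least one
300-bp window containing ≥ 4 same-lineage SNDs of which ≥ 80% are W→S.
Two numerical details:

* **Window enumeration.** The content of a width-w interval changes, as
  the interval slides, only at offsets x ∈ {p − w + 1} ∪ {p + 1} over SND
  positions p. Evaluating exactly these change-points enumerates every
  distinct SND subset any interval can contain, and is therefore exactly
  equivalent to scanning all integer offsets. (Scanning only windows
  anchored at SND positions is *not* equivalent: a left-shifted interval
  can exclude trailing non-W→S substitutions that would break the 80%
  fraction. The tests prove equivalence against a brute-force oracle that
  slides over every integer offset.)
* **Fraction threshold.** "≥ 80%" is compared in exact integer arithmetic
  (ws_count × 5 ≥ count × 4) after snapping the configured fraction to a
  small rational, so the 4-of-5 boundary case is kept rather than lost to
  binary floating-point representation.

**UBCS** of a region is observed BCS minus an expectation, with sign
observed − expected so that positive values mean an excess of clustered
bias (the sign convention is recorded in all outputs). The expectation is
defined by Monte-Carlo permutation: W→S labels are shuffled uniformly over
the region's SND positions (positions and the W→S count preserved),
default 1000 replicates, seeded per (seed, chromosome, region start) so a
region query reproduces the matching tile of a windowed scan. This null
conditions on local SND density and isolates clustering-of-bias as the
signal. Under i.i.d. labels the observed configuration is itself a draw
from the permutation null, so E[UBCS] = 0 exactly — the null-calibration
test verifies this. UBCS is *not* additive across regions: each region's
null is conditioned locally, so the statistic of a union need not equal
the sum.

## Fission dating

With R1 = UBCS_query/UBCS_target on the breakpoint flank and
R2 = UBCS_query(telomeric)/UBCS_query(interior control of equal width),

    T = T_DIV × (1 − R1/R2).

The estimator is implemented exactly in this printed form. T_DIV is always
supplied by the caller (e.g. from an external demographic analysis), never
estimated here. Estimates outside [0, T_DIV] are reported raw with an
out-of-range flag — clamping would hide model misfit. Degenerate inputs
(zero denominator UBCS) raise errors naming the offending region. Region
widths are free parameters of the BED input; the bundled generator uses
4-Mb regions (flank = breakpoint ± 2 Mb) as its study conditions, chosen
so that twenty desk-scale replicates estimate the recovery mean with a few
percent precision.

## The fission-triple generator

`simulate_fission_triple` plants lineage-polarized SNDs on one chromosome
(default 24 Mb, breakpoint at 16 Mb) with three labelled regions: an
always-telomeric region, an interior control of identical width, and the
breakpoint flank. Its parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `snd_rate` | 3×10⁻³ /bp | scattered SNDs per lineage (Poisson) |
| `ws_base_frac` | 0.1 | W→S fraction of scattered labels |
| `cluster_rate` | 3×10⁻⁵ /bp | baseline rate of coherent W→S clusters |
| `cluster_size`, `cluster_span` | 6 in 300 bp | SNDs per planted cluster |
| `k_tel` | 3 | telomeric amplification of cluster intensity |
| `f` | 0.4 | onset fraction T/T_DIV of the planted signal |
| `t_div` | 2.8×10⁶ yr | divergence time carried into the truth record |

Planted intensities: telomeric regions ×k_tel in both lineages, the query
breakpoint flank ×k_tel(1−f), the target flank and control ×1. This is a
**formula-consistent calibration**: it makes E[R1]/E[R2] = 1 − f by
construction, so the printed estimator recovers T = f·T_DIV in
expectation. The recovery tests therefore validate the *implementation* of
the statistic and estimator, not the biological derivation of the formula.

Two structural choices make the calibration hold for the statistic itself
and not merely for the planted intensities:

1. **Position/label decoupling.** Cluster *positions* are planted at the
   same rate (cluster_rate × k_tel) in every region; only the fraction of
   clusters whose labels are coherently W→S varies (activation
   probability m/k_tel for regional multiplier m). Inactive clusters get
   base-rate labels.
2. **Background-only compensation.** The W→S mass removed by deactivating
   clusters is returned to the *scattered* background (never to dense
   positions), holding each region's SND density and total W→S fraction
   constant.

Together these make the permutation expectation region-independent. This
matters because the expectation grows nonlinearly with a region's W→S
concentration (shuffled labels re-qualify dense windows); without the
decoupling, regional UBCS ratios are compressed or inflated by tens of
percent and the estimator is visibly biased. The low scattered W→S
fraction (0.1) likewise keeps the permutation null far from the planted
signal; it is lower than genome-wide W→S fractions in real mammalian
comparisons, a deliberate trade of realism for a sharp validation target.

The generated genomes carry terminal (TTAGGG)n arrays (30 kb) and an ITS
of the same repeat at the breakpoint, so the telomere stage can run on the
same simulation. SND base identities are drawn consistently with each
record's W→S status and outgroup-equals-ancestral polarization.

## Two-population generator and Da dating

`simulate_divergent_populations` draws independent biallelic sites of
three kinds on an L-bp chromosome (defaults L = 1 Mb, n = 13 + 14
diploids, μ = 3.03×10⁻⁹, T = 10⁵ generations, π_x = π_y = 10⁻³):

* **Fixed interspecific differences** with per-site probability
  calibrated so E[Da] = 2μT exactly (see below).
* **Shared ancestral polymorphism**: the same allele frequency
  q ~ U(0,1) in both populations, genotypes binomial. Such a site
  contributes 2q(1−q) to Dxy and 2q(1−q) to (π_x+π_y)/2 in expectation —
  identical, so Da is untouched. Sites occur at rate 3·min(π_x, π_y),
  since E[2q(1−q)] = 1/3.
* **Private polymorphism** (only when π_x ≠ π_y): derived allele at
  q ~ U(0,1) in one population, the other fixed ancestral. Per site this
  adds 1/2 to Dxy but only 1/6 through the mean-π term; the overshoot is
  subtracted from the fixed-difference budget, which errors out if the
  budget goes negative (infeasible parameter combination).

Consequences: E[Dxy] = 2μT + (π_x+π_y)/2 and E[Da] = 2μT hold exactly,
so T̂ = D̂a/(2μ) is unbiased under the generator; the recovery test checks
the 20-seed mean against truth within Monte-Carlo error. Sites are
independent — no linkage, no recombination structure, no mutation-rate
heterogeneity — which is adequate for mean statistics but says nothing
about haplotype-based inference.

Windowed estimation divides per-site sums by **callable sites** (supplied
as a BED, defaulting to the full window), so monomorphic callable sites
dilute the averages as they do in all-sites genotyping output.

## Differentiation statistics and filters

* Per-site π = 2j(n−j)/(n(n−1)) over called chromosomes; dxy =
  p_x(1−p_y) + p_y(1−p_x). Half-called genotypes contribute their called
  allele to π/dxy but are excluded from the FST components, which need
  heterozygote frequencies.
* FST follows Weir & Cockerham (1984), two populations, with windowed
  ratio-of-sums Σa/Σ(a+b+c) (the "weighted" convention); per-site
  components are also exposed. The tests verify the components against an
  independent ANOVA mean-squares implementation to 10⁻¹², and negative
  estimates are reported raw.
* The exact Hardy-Weinberg test is two-sided by probability mass over all
  heterozygote counts with the observed allele counts, applied after
  genotype masking.
* Mann-Whitney contrasts use exact enumeration when both samples have
  ≤ 12 observations — implemented as a generating-function DP over doubled
  midranks, so ties are handled exactly, with two-sided p defined as
  P(|T − E T| ≥ |t_obs − E T|) — and otherwise scipy's normal
  approximation with tie and continuity corrections. The two paths agree
  within |Δp| ≤ 0.02 at n = 12 vs 12 in the tests.
* The variant filter masks genotypes first (GQ < 20, DP outside [5, 150]),
  then removes sites in order: multiallelic, within 5 bp of an indel,
  called fraction < 0.95 ("max-missing" in the vcftools sense: 1 = no
  missing allowed), MAF < 0.05, exact-HWE p < 0.001. Each removed record
  carries its first failing rule; the filter is idempotent. The SV screen
  requires length ≥ 50 bp, missing rate ≤ 0.05, homozygous presence in
  every called focal individual and absence in every called non-focal one.
* Local-ancestry fractions are haplotype-base fractions: foreign bases in
  the window divided by (number of haplotypes × window length). Gene
  density counts genes by start position per tiling window.

## Telomere scanning

Non-overlapping exact matches of the repeat unit (default TTAGGG) and its
reverse complement are counted per tiling window (default 10 kb); density
is motif-bases over window-bases. Matches straddling a window boundary are
not counted — at most one unit per boundary, negligible against the
calling threshold. Calling merges windows with density ≥ 0.4 (gap
tolerance 1 window), keeps runs spanning ≥ 1 kb, and labels a run terminal
if it touches the first or last 100 kb of the chromosome. All thresholds
are package choices exposed as flags; no degenerate/fuzzy unit matching is
attempted. Planted-array recovery is window-quantized, hence the
"boundary error ≤ 1 window" contract in the tests.

## Synteny polarization

For each reference chromosome, blocks (≥ 8 kb after the standard length
filter) are partitioned by query chromosome. A candidate split needs ≥ 2
query chromosomes, each covering ≥ 5% of the reference chromosome with
≥ 2 blocks. The breakpoint is the gap between the two sides after
majority-ordering, tolerating up to 10% of block-bases as strays (flagged
in diagnostics); worse interleaving yields "ambiguous". Polarity comes
from the outgroup: a single outgroup chromosome covering both sides of the
candidate breakpoint means the ancestral state was intact — a fission in
the query lineage; two different outgroup chromosomes mean the reference
chromosome is a fusion product (also detected when the query side is 1:1).
Inversions never affect the call: only the query-chromosome identity of
blocks matters, strand is reported but unused. Support thresholds are
package choices sized so toy chromosomes with ≥ 10 blocks classify stably.

The fixture generator tiles chromosomes with 100–500-kb blocks, small
gaps, optional inversions and stray blocks, and never lets a block
straddle a planted breakpoint, so localization accuracy is bounded by one
inter-block gap.

## Splicing

The packaged SR-protein matrices (SRSF1/2/5/6) are **synthetic
stand-ins** — consensus-anchored log-odds tables built for this package
(see `src/fissionkit/data/ese_matrices/README.md`); their absolute scores
are not comparable to any external tool. A window's score is the sum of
per-position weights; a hit passes at the factor's threshold. "Disrupted"
means the wild type passes and the mutant does not (threshold crossing);
the raw Δscore is reported alongside, since any fixed cutoff is a coarse
reading of "significantly reduced". Matrices are strand-specific, so
reverse-complement scanning is intentionally not equivalent.

Exon skipping: frame preservation is the skipped exon's *coding* length
mod 3. The premature stop is found by translating the skipped isoform from
the CDS start; for frameshifts it is the first in-frame stop downstream of
the new junction. A frame-preserving skip can still create a junction stop
from fused codons — that case is detected and reported as a PTC too. A
domain whose exon range begins at or after the PTC exon is "lost"; one
that straddles it is "partially truncated". Amplicons are measured between
a forward anchor (inclusive) and reverse anchor (exclusive) in each
isoform's transcript coordinates, so inclusion − exclusion always equals
the skipped exon length. Skipping the CDS-start exon or a terminal exon is
rejected as unsupported; fully non-coding exons have no consequence to
call.

## What the tests do and do not show

Passing tests demonstrate that each statistic matches its mathematical
definition (exhaustive/brute-force oracles), that the estimators recover
the parameters of the generating models, and that the pipeline is
deterministic under seeds. The generators omit linkage, alignment error,
repeat-induced mis-polarization, CpG hypermutability, degenerate telomere
units and rate heterogeneity, so the recovery results do not certify
accuracy on real genomes — in particular, UBCS-based dating inherits the
printed estimator's assumptions and the user's T_DIV. Gel-measured
amplicon sizes in real experiments are approximate; consequence
predictions here are computed from whatever transcript model is supplied,
never hard-coded to a particular expected outcome.
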