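# fissionkit

Tools for dating and characterising **chromosomal fissions** from
comparative genomic data, built around the case of a centric fission that
distinguishes two sister species of zokor (subterranean rodents): one
lineage retains the ancestral chromosome, the other carries its two
fission products, each capped by a neo-telomere. The package implements
the computational core of such a study as a tested, reusable pipeline —
with seeded synthetic-data generators so every stage can be validated
against known ground truth without access to the original genomes.

Audience: comparative/population genomicists who need the individual
stages (UBCS dating, windowed differentiation, ITS scanning, synteny
polarization, splicing-consequence prediction) as a library or CLI.

## What it computes

**Fission dating from GC-biased clustered substitutions (UBCS).**
Single-nucleotide differences (SNDs) between a target and query genome are
polarized with an outgroup; a substitution is weak-to-strong (W→S) when an
ancestral A/T became G/C. A *bias-clustered substitution* (BCS) is a W→S
SND inside a 300-bp window holding ≥ 4 SNDs of which ≥ 80% are W→S — the
footprint of GC-biased gene conversion, strongly elevated near telomeres.
UBCS in a region is the excess of observed BCS over a seeded permutation
expectation (W→S labels shuffled over the region's SND positions). A
neo-telomere at a fission breakpoint has accumulated this signature for
only part of the species' history, so with

- R1 = UBCS(query breakpoint flank) / UBCS(target breakpoint flank),
- R2 = UBCS(query telomeric region) / UBCS(query interior control),

the fission age is estimated as **T = T_DIV × (1 − R1/R2)**.

**Da-based mutation dating.** Windowed π, Dxy and net divergence
Da = Dxy − (π_x + π_y)/2; divergence time **T = Da/(2μ)** generations
(default μ = 3.03 × 10⁻⁹ per site per generation, 1 year/generation).

**Windowed differentiation.** Weir–Cockerham (1984) FST components with
ratio-of-sums windowing, Dxy over callable sites, region-class contrasts
(breakpoint flank vs fissioned chromosome vs rest) with exact
Mann–Whitney rank-sum tests, local-ancestry fractions, gene and
selected-site densities, and the hard/soft SNP filter chain
(GQ/DP masking, biallelic, indel proximity, missingness, MAF, exact HWE)
plus an SV fixation screen.

**Telomere scanning.** (TTAGGG)n arrays per window, merged into terminal
telomeres vs interstitial telomeric sequences (ITS) — fission-seed
candidates.

**Synteny polarization.** Whether a chromosome split is a fission in the
query lineage or a fusion in the reference lineage, decided by outgroup
continuity across the candidate breakpoint, plus breakpoint localization.

**Splicing consequences.** Position-weight-matrix scanning for exonic
splicing enhancers (SR-protein motifs), classification of point mutations
as motif-disrupting, and exon-skipping outcomes: reading-frame
preservation (mod 3), premature termination codon location, truncated
protein domains, and RT-PCR amplicon sizes for both isoforms.

## Worked example

```bash
fissionkit demo --seed 7 --out-dir demo_out
```

prints

```
fission T-hat 1.005e+06 yr (truth 1.120e+06); Da T-hat 9.894e+04 gen (truth 1e5); 3 telomere-array calls; synteny: ['fission_in_query', 'none', 'none']
```

Reading: the demo simulates a genome triple whose planted fission signal
corresponds to a fission 1.12 Myr ago (T_DIV = 2.8 Myr, onset fraction
f = 0.4); the UBCS estimator recovers 1.005 Myr on this one seed. The
two-population simulation diverged 10⁵ generations ago and the Da
estimator returns 9.89 × 10⁴. The repeat scan on the simulated chromosome
finds its two terminal telomeres plus the planted interstitial array at
the breakpoint, and the synteny stage polarizes the planted event as a
fission in the query lineage with no events on the control chromosomes.
`demo_out/demo_report.json` holds the full numbers.

Each stage is also exposed separately — `sim`, `snd`, `ubcs`,
`date-fission`, `popgen`, `date-da`, `filter`, `telomere`, `synteny`,
`splice` — see `fissionkit <cmd> --help`; all stochastic stages take an
explicit `--seed` and echo it into their outputs.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generators and
their calibration, numerical choices, and known limitations.
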