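# Methods

## The inference problem

In a sample of clonally related strains, a variant observed in exactly one
strain (a singleton) arose on that strain's terminal branch. How long that
terminal branch is — equivalently, how recently the strain diverged from
its closest sampled relative — is estimated by the density of the strain's
singletons: a strain chromosome carrying *n* singletons on *L* kb assigns
age *n/L* (events/kb) to each of them. Density is a lineage-level proxy for
identity by descent, not a per-mutation clock: all singletons of one
(strain, chromosome) pair share one age, and the age is only as fine as the
genealogy is varied. The youngest density classes are enriched for
mutations below the selection–drift barrier, so their spectrum approaches
the raw mutational input, which is the quantity of interest.

Time is left in arbitrary units throughout; only relative ages matter, and
nothing in the pipeline attempts to calibrate generations or an absolute
per-generation mutation rate.

## Simulator

The generator produces the joint objects every downstream stage consumes:
reference, annotation, multi-sample variant set, and a truth ledger.

**Genealogy.** A random bifurcating tree over *N* strains with exponential
waiting times at rate k(k−1)/2 while k lineages remain (Kingman-type).
The first (most recent) coalescence can be pinned at `closest_pair_depth`,
guaranteeing one very recently diverged pair — without it the sample may
contain no very young singletons at all. Acceptance-level checks avoid any
dependence on finer tree-shape details than terminal vs internal.

**Reference genome.** Per chromosome, coding genes of 100–500 codons are
laid down until the target coding fraction (default 0.70) is met, separated
by noncoding gaps drawn multinomially; each gene is ATG + uniform sense
codons + a uniform stop, on a random strand. Uniform sense codons are
51.4% GC (94/183), so the noncoding composition is solved from
gc_nc = (gc_target − f·0.514)/(1 − f) to hit the genome-wide target
(default 0.38, yeast-like) within the ±2% contract.

**Mutations.** Events are Poisson with mean
`mutations_per_kb_total_depth × genome kb` summed over the genealogy;
`terminal_branch_fraction` (default 0.5) fixes the share of events on
terminal branches by re-weighting branch lengths, and each event's true age
is uniform along its branch. A SNP event draws one of the six
strand-collapsed classes from the spectrum and then a site uniformly among
sites whose collapsed base matches the class source (C-classes mutate C or
G sites, T-classes T or A sites); optional 32-triplet context modifiers
re-weight eligible sites multiplicatively. A second hit on an occupied
position is redrawn, so multi-allelic sites never arise. Indel events
(default 0.1 per SNP event) fall uniformly, half insertions half deletions,
lengths geometric (mean 2, capped at 6 bp); both representations are
left-normalised before emission.

**Selection.** A nonsynonymous or nonsense SNP of true age *a* survives
with probability 2^(−a/selection_halflife); synonymous and noncoding
mutations always survive; coding indels decay with their own (shorter)
half-life, and noncoding indels are neutral. This one-parameter survival
curve is deliberately minimal: it encodes "the older a constrained
mutation, the likelier selection has removed it" and nothing else.

**Emitted qualities.** Every record carries MQ=60, GQ=99, QUAL=100, DP=50
with half the reads supporting the alternate allele. Filter behaviour is
therefore exercised by deliberately corrupted fixtures in the tests, never
entangled with simulation randomness. Strains are haploid; recombination,
aneuploidy, introgression and sequencing-error models are out of scope.

## Statistics

**%Pn.** Nonsynonymous / (nonsynonymous + synonymous) among coding SNPs.
Nonsense changes are excluded from both counts by default: enumerating all
61×9 = 549 single-base codon changes at equal codon frequency and equal
per-change probability gives 392/526 = 0.745 → 0.75 under this convention
versus 415/549 = 0.756 → 0.76 when stop gains count as nonsynonymous; only
the former reproduces the canonical neutral value of 0.75, and the
convention is switchable (`nonsense_as_nonsyn`). Codons are read on the
annotated strand; a change inside a terminal stop codon is synonymous if it
hits another stop, otherwise nonsynonymous (stop loss). Overlapping
annotations resolve to the first interval, logged.

**Ts/Tv.** Transitions {A↔G, C↔T} over transversions; zero transversions
is reported as undefined, never infinity.

**GCeqm.** With v = (#AT→GC changes)/(#A/T sites) and u = (#GC→AT
changes)/(#G/C sites) over the analysed (mask-subtracted) genome,
GCeqm = 100·v/(u+v); GC-conservative changes (C↔G, A↔T) are ignored.
The estimator is the standard equilibrium of two opposing per-site fluxes:
if the genome already sits at GC = v/(u+v), opposing counts balance and the
estimate returns the genomic GC content.

**Rate tables.** Six-class rates are (class count)/(eligible source
sites), normalised to sum to one; the 32 neighbour environments (5' base ×
focal pyrimidine × 3' base, purine-focal triplets reverse-complemented)
are normalised by genomic occurrence counts of each environment. All
changes from a focal base are pooled per environment (outcome-subdivided
tables were considered and left out: pooling is the primary reading and
keeps per-cell counts usable at these sample sizes). Rate tables are
compared class-by-class with a pooled two-proportion Z-test on mutation
counts, Bonferroni-corrected by the number of classes compared (6 or 32),
with significance stars at 0.05/0.01/0.001.

**Bootstrap.** Standard errors come from 500 seeded resamples of variants
(the resampling unit is the variant, not the site). For rate tables, where
the statistic depends on the data only through class counts, row resampling
is performed as an equivalent multinomial redraw of the counts. A statistic
undefined on more than 10% of resamples raises rather than returning a
quietly truncated SE.

## Aging and binning choices

* Density groups are per (carrier strain, chromosome) — the strain's
  chromosome is the lineage unit; pooling across strains is available as a
  switch for comparison.
* Ages use full chromosome length by default; an effective-length switch
  ages against mask-subtracted length instead (the choice matters only at
  the ~5% level for yeast-like masking and is exposed, not decided).
* Equal-count binning keeps tied ages together, so bin sizes can differ by
  the largest tie group; fixed young edges (e.g. 0.005/kb for SNPs,
  0.002/kb for indels) can replace the youngest equal-count bins. One
  distinct age collapses to a single bin with a warning; asking for more
  bins than distinct ages is an error.

## Indel conventions

The anchor is the first affected reference base after left-normalisation
(first deleted base; base right of the insertion point). Flanks are the
10 reference bases on either side of the affected run. The headline STR
statistic counts an indel for run length m when a single-base run of ≥ m
touches the indel boundary (suffix of the 5' flank or prefix of the 3'
flank); a window-containment variant is provided since figure-level rules
differ between studies. Coding membership is by anchor position. Indels
within 10 bp of a contig end are dropped and counted.

## Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_strains | 20 | enough lineages for a graded age axis at desk scale |
| chromosome_lengths | 300/200/120 kb | multi-chromosome, 620 kb total |
| gc_content | 0.38 | yeast-like genomic GC |
| coding_fraction | 0.70 | coding share of the analysed yeast genome |
| mutations_per_kb_total_depth | 10 /kb | ~6,200 events per run: ≥ 5,000 for recovery studies at a few seconds per run |
| terminal_branch_fraction | 0.5 | half the input on terminal branches, giving ~3,000 singletons |
| closest_pair_depth | 0.02 | one recently diverged pair (tree depth is ~2) |
| selection_halflife | 0.25 | solved from 0.75·s/(0.75·s+0.25) ≈ 0.5 at the oldest singleton ages (~0.4), matching the observed fall of %Pn toward ~0.5 in old/common variant classes |
| indel_selection_halflife | 0.08 | solved from coding-indel survival ≈ 0.1 at mean indel age ~0.25, matching ~20% coding indels against a 70% coding genome |
| indel_rate_relative | 0.1 | indels observed an order of magnitude less often than SNPs |

Validation studies use 20 replicate seeds. The %Pn-recovery study runs on
a 50% GC genome: with equal A/T and G/C site counts a uniform class
spectrum is also uniform per site and per change, which is the assumption
under which the codon-table enumeration predicts 0.75; on a 38% GC genome
the same spectrum hits G/C sites 1.63× more often per site and the
recovered %Pn sits ~0.02 higher.

## Numerical and degenerate-case choices

All filter thresholds are strict inequalities, exactly as specified; MQ and
QUAL are site-level while GQ/DP/alt-read rules apply per carrier strain
(a pooled-carrier variant is a switch). Mask intervals are 0-based
half-open against 1-based variant positions (masked iff start < p ≤ end).
Undefined statistics (no coding variants, no transversions, no GC-changing
mutations, empty bins) raise typed errors at the statistic level and are
reported as NaN cells — never dropped rows — in per-bin tables. Bootstrap
and simulation randomness derive from explicit integer seeds; identical
configs reproduce byte-identical outputs.

## What passing tests do and do not show

The simulator validates internal consistency and statistical correctness:
that the pipeline recovers known spectra, equilibria and selection
ordering from data with idealised qualities, a clean annotation, haploid
genotypes and exactly one alternate allele per site. It does not emulate
mapping artefacts, context-dependent indel error rates, ploidy variation,
repeat-driven miscalls or introgression; agreement on simulated data
therefore demonstrates the estimators, not robustness to those real-data
failure modes (the strict filters and repeat mask exist to confront them).
One known scale limitation: simulated singletons are young relative to the
selection half-life, so the overall simulated indel coding fraction
(~0.54) sits well above the ~0.20 seen in deeply diverged natural samples,
although the young-vs-old ordering — the signature the pipeline tests —
is unaffected.
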