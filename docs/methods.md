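# Methods

## The comparison model

The package compares CpG methylation between two groups of individuals in
a regime where methylation is sparse (~0.1% of CG sites), coverage is a
few reads per strand, and per-site methylation levels are noisy mixtures
over cell types.  In that regime a quantitative per-site level comparison
is underpowered, so the core rule is presence/absence across individuals:

- a CG site, covered in both groups, methylated in at least
  `min_methylated_in` (default 3) individuals of one group and in at most
  `max_methylated_out` (default 1) of the other is a group-specific DMC;
- methylated in at least `min_methylated_in` individuals of both groups, a
  CMC;
- anything else in the joint-coverage universe is unclassified.

The thresholds are absolute, not proportional: with cohorts larger than
3 + 4 the defaults stay (3, 1) unless overridden, since the rule is a
fixed evidence bar ("three independent individuals agree"), not a
fraction.

### Coverage eligibility

"Covered in both groups" has two defensible readings and both are
implemented.  **Literal**: a site qualifies if any individual of each
group covers it, and an uncovered individual simply cannot contribute a
methylation call (it counts as unmethylated).  This mirrors the simplest
joint-universe construction but lets a site be declared group-specific
when the "absent" group was barely observed.  **Strict** (the default): a
site qualifies only when at least `min_methylated_in` individuals per
group cover it, so absence of calls is backed by actual sequencing.
Strict mode is what the truth-recovery tests use; literal mode exists for
reproducing literal joint-universe census numbers.

## mCG calling

The upstream caller is a reconstruction of the field-standard procedure
for sparse methylomes: per CG record with `t ≥ min_depth` reads, the
one-sided binomial tail P(X ≥ m | Bin(t, e)) is computed against the
background rate `e`, Benjamini–Hochberg is applied across all tested
sites of the individual, and sites at adjusted value ≤ `fdr_q` (default
0.01) are methylated.  `e` is estimated as the pooled methylated/total
ratio over non-CG cytosines (these genomes have essentially no non-CG
methylation, so the ratio measures conversion failure plus sequencing
error); the estimate is clamped below by 1e-4 so a spotless background
cannot produce a degenerate test, and a background of fewer than 1,000
reads is refused rather than trusted.  `min_depth` defaults to 1 because
at ~5x per-strand coverage any higher floor discards a large fraction of
the genome; a depth-1 site can still only be called when the FDR budget
allows, which in practice requires a very clean background.

Each strand's cytosine of a CpG is called independently (the data are
per-strand and the default pipeline never merges); `merge_strands` pools
the two records onto the dinucleotide start for users who prefer
dinucleotide units.

Coordinates: count reports are 1-based on disk, 0-based half-open in
memory, BED outputs 0-based.

## DMR detection

A DMR is a chain of same-direction DMCs in which **every** run of
`min_dmcs` (default 3) consecutive members spans at most `window`
(default 250) bp.  The scan marks each qualifying window start and merges
maximal runs of *consecutive* qualifying starts into one region.  Merging
any two windows that merely share a member can produce a region whose
middle triple spans more than the window (e.g. members at 0, 10, 20, 260,
265), which would silently weaken the definition; with consecutive-start
chaining every reported DMR satisfies the definition internally, at the
price that two adjacent DMRs may share a boundary DMC.  The union of all
member positions is identical under either convention and equals the
exhaustive sliding-window oracle, which the tests enforce.

Direction homogeneity is required by default — a mixture of group-A- and
group-B-hypermethylated sites is not one regulatory event — and can be
disabled, in which case mixed clusters are labelled `mixed`.

Gene association is by interval overlap: `body` against the transcript
span (exons plus introns), `upstream`/`downstream` against strand-aware
flanks of `flank` (default 2000) bp clipped at chromosome ends.  A DMR
may associate with several genes and categories; with none it is
intergenic.

`extrapolate_fixed` scales observed fixation proportions to the full DMR
census with integer truncation: `floor(n_total * observed / tested)`.

## Enrichment and profiles

Feature labels are multi-labels: within one gene model CDS beats intron
(the generator's exons are treated as coding), but a site keeps
independent TE/smRNA labels and may carry labels from several overlapping
gene models; `intergenic` is the complement.  The 2×2 enrichment table
puts the tested feature's DMC/CMC counts (both directions pooled) against
the reference feature's, and the test is Pearson's chi-square with one
degree of freedom, no Yates correction — the tables this pipeline is
meant for have thousands of counts per cell, where the correction only
biases the statistic; a flag enables it for small tables.

Metagene profiles use 20 bins of 100 bp per 2-kb flank and 20 fractional
bins per gene body, oriented by the coding strand (upstream bins run
farthest-to-TSS).  Body binning maps position fraction f to
`min(floor(20 f), 19)`; the TSS-side boundary lands in bin 0.  Genes
shorter than 20 bp are skipped and counted.  A site in the flanks of two
neighbouring genes contributes to both — the profile is a per-gene
average, so multiplicity is the correct accounting.  "Methylation
density" is ambiguous as a phrase, so both outputs exist: raw bin counts,
and counts divided by the number of jointly covered CG sites per bin when
a universe is supplied (this corrects for CG-composition differences
between flanks and bodies).

## Amplicon validation

Reads arrive with individual ids (barcode demultiplexing is upstream).
Matching replaces an external sequence-search tool with a built-in local
alignment (match +1, mismatch −2, gap open −4, extend −1) performed in
bisulfite space — C→T applied to both read and target — so methylation
state never penalises the match; perfect matches of at least
`min_read_len` (default 100) bp always pass, and shorter matches are
discarded.  Only the forward bisulfite strand is aligned; the reverse
strand is handled by listing its expected sequence as a separate target.
Methylation is read off at reference-C positions: C retained = methylated,
T = converted, anything else unscored.

Per-site levels are methylated reads over covering reads, per individual
or pooled per sample set (the pooled level is exactly the read-weighted
mean of the individual levels).  A region is informative with covering
data from ≥ 3 new group-A and ≥ 2 new group-B individuals, fully covered
when every expected individual has data.  The fixation test needs a
quantitative reading of "consistent": an individual is consistent when
every tested site lies on the expected side — level ≤ 0.2 in the
hypomethylated group, ≥ 0.5 in the hypermethylated group — and a cluster
is fixed with ≥ 2 consistent individuals per group.  The 0.2/0.5 defaults
are this package's operationalisation (hypermethylated individuals rarely
show 100% levels because methylation is cell-type specific); both are
parameters and the reports flag them as such.

## The synthetic generator

The generator emulates: per-strand CG records at CpG-dinucleotide density
1/16 bp; a subsample of non-CG cytosines (density 0.02/bp) whose only
role is to carry the conversion-failure background; methylation planted
per dinucleotide, symmetrically on both strands, at `mcg_density`
(default 0.001); a fraction `planted_dmc_fraction` (default 0.05, chosen
to match the observed ratio of differential to universe methylated sites
in this kind of cohort) of methylated dinucleotides made group-fixed,
plus `planted_dmr_count` (default 5) clusters of three dinucleotides
within 200 bp so the DMR stage has ground truth; per-individual
epipolymorphism (default 0.3) that deletes a group-level methylated state
from an individual; coverage as Bernoulli(`covered_fraction`, default
0.75) times a zero-truncated Poisson(`mean_coverage_per_strand`, default
5) so the covered-fraction invariant is exact; and methylated-read counts
Binomial(depth, p) with p = `partial_methylation_level` (default 0.8) at
methylated sites and `conversion_failure_rate` (default 0.005) elsewhere.
Defaults are the study conditions the rules assume: a 3 + 4 cohort, 0.1%
mCG, 4–6x per strand, ~75% of cytosines covered.

Randomness is one master seed with fixed substreams — annotation, truth
planting, one per individual — so adding an individual never perturbs the
data of earlier ones.

What the generator does **not** emulate: real sequence context (sites are
a positional catalogue, not drawn from an explicit genome sequence), read
mapping artefacts, strand-asymmetric or regionally clustered background
methylation, coverage autocorrelation along the genome, or non-CG
methylation.  Passing tests therefore demonstrate the correctness of the
rules and their power under idealised independent-site noise, not
robustness to alignment or sequence-composition artefacts in real
libraries.

The "noise-free limit" used in recovery tests sets conversion failure to
0, partial methylation to 1, epipolymorphism to 0 and coverage to 1;
coverage dropout counts as noise because with only three group-A
individuals the strict universe otherwise removes most planted sites and
the measurement becomes one of the universe, not of the caller.  In that
limit the only loss channel left is depth-1 sites whose single read
cannot clear the FDR bar, which is why sensitivity sits near 0.96 rather
than at 1.0.

## Problem sizes

The test suite and acceptance script run synthetic cohorts of ~1e5 CG
site records (800-kb genomes, 3 + 4 individuals, three seeds) for
recovery checks, 1,000 replicate tables for type-I calibration, and 200
reads per amplicon — sizes at which every quantity checked has stable
statistics while a full run stays in the tens of seconds on one CPU.

## Known limitations

- The per-sample caller's FDR is controlled per individual, not jointly
  across the cohort; the cross-individual rule is deliberately robust to
  that.
- Literal-mode universes treat lack of coverage as lack of methylation;
  census numbers from that mode are constructions, not inferences.
- The amplicon aligner is not an e-value-calibrated database search; on
  clean targeted data its decisions coincide, but highly diverged reads
  may be dropped rather than partially matched.
- The extrapolation is a point estimate with integer truncation; no
  interval is attached (with 1 fixed region observed among 25 tested, any
  honest interval would be very wide).
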