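# Methods

## Coordinate frame

All data live on a fixed grid of 0-based, half-open genomic bins (default
1 Mb). The built-in genome uses human chromosome lengths rounded to 1 Mb
(chr1–chr22 plus chrX; chrY is added for XY samples), 3,027 autosomal + X
bins in total. Counts, GC and mappability tracks, copy states and segments
are vectors aligned 1:1 with this grid. Alignment ingestion counts primary,
non-duplicate alignments with MAPQ ≥ 30 (the proxy for "uniquely mapped";
the cutoff is a config knob, not an estimate) by leftmost mapped base.

## Synthetic embryo model

The generator is the package's stand-in for real embryo sequencing data and
defines the conditions under which the pipeline is tested.

**Lineage.** Each embryo is a balanced binary tree with `n_generations`
divisions (default 6, i.e. 64 leaves — a plausible blastocyst scale).
Sequenced cells are a random sample of leaves partitioned into TE (default
8) and ICM (default 7); hESC cells are resampled from ICM leaves, optionally
with a multiplicative fitness penalty per aneuploid chromosome (default 0 —
the data motivating hESC selection suggest no particular mechanism, so none
is assumed).

**Errors.** With probability `p_meiotic` (default 0.35, matching the rough
prevalence of meiotic errors among blastocysts that reach testing) the
zygote carries a whole-chromosome or segmental event copied into every cell.
Each of the 2^g − 1 divisions independently errs with probability
`p_mitotic` (default 0.02). This per-division rate is a documented
assumption — no measured per-division rate exists for human embryos — chosen
to give cohorts in which mosaic, non-mosaic-aneuploid and euploid embryos
all occur. An error is a non-disjunction (both daughters get reciprocal
+1/−1 over the same region; the event pair is cross-linked) or an anaphase
lag (one daughter loses a copy) with equal probability. Events are whole
chromosome or segmental (length uniform on 15–80 Mb) with equal probability.
Placements that would drive any cell's copy number below zero are resampled;
explicitly forced configurations that would do so are rejected.

**Counts.** Expected reads in bin *b* of cell *c* are
`copy[c,b]/2 · g(GC_b) · map_b · mean_depth` with `mean_depth` = 500 reads
per bin at copy 2 (roughly the 0.3× regime at 1 Mb bins). `g` is a smooth
positive bump (floor 0.3 + Gaussian in GC centred at 0.45). Counts are
negative-binomial: variance = m + αm², with per-cell α log-normal around
0.03 (log-SD 0.4), giving corrected-count CVs of ~0.15–0.3 — amplification
evenness varies strongly between WGA cells, and this heterogeneity is what
the VS filter exists to catch. One percent of bins drop out to zero. A
`deterministic` flag replaces sampling with the rounded expectation for
noiseless-limit tests.

**What it does not emulate:** chimeric/locus-specific amplification
artifacts, replication-timing waves, GC–dispersion coupling, sub-bin
breakpoints, triploidy/haploidy, and cell-cycle (S-phase) effects. Passing
recovery tests on this generator therefore demonstrates correctness of the
statistical machinery under overdispersed, GC-biased, dropout-afflicted
counts — not performance on every real-data failure mode.

## Bias correction

Counts are divided by mappability; bins with mappability < 0.8, missing
track values, or zero counts are masked (a zero bin at ~500× bin depth is an
amplification dropout, and leaving it unmasked fragments whole-chromosome
calls). The GC curve is the median of mappability-scaled counts in 20 GC
quantile bins, linearly interpolated between bin centres and linearly
extrapolated beyond the outermost centres (constant extrapolation leaves a
residual trend in the GC tails). The corrected profile is normalized so the
median over unmasked autosomal bins is 1; this anchors baseline ploidy and
assumes most of the genome is at baseline — near-triploid cells violate the
assumption and are out of scope (they surface as unanalyzable or as
implausible karyotypes, not as silent errors). Cells with all-zero counts or
fewer than 200 usable autosomal bins are flagged unanalyzable and skipped.

## Variability score

"30 sliding windows" admits several readings; the frozen recipe is: a
chromosome with *n* unmasked bins is covered by exactly 30 windows of length
⌈n/30⌉ whose starts are evenly spaced over [0, n − L] (disjoint when they
can be, overlapping otherwise); chromosomes with fewer than 30 bins fall
back to length-1 windows (zero SDs) and are flagged. Sample SD (n−1
denominator). VS = mean of the five largest per-chromosome window-SD
averages. Exclusion is cohort-relative: exactly ⌊0.15 n⌋ cells with the
highest VS are dropped, ties broken by stable input order with a warning; an
absolute-threshold mode exists for reuse. Because the score depends on this
window recipe and on the data, absolute VS values from real cohorts are not
comparable and are not used as test targets.

## Copy-number HMM

Six states (copy 0–5), emission mean *s*/2 on the corrected scale, shared
per-cell SD estimated robustly from first differences
(1.4826 · median|Δ|/√2, floor 0.02) so segments do not inflate it. A single
self-transition probability (default 1 − 10⁻⁵) sets the switching penalty:
with default noise a state change must be supported by ≳ 26 nats, i.e.
events shorter than ~5 bins are not called — consistent with the 10 Mb
reporting rule. Start distribution uniform; chromosomes decoded
independently by Viterbi (ties broken toward the lower state, so decoding is
deterministic); forward–backward posteriors of the decoded state are
available on request. Bit-level concordance with any external HMM
implementation is a non-goal; the contract is the decoding itself, which is
tested against exhaustive path enumeration on short chromosomes.

## Karyotype reporting

Maximal constant-state runs become segments (masked bins split runs);
same-state calls separated only by masked bins are re-merged before the size
test; calls spanning < 10 Mb are dropped. A call is `whole` when its
unmasked bins cover ≥ 90% of the chromosome's unmasked length (the
whole/segmental boundary is not defined by convention; 0.9 maps cleanly onto
the whole/segmental dichotomy), else `segmental`. Baselines are sex-aware
(XX: X=2; XY: X=1, Y=1; chrY is masked for XX cells).

## Mosaicism analytics

*Equivalence.* Two karyotypes are equal iff a bijection exists between
calls with the same chromosome, same delta, and reciprocal overlap ≥ 0.8.
Greedy clustering against first-member representatives makes the (not
strictly transitive) relation a partition deterministically.

*Classification.* A lineage set is evaluable with ≥ 3 cells; smaller sets
never enter a denominator. Mosaic = ≥ 2 karyotype classes. The major
karyotype is the most frequent class; a tie goes to the class containing the
euploid karyotype, else to the earliest cell (with a warning). Mosaic rate =
fraction of cells off the major karyotype. Subtype comes from the classes of
the calls by which divergent cells differ from the major karyotype
(symmetric difference) — whole only / segmental only / both → complex; this
also resolves the case of an aneuploid major karyotype with euploid
divergent cells.

*Origin.* All analyzed cells of an embryo are pooled across lineages;
single calls are clustered by the same overlap rule; a cluster carried by
every analyzed cell is meiotic, otherwise mitotic. A `meiotic_tolerance`
knob (default 0 = strict) can absorb caller false negatives; strictness is
the default because the evaluable sets are small.

*Discordance.* Per resample, m = min(|TE|, |ICM|) cells are drawn from each
lineage without replacement, paired at random, and the unmatched fraction
recorded; the statistic is the mean over resamples (seed-controlled). Its
expectation equals the mean pairwise-unequal indicator over all TE × ICM
pairs, which is exposed as the analytic version and used as the test oracle.

*Pseudo-bulk.* A multi-cell biopsy is emulated by summing raw bin counts of
a sampled subset (default 5–10 cells) and re-running the full pipeline on
the sum. For an exactly balanced complementary pair the summed profile is
flat over the shared region, so the bulk karyotype there is baseline — the
masking phenomenon that motivates single-cell analysis.

*Rates.* Group comparisons use the two-tailed unpaired Student's t-test;
groups with fewer than two values are rejected, and the degenerate
zero-variance case returns (0, 1) or (∞, 0) with a warning.

## Problem sizes and numerical choices

The recovery benchmark uses 100 simulated embryos (15 cells each, full
23-chromosome grid, ~1,500 cells), chosen as the scale at which recovery
fractions have small Monte-Carlo error while the whole suite stays fast;
the VS oracle comparison uses 1,000 cells on a 6-chromosome genome. All
randomness is seed-derived (NumPy `SeedSequence` spawning), and identical
seeds give byte-identical simulator outputs. Degenerate inputs (all-zero
cells, < 30-bin chromosomes, empty lineages, single-observation t-tests,
all-aneuploid ICM under full hESC selection) are handled explicitly as
documented above.

## Known limitations

- Sub-10 Mb CNVs, SNV/LOH, uniparental disomy and breakpoint refinement
  below bin resolution are out of scope.
- Genome-wide ploidy shifts defeat median anchoring and are flagged, not
  called.
- True homozygous (copy-0) regions are indistinguishable from amplification
  dropout at these depths and are masked rather than called.
- The per-division mitotic error rate and the hESC selection strength are
  modelling assumptions, not estimates of any real cohort; statistics that
  depend on real amplification physics (absolute VS levels, real-data mosaic
  rates and discordance means) are reported by the pipeline but are not
  reproducible from simulation and are not test targets.
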