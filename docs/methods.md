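# Methods

## Scope and data model

`paneldx` operates strictly downstream of alignment and primary small-variant
calling. Its inputs are the artifacts a capture-panel pipeline produces per
batch: a BED panel of target regions (0-based half-open, name field
`GENE|EXONLABEL`), per-exon mean-depth matrices (exons × samples, with batch
labels), per-chromosome on-target read counts, variant call sets (simplified
TSV with 1-based loci, VCF convention), annotation tables keyed by
(chrom, pos, ref, alt), and a disease → candidate-gene map with inheritance
models. Coordinates are converted at the format boundary only.

## Coverage statistics

`capture_stats` reports on-target reads, on-target bases
(reads × read length), empirical mean depth, breadth (≥ 1×) and the fraction
of targeted bases at ≥ 20×. Mean depth is computed from the per-base depth
vector rather than as reads × length / target size: after duplicate removal
and clipping the naive quotient overstates usable depth, and on real capture
data the two definitions disagree by tens of percent. QC gates default to
the worst per-sample values the panel is designed to tolerate (mean depth
77.43×, ≥ 20× fraction 90.34%, breadth 99.4%) and are inclusive: a sample
exactly at a minimum passes, since those minima describe acceptable samples.

## Dosage calling

**Exon level.** The dosage ratio of exon *e* in test sample *t* against
in-batch controls is the double median ratio

r(e) = ( d(e,t) / median_e d(·,t) ) / median_c ( d(e,c) / median_e d(·,c) ).

Medians are used at both normalization steps so the test sample's own event
does not bias its library-size estimate, and an outlier control cannot bias
the reference profile. Exons whose across-control median is zero are
returned as NaN (flagged, never silently dropped). The ratio is invariant to
rescaling any sample's depths by a positive constant.

Calling scans each gene in genomic order for maximal runs of consecutive
exons at or beyond a threshold; one run is one call, with ratio = median over
the run and copy number = round(2·ratio). Thresholds default to the midpoints
between the diploid expectation (1.0) and the heterozygous-event expectations
(1.5 gain, 0.5 loss): gain ≥ 1.35, loss ≤ 0.65, both configurable. The
minimum run length defaults to 1 — nothing forbids single-exon events — but
single-exon calls carry a `single_unit_call` caveat flag because they rest
on one measurement.

**Chromosome level.** For chromosome c, each sample's count is divided by
its autosomal total *excluding c*; the test value over the reference median
is the dosage ratio. Excluding c from its own denominator makes the trisomy
expectation exactly 1.5 rather than 1.5/(1 + 0.5·w_c), where w_c is the
chromosome's footprint share. One aneuploidy still contaminates the
denominators of the *other* chromosomes, so a second pass recomputes all
ratios with first-pass aberrant chromosomes dropped from every denominator
(the usual robust-reference construction); unaffected chromosomes then sit
at exactly 1.0 in deterministic data. Sex chromosomes receive ratios but are
classified only on request, since references must be sex-matched for X/Y.

**Segment level.** Counts in fixed-width bins tiling one chromosome's
footprint are normalized per sample by the bin total (so per-bin target
content cancels against the reference median) and the resulting relative
dosage is rescaled by its own median, which pins unaffected bins at 1.0
whenever the event spans fewer than half the informative bins. Bins with no
reference signal carry no target content; they are skipped rather than
allowed to break an event run. Runs beyond threshold are reported with the
genomic interval spanned by their bins, so localization error is bounded by
one bin width per side.

**Sex inference** places a sample's X dosage (chrX count / autosomal total)
on the male→female axis defined by two reference profiles; scores inside the
central decision band (default 0.3–0.7) return `undetermined`, and where Y
is targeted the Y signal must agree with the X call. The X dosage statistic
is exactly 2× higher in 46,XX than 46,XY regardless of total read count,
because the autosomal denominator removes library size.

`expected_copy_ratio(copies, baseline_ploidy=2)` is the qPCR relative
quantification analogue used to interpret calls (3 copies → 1.5).

## Variant prioritization

Annotation joins calls against pluggable tables carrying a local cohort
frequency, a population frequency, a known-pathogenic flag, and the number
of in-silico tools voting deleterious. A call absent from the tables has
missing frequencies and is treated as novel; a table row with no frequency
evidence and no pathogenicity assertion is likewise novel.

Filtering keeps a record when every *available* frequency is ≤ `max_freq`
(default 0.005 — "extremely rare" on a cohort scale; configurable because no
single cutoff suits all tables) or when it is a known pathogenic allele
(pathogenicity overrides frequency: well-documented recessive alleles can be
common in carriers). Removal reasons are logged per record.

Evidence gating admits known-pathogenic records (tier 1) and novel records
that are predicted deleterious (≥ 1 in-silico vote) or truncating (tier 2).
Truncation is inferred from the mutation description: frameshift (`fs`),
nonsense (protein ends in `*`), or a splice offset within ±2 of an exon
boundary. Model consistency is then judged on the qualifying records of each
gene: AR needs a homozygote or ≥ 2 heterozygotes (reported as a putative
compound heterozygote, flagged `phase_unknown` — phase is never asserted
from a call set); a single AR heterozygote is `carrier_only` and yields a
*suspected* verdict noting a possible missed second allele; AD needs one
record; XL needs a hemizygote (male) or homozygote (female), with
heterozygous females `carrier_only`.

Pass 1 examines only the candidate genes of the clinical working diagnosis;
pass 2 runs only when pass 1 is empty and scans the remaining mapped panel
genes, reporting hits as tier 3 with consistency `reassigned:<disease>`. A
case with no qualifying variant anywhere is `negative`.

Trio segregation labels each proband variant by parental presence:
paternal / maternal / biparental / de novo, with Mendelian-error checks (a
homozygote requires the allele in both parents; a hemizygous X variant in a
male must be maternal). A dominant variant inherited from an unaffected
parent downgrades the verdict to *suspected* ("incomplete penetrance or
non-causal") rather than being dropped — either resolution is defensible and
the conservative one preserves the evidence.

## Evaluation arithmetic

Genotype concordance compares unordered allele pairs over the shared locus
set of two platforms; loci typed on only one platform are reported but never
counted. Replicate stability is the k-way intersection of coding-SNV key
sets divided by each replicate's total. All percentages are computed exactly,
averaged unrounded, and rounded half-away-from-zero to two decimals at
presentation only; rounding before averaging changes the mean at the second
decimal for realistic inputs (e.g. per-replicate 97.873/97.777/97.713 →
mean 97.79). The sex-sanity screen flags any chrY genotype in a female and
any heterozygous chrX genotype in a male outside the GRCh37 pseudoautosomal
regions.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, not
raw reads. Defaults describe the panel's working conditions: 80× mean depth
(the depth at which stability was characterized), 90 bp reads, log-normal
(σ = 0.25) per-exon capture effects reflecting uneven hybridization
efficiency, and 10 in-batch controls.

**Depth noise.** Observed exon depth is negative binomial about
μ = mean_depth × capture_effect × sample_scale × copies/2, applied at the
exon's read-count scale. The dispersion (default 0.05) uses the NB1
convention — variance = μ·(1 + α), a constant inflation over Poisson —
chosen deliberately over the NB2 convention (variance = μ + αμ²). NB2 with
α = 0.05 implies ≥ 22% CV per exon *after* capture-effect normalization;
at that noise level a heterozygous four-exon duplication at 80× is
unrecoverable at thresholds 1.35/0.65 (and a real pipeline with such noise
could not have produced confirmed exon-level calls whose per-exon ratios
cluster within a few percent of 1.5). Under NB1 the residual per-exon ratio
noise is ~7–10%, consistent with confirmed calls, and a four-exon
duplication is recovered in ≥ 99 of 100 replicates. The dispersion is a free
parameter for users who want to stress the caller.

**Noise-free mode** replaces every draw by its expectation and flattens
capture effects to 1. Both choices are needed for exact closed-form oracles:
with non-uniform effects, multiplying a few exons by 1.5 can shift the
within-sample median normalizer by a rank, perturbing the "exactly 1.5"
expectation at the fourth decimal. Noise-free mode is the reference oracle
for every dosage test; stochastic mode keeps the full noise model.

**Chromosome counts** are multinomial over weights ∝ footprint × copies/2
(with segment events adjusting the covered fraction); noise-free mode
returns the expectations. **Trio call sets** place causal configurations
(AR homozygote with carrier parents, compound heterozygote in trans, de novo
or inherited AD heterozygote, hemizygous XL male with carrier mother) in a
candidate gene and transmit common background variants Mendelian-consistently
at configurable rate; causal variants alternate between the known-pathogenic
and novel-deleterious evidence routes so both prioritization tiers are
exercised. **Concordance pairs** support an exact-count deterministic mode
(inject exactly k discordances) and a Bernoulli rate mode.

What the generators do *not* emulate — and therefore what passing tests do
not establish about real data: GC and mappability bias, batch effects beyond
a scalar library-size factor, correlated noise along the genome, genotyping
error modes of either platform, pseudoautosomal complications, mosaicism,
and variant-calling artifacts (all calls are taken at face value).

## Problem sizes and numerical choices

The test suite and the results script run on a 40-gene / 240-exon demo panel
(4 X-linked genes, 1 Y gene), 100 stochastic replicates for duplication
recovery, 60 noise-free trio cases (15 per inheritance configuration), a
300-gene single-chromosome footprint with 100 kb bins for microdeletion
localization, and 10 replicates for sex inference — sizes at which the
measured rates are stable to within a percentage point across seeds while
the whole suite stays fast. Stochastic assertions use 3σ bands. All
generators are pure functions of (inputs, seed); seeds are combined with
per-stream tags so sub-simulations are independent. Ties in copy-number
rounding follow Python's `round` (banker's) on 2·ratio, which is reached
only at exact half-integers; dosage ratios are never rounded elsewhere.

## Known limitations

* The exon CNV caller requires ≥ 1 in-batch control and assumes controls are
  copy-neutral over the tested genes; a shared CNV among controls masks the
  event.
* Run-based calling cannot resolve breakpoints below exon/bin granularity,
  and fragmented runs (one noisy exon inside an event) yield two calls
  rather than one.
* Compound-heterozygote calls are phase-unknown by construction; parental
  data is the only in-scope disambiguation.
* The frequency filter treats missing annotation as rarity, which is correct
  for curated tables but optimistic for sparsely annotated loci.
* Sex inference assumes a panel with a substantial X footprint; panels with
  few X targets widen the undetermined band in practice.
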