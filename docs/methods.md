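# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the underlying procedure left the design
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genotyping from allele depths

Genotypes are called per sample and site from raw REF/ALT read depths with
a fixed-fraction rule: letting the minor allele carry fraction f of the
total depth, the call is homozygous for the major allele when
f < `hom_fraction` (default 0.10) and heterozygous otherwise. The
inequality is strict — a minor fraction of exactly 10% stays heterozygous
— because the rule is stated as "less than". Two additions the rule itself
does not fix:

* `min_total_depth` (default 10 reads): below this the call is MISSING.
  The fraction rule exists to suppress low-depth errors, and below ~10
  reads a 10% threshold cannot even be expressed in whole reads.
* Multiallelic sites: the genotype is formed from the two best-supported
  alleles (depth ties broken by allele index, REF first, so output is
  deterministic). If any *third* allele reaches the homozygosity fraction,
  the two-allele model does not fit and the call is flagged ambiguous;
  downstream stages treat it like MISSING. Multiallelic records are kept
  throughout because a three-allele segregation pattern is only observable
  on them.

## Segregation patterns

With XY males, a site tied to the sex chromosomes shows one of three
progeny configurations: (1) every female the same homozygote and every
male heterozygous for one shared pair — a fixed X–Y difference, with the
Y allele the one absent from females; (2) every female heterozygous and
every male the same homozygote — a paternal-X variant, where genotypes
cannot distinguish a homozygous Y allele from Y hemizygosity (the call
carries a hemizygosity-unknown flag rather than a guess); (3) females
a/b, males a/c — a third allele on the Y. Classification uses progeny
only (parents of a cross need not be sequenced; if present they are not
consulted), and monoecious samples never enter it. By default a site
must be callable in all progeny (`require_complete`); with that relaxed,
each sex must retain `min_per_sex` (default 4) usable calls, preserving
the all-samples-consistent logic at reduced power. Per-unigene
aggregation counts a gene carrying several patterns once in the
deduplicated total.

## Exact association and MSY tiers

Sex association of a marker is a two-sided Fisher exact test on the 2×k
table of genotype classes by male vs female+monoecious (monoecious
individuals are pooled with females, matching how such panels are scored).
k = 3 is handled by full enumeration over the two free cells
(Freeman–Halton); point probabilities come from lgamma in log space, so
p-values far below double-precision factorial ratios (10⁻⁶⁰ and beyond)
are computed without approximation. Two-sidedness follows the
point-probability convention of standard statistical software — sum over
tables whose point probability does not exceed the observed one, with a
1+1e-7 relative slack against float noise in comparing log-probabilities.
Zero columns are dropped first (they carry no information and leave the
exact p unchanged). No multiple-testing correction is applied: the tier
thresholds (p < 1e-60 MSY, p < 1e-10 sex-associated, p ≤ 1e-5
recombining-or-recent) are interpreted on raw p.

Recombinant counting in a segregating population counts individuals whose
genotype contradicts the expected sex–genotype coupling (heterozygous
males, for a fixed X–Y difference); a marker with a single observed allele
is reported "n.v." (no variant) with the count undefined.

## ORF finding and phasing

The coding frame of a transcript is taken as the longest ATG-to-stop open
reading frame over all six frames (length includes the stop codon;
minimum 150 nt by default; ties break deterministically: forward strand,
lower frame, lower start). Open-ended runs without a stop are not ORFs.
X and Y allele CDSs are then built by substituting the classified X and Y
bases into the reference CDS at the SNP coordinates — alleles differ by
substitutions only, so no realignment is ever performed. For pattern-1
sites the Y base is the allele absent from female homozygotes.
Reverse-strand ORFs are skipped in the phasing stage (coordinate phasing
across strands invites sign errors for no gain on transcript data); the
skip is logged.

## Substitution rates and dating

K_A/K_S uses the classic pathway-counting method under the standard
nuclear genetic code (hard-coded deliberately — these are nuclear
transcripts, and making the code table configurable invites silent
misuse). Per codon, each position contributes a synonymous share equal to
the fraction of its possible single-base changes that preserve the amino
acid, with changes to stop codons excluded from the denominator, and
s + n = 3 per codon. Differences between codons are averaged over all
minimal mutational pathways; pathways passing through a stop are excluded,
and a pair whose every pathway is blocked is skipped and counted. Site
totals S and N are the averages of the two sequences; proportions
p = d/S are corrected for multiple hits with the Jukes–Cantor formula
K = −(3/4)·ln(1 − 4p/3), which errors at p ≥ 0.75 (saturation) rather
than returning a number. Codons containing ambiguity symbols are skipped
per codon (pairwise deletion); a terminal stop-codon pair is removed
before counting.

Divergence time is the molecular clock T = K_S/(2r)·g with defaults
r = 6.5×10⁻⁹ substitutions per site per generation and g = 1 year per
generation. Per-class summaries report the mean ± SE of per-gene K_S and
the time both ways — from the mean K_S and as the mean of per-gene times —
because the two aggregations differ in general and either may be quoted.

Class comparisons (MSY vs PAR K_S or K_A) use an exact two-sided Wilcoxon
rank-sum test: mid-ranks for ties, null distribution enumerated by dynamic
programming over doubled ranks (exact for group sizes up to ~30), p the
doubled smaller tail capped at 1.

## Expression

RPKM = reads / (length/1000) / (library/10⁶), with the per-sample library
size the column sum of mapped reads. Sex-biased expression is a two-group
one-way ANOVA F-test on log2(RPKM + pseudocount); the pseudocount
(default 0.01 RPKM) exists only because log2(0) is undefined, and the
samples are treated as independent replicates (df = (1, n−2); 4 vs 4
samples gives df = (1, 6)). The genome-wide DE fraction filters unigenes
to > 400 nt and counts p < 0.01 by default.

The Y/X expression ratio of a sex-linked gene pools allele read depths
over all male samples and all qualifying SNPs — pattern-1 sites
heterozygous in every male — and divides total Y-allele depth by total
X-allele depth. Pooling (rather than averaging per-SNP ratios) lets deep
SNPs weigh more and is scale-invariant; per-SNP ratios are emitted as
diagnostics. Genes with fewer than 2 qualifying SNPs are skipped: a
single SNP's ratio is dominated by binomial noise.

## The synthetic generator

`spinsex.syndata` generates the data structure the analysis assumes,
with truth tables for scoring:

* One cross — mother X1X2 × father X3Y — with the progeny sex ratio
  forced to the configured n per sex (default 8+8, a balanced panel).
* Three compartments. MSY genes carry only fixed X–Y differences: both
  lineages evolve independently from a common ancestral CDS for
  `xy_divergence_years` (default 0.4 My) at rate r (default 6.5e-9/site/
  year) under a Jukes–Cantor substitution model — uniform base exchange,
  chosen so the analysis-side JC correction matches the simulation model
  exactly — with non-synonymous proposals accepted at `ka_ks_target`
  (default 0.25) and proposals creating stops rejected. PAR and autosomal
  genes carry only segregating polymorphism (site density `pi`, default
  0.003). PAR genes recombine with the Y at `recomb_freq` (default 0.1)
  per meiosis; MSY genes never do.
* Depths: per site and sample, total ~ Poisson(`depth_mean`, default 50 —
  mid-range for transcript-level RNA-seq), split binomially between the
  two alleles of a heterozygote, with the paternal allele of a sex-linked
  gene in a male weighted by `allelic_bias`/(1+`allelic_bias`); each read
  miscalls to a uniform other base with probability `error_rate` (default
  0.005). Expression counts are negative-binomial (mean 400,
  dispersion 0.2).
* Gene length defaults to 1200 nt of coding sequence, a typical plant CDS
  length; sample sizes, depth, error and divergence defaults are the
  conditions of the study design the pipeline targets.
* All randomness flows from one seeded generator; a seed reproduces the
  dataset byte for byte. Truth tables record compartment, true X/Y
  sequences, every fixed difference with its syn/nonsyn class, and the
  segregation pattern implied by the noise-free genotypes at every
  variant site.

An unrelated association panel (default 104 males vs 108
females+monoecious) is simulated by drawing X copies independently from
the X haplotype pool and pairing male draws with the unrecombined Y —
sufficient for exact-test behaviour at panel scale without a coalescent
engine.

What the generator deliberately does not emulate: assembly artifacts and
paralog collapse, mapping bias between divergent alleles, coalescent
population structure in the panel, linked selection, isoform-level
expression, and read-level errors correlated along reads. Passing the
recovery tests therefore shows the inference machinery is correct under
the stated statistical model, not that real transcriptome assemblies are
free of the listed complications.

## Numerical and degenerate-input choices

* Exact-test log-probability comparisons use a 1+1e-7 relative slack;
  enumeration totals are checked against 1 in tests.
* A 2×k table reduced to a single informative column returns p = 1.
* `ng_differences` returns None (and `ka_ks` skips and counts the codon)
  when every pathway crosses a stop.
* Single- or few-codon alignments can put p_S outside the Jukes–Cantor
  domain; the correction raises at p ≥ 0.75 instead of clamping.
* Depth ties in genotype calling break by allele index; all output tables
  are sorted (unigene, position) so runs are reproducible file-to-file.
* The simulator leaves start and stop codons untouched by mutation so
  every simulated transcript keeps its ORF.

## Validation design and known limitations

The test suite scores the pipeline against independent oracles: exact
rational enumeration for the Fisher tests, permutation enumeration for
the rank-sum test, six-frame brute force for ORFs, and a separate
pathway-enumeration implementation (built on Biopython translation, no
shared code) for the NG86 engine. Recovery tests on the synthetic cross
check pattern-1 recall of true fixed differences, agreement of the
deduplicated sex-linked gene set with the noise-free truth, zero MSY
recombinants in the cross, clock dating within sampling error of the
simulated age, and Y/X ratio recovery with and without simulated Y
silencing. Problem sizes in the routine suite (hundreds of genes,
~1.2 kb CDS, 16 samples) were chosen so the full suite runs in well under
a minute while keeping per-gene SNP counts realistic (~2–3 fixed
differences per MSY gene at the default divergence).

Two properties worth knowing before quoting numbers from real data:

* **Ascertainment**: only genes with at least one detected fixed
  difference can be phased and dated, so the per-gene K_S of discovered
  genes is conditionally biased upward at low divergence (at the default
  settings the effect is of order +8% before the PAR admixture partly
  offsets it). The published-style estimate carries the same conditioning;
  the recovery test measures the pipeline as it would actually be used.
* **Stop-adjacent sites**: positions whose alternative bases are mostly
  stops evolve below the nominal neutral rate (stop-bound mutations are
  purged), while the site-counting convention still counts them as full
  sites. Measured synonymous divergence therefore runs a few percent
  below 2rT at interspecific distances; this is a property of the
  counting method, shared with its standard implementations, not of this
  package.
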