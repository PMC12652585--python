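# Methods

## Problem setting

`gbsex` screens a catalog of GBS/RAD tags — short restriction-fragment loci
carrying biallelic SNPs, genotyped in a panel of phenotypically sexed
individuals (the reference design is 10 males + 10 females) — for loci that
segregate with sex, and from them infers whether the species is male
heterogametic (XX/XY) or female heterogametic (ZZ/ZW). Downstream stages
place candidate markers on chromosomes from BLAST tabular output, intersect
them with candidate sex-determination genes (e.g. *DMRT1*), and design
diagnostic PCR primers.

The package consumes genotype matrices (VCF 4.x or a Stacks-style TSV), not
reads: everything upstream of genotypes (demultiplexing, de novo tag
assembly, SNP calling) is assumed done by the usual toolchain. One
consequence is that "a tag is absent in an individual" and "a tag was
genotyped but every site failed" are indistinguishable here; presence is
defined as "at least one called site" and the presence/absence detector
inherits that definition.

## The three detectors

Written for the XY case; each has an exact ZW mirror obtained by swapping
the sexes, and all thresholds are inclusive (≥).

**Frequency divergence (FREQ, site level).** At a fully X-linked SNP,
females (XX) are fixed for the X allele while X/Y-heterozygous males carry
one copy, so the X allele sits near 1.0 in females and near 0.5 in males.
A site is called XY when the female-majority allele has female frequency
≥ `fixation_min` (default 0.95) and its female-minus-male frequency
difference is ≥ `divergence_min` (default 0.4). The divergence is signed
and attached to the fixation allele. When both sexes share the same
majority allele the XY and ZW clauses are mutually exclusive; a site with
*opposite* near-fixation in the two sexes (all females hom-REF, all males
hom-ALT) satisfies both clauses, both calls are emitted, and the tag
resolves to AMBIGUOUS.

**Heterozygosity contrast (HET, site level).** Call XY when the proportion
of called females that are homozygous (either homozygote class) is
≥ `hom_prop_min` (0.5) and the proportion of called males that are
heterozygous is ≥ `het_prop_min` (0.5). At exact 50/50 mixtures in both
sexes a site can satisfy both the XY and ZW clause; both are emitted and
resolved at tag level. This criterion is deliberately permissive — at 10
individuals per sex a mid-frequency autosomal Hardy–Weinberg site fires it
with appreciable probability (see "Specificity" below).

**Presence/absence (PA, tag level).** A tag recovered in zero females and
in ≥ `presence_prop_min` (0.5) of all males is called male-limited (a
Y-specific fragment). "Entirely absent" is an exact zero — one female
recovery vetoes the call. The denominator is all individuals of the sex,
called or not, because absence is exactly the signal being scored.

Sites where either sex has fewer than `min_called_per_sex` (default 2)
called genotypes are skipped by FREQ and HET — a frequency estimated from
0 or 1 individuals is meaningless — but such tags remain eligible for PA.

**Aggregation.** Site calls are lifted to their parent tag; a tag whose
calls are all XY-patterned gets verdict XY, all-ZW gets ZW, and a mix is
AMBIGUOUS and excluded from system classification. SNP-level overlap
between FREQ and HET is reported alongside.

## Numerical boundary semantics

Dosage frequencies and proportions are ratios of small integers, and the
thresholds are decimal constants, so threshold comparisons are evaluated in
exact rational arithmetic (`fractions.Fraction`, with thresholds parsed
from their decimal representation: 0.4 means 4/10). A site whose divergence
is exactly 0.40 is therefore called, deterministically, on every platform —
a plain float comparison can miss such boundary cases by one ulp
(0.95 − 0.55 ≠ 0.4 in binary). Reported statistics are converted back to
floats for output only.

## System classification

Let n_XY and n_ZW be the counts of unambiguous tag verdicts. The package
tests k = max(n_XY, n_ZW) successes in n = n_XY + n_ZW trials against a
binomial null with p₀ = 0.5, two-sided, with the "minlike" definition (sum
of all PMF terms ≤ PMF(k)); the majority pattern is declared the system
when p ≤ α (default 0.01), else UNDETERMINED. No directional hypothesis is
assumed a priori, hence two-sided. The implementation is
`scipy.stats.binomtest`; the test suite verifies it against direct PMF
summation to 1e-12 relative tolerance.

Union accounting reports per-method tag counts, the FREQ ∩ HET overlap, the
union total, and the male-pattern percentage (two decimals, round-half-even
computed in decimal arithmetic). On the published counts (545 = 545 SNP-based
tags, 266 male-limited, 42 female-limited) it yields 853 total, 811
male-pattern, 95.08% — the printed 95.07% appears to be a truncation of
811/853 = 95.076…%.

## Chromosome assignment and gene colocalization

Each marker keeps its best BLAST hit: smallest e-value, ties broken by
larger bit score, then input order (BLAST output is not totally ordered; a
deterministic tie-break is required for reproducibility). A best hit with
e-value above `e_max` (default 1e-10) leaves the marker FILTERED; no hits
means UNMAPPED. Chromosome percentages use the full input set as
denominator (one decimal, round-half-even). Strand is recorded but ignored
for overlap. Genes whose intervals pass the filter on more than one
chromosome are flagged multi-locus and excluded from colocalization,
mirroring the exclusion of candidates with ambiguous chromosomal
localization; colocalization itself is interval intersection on 0-based
half-open coordinates, with an optional `max_gap` for near-misses. For gene
anchoring, stricter ceilings (e.g. 1e-20) are sometimes used in the
literature; `e_max` is exposed rather than hard-coded.

## Primer design

**PA (allele-specific) pairs** implement the classic ARMS idea: both
primers put a sex-specific variant at their 3′ terminal base, so extension
fails on the homogametic haplotype and only the heterogametic (Y)
haplotype amplifies — a band in males, none in females. The forward primer
is a window of the Y haplotype (the consensus with every Y allele
substituted) ending on one anchor site; the reverse primer is the reverse
complement of the window starting at the other anchor, placing the
complement of that Y allele at its own 3′ end. `product_len` is the full
amplicon length `rev_end − fwd_start`, including both primer footprints —
the quantity a gel band measures and the length in-silico PCR returns.

**SD (codominant) pairs** place both primers in windows containing no
sex-specific variant so they bind both haplotypes, and require the product
to span at least one dimorphic SNP strictly between the two 3′ ends;
sequencing the amplicon then shows a double peak in the heterogametic sex
and a single peak in the other.

Candidate primers are enumerated per 3′-end position over lengths 18–27 nt,
kept when GC ∈ [0.2, 0.8] and nearest-neighbor Tm ∈ [52, 62] °C
(SantaLucia 1998 unified parameters via Biopython's `Tm_NN`, 50 mM
monovalent salt, 250 nM oligo), and pairs are ranked by |Tm_F − Tm_R|.
Constraint defaults bracket the validated primer panel this design follows
(observed products 107–275 bp, annealing 55–60 °C); whether a panel's
printed "TM" is predicted melting or empirical annealing temperature is
generally unstated, so the module computes NN Tm and never asserts
equality with printed values. The SD search caps the number of flank
positions scanned per side (`max_starts`, default 30, nearest the target
region first), bounding Tm evaluations without losing short products.
Hairpin/dimer screening and multiplexing are out of scope.

**In-silico PCR** uses an exact full-length binding model. Real PCR
tolerates internal mismatches, but the diagnostic logic of a PA pair rests
entirely on the 3′ anchor, and exact matching makes the specificity
property provable: a PA pair designed on (X, Y) can never amplify from an
X/X template, because its 3′ base differs from X by construction. The
`allow_3prime_mismatch` flag exempts the terminal base to probe how much
of the discrimination the anchor carries. Typed design failures
(`NEEDS_TWO_SNPS`, `NO_FEASIBLE_PAIR`, `NO_CONSERVED_FLANKS`) let the CLI
fall back from PA to SD per tag.

## The simulator

`simulate_catalog` draws, per tag: a random consensus (300 bp), a
Poisson(1.5)-distributed SNP count (min 1), and genotypes by class:

* autosomal — Hardy–Weinberg genotypes at ALT frequency ~ U(0.05, 0.5),
  independent of sex (1000 tags by default);
* sex-linked — homogametic individuals homozygous for the consensus
  allele, heterogametic individuals X/Y heterozygous at every site; with
  probability λ (`recombination_leakage`) a heterogametic individual
  carries X/X across the whole tag, the simplest mechanism for the marker
  dropout produced by incomplete recombination suppression on homomorphic
  sex chromosomes (50 tags);
* sex-limited — recovered only in heterogametic individuals, each
  independently with probability 0.8 (20 tags);
* opposite-noise — sex-limited tags of the mirrored system (2 tags,
  scaled from the 42/853 minority observed in a real screen), so the
  binomial verdict is always exercised against a nonzero minority class.

Genotyping error (rate ε, miscall to a uniformly random other state) is
applied first, then missingness (rate μ); both only touch called cells.
All randomness flows from one seeded generator — equal seeds give
byte-identical output files. Defaults ε = 0.01, μ = 0.05, λ = 0 represent
a clean modern GBS screen; the robustness test raises λ to 0.1. Group
draws are made heterogametic-role-first, so an XY and a ZW run from the
same seed mirror each other exactly over the sex-linked blocks when the
sexes have equal size.

`simulate_mapping` gives 84.5% of sex-patterned tags a strong chr1 best
hit (four sex-linked tags are placed inside a DMRT1-like interval on
chr1), leaves the rest unhit or above the e-value ceiling, and scatters
autosomal tags over the other chromosomes, with occasional strictly worse
secondary hits to exercise best-hit selection.

**What the simulator does not emulate:** read-level data (depth, allele
dropout correlated with depth), linkage between tags, the skewed MAF
spectrum of real RAD data, null alleles from restriction-site
polymorphism, and population structure. Passing recovery tests therefore
demonstrates correctness of the screening logic under its stated model,
not performance on any particular empirical dataset.

## Specificity under these thresholds

At 10 + 10 individuals, a mid-MAF autosomal HWE site passes the HET
criterion with probability up to ≈ 0.3 per pattern (exactly computable by
enumerating the 66 × 66 joint genotype-count distributions of the two
sexes). These false positives are sex-symmetric, so they dilute but do not
bias the binomial system call; with the default simulation composition the
verdict remains XY, though the p-value sits much closer to α than the
planted 70:2 ratio alone would give. The test suite bounds the observed
autosomal false-positive count by this exact enumeration rather than
asserting a small rate. Practical screens rely on the downstream
confirmation stages (chromosome clustering, PCR validation) to remove this
noise — one reason the reference design validates markers across
populations before use.

## Problem sizes used in the validation suite

Recovery and symmetry suites run the full default composition
(1000 + 50 + 20 + 2 tags, ≈ 1500 SNPs, 20 individuals); the primer
property suite uses 200 random 300-bp fixtures; the specificity bound uses
300 autosomal tags (enumeration is exact, so a smaller sample only widens
the tolerated Poisson-binomial band). All suites are seeded and
deterministic.
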