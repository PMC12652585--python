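# gbsex

Sex-linked marker discovery, sex-determination-system classification, and
diagnostic PCR primer design from GBS/RAD genotype matrices.

Many amphibians and fishes carry homomorphic sex chromosomes: karyotypes do
not reveal the sex-determination system, but reduced-representation
sequencing of a handful of sexed individuals does. `gbsex` takes a catalog
of GBS tags (short restriction-fragment loci with biallelic SNPs) genotyped
in a sexed panel and answers three questions: *which loci segregate with
sex*, *is the species XX/XY or ZZ/ZW*, and *how do I genotype sex cheaply
by PCR afterwards*. It is aimed at population geneticists and breeders
establishing mono-sex lines in aquaculture species.

## Method

Three detectors, shown here for the XY case (each has an exact ZW mirror;
all thresholds are inclusive and configurable):

1. **Frequency divergence (FREQ).** At a fully X-linked SNP females (XX)
   are fixed for the X allele while X/Y males carry one copy. Call a site
   when the female-major allele has freq_F ≥ 0.95 and
   freq_F − freq_M ≥ 0.4.
2. **Heterozygosity contrast (HET).** Call when F_hom ≥ 0.5 (proportion of
   called females homozygous) and M_het ≥ 0.5 (proportion of called males
   heterozygous).
3. **Presence/absence (PA).** Call a tag male-limited when it is recovered
   in zero females and in ≥ 50 % of males — the signature of a Y-specific
   fragment.

Site calls are lifted to tags; a tag with both XY- and ZW-patterned calls
is AMBIGUOUS and excluded. With n_XY and n_ZW unambiguous tags, the system
is declared by an exact two-sided binomial test of
k = max(n_XY, n_ZW) in n = n_XY + n_ZW trials against p₀ = 0.5,
at α = 0.01.

Downstream, markers keep their best BLAST hit (min e-value, e ≤ 1e-10) for
chromosome assignment, are intersected with candidate sex-determination
gene intervals (e.g. *DMRT1*), and feed two primer strategies: **PA**
pairs anchor both 3′ termini on Y-specific bases so only males yield a
band, and **SD** pairs use conserved flanks spanning a dimorphic SNP for
codominant genotyping. An exact-match in-silico PCR verifies the designs.
A forward simulator (`gbsex simulate`) generates catalogs with known truth
— sex-linked, sex-limited, autosomal and opposite-pattern tags, genotyping
error, missingness, X–Y recombination leakage — so the whole pipeline is
testable without raw reads. See `docs/methods.md` for the full model.

## Worked example

Simulate a small XY screen (10 males + 10 females; 60 autosomal, 30
sex-linked, 10 male-limited and 2 female-limited tags; 1 % genotyping
error, 5 % missingness), then run discovery, mapping and reporting:

```sh
gbsex simulate --seed 42 --out demo/sim \
    --n-auto-tags 60 --n-sexlinked-tags 30 \
    --n-sexlimited-tags 10 --n-opposite-noise-tags 2
gbsex discover --genotypes demo/sim/genotypes.sumstats.tsv \
    --sex-map demo/sim/sex_map.tsv --out demo/run
gbsex map --classifications demo/run/tag_classifications.tsv \
    --blast demo/sim/blast_hits.tsv --bed demo/sim/genes.bed --out demo/run
gbsex report --dir demo/run
```

The discover step logs:

```
INFO gbsex: calls: 169; tags: 59 XY, 23 ZW, 3 ambiguous
INFO gbsex: system verdict: XY (p=8.72e-05)
```

and `demo/run/report.md` contains (abridged):

```
- frequency-divergence tags: 30
- heterozygosity-contrast tags: 74
- male-limited (PA) tags: 9
- female-limited (PA) tags: 2
...
- male-pattern tags: 83 (97.65%)
- exact binomial p = 8.72e-05 (alpha 0.01)
- declared system: **XY**
...
| chr1 | 34 | 40.0 |
...
- CLocus_208 within DMRT1 (overlap 300 bp)   (4 such markers)
```

Reading it: all 30 planted sex-linked tags were found by the frequency
method (74 tags passed the more permissive heterozygosity screen — at 10
individuals per sex it also catches mid-frequency autosomal sites, which
is why the binomial test, not a raw count, decides the system); 9 of 10
planted male-limited tags survived presence sampling; the XY majority is
decisive at p ≈ 9 × 10⁻⁵; chr1 is the modal chromosome and exactly the
four planted markers fall inside the DMRT1-like interval.

Primer design on the called tags:

```sh
gbsex primers --fasta demo/sim/tags.fasta \
    --calls demo/run/marker_calls.tsv --out demo/primers
```

```
locus       mode  fwd_seq                    rev_seq                fwd_tm  rev_tm  product_len  anchored_snps  spanned_snps
CLocus_62   PA    AAAGACTGGATAGGCTTATATTGA   GTTCCGAATTCTGAAATGCT   52.7    52.7    178          40;175
CLocus_61   SD    ACGGCCAGATAGCTCTTCC        CACTCACCGACCCTGGAA     57.4    57.4    103                         117
```

The PA pair ends on the Y-specific bases at tag offsets 40 and 175 (178 bp
band in males only); the SD pair flanks the dimorphic SNP at offset 117
with conserved primers (103 bp product in everyone, double peak in males).

Library use mirrors the CLI: `simulate_catalog`, `compute_site_stats`,
`detect_freq`/`detect_het`/`detect_pa`, `aggregate_tags`,
`binomial_system_test`, `assign_chromosomes`, `gene_colocalization`,
`design_pa`/`design_sd`, `in_silico_pcr`.

## Inputs and formats

| input | format |
|---|---|
| genotypes | VCF 4.x (GT field; one tag per contig) or TSV (`locus_id  site_offset  ref  alt  <sample>...` coded 0/1/2/NA) |
| sample sexes | 2-column TSV, sex ∈ {M, F, male, female} |
| tag consensus | FASTA, IDs matching tag ids |
| genome hits | BLAST outfmt 6 (12 columns) |
| gene intervals | BED3+ |

All outputs are UTF-8 TSV/JSON/FASTA with `#` comment headers carrying the
tool version and a configuration hash.
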