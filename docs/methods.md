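# Methods

`gardenscan` implements the population-genomic inference chain used to
look for viability-selection signals in a two-site conifer common-garden
design: a small group of trees that survived a harsh high-elevation
garden is contrasted against the survivors of a benign low-elevation
garden, SNP by SNP, and the extreme tail of the differentiation
distribution is filtered through a label-permutation procedure. This
note records the models, the estimators, the numerical conventions, and
the design choices that were genuinely open.

## Study design being emulated

Seven source populations (LJ, YL, BS, GS, YX, ZD, KM) are grown in two
gardens. At the low site 49 trees survive and are sampled
(10, 10, 5, 4, 5, 5, 10 per population); at the high site only 5 trees
survive, all originating from population KM. The 5 survivors are treated
as a selected population and contrasted with (a) the 20 lowland trees of
the same genetic cluster (KM + YL) and (b) all 44 lowland trees minus
the genetically distinct BS population. Total cohort: 54 diploid
individuals.

## Synthetic-data generator

The generator produces a genome, gene models, a genotype cohort with
known truth, and a gene-to-term map.

**Gene models.** Genes are placed without overlap on random scaffolds;
each has a 5'UTR exon, 1–3 CDS exons (30–120 codons, ATG start, clean
stop, no internal stops by construction), introns of 60–200 bp between
all exons, and a 3'UTR exon; strands are random. GFF3 phase is computed
per CDS segment. Defaults (8 scaffolds x 25 kb, 100 genes) give a
gene-dense genome (~40% genic) resembling a transcriptome-derived SNP
set rather than a whole genome.

**Allele frequencies.** Balding–Nichols: per SNP an ancestral frequency
p ~ Uniform(maf_floor, 1 − maf_floor) is drawn, and each population's
frequency comes from Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = `background_fst`. F is the single knob for background
differentiation; the default 0.05 is typical of range-wide conifer
population structure. F = 0 yields exact exchangeability across
populations.

**Viability selection.** `n_planted` SNPs are placed inside the CDS of
distinct genes. Their ancestral frequencies are drawn from
Uniform(maf_floor, 1 − shift − maf_floor) so the survivor group's
frequency, `clip(p_pop + shift, 0, 1)`, expresses the full configured
differential. Survivors are drawn as new individuals from the source
population's frequencies (they are distinct trees, not a re-sampled
subset of the lowland sample), with the shift applied only at planted
SNPs. Genotypes are Hardy–Weinberg binomial draws.

**QC annotations.** Per-site INFO fields (MQ, QD, FS, SOR, MQRankSum,
ReadPosRankSum) and per-genotype GQ/DP default to clearly passing
values; records that should fail a specific filter step are planted
explicitly (counts `n_fail_*`), which makes filter tests deterministic.
Near-indel failures place an indel 2 bp from an otherwise isolated SNP;
honest background indels are kept > window + span away from every SNP so
nothing fails by accident. MAF failures rig a single heterozygote;
missing-rate failures push just over 20% of genotypes below the GQ
threshold.

**Randomness.** One global seed drives independent named substreams
(genome, gene placement, SNP placement, frequencies, genotypes, QC,
missingness, indels, terms) via `numpy.random.SeedSequence.spawn`, so
changing one knob does not reshuffle unrelated draws; a fixed seed
reproduces every output file byte for byte.

**What the generator does not emulate:** linkage (SNPs are independent
draws; there is no recombination map or coalescent ancestry), sequencing
reads, genotyping error beyond the planted QC failures, relatedness
within populations (survivors are modelled as unrelated — the design
does not state their pedigree), or expression levels. Passing tests
therefore demonstrate correctness of the estimators and the procedure's
statistical behavior under idealized exchangeability — not robustness to
LD or cryptic relatedness in real data.

## Filtering

Order-fixed, each SNP attributed to the first failing step:

1. biallelic SNPs ≥ 5 bp from any indel REF span (distance to the
   nearest affected base; "at least 5" reads as ≥, so distance 4 removes
   and 5 keeps);
2. hard site filters MQ < 40, QD < 2, FS > 30, SOR > 4,
   MQRankSum < −12.5, ReadPosRankSum < −8 — any *present* violating
   annotation removes the site, absent annotations pass (the convention
   of variant callers when an annotation cannot be computed);
3. genotypes with GQ < 20 **or** DP < 10 are set missing (the
   disjunctive reading of the thresholds; the conjunctive rule is
   available via `mask_rule="and"`), then sites with missing rate
   strictly > 20% are removed;
4. MAF = min(p, 1−p) over non-missing alleles; strictly < 5% removes.
   Sites left with no called genotype are removed here and logged as a
   missing-data pathology.

The pipeline is idempotent on its own output and the report counts are
conserved (input = removed + retained).

## Effect classification

Every SNP gets exactly one of seven classes. Within a gene the
precedence is splice_site > CDS > 5'UTR > 3'UTR > intron; a position
inside a gene span but in no annotated feature is intronic; outside all
gene spans it is intergenic. Overlapping genes are resolved by the same
precedence, then by smallest gene id. Splice sites are the first/last 2
intron bases (canonical donor/acceptor dinucleotides; width
configurable). Coding SNPs substitute the ALT base into the codon
(reverse-complemented on minus-strand genes) and compare translations
under the standard genetic code; identical amino acid = synonymous.
A REF allele that disagrees with the genome is a hard error naming the
record. Percentages in summaries are half-up rounded to 2 decimals,
matching how such tables are conventionally printed.

## Estimators

**F_ST.** Weir & Cockerham (1984) moment estimator for r = 2 groups,
computed per SNP with the n_c correction for unequal sample sizes and
SNP-specific sample sizes (missing genotypes excluded at that site),
using observed heterozygote frequencies. theta = a/(a+b+c); negative
estimates are reported as computed. theta is undefined when either group
has < 2 called individuals or the denominator is 0 (e.g. monomorphic in
both groups). The implementation is vectorized over SNPs; the test suite
checks it at 1e-10 against an independent scalar per-allele-sum
formulation.

**π.** Per-site average pairwise difference 2·c_ref·c_alt/(n(n−1)) over
non-missing alleles, summed over SNPs inside the gene's CDS and divided
by the full coding length (monomorphic coding sites contribute length
but no differences). The SNP-covered-sites-only denominator was the
alternative; full coding length is the usual per-gene convention and the
default here.

**dN/dS.** Nei & Gojobori (1986) with pathway averaging for multi-hit
codons (pathways through stop codons are excluded unless every pathway
is blocked; mutations *to* stop codons count as nonsynonymous) and the
Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3); when p ≥ 3/4 the raw
proportion is reported and flagged. Unphased diploids are expanded into
two pseudo-haplotypes with ALT alleles assigned to haplotype 1 at
heterozygous sites (deterministic; random phasing with a seed is
available). At the diversity levels this pipeline targets (π ~ 0.002,
so double heterozygotes within a codon are rare) phase error is
negligible for pairwise counting. dN and dS are means over all
C(2n, 2) haplotype pairs; the gene-level ratio is undefined when
dS = 0, and group summaries average per-gene ratios (not the ratio of
averages). The terminal stop codon is excluded from site and difference
counting. Missing genotypes are treated as reference within a
haplotype.

**LD thinning.** Non-overlapping windows anchored at coordinate 1 of
each scaffold; the lowest-position SNP per non-empty window is kept
(anchoring and keep-rule are conventions; nothing downstream is
sensitive to them).

**PCA.** Missing dosages mean-imputed per SNP, columns centered by 2p̂
and scaled by sqrt(2p̂(1−p̂)) (Patterson normalization), zero-variance
SNPs dropped with a log line, scores from the SVD; variance fractions
sum to 1 over all components.

## Outlier scan

SNPs with defined theta are ranked; the threshold is the empirical
(1−q) quantile (q = 0.01) and everything ≥ the threshold is putative,
so ties can push the set past q·M. Each of `n_perm` = 100 permutations
re-partitions individuals, without replacement, into pseudo-groups of
the original sizes and re-runs the identical scan; the recurrence of a
putative SNP is the number of permutations in which it re-enters the
permuted putative set. Retained outliers have recurrence rate strictly
< 0.01 — with 100 permutations that means exactly zero recurrences.
The resampling pool defaults to the union of the two compared groups;
drawing from the whole cohort is available (`pool="all"`). Gene overlap
is the set of genes whose span contains a retained SNP.

### Statistical behavior of the recurrence filter

The strict zero-recurrence rule has a consequence worth stating plainly,
because the test suite measures it. Under an exchangeable null a
putative SNP re-enters a permuted top-1% set with probability ≈ q per
permutation, so it survives 100 permutations with probability
0.99^100 ≈ 0.366: roughly a third of chance outliers are retained *by
chance*, and the retained set is essentially never empty. Conversely,
truly selected SNPs recur *jointly* whenever a permutation concentrates
two or more survivors in the small pseudo-group (probability ≈ 0.25 per
permutation for 5-vs-20 groups), so their recurrence is almost never
zero and recall of planted signals in the retained set stays low
(~0.15–0.25 at a frequency shift of 0.6, versus ~0.7–0.85 recall in the
putative set). The filter, as printed, behaves closer to random
subsampling of the putative set than to false-discovery control; users
who want the planted-signal ranking should read the putative table and
its recurrence column rather than the retained set alone.

## Enrichment

Per-term hypergeometric upper tail P[X ≥ k] (identical to one-sided
Fisher) over the background of genes covered by ≥ 1 SNP after
filtering; the tested universe is terms with K ≥ 1 and k ≥ 1 (the
convention of common over-representation tools; configurable), and BH
correction runs over that universe with significance at q < 0.05. The
permutation check redraws random gene sets of the observed size and
counts how often each observed significant term is significant again;
genuinely enriched terms recur essentially never.

## Group-contrast test

Wilcoxon rank-sum (Mann–Whitney), two-sided by default, exact null
distribution for strata ≤ 25 genes and the continuity-corrected normal
approximation above.

## Problem sizes

Default simulated cohorts use 5,000 SNPs over a 200 kb, 100-gene
genome; the null-behavior suites use 10,000 SNPs with background F = 0,
and the planted-recovery suites 2,000 SNPs with 20 planted loci. These
sizes give stable estimates of the quantities of interest (quantile
thresholds, recurrence rates, recall) while keeping a full test run in
tens of seconds.

## Known limitations

- No LD: the permutation filter's joint-recurrence pathology would be
  stronger still with linked SNPs; the simulator cannot show that.
- dN/dS assumes deterministic pseudo-phasing; at high diversity or long
  genes with many double heterozygotes, use `phase="random"` and
  average over seeds.
- The splice-site class is a 2 bp core; tools with wider splice regions
  will classify more SNPs as splice-affecting.
- Enrichment ignores term topology (no GO DAG propagation, no pathway
  structure); term maps are flat inputs.
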