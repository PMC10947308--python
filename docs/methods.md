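# Methods

## Cross design and simulation

The simulated cross mirrors a field design: two heterozygous parents, one per
species (lowland *A. barrelieri* = founders 0/1, alpine *A. rupestre* =
founders 2/3), two full-sib F1s, and an F2 family (default n = 216). Genomes
are 8 chromosomes of 52.25 cM; crossovers are drawn per meiosis as a Poisson
process on the genetic scale (Haldane, no interference). ~1000 RAD loci are
placed along the physical genome (optionally evenly spaced); 57% are
polymorphic, each carrying a truncated-Poisson number of SNPs (mean 3, max 8)
within 630 bp. Observed SNP genotypes receive independent genotyping errors
(default 1%) and missingness increasing toward the locus's distal end
(default 10% overall). Quantitative traits are additive(+dominance) QTL
effects plus Gaussian noise; the trichome trait is a dominant suppressor
allele from the lowland parent. Transmission ratio distortion is simulated as
gamete-stage rejection: a gamete carrying a b allele at the distorter locus
is discarded with probability s, giving an expected b-allele frequency
0.5(1−s)/(1−0.5s).

## Haplotype calling and species-origin coding

SNPs within 1.5 kb on one chromosome are binned into a RAD locus. Locus
haplotypes are inferred from co-segregation: candidate haplotypes are the
observed complete SNP-vector combinations, each F2 is assigned the unique
consistent diplotype, and loci needing more than four haplotypes or without a
consistent assignment are flagged (`ambiguous` / `inconsistent`). Each
haplotype is traced to the parental species that carries it; F2 diplotypes
are then collapsed to species-origin genotypes bb / br / rr. Loci with more
than 25% missing calls are dropped; individuals whose genotype at ≥5 loci is
a within-locus singleton are flagged as low coverage.

## Linkage map

Two-point recombination fractions are maximum-likelihood estimates over the
9-cell two-locus F2 table, with LOD from the likelihood ratio against r =
0.5. Markers are grouped by single-linkage at LOD ≥ 6; each group is ordered
greedily by minimum sum of adjacent recombination fractions with a
window-polish pass, and adjacent distances converted to centimorgans with the
Kosambi map function. Genome length is estimated per group by the Chakravarti
(m+1)/(m−1) inflation of the observed span; coverage is observed/estimated
length (the 11-marker, 100 cM worked case gives 120 cM and coverage 0.833).

## Transmission ratio distortion

Per locus, a 1-df χ² on allele counts (b vs r among 2n typed alleles) and a
2-df genotype-phase χ² against Hardy–Weinberg proportions at the observed
allele frequency. Loci are flagged at the Bonferroni-corrected α; the flagged
fraction of the map (cM) is reported. Companion calibration tests: a
Lilliefors-style bootstrap of exponential inter-marker spacings (marker
placement randomness) and a χ² of polymorphic-locus runs (clustering of
polymorphism).

## QTL mapping

Genotype probabilities on a 1 cM grid come from a forward–backward HMM over
the species-origin codes (error rate 0.001, prior ¼/½/¼). Haley–Knott
regression on the additive (p_bb − p_rr) and dominance (p_br) expectations
gives LOD = (n/2)·log10(RSS0/RSS1); genome-wide thresholds are the α-quantile
of 1000 permutation maxima (permutations run as extra response columns of a
single QR solve). Multi-QTL models are built by forward/backward stepwise
search with a 10 cM exclusion window; per-QTL PVE is the drop-one RSS
difference over total SS, and support intervals are 1- and 2-LOD drops.
Colocalization of k of n QTL with reference intervals covering fraction p of
the genome is tested with the exact binomial tail P(X ≥ k).

## Morphology

Characters are natural-log transformed where right-skewed (plant height,
branch internodes, leaf area, flower number) and z-scored on the training
sample. The morphology index is a Fisher linear discriminant
w ∝ S_pooled⁻¹(μ_b − μ_r), scaled to unit pooled within-class variance and
oriented so *A. barrelieri* scores positive (ridge fallback when S_pooled is
ill-conditioned). Heritability is the intraclass correlation from a one-way
random-effects ANOVA over maternal families with the unbalanced-design n₀
coefficient. Pooling of sub-populations is checked by Welch t and two-sided F
tests at Bonferroni-corrected α. Population-level morphological intermediacy
subtracts each *A. barrelieri* population's index from the species maximum
and the species minimum from each *A. rupestre* population's, so the most
extreme population of each species scores 0 and values grow toward the other
species; intermediacy and genetic admixture are regressed on distance to the
nearest heterospecific population (floored at 0.1 km for sympatric sites).
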