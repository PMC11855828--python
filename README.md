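# germdiv

Phenotypic diversity analysis, PCA-based comprehensive scoring, and SNP
summary statistics for germplasm evaluation panels — in particular
EMS-mutagenized populations such as M2 lines of the processing tomato "M82".

## Who this is for

Breeders and genebank curators who score a panel of accessions for
qualitative traits (coded levels, e.g. `1 = vine type, 2 = half-vine type,
3 = upright`) and quantitative traits (plant height, fruit diameters,
soluble sugar, ...), and want to:

1. quantify per-trait variability and diversity,
2. screen trait correlations and cluster accessions into phenotype groups,
3. rank accessions by a single composite score, and
4. summarize the SNP landscape of the mutagenized population from a VCF.

## Methods at a glance

**Shannon–Wiener diversity.** For each trait, H′ = −Σᵢ Pᵢ ln Pᵢ over the
relative frequencies Pᵢ of its categories. Qualitative traits use their
observed level frequencies. Quantitative traits are first binned into 10
grades around the sample mean X with half-standard-deviation (δ) steps:
grade 1 below X − 2δ, grades 2–9 in successive 0.5δ intervals, grade 10 at
or above X + 2δ.

**Descriptive statistics.** Mean, sample (n−1) standard deviation, min,
max, range, and the coefficient of variation CV = 100·sd/mean.

**Comprehensive evaluation.** The quantitative trait matrix is
standardized (min–max "range method" or z-scores), factorability is checked
with the Kaiser–Meyer–Olkin measure and Bartlett's sphericity test, and the
Pearson correlation matrix is eigendecomposed. Components with eigenvalue
λ ≥ 1 are retained; each accession's component scores Yₖ are its projections
onto the unit eigenvectors, and the composite score is

    Z = Σₖ wₖ·Yₖ,   wₖ = contributionₖ / Σ contributions,

with ranks assigned by descending Z. Ward hierarchical clustering on the
standardized traits groups accessions, and each group's trait means are
flagged higher/lower than the panel mean.

**SNP summaries.** From a VCF (+ GFF3 + FASTA): transition/transversion
counts and Ts/Tv ratio, the strand-collapsed six-class substitution spectrum
(T:A→C:G, C:G→T:A, A:T→T:A, A:T→C:G, C:G→A:T, C:G→G:C — EMS predominantly
induces C:G→T:A), per-sample heterozygous / homozygous non-reference site
counts, and a region tally (upstream/downstream 2 kb flanks, exon split into
synonymous / nonsynonymous / stopgain / stoploss, intron, splice sites,
UTRs, intergenic).

Because the accession-level raw data behind the bundled summary tables are
not public, `germdiv.synthetic` generates trait matrices (multivariate
normal with the published means/SDs and a documented correlation preset;
categorical sampling from published level frequencies) and toy
genome/VCF/GFF3 files with a known truth table, so the whole pipeline is
testable end to end.

## Worked example

Generate a synthetic 33-accession panel with a 2000-SNP toy genome, rank
the accessions, and summarize the variants:

```sh
germdiv simulate --out demo --n-snps 2000 --seed 1
germdiv pca --traits demo/quantitative_traits.tsv --coding demo/coding.txt --out demo/pca
germdiv snp-summary --vcf demo/variants.vcf --gff demo/genes.gff3 \
    --fasta demo/genome.fa --out demo/snp
```

The PCA step prints

```
retained 5 components (cumulative 72.85%)
```

meaning five eigenvalues of the 15-trait correlation matrix were ≥ 1 and
together explain 72.85 % of the variance. `demo/pca/composite_scores.tsv`
then begins

```
        Y1      Y2      Y3      Y4      Y5      z       rank
30      1.5229  2.5688  0.9536  0.8522  -1.1028 1.3504  1
14      4.8122  0.2929  -1.9345 0.3387  0.2496  1.1837  2
31      1.1650  1.4743  1.6689  0.5234  0.0863  1.1416  3
```

— accession 30 has the best all-round phenotype under the
contribution-weighted composite score. The SNP step prints

```
2000 SNPs (Ts/Tv 2.33); wrote tables to demo/snp
```

and `demo/snp/snp_regions.tsv` tallies each SNP into exactly one region
category (here ~51 % intergenic, ~20 % in each 2 kb flank, with exonic SNPs
split by coding effect). The full pipeline — diversity tables,
correlations, clustering, PCA, scores, SNP summaries, and a run log — is one
command: `germdiv run --traits ... --coding ... --out ...`.

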