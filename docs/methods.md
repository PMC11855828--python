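# Methods

## Scope and model

`germdiv` implements the evaluation workflow applied to germplasm panels —
here an EMS-mutagenized M2 population of the processing tomato "M82" with
33 accessions, 16+ scored qualitative traits and 15 quantitative traits —
and the SNP-level characterization of such a population from variant calls.

### Trait model

A panel is a `TraitMatrix`: accession records validated against
`TraitDescriptor`s. Qualitative traits carry an ordered map of integer
level codes to labels (the national tomato germplasm description norms);
quantitative traits carry units. Missing values are explicit (`NA` in
files, `None` in memory); all downstream statistics use pairwise-complete
values. With n ≈ 33 accessions, imputation would manufacture information,
so none is attempted. Trait names are matched exactly after whitespace
trimming — fuzzy matching risks silent column misbinding. The package
imposes no fixed accession count.

### Diversity

H′ = −Σ Pᵢ ln Pᵢ (natural log); zero frequencies contribute 0 (the
p ln p → 0 limit). Quantitative traits are binned into 10 grades with cut
points X + k·0.5δ, k = −4..4, from the sample mean X and sample (n−1)
standard deviation δ. Intervals are closed on the left and open on the
right, so X itself falls in grade 6 and X + 2δ in grade 10; this makes the
grades an exhaustive partition of the real line (boundary values would
otherwise be unassigned under a strict reading of "less than X − 2δ" /
"greater than X + 2δ"). A constant trait (δ = 0) cannot be graded and is
rejected with advice to drop it from H′. Report tables round half away
from zero at 2 decimals; internal values keep full precision.

### Comprehensive evaluation

* **Standardization.** Range method x′ = (x − min)/(max − min) or z-scores.
  Component scores default to z-scored input: score magnitudes on the
  reference panel (|Y| up to ≈ 4.8) are unattainable from inputs confined
  to [0, 1], so z-scoring is the consistent reading; range scaling remains
  available (`standardization="range"`). The PCA itself is identical under
  either, being built on the Pearson correlation matrix.
* **Factorability.** KMO = Σr²ᵢⱼ/(Σr²ᵢⱼ + Σq²ᵢⱼ) over i ≠ j, with anti-image
  partial correlations qᵢⱼ = −(R⁻¹)ᵢⱼ/√((R⁻¹)ᵢᵢ(R⁻¹)ⱼⱼ); singular matrices
  are rejected (a small ridge may be added explicitly, never silently).
  Bartlett's sphericity: χ² = −(n − 1 − (2p + 5)/6)·ln|R| on p(p−1)/2 df.
* **PCA.** Eigendecomposition of the Pearson correlation matrix; eigenvalue
  sum equals the trait count; contribution = 100·λₖ/p. Eigenvector signs
  are fixed so the largest-magnitude entry of each component is positive
  (signs are otherwise arbitrary; this makes output deterministic).
  Components with λ ≥ 1 (Kaiser criterion, threshold configurable) are
  retained; if none qualifies the first is kept with a warning.
* **Scores.** Yₖ = eᵀₖ·x (unit eigenvector · standardized trait vector);
  Z = Σ wₖYₖ with wₖ = contributionₖ/Σ contributions. Z is invariant to
  rescaling all contributions by a constant. Rank 1 is the largest Z; ties
  break by ascending accession id for determinism.
* **Clustering.** Ward linkage on Euclidean distance of the standardized
  matrix (the linkage used in the field for quantitative trait matrices;
  configurable), cut at k groups (default 5). Group profiles flag each
  group's trait mean as higher/lower than the panel mean; flags are
  affine-invariant.
* **Correlation screening.** Pairwise-complete Pearson r with two-sided
  p-values from the t transform on n − 2 df. No multiple-testing correction
  by default (raw significance is what the field reports);
  `benjamini_hochberg` is available.

### SNP summaries

Biallelic SNPs only; indels and multi-allelic records are skipped with a
logged tally (splitting multi-allelics would double-count positions).
Transitions are A↔G and C↔T; the six strand-symmetric classes collapse each
ordered substitution with its reverse complement (A→G and T→C are both
T:A→C:G). "Homozygosity" counts homozygous **non-reference** sites —
variation between the sample and the reference genome; homozygous-reference
and missing genotypes count as neither het nor hom. This interpretation is
documented prominently because summary tables in the literature rarely
define it.

Region classification consumes GFF3 transcripts with precedence
splicing > exon > UTR5;UTR3 > UTR5 > UTR3 > intronic > upstream/downstream
> upstream > downstream > intergenic. Splicing means within 2 bp of an
exon–intron boundary inside the intron (the standard donor/acceptor window;
configurable). Flanks are 2000 bp from the transcript ends, strand-aware
(configurable); a SNP in the upstream flank of one gene and the downstream
flank of another is "upstream/downstream". VCF and GFF3 coordinates are
1-based inclusive at the boundary; internal arithmetic is kept simple and
interval-inclusive. Coding effects rebuild the affected codon from the
genome (strand-aware), substitute the alternate base, and translate with
the standard genetic code: new stop → stopgain, lost stop → stoploss, same
amino acid → synonymous, else nonsynonymous. A CDS whose length is not a
multiple of 3 is rejected naming the transcript. There is no
canonical-transcript logic and no HGVS output.

## Synthetic data generator

The reference study's accession-level data are available only on request,
so the generator emulates them:

* **Quantitative traits**: multivariate normal via the Cholesky factor of a
  target correlation matrix, scaled to the published per-trait means/SDs
  (33 accessions by default). Gaussian marginals match the grading scheme's
  presumption of roughly symmetric spread; a skewed-trait option can be
  layered by transforming columns. The default correlation preset encodes
  the published sign pattern (strong plant height–stem diameter and leaf
  dimension–area correlations, fruit length–yield coupling, sugar–acid
  positive and sugar–internode/leaf-width negative relations) at the
  reported moderate-to-strong magnitudes, shrunk minimally toward the
  identity to be positive definite. The organic-acid SD is printed as 0.00
  at two decimals; the generator derives it from the printed CV
  (sd = mean·cv/100) so the trait keeps its reported relative variability.
* **Qualitative traits**: categorical sampling from the published level
  frequencies (renormalized where printed rows do not sum exactly to 1).
  Descriptor levels come from the frequency table itself because published
  frequency columns are positional and do not always align with the coding
  dictionary's codes.
* **Variants**: uniform-random ACGT genome (2 × 30 kb by default), genes
  placed non-overlapping with disjoint 2 kb flanks so every position has an
  unambiguous region truth; each gene has 5′UTR, three CDS exons (360 bp
  total), two 200 bp introns and a 3′UTR, on a random strand. SNP classes
  are drawn from a six-class spectrum (default EMS-like, 55 % C:G→T:A) and
  realized at positions whose reference base admits the class; genotypes
  are 0/1 with the chosen heterozygous fraction, else 1/1, independently
  per sample. A truth table records every class/region/effect assignment
  via the generator's own layout arithmetic, independent of the classifier.

What the generator does **not** emulate: real linkage between variants and
traits, EMS dose–response, field/environment effects, non-Gaussian trait
distributions, overlapping gene models, and realistic chromosome-scale
genomes. Passing tests therefore demonstrate correctness of the statistics
and classifiers under the stated model, not robustness to every property of
real field or sequencing data.

## Problem sizes and numerical choices

Tests run the generator at n = 33 (panel realism), n = 1000–5000 (factor
and moment recovery), and n = 10⁵ for the CV law-of-large-numbers check;
the toy genome carries up to 10⁴ SNPs. Frequency tables validate ΣPᵢ = 1 to
1e−9; eigenvector unit norms to 1e−8; the KMO oracle agreement is asserted
at 1e−10. All generators are pure functions of their integer seed
(bit-identical reruns), and pipeline runs with identical config and seed
produce byte-identical reports.

## Known limitations

* KMO/Bartlett and the reference eigendecomposition cannot be checked
  against the original panel (raw matrix not public); they are verified by
  independent oracles and invariants instead.
* Published summary tables carry small internal inconsistencies (frequency
  rows not summing to 1, per-sample Ts + Tv differing slightly from the
  stated SNP number, region counts not summing to the stated population
  total). The package reports what the data yield; `summarize_annotation`
  accepts an explicit denominator for externally reported tables.
* Indel annotation, variant calling/filtering, factor rotation, biplots and
  bootstrap cluster stability are out of scope.
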