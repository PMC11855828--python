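"""Synthetic accession-trait and variant data generators.

The raw field data behind the bundled summary tables are not public, so this
module generates accession-level data with the same statistical structure:

* quantitative trait matrices drawn from a multivariate normal with the
  published per-trait means/SDs and a target correlation matrix (default
  preset encodes the reported sign pattern among growth and quality traits);
* qualitative trait matrices sampled from the published level frequencies;
* toy genomes with non-overlapping genes (UTR/exon/intron structure), a VCF
  of SNPs drawn from a chosen six-class substitution spectrum with a chosen
  heterozygosity rate, and a truth table recording every class / region /
  effect assignment by the generator's own placement bookkeeping.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import datasets
from .snp_summary import SPECTRUM_CLASSES, _CLASS_OF
from .trait_model import AccessionRecord, TraitDescriptor, TraitMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# ---------------------------------------------------------------------------
# Quantitative traits
# ---------------------------------------------------------------------------


@dataclass
class TraitGenSpec:
    """Target moments for a synthetic quantitative trait matrix."""

    means: dict[str, float]
    sds: dict[str, float]
    correlation: pd.DataFrame
    n_accessions: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("all target sds must be > 0")
        c = self.correlation.values
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")


def default_correlation_preset() -> pd.DataFrame:
    """A realistic synthetic correlation preset for the 15 quantitative traits.

    Encodes the reported sign pattern at moderate magnitudes: strong positive
    growth-trait block (plant height, stem diameter, leaf dimensions/area),
    a yield block tied to fruit longitudinal diameter, sugar-acid coupling,
    and the negative sugar vs internode/leaf-width relations. Shrunk toward
    the identity just enough to be positive definite.
    """
    traits = datasets.QUANTITATIVE_TRAITS
    idx = {t: i for i, t in enumerate(traits)}
    c = np.eye(len(traits))

    def put(a: str, b: str, r: float) -> None:
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r

    put("plant height (cm)", "stem diameter (mm)", 0.85)
    put("plant height (cm)", "leaf length (cm)", 0.60)
    put("plant height (cm)", "leaf area (cm2)", 0.51)
    put("internode length (mm)", "leaf length (cm)", 0.46)
    put("leaf length (cm)", "leaf width (cm)", 0.83)
    put("leaf length (cm)", "leaf area (cm2)", 0.92)
    put("leaf width (cm)", "leaf area (cm2)", 0.90)
    put("leaf length (cm)", "yield (t/667m2)", 0.42)
    put("leaf length (cm)", "yield per plant (kg)", 0.42)
    put("leaf area (cm2)", "yield (t/667m2)", 0.36)
    put("leaf area (cm2)", "yield per plant (kg)", 0.35)
    put("fruit longitudinal diameter (mm)", "yield (t/667m2)", 0.85)
    put("fruit longitudinal diameter (mm)", "yield per plant (kg)", 0.85)
    put("yield (t/667m2)", "yield per plant (kg)", 0.97)
    put("soluble sugar (mg/g)", "organic acid (%)", 0.51)
    put("soluble sugar (mg/g)", "internode length (mm)", -0.39)
    put("soluble sugar (mg/g)", "leaf width (cm)", -0.38)
    put("vitamin C (mg/100g)", "stem diameter (mm)", 0.45)
    put("vitamin C (mg/100g)", "fruit longitudinal diameter (mm)", 0.36)
    put("nitrate (mg/g)", "fruit transverse diameter (mm)", 0.39)

    # shrink toward identity until positive definite (deterministic)
    while np.linalg.eigvalsh(c).min() < 1e-6:
        c = 0.95 * c + 0.05 * np.eye(len(traits))
    return pd.DataFrame(c, index=traits, columns=traits)


def default_trait_spec(n_accessions: int = 33, seed: int = 0) -> TraitGenSpec:
    """Spec with the published per-trait means/SDs and the default preset.

    The organic-acid SD is printed as 0.00 at 2 dp; the generator instead
    derives it from the reported CV (sd = mean * cv / 100) so the trait
    carries its reported relative variability.
    """
    summary = datasets.QUANTITATIVE_SUMMARY
    means = summary["mean"].to_dict()
    sds = {}
    for trait, row in summary.iterrows():
        sd = row["sd"] if row["sd"] > 0 else row["mean"] * row["cv"] / 100.0
        sds[trait] = float(sd)
    return TraitGenSpec(means, sds, default_correlation_preset(),
                        n_accessions=n_accessions, seed=seed)


def gen_quant_traits(spec: TraitGenSpec) -> TraitMatrix:
    """Multivariate-normal trait matrix matching the spec's moments.

    Sampled via the Cholesky factor of the target correlation matrix, then
    scaled to the target means/SDs; deterministic given the seed.
    """
    traits = list(spec.correlation.columns)
    c = spec.correlation.values
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "target correlation matrix is not positive definite; project it "
            "to the nearest PSD matrix (e.g. clip negative eigenvalues and "
            "renormalize the diagonal) before generating") from exc
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_accessions, len(traits))) @ chol.T
    mu = np.array([spec.means[t] for t in traits])
    sd = np.array([spec.sds[t] for t in traits])
    x = mu + z * sd
    descriptors = [TraitDescriptor(t, "quantitative") for t in traits]
    records = [
        AccessionRecord(str(i + 1), dict(zip(traits, map(float, row))))
        for i, row in enumerate(x)
    ]
    return TraitMatrix(descriptors, records, provenance=f"synthetic(seed={spec.seed})")


# ---------------------------------------------------------------------------
# Qualitative traits
# ---------------------------------------------------------------------------

def default_qualitative_frequencies() -> dict[str, dict[int, float]]:
    """Published level frequencies per qualitative trait, renormalized to 1."""
    out: dict[str, dict[int, float]] = {}
    for trait, row in datasets.QUALITATIVE_FREQUENCIES.items():
        freqs = row["freqs"]
        total = sum(freqs.values())
        out[trait] = {code: p / total for code, p in freqs.items()}
    return out


def gen_qual_traits(freqs: dict[str, dict[int, float]], n: int,
                    seed: int = 0) -> TraitMatrix:
    """Categorically sampled qualitative trait matrix.

    ``freqs`` maps trait name -> {level code: probability}; probabilities of
    each trait must sum to 1.
    """
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    descriptors = []
    coding = {d.name: d for d in datasets.QUALITATIVE_CODING}
    for trait, table in freqs.items():
        codes = list(table)
        p = np.array([table[c] for c in codes], dtype=float)
        if (p < 0).any():
            raise ValueError(f"negative frequency for {trait!r}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies of {trait!r} sum to {p.sum()}, not 1")
        columns[trait] = rng.choice(codes, size=n, p=p)
        # descriptor levels come from the frequency table itself (published
        # frequency columns are positional and may not align with the coding
        # dictionary's codes); labels are taken from the coding when the code
        # exists there
        known = coding[trait].levels if trait in coding else {}
        levels = {int(c): known.get(int(c), f"level {c}") for c in codes}
        if len(levels) < 2:
            levels[max(levels, default=0) + 1] = "unused level"
        descriptors.append(TraitDescriptor(trait, "qualitative", levels=levels))
    records = [
        AccessionRecord(str(i + 1),
                        {t: int(columns[t][i]) for t in freqs})
        for i in range(n)
    ]
    return TraitMatrix(descriptors, records, provenance=f"synthetic(seed={seed})")


# ---------------------------------------------------------------------------
# Toy genome / gene models / VCF
# ---------------------------------------------------------------------------

@dataclass
class _GeneLayout:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr_left: tuple[int, int]
    utr_right: tuple[int, int]


@dataclass
class VariantGenSpec:
    """Parameters of the toy genome + variant generator."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30000, "chr2": 30000})
    n_snps: int = 10000
    spectrum: dict[str, float] = field(
        default_factory=lambda: {
            # EMS-like spectrum: C:G>T:A transitions dominate
            "C:G>T:A": 0.55, "T:A>C:G": 0.15, "A:T>T:A": 0.08,
            "A:T>C:G": 0.07, "C:G>A:T": 0.08, "C:G>G:C": 0.07})
    het_fraction: float = 0.5
    n_samples: int = 2
    genes_per_chrom: int = 3
    flank: int = 2000
    splice_window: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.spectrum) - set(SPECTRUM_CLASSES)
        if unknown:
            raise ValueError(f"unknown spectrum classes: {sorted(unknown)}")
        if abs(sum(self.spectrum.values()) - 1.0) > 1e-9:
            raise ValueError("spectrum proportions must sum to 1")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het fraction must be in [0, 1]")
        if self.n_snps > sum(self.chrom_lengths.values()):
            raise ValueError("more SNPs requested than genome positions")


# gene internal structure (bp): UTR + three CDS exons with two introns
_U5, _CDS_CHUNKS, _INTRON, _U3 = 60, (120, 90, 150), 200, 60


def _layout_genes(chrom: str, length: int, n_genes: int, flank: int,
                  rng: np.random.Generator) -> list[_GeneLayout]:
    span = _U5 + sum(_CDS_CHUNKS) + 2 * _INTRON + _U3
    spacing = span + 2 * flank + 500   # keeps flanks of neighbours disjoint
    layouts = []
    g = flank + 200
    i = 0
    while g + span - 1 <= length - flank - 200 and i < n_genes:
        e1 = (g, g + _U5 + _CDS_CHUNKS[0] - 1)
        e2s = e1[1] + _INTRON + 1
        e2 = (e2s, e2s + _CDS_CHUNKS[1] - 1)
        e3s = e2[1] + _INTRON + 1
        e3 = (e3s, e3s + _CDS_CHUNKS[2] + _U3 - 1)
        cds = [(g + _U5, e1[1]), e2, (e3s, e3s + _CDS_CHUNKS[2] - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        layouts.append(_GeneLayout(
            f"{chrom}_g{i + 1}", chrom, strand, g, e3[1],
            [e1, e2, e3], cds,
            utr_left=(g, g + _U5 - 1),
            utr_right=(e3s + _CDS_CHUNKS[2], e3[1])))
        g += spacing
        i += 1
    return layouts


def _truth_region(pos: int, layouts: list[_GeneLayout], flank: int,
                  splice_window: int) -> str:
    """Region of a position by the generator's own layout arithmetic."""
    for g in layouts:
        if g.start - flank <= pos <= g.end + flank:
            if pos < g.start:
                return "upstream" if g.strand == "+" else "downstream"
            if pos > g.end:
                return "downstream" if g.strand == "+" else "upstream"
            if any(s <= pos <= e for s, e in g.cds):
                return "exon"
            if g.utr_left[0] <= pos <= g.utr_left[1]:
                return "UTR5" if g.strand == "+" else "UTR3"
            if g.utr_right[0] <= pos <= g.utr_right[1]:
                return "UTR3" if g.strand == "+" else "UTR5"
            # intron
            near = any(0 < pos - e <= splice_window or 0 < s - pos <= splice_window
                       for s, e in g.exons)
            return "splicing" if near else "intronic"
    return "intergenic"


def _truth_effect(pos: int, alt: str, g: _GeneLayout, seq: str) -> str:
    """Coding effect by direct codon arithmetic on the generator's layout."""
    offset = 0
    for s, e in g.cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    cds_seq = "".join(seq[s - 1:e] for s, e in g.cds)
    mutated = cds_seq[:offset] + alt + cds_seq[offset + 1:]
    if g.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        offset = len(cds_seq) - 1 - offset
    k = (offset // 3) * 3
    old = str(Seq(cds_seq[k:k + 3]).translate())
    new = str(Seq(mutated[k:k + 3]).translate())
    if new == "*" and old != "*":
        return "stopgain"
    if old == "*" and new != "*":
        return "stoploss"
    return "synonymous" if old == new else "nonsynonymous"


def gen_variants(spec: VariantGenSpec, outdir: str | Path
                 ) -> dict[str, Path | pd.DataFrame]:
    """Write a toy FASTA + GFF3 + VCF and return paths plus the truth table.

    The genome is uniform-random over ACGT; genes are placed non-overlapping
    (flanks disjoint) so every position has an unambiguous region truth. SNP
    positions are uniform; each SNP's substitution class is drawn from the
    spectrum and realized at a position whose reference base admits it.
    Genotypes are heterozygous (0/1) with probability ``het_fraction`` and
    homozygous alternate (1/1) otherwise, independently per sample.

    Returns ``{"fasta": path, "gff": path, "vcf": path, "truth": path,
    "truth_table": DataFrame}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genomes: dict[str, str] = {}
    layouts: dict[str, list[_GeneLayout]] = {}
    for chrom, length in spec.chrom_lengths.items():
        genomes[chrom] = "".join(
            rng.choice(list("ACGT"), size=length))
        layouts[chrom] = _layout_genes(chrom, length, spec.genes_per_chrom,
                                       spec.flank, rng)

    # positions bucketed by reference base, shuffled once
    pools: dict[str, list[tuple[str, int]]] = {b: [] for b in "ACGT"}
    for chrom, seq in genomes.items():
        for i, base in enumerate(seq):
            pools[base].append((chrom, i + 1))
    for base in pools:
        perm = rng.permutation(len(pools[base]))
        pools[base] = [pools[base][j] for j in perm]

    class_names = list(spec.spectrum)
    counts = rng.multinomial(spec.n_snps,
                             [spec.spectrum[c] for c in class_names])
    ref_alt_of_class = {}
    for (r, a), label in _CLASS_OF.items():
        ref_alt_of_class.setdefault(label, []).append((r, a))

    snps: list[dict] = []
    for label, n_class in zip(class_names, counts):
        pairs = ref_alt_of_class[label]
        for _ in range(int(n_class)):
            sizes = np.array([len(pools[r]) for r, _ in pairs], dtype=float)
            if sizes.sum() == 0:
                raise ValueError(
                    f"genome exhausted: no positions left with a reference "
                    f"base admitting class {label}")
            r, a = pairs[int(rng.choice(len(pairs), p=sizes / sizes.sum()))]
            chrom, pos = pools[r].pop()
            gts = ["0/1" if rng.random() < spec.het_fraction else "1/1"
                   for _ in range(spec.n_samples)]
            snps.append({"chrom": chrom, "pos": pos, "ref": r, "alt": a,
                         "class6": label, "genotypes": gts})

    snps.sort(key=lambda s: (s["chrom"], s["pos"]))

    # truth bookkeeping
    rows = []
    for s in snps:
        region = _truth_region(s["pos"], layouts[s["chrom"]], spec.flank,
                               spec.splice_window)
        effect = ""
        if region == "exon":
            g = next(g for g in layouts[s["chrom"]]
                     if any(a <= s["pos"] <= b for a, b in g.cds))
            effect = _truth_effect(s["pos"], s["alt"], g, genomes[s["chrom"]])
        subst = ("transition" if (s["ref"], s["alt"]) in
                 {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
                 else "transversion")
        row = {"chrom": s["chrom"], "pos": s["pos"], "ref": s["ref"],
               "alt": s["alt"], "class6": s["class6"], "subst": subst,
               "region": region, "effect": effect}
        for i, gt in enumerate(s["genotypes"]):
            row[f"gt_{i}"] = gt
        rows.append(row)
    truth = pd.DataFrame(rows)

    fasta_path = outdir / "genome.fa"
    with fasta_path.open("w") as fh:
        for chrom, seq in genomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    gff_path = outdir / "genes.gff3"
    with gff_path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in spec.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for chrom in spec.chrom_lengths:
            for g in layouts[chrom]:
                gid, mid = g.gene_id, g.gene_id + ".1"
                base = f"{chrom}\tgermdiv\t"
                fh.write(base + f"gene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                                f"ID={gid}\n")
                fh.write(base + f"mRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                                f"ID={mid};Parent={gid}\n")
                for s, e in g.exons:
                    fh.write(base + f"exon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                                    f"Parent={mid}\n")
                chunks = g.cds if g.strand == "+" else list(reversed(g.cds))
                phases, cum = {}, 0
                for s, e in chunks:
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s + 1
                for s, e in g.cds:
                    fh.write(base + f"CDS\t{s}\t{e}\t.\t{g.strand}\t"
                                    f"{phases[(s, e)]}\tID={mid}.cds;Parent={mid}\n")
                u5 = g.utr_left if g.strand == "+" else g.utr_right
                u3 = g.utr_right if g.strand == "+" else g.utr_left
                fh.write(base + f"five_prime_UTR\t{u5[0]}\t{u5[1]}\t.\t"
                                f"{g.strand}\t.\tParent={mid}\n")
                fh.write(base + f"three_prime_UTR\t{u3[0]}\t{u3[1]}\t.\t"
                                f"{g.strand}\t.\tParent={mid}\n")

    vcf_path = outdir / "variants.vcf"
    sample_names = [f"s{i + 1}" for i in range(spec.n_samples)]
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in spec.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for s in snps:
            fh.write(f"{s['chrom']}\t{s['pos']}\t.\t{s['ref']}\t{s['alt']}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(s["genotypes"]) + "\n")

    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"fasta": fasta_path, "gff": gff_path, "vcf": vcf_path,
            "truth": truth_path, "truth_table": truth}
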