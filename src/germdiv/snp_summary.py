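"""SNP spectrum, zygosity, and gene-region / coding-effect summaries.

Consumes a variant-caller's VCF together with a GFF3 gene model file and the
genome FASTA, and produces the summary statistics used to characterize an
EMS-mutagenized population: transition/transversion counts and ratio, the
strand-collapsed six-class substitution spectrum (EMS predominantly induces
C:G>T:A transitions), per-sample heterozygous / homozygous non-reference
site counts, and a genomic-region tally (upstream, exon with coding effect,
intron, splice site, UTRs, downstream, intergenic).

Only biallelic SNPs are summarized; indels and multi-allelic records are
skipped with a logged tally. "Homozygous" counts are homozygous
*non-reference* sites (variation between the sample and the reference
genome); homozygous-reference and missing genotypes count as neither.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio.Seq import Seq
from cyvcf2 import VCF
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

NUCLEOTIDES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Strand-symmetric substitution classes; each ordered substitution and its
#: reverse complement collapse onto one class (A>G and T>C are both T:A>C:G).
SPECTRUM_CLASSES = ["T:A>C:G", "C:G>T:A", "A:T>T:A",
                    "A:T>C:G", "C:G>A:T", "C:G>G:C"]

_CLASS_OF: dict[tuple[str, str], str] = {}
for _label in SPECTRUM_CLASSES:
    _ref, _alt = _label.split(">")
    _r, _a = _ref.split(":")[0], _alt.split(":")[0]
    _CLASS_OF[(_r, _a)] = _label
    _CLASS_OF[(_COMPLEMENT[_r], _COMPLEMENT[_a])] = _label

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: Region categories in classification precedence order.
REGION_PRECEDENCE = ["splicing", "exon", "UTR5;UTR3", "UTR5", "UTR3",
                     "intronic", "upstream/downstream", "upstream",
                     "downstream", "intergenic"]

EFFECT_CATEGORIES = ["stopgain", "stoploss", "synonymous", "nonsynonymous"]


# ---------------------------------------------------------------------------
# Records and gene models
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample diploid genotypes.

    ``genotypes`` holds (allele1, allele2) integer pairs per sample; -1
    denotes a missing allele.
    """

    chrom: str
    pos: int                 # 1-based
    ref: str
    alt: str
    genotypes: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"not a SNP: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass
class GeneModel:
    """A transcript's intervals, 1-based inclusive, on one chromosome."""

    gene_id: str
    chrom: str
    strand: str              # '+' or '-'
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class VcfScan:
    """Biallelic SNPs read from a VCF plus skip tallies."""

    records: list[VariantRecord]
    samples: list[str]
    n_skipped_non_snp: int = 0
    n_skipped_multiallelic: int = 0


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> VcfScan:
    """Read biallelic SNP records from a VCF 4.x file.

    Non-SNP and multi-allelic records are skipped and tallied (EMS point
    mutations are the object of interest; splitting multi-allelic sites
    would double-count positions).
    """
    vcf = VCF(str(path))
    records: list[VariantRecord] = []
    non_snp = multi = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) > 1:
            multi += 1
            continue
        if len(v.REF) != 1 or not alts or len(alts[0]) != 1 \
                or v.REF not in NUCLEOTIDES or alts[0] not in NUCLEOTIDES:
            non_snp += 1
            continue
        gts = [(int(g[0]), int(g[1])) for g in v.genotypes]
        records.append(VariantRecord(v.CHROM, v.POS, v.REF, alts[0], gts))
    samples = list(vcf.samples)
    vcf.close()
    if non_snp or multi:
        logger.info("%s: skipped %d non-SNP and %d multi-allelic record(s)",
                    path, non_snp, multi)
    return VcfScan(records, samples, non_snp, multi)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read transcript gene models from a GFF3 file."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(mrna, level=1):
            interval = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(interval)
            elif child.featuretype == "CDS":
                cds.append(interval)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(interval)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(interval)
        models.append(GeneModel(mrna.id, mrna.seqid, mrna.strand,
                                mrna.start, mrna.end,
                                sorted(exons), sorted(cds),
                                sorted(utr5), sorted(utr3)))
    return models


# ---------------------------------------------------------------------------
# Substitution spectrum
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or 'transversion'."""
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"invalid bases {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref equals alt")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def substitution_class(ref: str, alt: str) -> str:
    """The strand-symmetric six-class label of an ordered substitution."""
    if classify_substitution(ref, alt):  # validates
        return _CLASS_OF[(ref, alt)]


def tstv_ratio(transitions: int, transversions: int) -> float:
    """Transition/transversion ratio; undefined when transversions = 0."""
    if transversions <= 0:
        raise ZeroDivisionError("Ts/Tv undefined: no transversions")
    return transitions / transversions


@dataclass
class SpectrumTable:
    """Six-class substitution spectrum plus zygosity totals."""

    class_counts: dict[str, int]
    transitions: int
    transversions: int
    het_count: int
    hom_count: int
    snp_total: int

    @property
    def ts_tv(self) -> float:
        return tstv_ratio(self.transitions, self.transversions)

    @property
    def proportions(self) -> dict[str, float]:
        total = max(self.snp_total, 1)
        return {c: n / total for c, n in self.class_counts.items()}


def spectrum_6class(records: list[VariantRecord]) -> SpectrumTable:
    """Tally records into the six strand-symmetric substitution classes."""
    counts = Counter({c: 0 for c in SPECTRUM_CLASSES})
    ts = het = hom = 0
    for rec in records:
        counts[substitution_class(rec.ref, rec.alt)] += 1
        if classify_substitution(rec.ref, rec.alt) == "transition":
            ts += 1
        for a, b in rec.genotypes:
            if a < 0 or b < 0:
                continue
            if a != b:
                het += 1
            elif a != 0:
                hom += 1
    total = len(records)
    return SpectrumTable(dict(counts), ts, total - ts, het, hom, total)


def zygosity_counts(records: list[VariantRecord],
                    samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample heterozygous / homozygous non-reference site counts."""
    if not records:
        raise ValueError("no records")
    n_samples = len(records[0].genotypes)
    if n_samples == 0:
        raise ValueError("records carry no genotypes (absent GT field)")
    het = [0] * n_samples
    hom = [0] * n_samples
    for rec in records:
        for i, (a, b) in enumerate(rec.genotypes):
            if a < 0 or b < 0:
                continue
            if a != b:
                het[i] += 1
            elif a != 0:
                hom[i] += 1
    index = samples if samples is not None else [f"sample{i}" for i in range(n_samples)]
    return pd.DataFrame({"het": het, "hom": hom}, index=index)


def summarize_samples(scan: VcfScan) -> pd.DataFrame:
    """Per-sample SNP count, Ts, Tv, Ts/Tv, het and hom site counts.

    A site counts for a sample when the sample carries at least one
    alternate allele.
    """
    n_samples = len(scan.samples)
    snp = [0] * n_samples
    ts = [0] * n_samples
    tv = [0] * n_samples
    for rec in scan.records:
        kind = classify_substitution(rec.ref, rec.alt)
        for i, (a, b) in enumerate(rec.genotypes):
            if max(a, b) > 0:
                snp[i] += 1
                if kind == "transition":
                    ts[i] += 1
                else:
                    tv[i] += 1
    zyg = zygosity_counts(scan.records, scan.samples)
    out = pd.DataFrame({"snp_number": snp, "transition": ts,
                        "transversion": tv}, index=scan.samples)
    out["ts_tv"] = [tstv_ratio(a, b) if b else float("nan")
                    for a, b in zip(out["transition"], out["transversion"])]
    out["het"] = zyg["het"]
    out["hom"] = zyg["hom"]
    return out


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def _in(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _labels_for_model(pos: int, model: GeneModel, flank: int,
                      splice_window: int) -> set[str]:
    labels: set[str] = set()
    if model.start <= pos <= model.end:
        if _in(pos, model.exons):
            if _in(pos, model.cds):
                labels.add("exon")
            elif _in(pos, model.utr5):
                labels.add("UTR5")
            elif _in(pos, model.utr3):
                labels.add("UTR3")
            else:
                labels.add("exon")
        else:
            # intron: within splice_window bp of an exon boundary -> splicing
            near = any(
                0 < pos - e <= splice_window or 0 < s - pos <= splice_window
                for s, e in model.exons)
            labels.add("splicing" if near else "intronic")
    else:
        five_end, three_end = ((model.start, model.end)
                               if model.strand == "+"
                               else (model.end, model.start))
        if model.strand == "+":
            if five_end - flank <= pos < five_end:
                labels.add("upstream")
            elif three_end < pos <= three_end + flank:
                labels.add("downstream")
        else:
            if five_end < pos <= five_end + flank:
                labels.add("upstream")
            elif three_end - flank <= pos < three_end:
                labels.add("downstream")
    return labels


def classify_region(record: VariantRecord, models: list[GeneModel],
                    flank: int = 2000, splice_window: int = 2) -> str:
    """Classify a SNP into a genomic region category.

    Precedence: splicing > exon > UTR5;UTR3 > UTR5 > UTR3 > intronic >
    upstream/downstream (in both flanks of different genes) > upstream >
    downstream > intergenic. Splicing means within ``splice_window`` bp of
    an exon-intron boundary inside the intron. Flanks are measured from the
    transcript ends, strand-aware.
    """
    labels: set[str] = set()
    for model in models:
        if model.chrom == record.chrom:
            labels |= _labels_for_model(record.pos, model, flank, splice_window)
    if {"UTR5", "UTR3"} <= labels:
        labels.add("UTR5;UTR3")
    if {"upstream", "downstream"} <= labels:
        labels.add("upstream/downstream")
    for category in REGION_PRECEDENCE:
        if category in labels:
            return category
    return "intergenic"


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

def coding_effect(record: VariantRecord, model: GeneModel, genome) -> str:
    """Effect of a CDS SNP: synonymous, nonsynonymous, stopgain or stoploss.

    Rebuilds the affected codon from the genome (strand-aware), substitutes
    the alternate base, translates both with the standard genetic code, and
    compares amino acids. ``genome`` is an indexed FASTA (``pyfaidx.Fasta``)
    or any mapping of chromosome name to sequence string.
    """
    cds = sorted(model.cds)
    cds_len = sum(e - s + 1 for s, e in cds)
    if cds_len % 3 != 0:
        raise ValueError(
            f"CDS length {cds_len} of {model.gene_id} not divisible by 3")
    if not _in(record.pos, cds):
        raise ValueError(f"{record.chrom}:{record.pos} not in CDS of {model.gene_id}")
    # offset of pos within the forward-strand CDS concatenation
    offset = 0
    for s, e in cds:
        if s <= record.pos <= e:
            offset += record.pos - s
            break
        offset += e - s + 1
    seq = _chrom_seq(genome, model.chrom)
    cds_seq = "".join(seq[s - 1:e] for s, e in cds).upper()
    ref_in_cds = cds_seq[offset]
    if ref_in_cds != record.ref:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome has {ref_in_cds}, record has {record.ref}")
    mutated = cds_seq[:offset] + record.alt + cds_seq[offset + 1:]
    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        offset = cds_len - 1 - offset
    codon_idx = offset // 3
    old_aa = str(Seq(cds_seq[codon_idx * 3: codon_idx * 3 + 3]).translate())
    new_aa = str(Seq(mutated[codon_idx * 3: codon_idx * 3 + 3]).translate())
    if new_aa == "*" and old_aa != "*":
        return "stopgain"
    if old_aa == "*" and new_aa != "*":
        return "stoploss"
    return "synonymous" if old_aa == new_aa else "nonsynonymous"


def _chrom_seq(genome, chrom: str) -> str:
    seq = genome[chrom]
    return str(seq[:]) if isinstance(genome, Fasta) else str(seq)


# ---------------------------------------------------------------------------
# Annotation tallies
# ---------------------------------------------------------------------------

@dataclass
class RegionTally:
    """Counts of SNPs per region category (exon split by coding effect)."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def annotate_regions(records: list[VariantRecord], models: list[GeneModel],
                     genome=None, flank: int = 2000,
                     splice_window: int = 2) -> RegionTally:
    """Tally records by region; exon SNPs are split by coding effect when a
    genome is supplied."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    counts: Counter = Counter()
    seen_chroms = {m.chrom for m in models}
    for rec in records:
        if rec.chrom not in seen_chroms:
            logger.warning("chromosome %r absent from gene models; "
                           "classifying %s:%d as intergenic",
                           rec.chrom, rec.chrom, rec.pos)
        chrom_models = by_chrom.get(rec.chrom, [])
        category = classify_region(rec, chrom_models, flank, splice_window)
        if category == "exon" and genome is not None:
            model = next(m for m in chrom_models
                         if m.chrom == rec.chrom and _in(rec.pos, m.cds))
            category = f"exon:{coding_effect(rec, model, genome)}"
        counts[category] += 1
    return RegionTally(dict(counts))


def summarize_annotation(tally: RegionTally | dict[str, int],
                         total: int | None = None) -> pd.DataFrame:
    """Per-category counts with percentages (2 dp scale, full precision kept).

    ``total`` defaults to the sum of the tally; an explicit denominator may
    be given when summarizing an externally reported table whose stated
    total differs from the category sum.
    """
    counts = tally.counts if isinstance(tally, RegionTally) else dict(tally)
    denom = total if total is not None else sum(counts.values())
    if denom <= 0:
        raise ValueError("zero total")
    df = pd.DataFrame({"count": pd.Series(counts, dtype=int)})
    df["percent"] = 100.0 * df["count"] / denom
    return df
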