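"""End-to-end evaluation pipeline: one config in, a report bundle out.

``run_evaluation`` loads a trait table (plus optional VCF/GFF/FASTA), runs
qualitative diversity, quantitative summaries, correlation screening,
clustering with group profiles, PCA with composite scoring/ranking, and the
optional SNP summary, writing each report as delimited text with a run log.
Any stage failure aborts the run with the stage name and removes partial
outputs. Rounding is applied only at serialization; internal values are
full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import diversity, multivariate, snp_summary
from .trait_model import load_coding, load_trait_table

logger = logging.getLogger(__name__)

REPORT_FILES = [
    "qualitative_diversity.tsv",
    "quantitative_summary.tsv",
    "correlations.tsv",
    "cluster_assignments.tsv",
    "group_profiles.tsv",
    "pca_components.tsv",
    "composite_scores.tsv",
]
SNP_REPORT_FILES = ["snp_sample_summary.tsv", "snp_regions.tsv"]


@dataclass
class RunConfig:
    """Configuration of one evaluation run."""

    trait_table: str | Path
    coding_file: str | Path
    output_dir: str | Path
    vcf: str | Path | None = None
    gff: str | Path | None = None
    fasta: str | Path | None = None
    standardization: str = "zscore"       # 'zscore' (scores) or 'range'
    eigenvalue_threshold: float = 1.0
    cluster_k: int = 5
    seed: int = 0
    report_digits: int = 4
    flank: int = 2000

    def __post_init__(self) -> None:
        if self.standardization not in ("zscore", "range"):
            raise ValueError("standardization must be 'zscore' or 'range'")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_evaluation(config: RunConfig) -> dict[str, Path]:
    """Run the full evaluation; returns report name -> written path."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    digits = config.report_digits

    def emit(name: str, df) -> None:
        path = outdir / name
        df.round(digits).to_csv(path, sep="\t")
        written[name] = path

    current_stage = "init"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        logger.info("stage: %s", name)

    try:
        stage("load")
        coding = load_coding(config.coding_file)
        matrix = load_trait_table(config.trait_table, coding)

        if matrix.qualitative_traits():
            stage("qualitative-diversity")
            emit("qualitative_diversity.tsv",
                 diversity.qualitative_diversity_table(matrix).set_index("trait"))

        stage("quantitative-summary")
        quant = matrix.quantitative_traits()
        if not quant:
            raise ValueError("no quantitative traits in table")
        emit("quantitative_summary.tsv",
             diversity.quantitative_summary_table(matrix))

        stage("correlation")
        corr = multivariate.correlation_matrix(matrix, quant)
        emit("correlations.tsv", corr.r)

        stage("standardize")
        df = matrix.to_dataframe()[quant]
        std = (multivariate.zscore_standardize(df)
               if config.standardization == "zscore"
               else multivariate.range_standardize(df))

        stage("cluster")
        assignment = multivariate.cluster_accessions(std, config.cluster_k)
        emit("cluster_assignments.tsv", assignment.groups.to_frame())
        emit("group_profiles.tsv",
             multivariate.profile_groups(df, assignment).set_index("group"))

        stage("pca")
        pca = multivariate.pca_correlation(std, config.eigenvalue_threshold)
        table = pca.eigenvectors.copy()
        table.loc["eigenvalue"] = pca.eigenvalues
        table.loc["contribution_pct"] = pca.contribution
        table.loc["cumulative_pct"] = pca.cumulative
        emit("pca_components.tsv", table.iloc[:, : max(pca.retained) + 1])

        stage("composite-score")
        y = multivariate.component_scores(std, pca)
        scores = multivariate.composite_score(
            y, pca.contribution[pca.retained])
        emit("composite_scores.tsv", multivariate.rank_accessions(scores))

        if config.vcf is not None:
            stage("snp-summary")
            scan = snp_summary.read_vcf(config.vcf)
            emit("snp_sample_summary.tsv", snp_summary.summarize_samples(scan))
            if config.gff is not None:
                models = snp_summary.read_gff(config.gff)
                genome = None
                if config.fasta is not None:
                    from pyfaidx import Fasta
                    genome = Fasta(str(config.fasta))
                tally = snp_summary.annotate_regions(
                    scan.records, models, genome, flank=config.flank)
                emit("snp_regions.tsv", snp_summary.summarize_annotation(tally))

        stage("run-log")
        log_path = outdir / "run_log.txt"
        with log_path.open("w") as fh:
            fh.write(f"germdiv {__version__}\n")
            for key, value in asdict(config).items():
                fh.write(f"{key} = {value}\n")
            fh.write(f"accessions = {len(matrix.records)}\n")
            fh.write(f"reports = {sorted(written)}\n")
        written["run_log.txt"] = log_path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise StageError(current_stage, exc) from exc
    return written
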