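"""End-to-end run configuration and orchestration.

``run_pipeline`` executes the full workflow — optional IMPUTE2 conversion,
annotated-VCF reading, HC filtering, matrix construction, compound-het
detection and the descriptive report — writing every artifact into one
output directory.  Outputs are staged in a temporary subdirectory and moved
into place only on success, so a failed run leaves no partial outputs.
"""

from __future__ import annotations

import logging
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import calling, reporting
from .impute2 import QualityThresholds, convert_to_vcf
from .trios import read_pedigree, validate_ch_transmission
from .vcf import read_annotated_vcf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    The resolved configuration is written next to the outputs
    (``run_config.yaml``) for provenance.
    """

    input_format: str = "vcf"            # "vcf" | "impute2"
    vcf_path: str | None = None
    gen_path: str | None = None
    haps_path: str | None = None
    sample_path: str | None = None
    info_path: str | None = None
    min_info: float = 0.9
    prob_cutoff: float = 0.05
    transcript_policy: str = "any"       # "any" | "canonical"
    keep_flagged_hc: bool = True
    assume_unphased: bool = False        # strip phase before calling
    pedigree_path: str | None = None
    pairs_path: str | None = None
    output_dir: str = "lofcall_out"
    seed: int = 0

    def validate(self) -> None:
        if self.input_format not in ("vcf", "impute2"):
            raise ValueError(f"unknown input format {self.input_format!r}")
        if self.input_format == "vcf":
            needed = [("vcf_path", self.vcf_path)]
        else:
            needed = [
                ("gen_path", self.gen_path), ("haps_path", self.haps_path),
                ("sample_path", self.sample_path),
                ("info_path", self.info_path),
            ]
        for name, value in needed:
            if value is None:
                raise ValueError(f"{name} is required for "
                                 f"{self.input_format} input")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
        for opt in (self.pedigree_path, self.pairs_path):
            if opt is not None and not Path(opt).exists():
                raise FileNotFoundError(f"{opt} does not exist")
        QualityThresholds(self.min_info, self.prob_cutoff)  # range check
        if self.transcript_policy not in ("any", "canonical"):
            raise ValueError(
                f"unknown transcript policy {self.transcript_policy!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    output_dir: Path
    summary: reporting.CohortSummary
    variant_matrix: calling.VariantZygosityMatrix
    gene_matrix: calling.GeneLossMatrix
    ch_events: list[calling.CHEvent]
    mechanism_labels: dict[str, str]
    transmission_summary: object | None = None
    mismatches: dict | None = None
    files: dict[str, Path] = field(default_factory=dict)


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed sample-pair line: {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the workflow described by ``config``; see module docstring."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = Path(tempfile.mkdtemp(prefix=".stage-", dir=out_dir))
    files: dict[str, Path] = {}
    try:
        vcf_path = config.vcf_path
        if config.input_format == "impute2":
            vcf_path = convert_to_vcf(
                config.gen_path, config.haps_path, config.sample_path,
                config.info_path,
                QualityThresholds(config.min_info, config.prob_cutoff),
                stage / "converted.vcf",
            )
            files["converted_vcf"] = Path("converted.vcf")
            logger.info("impute2 conversion complete: %s", vcf_path)

        cohort = read_annotated_vcf(vcf_path)
        if config.assume_unphased:
            cohort = cohort.strip_phase()
        logger.info("read %d variants x %d samples (phased=%s)",
                    cohort.n_variants, cohort.n_samples, cohort.cohort_phased)

        hc = calling.filter_hc(
            cohort,
            transcript_policy=config.transcript_policy,
            keep_flagged=config.keep_flagged_hc,
        )
        logger.info("HC LoF filter retained %d variants in %d genes",
                    hc.calls.n_variants, len(hc.gene_variants))

        variant_matrix = calling.build_variant_matrix(hc)
        gene_matrix = calling.build_gene_matrix(hc)
        ch_events = calling.detect_ch_events(hc)
        labels = calling.classify_two_copy_mechanism(gene_matrix)
        logger.info("matrices built: %d CH events, %d knocked-out genes",
                    len(ch_events), len(labels))

        variant_matrix.to_table().to_csv(stage / "lof_variants.tsv", sep="\t")
        gene_matrix.to_table().to_csv(stage / "lof_genes.tsv", sep="\t")
        calling.allele_frequencies(variant_matrix).to_csv(
            stage / "lof_allele_frequencies.tsv", sep="\t"
        )
        with open(stage / "ch_events.tsv", "w") as fh:
            fh.write("sample_id\tgene_id\tvariant1\tvariant2\n")
            for e in ch_events:
                fh.write(f"{e.sample_id}\t{e.gene_id}\t"
                         f"{e.variant_pair[0]}\t{e.variant_pair[1]}\n")
        with open(stage / "gene_mechanisms.tsv", "w") as fh:
            fh.write("gene_id\tmechanism_class\n")
            for g, lab in sorted(labels.items()):
                fh.write(f"{g}\t{lab}\n")
        files.update({
            "variant_matrix": Path("lof_variants.tsv"),
            "gene_matrix": Path("lof_genes.tsv"),
            "allele_frequencies": Path("lof_allele_frequencies.tsv"),
            "ch_events": Path("ch_events.tsv"),
            "gene_mechanisms": Path("gene_mechanisms.tsv"),
        })

        summary = reporting.summarize(variant_matrix, gene_matrix, ch_events)
        reporting.write_info_report(
            summary, stage / "cohort.info",
            provenance={"input": vcf_path, "min_info": config.min_info,
                        "prob_cutoff": config.prob_cutoff,
                        "transcript_policy": config.transcript_policy},
        )
        files["info_report"] = Path("cohort.info")

        tx_summary = None
        if config.pedigree_path:
            trios = read_pedigree(config.pedigree_path)
            results, tx_summary = validate_ch_transmission(
                trios, ch_events, cohort
            )
            with open(stage / "transmission.tsv", "w") as fh:
                fh.write("sample_id\tgene_id\tvariant1\tvariant2\tverdict\t"
                         "missing_data\tde_novo\n")
                for r in results:
                    verdict = ("true_transmission" if r.true_transmission
                               else "false_transmission")
                    fh.write(
                        f"{r.event.sample_id}\t{r.event.gene_id}\t"
                        f"{r.event.variant_pair[0]}\t{r.event.variant_pair[1]}"
                        f"\t{verdict}\t{int(r.missing_data)}\t"
                        f"{int(r.de_novo)}\n"
                    )
            files["transmission"] = Path("transmission.tsv")

        mismatches = None
        if config.pairs_path:
            pairs = _read_pairs(config.pairs_path)
            mismatches = calling.mismatch_genes(gene_matrix, pairs)
            with open(stage / "mismatched_genes.tsv", "w") as fh:
                fh.write("sample_from\tsample_to\tgene_id\n")
                for (a, b), directions in mismatches.items():
                    for direction, genes in directions.items():
                        src, dst = direction.split("->")
                        for g in genes:
                            fh.write(f"{src}\t{dst}\t{g}\n")
            files["mismatched_genes"] = Path("mismatched_genes.tsv")

        with open(stage / "run_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=False)
        files["run_config"] = Path("run_config.yaml")

        for name, rel in files.items():
            shutil.move(str(stage / rel), str(out_dir / rel))
            files[name] = out_dir / rel
    finally:
        shutil.rmtree(stage, ignore_errors=True)

    return PipelineResult(
        output_dir=out_dir,
        summary=summary,
        variant_matrix=variant_matrix,
        gene_matrix=gene_matrix,
        ch_events=ch_events,
        mechanism_labels=labels,
        transmission_summary=tx_summary,
        mismatches=mismatches,
        files=files,
    )
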