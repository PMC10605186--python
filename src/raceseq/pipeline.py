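"""End-to-end per-sample orchestration and report rendering."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

from . import varcall
from .align import Aligner, align_sample, write_sam
from .dedup import DedupResult, collapse, write_templates
from .expression import ExpressionProfile, profile_sample
from .fusion import FusionCall, call_fusions
from .panel import PanelDesign
from .simulate import read_fastq_pair
from .varcall import CallThresholds, VariantCall, write_vcf


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SampleReport:
    sample_id: str
    qc: str
    total_templates: int
    variants: list[VariantCall]
    fusions: list[FusionCall]
    expression: ExpressionProfile
    counters: dict[str, int]
    thresholds: CallThresholds = field(default_factory=CallThresholds)


def run_pipeline(
    reads,
    panel: PanelDesign,
    sample_id: str = "sample",
    thresholds: Optional[CallThresholds] = None,
    out_dir: Optional[str] = None,
    aligner: Optional[Aligner] = None,
) -> SampleReport:
    """Run preprocess -> align -> dedup -> variants/fusions/expression.

    *reads* is either a list of read-pair tuples (as produced by the
    simulator) or a ``(fastq_r1, fastq_r2)`` path pair.  The pipeline is
    deterministic: no stage draws random numbers.  With *out_dir* the
    intermediate SAM/TSV/VCF artifacts are persisted.
    """
    from .align import ReadPair

    thresholds = thresholds or CallThresholds()
    if isinstance(reads, tuple) and len(reads) == 2 and isinstance(reads[0], str):
        reads = read_fastq_pair(*reads)
    if not reads:
        raise PipelineError("preprocess", "no input read pairs")
    pairs = [ReadPair(id=r[0], r1_seq=r[1], r1_qual=r[2], r2_seq=r[3], r2_qual=r[4])
             for r in reads]

    if aligner is None:
        aligner = Aligner(panel)
    alignments, counters = align_sample(pairs, panel, aligner=aligner)

    result: DedupResult = collapse(alignments, panel,
                                   improper_count=counters["improper"])
    counters["offtarget_discarded"] = result.discarded_offtarget
    counters["templates"] = result.total_templates
    counters["kept_reads"] = result.conserved_reads()

    columns, indel_events = varcall.pileup(result.templates, panel, aligner=aligner)
    calls = varcall.call_variants(columns, panel, thresholds, indel_events)
    fusions = call_fusions(result.templates, panel, aligner=aligner)
    expression = profile_sample(result.templates, panel, sample_id=sample_id)

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        write_sam(alignments, panel.transcriptome, os.path.join(out_dir, f"{sample_id}.sam"))
        write_templates(result, os.path.join(out_dir, f"{sample_id}.templates.tsv"))
        write_vcf(calls, panel, os.path.join(out_dir, f"{sample_id}.vcf"))

    return SampleReport(
        sample_id=sample_id,
        qc=expression.qc,
        total_templates=result.total_templates,
        variants=calls,
        fusions=fusions,
        expression=expression,
        counters=counters,
        thresholds=thresholds,
    )


def render_report(report: SampleReport) -> tuple[str, str]:
    """Render a report as (stable JSON, human-readable text)."""
    payload = {
        "sample": report.sample_id,
        "qc": {
            "verdict": report.qc,
            "total_templates": report.total_templates,
            "note": "results unreliable" if report.qc == "FAIL" else "",
        },
        "fusions": [
            {
                "name": f.name,
                "gene5": f.gene5,
                "exon5": f.exon5,
                "breakpoint": f.breakpoint,
                "gene3": f.gene3,
                "exon3": f.exon3,
                "supporting_templates": f.supporting_templates,
            }
            for f in report.fusions
        ],
        "variants": [
            {
                "transcript": v.transcript_id,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "depth": v.depth,
                "alt_templates": v.alt_templates,
                "vaf": round(v.vaf, 4),
                "hotspot": v.hotspot_label,
                "protein_change": v.protein_change,
                "filter": v.filter,
            }
            for v in report.variants
        ],
        "expression": {
            gene: (None if g.value is None else round(g.value, 4))
            for gene, g in report.expression.genes.items()
        },
        "counters": dict(sorted(report.counters.items())),
    }
    text_lines = [f"Sample {report.sample_id}"]
    passing_fusions = report.fusions
    passing_variants = [v for v in report.variants if v.filter == "PASS"]
    if not passing_fusions and not passing_variants:
        text_lines.append("  no alterations detected")
    for f in passing_fusions:
        text_lines.append(f"  fusion   {f.name}  templates={f.supporting_templates}")
    for v in passing_variants:
        label = v.protein_change or f"{v.transcript_id}:{v.position + 1}{v.ref}>{v.alt}"
        text_lines.append(f"  variant  {label}  VAF={v.vaf:.3f}  depth={v.depth}")
    for gene, g in report.expression.genes.items():
        val = "NA" if g.value is None else f"{g.value:.3f}"
        text_lines.append(f"  expr     {gene}  {val}")
    text_lines.append(
        f"  QC       {report.qc}  templates={report.total_templates}"
    )
    return json.dumps(payload, indent=2, sort_keys=True), "\n".join(text_lines)
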