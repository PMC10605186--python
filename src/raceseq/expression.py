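"""qPCR-like expression quantification against referee genes.

For each gene of interest the unique-template count of one selected
fragment is divided by the counts of the three referee fragments
(DDX23 exons 8-9, GOLGA5 exons 5-6, SEL1L exons 13-14); the reported
value is the median of the three ratios, which tolerates one referee
behaving badly in a given sample.  Sample-level QC fails when fewer
than 3000 unique templates remain after duplicate removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Optional

from .dedup import TemplateCluster, count_templates
from .panel import EXPRESSION_GENES, REFEREE_GENES, PanelDesign, fragment_for

QC_MIN_TEMPLATES = 3000
OVEREXPRESSION_FACTOR = 5.0  # value > factor x cohort median flags overexpression


@dataclass
class GeneExpression:
    gene: str
    target_count: int
    ratios: Optional[tuple[float, float, float]]
    value: Optional[float]  # median of the three referee-normalized ratios


@dataclass
class ExpressionProfile:
    sample_id: str
    genes: dict[str, GeneExpression]
    referee_counts: dict[str, int]
    total_templates: int
    qc: str  # PASS | FAIL
    evaluable: bool = True

    def value(self, gene: str) -> Optional[float]:
        g = self.genes.get(gene)
        return g.value if g else None


def qc_sample(total_templates: int, threshold: int = QC_MIN_TEMPLATES) -> str:
    """FAIL iff fewer than *threshold* templates survived deduplication."""
    if total_templates < 0:
        raise ValueError("total_templates must be >= 0")
    return "FAIL" if total_templates < threshold else "PASS"


def normalized_expression(
    target_count: int, referee_counts: dict[str, int]
) -> tuple[tuple[float, float, float], float]:
    """Median-of-three referee normalization for one target gene.

    Raises ``ValueError`` when any referee count is zero: the sample's
    normalization has failed and no expression value is reportable.
    """
    if sorted(referee_counts) != sorted(REFEREE_GENES):
        raise ValueError(f"expected referee counts for {REFEREE_GENES}")
    if any(referee_counts[r] <= 0 for r in REFEREE_GENES):
        raise ValueError("referee dropout: expression not evaluable")
    ratios = tuple(target_count / referee_counts[r] for r in REFEREE_GENES)
    return ratios, float(median(ratios))


def profile_sample(
    templates: list[TemplateCluster],
    panel: PanelDesign,
    sample_id: str = "sample",
    qc_threshold: int = QC_MIN_TEMPLATES,
) -> ExpressionProfile:
    """Expression profile over the panel's six genes of interest.

    QC failure does not suppress the values; they are computed and
    flagged so a borderline sample remains inspectable.
    """
    referee_counts = {
        gene: count_templates(templates, fragment_for(gene, panel))
        for gene in REFEREE_GENES
    }
    total = len(templates)
    evaluable = all(v > 0 for v in referee_counts.values())
    genes = {}
    for gene in EXPRESSION_GENES:
        count = count_templates(templates, fragment_for(gene, panel))
        if evaluable:
            ratios, value = normalized_expression(count, referee_counts)
        else:
            ratios, value = None, None
        genes[gene] = GeneExpression(gene, count, ratios, value)
    return ExpressionProfile(
        sample_id=sample_id,
        genes=genes,
        referee_counts=referee_counts,
        total_templates=total,
        qc=qc_sample(total, qc_threshold),
        evaluable=evaluable,
    )


def overexpression_flags(
    profiles: list[ExpressionProfile], factor: float = OVEREXPRESSION_FACTOR
) -> dict[str, list[str]]:
    """Flag samples whose value exceeds *factor* x the cohort median per gene.

    A surrogate for gene amplification; the factor is a reporting
    convention, not a validated clinical cutoff.
    """
    flags: dict[str, list[str]] = {}
    for gene in EXPRESSION_GENES:
        values = [(p.sample_id, p.value(gene)) for p in profiles]
        present = sorted(v for _, v in values if v is not None)
        if not present:
            continue
        cohort_median = present[len(present) // 2] if len(present) % 2 else (
            (present[len(present) // 2 - 1] + present[len(present) // 2]) / 2
        )
        flags[gene] = [
            sid for sid, v in values
            if v is not None and cohort_median > 0 and v > factor * cohort_median
        ]
    return flags


def write_expression_matrix(profiles: list[ExpressionProfile], path: str) -> None:
    import pandas as pd

    rows = []
    for p in profiles:
        row = {"sample": p.sample_id, "total_templates": p.total_templates, "qc": p.qc}
        for gene in EXPRESSION_GENES:
            row[gene] = p.value(gene)
        for gene in REFEREE_GENES:
            row[f"{gene}_templates"] = p.referee_counts.get(gene)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
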