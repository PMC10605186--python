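"""Split-read detection of fusions with unknown 3' partners.

The 3' RACE chemistry reads from a gene-specific primer toward the
transcript 3' end, so a chimeric transcript whose 5' part is a panel
FGFR gene shows up as a template that aligns to the anchor gene up to a
conserved breakpoint (FGFR2: after exon 17, or the start of exon 18)
and then continues as a soft-clipped tail belonging to the partner.
Tails are re-aligned to the full bundled transcriptome; partners absent
from the annotation are reported as UNKNOWN -- capturing a partner no
assay was designed for is the point of the chemistry.

By construction only 3'-unknown-partner fusions are detectable; events
whose unknown partner is 5' of the kinase gene are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .align import Aligner, diagonal_align, seed_and_extend
from .dedup import TemplateCluster
from .panel import PanelDesign

MIN_TAIL = 25
BOUNDARY_SLOP = 5
MIN_SUPPORT = 5
MIN_DISTINCT_UMIS = 2


@dataclass
class ChimericCandidate:
    template: TemplateCluster
    anchor_gene: str
    anchor_exon: int
    anchor_transcript: str
    anchor_end: int  # transcript coordinate where the anchor alignment ends
    tail_seq: str
    partner_transcript: Optional[str] = None
    partner_start: Optional[int] = None


@dataclass
class FusionCall:
    gene5: str
    exon5: int
    breakpoint: int
    gene3: str  # symbol or "UNKNOWN"
    exon3: Optional[int]
    supporting_templates: int
    distinct_umis: int
    name: str
    tail_example: str = ""


def name_fusion(gene5: str, exon5: int, gene3: str, exon3: Optional[int]) -> str:
    """Render a fusion name like ``FGFR2-BICC1 (F17;B3)``.

    The short form uses the first letter of each gene symbol; unknown
    partners render as ``GENE5-UNKNOWN (X{exon5};?)``.
    """
    if gene3 == "UNKNOWN" or exon3 is None:
        suffix = "?" if gene3 == "UNKNOWN" else f"{gene3[0]}?"
        if gene3 == "UNKNOWN":
            return f"{gene5}-UNKNOWN ({gene5[0]}{exon5};?)"
        return f"{gene5}-{gene3} ({gene5[0]}{exon5};{gene3[0]}?)"
    return f"{gene5}-{gene3} ({gene5[0]}{exon5};{gene3[0]}{exon3})"


def find_candidates(
    templates: list[TemplateCluster],
    panel: PanelDesign,
    aligner: Optional[Aligner] = None,
    min_tail: int = MIN_TAIL,
    boundary_slop: int = BOUNDARY_SLOP,
) -> list[ChimericCandidate]:
    """Screen consensus templates for anchored chimeric alignments.

    A template is a candidate iff its alignment to an anchor gene ends
    within ``boundary_slop`` of a declared anchor boundary and carries a
    3' soft clip of at least ``min_tail`` nt.  Tails are re-aligned to
    the whole bundled transcriptome; unalignable tails are retained with
    an unknown partner.
    """
    if aligner is None:
        aligner = Aligner(panel)
    tr = panel.transcriptome
    anchors_by_tid: dict[str, list] = {}
    for a in panel.fusion_anchors:
        anchors_by_tid.setdefault(a.transcript_id, []).append(a)
    out = []
    for t in templates:
        if t.transcript_id not in anchors_by_tid:
            continue
        ref = tr.records[t.transcript_id]
        end = t.start + len(t.consensus_seq)
        # fast path: template fully matches the reference, no clip possible
        if 0 <= t.start and end <= len(ref) and ref[t.start:end] == t.consensus_seq:
            continue
        rec = diagonal_align(t.consensus_seq, ref, t.start, t.transcript_id)
        if rec is None:
            recs = seed_and_extend(t.consensus_seq, tr, aligner.index)
            recs = [r for r in recs if r.transcript_id == t.transcript_id]
            rec = recs[0] if recs else None
        if rec is None:
            continue
        if rec.clip3 < min_tail:
            continue
        anchor_end = rec.ref_end
        match = None
        for a in sorted(anchors_by_tid[t.transcript_id],
                        key=lambda a: (abs(a.boundary - anchor_end), a.exon_number)):
            if abs(a.boundary - anchor_end) <= boundary_slop:
                match = a
                break
        if match is None:
            continue
        tail = t.consensus_seq[len(t.consensus_seq) - rec.clip3 :]
        cand = ChimericCandidate(
            template=t,
            anchor_gene=match.gene,
            anchor_exon=match.exon_number,
            anchor_transcript=t.transcript_id,
            anchor_end=anchor_end,
            tail_seq=tail,
        )
        tail_recs = seed_and_extend(tail, tr, aligner.index)
        tail_recs = [r for r in tail_recs if r.transcript_id != t.transcript_id]
        if tail_recs:
            best = tail_recs[0]
            cand.partner_transcript = best.transcript_id
            cand.partner_start = best.start - best.clip5
        out.append(cand)
    return out


def cluster_calls(
    candidates: list[ChimericCandidate],
    panel: PanelDesign,
    min_support: int = MIN_SUPPORT,
    min_distinct_umis: int = MIN_DISTINCT_UMIS,
) -> list[FusionCall]:
    """Group concordant candidates into named fusion calls.

    Grouping is on (anchor gene, breakpoint, partner gene, partner
    exon); a call needs ``min_support`` unique templates carrying at
    least ``min_distinct_umis`` distinct pseudo-UMIs, which guards
    against a clonal artifact masquerading as recurrent evidence.
    """
    tr = panel.transcriptome
    groups: dict[tuple, list[ChimericCandidate]] = {}
    for c in candidates:
        if c.partner_transcript is not None:
            gene3 = tr.gene.get(c.partner_transcript, "UNKNOWN")
            exon3 = tr.exon_containing(c.partner_transcript, c.partner_start or 0)
        else:
            gene3, exon3 = "UNKNOWN", None
        key = (c.anchor_gene, c.anchor_exon, c.anchor_end, gene3, exon3)
        groups.setdefault(key, []).append(c)
    calls = []
    for (gene5, exon5, breakpoint, gene3, exon3), members in groups.items():
        umis = {m.template.umi_consensus for m in members}
        if len(members) < min_support or len(umis) < min_distinct_umis:
            continue
        calls.append(FusionCall(
            gene5=gene5,
            exon5=exon5,
            breakpoint=breakpoint,
            gene3=gene3,
            exon3=exon3,
            supporting_templates=len(members),
            distinct_umis=len(umis),
            name=name_fusion(gene5, exon5, gene3, exon3),
            tail_example=max((m.tail_seq for m in members), key=len),
        ))
    calls.sort(key=lambda c: (-c.supporting_templates, c.name))
    return calls


def call_fusions(
    templates: list[TemplateCluster],
    panel: PanelDesign,
    aligner: Optional[Aligner] = None,
    min_support: int = MIN_SUPPORT,
) -> list[FusionCall]:
    candidates = find_candidates(templates, panel, aligner=aligner)
    return cluster_calls(candidates, panel, min_support=min_support)
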