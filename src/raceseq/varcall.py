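"""Tumor-only variant calling on deduplicated templates.

Calling is template-level: each unique molecule contributes one vote per
covered position, so PCR duplicates cannot inflate support.  Tumor-only
RNA calling has no matched normal; specificity comes from template-count
and VAF floors, with a lower VAF floor at annotated hotspots where the
prior for a real activating event is high (in RNA the mutant allele of
an activating oncogene is often over-represented relative to its DNA
fraction, which is what makes a low floor safe and useful).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import pysam
from Bio.Seq import Seq

from .align import Aligner, AlignmentRecord, diagonal_align, seed_and_extend
from .dedup import TemplateCluster
from .panel import PanelDesign

MAX_INDEL_LEN = 10


@dataclass
class CallThresholds:
    min_depth: int = 50
    min_alt_templates: int = 3
    min_vaf_hotspot: float = 0.02
    min_vaf_other: float = 0.05
    min_mean_qual: float = 20.0


@dataclass
class PileupColumn:
    transcript_id: str
    position: int
    depth: int
    base_counts: dict[str, int]
    qual_sums: dict[str, float]

    def mean_qual(self, allele: str) -> float:
        n = self.base_counts.get(allele, 0)
        return self.qual_sums.get(allele, 0.0) / n if n else 0.0


@dataclass
class IndelEvent:
    transcript_id: str
    position: int  # anchor: base before the event (VCF-style)
    ref: str
    alt: str
    templates: int = 0
    qual_sum: float = 0.0


@dataclass
class VariantCall:
    transcript_id: str
    position: int
    ref: str
    alt: str
    alt_templates: int
    depth: int
    vaf: float
    hotspot_label: Optional[str] = None
    protein_change: Optional[str] = None
    filter: str = "PASS"


def _template_alignment(
    t: TemplateCluster, panel: PanelDesign, aligner: Optional[Aligner]
) -> Optional[AlignmentRecord]:
    ref = panel.transcriptome.records.get(t.transcript_id, "")
    end = t.start + len(t.consensus_seq)
    if 0 <= t.start and end <= len(ref):
        seg = ref[t.start:end]
        if seg == t.consensus_seq:
            return AlignmentRecord("", 1, t.transcript_id, t.start,
                                   [("M", len(t.consensus_seq))], 0, len(t.consensus_seq))
        # The chemistry anchors the R1 end at the enrichment primer, so a
        # template with a handful of substitutions is aligned end-to-end
        # (semi-global): a purely local alignment would clip true variant
        # bases sitting within a couple of nt of the insert edges.
        mism = sum(1 for a, b in zip(seg, t.consensus_seq) if a != b)
        if mism <= 5:
            return AlignmentRecord("", 1, t.transcript_id, t.start,
                                   [("M", len(t.consensus_seq))], mism,
                                   len(t.consensus_seq) - 3 * mism)
    rec = diagonal_align(t.consensus_seq, ref, t.start, t.transcript_id)
    if rec is not None and rec.clip5 <= 12 and rec.clip3 <= 12:
        return rec
    # a long clip on the fixed diagonal usually means an indel (or a
    # chimeric tail): let the gapped aligner resolve it
    if aligner is None:
        return rec
    recs = seed_and_extend(t.consensus_seq, panel.transcriptome, aligner.index)
    if recs:
        return recs[0]
    return rec


def _target_mask(panel: PanelDesign) -> dict[str, list[tuple[int, int]]]:
    mask: dict[str, list[tuple[int, int]]] = {}
    for f in panel.fragments:
        mask.setdefault(f.transcript_id, []).append((f.start, f.end))
    for e in panel.hotspots.entries:
        mask.setdefault(e.transcript_id, []).append((e.start, e.end))
    return mask


def _in_mask(mask, tid, pos) -> bool:
    return any(s <= pos < e for s, e in mask.get(tid, ()))


def pileup(
    templates: list[TemplateCluster],
    panel: PanelDesign,
    aligner: Optional[Aligner] = None,
) -> tuple[list[PileupColumn], list[IndelEvent]]:
    """Template-level pileup over panel fragments and hotspot regions.

    Substitution evidence accumulates per column; insertions and
    deletions (<= 10 nt) are collected as left-anchored events with their
    own template counts.  Columns are emitted in (transcript, position)
    order; zero-coverage positions are absent.

    Depth and quality run through per-transcript accumulator arrays;
    only non-reference bases are tracked individually, and reference
    counts are recovered as depth minus alternates.
    """
    mask = _target_mask(panel)
    tr = panel.transcriptome
    depth_arr: dict[str, "object"] = {}
    qsum_arr: dict[str, "object"] = {}
    import numpy as np

    for tid in tr.records:
        depth_arr[tid] = np.zeros(len(tr.records[tid]), dtype=np.int32)
        qsum_arr[tid] = np.zeros(len(tr.records[tid]), dtype=np.float64)
    alts: dict[tuple[str, int, str], list[float]] = {}  # (tid,pos,base) -> [count,qual]
    indels: dict[tuple[str, int, str, str], IndelEvent] = {}
    for t in templates:
        rec = _template_alignment(t, panel, aligner)
        if rec is None:
            continue
        tid = rec.transcript_id
        ref = panel.transcriptome.records[tid]
        qi, ri = 0, rec.start
        for op, n in rec.cigar:
            if op == "S":
                qi += n
            elif op == "M":
                seg = t.consensus_seq[qi : qi + n]
                quals = np.frombuffer(
                    t.consensus_qual[qi : qi + n].encode(), dtype=np.uint8
                ).astype(np.float64) - 33
                depth_arr[tid][ri : ri + n] += 1
                qsum_arr[tid][ri : ri + n] += quals
                if seg != ref[ri : ri + n]:
                    q = np.frombuffer(seg.encode(), dtype=np.uint8)
                    r = np.frombuffer(ref[ri : ri + n].encode(), dtype=np.uint8)
                    for k in np.flatnonzero(q != r):
                        k = int(k)
                        cell = alts.setdefault((tid, ri + k, seg[k]), [0, 0.0])
                        cell[0] += 1
                        cell[1] += quals[k]
                qi += n
                ri += n
            elif op == "I":
                if n <= MAX_INDEL_LEN and ri > 0 and _in_mask(mask, tid, ri - 1):
                    anchor = ri - 1
                    r = ref[anchor]
                    alt = r + t.consensus_seq[qi : qi + n]
                    key = (tid, anchor, r, alt)
                    ev = indels.setdefault(key, IndelEvent(tid, anchor, r, alt))
                    ev.templates += 1
                    ev.qual_sum += ord(t.consensus_qual[qi]) - 33 if qi < len(t.consensus_qual) else 0
                qi += n
            elif op == "D":
                if n <= MAX_INDEL_LEN and ri > 0 and _in_mask(mask, tid, ri - 1):
                    anchor = ri - 1
                    r = ref[anchor : ri + n]
                    key = (tid, anchor, r, r[0])
                    ev = indels.setdefault(key, IndelEvent(tid, anchor, r, r[0]))
                    ev.templates += 1
                    ev.qual_sum += ord(t.consensus_qual[qi - 1]) - 33 if 0 < qi <= len(t.consensus_qual) else 0
                ri += n
    # materialize columns for covered positions inside panel targets
    columns: dict[tuple[str, int], PileupColumn] = {}
    for tid, intervals in mask.items():
        depth = depth_arr.get(tid)
        if depth is None:
            continue
        ref = tr.records[tid]
        seen: set[int] = set()
        for s, e in intervals:
            for pos in range(max(0, s), min(len(ref), e)):
                if pos in seen or depth[pos] == 0:
                    continue
                seen.add(pos)
                col = PileupColumn(tid, pos, int(depth[pos]), {}, {})
                alt_n = 0
                alt_q = 0.0
                for base in "ACGTN":
                    cell = alts.get((tid, pos, base))
                    if cell:
                        col.base_counts[base] = int(cell[0])
                        col.qual_sums[base] = cell[1]
                        alt_n += int(cell[0])
                        alt_q += cell[1]
                ref_n = int(depth[pos]) - alt_n
                if ref_n > 0:
                    col.base_counts[ref[pos]] = ref_n
                    col.qual_sums[ref[pos]] = float(qsum_arr[tid][pos]) - alt_q
                columns[(tid, pos)] = col
    cols = [columns[k] for k in sorted(columns)]
    events = [indels[k] for k in sorted(indels)]
    return cols, events


def call_variants(
    columns: list[PileupColumn],
    panel: PanelDesign,
    thresholds: CallThresholds = CallThresholds(),
    indel_events: Optional[list[IndelEvent]] = None,
) -> list[VariantCall]:
    """Emit template-supported variant calls from a pileup.

    A candidate needs ``min_depth`` covering templates and
    ``min_alt_templates`` supporting templates; it is then PASS if the
    allele mean quality reaches ``min_mean_qual`` and the VAF reaches
    the hotspot or non-hotspot floor.
    """
    tr = panel.transcriptome
    calls: list[VariantCall] = []
    depth_at: dict[tuple[str, int], int] = {
        (c.transcript_id, c.position): c.depth for c in columns
    }
    for col in columns:
        if col.depth < thresholds.min_depth:
            continue
        ref_base = tr.records[col.transcript_id][col.position]
        for base, count in sorted(col.base_counts.items()):
            if base == ref_base or base == "N" or count < thresholds.min_alt_templates:
                continue
            vaf = count / col.depth
            entry = panel.hotspots.lookup(col.transcript_id, col.position)
            floor = thresholds.min_vaf_hotspot if entry else thresholds.min_vaf_other
            if col.mean_qual(base) < thresholds.min_mean_qual:
                status = "low_qual"
            elif vaf < floor:
                status = "low_vaf"
            else:
                status = "PASS"
            call = VariantCall(
                transcript_id=col.transcript_id,
                position=col.position,
                ref=ref_base,
                alt=base,
                alt_templates=count,
                depth=col.depth,
                vaf=vaf,
                hotspot_label=entry.label if entry else None,
                filter=status,
            )
            calls.append(annotate_protein(call, panel))
    for ev in indel_events or []:
        depth = depth_at.get((ev.transcript_id, ev.position), 0)
        if depth < thresholds.min_depth or ev.templates < thresholds.min_alt_templates:
            continue
        vaf = ev.templates / depth
        entry = panel.hotspots.lookup(ev.transcript_id, ev.position)
        floor = thresholds.min_vaf_hotspot if entry else thresholds.min_vaf_other
        mean_q = ev.qual_sum / ev.templates
        status = ("low_qual" if mean_q < thresholds.min_mean_qual
                  else "low_vaf" if vaf < floor else "PASS")
        calls.append(VariantCall(
            transcript_id=ev.transcript_id, position=ev.position,
            ref=ev.ref, alt=ev.alt, alt_templates=ev.templates, depth=depth,
            vaf=vaf, hotspot_label=entry.label if entry else None, filter=status,
        ))
    calls.sort(key=lambda c: (c.transcript_id, c.position, c.alt))
    return calls


def annotate_protein(call: VariantCall, panel: PanelDesign) -> VariantCall:
    """Attach an HGVS-style protein label to hotspot substitutions.

    Works from the transcript CDS frame recorded in the panel; only
    single-base substitutions within a hotspot entry are annotated, and
    synonymous changes get no label.
    """
    if len(call.ref) != 1 or len(call.alt) != 1:
        return call
    entry = panel.hotspots.lookup(call.transcript_id, call.position)
    if entry is None:
        return call
    cds = panel.hotspots.cds_start.get(call.transcript_id)
    if cds is None or call.position < cds:
        return call
    codon_index = (call.position - cds) // 3
    codon_start = cds + 3 * codon_index
    seq = panel.transcriptome.records[call.transcript_id]
    ref_codon = seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        return call
    offset = call.position - codon_start
    alt_codon = ref_codon[:offset] + call.alt + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return call
    label = f"{entry.gene} p.{ref_aa}{codon_index + 1}{alt_aa}"
    return replace(call, protein_change=label)


def passing(calls: list[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.filter == "PASS"]


# ---------------------------------------------------------------------------
# VCF emission

_VCF_INFO = [
    ("DP", 1, "Integer", "Unique-template depth"),
    ("AD", 1, "Integer", "Alternate-allele template count"),
    ("VAF", 1, "Float", "Variant allele fraction (templates)"),
    ("HOTSPOT", 1, "String", "Hotspot annotation"),
    ("PCHANGE", 1, "String", "Protein-level change"),
]


def write_vcf(calls: list[VariantCall], panel: PanelDesign, path: str) -> None:
    """Write calls as VCF 4.2 with transcript ids as contigs (1-based POS)."""
    header = pysam.VariantHeader()
    for tid in sorted(panel.transcriptome.records):
        header.contigs.add(tid, length=len(panel.transcriptome.records[tid]))
    for name, number, vtype, desc in _VCF_INFO:
        header.info.add(name, number, vtype, desc)
    header.filters.add("low_vaf", None, None, "VAF below floor")
    header.filters.add("low_qual", None, None, "Allele mean quality below floor")
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.transcript_id, c.position, c.alt)):
            rec = out.new_record(
                contig=c.transcript_id,
                start=c.position,
                stop=c.position + len(c.ref),
                alleles=(c.ref, c.alt),
                filter=c.filter if c.filter != "PASS" else "PASS",
            )
            rec.info["DP"] = c.depth
            rec.info["AD"] = c.alt_templates
            rec.info["VAF"] = round(c.vaf, 4)
            if c.hotspot_label:
                rec.info["HOTSPOT"] = c.hotspot_label.replace(" ", "_")
            if c.protein_change:
                rec.info["PCHANGE"] = c.protein_change.replace(" ", "_")
            out.write(rec)


def read_vcf(path: str) -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            filt = list(rec.filter.keys())
            calls.append(VariantCall(
                transcript_id=rec.contig,
                position=rec.start,
                ref=rec.ref,
                alt=rec.alts[0],
                alt_templates=int(rec.info["AD"]),
                depth=int(rec.info["DP"]),
                vaf=float(rec.info["VAF"]),
                hotspot_label=str(rec.info["HOTSPOT"]).replace("_", " ")
                if "HOTSPOT" in rec.info else None,
                protein_change=str(rec.info["PCHANGE"]).replace("_", " ")
                if "PCHANGE" in rec.info else None,
                filter=filt[0] if filt else "PASS",
            ))
    return calls
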