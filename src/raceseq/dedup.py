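"""PCR-duplicate collapsing with single-coordinate keys and pseudo-UMIs.

Anchored PCR fixes the R1 end of every molecule at its enrichment
primer, so only one coordinate per pair carries molecular information:
the RT-priming site where the random decamer annealed (the R2 start).
Pairs are grouped on the key ``(primer, transcript, rt_coordinate)`` and
then sub-clustered on the observed decamer: mismatches between the
random RT primer and the true mRNA sequence act as a weak molecular
barcode (a pseudo-UMI) that separates different templates sharing the
same coordinates.

The UMI clustering is the directional adjacency heuristic: an edge
u -> v exists when Hamming(u, v) == 1 and count(u) >= 2*count(v) - 1;
clusters are grown from unvisited highest-count nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .align import PairAlignment
from .panel import PanelDesign
from .simulate import DECAMER_LEN

UMI_LEN = DECAMER_LEN


@dataclass
class TemplateCluster:
    """One deduplicated molecule."""

    primer: str
    transcript_id: str
    rt_coord: int
    umi_consensus: str
    read_count: int
    member_ids: list[str]
    consensus_seq: str  # R1-derived insert consensus (primer and decamer trimmed)
    consensus_qual: str  # per-column quality of the consensus base (phred+33)
    start: int  # transcript coordinate of consensus_seq[0]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.primer, self.transcript_id, self.rt_coord)


@dataclass
class DedupResult:
    templates: list[TemplateCluster]
    total_templates: int
    discarded_offtarget: int
    discarded_improper: int

    def conserved_reads(self) -> int:
        return sum(t.read_count for t in self.templates)


def _hamming1(a: str, b: str) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return False
    return mm == 1


def cluster_umis_directional(umi_counts: dict[str, int]) -> list[list[str]]:
    """Cluster UMIs by the directional adjacency rule.

    Nodes are processed in descending count (ties lexicographic); from
    each unvisited node the cluster grows along edges u -> v where
    Hamming(u, v) == 1 and count(u) >= 2*count(v) - 1.  Each cluster's
    first element is its seed (the consensus UMI).
    """
    for u in umi_counts:
        if len(u) != UMI_LEN:
            raise ValueError(f"UMI {u!r} is not {UMI_LEN} nt")
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    visited: set[str] = set()
    clusters: list[list[str]] = []
    for seed in order:
        if seed in visited:
            continue
        cluster = [seed]
        visited.add(seed)
        frontier = [seed]
        while frontier:
            u = frontier.pop()
            for v in order:
                if v in visited:
                    continue
                if _hamming1(u, v) and umi_counts[u] >= 2 * umi_counts[v] - 1:
                    visited.add(v)
                    cluster.append(v)
                    frontier.append(v)
        clusters.append(cluster)
    return clusters


def _target_intervals(panel: PanelDesign) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for frag in panel.fragments:
        intervals.setdefault(frag.transcript_id, []).append((frag.start, frag.end))
    for entry in panel.hotspots.entries:
        intervals.setdefault(entry.transcript_id, []).append((entry.start, entry.end))
    return intervals


def _overlaps_panel(pa: PairAlignment, intervals: dict[str, list[tuple[int, int]]]) -> bool:
    """Whether either mate's aligned span touches a panel fragment or hotspot."""
    for rec in (pa.rec1, pa.rec2):
        if rec is None:
            continue
        for start, end in intervals.get(rec.transcript_id, ()):
            if rec.start < end and rec.ref_end > start:
                return True
    return False


def group_by_coordinate(
    alignments: Iterable[PairAlignment], panel: PanelDesign
) -> tuple[dict[tuple[str, str, int], list[PairAlignment]], int]:
    """Group proper pairs on (primer, R2 transcript, RT coordinate).

    Pairs lying outside all panel fragments and hotspot regions are
    discarded; the discard count is returned alongside the groups.
    """
    groups: dict[tuple[str, str, int], list[PairAlignment]] = {}
    discarded = 0
    intervals = _target_intervals(panel)
    for pa in alignments:
        if not pa.proper or pa.rec2 is None:
            continue
        if not _overlaps_panel(pa, intervals):
            discarded += 1
            continue
        key = (pa.pair.assigned_primer, pa.rec2.transcript_id, pa.rt_coord)
        groups.setdefault(key, []).append(pa)
    return groups, discarded


def _consensus(members: list[PairAlignment], ref: str) -> tuple[str, str, int, str]:
    """Majority-vote consensus of the R1 inserts of a cluster.

    Ties go to the higher summed base quality, then to the reference
    base.  Returns (sequence, per-column quality, alignment start,
    transcript id); the quality of a consensus column is the mean
    quality of the member reads voting for the chosen base.
    """
    best = members[0]
    start = best.rec1.start - best.rec1.clip5 if best.rec1 else 0
    tid = best.rec1.transcript_id if best.rec1 else ""
    seqs = [m.pair.r1_insert for m in members]
    if len(set(seqs)) == 1:
        return seqs[0], members[0].pair.r1_insert_qual, start, tid
    length = max(len(s) for s in seqs)
    cols = []
    quals = []
    for i in range(length):
        votes: dict[str, tuple[int, int]] = {}
        for m in members:
            s = m.pair.r1_insert
            if i < len(s):
                q = ord(m.pair.r1_insert_qual[i]) - 33 if i < len(m.pair.r1_insert_qual) else 0
                n, qs = votes.get(s[i], (0, 0))
                votes[s[i]] = (n + 1, qs + q)
        ref_base = ref[start + i] if 0 <= start + i < len(ref) else "N"
        base = min(votes, key=lambda b: (-votes[b][0], -votes[b][1], b != ref_base, b))
        cols.append(base)
        n, qs = votes[base]
        quals.append(chr(min(93, round(qs / n)) + 33))
    return "".join(cols), "".join(quals), start, tid


def collapse(
    alignments: Iterable[PairAlignment],
    panel: PanelDesign,
    improper_count: int = 0,
) -> DedupResult:
    """Collapse aligned pairs into unique templates.

    Processing is canonicalized by sorting groups and members, so the
    result is invariant to input order.
    """
    groups, discarded = group_by_coordinate(alignments, panel)
    templates: list[TemplateCluster] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda pa: pa.pair.id)
        umi_members: dict[str, list[PairAlignment]] = {}
        for pa in members:
            umi = (pa.pair.umi_obs or "N" * UMI_LEN)[:UMI_LEN]
            umi_members.setdefault(umi, []).append(pa)
        counts = {u: len(v) for u, v in umi_members.items()}
        for cluster in cluster_umis_directional(counts):
            cluster_members: list[PairAlignment] = []
            for u in cluster:
                cluster_members.extend(umi_members[u])
            cluster_members.sort(key=lambda pa: pa.pair.id)
            ref_tid = (cluster_members[0].rec1.transcript_id
                       if cluster_members[0].rec1 else key[1])
            ref = panel.transcriptome.records.get(ref_tid, "")
            seq, qual, start, tid = _consensus(cluster_members, ref)
            # The written decamer starts at the RT coordinate; when the
            # adapter was not visible on R1 (insert close to the read
            # length) the decamer bases survive trimming, so the
            # consensus is cut at the RT site -- those bases are
            # RT-primer-derived, not template evidence.
            if key[1] == tid:
                max_len = max(0, key[2] - start)
                seq, qual = seq[:max_len], qual[:max_len]
            templates.append(TemplateCluster(
                primer=key[0],
                transcript_id=tid or key[1],
                rt_coord=key[2],
                umi_consensus=cluster[0],
                read_count=len(cluster_members),
                member_ids=[pa.pair.id for pa in cluster_members],
                consensus_seq=seq,
                consensus_qual=qual,
                start=start,
            ))
    return DedupResult(
        templates=templates,
        total_templates=len(templates),
        discarded_offtarget=discarded,
        discarded_improper=improper_count,
    )


def count_templates(templates: list[TemplateCluster], fragment) -> int:
    """Unique templates whose consensus insert overlaps *fragment* by >= 1 nt."""
    n = 0
    for t in templates:
        if t.transcript_id != fragment.transcript_id:
            continue
        end = t.start + len(t.consensus_seq)
        if t.start < fragment.end and end > fragment.start:
            n += 1
    return n


def write_templates(result: DedupResult, path: str) -> None:
    rows = [
        (t.primer, t.transcript_id, t.rt_coord, t.umi_consensus, t.read_count,
         t.start, t.consensus_seq, ",".join(t.member_ids))
        for t in result.templates
    ]
    df = pd.DataFrame(rows, columns=[
        "primer", "transcript", "rt_coord", "umi", "read_count",
        "start", "consensus", "members",
    ])
    df.to_csv(path, sep="\t", index=False)
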