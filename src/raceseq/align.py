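"""Read preprocessing and transcriptome alignment.

The library chemistry fixes both read ends: R1 must begin with one of the
panel's enrichment primers and R2 begins with the 10-nt decamer written
by the random RT primer.  Preprocessing identifies the primer (the
anchored end), extracts the observed decamer as the pseudo-UMI, and trims
primer, decamer and adapter read-through.  The trimmed inserts are then
aligned to the panel transcriptome with a seed-and-extend local aligner
(exact k-mer seeds, affine-gap Smith-Waterman extension, soft clips for
unaligned termini) -- chimeric (fusion) reads surface as anchored
alignments with long 3' soft clips.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pysam

from .panel import PanelDesign, PrimerRecord, Transcriptome
from .simulate import DECAMER_LEN, R1_ADAPTER, R2_ADAPTER, revcomp

DEFAULT_K = 15
SEED_STRIDE = 5
MATCH = 1
MISMATCH = -2
GAP_OPEN = -4  # applied to the first base of a gap
GAP_EXTEND = -1
MIN_SCORE = 20
MAX_CANDIDATES = 8
PRIMER_START_SLOP = 2  # allowed deviation of R1 start from the primer 3' end


@dataclass
class ReadPair:
    id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    assigned_primer: Optional[str] = None
    umi_obs: Optional[str] = None
    r1_insert: str = ""
    r1_insert_qual: str = ""
    r2_insert: str = ""
    r2_insert_qual: str = ""
    r1_adapter_found: bool = False
    r2_adapter_found: bool = False
    unassigned_reason: Optional[str] = None


@dataclass
class AlignmentRecord:
    read_id: str
    mate: int  # 1 or 2
    transcript_id: str
    start: int  # 0-based
    cigar: list[tuple[str, int]]  # ops S, M, I, D; consume exactly the read
    nm: int
    score: int
    reverse: bool = False

    @property
    def clip5(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def clip3(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def query_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "SMI")

    @property
    def ref_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.start + self.ref_len


@dataclass
class PairAlignment:
    pair: ReadPair
    rec1: Optional[AlignmentRecord]
    rec2: Optional[AlignmentRecord]
    proper: bool
    reason: Optional[str] = None

    @property
    def rt_coord(self) -> Optional[int]:
        """Inferred RT-priming coordinate: the sense-strand end of R2.

        Soft-clipped 3' bases of the (reverse-complemented) R2 are
        extrapolated so sequencing errors at the decamer edge do not
        shift the deduplication coordinate.
        """
        if self.rec2 is None:
            return None
        return self.rec2.ref_end + self.rec2.clip3


# ---------------------------------------------------------------------------
# preprocessing


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_adapter(seq: str, adapter: str, min_probe: int = 10, max_mm: int = 1) -> int:
    """Position where adapter read-through begins, or -1.

    An exact 10-mer probe is tried first; a mismatch-tolerant fallback
    uses a longer 14-mer probe so that chance matches in template
    sequence stay negligible; finally short exact adapter prefixes
    hanging off the read end are trimmed.
    """
    probe = adapter[:min_probe]
    hit = seq.find(probe)
    if hit >= 0:
        return hit
    long_probe = adapter[: min(len(adapter), 14)]
    if len(seq) >= len(long_probe):
        # mismatch-tolerant scan, vectorized over all windows
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        parr = np.frombuffer(long_probe.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(long_probe))
        mm = (windows != parr).sum(axis=1)
        hits = np.flatnonzero(mm <= max_mm)
        if len(hits):
            return int(hits[0])
    # partial adapter at the very end of the read (exact only, >= 6 nt)
    for n in range(min_probe - 1, 5, -1):
        if seq.endswith(adapter[:n]):
            return len(seq) - n
    return -1


class PrimerMatcher:
    """Assigns R1 prefixes to panel primers (exact dict, Hamming fallback)."""

    def __init__(self, panel: PanelDesign, max_mm: int = 2):
        self.max_mm = max_mm
        self.by_len: dict[int, dict[str, PrimerRecord]] = {}
        for p in panel.primers:
            self.by_len.setdefault(len(p.sequence), {})[p.sequence] = p
        self.primers = list(panel.primers)

    def match(self, r1: str) -> Optional[PrimerRecord]:
        for ln, table in self.by_len.items():
            hit = table.get(r1[:ln])
            if hit is not None:
                return hit
        best: Optional[PrimerRecord] = None
        best_mm = self.max_mm + 1
        tie = False
        for p in self.primers:
            mm = _hamming(r1[: len(p.sequence)], p.sequence)
            if mm < best_mm:
                best, best_mm, tie = p, mm, False
            elif mm == best_mm:
                tie = True
        if best is None or best_mm > self.max_mm or tie:
            return None
        return best


def assign_primer_and_umi(
    pair: ReadPair, panel: PanelDesign, max_mm: int = 2,
    matcher: Optional[PrimerMatcher] = None,
) -> ReadPair:
    """Identify the enrichment primer on R1 and the decamer UMI on R2.

    Primer bases (R1) and decamer bases (R2) are trimmed from the inserts
    but retained as metadata; adapter read-through is trimmed from both
    mates.  When the R1 adapter is visible the insert's final 10 bases
    are the written decamer and are trimmed as well: they are
    primer-derived, not template evidence.
    """
    if matcher is None:
        matcher = PrimerMatcher(panel, max_mm=max_mm)
    primer = matcher.match(pair.r1_seq)
    if primer is None:
        return replace(pair, unassigned_reason="no-primer-match")
    r1 = pair.r1_seq[len(primer.sequence):]
    q1 = pair.r1_qual[len(primer.sequence):]
    r1_adapter = _find_adapter(r1, R1_ADAPTER)
    if r1_adapter >= 0:
        r1, q1 = r1[:r1_adapter], q1[:r1_adapter]
        if len(r1) >= DECAMER_LEN:
            r1, q1 = r1[:-DECAMER_LEN], q1[:-DECAMER_LEN]
        adapter1 = True
    else:
        adapter1 = False

    umi = pair.r2_seq[:DECAMER_LEN]
    r2 = pair.r2_seq[DECAMER_LEN:]
    q2 = pair.r2_qual[DECAMER_LEN:]
    r2_adapter = _find_adapter(r2, R2_ADAPTER)
    adapter2 = r2_adapter >= 0
    if adapter2:
        r2, q2 = r2[:r2_adapter], q2[:r2_adapter]

    return replace(
        pair,
        assigned_primer=primer.name,
        umi_obs=umi,
        r1_insert=r1,
        r1_insert_qual=q1,
        r2_insert=r2,
        r2_insert_qual=q2,
        r1_adapter_found=adapter1,
        r2_adapter_found=adapter2,
        unassigned_reason=None,
    )


# ---------------------------------------------------------------------------
# Smith-Waterman (affine gaps, vectorized rows, full traceback)


def smith_waterman(
    query: str,
    ref: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> tuple[int, int, int, int, int, list[tuple[str, int]]]:
    """Best local alignment of query vs ref.

    Returns ``(score, q_beg, q_end, r_beg, r_end, ops)`` with half-open
    query/ref spans and ops over M/I/D (I consumes query only).  A gap of
    length L costs ``gap_open + (L - 1) * gap_extend``.  Ties are broken
    toward the smallest (q_end, r_end) cell and diagonal moves first,
    which makes results deterministic.
    """
    m, n = len(query), len(ref)
    if m == 0 or n == 0:
        return 0, 0, 0, 0, 0, []
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    NEG = -(10 ** 6)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    ge = gap_extend
    go = gap_open
    j_idx = np.arange(n)
    for i in range(1, m + 1):
        sub = np.where(r == q[i - 1], match, mismatch)
        sub[r == ord("N")] = mismatch
        if q[i - 1] == ord("N"):
            sub[:] = mismatch
        hp = np.maximum(0, H[i - 1, :-1] + sub)  # diagonal (or restart)
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go, F[i - 1, 1:] + ge)
        hp = np.maximum(hp, F[i, 1:])
        # E via prefix max: E[j] = ge*(j-1) + max_{k<=j-1}(hp'[k] + go - ge*k)
        # where hp'[k] refers to column k (0-based over ref) = H'[i, k+1],
        # and k = 0 corresponds to a deletion starting after column 1.
        hp_full = np.concatenate(([0], hp))  # H'[i, 0..n]
        a = hp_full[:-1] + go - ge * np.arange(n)
        running = np.maximum.accumulate(a)
        E[i, 1:] = ge * j_idx + running
        H[i, 1:] = np.maximum(hp, E[i, 1:])
    score = int(H.max())
    if score <= 0:
        return 0, 0, 0, 0, 0, []
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    q_end, r_end = int(i), int(j)
    ops: list[tuple[str, int]] = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = match if (query[i - 1] == ref[j - 1] and query[i - 1] != "N") else mismatch
            if h == H[i - 1, j - 1] + s:
                push("M")
                i, j = i - 1, j - 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed")
        elif state == "F":
            push("I")
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:  # E
            push("D")
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    q_beg, r_beg = int(i), int(j)
    ops.reverse()
    return score, q_beg, q_end, r_beg, r_end, ops


def diagonal_align(
    seq: str, ref: str, start: int, tid: str = "", min_window: int = 20
) -> Optional[AlignmentRecord]:
    """Optimal ungapped local alignment of *seq* on a known diagonal.

    The best-scoring contiguous window of the fixed diagonal (a
    max-subarray over +1/-2 per-base scores) equals what Smith-Waterman
    would return whenever the alignment needs no gaps, at a fraction of
    the cost.  Returns None when the window carries more than two
    internal mismatches, in which case the caller should fall back to
    the full DP (an indel or a wrong diagonal is likely).
    """
    if start < 0 or start >= len(ref) or not seq:
        return None
    n_avail = min(len(seq), len(ref) - start)
    if n_avail < min_window:
        return None
    q = np.frombuffer(seq[:n_avail].encode(), dtype=np.uint8)
    r = np.frombuffer(ref[start : start + n_avail].encode(), dtype=np.uint8)
    scores = np.where(q == r, 1, -2).astype(np.int32)
    # max-subarray with earliest-window tie-break
    pre = np.concatenate(([0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(pre[:-1])
    gains = pre[1:] - run_min
    best_end = int(np.argmax(gains)) + 1
    best = int(gains[best_end - 1])
    best_start = int(np.argmin(pre[:best_end]))
    length = best_end - best_start
    if length < min_window:
        return None
    mismatches = int((q[best_start:best_end] != r[best_start:best_end]).sum())
    if mismatches > 2:
        return None
    cigar: list[tuple[str, int]] = []
    if best_start > 0:
        cigar.append(("S", best_start))
    cigar.append(("M", length))
    if best_end < len(seq):
        cigar.append(("S", len(seq) - best_end))
    return AlignmentRecord("", 0, tid, start + best_start, cigar, mismatches, best)


# ---------------------------------------------------------------------------
# seed index and seed-and-extend


class KmerIndex:
    """Exact k-mer index over the panel transcriptome."""

    def __init__(self, transcriptome: Transcriptome, k: int = DEFAULT_K):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for tid in sorted(transcriptome.records):
            seq = transcriptome.records[tid]
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((tid, pos))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def seed_and_extend(
    seq: str,
    transcriptome: Transcriptome,
    index: KmerIndex,
    min_score: int = MIN_SCORE,
    max_candidates: int = MAX_CANDIDATES,
) -> list[AlignmentRecord]:
    """Locate and extend exact k-mer seeds into local alignments.

    Seeds sharing a (transcript, diagonal) neighbourhood are chained into
    one candidate window; each window is resolved by Smith-Waterman (a
    full-length exact match short-circuits the DP).  Records are sorted
    by score descending with a deterministic (transcript, start)
    tie-break.
    """
    k = index.k
    if len(seq) < k:
        return []
    offsets = list(range(0, len(seq) - k + 1, SEED_STRIDE))
    if offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)
    hits: dict[tuple[str, int], list[int]] = {}
    for off in offsets:
        for tid, pos in index.hits(seq[off : off + k]):
            hits.setdefault((tid, pos - off), []).append(off)
    if not hits:
        return []
    # cluster nearby diagonals (tolerate small indels)
    clusters: dict[str, list[list[int]]] = {}
    for (tid, diag), offs in sorted(hits.items()):
        rows = clusters.setdefault(tid, [])
        for cl in rows:
            if abs(cl[0] - diag) <= 8:
                cl.append(diag)
                break
        else:
            rows.append([diag])
    candidates: list[tuple[int, str, int, int]] = []  # (-support, tid, dmin, dmax)
    for tid, rows in clusters.items():
        for cl in rows:
            support = sum(len(hits[(tid, d)]) for d in set(cl))
            candidates.append((-support, tid, min(cl), max(cl)))
    candidates.sort()
    records: list[AlignmentRecord] = []
    seen: set[tuple[str, int]] = set()
    for _, tid, dmin, dmax in candidates[:max_candidates]:
        ref = transcriptome.records[tid]
        # exact full-length fast path
        if dmin == dmax and 0 <= dmin and dmin + len(seq) <= len(ref):
            if ref[dmin : dmin + len(seq)] == seq:
                if (tid, dmin) not in seen:
                    seen.add((tid, dmin))
                    records.append(AlignmentRecord(
                        "", 0, tid, dmin, [("M", len(seq))], 0, len(seq) * MATCH))
                continue
        pad = 30
        wstart = max(0, dmin - pad)
        wend = min(len(ref), dmax + len(seq) + pad)
        score, qb, qe, rb, re_, ops = smith_waterman(seq, ref[wstart:wend])
        if score < min_score or not ops:
            continue
        cigar: list[tuple[str, int]] = []
        if qb > 0:
            cigar.append(("S", qb))
        cigar.extend(ops)
        if qe < len(seq):
            cigar.append(("S", len(seq) - qe))
        nm = _edit_distance_of(seq[qb:qe], ref[wstart + rb : wstart + re_], ops)
        key = (tid, wstart + rb)
        if key in seen:
            continue
        seen.add(key)
        records.append(AlignmentRecord("", 0, tid, wstart + rb, cigar, nm, score))
    records.sort(key=lambda r: (-r.score, r.transcript_id, r.start))
    return records


def _edit_distance_of(qseg: str, rseg: str, ops: list[tuple[str, int]]) -> int:
    nm = 0
    qi = ri = 0
    for op, n in ops:
        if op == "M":
            nm += sum(1 for a, b in zip(qseg[qi : qi + n], rseg[ri : ri + n]) if a != b)
            qi += n
            ri += n
        elif op == "I":
            nm += n
            qi += n
        elif op == "D":
            nm += n
            ri += n
    return nm


# ---------------------------------------------------------------------------
# pair alignment


class Aligner:
    """Aligns preprocessed pairs against the panel transcriptome."""

    def __init__(self, panel: PanelDesign, k: int = DEFAULT_K):
        self.panel = panel
        self.transcriptome = panel.transcriptome
        self.index = KmerIndex(panel.transcriptome, k=k)
        self.matcher = PrimerMatcher(panel)

    def align_pair(self, pair: ReadPair) -> PairAlignment:
        if pair.assigned_primer is None:
            return PairAlignment(pair, None, None, False, reason="unassigned")
        primer = self.panel.primer(pair.assigned_primer)
        tid = primer.transcript_id
        ref = self.transcriptome.records[tid]

        rec1 = self._align_anchored(pair.r1_insert, ref, tid, primer.end)
        if rec1 is None and pair.r1_insert:
            rec1 = diagonal_align(pair.r1_insert, ref, primer.end, tid)
        if rec1 is None:
            recs = seed_and_extend(pair.r1_insert, self.transcriptome, self.index)
            rec1 = recs[0] if recs else None
        if rec1 is not None:
            rec1 = replace(rec1, read_id=pair.id, mate=1)

        rc2 = revcomp(pair.r2_insert)
        rec2 = None
        if len(rc2) >= self.index.k:
            rec2 = self._align_seeded(rc2)
            if rec2 is None:
                recs = seed_and_extend(rc2, self.transcriptome, self.index)
                rec2 = recs[0] if recs else None
        if rec2 is not None:
            rec2 = replace(rec2, read_id=pair.id, mate=2, reverse=True)

        if rec1 is None and rec2 is None:
            return PairAlignment(pair, None, None, False, reason="unmapped")
        if rec1 is None or rec2 is None:
            return PairAlignment(pair, rec1, rec2, False, reason="half-mapped")
        # anchored-PCR concordance: R1 must start at the primer 3' end
        r1_start = rec1.start - rec1.clip5
        if rec1.transcript_id != tid or abs(r1_start - primer.end) > PRIMER_START_SLOP:
            return PairAlignment(pair, rec1, rec2, False, reason="primer-discordant")
        return PairAlignment(pair, rec1, rec2, True)

    def _align_anchored(
        self, seq: str, ref: str, tid: str, expected_start: int
    ) -> Optional[AlignmentRecord]:
        """Fast path: exact match at the coordinate the primer dictates."""
        if not seq:
            return None
        end = expected_start + len(seq)
        if end <= len(ref) and ref[expected_start:end] == seq:
            return AlignmentRecord("", 0, tid, expected_start,
                                   [("M", len(seq))], 0, len(seq) * MATCH)
        return None

    def _align_seeded(self, seq: str) -> Optional[AlignmentRecord]:
        """Fast path: single unique seed hit resolved on its diagonal."""
        k = self.index.k
        for off in (0, 5, 10, 15):
            if off + k > len(seq):
                break
            hits = self.index.hits(seq[off : off + k])
            if len(hits) == 1:
                tid, pos = hits[0]
                ref = self.transcriptome.records[tid]
                rec = diagonal_align(seq, ref, pos - off, tid)
                if rec is not None:
                    return rec
                return None
            if len(hits) > 1:
                return None
        return None


def align_sample(
    pairs: list[ReadPair], panel: PanelDesign, aligner: Optional[Aligner] = None
) -> tuple[list[PairAlignment], dict[str, int]]:
    """Assign, trim, and align a whole sample; returns alignments + counters."""
    if aligner is None:
        aligner = Aligner(panel)
    counters = {"input_pairs": len(pairs), "unassigned": 0, "improper": 0, "proper": 0}
    out = []
    for pair in pairs:
        pair = assign_primer_and_umi(pair, panel, matcher=aligner.matcher)
        if pair.assigned_primer is None:
            counters["unassigned"] += 1
            continue
        pa = aligner.align_pair(pair)
        if pa.proper:
            counters["proper"] += 1
        else:
            counters["improper"] += 1
        out.append(pa)
    return out, counters


# ---------------------------------------------------------------------------
# SAM IO

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CIGAR_CHAR = {v: k for k, v in _CIGAR_CODE.items()}


def sam_header(transcriptome: Transcriptome) -> dict:
    tids = sorted(transcriptome.records)
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": tid, "LN": len(transcriptome.records[tid])} for tid in tids],
    }


def write_sam(alignments: list[PairAlignment], transcriptome: Transcriptome, path: str) -> None:
    """Write aligned pairs as plain SAM (primer in XP, observed UMI in RX)."""
    header = pysam.AlignmentHeader.from_dict(sam_header(transcriptome))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for pa in alignments:
            for rec, mate in ((pa.rec1, 1), (pa.rec2, 2)):
                if rec is None:
                    continue
                seg = pysam.AlignedSegment(header)
                seg.query_name = pa.pair.id
                seq = pa.pair.r1_insert if mate == 1 else revcomp(pa.pair.r2_insert)
                qual = pa.pair.r1_insert_qual if mate == 1 else pa.pair.r2_insert_qual[::-1]
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(qual)
                seg.reference_id = header.get_tid(rec.transcript_id)
                seg.reference_start = rec.start
                seg.cigartuples = [(_CIGAR_CODE[op], n) for op, n in rec.cigar]
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if pa.proper:
                    flag |= 0x2
                if rec.reverse:
                    flag |= 0x10
                seg.flag = flag
                seg.mapping_quality = 60
                seg.set_tag("NM", rec.nm)
                seg.set_tag("AS", rec.score)
                seg.set_tag("XP", pa.pair.assigned_primer or "")
                seg.set_tag("RX", pa.pair.umi_obs or "")
                out.write(seg)


def read_sam(path: str) -> list[PairAlignment]:
    """Read a SAM written by :func:`write_sam` back into pair alignments."""
    by_id: dict[str, dict] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        records = []
        try:
            records = list(fh)
        except (OSError, ValueError) as exc:
            raise ValueError(
                f"malformed SAM record near line {len(records) + 1}: {exc}"
            ) from exc
        for seg in records:
            cigar = [(_CIGAR_CHAR[op], n) for op, n in (seg.cigartuples or [])]
            qlen = sum(n for op, n in cigar if op in "SMI")
            if seg.query_sequence and qlen != len(seg.query_sequence):
                raise ValueError(
                    f"CIGAR consumes {qlen} bases but read is "
                    f"{len(seg.query_sequence)} nt for {seg.query_name}"
                )
            mate = 1 if seg.flag & 0x40 else 2
            rec = AlignmentRecord(
                read_id=seg.query_name,
                mate=mate,
                transcript_id=seg.reference_name,
                start=seg.reference_start,
                cigar=cigar,
                nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                reverse=bool(seg.flag & 0x10),
            )
            entry = by_id.setdefault(seg.query_name, {
                "proper": bool(seg.flag & 0x2), "primer": None, "umi": None,
                "r1": None, "r2": None, "seq": {}, "qual": {},
            })
            entry[f"r{mate}"] = rec
            entry["seq"][mate] = seg.query_sequence or ""
            entry["qual"][mate] = pysam.qualities_to_qualitystring(seg.query_qualities or [])
            if seg.has_tag("XP"):
                entry["primer"] = seg.get_tag("XP")
            if seg.has_tag("RX"):
                entry["umi"] = seg.get_tag("RX")
    out = []
    for rid, entry in by_id.items():
        r2_sense = entry["seq"].get(2, "")
        pair = ReadPair(
            id=rid,
            r1_seq=entry["seq"].get(1, ""), r1_qual=entry["qual"].get(1, ""),
            r2_seq=revcomp(r2_sense), r2_qual=entry["qual"].get(2, "")[::-1],
            assigned_primer=entry["primer"], umi_obs=entry["umi"],
            r1_insert=entry["seq"].get(1, ""), r1_insert_qual=entry["qual"].get(1, ""),
            r2_insert=revcomp(r2_sense), r2_insert_qual=entry["qual"].get(2, "")[::-1],
        )
        out.append(PairAlignment(pair, entry["r1"], entry["r2"], entry["proper"]))
    return out
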