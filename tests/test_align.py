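"""Preprocessing and alignment: primer/UMI assignment, SW vs DP oracle,
seed-and-extend behavior, pair concordance, SAM round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raceseq.align import (
    Aligner,
    KmerIndex,
    ReadPair,
    align_sample,
    assign_primer_and_umi,
    diagonal_align,
    read_sam,
    seed_and_extend,
    smith_waterman,
    write_sam,
)
from raceseq.panel import Transcriptome
from raceseq.simulate import TruthModel, revcomp, simulate_sample


# ---------------------------------------------------------------------------
# independent full-DP oracle


def sw_oracle(q, r, match=1, mismatch=-2, go=-4, ge=-1):
    """Plain-Python affine-gap local alignment score (Gotoh, full matrices)."""
    m, n = len(q), len(r)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + ge, H[i][j - 1] + go)
            F[i][j] = max(F[i - 1][j] + ge, H[i - 1][j] + go)
            s = match if q[i - 1] == r[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _mutated_read(rng, ref, max_len=150):
    start = rng.integers(0, max(1, len(ref) - 40))
    length = int(rng.integers(30, min(max_len, len(ref) - start)))
    read = list(ref[start : start + length])
    for _ in range(rng.integers(0, 6)):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(read)))
        if op == 0:
            read[pos] = "ACGT"[rng.integers(0, 4)]
        elif op == 1 and len(read) > 31:
            del read[pos]
        else:
            read.insert(pos, "ACGT"[rng.integers(0, 4)])
    return "".join(read)


def test_smith_waterman_equals_dp_oracle_on_planted_reads():
    """Scores match an independent full-DP oracle on 50 mutated substrings."""
    rng = np.random.default_rng(1234)
    for _ in range(50):
        ref = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 200))))
        read = _mutated_read(rng, ref)
        score, qb, qe, rb, re_, ops = smith_waterman(read, ref)
        assert score == sw_oracle(read, ref)
        # CIGAR consistency: ops consume the aligned spans exactly
        qlen = sum(n for op, n in ops if op in "MI")
        rlen = sum(n for op, n in ops if op in "MD")
        assert qlen == qe - qb and rlen == re_ - rb


def test_smith_waterman_equals_dp_oracle_on_random_pairs():
    """Scores also match on unrelated random pairs (no planted homology)."""
    rng = np.random.default_rng(77)
    for _ in range(20):
        q = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
        r = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 120))))
        assert smith_waterman(q, r)[0] == sw_oracle(q, r)


def test_diagonal_align_matches_sw_for_substitutions():
    rng = np.random.default_rng(5)
    ref = "".join(rng.choice(list("ACGT"), size=300))
    for _ in range(20):
        start = int(rng.integers(0, 140))
        read = list(ref[start : start + 100])
        for pos in rng.choice(100, size=int(rng.integers(0, 3)), replace=False):
            read[pos] = "ACGT"[rng.integers(0, 4)]
        read = "".join(read)
        rec = diagonal_align(read, ref, start)
        assert rec is not None
        assert rec.score == sw_oracle(read, ref)


# ---------------------------------------------------------------------------
# seed-and-extend


def _toy_transcriptome(rng, n=3, length=400):
    records = {}
    for i in range(n):
        records[f"T{i}"] = "".join(rng.choice(list("ACGT"), size=length))
    return Transcriptome(
        records=records,
        exons={tid: [(1, 0, len(s))] for tid, s in records.items()},
        gene={tid: f"G{i}" for i, tid in enumerate(records)},
    )


def test_exact_substring_single_full_match():
    rng = np.random.default_rng(8)
    tr = _toy_transcriptome(rng)
    index = KmerIndex(tr)
    read = tr.records["T1"][100:200]
    recs = seed_and_extend(read, tr, index)
    assert recs[0].transcript_id == "T1"
    assert recs[0].start == 100
    assert recs[0].cigar == [("M", 100)]
    assert recs[0].nm == 0 and recs[0].score == 100


def test_chimeric_read_soft_clipped_at_junction(panel, aligner):
    """60 nt of FGFR2 ending at the exon-17 boundary + 60 nt partner is
    soft-clipped at the junction, up to any chance junction homology
    (the partner prefix may coincide with the reference continuation, in
    which case the anchor alignment legitimately extends through it)."""
    tr = panel.transcriptome
    boundary = [a for a in panel.fusion_anchors
                if a.gene == "FGFR2" and a.exon_number == 17][0].boundary
    anchor_ref = tr.records["FGFR2-201"]
    partner = tr.records["BICC1-201"]
    homology = 0
    while partner[150 + homology] == anchor_ref[boundary + homology]:
        homology += 1
    read = anchor_ref[boundary - 60 : boundary] + partner[150:210]
    recs = seed_and_extend(read, tr, aligner.index)
    best = recs[0]
    assert best.transcript_id == "FGFR2-201"
    assert best.ref_end == boundary + homology
    assert best.clip3 == 60 - homology
    assert best.clip3 >= 55  # homology is a few bases at most here


def test_random_read_absent_from_reference(aligner, panel):
    rng = np.random.default_rng(99)
    read = "".join(rng.choice(list("ACGT"), size=100))
    # retry until the random read shares no 15-mer with the panel (near-certain)
    recs = seed_and_extend(read, panel.transcriptome, aligner.index)
    assert recs == [] or all(r.score < 100 for r in recs)


# ---------------------------------------------------------------------------
# primer / UMI assignment


def _pair_from(seq1, seq2):
    return ReadPair(id="p", r1_seq=seq1, r1_qual="I" * len(seq1),
                    r2_seq=seq2, r2_qual="I" * len(seq2))


def test_exact_primer_prefix_assigned(panel, aligner):
    primer = panel.primer("IDH1_R132")
    r1 = primer.sequence + "ACGT" * 20
    pair = assign_primer_and_umi(_pair_from(r1, "ACGT" * 25), panel,
                                 matcher=aligner.matcher)
    assert pair.assigned_primer == "IDH1_R132"
    assert pair.umi_obs == "ACGTACGTAC"


def test_three_mismatches_unassigned(panel, aligner):
    primer = panel.primer("IDH1_R132")
    seq = list(primer.sequence)
    for i in (2, 8, 14):
        seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
    pair = assign_primer_and_umi(_pair_from("".join(seq) + "ACGT" * 20, "ACGT" * 25),
                                 panel, matcher=aligner.matcher)
    assert pair.assigned_primer is None
    assert pair.unassigned_reason == "no-primer-match"


def test_error_free_sample_fully_assigned_and_concordant(panel, aligner, uniform_weights):
    """Zero-error reads: 100% assigned to the ledger primer, aligned at the
    primer 3' end, with the RT coordinate equal to the ledger value."""
    truth = TruthModel(expression_weights=uniform_weights, n_templates=300,
                       seq_error_rate=0.0, seed=17)
    s = simulate_sample(panel, truth)
    by_id = {r.template_id: r for r in s.ledger}
    pairs = [ReadPair(id=r[0], r1_seq=r[1], r1_qual=r[2], r2_seq=r[3], r2_qual=r[4])
             for r in s.reads]
    alignments, counters = align_sample(pairs, panel, aligner=aligner)
    assert counters["unassigned"] == 0
    fused = {r.template_id for r in s.ledger if r.fusion}
    for pa in alignments:
        entry = by_id[pa.pair.id.split(".")[0]]
        assert pa.pair.assigned_primer == entry.primer
        assert pa.proper
        primer = panel.primer(entry.primer)
        assert pa.rec1.start - pa.rec1.clip5 == primer.end
        assert pa.rt_coord == entry.rt_coord


def test_r2_shorter_than_k_half_mapped(panel, aligner):
    primer = panel.primer("IDH1_R132")
    tid = primer.transcript_id
    ref = panel.transcriptome.records[tid]
    r1 = primer.sequence + ref[primer.end : primer.end + 60]
    r2 = "ACGTACGTAC" + revcomp(ref[primer.end : primer.end + 8])
    pair = assign_primer_and_umi(_pair_from(r1, r2), panel, matcher=aligner.matcher)
    pa = aligner.align_pair(pair)
    assert not pa.proper
    assert pa.reason in ("half-mapped", "unmapped")


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 32 - 1))
def test_softclip_plus_aligned_equals_read_length(seed):
    """Fuzz: CIGAR of any alignment consumes exactly the query length."""
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list("ACGT"), size=250))
    tr = Transcriptome(records={"T": ref}, exons={"T": [(1, 0, 250)]}, gene={"T": "G"})
    index = KmerIndex(tr)
    read = _mutated_read(rng, ref, max_len=120)
    for rec in seed_and_extend(read, tr, index):
        assert rec.query_len == len(read)


# ---------------------------------------------------------------------------
# SAM IO


def test_sam_round_trip(tmp_path, panel, aligner, uniform_weights):
    truth = TruthModel(expression_weights=uniform_weights, n_templates=50, seed=23)
    s = simulate_sample(panel, truth)
    pairs = [ReadPair(id=r[0], r1_seq=r[1], r1_qual=r[2], r2_seq=r[3], r2_qual=r[4])
             for r in s.reads]
    alignments, _ = align_sample(pairs, panel, aligner=aligner)
    path = str(tmp_path / "out.sam")
    write_sam(alignments, panel.transcriptome, path)
    restored = {pa.pair.id: pa for pa in read_sam(path)}
    assert len(restored) == len(alignments)
    for pa in alignments:
        back = restored[pa.pair.id]
        assert back.proper == pa.proper
        assert back.pair.assigned_primer == pa.pair.assigned_primer
        assert back.pair.umi_obs == pa.pair.umi_obs
        for orig, rec in ((pa.rec1, back.rec1), (pa.rec2, back.rec2)):
            assert rec.transcript_id == orig.transcript_id
            assert rec.start == orig.start
            assert rec.cigar == orig.cigar
            assert rec.nm == orig.nm
        assert back.rt_coord == pa.rt_coord


def test_empty_alignments_header_only(tmp_path, panel):
    path = str(tmp_path / "empty.sam")
    write_sam([], panel.transcriptome, path)
    lines = open(path).read().splitlines()
    assert lines and all(line.startswith("@") for line in lines)
    assert read_sam(path) == []


def test_corrupt_cigar_rejected(tmp_path, panel):
    path = str(tmp_path / "bad.sam")
    write_sam([], panel.transcriptome, path)
    with open(path, "a") as fh:
        fh.write("r1\t0\tIDH1-201\t11\t60\t5M\t*\t0\t0\tACGTACGT\tIIIIIIII\n")
    with pytest.raises(ValueError, match="CIGAR|malformed SAM"):
        read_sam(path)
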