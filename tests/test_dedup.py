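"""Duplicate collapsing: directional UMI clustering (vs an independent
oracle), coordinate grouping, conservation, order invariance, and
ledger-level template recovery."""

import random

import pytest

from raceseq.align import AlignmentRecord, Aligner, PairAlignment, ReadPair, align_sample
from raceseq.dedup import (
    cluster_umis_directional,
    collapse,
    count_templates,
    group_by_coordinate,
)
from raceseq.panel import fragment_for
from raceseq.simulate import TruthModel, revcomp, simulate_sample


# ---------------------------------------------------------------------------
# directional clustering


@pytest.mark.parametrize("counts,expected_clusters", [
    ({"AAAAAAAAAA": 10, "AAAAAAAAAT": 1}, 1),   # 10 >= 2*1-1: absorbed
    ({"AAAAAAAAAA": 5, "TTTTTTTTTT": 5}, 2),    # Hamming distance 10
    ({"AAAAAAAAAA": 3, "AAAAAAAAAT": 2}, 1),    # boundary: 3 >= 2*2-1 = 3
    ({"AAAAAAAAAA": 2, "AAAAAAAAAT": 2}, 2),    # 2 < 3: kept apart
])
def test_directional_rule_examples(counts, expected_clusters):
    clusters = cluster_umis_directional(counts)
    assert len(clusters) == expected_clusters
    # the seed of each cluster is its highest-count UMI
    for cl in clusters:
        assert counts[cl[0]] == max(counts[u] for u in cl)


def test_wrong_umi_length_rejected():
    with pytest.raises(ValueError):
        cluster_umis_directional({"AAAA": 2})


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def _directional_oracle(counts):
    """Independent implementation: explicit edge lists + reachability closure."""
    edges = {
        u: [v for v in counts
            if v != u and _hamming(u, v) == 1 and counts[u] >= 2 * counts[v] - 1]
        for u in counts
    }
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited, clusters = set(), []
    for seed in order:
        if seed in visited:
            continue
        comp, stack = [], [seed]
        visited.add(seed)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in sorted(edges[u]):
                if v not in visited:
                    visited.add(v)
                    stack.append(v)
        clusters.append(comp)
    return clusters


def test_directional_clustering_equals_oracle_small_instances():
    """Exhaustive comparison on random instances with <= 8 distinct UMIs.

    A two-letter alphabet concentrates the UMIs so Hamming-1 adjacency
    (and chained absorption) is common.
    """
    rng = random.Random(20240)
    for _ in range(300):
        n = rng.randint(1, 8)
        counts = {}
        while len(counts) < n:
            umi = "".join(rng.choice("AT") for _ in range(10))
            counts.setdefault(umi, rng.randint(1, 6))
        got = cluster_umis_directional(counts)
        expected = _directional_oracle(counts)
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))
        assert {cl[0] for cl in got} == {cl[0] for cl in expected}


# ---------------------------------------------------------------------------
# grouping and collapsing


def _mock_pair(pid, primer, tid, rt, umi, r1_start=0, seq="ACGTACGTACGTACGTACGT"):
    pair = ReadPair(id=pid, r1_seq=seq, r1_qual="I" * len(seq),
                    r2_seq=seq, r2_qual="I" * len(seq),
                    assigned_primer=primer, umi_obs=umi,
                    r1_insert=seq, r1_insert_qual="I" * len(seq),
                    r2_insert=seq, r2_insert_qual="I" * len(seq))
    rec1 = AlignmentRecord(pid, 1, tid, r1_start, [("M", len(seq))], 0, len(seq))
    rec2 = AlignmentRecord(pid, 2, tid, rt - len(seq), [("M", len(seq))], 0,
                           len(seq), reverse=True)
    return PairAlignment(pair, rec1, rec2, True)


def test_grouping_on_key_triple(panel):
    primer = panel.primer("IDH1_R132")
    pairs = [
        _mock_pair("a", "IDH1_R132", "IDH1-201", 450, "A" * 10, r1_start=primer.end),
        _mock_pair("b", "IDH1_R132", "IDH1-201", 450, "A" * 10, r1_start=primer.end),
        _mock_pair("c", "IDH2_R140", "IDH1-201", 450, "A" * 10, r1_start=primer.end),
    ]
    groups, discarded = group_by_coordinate(pairs, panel)
    assert discarded == 0
    sizes = sorted(len(v) for v in groups.values())
    assert sizes == [1, 2]


def test_pair_outside_panel_targets_discarded(panel):
    # LRBA carries no panel fragments or hotspots
    stray = _mock_pair("x", "IDH1_R132", "LRBA-201", 500, "A" * 10, r1_start=300)
    groups, discarded = group_by_coordinate([stray], panel)
    assert discarded == 1
    assert groups == {}


def _simulate_aligned(panel, aligner, **kw):
    truth = TruthModel(**kw)
    s = simulate_sample(panel, truth)
    pairs = [ReadPair(id=r[0], r1_seq=r[1], r1_qual=r[2], r2_seq=r[3], r2_qual=r[4])
             for r in s.reads]
    alignments, counters = align_sample(pairs, panel, aligner=aligner)
    return s, alignments, counters


def test_read_conservation_through_collapse(panel, aligner, uniform_weights):
    """Sum of cluster read counts + discards accounts for every input pair."""
    s, alignments, counters = _simulate_aligned(
        panel, aligner, expression_weights=uniform_weights, n_templates=400, seed=31)
    result = collapse(alignments, panel)
    assert (result.conserved_reads() + result.discarded_offtarget
            + counters["unassigned"] + counters["improper"]) == s.n_pairs


def test_collapse_invariant_to_input_order(panel, aligner, uniform_weights):
    _, alignments, _ = _simulate_aligned(
        panel, aligner, expression_weights=uniform_weights, n_templates=200, seed=37)
    fwd = collapse(alignments, panel)
    rev = collapse(list(reversed(alignments)), panel)
    key = lambda t: (t.primer, t.transcript_id, t.rt_coord, t.umi_consensus)
    assert sorted(map(key, fwd.templates)) == sorted(map(key, rev.templates))
    assert fwd.total_templates == rev.total_templates


def _ledger_expected_clusters(ledger):
    """Template count predicted from the ledger alone (error-free reads).

    Groups ledger templates on the dedup key and applies the directional
    rule to the written decamers (observed as reverse complements on R2).
    """
    groups = {}
    for r in ledger:
        groups.setdefault((r.primer, r.rt_coord), {})
    for r in ledger:
        counts = groups[(r.primer, r.rt_coord)]
        umi = revcomp(r.umi)
        counts[umi] = counts.get(umi, 0) + r.dup_count
    return sum(len(cluster_umis_directional(c)) for c in groups.values())


def test_collapse_recovers_ledger_template_count(panel, aligner, uniform_weights):
    """Pipeline template count equals the ledger-derived prediction exactly
    (error-free reads; pseudo-UMI collisions predicted from the ledger)."""
    s, alignments, _ = _simulate_aligned(
        panel, aligner, expression_weights=uniform_weights, n_templates=500,
        seq_error_rate=0.0, seed=41)
    result = collapse(alignments, panel)
    assert result.total_templates == _ledger_expected_clusters(s.ledger)


def test_all_unique_input_one_cluster_per_read(panel):
    primer = panel.primer("IDH1_R132")
    pairs = [
        _mock_pair(f"r{i}", "IDH1_R132", "IDH1-201", 430 + 7 * i, "A" * 10,
                   r1_start=primer.end)
        for i in range(5)
    ]
    result = collapse(pairs, panel)
    assert result.total_templates == 5
    assert all(t.read_count == 1 for t in result.templates)


def test_single_read_consensus_is_read(panel):
    primer = panel.primer("IDH1_R132")
    seq = panel.transcriptome.records["IDH1-201"][primer.end : primer.end + 20]
    pa = _mock_pair("solo", "IDH1_R132", "IDH1-201", 450, "A" * 10,
                    r1_start=primer.end, seq=seq)
    result = collapse([pa], panel)
    assert result.total_templates == 1
    assert result.templates[0].consensus_seq == seq


def test_count_templates_half_open_boundary(panel, aligner, uniform_weights):
    frag = fragment_for("DDX23", panel)
    s, alignments, _ = _simulate_aligned(
        panel, aligner, expression_weights=uniform_weights, n_templates=400,
        seq_error_rate=0.0, seed=43)
    result = collapse(alignments, panel)
    got = count_templates(result.templates, frag)
    expected = sum(
        1 for t in result.templates
        if t.transcript_id == frag.transcript_id
        and t.start < frag.end and t.start + len(t.consensus_seq) > frag.start
    )
    assert got == expected > 0
    # a template abutting the fragment end (half-open) is not counted
    outside = [t for t in result.templates
               if t.transcript_id == frag.transcript_id and t.start >= frag.end]
    assert all(
        count_templates([t], frag) == 0 for t in outside
    )
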