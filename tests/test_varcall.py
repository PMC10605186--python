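"""Variant calling: pileup construction, thresholds, protein annotation,
VCF round trips, monotonicity, and specificity on variant-free samples."""

import numpy as np
import pytest

from raceseq.dedup import TemplateCluster
from raceseq.pipeline import run_pipeline
from raceseq.simulate import TruthModel, VariantSpec, simulate_sample
from raceseq.varcall import (
    CallThresholds,
    PileupColumn,
    VariantCall,
    annotate_protein,
    call_variants,
    passing,
    pileup,
    read_vcf,
    write_vcf,
)


def _template(panel, tid, start, seq, primer="IDH1_R132", rt=None, umi="A" * 10,
              reads=2):
    return TemplateCluster(
        primer=primer, transcript_id=tid, rt_coord=rt or (start + len(seq)),
        umi_consensus=umi, read_count=reads, member_ids=[f"m{start}"],
        consensus_seq=seq, consensus_qual="?" * len(seq), start=start,
    )


def test_pileup_single_template_columns(panel):
    """One 30-nt template in the IDH1 hotspot region: depth-1 columns only
    at covered positions, nothing elsewhere."""
    tid = "IDH1-201"
    ref = panel.transcriptome.records[tid]
    t = _template(panel, tid, 400, ref[400:430])
    cols, _ = pileup([t], panel)
    by_pos = {c.position: c for c in cols}
    assert all(c.depth == 1 for c in cols)
    assert 408 in by_pos  # the R132 codon start
    assert all(400 <= p < 430 for p in by_pos)
    for c in cols:
        assert sum(c.base_counts.values()) == c.depth


def test_pileup_overlapping_templates_sum(panel):
    tid = "IDH1-201"
    ref = panel.transcriptome.records[tid]
    ts = [_template(panel, tid, 400, ref[400:430]),
          _template(panel, tid, 405, ref[405:435])]
    cols, _ = pileup(ts, panel)
    by_pos = {c.position: c for c in cols}
    assert by_pos[410].depth == 2
    assert by_pos[401].depth == 1


def _column(panel, pos, depth, alt, alt_count, tid="IDH1-201", qual=30.0):
    ref = panel.transcriptome.records[tid][pos]
    return PileupColumn(
        tid, pos, depth,
        {ref: depth - alt_count, alt: alt_count},
        {ref: qual * (depth - alt_count), alt: qual * alt_count},
    )


def test_hotspot_call_passes_at_seven_percent(panel):
    cols = [_column(panel, 408, 100, "T", 7)]
    calls = passing(call_variants(cols, panel))
    assert len(calls) == 1
    assert calls[0].vaf == pytest.approx(0.07)
    assert calls[0].hotspot_label == "IDH1 p.R132"
    assert calls[0].protein_change == "IDH1 p.R132C"


def test_single_alt_template_not_called(panel):
    cols = [_column(panel, 408, 100, "T", 1)]
    assert call_variants(cols, panel) == []


def test_hotspot_floor_lower_than_nonhotspot(panel):
    """3% VAF passes at a hotspot codon but is filtered elsewhere."""
    hot = _column(panel, 408, 200, "T", 6)          # IDH1 R132: floor 0.02
    cold = _column(panel, 520, 200, "T", 6)          # IDH1 UTR region: floor 0.05
    calls = call_variants([hot, cold], panel)
    status = {c.position: c.filter for c in calls}
    assert status[408] == "PASS"
    assert status.get(520, "absent") in ("low_vaf", "absent")


def test_low_quality_allele_filtered(panel):
    col = _column(panel, 408, 100, "T", 10, qual=12.0)
    calls = call_variants([col], panel)
    assert calls and calls[0].filter == "low_qual"


def test_depth_floor(panel):
    cols = [_column(panel, 408, 40, "T", 10)]
    assert call_variants(cols, panel) == []


def test_annotate_protein_synonymous_unlabelled(panel):
    # KRAS Q61 codon CAA; CAA->CAG is synonymous (Q->Q)
    pos = panel.hotspots.cds_start["KRAS-201"] + 3 * 60 + 2
    call = VariantCall("KRAS-201", pos, "A", "G", 10, 100, 0.1)
    assert annotate_protein(call, panel).protein_change is None


def test_annotate_protein_nonhotspot_unchanged(panel):
    call = VariantCall("IDH1-201", 520, "A", "T", 10, 100, 0.1)
    assert annotate_protein(call, panel).protein_change is None


@pytest.mark.parametrize("pos,ref,alt,expected", [
    (408, "C", "T", "IDH1 p.R132C"),   # CGT -> TGT
    (409, "G", "T", "IDH1 p.R132L"),   # CGT -> CTT
    (408, "C", "G", "IDH1 p.R132G"),   # CGT -> GGT
])
def test_annotate_known_hotspot_changes(panel, pos, ref, alt, expected):
    assert panel.transcriptome.records["IDH1-201"][pos] == ref
    call = VariantCall("IDH1-201", pos, ref, alt, 10, 100, 0.1)
    assert annotate_protein(call, panel).protein_change == expected


def test_raising_vaf_floor_shrinks_call_set(panel):
    """Monotonicity: a higher non-hotspot VAF floor never adds calls."""
    rng = np.random.default_rng(55)
    cols = []
    for _ in range(40):
        pos = int(rng.integers(500, 530))  # non-hotspot IDH1 region
        depth = int(rng.integers(50, 400))
        alt_n = int(rng.integers(3, max(4, depth // 3)))
        cols.append(_column(panel, pos, depth, "T", alt_n, tid="IDH1-201"))
    previous = None
    for floor in (0.02, 0.05, 0.10, 0.25):
        got = {(c.transcript_id, c.position, c.alt)
               for c in passing(call_variants(
                   cols, panel, CallThresholds(min_vaf_other=floor)))}
        if previous is not None:
            assert got <= previous
        previous = got


def test_no_pass_calls_on_variant_free_samples(panel, aligner, uniform_weights):
    """Error-only samples yield zero PASS calls under default thresholds."""
    for seed in range(3):
        truth = TruthModel(expression_weights=uniform_weights,
                           n_templates=2500, seed=100 + seed)
        s = simulate_sample(panel, truth)
        report = run_pipeline(s.reads, panel, aligner=aligner)
        assert passing(report.variants) == []


def test_spiked_substitution_recovered(panel, aligner, uniform_weights):
    truth = TruthModel(
        expression_weights=uniform_weights,
        variants=[VariantSpec("PIK3CA-201", 3163, "A", "G", 0.10)],
        n_templates=4000, seed=61,
    )
    s = simulate_sample(panel, truth)
    report = run_pipeline(s.reads, panel, aligner=aligner)
    hits = [v for v in passing(report.variants)
            if v.position == 3163 and v.alt == "G"]
    assert len(hits) == 1
    assert hits[0].vaf == pytest.approx(0.10, abs=0.05)
    assert hits[0].protein_change == "PIK3CA p.H1047R"


def test_spiked_insertion_recovered(panel, aligner, uniform_weights):
    """A 2-nt insertion at 10% allele fraction surfaces as an indel call."""
    truth = TruthModel(
        expression_weights=uniform_weights,
        variants=[VariantSpec("PIK3CA-201", 3170, "A", "ACT", 0.15)],
        n_templates=4000, seed=67,
    )
    ref = panel.transcriptome.records["PIK3CA-201"]
    assert ref[3170] == "A"
    s = simulate_sample(panel, truth)
    report = run_pipeline(s.reads, panel, aligner=aligner)
    indels = [v for v in passing(report.variants) if len(v.alt) > len(v.ref)]
    assert indels
    assert indels[0].vaf == pytest.approx(0.15, abs=0.08)


# ---------------------------------------------------------------------------
# VCF


def test_vcf_round_trip(tmp_path, panel):
    calls = [
        VariantCall("IDH1-201", 408, "C", "T", 7, 100, 0.07,
                    hotspot_label="IDH1 p.R132", protein_change="IDH1 p.R132C"),
        VariantCall("KRAS-201", 43, "G", "T", 12, 150, 0.08,
                    hotspot_label="KRAS p.G12", protein_change="KRAS p.G12C"),
        VariantCall("IDH1-201", 515, "A", "G", 9, 120, 0.075, filter="low_vaf"),
    ]
    path = str(tmp_path / "calls.vcf")
    write_vcf(calls, panel, path)
    restored = read_vcf(path)
    key = lambda c: (c.transcript_id, c.position, c.alt)
    assert sorted(map(key, restored)) == sorted(map(key, calls))
    by_key = {key(c): c for c in restored}
    orig = {key(c): c for c in calls}
    for k, c in by_key.items():
        assert c.depth == orig[k].depth
        assert c.alt_templates == orig[k].alt_templates
        assert c.vaf == pytest.approx(orig[k].vaf, abs=1e-4)
        assert c.filter == orig[k].filter
        assert c.hotspot_label == orig[k].hotspot_label


def test_vcf_vaf_four_decimals_and_one_based(tmp_path, panel):
    calls = [VariantCall("IDH1-201", 408, "C", "T", 1, 3, 1 / 3)]
    path = str(tmp_path / "one.vcf")
    write_vcf(calls, panel, path)
    body = [l for l in open(path) if not l.startswith("#")]
    assert len(body) == 1
    fields = body[0].split("\t")
    assert fields[1] == "409"  # 1-based POS
    assert "VAF=0.3333" in fields[7]


def test_empty_vcf_header_only(tmp_path, panel):
    path = str(tmp_path / "empty.vcf")
    write_vcf([], panel, path)
    assert all(l.startswith("#") for l in open(path))
    assert read_vcf(path) == []
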