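"""Bundled synthetic panel used for testing and demonstration.

The real enrichment panel targets human transcripts; its primer sequences
are not redistributable here, so the package ships a fully synthetic
stand-in that preserves the panel's *structure*: the same genes, the same
per-gene primer counts (29 + 3 + 9 + 7 + 1 + 17 + 1 + 3 = 70), the same
counted fragments (e.g. FGFR2 exons 16-17, the three referee fragments),
hotspot codons planted with their true reference codons (IDH1 R132 = CGT,
BRAF V600 = GTG, ...), and FGFR2 fusion anchors at the 3' end of exon 17 /
start of exon 18.  Transcript sequences are random but deterministic, so
every coordinate in the panel is reproducible.

Everything here is synthetic; no sequence corresponds to a real gene.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from .panel import (
    FusionAnchor,
    HotspotEntry,
    HotspotSet,
    PanelDesign,
    PrimerRecord,
    TargetFragment,
    Transcriptome,
    write_panel,
)

_SEQ_SEED = 20230  # fixes the synthetic transcript sequences
_PRIMER_LEN = 22
_COV_LEN = 120  # nominal region covered downstream of a hotspot/filler primer

# gene -> (exon length layout, CDS offset or None).  The final exon of each
# panel gene is oversized as a 3' UTR stand-in: the RT decamer may prime up to
# 240 nt (the insert cap) downstream of any primer, and priming sites must not
# pile up against the transcript end.
_GENE_LAYOUT: dict[str, tuple[list[int], int | None]] = {
    "FGFR1": ([118] * 16 + [80, 80, 260], 30),
    "FGFR2": ([126] * 15 + [45, 45, 90, 90], 24),
    "FGFR3": ([169] * 13 + [70, 70, 260], 33),
    "FGFR4": ([108] * 13 + [80, 80, 260], 21),
    "ERBB2": ([130] * 18 + [65, 65, 260], 30),
    "IDH1": ([90] * 6 + [180], 15),
    "IDH2": ([90] * 8 + [90], 21),
    "KRAS": ([30, 90, 90, 300, 90, 130], 10),
    "NRAS": ([30, 90, 90, 90, 90, 120], 10),
    "BRAF": ([127] * 15 + [160], 22),
    "PIK3CA": ([90] * 40, 24),
    "CD274": ([90] * 7, None),
    "DDX23": ([90] * 10, None),
    "GOLGA5": ([90] * 8, None),
    "SEL1L": ([90] * 15, None),
    # fusion partner genes (no primers; present so 3' tails can be annotated)
    "BICC1": ([75] * 16, None),
    "AHCYL1": ([120] * 3, None),
    "VCL": ([120] * 3, None),
    "CCDC6": ([120] * 3, None),
    "CFAP57": ([80] * 13, None),
    "LRBA": ([70] * 48, None),
    "LRRFIP2": ([110] * 4, None),
    "SLMAP": ([110] * 4, None),
    "SORBS1": ([110] * 4, None),
    "ZMYM4": ([120] * 3, None),
}

# gene -> {aa position: reference codon}; codons are written into the
# synthetic sequence so protein-level annotation is internally consistent.
_PLANTED_CODONS: dict[str, dict[int, str]] = {
    "FGFR1": {546: "AAC"},                       # N546
    "FGFR2": {276: "TTT", 382: "TGC", 547: "ATT", 549: "AAT"},  # F276 C382 I547 N549
    "FGFR3": {650: "AAG"},                       # K650
    "FGFR4": {388: "GGG"},                       # G388
    "ERBB2": {310: "TCC", 678: "CGG"},           # S310 R678
    "IDH1": {132: "CGT"},                        # R132
    "IDH2": {140: "CGG", 172: "AGG"},            # R140 R172
    "KRAS": {12: "GGT", 13: "GGC", 61: "CAA", 146: "GCA"},
    "NRAS": {12: "GGT", 61: "CAA"},
    "BRAF": {600: "GTG"},                        # V600
    "PIK3CA": {542: "GAG", 545: "GAG", 1047: "CAT"},
}

# expression-target and referee fragments: gene -> (first exon, last exon, role)
_COUNTED_FRAGMENTS = {
    "FGFR1": (17, 18, "expression-target"),
    "FGFR2": (16, 17, "expression-target"),
    "FGFR3": (14, 15, "expression-target"),
    "FGFR4": (14, 15, "expression-target"),
    "ERBB2": (19, 20, "expression-target"),
    "CD274": (5, 6, "expression-target"),
    "DDX23": (8, 9, "referee"),
    "GOLGA5": (5, 6, "referee"),
    "SEL1L": (13, 14, "referee"),
}

# filler primer starts per gene (regions tiled for fusion/hotspot coverage)
_FILLER_PRIMERS = {
    "FGFR1": [150, 450, 750, 1050],
    "FGFR2": [100, 300, 500, 700, 900, 1100],
    "FGFR3": [200, 500, 800, 1100],
    "FGFR4": [100, 300, 500, 700, 900],
    "ERBB2": [150, 400, 650, 1250, 1500, 1750],
    "KRAS": [480],
    "NRAS": [250],
    # PIK3CA's 17 primers tile its two hotspot regions with staggered
    # upstream offsets (redundant coverage of the helical E542/E545 and
    # kinase H1047 codons), plus a backbone tiling of the 5' half.
    "PIK3CA": [100 * i for i in range(1, 11)] + [1535, 1570, 3050, 3085, 3140],
}


def _tid(gene: str) -> str:
    return f"{gene}-201"


def _codon_pos(gene: str, aa: int) -> int:
    cds = _GENE_LAYOUT[gene][1]
    assert cds is not None
    return cds + 3 * (aa - 1)


@lru_cache(maxsize=1)
def synthetic_panel() -> PanelDesign:
    """Build the bundled synthetic panel (deterministic, cached)."""
    rng = np.random.default_rng(_SEQ_SEED)
    records: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int, int]]] = {}
    gene_map: dict[str, str] = {}

    for gene, (lens, _cds) in _GENE_LAYOUT.items():
        tid = _tid(gene)
        length = sum(lens)
        seq = rng.choice(list("ACGT"), size=length)
        seq = "".join(seq)
        # plant hotspot reference codons
        for aa, codon in _PLANTED_CODONS.get(gene, {}).items():
            pos = _codon_pos(gene, aa)
            seq = seq[:pos] + codon + seq[pos + 3 :]
        records[tid] = seq
        bounds = []
        pos = 0
        for i, ln in enumerate(lens, start=1):
            bounds.append((i, pos, pos + ln))
            pos += ln
        exons[tid] = bounds
        gene_map[tid] = gene
    transcriptome = Transcriptome(records=records, exons=exons, gene=gene_map)

    primers: list[PrimerRecord] = []
    fragments: list[TargetFragment] = []

    def add_primer(name: str, gene: str, start: int, covered: bool = False):
        tid = _tid(gene)
        seq = records[tid][start : start + _PRIMER_LEN]
        primers.append(PrimerRecord(name, gene, tid, start, seq))
        if not covered:
            end = min(start + _PRIMER_LEN + _COV_LEN, len(records[tid]))
            fragments.append(TargetFragment(
                f"{name}_cov", gene, tid, start + _PRIMER_LEN, end, "hotspot-region"))

    # expression / referee fragments with their single counted primer
    for gene, (e1, e2, role) in _COUNTED_FRAGMENTS.items():
        tid = _tid(gene)
        start, _ = transcriptome.exon_bounds(tid, e1)
        _, end = transcriptome.exon_bounds(tid, e2)
        fragments.append(TargetFragment(f"{gene}_e{e1}_{e2}", gene, tid, start, end, role))
        add_primer(f"{gene}_e{e1}", gene, start, covered=True)

    # hotspot primers (placed ~45 nt upstream of the first hotspot codon)
    hotspot_primers = {
        "FGFR1": {"N546": 1620},
        "FGFR2": {"F276": 804, "C382": 1122, "I547": 1617},
        "FGFR3": {"K650": 1935},
        "FGFR4": {"G388": 1137},
        "ERBB2": {"S310": 912, "R678": 2016},
        "IDH1": {"R132": 363},
        "IDH2": {"R140": 393, "R172": 489},
        "KRAS": {"g12": 0, "q61": 145, "a146": 400},
        "NRAS": {"g12": 0, "q61": 145},
        "BRAF": {"V600": 1774},
        "PIK3CA": {"helical": 1602, "kinase": 3117},
    }
    region_fragments = {  # named hotspot regions quoted in the panel description
        "KRAS": ("KRAS_e2_4", 2, 4),
        "NRAS": ("NRAS_e2_3", 2, 3),
        "BRAF": ("BRAF_e15", 15, 15),
    }
    for gene, (label, e1, e2) in region_fragments.items():
        tid = _tid(gene)
        start, _ = transcriptome.exon_bounds(tid, e1)
        _, end = transcriptome.exon_bounds(tid, e2)
        fragments.append(TargetFragment(label, gene, tid, start, end, "hotspot-region"))
    for gene, table in hotspot_primers.items():
        covered = gene in region_fragments
        for tag, start in table.items():
            add_primer(f"{gene}_{tag}", gene, start, covered=covered)
    for gene, starts in _FILLER_PRIMERS.items():
        for i, start in enumerate(starts, start=1):
            add_primer(f"{gene}_f{i}", gene, start)

    # hotspot codon entries
    entries: list[HotspotEntry] = []
    for gene, codons in _PLANTED_CODONS.items():
        tid = _tid(gene)
        for aa, codon in sorted(codons.items()):
            pos = _codon_pos(gene, aa)
            ref_aa = str(Seq(codon).translate())
            entries.append(HotspotEntry(gene, tid, pos, pos + 3,
                                        f"{gene} p.{ref_aa}{aa}", aa_pos=aa))
    cds_start = {_tid(g): c for g, (_lens, c) in _GENE_LAYOUT.items() if c is not None}
    hotspots = HotspotSet(entries=entries, cds_start=cds_start)

    # fusion anchors: FGFR2 breakpoints after exon 17 / at the start of exon 18
    anchors = []
    for gene, exon in [("FGFR1", 17), ("FGFR3", 14), ("FGFR4", 14)]:
        tid = _tid(gene)
        _, end = transcriptome.exon_bounds(tid, exon)
        anchors.append(FusionAnchor(gene, exon, end, tid))
    tid = _tid("FGFR2")
    _, e17_end = transcriptome.exon_bounds(tid, 17)
    e18_start, _ = transcriptome.exon_bounds(tid, 18)
    anchors.append(FusionAnchor("FGFR2", 17, e17_end, tid))
    anchors.append(FusionAnchor("FGFR2", 18, e18_start, tid))

    panel = PanelDesign(transcriptome, primers, fragments, hotspots, anchors)
    errors = panel.validate()
    if errors:  # pragma: no cover - construction bug guard
        raise AssertionError("synthetic panel failed validation:\n" + "\n".join(errors))
    return panel


def write_synthetic_panel(directory: str) -> str:
    """Write the bundled panel to *directory*; returns the YAML config path."""
    return write_panel(synthetic_panel(), directory)


def primer_category_counts(panel: PanelDesign) -> dict[str, int]:
    """Primer counts per panel category (gene groups of the panel design)."""
    groups = {
        "FGFR1-4": ("FGFR1", "FGFR2", "FGFR3", "FGFR4"),
        "IDH1/2": ("IDH1", "IDH2"),
        "ERBB2": ("ERBB2",),
        "KRAS/NRAS": ("KRAS", "NRAS"),
        "BRAF": ("BRAF",),
        "PIK3CA": ("PIK3CA",),
        "PD-L1": ("CD274",),
        "referee": ("DDX23", "GOLGA5", "SEL1L"),
    }
    counts = {}
    for label, genes in groups.items():
        counts[label] = sum(1 for p in panel.primers if p.gene in genes)
    return counts
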