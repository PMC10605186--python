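"""Panel model: transcriptome, primers, target fragments, hotspots.

The panel is defined entirely in transcript space.  All coordinates are
0-based, half-open; 1-based coordinates appear only in SAM/VCF emissions.

An anchored-PCR (3' RACE) panel couples one gene-specific primer per
target region with a universal adapter primer, so each gene-specific
primer must on its own be specific to a single locus.  The panel object
validates primer/transcriptome consistency and exposes the queries the
rest of the pipeline needs: fragment lookup, hotspot lookup, fusion
anchors, and a primer specificity screen.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp

# Fixed oligos of the library chemistry.  The reverse-transcription primer
# carries a 10-nt random 3' end (the "decamer") whose mismatches against the
# template serve as pseudo-UMIs downstream.
RT_PRIMER_TAIL = "GTTCAGACGTGTGCTCTTCCGATCT"
RT_PRIMER = RT_PRIMER_TAIL + "N" * 10  # R10_AD2
INDEX_PRIMER_7 = "CAAGCAGAAGACGGCATACGAGAT{index}GTGACTGGAGTTCAGACGTGTGCTCTTCC"
LIBRARY_PRIMER = "CAAGCAGAAGACGGCATACG"  # AMP-PCR2s
INDEX_PRIMER_5 = "AATGATACGGCGACCACCGAGATCTACAC{index}ACACTCTTTCCCTACACGACGCTCTTCC"

PRIMER_MIN_LEN = 18
PRIMER_MAX_LEN = 35

REFEREE_GENES = ("DDX23", "GOLGA5", "SEL1L")
EXPRESSION_GENES = ("ERBB2", "FGFR1", "FGFR2", "FGFR3", "FGFR4", "CD274")

FRAGMENT_ROLES = ("expression-target", "referee", "hotspot-region", "fusion-anchor")

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class PanelError(ValueError):
    """Raised when a panel definition fails validation."""


@dataclass
class Transcriptome:
    """Panel transcript sequences with exon structure and gene symbols.

    ``exons[tid]`` is an ordered list of ``(exon_number, start, end)`` in
    transcript coordinates; the intervals must tile ``[0, len)`` contiguously.
    """

    records: dict[str, str]
    exons: dict[str, list[tuple[int, int, int]]]
    gene: dict[str, str]

    def validate(self) -> list[str]:
        errors = []
        for tid, seq in self.records.items():
            if tid not in self.exons:
                errors.append(f"transcript {tid} has no exon annotation")
                continue
            if tid not in self.gene:
                errors.append(f"transcript {tid} has no gene symbol")
            pos = 0
            for i, (num, start, end) in enumerate(self.exons[tid], start=1):
                if num != i:
                    errors.append(f"{tid}: exon numbers not consecutive at {num}")
                if start != pos or end <= start:
                    errors.append(f"{tid}: exons do not tile transcript at exon {num}")
                    break
                pos = end
            else:
                if pos != len(seq):
                    errors.append(f"{tid}: exons cover {pos} nt but transcript is {len(seq)} nt")
        for tid in self.exons:
            if tid not in self.records:
                errors.append(f"exon table names unknown transcript {tid}")
        return errors

    def transcripts_of_gene(self, gene: str) -> list[str]:
        return [tid for tid, g in self.gene.items() if g == gene]

    def exon_containing(self, tid: str, pos: int) -> Optional[int]:
        for num, start, end in self.exons[tid]:
            if start <= pos < end:
                return num
        return None

    def exon_bounds(self, tid: str, exon_number: int) -> tuple[int, int]:
        for num, start, end in self.exons[tid]:
            if num == exon_number:
                return start, end
        raise KeyError(f"{tid} has no exon {exon_number}")


@dataclass
class PrimerRecord:
    """A gene-specific enrichment primer, sense on the mRNA."""

    name: str
    gene: str
    transcript_id: str
    start: int
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class TargetFragment:
    label: str
    gene: str
    transcript_id: str
    start: int
    end: int
    role: str


@dataclass
class HotspotEntry:
    """A mutational hotspot: either a single codon or a wider region.

    ``aa_pos`` is set for codon hotspots (e.g. IDH1 R132); region entries
    (e.g. KRAS exons 2-4) cover an interval and leave it ``None``.
    """

    gene: str
    transcript_id: str
    start: int
    end: int
    label: str
    aa_pos: Optional[int] = None

    def contains(self, tid: str, pos: int) -> bool:
        return tid == self.transcript_id and self.start <= pos < self.end


@dataclass
class HotspotSet:
    entries: list[HotspotEntry]
    cds_start: dict[str, int]

    def lookup(self, tid: str, pos: int) -> Optional[HotspotEntry]:
        for entry in self.entries:
            if entry.contains(tid, pos):
                return entry
        return None


@dataclass
class FusionAnchor:
    gene: str
    exon_number: int
    boundary: int  # transcript coordinate of the breakpoint junction
    transcript_id: str = ""


@dataclass
class SpecificityReport:
    primer: str
    on_target_site: Optional[tuple[str, int]]
    offtarget_sites: list[tuple[str, int, int]]  # (transcript, seed start, mismatches)
    tm_celsius: float

    @property
    def specific(self) -> bool:
        return len(self.offtarget_sites) == 0


@dataclass
class PanelDesign:
    transcriptome: Transcriptome
    primers: list[PrimerRecord]
    fragments: list[TargetFragment]
    hotspots: HotspotSet
    fusion_anchors: list[FusionAnchor]
    _primer_by_name: dict[str, PrimerRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._primer_by_name = {p.name: p for p in self.primers}

    def primer(self, name: str) -> PrimerRecord:
        return self._primer_by_name[name]

    def primers_for_gene(self, gene: str) -> list[PrimerRecord]:
        return [p for p in self.primers if p.gene == gene]

    def fragments_on(self, tid: str) -> list[TargetFragment]:
        return [f for f in self.fragments if f.transcript_id == tid]

    def anchors_for(self, gene: str) -> list[FusionAnchor]:
        return [a for a in self.fusion_anchors if a.gene == gene]

    # -- validation ---------------------------------------------------

    def validate(self) -> list[str]:
        errors = list(self.transcriptome.validate())
        seqs = self.transcriptome.records
        gene_of = self.transcriptome.gene

        seen = set()
        for p in self.primers:
            if p.name in seen:
                errors.append(f"duplicate primer name {p.name}")
            seen.add(p.name)
            if not (PRIMER_MIN_LEN <= len(p.sequence) <= PRIMER_MAX_LEN):
                errors.append(f"primer {p.name}: length {len(p.sequence)} outside 18-35 nt")
            if p.transcript_id not in seqs:
                errors.append(f"primer {p.name}: unknown transcript {p.transcript_id}")
                continue
            ref = seqs[p.transcript_id][p.start:p.end]
            if ref != p.sequence:
                errors.append(
                    f"primer {p.name}: sequence mismatch vs transcriptome at "
                    f"{p.transcript_id}:{p.start} (expected {ref!r}, observed {p.sequence!r})"
                )
            frag_genes = {f.gene for f in self.fragments}
            if p.gene not in frag_genes:
                errors.append(f"primer {p.name}: gene {p.gene} has no target fragment")

        for f in self.fragments:
            if f.role not in FRAGMENT_ROLES:
                errors.append(f"fragment {f.label}: unknown role {f.role}")
            if f.transcript_id not in seqs:
                errors.append(f"fragment {f.label}: unknown transcript {f.transcript_id}")
            elif not (0 <= f.start < f.end <= len(seqs[f.transcript_id])):
                errors.append(f"fragment {f.label}: interval outside transcript bounds")

        # Exactly three referee fragments, one per referee gene.
        referees = [f for f in self.fragments if f.role == "referee"]
        ref_genes = sorted(f.gene for f in referees)
        if ref_genes != sorted(REFEREE_GENES):
            missing = sorted(set(REFEREE_GENES) - set(ref_genes))
            errors.append(
                f"expected exactly three referee fragments {REFEREE_GENES}, "
                f"found {ref_genes or 'none'}; missing {missing}"
            )

        # One expression fragment per expression-target gene.
        expr = [f for f in self.fragments if f.role == "expression-target"]
        for gene in {f.gene for f in expr}:
            if sum(1 for f in expr if f.gene == gene) != 1:
                errors.append(f"gene {gene} has more than one expression fragment")

        labels = [e.label for e in self.hotspots.entries]
        if len(labels) != len(set(labels)):
            errors.append("hotspot labels are not unique")
        for e in self.hotspots.entries:
            if e.transcript_id not in seqs:
                errors.append(f"hotspot {e.label}: unknown transcript {e.transcript_id}")
            elif not (0 <= e.start < e.end <= len(seqs[e.transcript_id])):
                errors.append(f"hotspot {e.label}: coordinates outside transcript")

        for a in self.fusion_anchors:
            if a.transcript_id not in seqs:
                errors.append(f"fusion anchor {a.gene}: unknown transcript {a.transcript_id}")

        # The FGFR2 primary anchor must sit at the 3' end of exon 17.
        fgfr2 = [a for a in self.fusion_anchors if a.gene == "FGFR2" and a.exon_number == 17]
        for a in fgfr2:
            _, e17_end = self.transcriptome.exon_bounds(a.transcript_id, 17)
            if a.boundary != e17_end:
                errors.append(
                    f"FGFR2 anchor boundary {a.boundary} is not the 3' end of exon 17 ({e17_end})"
                )
        return errors


# ---------------------------------------------------------------------------
# queries


def fragment_for(gene: str, panel: PanelDesign) -> TargetFragment:
    """Return the unique expression/referee fragment counted for *gene*."""
    hits = [
        f for f in panel.fragments
        if f.gene == gene and f.role in ("expression-target", "referee")
    ]
    if not hits:
        raise KeyError(f"gene {gene} has no expression or referee fragment in the panel")
    if len(hits) > 1:
        raise PanelError(f"gene {gene} has {len(hits)} countable fragments; expected one")
    return hits[0]


def _seed_matches(seed: str, window: str, max_mm: int) -> int:
    """Mismatch count of an IUPAC seed vs an ACGT window, or -1 if > max_mm."""
    mm = 0
    for s, w in zip(seed, window):
        if w not in IUPAC_SETS.get(s, ""):
            mm += 1
            if mm > max_mm:
                return -1
    return mm


def screen_primer_specificity(
    primer: PrimerRecord,
    transcriptome: Transcriptome,
    seed_len: int = 12,
    max_offtarget_mismatches: int = 1,
) -> SpecificityReport:
    """Scan the transcriptome for sites the primer's 3'-terminal seed can prime.

    Anchored PCR relies on every gene-specific primer being individually
    specific, so any additional site whose sequence matches the 3' seed with
    at most ``max_offtarget_mismatches`` mismatches is reported as off-target.
    Matching is on the mRNA sense strand, which is where a 3' RACE enrichment
    primer anneals (on the first-strand cDNA).
    """
    if len(primer.sequence) < seed_len:
        raise PanelError(f"primer {primer.name} shorter than seed length {seed_len}")
    n_degenerate = sum(1 for b in primer.sequence if b not in "ACGT")
    if n_degenerate > 2:
        raise PanelError(
            f"primer {primer.name} has {n_degenerate} degenerate bases; at most 2 supported"
        )
    seed = primer.sequence[-seed_len:]
    on_target = (primer.transcript_id, primer.end - seed_len)
    on_target_found = None
    offtargets = []
    for tid, seq in transcriptome.records.items():
        for pos in range(len(seq) - seed_len + 1):
            mm = _seed_matches(seed, seq[pos : pos + seed_len], max_offtarget_mismatches)
            if mm < 0:
                continue
            if (tid, pos) == on_target:
                on_target_found = (tid, pos)
            else:
                offtargets.append((tid, pos, mm))
    tm = round(float(MeltingTemp.Tm_NN(Seq(primer.sequence.replace("N", "A")))), 1)
    return SpecificityReport(
        primer=primer.name,
        on_target_site=on_target_found,
        offtarget_sites=offtargets,
        tm_celsius=tm,
    )


# ---------------------------------------------------------------------------
# serialization

_EXON_COLS = ["transcript", "start", "end", "exon_number"]
_PRIMER_COLS = ["name", "gene", "transcript", "start", "sequence"]
_FRAGMENT_COLS = ["label", "gene", "transcript", "start", "end", "role"]
_HOTSPOT_COLS = ["gene", "transcript", "start", "end", "label", "aa_pos"]


def write_panel(panel: PanelDesign, directory: str) -> str:
    """Write a panel to *directory* as FASTA + TSV tables + a YAML config.

    Returns the path of the YAML config, suitable for :func:`load_panel`.
    """
    os.makedirs(directory, exist_ok=True)
    fasta = os.path.join(directory, "transcriptome.fa")
    records = [
        SeqRecord(Seq(seq), id=tid, description=panel.transcriptome.gene[tid])
        for tid, seq in sorted(panel.transcriptome.records.items())
    ]
    SeqIO.write(records, fasta, "fasta")

    def _tsv(name, header, rows):
        path = os.path.join(directory, name)
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    exon_rows = [
        (tid, start, end, num)
        for tid in sorted(panel.transcriptome.exons)
        for num, start, end in panel.transcriptome.exons[tid]
    ]
    exons = _tsv("exons.tsv", _EXON_COLS, exon_rows)
    _tsv("primers.tsv", _PRIMER_COLS,
         [(p.name, p.gene, p.transcript_id, p.start, p.sequence) for p in panel.primers])
    _tsv("fragments.tsv", _FRAGMENT_COLS,
         [(f.label, f.gene, f.transcript_id, f.start, f.end, f.role) for f in panel.fragments])
    _tsv("hotspots.tsv", _HOTSPOT_COLS,
         [(e.gene, e.transcript_id, e.start, e.end, e.label,
           e.aa_pos if e.aa_pos is not None else ".") for e in panel.hotspots.entries])

    config = {
        "fasta": "transcriptome.fa",
        "exons": "exons.tsv",
        "primers": "primers.tsv",
        "fragments": "fragments.tsv",
        "hotspots": "hotspots.tsv",
        "genes": dict(sorted(panel.transcriptome.gene.items())),
        "cds_start": dict(sorted(panel.hotspots.cds_start.items())),
        "fusion_anchors": [
            {"gene": a.gene, "exon": a.exon_number,
             "boundary": a.boundary, "transcript": a.transcript_id}
            for a in panel.fusion_anchors
        ],
    }
    config_path = os.path.join(directory, "panel.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path


def _read_tsv(path: str, columns: list[str]) -> list[dict]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != columns:
            raise PanelError(f"{path}: expected columns {columns}, found {header}")
        rows = []
        for line in fh:
            if line.strip():
                rows.append(dict(zip(columns, line.rstrip("\n").split("\t"))))
    return rows


def load_panel(config_path: str, strict: bool = True) -> PanelDesign:
    """Load and validate a panel definition from its YAML config.

    With ``strict=True`` (default) any validation error is fatal; with
    ``strict=False`` the panel is returned and errors can be inspected via
    :meth:`PanelDesign.validate`.
    """
    base = os.path.dirname(os.path.abspath(config_path))
    with open(config_path) as fh:
        config = yaml.safe_load(fh)

    def _path(key):
        return os.path.join(base, config[key])

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(_path("fasta"), "fasta")}
    exons: dict[str, list[tuple[int, int, int]]] = {}
    for row in _read_tsv(_path("exons"), _EXON_COLS):
        exons.setdefault(row["transcript"], []).append(
            (int(row["exon_number"]), int(row["start"]), int(row["end"]))
        )
    for tid in exons:
        exons[tid].sort()
    gene_map = {str(k): str(v) for k, v in config["genes"].items()}
    missing = sorted(set(gene_map) - set(exons)) + sorted(set(gene_map) - set(seqs))
    if missing:
        raise PanelError(f"transcripts named in config but missing from inputs: {missing[0]}")
    transcriptome = Transcriptome(records=seqs, exons=exons, gene=gene_map)

    primers = [
        PrimerRecord(row["name"], row["gene"], row["transcript"],
                     int(row["start"]), row["sequence"].upper())
        for row in _read_tsv(_path("primers"), _PRIMER_COLS)
    ]
    fragments = [
        TargetFragment(row["label"], row["gene"], row["transcript"],
                       int(row["start"]), int(row["end"]), row["role"])
        for row in _read_tsv(_path("fragments"), _FRAGMENT_COLS)
    ]
    entries = [
        HotspotEntry(row["gene"], row["transcript"], int(row["start"]), int(row["end"]),
                     row["label"], None if row["aa_pos"] == "." else int(row["aa_pos"]))
        for row in _read_tsv(_path("hotspots"), _HOTSPOT_COLS)
    ]
    hotspots = HotspotSet(entries=entries,
                          cds_start={str(k): int(v) for k, v in config["cds_start"].items()})
    anchors = [
        FusionAnchor(a["gene"], int(a["exon"]), int(a["boundary"]), a["transcript"])
        for a in config.get("fusion_anchors", [])
    ]
    panel = PanelDesign(transcriptome, primers, fragments, hotspots, anchors)
    errors = panel.validate()
    if errors and strict:
        raise PanelError("panel validation failed:\n  " + "\n  ".join(errors))
    return panel
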