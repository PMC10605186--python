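"""Paired-read simulator for the 3' RACE library architecture.

Each unique template corresponds to one reverse-transcription event:

1. a source transcript copy is drawn by expression weight (per primer,
   so every enrichment primer samples the transcript pool independently,
   as in the real multiplex reaction), with variants applied at their
   allele fractions and fusion templates built as the anchor gene up to
   the anchor boundary joined to the partner sequence;
2. an RT priming site is drawn downstream of the enrichment primer from
   the insert-length distribution;
3. the 10-nt decamer actually written into the molecule is the template
   10-mer mutated at ``rt_mismatch_rate`` per base -- these written bases
   REPLACE the template bases and create the pseudo-UMI signal;
4. the molecule is PCR-replicated ``Geometric(dup_geometric_p)`` times
   (support >= 1) and each replicate is sequenced 2 x 150 with
   independent per-base errors.  R1 starts at the enrichment primer 5'
   end reading sense; R2 starts at the decamer reading antisense; both
   read through into the adapters when the insert is shorter than 150.

Identical seeds give byte-identical output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import INDEX_PRIMER_5, INDEX_PRIMER_7, RT_PRIMER_TAIL, PanelDesign, PrimerRecord

READ_LEN = 150
DECAMER_LEN = 10
BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# adapter read-through, in read orientation (after the insert ends)
_I7_INDEX = "ATCACGAT"
_I5_INDEX = "CGATGTTT"
R1_ADAPTER = revcomp(RT_PRIMER_TAIL)  # AGATCGGAAGAGC... seen at the R1 3' end
# the index primer overlaps all but the last 5 nt of the RT tail, so the
# sense strand past the insert is AGATC + the reverse complement of it
_R1_TAIL = "AGATC" + revcomp(INDEX_PRIMER_7.format(index=_I7_INDEX))
R2_ADAPTER = revcomp(INDEX_PRIMER_5.format(index="")[29:])  # read-1 primer region, RC
_R2_TAIL = R2_ADAPTER + revcomp(_I5_INDEX) + revcomp(INDEX_PRIMER_5.format(index="")[:29])

BASE_QUAL = 30  # constant baseline quality
ERROR_QUAL = 14  # quality assigned to half of the miscalled bases


@dataclass
class VariantSpec:
    transcript_id: str
    position: int
    ref: str
    alt: str  # same-length substitution, or insertion/deletion (<= 10 nt)
    allele_fraction: float


@dataclass
class FusionSpec:
    anchor_gene: str
    anchor_exon: int
    partner_transcript: Optional[str] = None
    partner_breakpoint: int = 0
    partner_sequence: Optional[str] = None  # overrides transcript lookup
    fusion_fraction: float = 0.0


@dataclass
class TruthModel:
    """Study conditions for one simulated sample."""

    expression_weights: dict[str, float] = field(default_factory=dict)
    variants: list[VariantSpec] = field(default_factory=list)
    fusions: list[FusionSpec] = field(default_factory=list)
    n_templates: int = 10_000
    dup_geometric_p: float = 0.5
    seq_error_rate: float = 0.001
    rt_mismatch_rate: float = 0.1
    insert_mean: float = 120.0
    insert_sd: float = 30.0
    insert_min: int = 50
    insert_max: int = 240
    seed: int = 0

    def validate(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        for v in self.variants:
            if not 0 <= v.allele_fraction <= 1:
                raise ValueError(f"allele fraction {v.allele_fraction} outside [0, 1]")
        for f in self.fusions:
            if not 0 <= f.fusion_fraction <= 1:
                raise ValueError(f"fusion fraction {f.fusion_fraction} outside [0, 1]")
        if self.expression_weights:
            w = list(self.expression_weights.values())
            if min(w) < 0 or max(w) == 0:
                raise ValueError("expression weights must be >= 0 and not all zero")


@dataclass
class TemplateRecord:
    template_id: str
    primer: str
    transcript_id: str
    rt_coord: int  # transcript coordinate where the written decamer begins
    umi: str  # decamer as written into the molecule (sense orientation)
    umi_mismatch_positions: tuple[int, ...]
    dup_count: int
    variants: tuple[str, ...]
    fusion: str  # partner transcript id, or ""


TruthLedger = list[TemplateRecord]

LEDGER_COLUMNS = [
    "template_id", "primer", "transcript", "rt_coord", "umi",
    "umi_mismatch_positions", "dup_count", "variants", "fusion",
]


@dataclass
class SimulatedSample:
    reads: list[tuple[str, str, str, str, str]]  # (id, r1, q1, r2, q2)
    ledger: TruthLedger

    @property
    def n_pairs(self) -> int:
        return len(self.reads)


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    if len(positions) == 0:
        return seq
    out = list(seq)
    for pos in positions:
        base = out[pos]
        choices = [b for b in "ACGT" if b != base]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def _apply_variants(
    seq: str, variants: Sequence[VariantSpec], rng: np.random.Generator
) -> tuple[str, list[str]]:
    """Apply each variant independently at its allele fraction.

    Variants are applied right-to-left so indels do not shift the
    coordinates of variants upstream of them.
    """
    applied = []
    for v in sorted(variants, key=lambda v: -v.position):
        if rng.random() >= v.allele_fraction:
            continue
        if seq[v.position : v.position + len(v.ref)] != v.ref:
            raise ValueError(
                f"variant ref {v.ref!r} does not match template at "
                f"{v.transcript_id}:{v.position}"
            )
        seq = seq[: v.position] + v.alt + seq[v.position + len(v.ref) :]
        applied.append(f"{v.transcript_id}:{v.position}:{v.ref}>{v.alt}")
    return seq, applied[::-1]


def simulate_sample(panel: PanelDesign, truth: TruthModel) -> SimulatedSample:
    """Generate one sample's read pairs plus the ground-truth ledger."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    tr = panel.transcriptome

    weights = truth.expression_weights or {g: 1.0 for g in set(tr.gene.values())}
    for v in truth.variants:
        if v.transcript_id not in tr.records:
            raise ValueError(f"variant transcript {v.transcript_id} not in panel")
    fusion_by_gene: dict[str, FusionSpec] = {}
    for f in truth.fusions:
        partner = f.partner_sequence
        if partner is None:
            if f.partner_transcript not in tr.records:
                raise ValueError(f"fusion partner {f.partner_transcript} not in panel")
            partner = tr.records[f.partner_transcript][f.partner_breakpoint :]
        if len(partner) < 25:
            raise ValueError("fusion partner sequence shorter than 25 nt is undetectable")
        fusion_by_gene[f.anchor_gene] = f

    # per-primer sampling weights proportional to gene abundance
    primers = [p for p in panel.primers if weights.get(p.gene, 0.0) > 0]
    if not primers:
        raise ValueError("no primer has positive expression weight")
    pw = np.array([weights[p.gene] for p in primers], dtype=float)
    pw /= pw.sum()

    variants_by_tid: dict[str, list[VariantSpec]] = {}
    for v in truth.variants:
        variants_by_tid.setdefault(v.transcript_id, []).append(v)

    reads = []
    ledger: TruthLedger = []
    primer_idx = rng.choice(len(primers), size=truth.n_templates, p=pw)
    for t in range(truth.n_templates):
        p: PrimerRecord = primers[primer_idx[t]]
        template = tr.records[p.transcript_id]
        fusion_tag = ""
        fspec = fusion_by_gene.get(p.gene)
        if fspec is not None and rng.random() < fspec.fusion_fraction:
            anchors = [a for a in panel.anchors_for(p.gene) if a.exon_number == fspec.anchor_exon]
            if not anchors:
                raise ValueError(f"no anchor for {p.gene} exon {fspec.anchor_exon}")
            boundary = anchors[0].boundary
            if p.start < boundary:
                partner = fspec.partner_sequence
                if partner is None:
                    partner = tr.records[fspec.partner_transcript][fspec.partner_breakpoint :]
                template = template[:boundary] + partner
                fusion_tag = fspec.partner_transcript or "custom"
        template, applied = _apply_variants(
            template, variants_by_tid.get(p.transcript_id, []), rng
        )

        insert_len = int(round(rng.normal(truth.insert_mean, truth.insert_sd)))
        insert_len = max(truth.insert_min, min(truth.insert_max, insert_len))
        # rt_coord: transcript coordinate where the written decamer begins
        rt_coord = p.start + insert_len - DECAMER_LEN
        rt_coord = min(rt_coord, len(template) - DECAMER_LEN)
        rt_coord = max(rt_coord, p.end)

        ref10 = template[rt_coord : rt_coord + DECAMER_LEN]
        mism = np.flatnonzero(rng.random(DECAMER_LEN) < truth.rt_mismatch_rate)
        written10 = _mutate(ref10, mism, rng)
        insert = template[p.start : rt_coord] + written10

        dup_count = int(rng.geometric(truth.dup_geometric_p))
        template_id = f"T{t:06d}"
        ledger.append(TemplateRecord(
            template_id=template_id,
            primer=p.name,
            transcript_id=p.transcript_id,
            rt_coord=rt_coord,
            umi=written10,
            umi_mismatch_positions=tuple(int(i) for i in mism),
            dup_count=dup_count,
            variants=tuple(applied),
            fusion=fusion_tag,
        ))

        r1_full = (insert + _R1_TAIL)[:READ_LEN]
        r2_full = (revcomp(insert) + _R2_TAIL)[:READ_LEN]
        for d in range(dup_count):
            pair_id = f"{template_id}.{d}"
            r1, q1 = _sequence(r1_full, truth.seq_error_rate, rng)
            r2, q2 = _sequence(r2_full, truth.seq_error_rate, rng)
            reads.append((pair_id, r1, q1, r2, q2))
    return SimulatedSample(reads=reads, ledger=ledger)


def _sequence(seq: str, error_rate: float, rng: np.random.Generator) -> tuple[str, str]:
    qual = np.full(len(seq), BASE_QUAL, dtype=int)
    if error_rate > 0:
        errs = np.flatnonzero(rng.random(len(seq)) < error_rate)
        if len(errs):
            seq = _mutate(seq, errs, rng)
            low = errs[rng.random(len(errs)) < 0.5]
            qual[low] = ERROR_QUAL
    qstr = "".join(chr(q + 33) for q in qual)
    return seq, qstr


# ---------------------------------------------------------------------------
# IO


def write_fastq(sample: SimulatedSample, path_r1: str, path_r2: str) -> None:
    def _open(path):
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open(path_r1) as f1, _open(path_r2) as f2:
        for rid, r1, q1, r2, q2 in sample.reads:
            f1.write(f"@{rid}/1\n{r1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{q2}\n")


def read_fastq_pair(path_r1: str, path_r2: str) -> list[tuple[str, str, str, str, str]]:
    def _read(path):
        opener = gzip.open if path.endswith(".gz") else open
        out = []
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline().strip()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                out.append((header[1:].split("/")[0].split()[0], seq, qual))
        return out

    r1s, r2s = _read(path_r1), _read(path_r2)
    if len(r1s) != len(r2s):
        raise ValueError("R1 and R2 FASTQ files have different read counts")
    reads = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1s, r2s):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1} vs {id2}")
        reads.append((id1, s1, q1, s2, q2))
    return reads


def write_truth(ledger: TruthLedger, path: str) -> None:
    """Write the ledger as a 9-column TSV (deterministic column order)."""
    rows = [
        (r.template_id, r.primer, r.transcript_id, r.rt_coord, r.umi,
         ",".join(str(i) for i in r.umi_mismatch_positions) or ".",
         r.dup_count, ";".join(r.variants) or ".", r.fusion or ".")
        for r in ledger
    ]
    df = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> TruthLedger:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ledger = []
    for row in df.itertuples(index=False):
        mism = () if row.umi_mismatch_positions == "." else tuple(
            int(x) for x in row.umi_mismatch_positions.split(","))
        variants = () if row.variants == "." else tuple(row.variants.split(";"))
        ledger.append(TemplateRecord(
            template_id=row.template_id,
            primer=row.primer,
            transcript_id=row.transcript,
            rt_coord=int(row.rt_coord),
            umi=row.umi,
            umi_mismatch_positions=mism,
            dup_count=int(row.dup_count),
            variants=variants,
            fusion="" if row.fusion == "." else row.fusion,
        ))
    return ledger
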