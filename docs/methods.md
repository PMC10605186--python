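# Methods

This note documents the models, algorithms, defaults and known
limitations of the `raceseq` pipeline and its simulator.

## Library model

A 3′ RACE anchored-PCR library is modeled per molecule as:

```
5'- [gene-specific primer] ... template ... [written decamer(10)] [adapter] -3'
```

Reverse transcription is primed by a tailed random decamer
(`GTTCAGACGTGTGCTCTTCCGATCT + N10`). The ten bases the RT primer writes
*replace* the template bases at the priming site: where the annealed
decamer mismatched the mRNA, the molecule carries the primer's base, not
the template's. R1 sequences the molecule sense from the primer's 5′ end;
R2 sequences antisense from the decamer, so the R2 prefix is the reverse
complement of the written decamer. When the insert is shorter than the
150-nt read, both reads run into the (verbatim) adapter/index oligos.

The simulator (`raceseq.simulate`) draws, per template: a source primer
with probability proportional to its gene's abundance weight (every
primer samples the molecule pool independently, as in the real multiplex
reaction); an insert length from a truncated normal (mean 120, SD 30,
min 50, max 240) — consistent with the ~250 bp library size minus
adapters and the 80–150 bp RNA template range of comparable libraries;
decamer mismatches at `rt_mismatch_rate` (default 0.1/base, i.e. ~65% of
decamers carry ≥1 mismatch); a PCR duplicate count from Geometric(p)
with p = 0.5 (mean 2 reads/template), mimicking exponential
amplification with stochastic efficiency; and per-base sequencing errors
at 0.001 on a constant Q30 baseline (half of the miscalled bases get
Q14, as miscalls are often low-quality). Variants apply independently
per template at their allele fraction; fusion templates join the anchor
transcript up to the anchor boundary to the partner sequence. Identical
seeds give byte-identical FASTQ.

What the simulator does *not* model: RNA degradation profiles, DNase
pretreatment, index hopping, primer-dimer artifacts, strand-specific
biases, or non-uniform error spectra. Tests passing on simulated data
therefore demonstrate algorithmic correctness under the stated library
model, not robustness to every FFPE artifact.

## Preprocessing and alignment

R1 must begin with a panel primer (the chemistry guarantees it): the
prefix is matched exactly, then by Hamming distance ≤ 2 with a
unique-best rule; ties and misses are dropped and counted. The R2 10-nt
prefix is recorded as the observed pseudo-UMI. Adapter read-through is
trimmed (exact 10-mer probe; 14-mer probe with one mismatch as
fallback; ≥6-nt exact terminal overlap), and when the R1 adapter is
visible the preceding ten bases (the written decamer) are trimmed too —
they are primer-derived, not template evidence.

Alignment is transcriptome-space only (the panel is transcript-defined;
fusion partners are handled by tail realignment). The aligner is
seed-and-extend: exact 15-mers from a prebuilt index (query stride 5),
diagonal clustering with ±8 indel tolerance, then affine-gap
Smith–Waterman (match +1, mismatch −2, gap open −4, extend −1; a gap of
length L costs open + (L−1)·extend) on a padded window, with unaligned
termini reported as soft clips. Two fast paths bypass the DP without
changing results: a full-length exact match, and an ungapped
max-subarray alignment on a known diagonal, accepted only when the best
window carries ≤2 internal mismatches (this equals the DP whenever no
gap is needed). For the *pileup* path specifically, templates with ≤5
position-wise substitutions are aligned end-to-end (semi-global):
local alignment would clip a true variant sitting within ~2 nt of an
insert edge, eroding VAF next to primers.

Pair-level concordance implements the anchored-PCR constraint: the R1
alignment must start at the assigned primer's 3′-end coordinate ±2 nt
on the primer's transcript, else the pair is flagged improper and
excluded. The deduplication coordinate is the sense-strand end of the
R2 alignment (the RT-priming site), with 3′ soft-clipped bases
extrapolated so edge errors cannot shift it.

## Pseudo-UMI deduplication

Pairs are grouped on (primer, R2 transcript, RT coordinate); pairs
overlapping no panel fragment or hotspot region are discarded and
counted. Within each group, observed decamers are clustered with the
directional adjacency rule (edge u→v iff Hamming(u,v)=1 and
count(u) ≥ 2·count(v)−1; clusters grow from unvisited highest-count
nodes, ties lexicographic). Clustering is per-coordinate — the only
reading consistent with distinguishing "templates with the same
coordinates". The full observed decamer is the UMI (strictly more
informative than mismatch positions alone, and identical when no
mismatch exists).

Each cluster becomes one template with a majority-vote consensus over
member R1 inserts (ties: higher summed base quality, then the reference
base), truncated at the RT coordinate because bases at and beyond it are
RT-primer-derived. Without this truncation, inserts within ~5 nt of the
read length leave the decamer untrimmed and its mismatches accumulate at
a fixed offset downstream of every primer — a reproducible low-VAF
artifact.

**Saturation (known limitation).** Templates sharing an RT coordinate
draw their pseudo-UMIs from the *same* reference decamer, so two
mismatch-free decamers (35% of templates each at rate 0.1) are
indistinguishable and must merge, and directional chains absorb many
1–2-mismatch neighbours. At per-primer occupancies around one template
per effective RT coordinate (~100 coordinates per primer under the
default insert distribution) the under-count is ~10%; at occupancy ~4 it
reaches 30–40%. Template counts are therefore a *lower bound* that
saturates with coverage — the motivation for pseudo-UMIs in the first
place is to soften, not eliminate, this under-count. Downstream
consequences: VAF estimates stay nearly unbiased (both alleles lose
templates at almost the same rate; the residual bias measured at
occupancy ≲1 is under 0.01), but referee-normalized expression values
compress at the top of the dynamic range (a 4× abundance spike reports
~2.9× at 10,000 templates under uniform background). Expression values
should be read as rank/threshold markers (amplified vs not), not as
unbiased fold changes.

## Variant calling

Calling is template-level (post-dedup), so duplicates cannot inflate
support. Pileup columns cover panel fragments and hotspot regions;
insertions and deletions ≤10 nt are collected as left-anchored events.
Default thresholds: depth ≥ 50 templates, alt ≥ 3 templates, allele mean
quality ≥ Q20, VAF ≥ 2% at annotated hotspots and ≥ 5% elsewhere. The
two-tier VAF floor encodes the assay's purpose: in RNA the mutant allele
of an activating oncogene is typically over-represented relative to its
DNA fraction, so a low hotspot floor buys sensitivity (e.g. a 6.7%
mutant fraction) without flooding the output elsewhere. All thresholds
are configurable; sub-threshold candidates are emitted with filter
reasons (`low_vaf`, `low_qual`) rather than silently dropped. Hotspot
substitutions get HGVS-style protein labels from the panel's CDS frames
(synonymous changes are unlabelled). VCF 4.2 is emitted with transcript
ids as contigs, 1-based positions, and DP/AD/VAF/HOTSPOT/PCHANGE INFO
fields.

## Fusion calling

A consensus template is a chimeric candidate iff its anchor-gene
alignment ends within ±5 nt of a declared anchor boundary (FGFR2: 3′
end of exon 17 / start of exon 18 — the same coordinate in transcript
space; both classes are declared for fidelity to the assay design) and
carries a 3′ soft clip ≥ 25 nt. Tails are realigned to the whole bundled
transcriptome; unalignable tails are kept with partner UNKNOWN, since
recovering partners absent from any annotation is the point of 3′ RACE.
Calls group on (anchor gene, anchor exon, breakpoint, partner gene,
partner exon) and require ≥5 unique templates with ≥2 distinct
pseudo-UMIs (guarding against clonal artifacts). Names follow the
`GENE5-GENE3 (F17;B3)` convention (first letter of each symbol + exon
numbers; `(F17;?)` for unknown partners).

When the first partner bases coincide with the anchor reference past
the boundary (junction micro-homology), the anchor alignment extends
through the homologous bases and the reported breakpoint shifts
accordingly — the standard split-read ambiguity; all templates of one
fusion shift identically, so calls do not fragment. Reciprocal and
5′-unknown-partner fusions (the ALK/ROS1/RET/NTRK class) are
undetectable by construction of the chemistry.

## Expression and QC

For each gene of interest the unique-template count of its counted
fragment is divided by each referee fragment count; the reported value
is the median of the three ratios (robust to one misbehaving referee).
Ratios are linear; counts are used raw since all counted fragments are
of comparable design length. Any referee at zero marks the sample
not-evaluable. A sample with fewer than 3000 templates after duplicate
removal is a QC failure (strict `< 3000`; values are still computed and
flagged). As an amplification surrogate, values above 5× the cohort
median can be flagged as overexpressed; the factor is a reporting
convention, not a validated clinical cutoff.

## Cohort statistics

The r×2 exact Fisher test enumerates the margin-constrained lattice and
sums the probabilities of all tables no more probable than the observed
one (relative tie tolerance 1e-7) — the two-sided convention of
mainstream statistical environments, which reproduces the published
per-marker p-values at three decimals. Chi-squared is Pearson without
continuity correction; Kruskal–Wallis is tie-corrected with the χ²
approximation; Mann–Whitney U is enumerated exactly (tie-safe) up to
n₁+n₂ ≤ 12 and uses the tie-corrected normal approximation above that.
Not-determined samples are excluded listwise per marker, matching the
published denominators. The published 168-sample marker counts ship as
module data (`raceseq.stats.BTC_MARKER_COUNTS`); the iCCA MSI row sums
to 82 of 83 exactly as printed.

## Bundled synthetic panel

Transcript sequences are random but deterministic (fixed generator
seed); coordinates, not sequences, carry the panel's meaning. Design
choices that matter:

- per-gene primer counts match the published panel composition
  (29/3/9/7/1/17/1/3 = 70);
- hotspot codons are planted with their true reference codons (IDH1
  R132 = CGT, BRAF V600 = GTG, KRAS G12 = GGT, ...), so protein-level
  annotation is internally consistent;
- each counted expression/referee fragment is reachable by exactly one
  primer (other primers of the gene sit ≥260 nt upstream, beyond the
  insert cap), so normalized values estimate abundance ratios directly;
- PIK3CA's seventeen primers tile its helical and kinase hotspot
  regions with staggered offsets, reflecting the redundant hotspot
  coverage the real panel's primer count implies and spreading
  coordinate occupancy at hotspots;
- every gene layout ends in an oversized 3′-UTR-like exon so RT priming
  sites cannot pile up against the transcript end;
- fusion partner genes (BICC1, AHCYL1, VCL, CCDC6, CFAP57, LRBA,
  LRRFIP2, SLMAP, SORBS1, ZMYM4) are present with exon structures deep
  enough to reproduce the observed partner-exon nomenclature (e.g.
  LRBA exon 48).

## Problem sizes used in tests and the acceptance script

Simulated experiments use 3000–12,000 true templates per sample
(6000–24,000 read pairs), 10–20 seeds per condition: fusion performance
at 4500 templates with fusion fraction 0.3 (anchor-primer support ~15
templates per positive sample); VAF recovery at 6000 templates uniform
(≥200-template depth at the tiled PIK3CA hotspot); the low-fraction
IDH1 scenario at 3000 templates with IDH1 abundance raised so its
single primer reaches ~300-template coverage, the per-fragment coverage
a passing clinical sample shows; expression recovery at 10,000
templates. These sizes put each measurement in the intended coverage
regime while keeping a full run in minutes on one CPU.
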