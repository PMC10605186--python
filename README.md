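# raceseq

Targeted RNA-seq analysis for 3′ RACE anchored-PCR panels, built around the
kind of assay used for molecular profiling of biliary tract cancers (BTC):
detection of *FGFR2* fusions with **unknown 3′ partners**, tumor-only calling
of activating hotspot mutations (*IDH1/2*, *KRAS*, *NRAS*, *BRAF*, *PIK3CA*,
*ERBB2*, *FGFR1–4*), and qPCR-like expression measurement of *ERBB2*,
*FGFR1–4* and *PD-L1* against three referee genes — all from one paired-end
library.

## The assay and the analysis problem

Reverse transcription is primed by a tailed random decamer, so every cDNA
molecule ends in a sequencing adapter on the 3′ side; enrichment PCR then
uses one gene-specific primer per target and a universal adapter primer
(anchored multiplex PCR). Consequently:

- **R1** begins with a known enrichment primer and reads toward the
  transcript 3′ end — a chimeric transcript shows up as an anchored
  alignment with a soft-clipped tail belonging to the (possibly unknown)
  partner. For *FGFR2* the breakpoint is conserved: after exon 17, or at
  the start of exon 18.
- **R2** begins with the 10-nt decamer the RT primer wrote into the
  molecule. Because one read end is fixed by the primer, PCR duplicates can
  only be recognized by a *single* coordinate (the RT-priming site), which
  under-counts templates at high coverage. The decamer's mismatches against
  the true mRNA act as a **pseudo-UMI** that separates templates sharing a
  coordinate.
- Expression is measured "qPCR-like": unique-template coverage of one
  fragment per gene of interest, divided by the coverage of three referee
  fragments (*DDX23* e8–9, *GOLGA5* e5–6, *SEL1L* e13–14); the reported
  value is the median of the three ratios. Samples with fewer than 3000
  templates after duplicate removal fail QC.

The package implements the full pipeline (primer/UMI assignment,
seed-and-extend transcriptome alignment, directional pseudo-UMI
deduplication, template-level variant calling, split-read fusion calling,
expression normalization) plus a read simulator that reproduces the library
chemistry with a ground-truth ledger, and the exact cohort statistics
(r×2 Fisher, χ², Kruskal–Wallis, Mann–Whitney U) used for marker-by-subtype
tables.

## Worked example

The bundled synthetic panel (`raceseq.datasets.synthetic_panel()`) mirrors
the real panel's structure: 70 primers (29 *FGFR1–4*, 3 *IDH1/2*, 9 *ERBB2*,
7 *KRAS/NRAS*, 1 *BRAF*, 17 *PIK3CA*, 1 *PD-L1*, 3 referees) on synthetic
transcripts with hotspot codons planted at their true reference codons.

```python
from raceseq.datasets import synthetic_panel
from raceseq.simulate import TruthModel, VariantSpec, FusionSpec, simulate_sample
from raceseq.pipeline import run_pipeline, render_report

panel = synthetic_panel()
truth = TruthModel(
    expression_weights={"FGFR2": 3, "IDH1": 2, "DDX23": 1, "GOLGA5": 1,
                        "SEL1L": 1, "ERBB2": 1, "CD274": 1, "FGFR1": 1,
                        "FGFR3": 1, "FGFR4": 1, "KRAS": 1, "NRAS": 1,
                        "BRAF": 1, "PIK3CA": 1, "IDH2": 1},
    variants=[VariantSpec("IDH1-201", 408, "C", "T", 0.10)],   # IDH1 p.R132C
    fusions=[FusionSpec("FGFR2", 17, partner_transcript="BICC1-201",
                        partner_breakpoint=150, fusion_fraction=0.3)],
    n_templates=12_000, seed=7,
)
sample = simulate_sample(panel, truth)          # 23,981 read pairs
report = run_pipeline(sample.reads, panel, sample_id="demo")
print(render_report(report)[1])
```

```
Sample demo
  fusion   FGFR2-BICC1 (F17;B3)  templates=38
  variant  IDH1 p.R132C  VAF=0.114  depth=175
  expr     ERBB2  1.064
  expr     FGFR1  0.908
  expr     FGFR2  2.468
  expr     FGFR3  1.000
  expr     FGFR4  0.972
  expr     CD274  1.165
  QC       PASS  templates=8999
```

Reading the output: the spiked fusion is recovered and named in the
`GENE5-GENE3 (F17;B3)` convention (anchor exon 17, partner exon 3) with 38
unique supporting templates; the 10% *IDH1* R132C spike-in is called at an
estimated VAF of 0.114 on 175 unique templates; expression values are
referee-normalized ratios (≈1 for genes at referee abundance; *FGFR2* at
weight 3 reports 2.47 — high-abundance values compress slightly because
pseudo-UMI deduplication saturates, see `docs/methods.md`); the sample
passes the 3000-template QC floor with 8999 templates.

The same pipeline is scriptable from the shell:

```bash
raceseq make-panel panel/                 # write the bundled panel to disk
raceseq simulate --panel panel/panel.yaml --seed 7 --out-prefix demo
raceseq run --panel panel/panel.yaml --fastq1 demo_R1.fastq.gz \
            --fastq2 demo_R2.fastq.gz --out-dir results/
raceseq cohort-stats                      # published marker tables + Fisher p
```

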