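# cernaforge

A tested, reusable pipeline for competing-endogenous-RNA (ceRNA) network
analysis of whole-transcriptome count data, built for two-group cell-culture
designs (e.g. amino-acid-treated vs control muscle satellite cells with five
biological replicates per group). It covers the full downstream analysis that
follows read quantification:

1. **Differential expression** of four RNA classes (mRNA, lncRNA, circRNA,
   miRNA) from raw count matrices — median-of-ratios normalization, a
   negative-binomial Wald test, and the standard call rule
   *p* < 0.05 and |log₂FC| ≥ 2;
2. **Miranda-style miRNA target prediction** over mRNA 3'UTRs, lncRNAs and
   circRNAs — strict 5' seed pairing (miRNA positions 2–8, Watson–Crick only),
   alignment score S ≥ 150 with the published Miranda weights, and
   nearest-neighbor duplex free energy ΔG ≤ −30 kcal/mol; circRNAs are
   scanned circularly so backsplice-junction-spanning sites are found;
3. **Co-expression screening** between differential mRNAs and differential
   lncRNAs/circRNAs — Pearson correlation on log-normalized counts, positive
   significant pairs, top 100 by |r|;
4. **ceRNA assembly** — a (sponge, miRNA, mRNA) triad requires the same miRNA
   to target both co-expressed, differential partners; lncRNA and circRNA
   networks are integrated by keeping miRNAs that sponge both classes;
5. **Interaction-network modules and hubs** — MCODE clustering
   (score = density × size = 2E/(N−1), threshold ≥ 5) and degree-ranked hubs;
6. **Hypergeometric gene-set enrichment** with Benjamini–Hochberg q-values,
   plus the comparative 2^−ΔΔCT qPCR fold-change helper.

Because real accession-scale data and live interaction/annotation databases
are out of scope, the package ships a first-class **synthetic data generator**
that emulates the statistical structure this analysis assumes — NB counts
(Var = μ + αμ²) with planted ≥4-fold effects, transcript sequences with
planted full-complement miRNA sites, latent-factor-driven positive
co-expression among ceRNA partners, near-clique interaction modules, and an
enriched gene set — together with a machine-readable ledger of every planted
truth, so every stage is testable for recall, precision, and calibration.

## Worked example

```bash
cerna-forge run-all --seed 42 --outdir demo/
```

runs simulate → DE → targets → co-expression → ceRNA → modules → enrichment
and prints the stage list; `demo/manifest.json` records per-stage row counts
and `demo/evaluation.json` scores the run against the planted truth. With the
default configuration (seed 42) the run reports:

* differential features — mRNA 19 (6 up, 13 down), lncRNA 9, circRNA 9,
  miRNA 6; the planted differential features are all recalled
  (`de_recall_* = 1.0`);
* 12 predicted miRNA sites (4 per transcript class) — exactly the planted
  sites, none spurious (`target_recall = 1.0`): random background sequence
  essentially never reaches S ≥ 150;
* 75 lncRNA–mRNA and 95 circRNA–mRNA significant positive co-expression
  pairs; all 8 planted triads assembled with precision 1.0, and all 8 survive
  three-way integration (their miRNAs sponge both a lncRNA and a circRNA);
* 4 interaction modules recovered with Jaccard 1.0 against the planted
  near-cliques — e.g. a 9-node, 35-edge module scores 2·35/8 = 8.75;
* the planted enriched gene set ranks first with q ≈ 2.7 × 10⁻⁸.

Every stage is also exposed as a library function
(`cernaforge.nb_wald_test`, `scan_transcriptome`, `screen_pairs`,
`build_sponge_network`, `mcode_find_modules`, `enrich`, …) and as an
individual CLI subcommand (`simulate`, `de`, `targets`, `coexpr`, `modules`,
`hubs`, `enrich`, `qpcr`, `run-all`) over plain TSV/FASTA/GMT/SIF files.

## Layout

```
src/cernaforge/
  synthetic.py     planted-truth experiment bundles
  diffexpr.py      size factors, NB Wald test, FPKM, summaries
  targets.py       seed matching, duplex scoring/energy, transcriptome scan
  coexpression.py  Pearson screening, top-k ranking
  cerna.py         triad assembly, network integration, summaries
  netmodules.py    MCODE weights/modules, degree ranking
  enrichment.py    hypergeometric test, BH q-values, 2^-ddCt
  pipeline.py      orchestration, config, manifest, truth evaluation
  io.py            TSV / FASTA / GMT / SIF / JSON readers and writers
  cli.py           click command group
docs/methods.md    model assumptions, parameter choices, limitations
```
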