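# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic generator does and does not emulate, and the design
choices made where the underlying procedure is commonly left unspecified.

## Differential expression

Counts are modelled as negative binomial with the mean–dispersion
parameterization Var = μ + αμ². Libraries are normalized with
median-of-ratios size factors (per sample, the median over features expressed
in all samples of count / gene-wise geometric mean). The test statistic is a
Wald ratio on log₂(fold change), with the fold change computed from
normalized group means plus a pseudocount of ε = 0.5 (zero/zero yields
log₂FC = 0), and its standard error from the delta method with a per-gene
dispersion estimated by method of moments, pooled across the two groups and
floored at 10⁻⁸. The statistic is referred to a *t* distribution with
n₁ + n₂ − 2 degrees of freedom rather than a normal: at five replicates per
group the moment estimate of the dispersion is noisy, and the heavier-tailed
reference keeps the type-I error at its nominal level (Monte-Carlo
calibration over 50 simulated null experiments lands within 0.05 ± 0.015;
the normal reference is anti-conservative at this sample size).

A feature is called differential when *p* < 0.05 (strict) **and**
|log₂FC| ≥ 2 (inclusive) — both arms deliberately literal. No
multiple-testing correction is applied in the default call rule, matching the
raw-p convention of the analysis this pipeline reproduces; a
Benjamini–Hochberg option exists behind the `bh` flag. Exact DESeq-style
dispersion shrinkage is intentionally not reproduced: the accepted surface is
calibration and planted-effect recovery, not equality with a particular
implementation. All four RNA classes are tested from raw counts with the
same machinery.

FPKM is provided as counts × 10⁹ / (column total × length); it is not used
by any decision rule.

## Target prediction

A reportable site must satisfy three criteria.

**Seed.** miRNA positions 2–8 (5'→3') must be Watson–Crick-complementary to
the aligned target window read 3'→5'. "Strict" is interpreted as *no G:U
wobble in the seed*; this is the most common reading and is applied
uniformly (wobble remains allowed, at +1, outside the seed).

**Alignment score.** A local Smith–Waterman alignment of the miRNA against
the reversed site with the published Miranda default weights — match +5,
G:U +1, mismatch −3, gap open −9, gap extend −4 — with substitution scores
doubled at miRNA positions 2–8. Threshold S ≥ 150. A perfect full-length
complement therefore scores 5L + 35; the threshold is reachable only for
miRNAs of length ≥ 23.

**Duplex energy.** Nearest-neighbor stacking free energy over consecutive
paired alignment columns using an embedded Turner-style ΔG°₃₇ table for the
ten unique Watson–Crick stacks (expanded by rotational symmetry), a flat
−1.0 kcal/mol for stacks involving a wobble pair, a duplex initiation
penalty of +4.09 kcal/mol, and +0.5 kcal/mol per base left unpaired between
the first and last paired columns. Terminal-AU penalties and explicit
loop/bulge tables are omitted — the model only needs correct threshold
behavior and strict internal monotonicity (more pairing ⇒ lower ΔG), both of
which are tested. Threshold ΔG ≤ −30 kcal/mol. S and ΔG are per site, not
per transcript pair.

Scanning enumerates every seed-complementary 7-mer on the transcript and
aligns a window of miRNA length + 7 nt ending one base 3' of the seed block.
Coordinates are 1-based inclusive on the transcript's 5'→3' strand.
circRNAs are scanned circularly: the linearized record's backsplice junction
sits between its last and first nucleotide, and the scan sequence is padded
on both sides with wrap-around context so junction-spanning duplexes align
with their full site; such hits are reported once with wrapped coordinates
and a junction flag. Overlapping sites of the same (miRNA, transcript) pair
collapse to the best-S site per region (ties to the leftmost start). The
scanner is verified equal to an all-offsets brute-force scan on short
inputs.

## Co-expression

Pearson correlation on log₂(normalized counts + 1) — the log stabilizes NB
variance and is the conventional scale for correlation work on counts; the
two-sided p-value uses t = r√((n−2)/(1−r²)) with n − 2 df. Pairs are screened
between differential mRNAs and differential lncRNAs (or circRNAs), kept when
raw *p* < 0.05 and (by default) r > 0, ranked by |r| descending with ties
broken by p then identifiers, and truncated to the top 100. The positivity
filter is applied *before* the top-100 cut, so the kept list is the 100
strongest positive relationships. Constant features are skipped with a
logged reason.

## ceRNA assembly

A triad (sponge, miRNA, mRNA) is emitted exactly when (1) the (mRNA, sponge)
pair is in the screened positive co-expression list, (2) the miRNA has a
passing predicted site against both members, and (3) all three members are
significantly differential. Membership in the co-expression list is
*required* — the regulation route alone does not admit a pair. miRNA–target
expression anticorrelation is *not* required by default (the reproduced
analysis reports mixed-direction networks); an `antagonistic` flag enforces
opposite DE direction. Multiple sites of one (miRNA, transcript) pair
collapse to one triad. Integration keeps only triads whose miRNA appears in
at least one lncRNA triad and at least one circRNA triad; it is idempotent.
Output ordering is deterministic: (sponge class, miRNA, sponge, mRNA)
lexicographic. Networks serialize as SIF plus a node-attribute table
(class, direction).

## Interaction modules and hubs

The module score of N nodes with E edges is density × N = 2E/(N(N−1)) × N =
2E/(N−1), on simple graphs without self-loops — this form reproduces all
four reported nine-node module scores (8.75, 5.25, 8.75, 6). Vertex weights
follow MCODE: the highest k-core of the node's closed neighborhood times
that core's density. Module prediction seeds at the highest-weight unvisited
vertex and breadth-first-includes neighbors with weight ≥ seed weight ×
(1 − node_score_cutoff), default cutoff 0.2; visited-flag semantics make
returned modules vertex-disjoint. Modules scoring below 5 are dropped.
Post-processing options "haircut" (prune degree-1 members) and "fluff" are
implemented but off by default, since only the score threshold is part of
the reproduced procedure. Hub ranking is by degree (descending, ties
lexicographic); other centralities are out of scope. The interaction graph
is always an input file — no live database is queried — so identifier
normalization across annotation sources is the caller's responsibility.

## Enrichment and qPCR

Over-representation only: p = P(X ≥ k) for X ~ Hypergeometric(N, K, n),
delegated to scipy's stable implementation and verified against exact
combinatorial enumeration for every universe size ≤ 25. q-values are
Benjamini–Hochberg across the tested sets (the conventional reading of
"q-value"). The universe defaults to all features quantified in the class
under test, at gene level, not the genome. Relative qPCR expression is
2^−ΔΔCT with ΔΔCT = (Ct_t,case − Ct_ref,case) − (Ct_t,ctrl − Ct_ref,ctrl).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, at
desk scale, with every planted object recorded in a truth ledger.

* **Counts**: NB with common dispersion α = 0.05 and gene-wise baseline
  means log-uniform on [20, 2000], so both low- and high-count regimes are
  exercised; 5 replicates per group; per-sample size factors spread
  2^U(−0.25, 0.25) (real library-size variation is unknown, so the spread is
  an explicit parameter rather than a guess). A de_fraction (default 0.05)
  of features has its treated-group mean multiplied by 2^±3 (planted
  |log₂FC| = 3 clears the ≥ 2 call threshold with margin).
* **ceRNA structure**: 8 planted triads in lncRNA/circRNA pairs sharing a
  miRNA and mRNA, so the integrated network is non-empty by construction.
  Triad members are planted differential, with sponge and mRNA sharing a
  direction; co-expression is induced by one shared log-normal latent factor
  per miRNA family (σ = 0.5, multiplicative on the mean), its log offsets
  centered within each group so the factor perturbs correlation but not the
  planted fold change. Feature counts (300/100/100/40) and de_fraction are
  sized so the expected number of competing significant pairs stays below
  the top-100 cut and planted pairs are retained.
* **Sequences**: background transcripts are i.i.d. uniform DNA (FASTA on
  disk; U↔T mapped at the boundary); each planted target pair receives one
  inserted site perfectly complementary to the miRNA's full length. Planted
  miRNAs are drawn at 23–25 nt — the subrange of mature-miRNA lengths for
  which a perfect complement can reach S ≥ 150 — and rejection-sampled until
  the perfect duplex passes both thresholds (a composition-skewed duplex can
  otherwise miss ΔG ≤ −30). circRNA records carry their backsplice junction
  at the linearization boundary; a helper plants junction-spanning sites for
  testing circular-aware scanning.
* **Interaction graph**: planted disjoint near-cliques (default four
  9-node cliques with one edge removed → 35 edges each, matching the
  reported module shapes) in an Erdős–Rényi background (p = 0.02) over pairs
  with at least one non-planted endpoint, so planted modules remain
  separable — with direct clique-to-clique bridges the greedy expansion
  would merge them, which is a property of MCODE, not of this
  implementation. The default graph has ~62 nodes and ~165 edges.
* **Gene sets**: random sets of 30–80 mRNAs plus one set sampled with
  odds 8 in favor of planted differential mRNAs; odds 1 reduces it to an
  ordinary random set (verified by a uniformity check on its enrichment
  p-values).

Everything derives from one integer seed fanned out to per-component child
streams via `numpy.random.SeedSequence.spawn`, so a fixed seed yields a
byte-identical bundle and each component is independently reproducible.

**What passing tests do not show.** The generator does not simulate reads,
alignment or quantification noise, gene-length or GC biases, overdispersion
heterogeneity across genes, realistic sequence composition or conserved
miRNA families, hub-and-spoke interaction topology, or annotation-driven
gene-set correlation structure. Recovery results on synthetic bundles
demonstrate internal correctness of the statistics and algorithms, not
performance on accession-scale data.

## Numerical choices and degenerate inputs

Fold-change pseudocount 0.5; dispersion floor 10⁻⁸; r clipped to [−1, 1]
with |r| = 1 mapped to p = 0; hypergeometric k = 0 returns p = 1; empty
inputs yield empty, well-formed tables (alpha = 0 runs the whole pipeline to
empty outputs); ties broken deterministically everywhere (stable sorts,
lexicographic ids). All tables are UTF-8, tab-separated with header rows.
Default problem sizes (300/100/100/40 features, 10 samples, ~62-node graph)
keep a full pipeline run to a few seconds; they are scale models of the
experiment, chosen for tight statistical tests rather than realism of
magnitude.
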