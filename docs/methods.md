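# Methods

## The analysis model

`tristate` analyses combinatorial histone H3 methylation states of genes
from ChIP-seq peak calls of three marks — H3K4me3 (transcription
initiation), H3K27me3 (repression) and H3K36me3 (elongation) — measured in
two replicates per biological condition. The chain is:

1. **Replicate consolidation.** For each condition and mark, the two
   replicate peak lists are reduced to a "summarized quality peak list":
   peaks detected in both replicates (any positional overlap, configurable
   via `min_rep_overlap`) are merged into one peak carrying the broadest
   supporting interval and the maximum tag density; peaks found in a single
   replicate are rescued only when their MACS fold enrichment strictly
   exceeds a reliability threshold (default 5.0). Overlap matching is
   bipartite between the replicates; a chain of overlaps (two peaks of one
   replicate bridged by one of the other) collapses to a single consolidated
   peak, the simplest closure of the rule. Consolidated peaks are not
   re-merged with one another: downstream calls are binary, so residual
   overlap between consolidated peaks is harmless.
2. **Gene association.** A gene is called "modified" for a mark when some
   consolidated peak of that mark overlaps the gene's promoter (strand-aware
   TSS ± 1000 bases) and/or gene body (the genomic txStart–txEnd span) by at
   least 5% — interpreted as a fraction of the *peak's* length, which is how
   the rule reads most naturally; a `region` denominator is available as a
   config switch. The comparison is inclusive (a peak at exactly 5%
   qualifies), with a 1e-9 absolute slack so the exact boundary is not lost
   to binary-float rounding of 0.05. Multi-transcript genes are called per
   transcript and OR-reduced to the gene symbol. Genes and peaks on
   chrX/chrY are excluded to avoid sex-specific artifacts; mitochondrial
   and unplaced contigs are retained.
3. **State coding and transitions.** Calls concatenate to a per-gene triplet
   code in the order [H3K4me3 H3K27me3 H3K36me3]. Between two conditions,
   genes with unequal codes are differentially modified; a transition matrix
   over the k most frequent states (k = 5 by default, frequency measured in
   the control condition) counts genes per (state_from, state_to) cell.
   States are arranged on a fixed activation axis
   [010] < [000] < [110] < [100] < [101]; cells below the diagonal are
   epigenetic activations, above are repressions. The codes 001, 011 and
   111 have no defined activation rank and are excluded from
   activated/repressed totals (they still appear in full 8×8 matrices).
   Differential calls are exact string inequality — no probabilistic
   smoothing. Named transition sets (e.g. 100→101) are the genes of one
   cell; sets with the same label from different condition pairs can be
   intersected directly.
4. **Gene-set scoring.** The GSZ score standardizes the sum of per-gene
   values over a set against a sampling-without-replacement null:
   GSZ = (Σ_S v − m·μ) / √(m·σ²·(N−m)/(N−1)) with μ, σ² the population mean
   and variance of the N-gene universe. No shrinkage constants or
   membership weights are applied; the correctness contract is the
   permutation null (empirical mean ≈ 0, SD ≈ 1 over random same-size
   sets), which the finite-population form satisfies exactly in
   expectation. Degenerate nulls (zero variance, set = universe) return 0.
   Over-representation uses the hypergeometric upper tail P(X ≥ k); no
   multiple-testing correction is applied by default (Benjamini–Hochberg is
   available via `adjust_pvalues`).
5. **Expression preprocessing.** RNA-seq counts become log2(RPKM + 1); the
   base and pseudocount are options. Array intensities are filtered to
   genes detected (p < 0.05) in at least one sample — "at least one" is a
   choice, exposed as an option — then quantile-normalized (columns =
   samples; ties receive the value interpolated at their average rank,
   which makes the transform idempotent to 1e-12).
6. **Conservation.** Source-species states are paired with target-species
   states through an ortholog table. "Conserved" is operational: the gene
   has an ortholog *present in the target state table* (orthology without
   target data counts as non-conserved). One-to-many orthology resolves to
   the highest-confidence target, ties to the lexicographically smallest
   id. Reported percentages round half-up at a configurable precision
   (`auto` = one decimal below 80%, integer at/above), because published
   reports mix both conventions. For datasets of unequal sensitivity,
   `top_peaks_by_quality` truncates each peak list to an equal number of
   best fold-enrichment peaks before annotation; the truncation count is a
   free parameter.

Coordinates are 0-based half-open (BED convention) everywhere, including
the MACS-1.4-style TSV dialect this package reads and writes; the `length`
column equals end − start.

## The synthetic study generator

`tristate.synthetic` emulates the statistical structure the analysis
assumes, not sequencing physics: no reads, fragments or signal tracks are
simulated (peak calling is upstream of this package's scope).

* **Gene models.** Non-overlapping transcripts laid left-to-right per
  chromosome, lengths uniform on 2–20 kb, intergenic gaps 6–16 kb (so
  promoters never reach a neighbouring gene), random strand, ~4% of genes
  on chrX/chrY (roughly the mammalian fraction). One transcript per gene by
  default; `transcripts_per_gene > 1` adds shifted-start transcripts to
  exercise the gene-symbol collapse rule.
* **States.** Control-condition frequencies default to
  100: 0.35, 000: 0.25, 010: 0.15, 110: 0.12, 101: 0.08, 001: 0.03,
  011: 0.01, 111: 0.01 — the qualitative profile of a control intestine
  (H3K4me3-only most frequent, [101] a small minority, [011]/[111] rare).
  Each non-base condition applies per-gene transitions to the base state;
  defaults plant the two canonical transitions (100→101 with probability
  0.8, 010→110 with 0.3) plus de-novo H3K4me3 at unmodified genes
  (000→100, 0.1), so the mutant-like condition reaches a [101] plurality.
* **Peaks.** H3K4me3 peaks are sharp (1 kb, centred on the TSS); H3K27me3
  and H3K36me3 peaks span the gene body — mirroring sharp/broad calling
  without implementing a caller. A planted gene-mark emits in both
  replicates with probability 1 − dropout (default dropout 0.1), else in
  one replicate; fold enrichment is drawn per record from a lognormal
  (median 6, σ_log 0.7, a plausible range for retained MACS peaks), so
  singleton peaks are rescued only when their draw exceeds the threshold.
  Edges are jittered by a rounded Gaussian (default SD 50 bp). False peaks
  (default 2 per Mb per condition and mark) are placed ≥ 2 kb from any gene
  so the zero-noise oracle stays clean: they inflate peak counts but never
  produce gene calls.
* **Expression.** Per gene and condition, value = state mean + Gaussian
  noise (SD 1.0 log2 units). Default means (log2 scale) order the states
  101 (8.0) > 100 (6.0) > 000 = 110 (4.0) > 010 (2.0), with the unranked
  states in between.
* **Orthologs.** A conserved fraction (default 0.85, matching typical
  mouse–human one-to-one orthology coverage) of genes gets a target id;
  10% of those get a second, lower-confidence target to exercise
  de-duplication. A synthetic target-species state table keeps the source
  state with probability 0.5 and otherwise redraws from the base
  frequencies — a stand-in for an independently measured dataset, clearly
  weaker than real cross-species coupling.
* **Reproducibility.** Each generator call derives its RNG from
  (config.seed, operation name) via `SeedSequence`, so any single output
  can be regenerated independently and whole runs are byte-identical.

What passing tests on this generator do **not** show about real data: peak
breadth and tag-density distributions are stylized; replicate disagreement
is independent across gene-marks (no antibody- or batch-level structure);
false peaks never fall near genes; expression noise is homoscedastic
Gaussian. The generator validates the *logic* of the pipeline (rules,
set algebra, calibration), not its robustness to real ChIP-seq artifacts.

## Numerical and design choices

* Consolidation tie-breaks: the "broadest" component member is chosen by
  (max length, min start, min end), which is invariant to swapping the
  replicates; output is sorted by (chrom, start).
* Differential comparison requires a shared gene universe; unequal
  universes intersect with a warning, disjoint ones are an error.
* Top-k state selection breaks frequency ties lexicographically; states
  outside the activation axis are appended by frequency.
* `transition_spec` accepts a flat {(from, to): p} map applied to every
  non-base condition, or a per-condition mapping for multi-condition
  designs (e.g. 2 genotypes × 2 treatments).
* Problem sizes in the test-suite and in `scripts/acceptance.py` (2000-gene
  round trips, 10–20 random oracle instances of ≤ 500 peaks × 200 genes,
  10,000-draw GSZ null at N = 1000, m = 50) were chosen so the whole
  validation runs in well under a minute on one core while keeping binomial
  standard errors small relative to the asserted tolerances.

## Known limitations

* The consolidation rule is binary per mark and ignores peak strength
  beyond the rescue threshold; there is no IDR-style reproducibility model.
* "Consistently detected" is operationalized as ≥ 1 bp overlap; data with
  systematically shifted replicates may want `min_rep_overlap` as a
  fraction.
* The GSZ variant implements plain finite-population standardization; other
  published variants add shrinkage for very small sets.
* Conservation percentages conflate orthology and data availability by
  design (the operational definition used in cross-species comparisons of
  this kind).
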