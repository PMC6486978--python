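# tristate

Combinatorial histone-modification state analysis for multi-condition
ChIP-seq studies.

Genes carry combinations of histone H3 methylation marks — H3K4me3
(transcription initiation), H3K27me3 (repression), H3K36me3 (elongation) —
and the combination, not any single mark, tracks a gene's regulatory state.
`tristate` turns replicate peak calls of these three marks into a per-gene
binary triplet code **[H3K4me3 H3K27me3 H3K36me3]** per condition
("100" = H3K4me3 only, "110" = bivalent, "101" = stable activation), then
compares conditions: which genes change state, in which direction along the
activation axis [010] < [000] < [110] < [100] < [101], which named
transition sets (e.g. 100→101, H3K36me3 recruitment at active promoters)
they form, how those sets score on functional gene sets, how they relate to
expression, and whether their states are conserved across species.

It is written for epigenomics analysts comparing chromatin states between
genotypes, treatments, tissues or species from standard peak-caller output.

## What it computes

* **Replicate consolidation** — a "summarized quality peak list" per
  condition and mark: peaks detected in both replicates (merged with the
  maximum breadth and tag density) plus single-replicate peaks rescued by
  fold enrichment > 5.0.
* **Gene association** — binary per-gene mark calls via a ≥ 5%-of-peak
  overlap with the promoter (strand-aware TSS ± 1 kb) and/or gene body;
  chrX/chrY excluded.
* **States and transitions** — triplet coding, state distributions,
  differential genes, transition matrices over the top-k states, transition
  sets and their intersections.
* **Scoring** — GSZ gene-set score
  GSZ(S) = (Σ_{g∈S} v_g − m·μ) / √(m·σ²·(N−m)/(N−1))
  (standardized set sum under sampling without replacement), hypergeometric
  over-representation, log2(RPKM + 1), detection-filtered quantile
  normalization, expression-by-state summaries.
* **Conservation** — ortholog-mapped cross-species state agreement with
  report-precision percentages.
* **Synthetic studies** — a generator with planted states, transitions,
  replicate dropout, jitter, false peaks and state-ordered expression, so
  every stage is testable with a known ground truth.

## Worked example

Simulate a two-condition study (default noise settings), run the chain, and
compare the conditions:

```python
from tristate import (SynthConfig, MARKS, consolidate_replicates,
                      generate_gene_models, generate_truth,
                      generate_peak_replicates, encode_states,
                      assign_modifications, differential_genes,
                      extract_transition_set, transition_matrix, top_k_states)

cfg = SynthConfig(n_genes=500, seed=1)
genes = generate_gene_models(cfg)
truth = generate_truth(genes, cfg)
peaks, truth = generate_peak_replicates(truth, genes, cfg)

states = {}
for cond in cfg.conditions:
    merged = {m: consolidate_replicates(peaks[(cond, m, "rep1")],
                                        peaks[(cond, m, "rep2")])
              for m in MARKS}
    states[cond] = encode_states(assign_modifications(merged, genes,
                                                      condition=cond))

wt, mut = states["wildtype"], states["mutant"]
top = top_k_states(wt, 5)
tm = transition_matrix(wt, mut, top)
print(f"genes analysed: {len(wt)}")
print(f"differentially modified: {len(differential_genes(wt, mut))}")
print(f"top-5 states (activation order): {top}")
print(f"100->101 transition set: "
      f"{len(extract_transition_set(wt, mut, '100', '101'))} genes")
print(f"activated: {tm.n_activated}, repressed: {tm.n_repressed}")
```

Output:

```
genes analysed: 480
differentially modified: 187
top-5 states (activation order): ['010', '000', '110', '100', '101']
100->101 transition set: 123 genes
activated: 173, repressed: 11
```

480 of the 500 simulated genes are autosomal and enter the analysis. 187
change state between the conditions; the dominant change is the planted
100→101 transition (123 genes gaining H3K36me3 at H3K4me3-marked
promoters), and activations outnumber repressions 173 : 11 — the imbalance
the transition matrix is designed to expose. With the noise knobs set to
zero the recovered states equal the planted truth exactly; the defaults
shown include 10% replicate dropout, 50 bp jitter and intergenic false
peaks.

The same run is available from a shell:

```sh
tristate run --config run.yaml      # simulate -> ... -> summary.json
tristate consolidate --rep1 r1.tsv --rep2 r2.tsv --mark H3K36me3 --out peaks.tsv
tristate annotate --peaks-k4 k4.tsv --genes refflat.txt --out calls.tsv
```

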