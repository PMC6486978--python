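"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid interval trees and union-find: consolidation uses
an all-pairs overlap graph via networkx, annotation loops over every
peak x gene-region pair, and transition tabulation is a plain dict count.
"""
from __future__ import annotations

import networkx as nx

from tristate.annotate import SEX_CHROMS, gene_body_interval, promoter_interval
from tristate.peaks import ConsolidatedPeak, MARKS


def consolidate_oracle(rep1, rep2, fe_threshold=5.0):
    records = list(rep1) + list(rep2)
    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    for i, a in enumerate(rep1):
        for j, b in enumerate(rep2):
            if a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= 1:
                g.add_edge(i, len(rep1) + j)
    out = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        reps = {records[i].replicate for i in members}
        if len(reps) >= 2:
            broadest = min(members, key=lambda i: (-records[i].length,
                                                   records[i].start,
                                                   records[i].end))
            b = records[broadest]
            out.append(ConsolidatedPeak(
                chrom=b.chrom, start=b.start, end=b.end, mark=b.mark,
                tags=max(records[i].tags for i in members),
                support="both_replicates",
                source_ids=tuple(sorted(records[i].record_id for i in members)),
                fold_enrichment=max(records[i].fold_enrichment for i in members),
            ))
        else:
            (i,) = members
            r = records[i]
            if r.fold_enrichment > fe_threshold:
                out.append(ConsolidatedPeak(
                    chrom=r.chrom, start=r.start, end=r.end, mark=r.mark,
                    tags=r.tags, support="single_high_fe",
                    source_ids=(r.record_id,), fold_enrichment=r.fold_enrichment,
                ))
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def assign_oracle(peaks_by_mark, genes, min_overlap_frac=0.05, flank=1000):
    """All-pairs peak x gene-region call table as a {gene: {mark: 0/1}} dict."""
    auto = genes[~genes["chrom"].isin(SEX_CHROMS)]
    calls = {g: {m: 0 for m in MARKS} for g in auto["gene_symbol"].unique()}
    for mark, peaks in peaks_by_mark.items():
        for peak in peaks:
            if peak.chrom in SEX_CHROMS:
                continue
            for row in auto.itertuples(index=False):
                if row.chrom != peak.chrom:
                    continue
                for lo, hi in (promoter_interval(row, flank),
                               gene_body_interval(row)):
                    ov = min(peak.end, hi) - max(peak.start, lo)
                    if ov > 0 and ov >= min_overlap_frac * peak.length - 1e-9:
                        calls[row.gene_symbol][mark] = 1
    return calls


def transition_counts_oracle(a, b, state_list):
    """Plain dict tabulation of (state_from, state_to) gene counts."""
    counts = {(sf, st): 0 for sf in state_list for st in state_list}
    allowed = set(state_list)
    for gene in a.index.intersection(b.index):
        sf, st = a[gene], b[gene]
        if sf in allowed and st in allowed:
            counts[(sf, st)] += 1
    return counts
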