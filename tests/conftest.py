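from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tristate import (
    MARKS,
    SynthConfig,
    consolidate_replicates,
    encode_states,
    generate_gene_models,
    generate_peak_replicates,
    generate_truth,
)
from tristate.annotate import assign_modifications
from tristate.peaks import PeakRecord


def make_peak(chrom="chr1", start=0, end=100, mark="H3K4me3", replicate="rep1",
              fe=3.0, tags=10, record_id=""):
    return PeakRecord(chrom=chrom, start=start, end=end, mark=mark,
                      replicate=replicate, fold_enrichment=fe, tags=tags,
                      record_id=record_id or f"{replicate}:{start}-{end}")


def random_peaks(rng: np.random.Generator, n: int, replicate: str,
                 mark: str = "H3K36me3", chroms=("chr1",),
                 chrom_len: int = 1_000_000) -> list[PeakRecord]:
    out = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 5000))
        length = int(rng.integers(200, 5000))
        out.append(PeakRecord(
            chrom=str(rng.choice(chroms)), start=start, end=start + length,
            mark=mark, replicate=replicate,
            fold_enrichment=float(rng.uniform(0, 12)),
            tags=int(rng.integers(1, 500)),
            record_id=f"{replicate}:{i}",
        ))
    return out


def run_core_pipeline(config: SynthConfig):
    """simulate -> consolidate -> annotate -> encode, in memory.

    Returns (genes, truth, per-condition state tables).
    """
    genes = generate_gene_models(config)
    truth = generate_truth(genes, config)
    peak_tables, truth = generate_peak_replicates(truth, genes, config)
    state_tables = {}
    for cond in config.conditions:
        merged = {
            mark: consolidate_replicates(peak_tables[(cond, mark, "rep1")],
                                         peak_tables[(cond, mark, "rep2")])
            for mark in MARKS
        }
        calls = assign_modifications(merged, genes, condition=cond)
        state_tables[cond] = encode_states(calls)
    return genes, truth, state_tables


@pytest.fixture(scope="session")
def noise_free_study():
    """A small two-condition study with all noise switched off."""
    config = SynthConfig(n_genes=300, replicate_dropout=0.0, jitter_sd=0.0,
                         false_peak_rate=0.0, seed=11)
    genes, truth, state_tables = run_core_pipeline(config)
    return config, genes, truth, state_tables


@pytest.fixture()
def random_state_pair():
    """Two random planted state tables over a shared 400-gene universe."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:04d}" for i in range(400)]
    codes = [f"{i:03b}" for i in range(8)]
    a = pd.Series(rng.choice(codes, size=400), index=genes, name="A")
    b = a.copy()
    flip = rng.random(400) < 0.3
    b[flip] = rng.choice(codes, size=int(flip.sum()))
    b.name = "B"
    return a, b
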