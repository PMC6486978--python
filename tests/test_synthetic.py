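"""Generator contracts: validation, determinism, planted structure."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from tristate import (
    ConfigurationError,
    ConsistencyError,
    MARKS,
    SynthConfig,
    consolidate_replicates,
    encode_states,
    generate_expression,
    generate_gene_models,
    generate_ortholog_map,
    generate_peak_replicates,
    generate_truth,
)
from tristate.annotate import assign_modifications

from .conftest import run_core_pipeline


class TestConfigValidation:
    @pytest.mark.parametrize(
        ("kwargs", "fieldname"),
        [
            ({"n_genes": 0}, "n_genes"),
            ({"sex_chrom_fraction": 1.5}, "sex_chrom_fraction"),
            ({"chrom_names": ("chr1",), "sex_chrom_fraction": 0.1}, "chrom_names"),
            ({"state_freqs": {"100": 0.6, "000": 0.3}}, "state_freqs"),
            ({"state_freqs": {"100": 0.5, "201": 0.5}}, "state_freqs"),
            ({"replicate_dropout": -0.1}, "replicate_dropout"),
            ({"jitter_sd": -1.0}, "jitter_sd"),
            ({"transition_spec": {("100", "101"): 0.7, ("100", "110"): 0.5}},
             "transition_spec"),
            ({"gene_length_range": (500, 2000)}, "gene_length_range"),
        ],
    )
    def test_invalid_config_names_the_field(self, kwargs, fieldname):
        with pytest.raises(ConfigurationError, match=fieldname):
            generate_gene_models(SynthConfig(**kwargs))

    def test_missing_expression_mean_is_a_config_error(self):
        cfg = SynthConfig(n_genes=50, expr_state_means={"000": 1.0}, seed=1)
        genes = generate_gene_models(cfg)
        with pytest.raises(ConfigurationError, match="expr_state_means"):
            generate_truth(genes, cfg)


class TestGeneModels:
    def test_identical_seed_gives_byte_identical_tables(self):
        cfg = SynthConfig(n_genes=150, seed=7)
        a = generate_gene_models(cfg)
        b = generate_gene_models(SynthConfig(n_genes=150, seed=7))
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_different_seed_changes_layout(self):
        a = generate_gene_models(SynthConfig(n_genes=150, seed=7))
        b = generate_gene_models(SynthConfig(n_genes=150, seed=8))
        assert not a.equals(b)

    def test_transcripts_do_not_overlap_within_chromosome(self):
        genes = generate_gene_models(SynthConfig(n_genes=400, seed=3))
        for _, sub in genes.groupby("chrom"):
            spans = sorted(zip(sub["txStart"], sub["txEnd"]))
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2
        assert (genes["txEnd"] - genes["txStart"] >= 2000).all()
        assert genes["strand"].isin(["+", "-"]).all()

    def test_sex_chromosome_gene_count_at_fixed_seed(self):
        # frozen binomial draw: n=1000, p=0.05, seed=7 (expectation 50, SD 6.9)
        genes = generate_gene_models(
            SynthConfig(n_genes=1000, sex_chrom_fraction=0.05, seed=7))
        n_sex = int(genes["chrom"].isin(["chrX", "chrY"]).sum())
        assert n_sex == 60
        assert abs(n_sex - 50) <= 3 * math.sqrt(1000 * 0.05 * 0.95)


class TestPeakReplicates:
    def test_truth_gene_missing_from_models_raises(self):
        cfg = SynthConfig(n_genes=20, seed=1)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        with pytest.raises(ConsistencyError):
            generate_peak_replicates(
                truth.assign(gene_id="ghost"), genes, cfg)

    def test_determinism_of_peak_tables(self):
        cfg = SynthConfig(n_genes=60, seed=7)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        t1, _ = generate_peak_replicates(truth, genes, cfg)
        t2, _ = generate_peak_replicates(truth, genes, cfg)
        assert t1 == t2

    def test_total_dropout_with_low_fe_gives_all_unmodified(self):
        cfg = SynthConfig(n_genes=80, replicate_dropout=1.0, jitter_sd=0.0,
                          false_peak_rate=0.0, fe_lognorm=(np.log(0.5), 0.01),
                          conditions=("only",), seed=5)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        tables, _ = generate_peak_replicates(truth, genes, cfg)
        merged = {m: consolidate_replicates(tables[("only", m, "rep1")],
                                            tables[("only", m, "rep2")])
                  for m in MARKS}
        assert all(len(v) == 0 for v in merged.values())
        states = encode_states(assign_modifications(merged, genes))
        assert (states == "000").all()

    def test_dropout_recovery_rate_matches_closed_form(self):
        # planted mark survives iff both replicates (p = 1 - dropout) or the
        # singleton's FE draw exceeds 5 (p = dropout * P(FE > 5)); with the FE
        # median at 5, recovery = 1 - 0.3 * 0.5 = 0.85
        cfg = SynthConfig(n_genes=2000, replicate_dropout=0.3, jitter_sd=0.0,
                          false_peak_rate=0.0, fe_lognorm=(float(np.log(5.0)), 0.7),
                          conditions=("only",), seed=13)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        tables, _ = generate_peak_replicates(truth, genes, cfg)
        merged = {m: consolidate_replicates(tables[("only", m, "rep1")],
                                            tables[("only", m, "rep2")])
                  for m in MARKS}
        states = encode_states(assign_modifications(merged, genes))
        planted = truth.set_index("gene_id")["state"]
        n_planted = n_recovered = 0
        for gene in states.index:
            for i in range(3):
                if planted[gene][i] == "1":
                    n_planted += 1
                    n_recovered += states[gene][i] == "1"
        p = 1 - 0.3 * 0.5
        se = math.sqrt(p * (1 - p) / n_planted)
        assert abs(n_recovered / n_planted - p) <= 3 * se

    def test_false_peaks_are_intergenic_and_never_called(self):
        cfg = SynthConfig(n_genes=100, replicate_dropout=0.0, jitter_sd=0.0,
                          false_peak_rate=20.0, seed=9)
        genes, truth, state_tables = run_core_pipeline(cfg)
        tables, _ = generate_peak_replicates(truth, genes, cfg)
        n_false = sum(1 for recs in tables.values() for r in recs
                      if "false" in r.record_id)
        assert n_false > 0
        for cond in cfg.conditions:
            planted = truth[truth["condition"] == cond].set_index("gene_id")["state"]
            st = state_tables[cond]
            assert (st == planted.loc[st.index]).all()


class TestExpression:
    def test_zero_noise_reproduces_state_means_exactly(self):
        cfg = SynthConfig(n_genes=200, expr_noise_sd=0.0, seed=3)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        expr = generate_expression(truth, cfg)
        merged = truth.merge(expr, on=["gene_id", "condition"])
        assert (merged["value"] == merged["expression_mean"]).all()

    def test_default_group_means_are_state_ordered(self):
        cfg = SynthConfig(n_genes=5000, seed=21)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        expr = generate_expression(truth, cfg)
        merged = truth.merge(expr, on=["gene_id", "condition"])
        means = merged.groupby("state")["value"].mean()
        assert means["101"] > means["100"] > means["000"] > means["010"]
        assert means["100"] > means["110"] > means["010"]

    def test_single_planted_state_still_summarized(self):
        cfg = SynthConfig(n_genes=30, state_freqs={"100": 1.0},
                          conditions=("only",), transition_spec={}, seed=2)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        expr = generate_expression(truth, cfg)
        assert len(expr) == 30
        assert truth["state"].eq("100").all()


class TestOrthologMap:
    def test_full_conservation_maps_every_gene(self):
        cfg = SynthConfig(n_genes=100, conserved_fraction=1.0,
                          one_to_many_fraction=0.0, seed=4)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        om = generate_ortholog_map(truth, cfg)
        assert om["source_gene"].nunique() == 100

    def test_zero_conservation_gives_empty_map(self):
        cfg = SynthConfig(n_genes=100, conserved_fraction=0.0, seed=4)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        assert generate_ortholog_map(truth, cfg).empty

    def test_mapped_gene_count_at_study_scale(self):
        # frozen binomial draw at seed 7: 5049 of 5984 genes mapped
        # (expectation 5086.4, SD 27.6)
        cfg = SynthConfig(n_genes=5984, conserved_fraction=0.85,
                          one_to_many_fraction=0.0, seed=7)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        n = generate_ortholog_map(truth, cfg)["source_gene"].nunique()
        assert n == 5049
        assert abs(n - 5984 * 0.85) <= 3 * math.sqrt(5984 * 0.85 * 0.15)

    def test_one_to_many_entries_have_lower_confidence(self):
        cfg = SynthConfig(n_genes=50, conserved_fraction=1.0,
                          one_to_many_fraction=1.0, seed=4)
        genes = generate_gene_models(cfg)
        truth = generate_truth(genes, cfg)
        om = generate_ortholog_map(truth, cfg)
        assert len(om) == 100  # two targets per gene
        per_gene = om.groupby("source_gene")["confidence"]
        assert (per_gene.max() > per_gene.min()).all()
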