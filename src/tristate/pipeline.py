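"""End-to-end pipeline: simulate/read -> consolidate -> annotate -> encode
-> transitions -> score -> conserve, with a machine-readable run summary.

A run is driven by one YAML config (see :func:`load_run_config`). The first
condition listed is the base/control; every other condition is compared
against it. Re-running the same config produces byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate, conservation, peaks as peaks_mod, scoring, states as states_mod
from .errors import ConfigurationError, TristateError
from .peaks import MARKS
from .synthetic import SynthConfig, simulate_study

log = logging.getLogger("tristate")

DEFAULT_TRANSITIONS_OF_INTEREST = ("100->101", "010->110")


class PipelineStageError(TristateError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either ``synthetic`` (a :class:`SynthConfig`) or ``inputs`` (paths to
    existing peak/gene/expression tables) must be set. Analysis defaults
    follow the standard parameterization: promoter flank 1000 bp, 5% peak
    overlap, fold-enrichment rescue threshold 5.0, top-5 state transition
    matrix.
    """

    outdir: str = "tristate_run"
    seed: int = 0
    synthetic: SynthConfig | None = None
    inputs: dict[str, Any] | None = None
    fe_threshold: float = 5.0
    flank: int = 1000
    min_overlap_frac: float = 0.05
    overlap_denominator: str = "peak"
    k: int = 5
    transitions_of_interest: tuple[str, ...] = DEFAULT_TRANSITIONS_OF_INTEREST

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' or 'inputs' must be configured")
        if self.fe_threshold < 0 and self.fe_threshold != -1:
            raise ConfigurationError("fe_threshold: must be >= 0 (or -1 to disable)")
        if not 0 <= self.min_overlap_frac:
            raise ConfigurationError("min_overlap_frac: must be >= 0")
        if not 1 <= self.k <= 8:
            raise ConfigurationError("k: must be in [1, 8]")
        for label in self.transitions_of_interest:
            parts = label.split("->")
            if len(parts) != 2 or any(len(p) != 3 or set(p) - {"0", "1"}
                                      for p in parts):
                raise ConfigurationError(
                    f"transitions_of_interest: malformed label {label!r}")
        if self.synthetic is not None:
            self.synthetic.validate()
        if self.inputs is not None:
            for key in ("genes", "conditions"):
                if key not in self.inputs:
                    raise ConfigurationError(f"inputs: missing {key!r}")


def _parse_transition_spec(raw: dict) -> dict:
    """YAML transition specs use 'XYZ->XYZ' string keys; convert to tuples."""
    def split(key: str) -> tuple[str, str]:
        a, _, b = key.partition("->")
        return (a.strip(), b.strip())

    if not raw:
        return {}
    first = next(iter(raw.values()))
    if isinstance(first, dict):
        return {cond: {split(k): float(p) for k, p in sub.items()}
                for cond, sub in raw.items()}
    return {split(k): float(p) for k, p in raw.items()}


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    cfg = RunConfig()
    params = doc.pop("parameters", {}) or {}
    for source in (doc, params):
        for key, value in list(source.items()):
            if key in ("synthetic", "inputs"):
                continue
            if not any(f.name == key for f in dc_fields(RunConfig)):
                raise ConfigurationError(f"unknown config key {key!r}")
            if key == "transitions_of_interest":
                value = tuple(value)
            setattr(cfg, key, value)
    if "synthetic" in doc:
        raw = dict(doc["synthetic"] or {})
        if "transition_spec" in raw:
            raw["transition_spec"] = _parse_transition_spec(raw["transition_spec"])
        for tup_key in ("chrom_names", "conditions", "fe_lognorm",
                        "gene_length_range", "gap_range"):
            if tup_key in raw:
                raw[tup_key] = tuple(raw[tup_key])
        valid = {f.name for f in dc_fields(SynthConfig)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigurationError(f"synthetic: unknown key(s) {sorted(unknown)}")
        raw.setdefault("seed", cfg.seed)
        cfg.synthetic = SynthConfig(**raw)
    if "inputs" in doc:
        cfg.inputs = dict(doc["inputs"] or {})
    cfg.validate()
    return cfg


def _load_inputs(cfg: RunConfig, outdir: Path):
    """Return (conditions, peak tables, genes, expression, orthologs, target states)."""
    if cfg.synthetic is not None:
        scfg = cfg.synthetic
        simdir = outdir / "simulated"
        paths = simulate_study(scfg, simdir)
        conditions = list(scfg.conditions)
        raw = {}
        for cond in conditions:
            for mark in MARKS:
                for rep in ("rep1", "rep2"):
                    raw[(cond, mark, rep)] = peaks_mod.read_peak_table(
                        paths[f"peaks/{cond}.{mark}.{rep}"], "macs14_tsv",
                        mark, rep)
        genes = annotate.read_refflat(paths["genes"])
        expr = pd.read_csv(paths["expression"], sep="\t")
        orthologs = conservation.read_orthologs(paths["orthologs"])
        target_states = states_mod.read_state_table(paths["target_states"], "target")
        return conditions, raw, genes, expr, orthologs, target_states

    inputs = cfg.inputs
    dialect = inputs.get("dialect", "macs14_tsv")
    conditions = list(inputs["conditions"])
    raw = {}
    for cond, marks in inputs["conditions"].items():
        for mark, rep_paths in marks.items():
            for i, p in enumerate(rep_paths, start=1):
                rep = f"rep{i}"
                raw[(cond, mark, rep)] = peaks_mod.read_peak_table(
                    p, dialect, mark, rep)
    genes = annotate.read_refflat(inputs["genes"])
    expr = (pd.read_csv(inputs["expression"], sep="\t")
            if inputs.get("expression") else None)
    orthologs = (conservation.read_orthologs(inputs["orthologs"])
                 if inputs.get("orthologs") else None)
    target_states = (states_mod.read_state_table(inputs["target_states"], "target")
                     if inputs.get("target_states") else None)
    return conditions, raw, genes, expr, orthologs, target_states


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages and return (and write) the JSON-able run summary.

    Stage outputs land under ``cfg.outdir``: consolidated peak tables,
    per-condition call and state tables, transition-set gene lists, and
    ``summary.json`` holding every reported count so each number is
    reproducible from the on-disk stage outputs.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"parameters": {
        "fe_threshold": cfg.fe_threshold, "flank": cfg.flank,
        "min_overlap_frac": cfg.min_overlap_frac, "k": cfg.k,
        "seed": cfg.seed,
    }}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineStageError(name, exc) from exc
            return out
        return wrap

    conditions, raw, genes, expr, orthologs, target_states = \
        stage("load")(_load_inputs, cfg, outdir)
    log.info("loaded %d raw peak tables, %d gene models",
             len(raw), len(genes))

    # --- consolidation -----------------------------------------------------
    cons_dir = outdir / "consolidated"
    cons_dir.mkdir(exist_ok=True)
    consolidated: dict[str, dict[str, list]] = {}
    summary["peaks"] = {}
    for cond in conditions:
        consolidated[cond] = {}
        counts = {}
        for mark in MARKS:
            merged = stage("consolidate")(
                peaks_mod.consolidate_replicates,
                raw.get((cond, mark, "rep1"), []),
                raw.get((cond, mark, "rep2"), []),
                cfg.fe_threshold)
            consolidated[cond][mark] = merged
            peaks_mod.write_consolidated_tsv(
                merged, cons_dir / f"{cond}.{mark}.tsv")
            counts[mark] = len(merged)
        all_peaks = [p for mark in MARKS for p in consolidated[cond][mark]]
        flags = stage("annotate")(
            annotate.gene_associated_flags, all_peaks, genes,
            cfg.min_overlap_frac, cfg.flank, cfg.overlap_denominator)
        summary["peaks"][cond] = {
            "per_mark": counts,
            "total": int(sum(counts.values())),
            "gene_associated_pct": (100.0 * sum(flags) / len(flags)
                                    if flags else 0.0),
        }
        log.info("%s: %d consolidated peaks", cond, sum(counts.values()))

    # --- per-gene calls and states ----------------------------------------
    state_tables: dict[str, pd.Series] = {}
    summary["state_distribution"] = {}
    for cond in conditions:
        calls = stage("annotate")(
            annotate.assign_modifications, consolidated[cond], genes,
            cfg.min_overlap_frac, cfg.flank, cfg.overlap_denominator, cond)
        annotate.write_call_table(calls, outdir / f"calls.{cond}.tsv")
        st = states_mod.encode_states(calls)
        states_mod.write_state_table(st, outdir / f"states.{cond}.tsv")
        state_tables[cond] = st
        dist = states_mod.state_distribution(st)
        summary["state_distribution"][cond] = {
            s: int(c) for s, c in dist["count"].items()}
    summary["n_genes"] = int(len(state_tables[conditions[0]]))

    # --- transitions vs the base condition ---------------------------------
    base = conditions[0]
    top = states_mod.top_k_states(state_tables[base], cfg.k)
    summary["top_states"] = top
    summary["comparisons"] = {}
    sets_by_label: dict[str, dict[str, states_mod.TransitionSet]] = {
        label: {} for label in cfg.transitions_of_interest}
    for cond in conditions[1:]:
        a, b = state_tables[base], state_tables[cond]
        diff = stage("transitions")(states_mod.differential_genes, a, b)
        tm = stage("transitions")(states_mod.transition_matrix, a, b, top)
        comp: dict[str, Any] = {
            "n_differential": len(diff),
            "transition_matrix": {
                sf: {st: int(tm.counts.at[sf, st]) for st in top} for sf in top},
            "n_activated": tm.n_activated,
            "n_repressed": tm.n_repressed,
            "transition_sets": {},
        }
        for label in cfg.transitions_of_interest:
            sf, st = label.split("->")
            tset = stage("transitions")(
                states_mod.extract_transition_set, a, b, sf, st)
            sets_by_label[label][cond] = tset
            comp["transition_sets"][label] = len(tset)
            with open(outdir / f"set.{label.replace('->', '_to_')}.{cond}.txt",
                      "w") as fh:
                fh.write("\n".join(sorted(tset.genes)) + "\n")
        summary["comparisons"][f"{base}_vs_{cond}"] = comp

    # --- intersections across comparisons ----------------------------------
    summary["intersections"] = {}
    for label, per_cond in sets_by_label.items():
        conds = sorted(per_cond)
        for i, c1 in enumerate(conds):
            for c2 in conds[i + 1:]:
                inter = states_mod.intersect_transition_sets(
                    per_cond[c1], per_cond[c2])
                summary["intersections"][f"{label}|{c1}&{c2}"] = len(inter)

    # --- [101] stable-activation overlap counts ----------------------------
    base_101 = set(state_tables[base].index[state_tables[base] == "101"])
    summary["state_101"] = {base: {"n": len(base_101)}}
    for cond in conditions[1:]:
        cur = set(state_tables[cond].index[state_tables[cond] == "101"])
        summary["state_101"][cond] = {
            "n": len(cur), "shared_with_base": len(cur & base_101)}

    # --- expression ---------------------------------------------------------
    if expr is not None:
        summary["expression_by_state"] = {}
        for cond in conditions:
            sub = expr[expr["condition"] == cond] if "condition" in expr else expr
            vec = sub.set_index("gene_id")["value"]
            try:
                by_state = stage("score")(
                    scoring.expression_by_state, state_tables[cond], vec)
            except PipelineStageError:
                continue
            summary["expression_by_state"][cond] = {
                s: round(float(row["mean"]), 6)
                for s, row in by_state.iterrows()}

    # --- conservation -------------------------------------------------------
    if orthologs is not None and target_states is not None:
        paired = stage("conserve")(
            conservation.map_orthologs, state_tables[base], orthologs,
            target_states)
        paired.to_csv(outdir / "paired_states.tsv", sep="\t", index=False)
        summary["conservation"] = {}
        for label, per_cond in sets_by_label.items():
            for cond, tset in per_cond.items():
                if not tset.genes:
                    continue
                cs = stage("conserve")(
                    conservation.conservation_summary, tset, paired,
                    tset.from_state)
                summary["conservation"][f"{label}|{cond}"] = {
                    "n_source": cs.n_source,
                    "n_conserved": cs.n_conserved,
                    "conserved_pct": round(cs.conserved_pct, 4),
                    "reference_state_pct": (round(cs.reference_state_pct, 4)
                                            if cs.reference_state_pct is not None
                                            else None),
                }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
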