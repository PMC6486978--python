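"""Synthetic histone-modification study with planted ground truth.

Emulates the data layout of a multi-condition intestinal ChIP-seq study:
three H3 methylation marks (H3K4me3 sharp at promoters; H3K27me3 and
H3K36me3 broad over gene bodies), two replicates per condition, per-gene
planted triplet states, planted state transitions between a base condition
and each other condition, replicate dropout with fold-enrichment rescue,
coordinate jitter, intergenic false peaks, sex-chromosome genes, and
expression ordered by state. With all noise switched off, the downstream
pipeline recovers the planted truth exactly, which is the basis of the
round-trip tests.

Every generator draws from its own RNG seeded by (config.seed, operation
name), so individual outputs can be regenerated independently and runs are
fully reproducible.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GENE_COLUMNS, write_refflat
from .errors import ConfigurationError, ConsistencyError
from .peaks import MARKS, PeakRecord, write_peak_table
from .states import ALL_STATES

# Planted state frequencies of the base (control) condition. Qualitative
# shape of a control mouse intestine: H3K4me3-only promoters dominate,
# unmodified and H3K27me3-only genes follow, bivalent genes are common,
# stable-activation [101] genes are a small minority, [011]/[111] are rare.
DEFAULT_STATE_FREQS: dict[str, float] = {
    "100": 0.35, "000": 0.25, "010": 0.15, "110": 0.12,
    "101": 0.08, "001": 0.03, "011": 0.01, "111": 0.01,
}

# Planted transitions from the base condition to each other condition:
# bulk H3K36me3 recruitment at H3K4me3-only genes (100->101, the dominant
# "Set1" transition), H3K4me3 recruitment at repressed genes (010->110,
# "Set2"), and some de-novo H3K4me3 at unmodified genes.
DEFAULT_TRANSITIONS: dict[tuple[str, str], float] = {
    ("100", "101"): 0.80,
    ("010", "110"): 0.30,
    ("000", "100"): 0.10,
}

# log2-scale expression means per state, ordered
# 101 > 100 > 000 ~ 110 > 010 with the unranked states in between.
DEFAULT_EXPR_MEANS: dict[str, float] = {
    "101": 8.0, "100": 6.0, "001": 5.0, "111": 5.0,
    "000": 4.0, "110": 4.0, "011": 3.0, "010": 2.0,
}

DEFAULT_CHROMS = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX", "chrY")


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Noise knobs (``replicate_dropout``, ``jitter_sd``, ``false_peak_rate``)
    set to zero give a noise-free dataset from which the pipeline recovers
    the planted truth exactly.
    """

    n_genes: int = 2000
    chrom_names: tuple[str, ...] = DEFAULT_CHROMS
    sex_chrom_fraction: float = 0.04
    conditions: tuple[str, ...] = ("wildtype", "mutant")
    state_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_FREQS))
    #: either {(from,to): prob} applied base->every other condition, or
    #: {condition: {(from,to): prob}} per non-base condition.
    transition_spec: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS))
    replicate_dropout: float = 0.1
    #: lognormal (mean, sigma) of underlying normal for fold enrichment
    fe_lognorm: tuple[float, float] = (float(np.log(6.0)), 0.7)
    jitter_sd: float = 50.0
    false_peak_rate: float = 2.0          # peaks per Mb, per condition+mark
    expr_state_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPR_MEANS))
    expr_noise_sd: float = 1.0
    conserved_fraction: float = 0.85
    one_to_many_fraction: float = 0.10
    ortholog_state_agreement: float = 0.5
    gene_length_range: tuple[int, int] = (2000, 20000)
    gap_range: tuple[int, int] = (6000, 16000)
    promoter_flank: int = 1000
    k4_breadth: int = 1000
    false_peak_breadth: int = 500
    transcripts_per_gene: int = 1
    seed: int = 0

    def validate(self) -> None:
        def err(fieldname: str, msg: str) -> ConfigurationError:
            return ConfigurationError(f"{fieldname}: {msg}")

        if self.n_genes < 1:
            raise err("n_genes", f"must be >= 1, got {self.n_genes}")
        if not 0 <= self.sex_chrom_fraction <= 1:
            raise err("sex_chrom_fraction", "must be in [0, 1]")
        if self.sex_chrom_fraction > 0 and not (
                set(self.chrom_names) & {"chrX", "chrY"}):
            raise err("chrom_names", "must include chrX/chrY when "
                      "sex_chrom_fraction > 0")
        if not [c for c in self.chrom_names if c not in ("chrX", "chrY")]:
            raise err("chrom_names", "needs at least one autosome")
        if len(self.conditions) < 1:
            raise err("conditions", "needs at least one condition")
        total = sum(self.state_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise err("state_freqs", f"probabilities sum to {total}, not 1")
        for s, p in self.state_freqs.items():
            if s not in ALL_STATES:
                raise err("state_freqs", f"unknown state code {s!r}")
            if not 0 <= p <= 1:
                raise err("state_freqs", f"probability {p} outside [0, 1]")
        for cond, spec in self._transitions_by_condition().items():
            by_from: dict[str, float] = {}
            for (sf, st), p in spec.items():
                if sf not in ALL_STATES or st not in ALL_STATES:
                    raise err("transition_spec", f"unknown state in {(sf, st)}")
                if not 0 <= p <= 1:
                    raise err("transition_spec", f"probability {p} outside [0, 1]")
                by_from[sf] = by_from.get(sf, 0.0) + p
            for sf, tot in by_from.items():
                if tot > 1 + 1e-9:
                    raise err("transition_spec",
                              f"{cond}: probabilities out of {sf} sum to {tot} > 1")
        for name, p in (("replicate_dropout", self.replicate_dropout),
                        ("conserved_fraction", self.conserved_fraction),
                        ("one_to_many_fraction", self.one_to_many_fraction),
                        ("ortholog_state_agreement", self.ortholog_state_agreement)):
            if not 0 <= p <= 1:
                raise err(name, "must be in [0, 1]")
        for name, v in (("jitter_sd", self.jitter_sd),
                        ("false_peak_rate", self.false_peak_rate),
                        ("expr_noise_sd", self.expr_noise_sd)):
            if v < 0:
                raise err(name, "must be >= 0")
        if self.gene_length_range[0] < 2 * self.promoter_flank:
            raise err("gene_length_range",
                      "minimum gene length must be >= 2 * promoter_flank")
        if self.fe_lognorm[1] < 0:
            raise err("fe_lognorm", "sigma must be >= 0")
        if self.transcripts_per_gene < 1:
            raise err("transcripts_per_gene", "must be >= 1")

    def _transitions_by_condition(self) -> dict[str, dict[tuple[str, str], float]]:
        others = list(self.conditions[1:])
        spec = self.transition_spec or {}
        if spec and all(isinstance(k, tuple) for k in spec):
            return {c: dict(spec) for c in others}
        out = {}
        for c in others:
            sub = spec.get(c, {})
            if not all(isinstance(k, tuple) for k in sub):
                raise ConfigurationError(
                    f"transition_spec: entry for condition {c!r} must map "
                    "(state_from, state_to) -> prob")
            out[c] = dict(sub)
        return out


def _rng(config: SynthConfig, operation: str) -> np.random.Generator:
    """One generator per operation, derived from (seed, operation name)."""
    key = zlib.crc32(operation.encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, key]))


def generate_gene_models(config: SynthConfig) -> pd.DataFrame:
    """Non-overlapping single-transcript gene models on the configured chromosomes.

    Genes are laid out left to right per chromosome with intergenic gaps
    drawn from ``gap_range``, so promoters never reach a neighbouring gene
    and false peaks can be placed safely between genes. A configurable
    fraction of genes lands on chrX/chrY. With ``transcripts_per_gene > 1``
    each gene gets additional transcripts with a shifted start (to exercise
    the gene-symbol collapse rule downstream).
    """
    config.validate()
    rng = _rng(config, "gene_models")
    n = config.n_genes
    autosomes = [c for c in config.chrom_names if c not in ("chrX", "chrY")]
    sex_chroms = [c for c in config.chrom_names if c in ("chrX", "chrY")]

    is_sex = rng.random(n) < config.sex_chrom_fraction
    chroms = np.where(
        is_sex,
        rng.choice(sex_chroms if sex_chroms else autosomes, size=n),
        rng.choice(autosomes, size=n),
    )
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, size=n)
    gaps = rng.integers(config.gap_range[0], config.gap_range[1] + 1, size=n)
    strands = rng.choice(["+", "-"], size=n)

    cursor: dict[str, int] = {}
    rows = []
    for i in range(n):
        gene = f"gene{i:05d}"
        chrom = str(chroms[i])
        pos = cursor.get(chrom, int(gaps[i]))
        tx_start = pos
        tx_end = pos + int(lengths[i])
        cursor[chrom] = tx_end + int(gaps[i])
        rows.append((gene, f"{gene}.t1", chrom, str(strands[i]), tx_start, tx_end))
        for t in range(2, config.transcripts_per_gene + 1):
            shift = min(500 * (t - 1), (tx_end - tx_start) // 2)
            rows.append((gene, f"{gene}.t{t}", chrom, str(strands[i]),
                         tx_start + shift, tx_end))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def generate_truth(genes: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Planted per-gene, per-condition states, expression means, orthologs.

    Base-condition states are drawn from ``state_freqs``; each other
    condition applies ``transition_spec`` to the base state gene-wise.
    Conserved genes (a ``conserved_fraction`` Bernoulli draw) are assigned a
    target-species ortholog identifier.
    """
    config.validate()
    rng = _rng(config, "truth")
    gene_ids = list(dict.fromkeys(genes["gene_symbol"]))
    n = len(gene_ids)
    codes = sorted(config.state_freqs)
    probs = np.array([config.state_freqs[s] for s in codes])
    base_states = rng.choice(codes, size=n, p=probs / probs.sum())

    states_by_cond: dict[str, np.ndarray] = {config.conditions[0]: base_states}
    per_cond = config._transitions_by_condition()
    for cond in config.conditions[1:]:
        spec = per_cond.get(cond, {})
        by_from: dict[str, list[tuple[str, float]]] = {}
        for (sf, st), p in spec.items():
            by_from.setdefault(sf, []).append((st, p))
        u = rng.random(n)
        new = base_states.copy()
        for i, s in enumerate(base_states):
            acc = 0.0
            for st, p in by_from.get(s, ()):
                acc += p
                if u[i] < acc:
                    new[i] = st
                    break
        states_by_cond[cond] = new

    conserved = rng.random(n) < config.conserved_fraction
    orthologs = np.array([f"h-{g}" if c else "" for g, c in zip(gene_ids, conserved)])

    missing = sorted({s for arr in states_by_cond.values() for s in arr}
                     - set(config.expr_state_means))
    if missing:
        raise ConfigurationError(
            f"expr_state_means: no mean defined for planted state(s) {missing}")

    rows = []
    for cond in config.conditions:
        arr = states_by_cond[cond]
        for i, g in enumerate(gene_ids):
            rows.append((g, cond, arr[i], config.expr_state_means[arr[i]],
                         orthologs[i] or None))
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "state",
                       "expression_mean", "species_ortholog"])


def _planted_peak(mark: str, strand: str, tx_start: int, tx_end: int,
                  config: SynthConfig) -> tuple[int, int]:
    if mark == "H3K4me3":  # sharp peak centred on the TSS
        pos = tx_start if strand == "+" else tx_end - 1
        start = max(0, pos - config.k4_breadth // 2)
        return start, start + config.k4_breadth
    return tx_start, tx_end  # broad peak spanning the gene body


def generate_peak_replicates(
    truth: pd.DataFrame, genes: pd.DataFrame, config: SynthConfig,
) -> tuple[dict[tuple[str, str, str], list[PeakRecord]], pd.DataFrame]:
    """Two replicate peak tables per condition and mark.

    For every gene-mark planted as 1, a peak is emitted in both replicates
    with probability 1 - ``replicate_dropout``, otherwise in one randomly
    chosen replicate; fold enrichment is drawn per record from the
    configured lognormal, so single-replicate peaks survive downstream
    consolidation only when their draw exceeds the reliability threshold.
    Peak edges are jittered by a rounded Gaussian of SD ``jitter_sd``.
    False peaks (both replicates, per-mark rate per Mb) are placed at least
    2 kb away from any gene so they never contribute gene calls.

    Returns the peak tables keyed by (condition, mark, replicate) and the
    unchanged truth table.
    """
    config.validate()
    rng = _rng(config, "peaks")
    gene_info = {}
    for row in genes.itertuples(index=False):
        gene_info.setdefault(row.gene_symbol, row)
    unknown = sorted(set(truth["gene_id"]) - set(gene_info))
    if unknown:
        raise ConsistencyError(
            f"truth references genes absent from the models (e.g. {unknown[:3]})")

    replicates = ("rep1", "rep2")
    tables: dict[tuple[str, str, str], list[PeakRecord]] = {
        (c, m, r): [] for c in config.conditions for m in MARKS for r in replicates}

    mu, sigma = config.fe_lognorm

    def emit(cond: str, mark: str, rep: str, chrom: str, start: int, end: int,
             tag: str) -> None:
        if config.jitter_sd > 0:
            start = max(0, start + int(round(rng.normal(0, config.jitter_sd))))
            end = end + int(round(rng.normal(0, config.jitter_sd)))
            end = max(end, start + 50)
        fe = float(rng.lognormal(mu, sigma))
        tags = int(rng.poisson(60 if mark == "H3K4me3" else 200)) + 1
        key = (cond, mark, rep)
        tables[key].append(PeakRecord(
            chrom=chrom, start=start, end=end, mark=mark, replicate=rep,
            fold_enrichment=fe, tags=tags, summit=(end - start) // 2,
            neg_log10_p=float(rng.uniform(50, 300)),
            record_id=f"{cond}:{mark}:{rep}:{tag}",
        ))

    for cond in config.conditions:
        sub = truth[truth["condition"] == cond]
        for g, state in zip(sub["gene_id"], sub["state"]):
            info = gene_info[g]
            for mark, bit in zip(MARKS, state):
                if bit != "1":
                    continue
                start, end = _planted_peak(mark, info.strand, info.txStart,
                                           info.txEnd, config)
                both = rng.random() >= config.replicate_dropout
                if both:
                    reps = replicates
                else:
                    reps = (replicates[int(rng.integers(0, 2))],)
                for rep in reps:
                    emit(cond, mark, rep, info.chrom, start, end, g)

    if config.false_peak_rate > 0:
        segments = _intergenic_segments(genes, config)
        total = sum(e - s for _, s, e in segments)
        weights = np.array([e - s for _, s, e in segments], dtype=float)
        if total > 0:
            weights /= weights.sum()
            for cond in config.conditions:
                for mark in MARKS:
                    n_false = int(rng.poisson(config.false_peak_rate * total / 1e6))
                    for j in range(n_false):
                        chrom, s, e = segments[int(rng.choice(len(segments), p=weights))]
                        pos = int(rng.integers(s, e))
                        for rep in replicates:
                            emit(cond, mark, rep, chrom, pos,
                                 pos + config.false_peak_breadth, f"false{j}")

    for key in tables:
        tables[key].sort(key=lambda r: (r.chrom, r.start, r.end))
    return tables, truth


def _intergenic_segments(genes: pd.DataFrame,
                         config: SynthConfig) -> list[tuple[str, int, int]]:
    """Intervals >= 2 kb clear of any gene where false peaks may start."""
    margin = 2000
    breadth = config.false_peak_breadth
    segments = []
    for chrom, sub in genes.groupby("chrom"):
        spans = sorted(zip(sub["txStart"], sub["txEnd"]))
        prev_end = 0
        for s, e in spans:
            lo, hi = prev_end + margin, s - margin - breadth
            if hi > lo:
                segments.append((chrom, lo, hi))
            prev_end = max(prev_end, e)
    return segments


def generate_expression(truth: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Per-gene, per-condition log-scale expression values.

    value = planted state mean + Gaussian(0, ``expr_noise_sd``); the default
    means order the states 101 > 100 > 000 ~ 110 > 010.
    """
    config.validate()
    rng = _rng(config, "expression")
    missing = sorted(set(truth["state"]) - set(config.expr_state_means))
    if missing:
        raise ConfigurationError(
            f"expr_state_means: no mean defined for state(s) {missing}")
    noise = rng.normal(0.0, config.expr_noise_sd, size=len(truth)) \
        if config.expr_noise_sd > 0 else np.zeros(len(truth))
    out = truth[["gene_id", "condition"]].copy()
    out["value"] = truth["state"].map(config.expr_state_means).to_numpy() + noise
    return out


def generate_ortholog_map(truth: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Two-column (+confidence) ortholog map for the conserved genes.

    A ``one_to_many_fraction`` of conserved genes receives a second,
    lower-confidence target to exercise the de-duplication rule downstream.
    """
    config.validate()
    rng = _rng(config, "orthologs")
    base = truth[truth["condition"] == truth["condition"].iloc[0]] if len(truth) else truth
    conserved = base[base["species_ortholog"].notna()]
    rows = []
    for g, t in zip(conserved["gene_id"], conserved["species_ortholog"]):
        conf = float(rng.uniform(0.5, 1.0))
        rows.append((g, t, conf))
        if rng.random() < config.one_to_many_fraction:
            rows.append((g, f"{t}-alt", conf * 0.5))
    return pd.DataFrame(rows, columns=["source_gene", "target_gene", "confidence"])


def generate_ortholog_states(truth: pd.DataFrame, orthologs: pd.DataFrame,
                             config: SynthConfig,
                             condition: str | None = None) -> pd.Series:
    """Synthetic target-species state table for the mapped orthologs.

    Each primary ortholog keeps the source gene's state with probability
    ``ortholog_state_agreement`` and otherwise draws a state from
    ``state_freqs``; secondary ("-alt") targets always draw at random. This
    stands in for an independently measured target-species state table.
    """
    config.validate()
    rng = _rng(config, "ortholog_states")
    cond = condition or truth["condition"].iloc[0]
    source = truth[truth["condition"] == cond].set_index("gene_id")["state"]
    codes = sorted(config.state_freqs)
    probs = np.array([config.state_freqs[s] for s in codes])
    probs = probs / probs.sum()
    out = {}
    for row in orthologs.itertuples(index=False):
        primary = not row.target_gene.endswith("-alt")
        src_state = source.get(row.source_gene)
        if primary and src_state is not None and \
                rng.random() < config.ortholog_state_agreement:
            out[row.target_gene] = src_state
        else:
            out[row.target_gene] = str(rng.choice(codes, p=probs))
    s = pd.Series(out, dtype=str)
    s.index.name = "gene_symbol"
    s.name = "target"
    return s


def simulate_study(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic study to ``outdir``.

    Writes gene models (refFlat TSV), the truth table, per-condition
    per-mark per-replicate MACS-style peak tables, expression, the ortholog
    map, and a synthetic target-species state table. Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = generate_gene_models(config)
    truth = generate_truth(genes, config)
    peaks, truth = generate_peak_replicates(truth, genes, config)
    expr = generate_expression(truth, config)
    orthologs = generate_ortholog_map(truth, config)
    target_states = generate_ortholog_states(truth, orthologs, config)

    paths: dict[str, Path] = {}
    paths["genes"] = outdir / "genes.refflat.tsv"
    write_refflat(genes, paths["genes"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False)
    paths["orthologs"] = outdir / "orthologs.tsv"
    orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
    paths["target_states"] = outdir / "target_states.tsv"
    target_states.rename("state").rename_axis("gene_symbol").to_csv(
        paths["target_states"], sep="\t")
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (cond, mark, rep), records in peaks.items():
        p = peak_dir / f"{cond}.{mark}.{rep}.tsv"
        write_peak_table(records, p)
        paths[f"peaks/{cond}.{mark}.{rep}"] = p
    return paths
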