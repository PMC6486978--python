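"""Gene-set scoring and expression preprocessing.

The GSZ score standardizes the sum of per-gene values over a gene set
against a sampling-without-replacement null: drawing m of the N universe
genes at random,

    GSZ(S) = (sum_{g in S} v_g - m*mu) / sqrt(m * sigma^2 * (N-m)/(N-1))

with mu and sigma^2 the population mean and variance of the universe
values. Applied to binary modification indicators it measures how strongly
a functional gene set is dominated by modified genes; applied to
log-expression it is a set-level expression score. Over-representation of a
gene set in an annotation uses the hypergeometric upper tail.

Expression preprocessing mirrors common practice: RNA-seq counts to
log2(RPKM + 1); array intensities filtered on detection p-values and
quantile-normalized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolation
from .states import TransitionSet


def gsz_score(values: pd.Series, gene_set: Iterable[str], min_size: int = 2) -> float:
    """Standardized gene-set sum of per-gene values (GSZ score).

    ``values`` is the universe vector (index = gene symbols); genes of
    ``gene_set`` outside the universe are ignored. Returns 0.0 for the
    degenerate nulls (zero universe variance, or the set being the whole
    universe). Raises on sets smaller than ``min_size`` after intersection.
    """
    if values.isna().any() or not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("universe values must be finite")
    members = values.index.intersection(pd.Index(list(gene_set)))
    m = len(members)
    n = len(values)
    if m < min_size:
        raise ContractViolation(
            f"gene set has {m} genes in the universe; minimum is {min_size}"
        )
    v = values.to_numpy(dtype=float)
    mu = v.mean()
    var = v.var()  # population variance
    if var == 0 or m == n:
        return 0.0
    set_sum = float(values.loc[members].sum())
    denom = math.sqrt(m * var * (n - m) / (n - 1))
    return (set_sum - m * mu) / denom


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of ``annotation`` genes within a gene set."""

    set_id: str
    set_size: int          # n drawn
    overlap: int           # k observed
    expected: float        # n*K/N under the null
    p_value: float         # P(X >= k), hypergeometric upper tail
    direction: str         # "over" | "under"


def hypergeometric_enrichment(gene_set: Iterable[str], annotation: Iterable[str],
                              universe: Iterable[str],
                              set_id: str = "") -> EnrichmentResult:
    """Hypergeometric over-representation test.

    With N = |universe|, K = |annotation|, n = |gene_set| and k the observed
    overlap, p = P(X >= k) for X ~ Hypergeom(N, K, n). Genes outside the
    universe are dropped from both sets.
    """
    uni = set(universe)
    if not uni:
        raise ContractViolation("universe is empty")
    s = set(gene_set) & uni
    ann = set(annotation) & uni
    n, big_k, big_n = len(s), len(ann), len(uni)
    k = len(s & ann)
    expected = n * big_k / big_n
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return EnrichmentResult(
        set_id=set_id, set_size=n, overlap=k, expected=expected,
        p_value=p, direction="over" if k >= expected else "under",
    )


def adjust_pvalues(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvalues), method="fdr_bh")[1]


def rpkm_log(counts: pd.Series, gene_lengths: Mapping[str, float],
             library_size: float | None = None, base: float = 2.0,
             pseudocount: float = 1.0) -> pd.Series:
    """Raw counts to log-scale RPKM: log2(RPKM + 1) by default.

    RPKM = count / ((length/1000) * (library_size/1e6)). ``library_size``
    defaults to the sum of counts.
    """
    missing = [g for g in counts.index if g not in gene_lengths]
    if missing:
        raise ContractViolation(
            f"{len(missing)} counted genes lack a length (e.g. {missing[:3]})"
        )
    if library_size is None:
        library_size = float(counts.sum())
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    lengths = pd.Series({g: float(gene_lengths[g]) for g in counts.index})
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rpkm = counts / ((lengths / 1e3) * (library_size / 1e6))
    out = np.log(rpkm + pseudocount) / np.log(base)
    out.name = counts.name
    return out


def quantile_normalize(matrix: pd.DataFrame,
                       detection_p: pd.DataFrame | None = None,
                       p_cut: float = 0.05) -> pd.DataFrame:
    """Quantile normalization of a genes x samples matrix.

    When ``detection_p`` is given (same shape), genes are first filtered to
    those detected (p < ``p_cut``) in at least one sample. Then each
    column's sorted values are replaced by the across-sample mean at each
    rank; ties receive the interpolated value at their average rank.
    """
    if matrix.shape[1] < 2:
        raise ContractViolation("quantile normalization needs >= 2 samples")
    if detection_p is not None:
        detected = (detection_p.reindex_like(matrix) < p_cut).any(axis=1)
        matrix = matrix.loc[detected]
        if matrix.empty:
            raise ContractViolation("all genes removed by the detection filter")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    ranks = matrix.rank(method="average").to_numpy()  # 1-based, fractional on ties
    out = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def expression_by_state(states: pd.Series, expr: pd.Series) -> pd.DataFrame:
    """Expression summary (n, mean, quartiles) per triplet state.

    Only genes present in both tables contribute. Rows are the states
    observed among shared genes, ordered by descending mean expression.
    """
    common = states.index.intersection(expr.index)
    if len(common) == 0:
        raise ContractViolation("states and expression share no genes")
    df = pd.DataFrame({"state": states.loc[common], "value": expr.loc[common]})
    summary = df.groupby("state")["value"].agg(
        n="size", mean="mean", median="median",
        q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75),
    )
    return summary.sort_values("mean", ascending=False)


def set_vs_stable_expression(tset: TransitionSet, states_a: pd.Series,
                             states_b: pd.Series, expr: pd.Series) -> pd.DataFrame:
    """Compare a transition set's expression with its stable flanking states.

    Returns summaries for the set's genes and for genes stably in the
    from-state and stably in the to-state across both conditions (e.g. a
    100->101 set against stable [100] and stable [101] genes).
    """
    common = states_a.index.intersection(states_b.index).intersection(expr.index)
    if len(common) == 0:
        raise ContractViolation("no genes shared between states and expression")
    av, bv = states_a.loc[common], states_b.loc[common]
    groups = {
        tset.label: common.intersection(pd.Index(list(tset.genes))),
        f"stable {tset.from_state}": common[(av == tset.from_state).values
                                            & (bv == tset.from_state).values],
        f"stable {tset.to_state}": common[(av == tset.to_state).values
                                          & (bv == tset.to_state).values],
    }
    rows = {}
    for label, idx in groups.items():
        vals = expr.loc[idx]
        rows[label] = {
            "n": len(vals),
            "mean": vals.mean() if len(vals) else float("nan"),
            "median": vals.median() if len(vals) else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3 and f[0]:
                sets[f[0]] = {g for g in f[2:] if g}
    return sets
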