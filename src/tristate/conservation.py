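"""Cross-species state conservation via an ortholog map.

Source-species gene states (e.g. mouse intestine) are paired with
target-species states (e.g. human colon, or an independent mouse dataset
treated the same way) through a two- or three-column ortholog table.
"Conserved" is operational: a gene counts as conserved when it has an
ortholog that is present in the target state table. One-to-many orthology
is resolved to the highest-confidence target, ties to the lexicographically
smallest target id.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ContractViolation, ParseError
from .states import TransitionSet


def read_orthologs(path: str | Path) -> pd.DataFrame:
    """Read an ortholog map TSV: source_gene, target_gene[, confidence]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, header=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected >= 2 columns")
    df = df.rename(columns={df.columns[0]: "source_gene",
                            df.columns[1]: "target_gene"})
    if df.shape[1] >= 3:
        df = df.rename(columns={df.columns[2]: "confidence"})
    else:
        df["confidence"] = 1.0
    if (df["source_gene"].astype(str).str.len() == 0).any() or \
       (df["target_gene"].astype(str).str.len() == 0).any():
        raise ParseError(f"{path}: empty gene identifier")
    return df[["source_gene", "target_gene", "confidence"]]


def map_orthologs(states_source: pd.Series, orthologs: pd.DataFrame,
                  states_target: pd.Series) -> pd.DataFrame:
    """Pair source genes with their ortholog's state in the target species.

    Only orthologs present in the target state table count; among those,
    each source gene keeps its single best pairing (highest confidence,
    then smallest target id). Result columns: source_gene, source_state,
    target_gene, target_state. An empty pairing is valid.
    """
    ortho = orthologs.copy()
    if "confidence" not in ortho.columns:
        ortho["confidence"] = 1.0
    ortho = ortho[ortho["source_gene"].isin(states_source.index)
                  & ortho["target_gene"].isin(states_target.index)]
    ortho = ortho.sort_values(
        ["source_gene", "confidence", "target_gene"],
        ascending=[True, False, True], kind="mergesort",
    ).drop_duplicates("source_gene", keep="first")
    paired = pd.DataFrame({
        "source_gene": ortho["source_gene"].to_numpy(),
        "source_state": states_source.loc[ortho["source_gene"]].to_numpy(),
        "target_gene": ortho["target_gene"].to_numpy(),
        "target_state": states_target.loc[ortho["target_gene"]].to_numpy(),
    })
    return paired.sort_values("source_gene", kind="mergesort").reset_index(drop=True)


def printed_pct(value: float, decimals: int | str = "auto") -> float:
    """Round a percentage half-up at a report precision.

    ``decimals="auto"`` uses one decimal below 80% and integers at or above
    (the mixed convention of typical reports); an integer forces that many
    decimals.
    """
    if decimals == "auto":
        decimals = 1 if value < 80 else 0
    q = Decimal(1).scaleb(-int(decimals))
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CrossSpeciesSummary:
    """Conservation of a gene set's modification states across species."""

    label: str
    n_source: int
    n_conserved: int
    conserved_pct: float                      # 100 * n_conserved / n_source
    state_profile_pct: dict[str, float] = field(default_factory=dict)
    reference_state: str | None = None
    reference_state_pct: float | None = None  # % of conserved in reference state

    def printed(self, decimals: int | str = "auto") -> dict[str, float]:
        out = {"conserved_pct": printed_pct(self.conserved_pct, decimals)}
        if self.reference_state_pct is not None:
            out["reference_state_pct"] = printed_pct(self.reference_state_pct, decimals)
        return out


def conservation_summary(gene_set: TransitionSet | Iterable[str],
                         paired: pd.DataFrame,
                         reference_state: str | None = None,
                         label: str | None = None) -> CrossSpeciesSummary:
    """Summarize cross-species conservation for one gene set.

    ``n_conserved`` counts set members with a pairing; the state profile
    gives the percentage of each target state among conserved members.
    ``reference_state`` (typically the set's source-species state) adds the
    percentage of conserved members whose target state matches it.
    """
    if isinstance(gene_set, TransitionSet):
        members = set(gene_set.genes)
        label = label or gene_set.label
    else:
        members = set(gene_set)
        label = label or "gene_set"
    if not members:
        raise ContractViolation("gene set is empty")

    sub = paired[paired["source_gene"].isin(members)]
    n_source = len(members)
    n_conserved = len(sub)
    conserved_pct = 100.0 * n_conserved / n_source
    profile: dict[str, float] = {}
    ref_pct: float | None = None
    if n_conserved:
        counts = sub["target_state"].value_counts()
        profile = {s: 100.0 * c / n_conserved for s, c in sorted(counts.items())}
        if reference_state is not None:
            ref_pct = profile.get(reference_state, 0.0)
    elif reference_state is not None:
        ref_pct = 0.0
    return CrossSpeciesSummary(
        label=label, n_source=n_source, n_conserved=n_conserved,
        conserved_pct=conserved_pct, state_profile_pct=profile,
        reference_state=reference_state, reference_state_pct=ref_pct,
    )
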