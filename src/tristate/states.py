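"""Triplet state coding and state-transition analysis between conditions.

Each gene gets a 3-character 0/1 code in the mark order
[H3K4me3 H3K27me3 H3K36me3]: "100" = H3K4me3 only, "101" = H3K4me3 +
H3K36me3 (stable activation), "110" = bivalent, "010" = H3K27me3 only
(repression). Comparing two conditions, genes with unequal codes are
"differentially modified"; a transition matrix over the most frequent
states counts genes per (state_from, state_to) cell, and named transition
sets (e.g. 100->101) collect the genes of one cell.

A StateTable is a :class:`pandas.Series` mapping gene_symbol -> state code,
with the condition label in ``.name``.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ContractViolation
from .peaks import MARKS

#: All eight triplet codes, "000" .. "111".
ALL_STATES = tuple(f"{i:03b}" for i in range(8))

#: Epigenetic activation ordering, ascending from repression to stable
#: activation. States 001/011/111 have no defined rank and are excluded
#: from activated/repressed totals.
ACTIVATION_ORDER = ("010", "000", "110", "100", "101")
_ACTIVATION_RANK = {s: i for i, s in enumerate(ACTIVATION_ORDER)}

_STATE_RE = re.compile(r"^[01]{3}$")


def _check_state(state: str) -> str:
    if not isinstance(state, str) or not _STATE_RE.match(state):
        raise ValueError(f"malformed state code {state!r}; expected 3 chars over {{0,1}}")
    return state


def encode_states(calls: pd.DataFrame) -> pd.Series:
    """Concatenate the three 0/1 mark calls into per-gene triplet codes."""
    missing = [m for m in MARKS if m not in calls.columns]
    if missing:
        raise ContractViolation(f"call table lacks mark columns {missing}")
    codes = (
        calls[MARKS[0]].astype(int).astype(str)
        + calls[MARKS[1]].astype(int).astype(str)
        + calls[MARKS[2]].astype(int).astype(str)
    )
    codes.name = calls.attrs.get("condition")
    return codes


def decode_state(state: str) -> dict[str, int]:
    """Inverse of :func:`encode_states` for a single code."""
    _check_state(state)
    return {mark: int(bit) for mark, bit in zip(MARKS, state)}


def state_distribution(states: pd.Series) -> pd.DataFrame:
    """Counts and fractions of genes per triplet state.

    All eight codes appear (zero counts included); rows are ordered by
    descending count, ties broken by code.
    """
    if states is None or len(states) == 0:
        raise ContractViolation("state table is empty")
    counts = states.value_counts().reindex(ALL_STATES, fill_value=0)
    dist = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    dist.index.name = "state"
    return dist.sort_values(["count", "state"], ascending=[False, True],
                            kind="mergesort")


def _shared_universe(a: pd.Series, b: pd.Series) -> pd.Index:
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ContractViolation("state tables share no genes")
    if len(common) != len(a) or len(common) != len(b):
        warnings.warn(
            f"state tables have unequal gene universes ({len(a)} vs {len(b)}); "
            f"using the {len(common)}-gene intersection",
            stacklevel=3,
        )
    return common


def differential_genes(a: pd.Series, b: pd.Series) -> set[str]:
    """Genes whose triplet state differs between the two conditions."""
    common = _shared_universe(a, b)
    av, bv = a.loc[common], b.loc[common]
    return set(common[av.values != bv.values])


def top_k_states(states: pd.Series, k: int = 5,
                 reference: pd.Series | None = None) -> list[str]:
    """The ``k`` most frequent states, in activation order.

    Frequency is measured in ``reference`` (default: ``states`` itself,
    conventionally the untreated control condition). The selected states are
    arranged ascending from epigenetic repression [010] to stable activation
    [101]; states outside that ordering are appended by descending
    frequency, ties broken lexicographically.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    ref = states if reference is None else reference
    counts = ref.value_counts()
    ranked = sorted(counts.index, key=lambda s: (-counts[s], s))
    chosen = ranked[:k]
    in_order = [s for s in ACTIVATION_ORDER if s in chosen]
    extra = sorted((s for s in chosen if s not in _ACTIVATION_RANK),
                   key=lambda s: (-counts[s], s))
    return in_order + extra


@dataclass
class TransitionMatrix:
    """Gene counts per (state_from, state_to) over an ordered state list."""

    states: list[str]
    counts: pd.DataFrame  # index = state_from, columns = state_to
    n_activated: int
    n_repressed: int
    n_diagonal: int
    condition_pair: tuple[str | None, str | None] = (None, None)

    @property
    def n_differential(self) -> int:
        """Off-diagonal total: differential genes within the state list."""
        total = int(self.counts.values.sum())
        return total - self.n_diagonal


@dataclass(frozen=True)
class TransitionSet:
    """Genes sharing one state change, labelled ``XYZ->X'Y'Z'``."""

    label: str
    genes: frozenset[str]

    @property
    def from_state(self) -> str:
        return self.label.split("->")[0]

    @property
    def to_state(self) -> str:
        return self.label.split("->")[1]

    def __len__(self) -> int:
        return len(self.genes)


def transition_matrix(a: pd.Series, b: pd.Series,
                      state_list: list[str] | None = None) -> TransitionMatrix:
    """Tabulate state changes between condition a and condition b.

    Only genes whose state lies in ``state_list`` in *both* conditions are
    counted. The diagonal holds unchanged genes. With the states arranged in
    activation order, cells below the diagonal are epigenetic activations
    and cells above are repressions; totals count only ranked states.
    """
    if state_list is None:
        state_list = list(ALL_STATES)
    if not state_list:
        raise ContractViolation("state_list must be non-empty")
    for s in state_list:
        _check_state(s)
    common = _shared_universe(a, b)
    av, bv = a.loc[common], b.loc[common]
    keep = av.isin(state_list) & bv.isin(state_list)
    av, bv = av[keep], bv[keep]

    counts = pd.crosstab(av, bv).reindex(
        index=state_list, columns=state_list, fill_value=0
    )
    counts.index.name = "state_from"
    counts.columns.name = "state_to"

    n_act = n_rep = n_diag = 0
    for sf in state_list:
        for st in state_list:
            c = int(counts.at[sf, st])
            if sf == st:
                n_diag += c
            elif sf in _ACTIVATION_RANK and st in _ACTIVATION_RANK:
                if _ACTIVATION_RANK[st] > _ACTIVATION_RANK[sf]:
                    n_act += c
                else:
                    n_rep += c
    return TransitionMatrix(
        states=list(state_list), counts=counts,
        n_activated=n_act, n_repressed=n_rep, n_diagonal=n_diag,
        condition_pair=(a.name, b.name),
    )


def extract_transition_set(a: pd.Series, b: pd.Series,
                           from_state: str, to_state: str) -> TransitionSet:
    """All genes with state ``from_state`` in a and ``to_state`` in b."""
    _check_state(from_state)
    _check_state(to_state)
    common = _shared_universe(a, b)
    av, bv = a.loc[common], b.loc[common]
    members = common[(av.values == from_state) & (bv.values == to_state)]
    return TransitionSet(label=f"{from_state}->{to_state}",
                         genes=frozenset(members))


def intersect_transition_sets(s1: TransitionSet, s2: TransitionSet,
                              allow_label_mismatch: bool = False) -> TransitionSet:
    """Intersection of two transition sets (same state change required).

    Two sets from different condition pairs but the same XYZ->X'Y'Z' label
    intersect directly (e.g. Set1 after mutation vs Set1 after radiation);
    intersecting different state changes requires ``allow_label_mismatch``.
    """
    if s1.label != s2.label and not allow_label_mismatch:
        raise ContractViolation(
            f"transition-set labels differ ({s1.label} vs {s2.label}); "
            "pass allow_label_mismatch=True to intersect anyway"
        )
    label = s1.label if s1.label == s2.label else f"{s1.label}&{s2.label}"
    return TransitionSet(label=label, genes=s1.genes & s2.genes)


def write_state_table(states: pd.Series, path: str | Path) -> None:
    states.rename("state").rename_axis("gene_symbol").to_csv(path, sep="\t")


def read_state_table(path: str | Path, condition: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("gene_symbol")
    s = df["state"].map(_check_state)
    s.name = condition
    return s
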