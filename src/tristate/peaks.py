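"""Peak records, peak-table IO, and replicate consolidation.

A condition is assayed in two ChIP-seq replicates per histone mark. The
"summarized quality peak list" for the condition keeps a peak if it is
detected in both replicates (any positional overlap) or, when found in one
replicate only, if its MACS fold enrichment exceeds a reliability threshold
(default 5.0, strict). For replicate-consistent peaks the consolidated
interval is that of the broadest supporting peak and the tag density is the
maximum over supporting peaks.

Coordinates are 0-based half-open (BED convention) in every dialect read or
written here; the ``length`` column of the MACS-style table equals
``end - start``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ContractViolation, ParseError

#: The three histone-H3 tri-methylation marks, in triplet-code order.
MARKS = ("H3K4me3", "H3K27me3", "H3K36me3")

MACS14_COLUMNS = (
    "chr",
    "start",
    "end",
    "length",
    "summit",
    "tags",
    "-10*log10(pvalue)",
    "fold_enrichment",
)

DIALECTS = ("macs14_tsv", "bed6", "narrowPeak")


@dataclass(frozen=True)
class PeakRecord:
    """One called peak for one mark in one replicate."""

    chrom: str
    start: int
    end: int
    mark: str
    replicate: str
    fold_enrichment: float
    tags: int = 0
    summit: int | None = None
    neg_log10_p: float | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConsolidatedPeak:
    """A peak retained in the per-condition summarized quality list.

    ``support`` records why it survived: ``both_replicates`` (overlapping
    calls in rep1 and rep2; interval of the broadest source, tags = max) or
    ``single_high_fe`` (one replicate only, fold enrichment above threshold).
    """

    chrom: str
    start: int
    end: int
    mark: str
    tags: int
    support: str
    source_ids: tuple[str, ...] = field(default_factory=tuple)
    fold_enrichment: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_fields(fields: list[str], dialect: str, mark: str, replicate: str,
                  lineno: int, path: str) -> PeakRecord:
    def bad(msg: str) -> ParseError:
        return ParseError(f"{path}:{lineno}: {msg}")

    try:
        if dialect == "macs14_tsv":
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            summit = int(fields[4])
            tags = int(fields[5])
            nlp = float(fields[6])
            fe = float(fields[7])
        elif dialect == "bed6":
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            summit, nlp = None, None
            tags = 0
            fe = float(fields[4])  # score column doubles as fold enrichment
        elif dialect == "narrowPeak":
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            tags = int(float(fields[4]))
            fe = float(fields[6])  # signalValue
            nlp = float(fields[7])
            summit = int(fields[9])
            if summit < 0:
                summit = None
        else:
            raise ParseError(f"unknown peak dialect {dialect!r}; expected one of {DIALECTS}")
    except (IndexError, ValueError) as exc:
        if isinstance(exc, ParseError):
            raise
        raise bad(f"malformed {dialect} line: {exc}") from None
    if end <= start:
        raise bad(f"negative-length interval {chrom}:{start}-{end}")
    return PeakRecord(
        chrom=chrom, start=start, end=end, mark=mark, replicate=replicate,
        fold_enrichment=fe, tags=tags, summit=summit, neg_log10_p=nlp,
        record_id=f"{replicate}:{lineno}",
    )


def read_peak_table(path: str | Path, dialect: str, mark: str,
                    replicate: str = "rep1") -> list[PeakRecord]:
    """Read a per-replicate peak table into :class:`PeakRecord` objects.

    Parameters
    ----------
    path
        TSV file in the named dialect. ``macs14_tsv`` expects a header line
        with columns ``chr start end length summit tags -10*log10(pvalue)
        fold_enrichment``; ``bed6`` and ``narrowPeak`` are headerless.
    dialect
        One of ``macs14_tsv``, ``bed6``, ``narrowPeak``. For narrowPeak the
        signalValue column is used as the fold enrichment.
    mark, replicate
        Labels attached to every record (the files carry neither).
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown peak dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "macs14_tsv" and lineno == 1 and fields[0] == "chr":
                continue  # header
            records.append(_parse_fields(fields, dialect, mark, replicate,
                                         lineno, str(path)))
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    """Write records as a MACS-1.4-style TSV (header + 8 columns)."""
    with open(path, "w") as fh:
        fh.write("\t".join(MACS14_COLUMNS) + "\n")
        for r in records:
            summit = r.summit if r.summit is not None else r.length // 2
            nlp = r.neg_log10_p if r.neg_log10_p is not None else 0.0
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.length}\t{summit}\t"
                f"{r.tags}\t{nlp:.2f}\t{r.fold_enrichment:.5f}\n"
            )


def write_consolidated_bed(peaks: Iterable[ConsolidatedPeak], path: str | Path) -> None:
    """Write consolidated peaks as BED6 (name = support, score = tags)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.support}\t{p.tags}\t.\n")


def write_consolidated_tsv(peaks: Iterable[ConsolidatedPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmark\ttags\tsupport\tfold_enrichment\tsource_ids\n")
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.mark}\t{p.tags}\t{p.support}\t"
                f"{p.fold_enrichment:.5f}\t{','.join(p.source_ids)}\n"
            )


def read_consolidated_tsv(path: str | Path) -> list[ConsolidatedPeak]:
    peaks: list[ConsolidatedPeak] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ParseError(f"{path}:1: expected consolidated-peak header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(ConsolidatedPeak(
                chrom=f[0], start=int(f[1]), end=int(f[2]), mark=f[3],
                tags=int(f[4]), support=f[5], fold_enrichment=float(f[6]),
                source_ids=tuple(f[7].split(",")) if len(f) > 7 and f[7] else (),
            ))
    return peaks


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _overlap_len(a: PeakRecord, b: PeakRecord) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def _matches(a: PeakRecord, b: PeakRecord, min_rep_overlap: float) -> bool:
    ov = _overlap_len(a, b)
    if min_rep_overlap < 1:  # fraction of the shorter peak
        need = min_rep_overlap * min(a.length, b.length)
        return ov >= need - 1e-9 and ov > 0
    return ov >= min_rep_overlap


def consolidate_replicates(
    rep1: Sequence[PeakRecord],
    rep2: Sequence[PeakRecord],
    fe_threshold: float = 5.0,
    min_rep_overlap: float = 1,
) -> list[ConsolidatedPeak]:
    """Build the summarized quality peak list from two replicates.

    Overlapping rep1/rep2 peaks are grouped into connected components; each
    component containing peaks from both replicates becomes one consolidated
    peak with the interval of its broadest member and the maximum tag count.
    Peaks with no cross-replicate match are kept only if their fold
    enrichment strictly exceeds ``fe_threshold``.

    ``min_rep_overlap`` is the match criterion: an integer >= 1 is a minimum
    overlap in bases (default 1 bp); a value < 1 is interpreted as a fraction
    of the shorter peak's length.
    """
    records = list(rep1) + list(rep2)
    if not records:
        return []
    marks = {r.mark for r in records}
    if len(marks) > 1:
        raise ContractViolation(f"mixed marks in consolidation input: {sorted(marks)}")
    labels1 = {r.replicate for r in rep1}
    labels2 = {r.replicate for r in rep2}
    if labels1 & labels2:
        raise ContractViolation(
            f"replicate labels are not distinct: {sorted(labels1 & labels2)}"
        )

    n1 = len(rep1)
    uf = _UnionFind(len(records))
    # bipartite overlap edges rep1 <-> rep2, per chromosome
    trees: dict[str, IntervalTree] = {}
    for j, r in enumerate(rep2):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, n1 + j)
    for i, r in enumerate(rep1):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            if _matches(r, rep2[iv.data - n1], min_rep_overlap):
                uf.union(i, iv.data)

    components: dict[int, list[int]] = {}
    for idx in range(len(records)):
        components.setdefault(uf.find(idx), []).append(idx)

    out: list[ConsolidatedPeak] = []
    for members in components.values():
        reps = {records[i].replicate for i in members}
        if len(reps) >= 2:
            broadest = min(
                members,
                key=lambda i: (-records[i].length, records[i].start, records[i].end),
            )
            b = records[broadest]
            out.append(ConsolidatedPeak(
                chrom=b.chrom, start=b.start, end=b.end, mark=b.mark,
                tags=max(records[i].tags for i in members),
                support="both_replicates",
                source_ids=tuple(sorted(records[i].record_id for i in members)),
                fold_enrichment=max(records[i].fold_enrichment for i in members),
            ))
        else:
            for i in members:  # singletons (bipartite graph: one peak each)
                r = records[i]
                if r.fold_enrichment > fe_threshold:
                    out.append(ConsolidatedPeak(
                        chrom=r.chrom, start=r.start, end=r.end, mark=r.mark,
                        tags=r.tags, support="single_high_fe",
                        source_ids=(r.record_id,),
                        fold_enrichment=r.fold_enrichment,
                    ))
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def top_peaks_by_quality(peaks: Sequence[ConsolidatedPeak], n: int) -> list[ConsolidatedPeak]:
    """The ``n`` best-quality peaks by fold enrichment (ties: tags, position).

    Used to compare datasets measured with different sensitivity by
    truncating each to an equal number of best peaks.
    """
    ranked = sorted(
        peaks,
        key=lambda p: (-p.fold_enrichment, -p.tags, p.chrom, p.start),
    )
    return ranked[:n]
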