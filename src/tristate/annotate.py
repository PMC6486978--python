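"""Peak-to-gene annotation: binary per-gene modification calls.

A gene is called "modified" for a mark when some consolidated peak of that
mark overlaps the gene's promoter (strand-aware TSS +/- 1 kb) and/or gene
body (genomic txStart..txEnd span) by at least 5% of the peak's length.
Genes and peaks on chrX/chrY are excluded to avoid sex-specific artifacts.
Multi-transcript genes are called per transcript and OR-reduced to the gene
symbol.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ContractViolation, ParseError
from .peaks import MARKS, ConsolidatedPeak

SEX_CHROMS = frozenset({"chrX", "chrY"})

GENE_COLUMNS = ["gene_symbol", "transcript_id", "chrom", "strand", "txStart", "txEnd"]


def read_refflat(path: str | Path) -> pd.DataFrame:
    """Read gene models from a refFlat-style TSV.

    Accepts either the 6-column subset (geneName, transcript, chrom, strand,
    txStart, txEnd) or full 11-column refFlat; extra columns are ignored.
    Lines starting with ``#`` are comments.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(f)}")
            try:
                start, end = int(f[4]), int(f[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: txEnd must exceed txStart")
            if f[3] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            rows.append((f[0], f[1], f[2], f[3], start, end))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_refflat(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", header=False, index=False,
                 columns=GENE_COLUMNS)


def tss(strand: str, tx_start: int, tx_end: int) -> int:
    """Strand-aware transcription start site (0-based position)."""
    return tx_start if strand == "+" else tx_end - 1


def promoter_interval(gene, flank: int = 1000) -> tuple[int, int]:
    """Promoter region: TSS +/- ``flank`` bases, half-open, clipped at 0.

    ``gene`` is any object/row with ``strand``, ``txStart``, ``txEnd``
    attributes. For a + strand gene with txStart t the interval is
    [t - flank, t + flank + 1); for - strand the TSS is txEnd - 1.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    pos = tss(gene.strand, gene.txStart, gene.txEnd)
    return (max(0, pos - flank), pos + flank + 1)


def gene_body_interval(gene) -> tuple[int, int]:
    """Gene body: the genomic txStart..txEnd span, strand-independent."""
    return (gene.txStart, gene.txEnd)


def _call_one(peak: ConsolidatedPeak, region: tuple[int, int],
              min_overlap_frac: float, denominator: str) -> bool:
    ov = min(peak.end, region[1]) - max(peak.start, region[0])
    if ov <= 0:
        return False
    denom = peak.length if denominator == "peak" else region[1] - region[0]
    # 1e-9 slack so the exact 5% boundary is not lost to float rounding
    return ov >= min_overlap_frac * denom - 1e-9


def assign_modifications(
    peaks_by_mark: Mapping[str, Sequence[ConsolidatedPeak]],
    genes: pd.DataFrame,
    min_overlap_frac: float = 0.05,
    flank: int = 1000,
    overlap_denominator: str = "peak",
    condition: str | None = None,
) -> pd.DataFrame:
    """Binary gene x mark modification call table for one condition.

    Parameters
    ----------
    peaks_by_mark
        Mapping mark -> consolidated peaks. Missing marks yield all-zero
        columns.
    genes
        Gene models (``read_refflat`` layout); all transcripts of a gene
        symbol contribute (OR-reduced).
    min_overlap_frac
        Minimum overlap as a fraction of the peak length (default 5%,
        inclusive). With ``overlap_denominator="region"`` the fraction is of
        the promoter/gene-body region instead.

    Returns
    -------
    DataFrame indexed by gene_symbol (autosomal + unplaced only; chrX/chrY
    genes are dropped), columns = the three marks, values in {0, 1}.
    """
    if genes is None or len(genes) == 0:
        raise ContractViolation("gene model table is empty")
    if overlap_denominator not in ("peak", "region"):
        raise ValueError("overlap_denominator must be 'peak' or 'region'")

    auto = genes[~genes["chrom"].isin(SEX_CHROMS)]
    symbols = sorted(auto["gene_symbol"].unique())
    calls = pd.DataFrame(0, index=pd.Index(symbols, name="gene_symbol"),
                         columns=list(MARKS), dtype="int8")

    # interval trees of gene regions per chromosome; payload = gene symbol
    trees: dict[str, IntervalTree] = {}
    for row in auto.itertuples(index=False):
        for lo, hi in (promoter_interval(row, flank), gene_body_interval(row)):
            if hi > lo:
                trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene_symbol)

    for mark, peaks in peaks_by_mark.items():
        if mark not in MARKS:
            raise ContractViolation(f"unknown mark {mark!r}")
        for peak in peaks:
            if peak.chrom in SEX_CHROMS:
                continue
            tree = trees.get(peak.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(peak.start, peak.end):
                if _call_one(peak, (iv.begin, iv.end), min_overlap_frac,
                             overlap_denominator):
                    calls.at[iv.data, mark] = 1

    calls.attrs["condition"] = condition
    calls.attrs["min_overlap_frac"] = min_overlap_frac
    calls.attrs["flank"] = flank
    return calls


def gene_associated_flags(
    peaks: Sequence[ConsolidatedPeak],
    genes: pd.DataFrame,
    min_overlap_frac: float = 0.05,
    flank: int = 1000,
    overlap_denominator: str = "peak",
) -> list[bool]:
    """Per-peak flags: does the peak hit any gene's promoter or body?

    Uses the same 5%-of-peak overlap rule as :func:`assign_modifications`.
    Sex-chromosome peaks and genes are excluded; a chrX/chrY peak is flagged
    False. Used to report the fraction of quality peaks that are
    gene-associated.
    """
    auto = genes[~genes["chrom"].isin(SEX_CHROMS)]
    trees: dict[str, IntervalTree] = {}
    for row in auto.itertuples(index=False):
        for lo, hi in (promoter_interval(row, flank), gene_body_interval(row)):
            if hi > lo:
                trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene_symbol)
    flags = []
    for peak in peaks:
        hit = False
        if peak.chrom not in SEX_CHROMS:
            tree = trees.get(peak.chrom)
            if tree is not None:
                for iv in tree.overlap(peak.start, peak.end):
                    if _call_one(peak, (iv.begin, iv.end), min_overlap_frac,
                                 overlap_denominator):
                        hit = True
                        break
        flags.append(hit)
    return flags


def write_call_table(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t")


def read_call_table(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col="gene_symbol")
    return calls[list(MARKS)].astype("int8")
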