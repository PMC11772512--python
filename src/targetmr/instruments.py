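"""Cis-eQTL instrument selection and instrument-strength metrics.

Instruments for a gene are its cis-eQTLs passing a genome-wide significance
threshold within a window of the transcription start site, with a minor
allele frequency floor, thinned to independence by greedy LD clumping.
Strength is summarised per SNP by the variance in expression explained
(R^2, via the standardized 2p(1-p)b^2 approximation) and the corresponding
F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .exceptions import FormatError, StrengthUnavailableError
from .sumstats import LDMatrix, SummaryStatSet, SUMSTAT_COLUMNS, clump


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene id/symbol with TSS coordinate (1-based) and strand."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.tss <= 0:
            raise ValueError(f"{self.gene_id}: tss must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class InstrumentSet:
    """Post-filter, post-clump instruments for one gene in one eQTL dataset,
    with per-SNP F and R^2 (NaN where eaf or n is missing)."""

    gene_id: str
    dataset_id: str
    snps: SummaryStatSet
    f_stats: np.ndarray
    r2: np.ndarray

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def is_empty(self) -> bool:
        return len(self.snps) == 0


def instrument_strength(beta: float, eaf: Optional[float], n: Optional[float]) -> tuple[float, float]:
    """Variance explained and F statistic for one instrument.

    R^2 = 2*eaf*(1-eaf)*beta^2 under a standardized trait (capped just
    below 1); F = (n-2) * R^2 / (1 - R^2).
    """
    if eaf is None or n is None or (isinstance(eaf, float) and np.isnan(eaf)) or (
        isinstance(n, float) and np.isnan(n)
    ):
        raise StrengthUnavailableError("eaf and n are required for F/R^2")
    if not 0 < eaf < 1:
        raise StrengthUnavailableError(f"eaf {eaf} outside (0, 1)")
    if n <= 2:
        raise StrengthUnavailableError(f"n {n} too small for F")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    r2 = min(r2, 1.0 - 1e-12)
    f = (n - 2.0) * r2 / (1.0 - r2)
    return r2, f


def select_cis_instruments(
    eqtl: SummaryStatSet,
    gene: GeneAnnotation,
    ld: LDMatrix,
    p_max: float = 5e-8,
    window_kb: int = 100,
    maf_min: float = 0.01,
    clump_r2: float = 0.001,
    clump_window_kb: int = 10_000,
) -> InstrumentSet:
    """Select independent cis instruments for ``gene``.

    Filters: p < ``p_max``; |pos - tss| <= ``window_kb`` kb; minor allele
    frequency > ``maf_min`` (rows with missing eaf fail the MAF filter);
    then greedy clumping at r^2 < ``clump_r2`` within ``clump_window_kb``.
    An empty survivor set is returned as an empty InstrumentSet, not an
    error: downstream stages record the gene as untestable.
    """
    df = eqtl.df
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = (
        (df["pval"] < p_max)
        & ((df["pos"] - gene.tss).abs() <= window_kb * 1000)
        & maf.notna()
        & (maf > maf_min)
    )
    filtered = SummaryStatSet(
        eqtl.trait_id, eqtl.trait_type, df[keep][SUMSTAT_COLUMNS], eqtl.region
    )
    if len(filtered) > 0:
        filtered = clump(filtered, ld, r2_max=clump_r2, window_kb=clump_window_kb)
    r2 = np.full(len(filtered), np.nan)
    f = np.full(len(filtered), np.nan)
    for i, row in enumerate(filtered.df.itertuples(index=False)):
        try:
            r2[i], f[i] = instrument_strength(row.beta, row.eaf, row.n)
        except StrengthUnavailableError:
            pass
    return InstrumentSet(gene.gene_id, eqtl.trait_id, filtered, f, r2)


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED-like annotation table.

    Columns (tab-separated, no header): chrom, tss-1, tss, gene_id, symbol,
    strand. The two coordinate columns follow BED's 0-based half-open
    convention; everywhere else in the package the 1-based ``tss`` is used.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "tss", "gene_id", "symbol", "strand"],
        dtype={"chrom": str, "gene_id": str, "symbol": str, "strand": str},
    )
    if ((df["tss"] - df["start0"]) != 1).any():
        raise FormatError(f"{path}: coordinate columns are not a 1-bp BED interval")
    return [
        GeneAnnotation(r.gene_id, r.symbol, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_gene_annotations(genes: list[GeneAnnotation], path: str | Path) -> None:
    rows = [(g.chrom, g.tss - 1, g.tss, g.gene_id, g.symbol, g.strand) for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
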