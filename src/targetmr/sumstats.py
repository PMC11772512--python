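"""GWAS / eQTL summary-statistic containers, file IO, allele harmonization
and LD clumping.

The universal currency of the pipeline is the :class:`SummaryStatSet`: one
trait's per-SNP association records (effect sizes are log odds ratios for
binary traits, SD units for quantitative traits), backed by a validated
pandas DataFrame. An :class:`LDMatrix` carries the signed correlation matrix
of a user-supplied reference panel for one region.

File conventions: tab-separated text with header columns
``snp_id chrom pos effect_allele other_allele eaf beta se pval n`` and ``.``
for missing values; positions are 1-based and intervals closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyPairError,
    FormatError,
    ValidationError,
)

SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


@dataclass(frozen=True)
class SNPRecord:
    """One SNP's association record for one trait.

    ``beta`` is the effect per copy of ``effect_allele``; ``eaf`` and ``n``
    may be None when the source file did not report them.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: Optional[float]

    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryStatSet:
    """Per-SNP summary statistics for one trait, optionally restricted to a
    region (chrom, start, end), 1-based closed."""

    trait_id: str
    trait_type: Literal["binary", "quantitative"]
    df: pd.DataFrame
    region: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_frame(self.df)
        if self.region is not None:
            chrom = str(self.region[0])
            off = self.df.index[self.df["chrom"].astype(str) != chrom]
            if len(off):
                raise ValidationError(
                    f"{len(off)} records off region chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def zscores(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy()

    def record(self, snp_id: str) -> SNPRecord:
        sub = self.df[self.df["snp_id"] == snp_id]
        if sub.empty:
            raise KeyError(snp_id)
        return _row_to_record(sub.iloc[0])

    def records(self) -> list[SNPRecord]:
        return [_row_to_record(r) for _, r in self.df.iterrows()]

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStatSet":
        """Restrict to ``snp_ids``, preserving their order."""
        idx = self.df.set_index("snp_id")
        missing = [s for s in snp_ids if s not in idx.index]
        if missing:
            raise KeyError(f"SNPs not in set: {missing[:5]}")
        sub = idx.loc[list(snp_ids)].reset_index()
        return SummaryStatSet(self.trait_id, self.trait_type, sub[SUMSTAT_COLUMNS], self.region)

    def top_snp(self) -> SNPRecord:
        """Minimum-p record; ties broken by position then id."""
        d = self.df.sort_values(["pval", "pos", "snp_id"], kind="mergesort")
        return _row_to_record(d.iloc[0])


def _row_to_record(row: pd.Series) -> SNPRecord:
    eaf = None if pd.isna(row["eaf"]) else float(row["eaf"])
    n = None if pd.isna(row["n"]) else float(row["n"])
    return SNPRecord(
        snp_id=str(row["snp_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=eaf,
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        n=n,
    )


def _validate_frame(df: pd.DataFrame, line_offset: int = 0) -> None:
    """Validate a summary-statistic frame in place.

    ``line_offset`` maps frame row 0 to a 1-based file line for error
    reporting (2 for a file with one header line).
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    def lines(mask) -> list[int]:
        return [int(i) + line_offset for i in df.index[mask]]

    problems: list[str] = []
    bad_lines: list[int] = []

    for col in ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval"):
        mask = df[col].isna()
        if mask.any():
            problems.append(f"missing {col}")
            bad_lines += lines(mask)
    if problems:
        raise ValidationError(
            f"invalid rows ({'; '.join(problems)}) at lines {sorted(set(bad_lines))}",
            lines=sorted(set(bad_lines)),
        )

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df["effect_allele"] = ea
    df["other_allele"] = oa

    checks = [
        (~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES), "allele not in {A,C,G,T}"),
        (ea == oa, "effect_allele equals other_allele"),
        (df["se"] <= 0, "se <= 0"),
        ((df["pval"] <= 0) | (df["pval"] > 1), "pval outside (0, 1]"),
        (df["pos"] <= 0, "pos <= 0"),
        (df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "eaf outside (0, 1)"),
        (df["n"].notna() & (df["n"] <= 0), "n <= 0"),
    ]
    for mask, label in checks:
        if mask.any():
            problems.append(label)
            bad_lines += lines(mask)
    dup = df["snp_id"].duplicated(keep=False)
    if dup.any():
        problems.append("duplicate snp_id")
        bad_lines += lines(dup)
    if problems:
        raise ValidationError(
            f"invalid rows ({'; '.join(problems)}) at lines {sorted(set(bad_lines))}",
            lines=sorted(set(bad_lines)),
        )
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = df[col].astype(float)


def read_sumstats(
    path: str | Path,
    trait_type: Literal["binary", "quantitative"],
    trait_id: Optional[str] = None,
    region: Optional[tuple[str, int, int]] = None,
) -> SummaryStatSet:
    """Read a tab-separated summary-statistic file into a validated set.

    Malformed rows raise :class:`ValidationError` naming 1-based file line
    numbers; a missing column raises :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["."],
        dtype={"snp_id": str, "chrom": str, "effect_allele": str, "other_allele": str},
    )
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[SUMSTAT_COLUMNS].copy()
    # header is file line 1, so frame row i sits on line i + 2
    _validate_frame(df, line_offset=2)
    return SummaryStatSet(trait_id or path.stem, trait_type, df, region)


def write_sumstats(stats: SummaryStatSet, path: str | Path) -> None:
    """Write a set back to the tab-separated format ('.' for missing)."""
    out = stats.df[SUMSTAT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


@dataclass
class LDMatrix:
    """Signed SNP-SNP correlation matrix ``r`` over ``snp_ids``."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValidationError(
                f"LD matrix shape {self.r.shape} does not match {k} snp_ids"
            )
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValidationError("LD matrix diagonal is not all 1")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric within 1e-8")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValidationError("LD correlations outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise ConfigurationError(f"SNPs absent from LD reference: {missing[:5]}")
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square tab-separated LD matrix with snp_id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise FormatError(f"{path}: LD row ids do not match column ids")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.8g"
    )


@dataclass
class HarmonizedPair:
    """Exposure/outcome effect vectors aligned to a shared effect allele."""

    exposure_id: str
    outcome_id: str
    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k = len(self.snp_ids)
        for v in (self.beta_x, self.se_x, self.beta_y, self.se_y):
            if v.shape != (k,):
                raise ValidationError("harmonized vectors must share length")
        for snp, reason in self.dropped:
            if reason not in {"missing_in_outcome", "palindromic", "allele_mismatch"}:
                raise ValidationError(f"unknown drop reason {reason!r} for {snp}")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int]) -> "HarmonizedPair":
        keep = list(keep)
        return HarmonizedPair(
            self.exposure_id,
            self.outcome_id,
            [self.snp_ids[i] for i in keep],
            self.beta_x[keep],
            self.se_x[keep],
            self.beta_y[keep],
            self.se_y[keep],
            dropped=list(self.dropped),
        )


def harmonize(exposure: SummaryStatSet, outcome: SummaryStatSet) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect allele per SNP.

    Matching is by snp_id. When the outcome's effect allele is the
    exposure's other allele, the outcome beta sign is flipped; A/T and C/G
    SNPs are dropped as palindromic unconditionally (strand is
    unresolvable); SNPs missing from the outcome, or with incompatible
    allele pairs, are dropped with a reason. Raises :class:`EmptyPairError`
    if nothing survives.
    """
    out_idx = outcome.df.set_index("snp_id")
    snp_ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    dropped: list[tuple[str, str]] = []
    for row in exposure.df.itertuples(index=False):
        sid = row.snp_id
        if (row.effect_allele, row.other_allele) in _PALINDROMIC:
            dropped.append((sid, "palindromic"))
            continue
        if sid not in out_idx.index:
            dropped.append((sid, "missing_in_outcome"))
            continue
        o = out_idx.loc[sid]
        oea, ooa = o["effect_allele"], o["other_allele"]
        if (oea, ooa) == (row.effect_allele, row.other_allele):
            b_y = float(o["beta"])
        elif (oea, ooa) == (row.other_allele, row.effect_allele):
            b_y = -float(o["beta"])
        else:
            dropped.append((sid, "allele_mismatch"))
            continue
        snp_ids.append(sid)
        bx.append(float(row.beta))
        sx.append(float(row.se))
        by.append(b_y)
        sy.append(float(o["se"]))
    if not snp_ids:
        raise EmptyPairError(
            f"no SNPs shared between {exposure.trait_id} and {outcome.trait_id} "
            f"after harmonization ({len(dropped)} dropped)"
        )
    return HarmonizedPair(
        exposure.trait_id, outcome.trait_id, snp_ids,
        np.array(bx), np.array(sx), np.array(by), np.array(sy), dropped,
    )


def clump(
    stats: SummaryStatSet,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryStatSet:
    """Greedy p-value clumping.

    Repeatedly keep the remaining SNP with the smallest p-value (ties broken
    by smaller position, then lexicographic snp_id) and discard every other
    remaining SNP within ``window_kb`` whose squared correlation to it is at
    least ``r2_max``. The window bounds the LD search only: a SNP beyond the
    window is never removed on account of the current index SNP. Output is
    sorted by position.
    """
    for sid in stats.df["snp_id"]:
        if sid not in ld:
            raise ConfigurationError(f"SNP {sid} absent from LD reference")
    df = stats.df.sort_values(["pval", "pos", "snp_id"], kind="mergesort")
    remaining = list(df.itertuples(index=False))
    kept_ids: list[str] = []
    window_bp = window_kb * 1000
    while remaining:
        index_snp = remaining.pop(0)
        kept_ids.append(index_snp.snp_id)
        survivors = []
        for cand in remaining:
            if abs(cand.pos - index_snp.pos) <= window_bp:
                r = ld.r_between(index_snp.snp_id, cand.snp_id)
                if r * r >= r2_max:
                    continue
            survivors.append(cand)
        remaining = survivors
    out = stats.df[stats.df["snp_id"].isin(kept_ids)].sort_values(
        ["pos", "snp_id"], kind="mergesort"
    )
    return SummaryStatSet(stats.trait_id, stats.trait_type, out[SUMSTAT_COLUMNS], stats.region)
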