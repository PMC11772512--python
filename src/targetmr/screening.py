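"""The end-to-end druggable-gene screening cascade.

Per gene x eQTL dataset x outcome, four stages run in order, each gating
the next:

1. SMR at the top cis-eQTL — keep p_SMR < 0.05 (HEIDI reported alongside;
   an optional threshold turns it into a filter).
2. Two-sample MR on clumped cis instruments — Wald ratio with one SNP, IVW
   otherwise, with the sensitivity estimators when >= 3; keep BH-FDR
   adjusted primary p < 0.05, all computed methods' effects sharing one
   sign, and (with > 2 SNPs) an MR-Egger intercept p >= 0.05. The BH family
   is the set of genes evaluated at this stage for one (outcome, dataset)
   pair.
3. Bayesian colocalization over the gene's region — keep PPH4 > 0.75 or
   PPH3 + PPH4 > 0.8, recording which clause fired.
4. Druggability — keep genes in the supplied druggable-genome list.

Every gene attempted gets a ledger row; a failed stage short-circuits the
later ones to "not evaluated", and a gene that cannot be tested at a stage
(no instruments, missing LD) is marked untestable there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .coloc import ColocModel, ColocPriors
from .exceptions import ConfigurationError, EmptyPairError, TargetMRError
from .instruments import GeneAnnotation, select_cis_instruments
from .mr import MRModel, bh_fdr, sign_concordant
from .smr import SMRModel
from .sumstats import LDMatrix, SummaryStatSet, SUMSTAT_COLUMNS, harmonize


@dataclass(frozen=True)
class DruggableGeneList:
    """Upper-cased gene symbols standing in for a druggable-genome export."""

    symbols: frozenset[str]
    source_tag: str = "local"

    def __post_init__(self):
        if not self.symbols:
            raise ConfigurationError("druggable gene list is empty")
        object.__setattr__(self, "symbols", frozenset(s.upper() for s in self.symbols))

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def load_druggable_list(path: str | Path, source_tag: Optional[str] = None) -> DruggableGeneList:
    """Read a druggable-gene list: one symbol per line, or two tab-separated
    columns (symbol, category) where only 'druggable genome' rows count."""
    path = Path(path)
    symbols: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2 and parts[1].strip():
            if parts[1].strip().lower() != "druggable genome":
                continue
        symbols.add(parts[0].strip().upper())
    return DruggableGeneList(frozenset(symbols), source_tag or path.name)


@dataclass(frozen=True)
class CascadeThresholds:
    """All stage thresholds; defaults follow the screen's standard settings."""

    smr_p: float = 0.05
    instrument_p: float = 5e-8
    instrument_window_kb: int = 100
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    fdr_alpha: float = 0.05
    egger_intercept_p_min: float = 0.05
    coloc_region_kb: int = 500
    pph4_min: float = 0.75
    pph34_min: float = 0.8
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    coloc_prior_sd_eqtl: float = 0.15
    coloc_prior_sd_gwas: float = 0.2
    heidi_filter_p: Optional[float] = None  # None => HEIDI reported, not gated


@dataclass
class StageResult:
    status: str = "not_evaluated"  # pass | fail | untestable | not_evaluated
    metrics: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


@dataclass
class ScreeningRecord:
    """One gene x dataset x outcome row of the screening ledger."""

    gene_id: str
    symbol: str
    dataset_id: str
    outcome_id: str
    stage1_smr: StageResult = field(default_factory=StageResult)
    stage2_mr: StageResult = field(default_factory=StageResult)
    stage3_coloc: StageResult = field(default_factory=StageResult)
    stage4_druggable: StageResult = field(default_factory=StageResult)

    @property
    def final(self) -> bool:
        return all(
            s.passed
            for s in (self.stage1_smr, self.stage2_mr, self.stage3_coloc, self.stage4_druggable)
        )

    @property
    def failing_stage(self) -> Optional[str]:
        for name in ("stage1_smr", "stage2_mr", "stage3_coloc", "stage4_druggable"):
            if not getattr(self, name).passed:
                return name
        return None


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "symbol": r.symbol,
            "dataset_id": r.dataset_id,
            "outcome_id": r.outcome_id,
            "final": r.final,
            "failing_stage": r.failing_stage or "",
        }
        for name in ("stage1_smr", "stage2_mr", "stage3_coloc", "stage4_druggable"):
            st = getattr(r, name)
            row[f"{name}_status"] = st.status
            for k, v in st.metrics.items():
                row[f"{name}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _region_subset(stats: SummaryStatSet, chrom: str, lo: int, hi: int) -> SummaryStatSet:
    df = stats.df
    keep = (df["chrom"].astype(str) == str(chrom)) & df["pos"].between(lo, hi)
    return SummaryStatSet(stats.trait_id, stats.trait_type, df[keep][SUMSTAT_COLUMNS])


def run_cascade(
    genes: list[GeneAnnotation],
    eqtl: Mapping[str, SummaryStatSet],
    gwas: Mapping[str, SummaryStatSet],
    ld: Mapping[str, LDMatrix],
    druggable: DruggableGeneList,
    thresholds: CascadeThresholds = CascadeThresholds(),
    seed: int = 0,
) -> list[ScreeningRecord]:
    """Run the four-stage screen over one eQTL dataset and one outcome.

    ``eqtl``, ``gwas`` and ``ld`` map gene_id to that gene's cis-region
    summary statistics and LD reference. Returns one ledger record per
    gene, in input order. A gene whose LD reference is missing at stage 3
    is marked untestable there and the run continues.
    """
    if not isinstance(druggable, DruggableGeneList):
        raise ConfigurationError("druggable must be a DruggableGeneList")
    th = thresholds
    records: list[ScreeningRecord] = []
    stage2_pvals: list[float] = []
    stage2_entries: list[tuple[ScreeningRecord, dict]] = []

    for gi, gene in enumerate(genes):
        e = eqtl[gene.gene_id]
        g = gwas[gene.gene_id]
        rec = ScreeningRecord(gene.gene_id, gene.symbol, e.trait_id, g.trait_id)
        records.append(rec)

        # ---- stage 1: SMR (+ HEIDI, report-only unless gated). A missing LD
        # reference only disables HEIDI here; clumping needs it at stage 2.
        gene_ld = ld.get(gene.gene_id)
        smr = SMRModel(e, g, gene_ld).fit(
            p_max=th.instrument_p,
            maf_min=th.maf_min,
            gene_id=gene.gene_id,
            run_heidi=gene_ld is not None,
        )
        if smr is None:
            rec.stage1_smr = StageResult(
                "untestable", {"reason": "no genome-wide-significant cis-eQTL"}
            )
            continue
        metrics = {
            "top_snp": smr.top_snp,
            "b_smr": smr.b_smr,
            "p_smr": smr.p_smr,
            "p_heidi": smr.p_heidi if smr.p_heidi is not None else np.nan,
            "m_heidi": smr.m_heidi,
        }
        ok = smr.p_smr < th.smr_p
        if ok and th.heidi_filter_p is not None and smr.p_heidi is not None:
            ok = smr.p_heidi >= th.heidi_filter_p
        rec.stage1_smr = StageResult("pass" if ok else "fail", metrics)
        if not ok:
            continue

        # ---- stage 2: two-sample MR on clumped cis instruments
        if gene_ld is None:
            rec.stage2_mr = StageResult(
                "untestable", {"reason": "missing LD reference for clumping"}
            )
            continue
        iv = select_cis_instruments(
            e, gene, gene_ld,
            p_max=th.instrument_p,
            window_kb=th.instrument_window_kb,
            maf_min=th.maf_min,
            clump_r2=th.clump_r2,
            clump_window_kb=th.clump_window_kb,
        )
        if iv.is_empty:
            rec.stage2_mr = StageResult("untestable", {"reason": "no instruments"})
            continue
        try:
            pair = harmonize(iv.snps, g)
        except EmptyPairError:
            rec.stage2_mr = StageResult(
                "untestable", {"reason": "no instruments after harmonization"}
            )
            continue
        model = MRModel(pair, seed=seed + gi)
        results = model.fit_all()
        primary = results.get("wald") or results["ivw"]
        concordant = sign_concordant(results)
        egger = results.get("egger")
        egger_ok = True
        if model.n_snp > 2 and egger is not None:
            egger_ok = egger.egger_intercept_pval >= th.egger_intercept_p_min
        m2 = {
            "method": primary.method,
            "n_snp": primary.n_snp,
            "beta": primary.beta,
            "or": primary.or_,
            "ci_low": primary.ci_low,
            "ci_high": primary.ci_high,
            "pval": primary.pval,
            "q_pval": primary.q_pval if primary.q_pval is not None else np.nan,
            "egger_intercept_pval": (
                egger.egger_intercept_pval if egger is not None else np.nan
            ),
            "sign_concordant": concordant,
            "egger_ok": egger_ok,
            "mean_f": float(np.nanmean(iv.f_stats)) if len(iv.f_stats) else np.nan,
        }
        rec.stage2_mr = StageResult("fail", m2)  # finalized after FDR below
        stage2_pvals.append(primary.pval)
        stage2_entries.append((rec, m2))

    # one BH family per (outcome, dataset) pair = this run
    if stage2_pvals:
        adj = bh_fdr(stage2_pvals)
        for (rec, m2), pfdr in zip(stage2_entries, adj):
            m2["pfdr"] = float(pfdr)
            ok = pfdr < th.fdr_alpha and m2["sign_concordant"] and m2["egger_ok"]
            rec.stage2_mr = StageResult("pass" if ok else "fail", m2)

    # ---- stages 3 and 4 for stage-2 passers
    gene_by_id = {g.gene_id: g for g in genes}
    for rec in records:
        if not rec.stage2_mr.passed:
            continue
        gene = gene_by_id[rec.gene_id]
        span = thresholds.coloc_region_kb * 1000
        lo, hi = max(1, gene.tss - span), gene.tss + span
        e_reg = _region_subset(eqtl[gene.gene_id], gene.chrom, lo, hi)
        g_reg = _region_subset(gwas[gene.gene_id], gene.chrom, lo, hi)
        shared = [s for s in e_reg.snp_ids if s in set(g_reg.snp_ids)]
        if not shared:
            rec.stage3_coloc = StageResult(
                "untestable", {"reason": "no shared region SNPs"}
            )
            continue
        try:
            coloc = ColocModel(
                e_reg.subset(shared),
                g_reg.subset(shared),
                priors=th.coloc_priors,
                prior_sd1=th.coloc_prior_sd_eqtl,
                prior_sd2=th.coloc_prior_sd_gwas,
            ).fit()
        except TargetMRError as exc:
            rec.stage3_coloc = StageResult("untestable", {"reason": str(exc)})
            continue
        ok, rule = coloc.decision(th.pph4_min, th.pph34_min)
        rec.stage3_coloc = StageResult(
            "pass" if ok else "fail",
            {
                "pph3": coloc.pph3,
                "pph4": coloc.pph4,
                "n_snps": coloc.n_snps,
                "rule_fired": rule or "",
            },
        )
        if not ok:
            continue
        in_list = rec.symbol in druggable
        rec.stage4_druggable = StageResult(
            "pass" if in_list else "fail", {"in_list": in_list}
        )
    return records
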