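"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR tests whether a gene's expression is associated with an outcome by
combining the top cis-eQTL's z-score with the outcome GWAS z-score at the
same SNP:

    b_SMR  = beta_GWAS / beta_eQTL
    T_SMR  = z_x^2 z_y^2 / (z_x^2 + z_y^2)   ~  chi^2(1) under H0

A small SMR p-value is consistent with either one shared causal variant
(pleiotropy) or two distinct variants in LD (linkage). HEIDI distinguishes
the two: under a single shared variant, the SMR ratio estimated at every
cis-SNP in LD with the top SNP is the same, so the deviations
d_i = b_SMR(i) - b_SMR(top) are jointly zero-mean. The test statistic sums
the squared standardized deviations; its null distribution (a correlated
chi-square sum, with LD-derived covariance between the d_i) is approximated
by Satterthwaite moment matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigurationError, UndefinedRatioError
from .sumstats import HarmonizedPair, LDMatrix, SNPRecord, SummaryStatSet, harmonize

# HEIDI defaults follow the conventions of the original SMR tool.
HEIDI_P_INCLUSION = 1.57e-3
HEIDI_R2_RANGE = (0.05, 0.9)
HEIDI_M_MAX = 20
HEIDI_M_MIN = 3


@dataclass
class SMRResult:
    """SMR test result for one gene x outcome at the top cis-eQTL."""

    gene_id: str
    dataset_id: str
    outcome_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    t_smr: float
    p_smr: float
    p_heidi: Optional[float] = None
    m_heidi: int = 0
    heidi_reason: Optional[str] = None

    def summary(self) -> str:
        heidi = "NA" if self.p_heidi is None else f"{self.p_heidi:.3g}"
        return (
            f"SMR {self.gene_id} -> {self.outcome_id} [{self.dataset_id}] "
            f"top={self.top_snp} b={self.b_smr:.4f} se={self.se_smr:.4f} "
            f"p={self.p_smr:.3g} p_HEIDI={heidi} (m={self.m_heidi})"
        )


def smr_test(
    eqtl_top: SNPRecord,
    gwas_at_top: SNPRecord,
    gene_id: str = "",
    dataset_id: str = "",
    outcome_id: str = "",
) -> SMRResult:
    """SMR chi-square test at the top cis-eQTL.

    Both records must refer to the same SNP in the same allele orientation.
    """
    if eqtl_top.snp_id != gwas_at_top.snp_id:
        raise ConfigurationError(
            f"SMR records refer to different SNPs: {eqtl_top.snp_id} vs {gwas_at_top.snp_id}"
        )
    if eqtl_top.beta == 0:
        raise UndefinedRatioError(f"eQTL beta is zero at {eqtl_top.snp_id}")
    z_x = eqtl_top.beta / eqtl_top.se
    z_y = gwas_at_top.beta / gwas_at_top.se
    b = gwas_at_top.beta / eqtl_top.beta
    zx2, zy2 = z_x * z_x, z_y * z_y
    t = zx2 * zy2 / (zx2 + zy2)
    p = float(sps.chi2.sf(t, df=1))
    if z_y == 0:
        se = abs(gwas_at_top.se / eqtl_top.beta)  # delta-method limit at b = 0
    else:
        se = abs(b) * np.sqrt(1.0 / zx2 + 1.0 / zy2)
    return SMRResult(
        gene_id=gene_id,
        dataset_id=dataset_id,
        outcome_id=outcome_id,
        top_snp=eqtl_top.snp_id,
        b_smr=float(b),
        se_smr=float(se),
        t_smr=float(t),
        p_smr=p,
    )


def _smr_cov(bx, sx, by, sy, b, r):
    """Delta-method covariance of the per-SNP SMR ratios b_i = by_i/bx_i,
    with LD correlation r between both traits' effect estimates."""
    inv_bx = 1.0 / bx
    cov_y = r * np.outer(sy, sy) * np.outer(inv_bx, inv_bx)
    cov_x = r * np.outer(sx, sx) * np.outer(inv_bx, inv_bx) * np.outer(b, b)
    return cov_y + cov_x


def heidi_test(
    eqtl: SummaryStatSet,
    gwas: SummaryStatSet,
    ld: LDMatrix,
    top_snp: str,
    p_inclusion: float = HEIDI_P_INCLUSION,
    r2_range: tuple[float, float] = HEIDI_R2_RANGE,
    m_max: int = HEIDI_M_MAX,
    m_min: int = HEIDI_M_MIN,
) -> tuple[Optional[float], int, Optional[str]]:
    """HEIDI test around ``top_snp``.

    Returns ``(p_heidi, m_used, reason)`` where ``p_heidi`` is None (with a
    reason) when fewer than ``m_min`` cis-SNPs are eligible. Eligible SNPs
    have eQTL p below ``p_inclusion`` and r^2 to the top SNP within
    ``r2_range``; at most ``m_max`` (smallest eQTL p) are used.
    """
    if top_snp not in ld:
        raise ConfigurationError(f"top SNP {top_snp} absent from LD reference")
    pair = harmonize(eqtl, gwas)
    if top_snp not in pair.snp_ids:
        raise ConfigurationError(f"top SNP {top_snp} lost in harmonization")
    eqtl_p = eqtl.df.set_index("snp_id")["pval"]

    r2_lo, r2_hi = r2_range
    eligible: list[tuple[float, int]] = []
    for i, sid in enumerate(pair.snp_ids):
        if sid == top_snp or sid not in ld:
            continue
        r = ld.r_between(top_snp, sid)
        if not (r2_lo <= r * r <= r2_hi):
            continue
        p = float(eqtl_p.loc[sid])
        if p < p_inclusion:
            eligible.append((p, i))
    eligible.sort()
    eligible = eligible[:m_max]
    m = len(eligible)
    if m < m_min:
        return None, m, f"only {m} eligible SNPs (minimum {m_min})"

    top_i = pair.snp_ids.index(top_snp)
    idx = [top_i] + [i for _, i in eligible]
    ids = [pair.snp_ids[i] for i in idx]
    bx = pair.beta_x[idx]
    sx = pair.se_x[idx]
    by = pair.beta_y[idx]
    sy = pair.se_y[idx]
    if np.any(bx == 0):
        raise UndefinedRatioError("zero eQTL beta among HEIDI SNPs")
    b = by / bx
    r = ld.submatrix(ids).r
    cov_b = _smr_cov(bx, sx, by, sy, b, r)

    # covariance of d_i = b_i - b_top, i = 1..m
    c00 = cov_b[0, 0]
    c0 = cov_b[0, 1:]
    d_cov = cov_b[1:, 1:] - c0[None, :] - c0[:, None] + c00
    d = b[1:] - b[0]
    sd = np.sqrt(np.diag(d_cov))
    t_stat = float(np.sum((d / sd) ** 2))

    corr = d_cov / np.outer(sd, sd)
    mean = float(m)
    var = 2.0 * float(np.sum(corr * corr))
    scale = var / (2.0 * mean)
    dof = 2.0 * mean * mean / var
    p_heidi = float(sps.chi2.sf(t_stat / scale, df=dof))
    return p_heidi, m, None


class SMRModel:
    """SMR + HEIDI for one gene's cis region against one outcome GWAS.

    Parameters
    ----------
    eqtl, gwas : SummaryStatSet
        Cis-eQTL and outcome summary statistics over the region, in a
        shared allele frame per SNP id.
    ld : LDMatrix
        Signed LD for the region's SNPs.
    """

    def __init__(self, eqtl: SummaryStatSet, gwas: SummaryStatSet, ld: LDMatrix):
        self.eqtl = eqtl
        self.gwas = gwas
        self.ld = ld

    def fit(
        self,
        p_max: float = 5e-8,
        maf_min: float = 0.01,
        gene_id: str = "",
        outcome_id: Optional[str] = None,
        run_heidi: bool = True,
        **heidi_kwargs,
    ) -> Optional[SMRResult]:
        """Run SMR at the top eligible cis-eQTL, then HEIDI.

        The top SNP is the minimum-p eQTL with p < ``p_max`` and
        MAF > ``maf_min`` that survives harmonization with the GWAS.
        Returns None when no SNP is eligible (gene untestable).
        """
        df = self.eqtl.df
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        eligible = df[(df["pval"] < p_max) & maf.notna() & (maf > maf_min)]
        if eligible.empty:
            return None
        pair = harmonize(self.eqtl, self.gwas)
        eligible = eligible[eligible["snp_id"].isin(pair.snp_ids)]
        if eligible.empty:
            return None
        top = eligible.sort_values(["pval", "pos", "snp_id"], kind="mergesort").iloc[0]
        top_id = str(top["snp_id"])
        i = pair.snp_ids.index(top_id)
        eq_rec = self.eqtl.record(top_id)
        # GWAS record in the exposure allele frame
        gw_rec = SNPRecord(
            snp_id=top_id, chrom=eq_rec.chrom, pos=eq_rec.pos,
            effect_allele=eq_rec.effect_allele, other_allele=eq_rec.other_allele,
            eaf=None, beta=float(pair.beta_y[i]), se=float(pair.se_y[i]),
            pval=1.0, n=None,
        )
        res = smr_test(
            eq_rec, gw_rec,
            gene_id=gene_id,
            dataset_id=self.eqtl.trait_id,
            outcome_id=outcome_id or self.gwas.trait_id,
        )
        if run_heidi:
            try:
                p_h, m, reason = heidi_test(
                    self.eqtl, self.gwas, self.ld, top_id, **heidi_kwargs
                )
            except ConfigurationError:
                p_h, m, reason = None, 0, "top SNP absent from LD reference"
            res.p_heidi, res.m_heidi, res.heidi_reason = p_h, m, reason
        return res
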