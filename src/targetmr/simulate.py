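"""Synthetic GWAS/eQTL summary statistics with known ground truth.

The generator emulates the statistical structure of the consortium data the
screen consumes: a cis region of LD-correlated SNPs, quantitative eQTL
effects from a large expression panel (default n = 31,684, blood-eQTL
scale), and binary-trait log-odds effects from a case-control GWAS
(default 7,495 cases / 71,934 controls, intracranial-aneurysm scale).

Five scenarios mirror the colocalization hypotheses: H0 no causal variant;
H1 an eQTL-only variant; H2 an outcome-only variant; H3 two distinct
variants in LD; H4 one shared variant whose effect on the outcome flows
through expression (per-SD log odds ratio ``causal_effect``).

Everything is computed on the standardized-genotype scale — the causal
standardized eQTL effect is sqrt(eqtl_var_explained); true marginal
effects are the LD matrix times the causal vector; observed effects are
drawn multivariate normal around truth with correlation equal to LD — and
converted to the per-allele scale via sqrt(2 p (1-p)). Binary-trait
standard errors use the case-control approximation
se = 1 / sqrt(2 p (1-p) * n * phi * (1-phi)) with case fraction phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError
from .instruments import GeneAnnotation
from .sumstats import HarmonizedPair, LDMatrix, SummaryStatSet, SUMSTAT_COLUMNS

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass
class ScenarioConfig:
    """One simulated cis region's generative parameters."""

    scenario: Literal["H0", "H1", "H2", "H3", "H4"]
    seed: int
    n_snps: int = 200
    ld_model: Literal["ar1", "block"] = "ar1"
    ld_param: float = 0.9
    block_size: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_eqtl: int = 31_684
    n_gwas: int = 79_429
    gwas_case_fraction: float = 7_495 / 79_429
    gwas_trait_type: Literal["binary", "quantitative"] = "binary"
    eqtl_var_explained: float = 0.02
    causal_effect: float = 0.0
    pleiotropy_sd: float = 0.0
    h3_r2: float = 0.3
    chrom: str = "1"
    tss: int = 1_000_000
    spacing_bp: int = 1_000

    def __post_init__(self):
        if self.scenario not in ("H0", "H1", "H2", "H3", "H4"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not 0 <= self.eqtl_var_explained < 1:
            raise ConfigurationError(
                f"eqtl_var_explained {self.eqtl_var_explained} infeasible: a cis "
                "variant cannot explain >= 100% of expression variance at any maf"
            )
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


@dataclass
class RegionTruth:
    """Latent ground truth behind one simulated region."""

    scenario: str
    snp_ids: list[str]
    causal_eqtl_snp: Optional[str]
    causal_gwas_snp: Optional[str]
    gamma_std: float          # standardized causal eQTL effect
    lambda_std: float         # standardized causal GWAS effect
    causal_effect: float      # log-OR per SD expression (H4 path)
    true_eqtl_beta_std: np.ndarray = field(repr=False, default=None)
    true_gwas_beta_std: np.ndarray = field(repr=False, default=None)


def _build_ld(cfg: ScenarioConfig) -> np.ndarray:
    k = cfg.n_snps
    if cfg.ld_model == "ar1":
        idx = np.arange(k)
        r = cfg.ld_param ** np.abs(idx[:, None] - idx[None, :])
    elif cfg.ld_model == "block":
        block = np.arange(k) // cfg.block_size
        same = block[:, None] == block[None, :]
        r = np.where(same, cfg.ld_param, 0.0)
        np.fill_diagonal(r, 1.0)
    else:
        raise ConfigurationError(f"unknown ld_model {cfg.ld_model!r}")
    return r


def _frame(ids, cfg, pos, mafs, beta, se, n) -> pd.DataFrame:
    z = beta / se
    pval = np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(len(ids))]
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": cfg.chrom,
            "pos": pos,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": mafs,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
        }
    )[SUMSTAT_COLUMNS]


def simulate_region(
    cfg: ScenarioConfig, gene_id: str = "GENE", eqtl_id: str = "eqtl", gwas_id: str = "gwas"
) -> tuple[SummaryStatSet, SummaryStatSet, LDMatrix, RegionTruth]:
    """Simulate one cis region's paired eQTL and GWAS summary statistics."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    r = _build_ld(cfg)
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(k))
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    pos = cfg.tss - (k // 2) * cfg.spacing_bp + np.arange(k) * cfg.spacing_bp
    pos = np.maximum(pos, 1)
    ids = [f"rs{gene_id}_{i:04d}" for i in range(k)]

    mid = k // 2
    gamma = np.sqrt(cfg.eqtl_var_explained)
    lam = cfg.causal_effect * gamma  # standardized outcome effect magnitude

    eqtl_causal = np.zeros(k)
    gwas_causal = np.zeros(k)
    causal_eqtl_snp = causal_gwas_snp = None
    if cfg.scenario in ("H1", "H3", "H4"):
        eqtl_causal[mid] = gamma
        causal_eqtl_snp = ids[mid]
    if cfg.scenario == "H4":
        gwas_causal[mid] = lam
        causal_gwas_snp = ids[mid]
    elif cfg.scenario in ("H2", "H3"):
        if cfg.scenario == "H2":
            j = mid
        else:
            # distinct GWAS variant at the separation giving r^2 ~ h3_r2
            if cfg.ld_model == "ar1" and cfg.ld_param > 0:
                sep = max(1, round(np.log(np.sqrt(cfg.h3_r2)) / np.log(cfg.ld_param)))
            else:
                sep = 1
            j = min(mid + sep, k - 1)
        gwas_causal[j] = lam
        causal_gwas_snp = ids[j]

    true_eq_std = r @ eqtl_causal
    true_gw_std = r @ gwas_causal
    if cfg.pleiotropy_sd > 0:
        true_gw_std = true_gw_std + rng.normal(0.0, cfg.pleiotropy_sd, size=k)

    se_eq_std = np.full(k, 1.0 / np.sqrt(cfg.n_eqtl))
    if cfg.gwas_trait_type == "binary":
        phi = cfg.gwas_case_fraction
        se_gw_std = np.full(k, 1.0 / np.sqrt(cfg.n_gwas * phi * (1.0 - phi)))
    else:
        se_gw_std = np.full(k, 1.0 / np.sqrt(cfg.n_gwas))

    obs_eq_std = true_eq_std + se_eq_std * (chol @ rng.standard_normal(k))
    obs_gw_std = true_gw_std + se_gw_std * (chol @ rng.standard_normal(k))

    denom = np.sqrt(2.0 * mafs * (1.0 - mafs))
    eqtl = SummaryStatSet(
        eqtl_id,
        "quantitative",
        _frame(ids, cfg, pos, mafs, obs_eq_std / denom, se_eq_std / denom, cfg.n_eqtl),
        region=(cfg.chrom, int(pos[0]), int(pos[-1])),
    )
    gwas = SummaryStatSet(
        gwas_id,
        cfg.gwas_trait_type,
        _frame(ids, cfg, pos, mafs, obs_gw_std / denom, se_gw_std / denom, cfg.n_gwas),
        region=(cfg.chrom, int(pos[0]), int(pos[-1])),
    )
    ld = LDMatrix(ids, r)
    truth = RegionTruth(
        scenario=cfg.scenario,
        snp_ids=ids,
        causal_eqtl_snp=causal_eqtl_snp,
        causal_gwas_snp=causal_gwas_snp,
        gamma_std=float(gamma),
        lambda_std=float(lam),
        causal_effect=cfg.causal_effect,
        true_eqtl_beta_std=true_eq_std,
        true_gwas_beta_std=true_gw_std,
    )
    return eqtl, gwas, ld, truth


def simulate_mr_pair(
    n_instruments: int,
    true_effect: float,
    seed: int,
    beta_x_range: tuple[float, float] = (0.05, 0.2),
    se_x: float = 0.005,
    se_y: float = 0.02,
    pleiotropy_sd: float = 0.0,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> tuple[HarmonizedPair, float]:
    """Independent-instrument two-sample MR data for calibration studies.

    Instrument effects on the exposure are uniform over ``beta_x_range``;
    balanced pleiotropy adds N(0, pleiotropy_sd^2) direct effects on the
    outcome. Returns the pair and the true causal effect.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(*beta_x_range, size=n_instruments)
    pleio = rng.normal(0.0, pleiotropy_sd, size=n_instruments) if pleiotropy_sd > 0 else 0.0
    bx = rng.normal(a, se_x)
    by = rng.normal(true_effect * a + pleio, se_y)
    ids = [f"iv{i:03d}" for i in range(n_instruments)]
    pair = HarmonizedPair(
        exposure_id, outcome_id, ids,
        bx, np.full(n_instruments, se_x), by, np.full(n_instruments, se_y),
    )
    return pair, true_effect


@dataclass
class MediationTruth:
    exp_to_med: float
    med_to_out: float
    direct: float
    total: float
    proportion: float


def simulate_mediation_chain(
    effects: tuple[float, float, float],
    ses: tuple[float, float, float] = (0.005, 0.01, 0.02),
    n_instruments: int = 30,
    seed: int = 0,
) -> tuple[HarmonizedPair, HarmonizedPair, HarmonizedPair, MediationTruth]:
    """Instrument-level summary statistics for an X -> M -> Y chain.

    ``effects`` is (x_to_m, m_to_y, x_to_y_direct); the implied total
    effect is direct + x_to_m * m_to_y and the true proportion mediated is
    their ratio. Returns pairs (X,Y), (X,M), (M,Y) — the M -> Y pair uses
    an independent instrument set — plus the truth record.
    """
    t_xm, t_my, direct = effects
    se_x, se_m, se_y = ses
    total = direct + t_xm * t_my
    rng = np.random.default_rng(seed)

    a = rng.uniform(0.05, 0.2, size=n_instruments)  # instruments for X
    d = rng.uniform(0.05, 0.2, size=n_instruments)  # instruments for M
    ids_x = [f"ivx{i:03d}" for i in range(n_instruments)]
    ids_m = [f"ivm{i:03d}" for i in range(n_instruments)]

    bx = rng.normal(a, se_x)
    bm_from_x = rng.normal(t_xm * a, se_m)
    by_from_x = rng.normal(total * a, se_y)
    bm = rng.normal(d, se_m)
    by_from_m = rng.normal(t_my * d, se_y)

    kf = np.full(n_instruments, 1.0)
    pair_xy = HarmonizedPair("X", "Y", ids_x, bx, kf * se_x, by_from_x, kf * se_y)
    pair_xm = HarmonizedPair("X", "M", ids_x, bx, kf * se_x, bm_from_x, kf * se_m)
    pair_my = HarmonizedPair("M", "Y", ids_m, bm, kf * se_m, by_from_m, kf * se_y)
    truth = MediationTruth(
        exp_to_med=t_xm,
        med_to_out=t_my,
        direct=direct,
        total=total,
        proportion=(t_xm * t_my / total) if total != 0 else np.nan,
    )
    return pair_xy, pair_xm, pair_my, truth


# ------------------------------------------------------------------ benchmark

#: per-gene benchmark roles: (scenario, causal_effect, druggable)
_BENCHMARK_ROLES = (
    [("H4", 1.0, True)] * 3          # planted true targets
    + [("H4", 1.0, False)] * 2       # causal but not druggable
    + [("H3", 1.0, False)] * 3       # linkage decoys, not druggable
    + [("H1", 0.0, True)] * 8        # eQTL-only decoys, druggable
    + [("H0", 0.0, True)] * 3        # pure-noise decoys, druggable
    + [("H1", 0.0, False)] * 1
)


@dataclass
class Benchmark:
    """A multi-gene synthetic screening benchmark with known positives."""

    genes: list[GeneAnnotation]
    eqtl: dict[str, SummaryStatSet]
    gwas: dict[str, SummaryStatSet]
    ld: dict[str, LDMatrix]
    truths: dict[str, RegionTruth]
    druggable_symbols: set[str]
    planted: list[str]


def simulate_benchmark(
    seed: int,
    n_snps: int = 200,
    eqtl_var_explained: float = 0.05,
    causal_effect: float = 1.0,
    outcome_id: str = "outcome",
    eqtl_dataset_id: str = "eqtl_panel",
) -> Benchmark:
    """The 20-gene screening benchmark: 3 planted druggable true targets
    among causal-but-undruggable, linkage, eQTL-only, and noise decoys.

    Each gene occupies its own chromosome so regions are independent.
    """
    rng = np.random.default_rng(seed)
    genes, eqtl, gwas, ld, truths = [], {}, {}, {}, {}
    druggable: set[str] = set()
    planted: list[str] = []
    for g, (scenario, effect, is_druggable) in enumerate(_BENCHMARK_ROLES):
        gene_id = f"G{g + 1:02d}"
        symbol = f"SYM{g + 1:02d}"
        cfg = ScenarioConfig(
            scenario=scenario,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_snps=n_snps,
            eqtl_var_explained=eqtl_var_explained,
            causal_effect=effect,
            chrom=str(g + 1),
        )
        e, w, l, t = simulate_region(
            cfg, gene_id=gene_id, eqtl_id=eqtl_dataset_id, gwas_id=outcome_id
        )
        genes.append(GeneAnnotation(gene_id, symbol, cfg.chrom, cfg.tss, "+"))
        eqtl[gene_id], gwas[gene_id], ld[gene_id], truths[gene_id] = e, w, l, t
        if is_druggable:
            druggable.add(symbol)
        if scenario == "H4" and effect != 0 and is_druggable:
            planted.append(gene_id)
    return Benchmark(genes, eqtl, gwas, ld, truths, druggable, planted)
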