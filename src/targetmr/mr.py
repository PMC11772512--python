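"""Two-sample Mendelian randomization estimators and diagnostics.

The causal effect of an exposure on an outcome is estimated from per-SNP
summary statistics: each independent instrument i gives a ratio estimate
beta_yi / beta_xi, and the estimators combine the ratios.

* Wald ratio — the single-instrument estimate (primary method with 1 SNP).
* IVW — inverse-variance-weighted mean of the ratios (primary with >1 SNP),
  with multiplicative random-effects inflation of the standard error by
  sqrt(max(1, Q/(k-1))); never deflated below the fixed-effect value.
* MR-Egger — weighted regression of beta_y on beta_x with an intercept
  quantifying directional pleiotropy.
* Weighted median / weighted mode — sensitivity estimators robust to
  invalid instruments; bootstrap standard errors.

Diagnostics: Cochran's Q heterogeneity, leave-one-out influence,
Benjamini-Hochberg FDR, and odds-ratio/CI reporting arithmetic. For binary
outcomes effects are log odds ratios per 1-SD change in the exposure, so
OR = exp(beta).

Usage follows the model/results pattern::

    model = MRModel(pair, seed=17)
    res = model.fit("ivw")        # MRResults
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import UndefinedRatioError, ValidationError
from .sumstats import HarmonizedPair

Z975 = float(sps.norm.ppf(0.975))  # 1.959964...

METHODS = ("wald", "ivw", "egger", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class RatioEstimate:
    snp_id: str
    ratio: float
    se_ratio: float

    def __post_init__(self):
        if self.se_ratio <= 0:
            raise ValidationError(f"{self.snp_id}: se_ratio must be positive")


@dataclass
class MRResults:
    """One estimator's causal estimate with uncertainty and diagnostics."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q_stat: Optional[float] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    se_fixed: Optional[float] = None
    pfdr: Optional[float] = None

    def __post_init__(self):
        self.or_, self.ci_low, self.ci_high = or_ci(self.beta, self.se)

    def summary(self) -> str:
        lines = [
            f"MR results ({self.method}, {self.n_snp} SNP{'s' if self.n_snp != 1 else ''})",
            f"  beta = {self.beta:.4f}  se = {self.se:.4f}  p = {self.pval:.3g}",
            f"  OR = {self.or_:.3f}  95% CI ({self.ci_low:.3f}, {self.ci_high:.3f})",
        ]
        if self.q_stat is not None:
            lines.append(f"  Cochran Q = {self.q_stat:.3f}  p = {self.q_pval:.3g}")
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger intercept = {self.egger_intercept:.4f}"
                f"  p = {self.egger_intercept_pval:.3g}"
            )
        if self.pfdr is not None:
            lines.append(f"  FDR-adjusted p = {self.pfdr:.3g}")
        return "\n".join(lines)


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and Wald confidence bounds: exp(beta -/+ z*se)."""
    if se <= 0:
        if se == 0:
            e = float(np.exp(beta))
            return e, e, e
        raise ValidationError("se must be positive")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def p_from_or_ci(or_: float, ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Two-sided normal p-value reconstructed from a printed OR and CI."""
    if not (0 < ci_low < or_ < ci_high):
        raise ValidationError(
            f"CI ({ci_low}, {ci_high}) does not bracket OR {or_}"
        )
    z_level = float(sps.norm.ppf(0.5 + level / 2.0))
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * z_level)
    z = np.log(or_) / se
    return float(2.0 * sps.norm.sf(abs(z)))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def cochran_q(ratios: Sequence[RatioEstimate], beta_ivw: float) -> tuple[float, float]:
    """Cochran's Q over ratio estimates around the IVW mean; p ~ chi2(k-1)."""
    if len(ratios) < 2:
        raise ValidationError("Cochran's Q needs at least 2 ratios")
    r = np.array([x.ratio for x in ratios])
    w = np.array([1.0 / x.se_ratio**2 for x in ratios])
    q = float(np.sum(w * (r - beta_ivw) ** 2))
    p = float(sps.chi2.sf(q, df=len(ratios) - 1))
    return q, p


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint interpolation; a ratio carrying more
    than half the total weight is returned directly (it is the median)."""
    w = weights / weights.sum()
    if np.max(w) > 0.5:
        return float(ratios[np.argmax(w)])
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], w[order]
    knots = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, knots, r))


def _weighted_mad_scale(ratios: np.ndarray, weights: np.ndarray) -> float:
    med = _weighted_median_point(ratios, weights)
    return 1.4826 * _weighted_median_point(np.abs(ratios - med), weights)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float
) -> float:
    s = _weighted_mad_scale(ratios, weights)
    if s == 0:
        # degenerate cluster: all (weight-carrying) ratios effectively equal
        return _weighted_median_point(ratios, weights)
    h = bandwidth_factor * s
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 1024)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


class MRModel:
    """Two-sample MR model over a harmonized exposure/outcome pair.

    Per-SNP ratio standard errors use the first-order delta approximation
    se_y / |beta_x| (exposure uncertainty ignored, standard two-sample
    practice). Instruments with beta_x = 0 are dropped with a warning.

    Parameters
    ----------
    pair : HarmonizedPair
    n_boot : int
        Parametric bootstrap draws for median/mode standard errors.
    seed : int, optional
        Seed for the bootstrap generator; recorded on results via the
        model. Required for reproducible median/mode fits.
    """

    def __init__(self, pair: HarmonizedPair, n_boot: int = 1000, seed: Optional[int] = None):
        self.pair = pair
        self.n_boot = n_boot
        self.seed = seed
        keep = pair.beta_x != 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} instrument(s) with zero exposure beta"
            )
        idx = np.flatnonzero(keep)
        self._sub = pair.subset(idx) if len(idx) != len(pair) else pair
        bx, by = self._sub.beta_x, self._sub.beta_y
        self.ratios = [
            RatioEstimate(s, float(by[i] / bx[i]), float(self._sub.se_y[i] / abs(bx[i])))
            for i, s in enumerate(self._sub.snp_ids)
        ]

    @property
    def n_snp(self) -> int:
        return len(self.ratios)

    # ------------------------------------------------------------------ fits

    def fit(self, method: str = "auto", **kwargs) -> MRResults:
        """Fit one estimator; ``auto`` is Wald with one SNP, IVW otherwise."""
        if method == "auto":
            method = "wald" if self.n_snp == 1 else "ivw"
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        return getattr(self, f"_fit_{method}")(**kwargs)

    def fit_all(self, methods: Optional[Sequence[str]] = None) -> dict[str, MRResults]:
        """Fit every estimator applicable to this instrument count."""
        if methods is None:
            if self.n_snp == 1:
                methods = ["wald"]
            elif self.n_snp == 2:
                methods = ["ivw"]
            else:
                methods = ["ivw", "egger", "weighted_median", "weighted_mode"]
        return {m: self.fit(m) for m in methods}

    def _fit_wald(self) -> MRResults:
        if self.n_snp != 1:
            raise ValidationError(f"Wald ratio needs exactly 1 SNP, have {self.n_snp}")
        r = self.ratios[0]
        z = r.ratio / r.se_ratio
        p = float(2.0 * sps.norm.sf(abs(z)))
        return MRResults("wald", 1, r.ratio, r.se_ratio, p)

    def _fit_ivw(self) -> MRResults:
        if self.n_snp < 2:
            res = self._fit_wald()  # degenerate fall-back
            return res
        r = np.array([x.ratio for x in self.ratios])
        w = np.array([1.0 / x.se_ratio**2 for x in self.ratios])
        beta = float(np.sum(w * r) / np.sum(w))
        se_fixed = float(np.sum(w) ** -0.5)
        q, q_p = cochran_q(self.ratios, beta)
        inflate = np.sqrt(max(1.0, q / (self.n_snp - 1)))
        se = se_fixed * float(inflate)
        p = float(2.0 * sps.norm.sf(abs(beta / se)))
        return MRResults(
            "ivw", self.n_snp, beta, se, p, q_stat=q, q_pval=q_p, se_fixed=se_fixed
        )

    def _fit_egger(self) -> MRResults:
        if self.n_snp < 3:
            raise ValidationError(f"MR-Egger needs >= 3 SNPs, have {self.n_snp}")
        # orient exposure effects non-negative (flip outcome accordingly)
        flip = np.sign(self._sub.beta_x)
        flip[flip == 0] = 1.0
        bx = self._sub.beta_x * flip
        by = self._sub.beta_y * flip
        w = 1.0 / self._sub.se_y**2
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=w).fit()
        # multiplicative over-dispersion, never below 1
        sigma = max(1.0, np.sqrt(fit.scale))
        slope, slope_se = float(fit.params[1]), float(fit.bse[1] / np.sqrt(fit.scale) * sigma)
        icpt, icpt_se = float(fit.params[0]), float(fit.bse[0] / np.sqrt(fit.scale) * sigma)
        p_slope = float(2.0 * sps.norm.sf(abs(slope / slope_se)))
        p_icpt = float(2.0 * sps.norm.sf(abs(icpt / icpt_se)))
        q, q_p = cochran_q(self.ratios, self._fit_ivw().beta)
        return MRResults(
            "egger", self.n_snp, slope, slope_se, p_slope,
            q_stat=q, q_pval=q_p,
            egger_intercept=icpt, egger_intercept_pval=p_icpt,
        )

    def _boot_se(self, point_fn) -> float:
        rng = np.random.default_rng(self.seed)
        bx = self._sub.beta_x
        by = self._sub.beta_y
        sx = self._sub.se_x
        sy = self._sub.se_y
        k = len(bx)
        draws = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            bxs[bxs == 0] = 1e-300
            ratios = bys / bxs
            weights = (np.abs(bxs) / sy) ** 2
            draws[b] = point_fn(ratios, weights)
        return float(np.std(draws, ddof=1))

    def _fit_weighted_median(self) -> MRResults:
        if self.n_snp < 3:
            raise ValidationError(f"weighted median needs >= 3 SNPs, have {self.n_snp}")
        r = np.array([x.ratio for x in self.ratios])
        w = np.array([1.0 / x.se_ratio**2 for x in self.ratios])
        beta = _weighted_median_point(r, w)
        se = self._boot_se(_weighted_median_point)
        p = 1.0 if se == 0 and beta == 0 else float(2.0 * sps.norm.sf(abs(beta / max(se, 1e-300))))
        res = MRResults("weighted_median", self.n_snp, beta, max(se, 1e-300), p)
        res.se = se  # report the raw bootstrap se even if zero
        return res

    def _fit_weighted_mode(self, bandwidth_factor: float = 1.0) -> MRResults:
        if self.n_snp < 3:
            raise ValidationError(f"weighted mode needs >= 3 SNPs, have {self.n_snp}")
        r = np.array([x.ratio for x in self.ratios])
        w = np.array([1.0 / x.se_ratio**2 for x in self.ratios])
        if np.ptp(r) == 0:
            res = MRResults("weighted_mode", self.n_snp, float(r[0]), 1e-300, 0.0 if r[0] else 1.0)
            res.se = 0.0
            return res
        beta = _weighted_mode_point(r, w, bandwidth_factor)
        se = self._boot_se(
            lambda rr, ww: _weighted_mode_point(rr, ww, bandwidth_factor)
        )
        p = float(2.0 * sps.norm.sf(abs(beta / max(se, 1e-300))))
        res = MRResults("weighted_mode", self.n_snp, beta, max(se, 1e-300), p)
        res.se = se
        return res

    # ----------------------------------------------------------- diagnostics

    def leave_one_out(self, flag_se_multiple: float = 1.0) -> list[dict]:
        """IVW re-estimated omitting each SNP in turn.

        A SNP is flagged when its omission flips the estimate's sign or
        moves it by more than ``flag_se_multiple`` times the full-model se.
        """
        if self.n_snp < 3:
            raise ValidationError("leave-one-out needs >= 3 SNPs")
        full = self._fit_ivw()
        out = []
        for i, snp in enumerate(self._sub.snp_ids):
            keep = [j for j in range(self.n_snp) if j != i]
            sub_model = MRModel(self._sub.subset(keep), n_boot=self.n_boot, seed=self.seed)
            res = sub_model.fit("ivw" if len(keep) >= 2 else "wald")
            moved = abs(res.beta - full.beta) > flag_se_multiple * full.se
            flipped = np.sign(res.beta) != np.sign(full.beta) and full.beta != 0
            out.append(
                {"snp_id": snp, "result": res, "flagged": bool(moved or flipped)}
            )
        return out


# --------------------------------------------------------------- functional

def wald_ratio(pair: HarmonizedPair) -> MRResults:
    if len(pair) != 1:
        raise ValidationError("wald_ratio requires exactly 1 SNP")
    if pair.beta_x[0] == 0:
        raise UndefinedRatioError("exposure beta is zero")
    return MRModel(pair).fit("wald")


def ivw(pair: HarmonizedPair, **kw) -> MRResults:
    return MRModel(pair, **kw).fit("ivw")


def egger(pair: HarmonizedPair, **kw) -> MRResults:
    return MRModel(pair, **kw).fit("egger")


def weighted_median(pair: HarmonizedPair, **kw) -> MRResults:
    return MRModel(pair, **kw).fit("weighted_median")


def weighted_mode(pair: HarmonizedPair, bandwidth_factor: float = 1.0, **kw) -> MRResults:
    return MRModel(pair, **kw).fit("weighted_mode", bandwidth_factor=bandwidth_factor)


def leave_one_out(pair: HarmonizedPair, flag_se_multiple: float = 1.0, **kw) -> list[dict]:
    return MRModel(pair, **kw).leave_one_out(flag_se_multiple=flag_se_multiple)


def sign_concordant(results: dict[str, MRResults]) -> bool:
    """True when every computed method's beta shares one strict sign."""
    signs = {np.sign(r.beta) for r in results.values()}
    return len(signs) == 1 and 0 not in signs
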