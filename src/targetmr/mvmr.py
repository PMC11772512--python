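"""Multivariable MR and coefficient-product mediation.

MVMR regresses per-SNP outcome effects on the matrix of per-SNP exposure
effects (no intercept, inverse-variance weights), giving each exposure's
direct effect conditional on the others. Mediation decomposes a total
effect X -> Y through mediator M: the indirect effect is the product of the
X -> M and M -> Y coefficients, the proportion mediated is indirect/total
(legitimately outside [0, 1] under inconsistent mediation), and the
indirect-effect standard error comes from the product delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import CollinearityError, ValidationError


@dataclass
class MVMRResults:
    """Joint direct effects of several exposures on one outcome."""

    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snp: int
    conditional_f: Optional[np.ndarray] = None

    def __post_init__(self):
        k = len(self.exposures)
        for v in (self.betas, self.ses, self.pvals):
            if len(v) != k:
                raise ValidationError("per-exposure vectors must match exposure count")

    def summary(self) -> str:
        lines = [f"MVMR results ({self.n_snp} SNPs, {len(self.exposures)} exposures)"]
        for i, name in enumerate(self.exposures):
            cf = (
                f"  cond.F = {self.conditional_f[i]:.1f}"
                if self.conditional_f is not None
                else ""
            )
            lines.append(
                f"  {name}: beta = {self.betas[i]:.4f}  se = {self.ses[i]:.4f}"
                f"  OR = {np.exp(self.betas[i]):.3f}  p = {self.pvals[i]:.3g}{cf}"
            )
        return "\n".join(lines)


@dataclass
class MediationResult:
    """Coefficient-product decomposition of a total effect through one mediator."""

    exposure: str
    mediator: str
    outcome: str
    total: float
    indirect: float
    se_indirect: float
    proportion: Optional[float]
    direct: float = field(init=False)
    inconsistent: bool = field(init=False)

    def __post_init__(self):
        self.direct = self.total - self.indirect
        self.inconsistent = self.proportion is not None and not (0 <= self.proportion <= 1)

    def summary(self) -> str:
        prop = "undefined" if self.proportion is None else f"{100 * self.proportion:.1f}%"
        tag = "  [inconsistent mediation]" if self.inconsistent else ""
        return (
            f"Mediation {self.exposure} -> {self.mediator} -> {self.outcome}: "
            f"total = {self.total:.4f}, indirect = {self.indirect:.4f} "
            f"(se {self.se_indirect:.4f}), direct = {self.direct:.4f}, "
            f"proportion mediated = {prop}{tag}"
        )


class MVMRModel:
    """Multivariable IVW model.

    Parameters
    ----------
    outcome_betas, outcome_ses : arrays, length k
        Per-SNP outcome effects and standard errors, harmonized with the
        exposures to one effect-allele frame.
    exposure_matrix : array, k x p
        Per-SNP effects on each exposure.
    exposures : sequence of str, optional
        Exposure names (column labels).
    """

    def __init__(
        self,
        outcome_betas: np.ndarray,
        outcome_ses: np.ndarray,
        exposure_matrix: np.ndarray,
        exposures: Optional[Sequence[str]] = None,
        exposure_ses: Optional[np.ndarray] = None,
    ):
        self.by = np.asarray(outcome_betas, dtype=float)
        self.sy = np.asarray(outcome_ses, dtype=float)
        self.X = np.atleast_2d(np.asarray(exposure_matrix, dtype=float))
        if self.X.shape[0] != self.by.size:
            self.X = self.X.T
        k, p = self.X.shape
        self.exposures = list(exposures) if exposures else [f"x{i}" for i in range(p)]
        if len(self.exposures) != p:
            raise ValidationError("exposure names must match matrix columns")
        if k <= p:
            raise ValidationError(f"need more SNPs ({k}) than exposures ({p})")
        if np.any(self.sy <= 0):
            raise ValidationError("outcome ses must be positive")
        self.exposure_ses = (
            None if exposure_ses is None else np.asarray(exposure_ses, dtype=float)
        )

    def fit(self) -> MVMRResults:
        """Weighted least squares with multiplicative over-dispersion >= 1."""
        k, p = self.X.shape
        rank = np.linalg.matrix_rank(self.X)
        if rank < p:
            # name the dependent columns via QR pivoting on the scaled matrix
            q, r = np.linalg.qr(self.X)
            bad = [self.exposures[j] for j in range(p) if abs(r[j, j]) < 1e-10 * max(1, abs(r[0, 0]))]
            raise CollinearityError(
                f"exposure matrix is rank deficient (rank {rank} < {p})", columns=bad or self.exposures
            )
        w = 1.0 / self.sy**2
        fit = sm.WLS(self.by, self.X, weights=w).fit()
        sigma = max(1.0, np.sqrt(fit.scale))
        betas = np.asarray(fit.params, dtype=float)
        ses = np.asarray(fit.bse, dtype=float) / np.sqrt(fit.scale) * sigma
        pvals = 2.0 * sps.norm.sf(np.abs(betas / ses))
        return MVMRResults(
            exposures=list(self.exposures),
            betas=betas,
            ses=ses,
            pvals=np.asarray(pvals, dtype=float),
            n_snp=k,
            conditional_f=self._conditional_f(),
        )

    def _conditional_f(self) -> Optional[np.ndarray]:
        """Approximate conditional instrument strength per exposure.

        For exposure j, the residual of a weighted regression of its
        instrument effects on the other exposures' effects is compared with
        the exposure's estimation error: a Q-statistic analogue divided by
        its degrees of freedom. Requires per-SNP exposure ses; ignores
        covariance between exposure estimates (documented approximation).
        """
        if self.exposure_ses is None:
            return None
        k, p = self.X.shape
        if self.exposure_ses.shape != (k, p):
            raise ValidationError("exposure_ses must be k x p")
        out = np.empty(p)
        for j in range(p):
            others = np.delete(self.X, j, axis=1)
            sx = self.exposure_ses[:, j]
            w = 1.0 / sx**2
            if others.shape[1] == 0:
                resid = self.X[:, j]
            else:
                fitj = sm.WLS(self.X[:, j], others, weights=w).fit()
                resid = self.X[:, j] - others @ fitj.params
            q = np.sum((resid / sx) ** 2)
            out[j] = q / max(k - p + 1, 1)
        return out


def mvmr_ivw(
    outcome_betas: np.ndarray,
    outcome_ses: np.ndarray,
    exposure_matrix: np.ndarray,
    exposures: Optional[Sequence[str]] = None,
    exposure_ses: Optional[np.ndarray] = None,
) -> MVMRResults:
    return MVMRModel(
        outcome_betas, outcome_ses, exposure_matrix, exposures, exposure_ses
    ).fit()


def mediation_product(
    total: tuple[float, float],
    exp_to_med: tuple[float, float],
    med_to_out: tuple[float, float],
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Coefficient-product mediation from three (effect, se) estimates.

    All three effects must be on consistent (log-odds or SD) scales and
    orientations. When the total effect is zero the proportion is
    undefined and reported as None.
    """
    b_tot, _ = total
    b1, s1 = exp_to_med
    b2, s2 = med_to_out
    indirect = b1 * b2
    se_ind = float(np.sqrt(b1 * b1 * s2 * s2 + b2 * b2 * s1 * s1))
    proportion = None if b_tot == 0 else indirect / b_tot
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total=float(b_tot),
        indirect=float(indirect),
        se_indirect=se_ind,
        proportion=proportion,
    )
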