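"""Bayesian colocalization of two traits from per-SNP summary statistics.

Assuming at most one causal variant per trait in the region, each of the
five hypotheses is scored from per-SNP Wakefield approximate Bayes factors:

* H0 — no association with either trait
* H1 / H2 — association with trait 1 / trait 2 only
* H3 — both traits associated, two distinct causal variants
* H4 — both traits associated, one shared causal variant

For SNP i with estimate beta, variance V = se^2 and prior effect variance
W = prior_sd^2, the log approximate Bayes factor is

    lABF_i = 0.5 * [ ln(V / (V + W)) + z^2 * W / (V + W) ]

Per-SNP priors p1, p2, p12 weight the configurations; all sums are taken
in log space so the method survives |z| > 40.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConfigurationError, ValidationError
from .sumstats import SummaryStatSet

HYPOTHESES = ("PPH0", "PPH1", "PPH2", "PPH3", "PPH4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association with trait 1 only (p1),
    trait 2 only (p2), and both (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValidationError("p1 + p2 + p12 must be < 1")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    n_snps: int
    pp: dict[str, float]
    top_shared_snp: str
    region: Optional[tuple[str, int, int]] = None

    def __post_init__(self):
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"posterior probabilities sum to {total}, not 1")

    @property
    def pph4(self) -> float:
        return self.pp["PPH4"]

    @property
    def pph3(self) -> float:
        return self.pp["PPH3"]

    def decision(self, pph4_min: float = 0.75, pph34_min: float = 0.8) -> tuple[bool, Optional[str]]:
        """Apply the screening rule, reporting which clause fired."""
        if self.pp["PPH4"] > pph4_min:
            return True, "PPH4"
        if self.pp["PPH3"] + self.pp["PPH4"] > pph34_min:
            return True, "PPH3+PPH4"
        return False, None

    def summary(self) -> str:
        probs = "  ".join(f"{h}={self.pp[h]:.4f}" for h in HYPOTHESES)
        return f"Colocalization over {self.n_snps} SNPs: {probs}  top_shared={self.top_shared_snp}"


def wakefield_labf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one SNP-trait association."""
    if se <= 0:
        raise ValidationError("se must be positive")
    v = se * se
    w = prior_sd * prior_sd
    z = beta / se
    return 0.5 * (np.log(v / (v + w)) + z * z * w / (v + w))


def _labf_vector(stats: SummaryStatSet, prior_sd: float) -> np.ndarray:
    b = stats.df["beta"].to_numpy()
    s = stats.df["se"].to_numpy()
    v = s * s
    w = prior_sd * prior_sd
    z2 = (b / s) ** 2
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def coloc_posteriors(
    trait1: SummaryStatSet,
    trait2: SummaryStatSet,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.2,
) -> ColocResult:
    """Posterior probabilities PPH0..PPH4 for a shared region.

    Both sets must cover the same SNPs (matched by id; trait2 is reordered
    to trait1's order). ``prior_sd1``/``prior_sd2`` are the prior effect-size
    SDs (defaults: 0.15 for a quantitative trait, 0.2 log-odds for binary).
    With a single SNP the two-distinct-variant hypothesis is impossible, so
    PPH3 = 0 by construction.
    """
    ids1 = trait1.snp_ids
    if set(ids1) != set(trait2.snp_ids):
        raise ConfigurationError("trait sets must cover identical SNPs")
    t2 = trait2.subset(ids1)

    l1 = _labf_vector(trait1, prior_sd1)
    l2 = _labf_vector(t2, prior_sd2)
    n = len(l1)

    lsum1 = logsumexp(l1)          # sum_i BF1_i
    lsum2 = logsumexp(l2)          # sum_j BF2_j
    lsum12 = logsumexp(l1 + l2)    # sum_i BF1_i * BF2_i

    lh0 = 0.0
    lh1 = np.log(priors.p1) + lsum1
    lh2 = np.log(priors.p2) + lsum2
    lh4 = np.log(priors.p12) + lsum12
    # H3: sum over ordered pairs i != j = (sum_i)(sum_j) - sum_i (i=j)
    cross = lsum1 + lsum2
    if n < 2 or cross <= lsum12:
        lh3 = -np.inf
    else:
        # stable log(exp(cross) - exp(lsum12))
        lh3 = np.log(priors.p1) + np.log(priors.p2) + cross + np.log1p(
            -np.exp(lsum12 - cross)
        )
    lhyp = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lhyp - logsumexp(lhyp))
    pp = pp / pp.sum()

    shared = l1 + l2
    top = ids1[int(np.argmax(shared))]
    return ColocResult(
        n_snps=n,
        pp={h: float(p) for h, p in zip(HYPOTHESES, pp)},
        top_shared_snp=top,
        region=trait1.region,
    )


class ColocModel:
    """Model-object wrapper: ``ColocModel(eqtl, gwas).fit()`` -> ColocResult."""

    def __init__(
        self,
        trait1: SummaryStatSet,
        trait2: SummaryStatSet,
        priors: ColocPriors = ColocPriors(),
        prior_sd1: float = 0.15,
        prior_sd2: float = 0.2,
    ):
        self.trait1 = trait1
        self.trait2 = trait2
        self.priors = priors
        self.prior_sd1 = prior_sd1
        self.prior_sd2 = prior_sd2

    def fit(self) -> ColocResult:
        return coloc_posteriors(
            self.trait1, self.trait2, self.priors, self.prior_sd1, self.prior_sd2
        )
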