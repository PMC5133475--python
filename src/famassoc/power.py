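"""Analytic power for a single-SNP additive effect on a quantitative trait.

Under an unrelated-sample linear model, the 1-df association test has
noncentrality lambda = n * 2 maf (1 - maf) * beta^2 / sigma^2, so power is
the noncentral chi-square(1, lambda) upper tail at the central chi-square
critical value for alpha. Family data are less informative than unrelated
samples of the same size, so these values are upper limits for related
designs.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    n: int
    maf: float
    beta: float          # trait units per minor allele
    residual_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1 or not (0 < self.maf <= 0.5):
            raise ValueError("need n >= 1 and maf in (0, 0.5]")
        if self.residual_sd <= 0 or not (0 < self.alpha < 1):
            raise ValueError("need residual_sd > 0 and alpha in (0, 1)")

    @property
    def noncentrality(self) -> float:
        return (self.n * 2.0 * self.maf * (1.0 - self.maf)
                * self.beta ** 2 / self.residual_sd ** 2)


def analytic_power(spec: PowerSpec) -> float:
    """Power of the 1-df test at level alpha."""
    crit = stats.chi2.isf(spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=spec.noncentrality))


def power_from_variance_explained(n: int, r2: float,
                                  alpha: float = 0.05) -> float:
    """Power parameterized by the fraction of trait variance the SNP explains.

    lambda = n * r2 / (1 - r2); convenient when meta-analyses report explained
    variance instead of (maf, beta).
    """
    if not (0 < r2 < 1):
        raise ValueError("r2 must lie in (0, 1)")
    lam = n * r2 / (1.0 - r2)
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))
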