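"""Combined evidence over a set of association tests.

The set statistic is the untruncated sum T = -sum_i log10 p_i (a monotone
transform of Fisher's product). Its null distribution is simulated with a
Gaussian copula: a latent multivariate normal Z with a test-level correlation
matrix derived from LD between nearby SNPs is mapped to two-sided tail
p-values p_i = 2 Phi(-|Z_i|), and the overall p-value is the proportion of
simulated statistics strictly greater than the observed one. The exact
independence closed form (a Gamma tail) serves as oracle and fallback, and
Bonferroni / Benjamini-Yekutieli utilities cover per-test multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import LDMatrix
from .kinship import repair_psd

LD_WINDOW_BP = 2_000_000

LN10 = math.log(10.0)


@dataclass(frozen=True)
class TestEntry:
    """One constituent test: its p-value and the SNP(s) it involves.

    ``snps`` holds (snp_id, chromosome, position) coordinates; single-SNP
    tests have one entry, interaction tests two. ``trait`` identifies the
    response variable — under the null, tests of different responses are
    independent regardless of SNP sharing, so correlation modeling applies
    only within a shared trait. Leave ``trait`` None to treat all tests as
    sharing one response.
    """

    test_id: str
    p: float
    snps: tuple[tuple[str, int, int], ...] = ()
    trait: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(
                f"{self.test_id}: p must lie in (0, 1]; floor exact zeros at "
                "the smallest representable positive value before combining")


@dataclass
class PValueSet:
    tests: list[TestEntry]

    def __post_init__(self) -> None:
        if not self.tests:
            raise ValueError("empty p-value set")

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([t.p for t in self.tests])

    @property
    def n(self) -> int:
        return len(self.tests)


@dataclass
class SetTestResult:
    statistic: float
    n_tests: int
    overall_p: float
    n_replicates: int
    method: str  # "monte_carlo" or "fisher_independent"
    seed: int | None = None


def combined_statistic(pset: PValueSet | np.ndarray) -> float:
    """T = -sum_i log10 p_i over the set."""
    p = pset.pvalues if isinstance(pset, PValueSet) else np.asarray(pset, float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1] (floor exact zeros first)")
    return float(-np.log10(p).sum())


def fisher_independent(pset: PValueSet) -> SetTestResult:
    """Closed-form overall p under independence.

    T * ln 10 is Fisher's combined statistic halved, i.e. a sum of n
    Exp(1) variables, so the overall p is the Gamma(n, 1) upper tail at
    T * ln 10 (equivalently chi-square with 2n df at 2 ln 10 * T).
    """
    T = combined_statistic(pset)
    p = float(stats.gamma.sf(T * LN10, a=pset.n))
    return SetTestResult(T, pset.n, p, 0, "fisher_independent")


def build_test_correlation(pset: PValueSet, ld: LDMatrix | None,
                           window: int = LD_WINDOW_BP) -> np.ndarray:
    """Latent test-level correlation matrix for the copula null.

    SNP-level latent correlation is sqrt(r^2) for same-chromosome SNPs within
    the window (1 for a SNP with itself), else 0. A pair of single-SNP tests
    uses the SNP correlation directly; a pair of interaction tests uses the
    product of constituent correlations under the alignment maximizing the
    product. Tests declaring different ``trait`` ids are uncorrelated. The
    result is PSD-repaired.
    """
    def snp_corr(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
        if a[0] == b[0]:
            return 1.0
        if a[1] != b[1] or abs(a[2] - b[2]) >= window:
            return 0.0
        if ld is None:
            return 0.0
        r2 = ld.r2[ld.index_of(a[0]), ld.index_of(b[0])]
        return math.sqrt(r2)

    tests = pset.tests
    n = len(tests)
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = tests[i], tests[j]
            if ti.trait is not None and tj.trait is not None \
                    and ti.trait != tj.trait:
                continue
            if not ti.snps or not tj.snps:
                continue
            if len(ti.snps) == 1 and len(tj.snps) == 1:
                rho = snp_corr(ti.snps[0], tj.snps[0])
            elif len(ti.snps) == 2 and len(tj.snps) == 2:
                a1, a2 = ti.snps
                b1, b2 = tj.snps
                rho = max(snp_corr(a1, b1) * snp_corr(a2, b2),
                          snp_corr(a1, b2) * snp_corr(a2, b1))
            else:
                rho = 0.0  # mixed single-vs-pair sets are not modeled
            R[i, j] = R[j, i] = rho
    return repair_psd(R)


def simulate_null(pset: PValueSet, corr: np.ndarray | None,
                  n_replicates: int, seed: int,
                  add_one: bool = False,
                  chunk: int = 500_000) -> SetTestResult:
    """Monte-Carlo overall p-value under the correlated copula null.

    Draws latent N(0, corr) vectors, maps each coordinate to a two-sided
    tail p_i = 2 Phi(-|Z_i|), computes T per replicate, and reports the
    strictly-greater tail proportion (``add_one`` gives the conservative
    (b + 1) / (B + 1) variant).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    T_obs = combined_statistic(pset)
    n = pset.n
    if corr is None:
        corr = np.eye(n)
    corr = np.asarray(corr, float)
    if corr.shape != (n, n):
        raise ValueError("correlation matrix does not match the test count")
    w, V = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("correlation model is not PSD; apply repair_psd")
    L = V * np.sqrt(np.clip(w, 0.0, None))[None, :]

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_replicates:
        b = min(chunk, n_replicates - done)
        Z = rng.standard_normal((b, n)) @ L.T
        logp = np.log10(2.0) + stats.norm.logsf(np.abs(Z)) / LN10
        T = -logp.sum(axis=1)
        exceed += int((T > T_obs).sum())
        done += b
    if add_one:
        overall = (exceed + 1) / (n_replicates + 1)
    else:
        overall = exceed / n_replicates
    return SetTestResult(T_obs, n, float(overall), n_replicates,
                         "monte_carlo", seed)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests (exact; see ``round_sig``)."""
    if not (0 < alpha < 1) or n_tests < 1:
        raise ValueError("need alpha in (0,1) and n_tests >= 1")
    return alpha / n_tests


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures (display convention for thresholds)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1))


def by_fdr(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    BH with the harmonic-number penalty c(n) = sum_{k<=n} 1/k, valid under
    arbitrary dependence; adjusted values are clipped at 1 and made monotone.
    """
    if isinstance(pvalues, PValueSet):
        p = pvalues.pvalues
    else:
        p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    n = p.size
    c_n = np.sum(1.0 / np.arange(1, n + 1))
    order = np.argsort(p)
    ranked = p[order] * n * c_n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
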