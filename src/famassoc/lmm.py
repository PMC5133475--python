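"""Kinship-structured linear mixed models by spectral decomposition.

Model: y = X b + g + e with g ~ N(0, sigma_g^2 K) and e ~ N(0, sigma_e^2 I).
A single eigendecomposition K = U S U' rotates the data so the covariance is
diagonal, sigma_g^2 (S + delta I) with delta = sigma_e^2 / sigma_g^2; the
profile (restricted) log-likelihood is then a cheap one-dimensional function
of delta, maximized by a log-spaced grid search plus bounded refinement.

Single-SNP association scans fit the null and SNP-augmented models by ML and
compare them with a 1-df likelihood-ratio test; plain linear regression
(``ols_assoc``) covers the unrelated-sample case, which is also the exact
K = I degenerate case of the LMM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import GenotypeMatrix, KinshipMatrix
from .phenotypes import DerivedTrait

logger = logging.getLogger("famassoc")

DELTA_GRID = np.logspace(-5, 5, 64)
_EIG_FLOOR = -1e-8  # K eigenvalues below this mean K needs repair


@dataclass
class LMMFit:
    """Maximum-(restricted-)likelihood solution of the mixed model."""

    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float          # sigma_e^2 / sigma_g^2
    log_likelihood: float
    method: str           # "ML" or "REML"
    beta_se: np.ndarray | None = None


@dataclass
class AssocResult:
    """One SNP's association test: LRT statistic vs chi-square(1)."""

    snp_id: str
    beta_snp: float
    se: float
    statistic: float
    df: int
    p: float


class SpectralLMM:
    """Reusable solver bound to one kinship matrix (one eigendecomposition)."""

    def __init__(self, K: KinshipMatrix | np.ndarray):
        vals = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("K must be square")
        S, U = np.linalg.eigh((vals + vals.T) / 2.0)
        if S.min() < _EIG_FLOOR:
            raise ValueError(
                f"K has eigenvalue {S.min():.3g} < 0; apply kinship.repair_psd first")
        self.S = np.clip(S, 0.0, None)
        self.U = U
        self.n = vals.shape[0]

    # -- profile likelihood machinery -------------------------------------

    def _profile(self, deltas: np.ndarray, yr: np.ndarray, Xr: np.ndarray,
                 method: str, logdet_xtx: float) -> np.ndarray:
        """Profile log-likelihood at each delta (vectorized over the grid)."""
        n, p = Xr.shape
        S = self.S
        out = np.empty(len(deltas))
        for k, d in enumerate(deltas):
            w = 1.0 / (S + d)
            Xw = Xr * w[:, None]
            XtWX = Xr.T @ Xw
            XtWy = Xw.T @ yr
            try:
                beta = np.linalg.solve(XtWX, XtWy)
            except np.linalg.LinAlgError:
                out[k] = -np.inf
                continue
            r = yr - Xr @ beta
            q = float(w @ (r * r))
            if q <= 0:
                q = np.finfo(float).tiny
            logdet_v = float(np.log(S + d).sum())
            if method == "ML":
                s2 = q / n
                out[k] = -0.5 * (n * np.log(2 * np.pi * s2) + logdet_v + n)
            else:
                s2 = q / (n - p)
                sign, logdet_w = np.linalg.slogdet(XtWX)
                out[k] = -0.5 * ((n - p) * np.log(2 * np.pi * s2) + logdet_v
                                 + logdet_w - logdet_xtx + (n - p))
        return out

    def fit(self, y: np.ndarray, X: np.ndarray, method: str = "ML") -> LMMFit:
        """Maximize the profile likelihood in delta; back out b and variances."""
        method = method.upper()
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        y = np.asarray(y, float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != self.n or y.shape[0] != self.n:
            raise ValueError("y, X row counts must match K")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix X is rank-deficient after pruning")
        yr = self.U.T @ y
        Xr = self.U.T @ X
        _, logdet_xtx = np.linalg.slogdet(X.T @ X)

        ll_grid = self._profile(DELTA_GRID, yr, Xr, method, logdet_xtx)
        best = int(np.argmax(ll_grid))  # first max -> smaller delta on ties
        lo = DELTA_GRID[max(best - 1, 0)]
        hi = DELTA_GRID[min(best + 1, len(DELTA_GRID) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda t: -self._profile(np.array([10.0 ** t]), yr, Xr,
                                         method, logdet_xtx)[0],
                bounds=(np.log10(lo), np.log10(hi)), method="bounded",
                options={"xatol": 1e-7})
            cand_delta, cand_ll = 10.0 ** res.x, -res.fun
        else:
            cand_delta, cand_ll = DELTA_GRID[best], ll_grid[best]
        if cand_ll > ll_grid[best]:
            delta, ll = float(cand_delta), float(cand_ll)
        else:
            delta, ll = float(DELTA_GRID[best]), float(ll_grid[best])

        w = 1.0 / (self.S + delta)
        Xw = Xr * w[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        r = yr - Xr @ beta
        q = float(w @ (r * r))
        n, p = Xr.shape
        sigma_g2 = q / (n if method == "ML" else n - p)
        sigma_e2 = delta * sigma_g2
        cov = sigma_g2 * np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return LMMFit(beta, sigma_g2, sigma_e2, delta, ll, method, se)


def fit_lmm(y: np.ndarray, X: np.ndarray, K: KinshipMatrix | np.ndarray,
            method: str = "ML") -> LMMFit:
    """One-shot fit (eigendecomposes K; use :class:`SpectralLMM` to reuse)."""
    return SpectralLMM(K).fit(y, X, method)


def lrt_pvalue(ll_alt: float, ll_null: float, df: int = 1) -> tuple[float, float]:
    """Clamped likelihood-ratio statistic and its chi-square survival p."""
    stat = 2.0 * (ll_alt - ll_null)
    if stat < 0:
        if stat < -1e-8:
            logger.warning("negative LRT %.3g clamped to 0", stat)
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df))


def _trait_series(trait) -> pd.Series:
    if isinstance(trait, DerivedTrait):
        return trait.values
    return trait


def _align(genotypes: GenotypeMatrix, trait_s: pd.Series,
           K: KinshipMatrix | None):
    """Intersect individuals across genotypes, trait and kinship (genotype order)."""
    trait_idx = {k: i for i, k in enumerate(trait_s.index)}
    if K is not None and K.individuals is not None:
        k_idx = {k: i for i, k in enumerate(K.individuals)}
    else:
        k_idx = None
    rows, t_rows, k_rows = [], [], []
    for i, key in enumerate(genotypes.individuals):
        if key not in trait_idx:
            continue
        if k_idx is not None and key not in k_idx:
            continue
        rows.append(i)
        t_rows.append(trait_idx[key])
        k_rows.append(k_idx[key] if k_idx is not None else i)
    if not rows:
        raise ValueError("no individuals shared between genotypes, trait "
                         "and kinship (check id types and labels)")
    rows = np.array(rows, dtype=int)
    y = trait_s.to_numpy(dtype=float)[t_rows]
    if K is None:
        Kv = None
    elif k_idx is None:
        Kv = K.values[np.ix_(rows, rows)]
    else:
        k_rows = np.array(k_rows, dtype=int)
        Kv = K.values[np.ix_(k_rows, k_rows)]
    return rows, y, Kv


def assoc_scan(genotypes: GenotypeMatrix, trait, K: KinshipMatrix,
               snp_ids: list[str] | None = None,
               covariates: np.ndarray | None = None,
               method: str = "ML") -> list[AssocResult]:
    """Single-SNP association by mixed-model likelihood-ratio tests.

    For each SNP, the null model (intercept + covariates) and the alternative
    (plus the SNP dosage) are fit by ML with delta re-optimized under each;
    p-values come from chi-square(1). Individuals missing the SNP's dosage
    are dropped for that SNP only; SNPs monomorphic in the analysis subsample
    yield p = NaN with a logged reason. Missing-data patterns share their
    eigendecompositions.
    """
    trait_s = _trait_series(trait)
    rows, y, Kv = _align(genotypes, trait_s, K)
    if snp_ids is None:
        snp_ids = genotypes.snp_ids
    D = genotypes.dosage[rows][:, [genotypes.snp_index(s) for s in snp_ids]]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != len(genotypes.individuals):
            raise ValueError("covariates must have one row per genotype individual")
        covariates = covariates[rows]

    # group SNPs by missingness pattern so each pattern fits its null once
    patterns: dict[bytes, list[int]] = {}
    for j in range(D.shape[1]):
        patterns.setdefault(np.isnan(D[:, j]).tobytes(), []).append(j)

    results: list[AssocResult | None] = [None] * len(snp_ids)
    for pat, cols in patterns.items():
        keep = ~np.frombuffer(pat, dtype=bool)
        yk = y[keep]
        Xnull = np.ones((keep.sum(), 1))
        if covariates is not None:
            Xnull = np.column_stack([Xnull, covariates[keep]])
        solver = SpectralLMM(Kv[np.ix_(keep, keep)])
        null_fit = solver.fit(yk, Xnull, method)
        for j in cols:
            d = D[keep, j]
            if np.ptp(d) == 0:
                logger.warning("SNP %s monomorphic in analysis subsample; "
                               "p set to NaN", snp_ids[j])
                results[j] = AssocResult(snp_ids[j], np.nan, np.nan,
                                         np.nan, 1, np.nan)
                continue
            alt_fit = solver.fit(yk, np.column_stack([Xnull, d]), method)
            stat, p = lrt_pvalue(alt_fit.log_likelihood, null_fit.log_likelihood)
            results[j] = AssocResult(snp_ids[j], float(alt_fit.beta[-1]),
                                     float(alt_fit.beta_se[-1]), stat, 1, p)
    return results  # type: ignore[return-value]


def ols_assoc(genotypes: GenotypeMatrix, trait,
              covariates: np.ndarray | None = None,
              snp_ids: list[str] | None = None) -> list[AssocResult]:
    """Per-SNP linear-regression Wald t-tests (unrelated samples).

    Equivalent to the K = I mixed model up to the Wald-vs-LRT asymptotic
    difference. Covariates enter the design alongside the intercept.
    """
    trait_s = _trait_series(trait)
    rows, y, _ = _align(genotypes, trait_s, None)
    if snp_ids is None:
        snp_ids = genotypes.snp_ids
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))[rows]

    results = []
    for s in snp_ids:
        d = genotypes.dosage[rows, genotypes.snp_index(s)]
        keep = ~np.isnan(d) & ~np.isnan(y)
        dk, yk = d[keep], y[keep]
        if np.ptp(dk) == 0:
            logger.warning("SNP %s monomorphic; p set to NaN", s)
            results.append(AssocResult(s, np.nan, np.nan, np.nan, 1, np.nan))
            continue
        X = np.column_stack(
            [np.ones(keep.sum())]
            + ([covariates[keep]] if covariates is not None else [])
            + [dk])
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(f"design is rank-deficient at SNP {s} "
                             "(collinear covariate?)")
        beta, _, _, _ = np.linalg.lstsq(X, yk, rcond=None)
        r = yk - X @ beta
        s2 = float(r @ r) / (n - p)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[-1, -1]))
        t = beta[-1] / se
        pval = float(2.0 * stats.t.sf(abs(t), n - p))
        results.append(AssocResult(s, float(beta[-1]), se, float(t), n - p, pval))
    return results
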