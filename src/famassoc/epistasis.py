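"""SNP x SNP interaction tests on expression traits.

Two nested kinship mixed models are compared by maximum-likelihood ratio:
the base model carries an intercept and the two minor-allele dosages, the
alternative adds their element-wise product (an additive x additive
interaction term). The statistic 2(l1 - l0), clamped at zero, is referred to
chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, KinshipMatrix
from .kinship import repair_psd
from .lmm import SpectralLMM, lrt_pvalue
from .phenotypes import adjust_and_average, DerivedTrait
from .datamodel import PhenotypeTable

MIN_N = 10


@dataclass
class InteractionResult:
    snp1: str
    snp2: str
    gene: str
    probe: str
    gamma: float          # interaction coefficient in the alternative model
    lrt_statistic: float
    df: int
    p: float


def interaction_test(expr: np.ndarray, d1: np.ndarray, d2: np.ndarray,
                     K: KinshipMatrix | np.ndarray,
                     snp1: str = "snp1", snp2: str = "snp2",
                     gene: str = "", probe: str = "") -> InteractionResult:
    """Additive x additive likelihood-ratio test for one SNP pair.

    ``expr`` is the covariate-adjusted expression trait; ``d1``, ``d2`` are
    minor-allele dosages aligned to it. Individuals missing either dosage or
    the trait are dropped; both SNPs must remain polymorphic and the product
    column must not be collinear with the base design.
    """
    expr = np.asarray(expr, float)
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    keep = ~(np.isnan(expr) | np.isnan(d1) | np.isnan(d2))
    if keep.sum() < MIN_N:
        raise ValueError(f"fewer than {MIN_N} complete individuals")
    y, d1k, d2k = expr[keep], d1[keep], d2[keep]
    Kk = Kv[np.ix_(keep, keep)]
    for name, d in ((snp1, d1k), (snp2, d2k)):
        if np.ptp(d) == 0:
            raise ValueError(f"SNP {name} monomorphic in analysis subsample")

    X0 = np.column_stack([np.ones(len(y)), d1k, d2k])
    prod = d1k * d2k
    X1 = np.column_stack([X0, prod])
    if np.linalg.matrix_rank(X1) < 4:
        raise ValueError(
            f"product column d({snp1}) * d({snp2}) is collinear with the "
            "main-effect design (degenerate dosage configuration)")

    solver = SpectralLMM(repair_psd(Kk))
    fit0 = solver.fit(y, X0, "ML")
    fit1 = solver.fit(y, X1, "ML")
    stat, p = lrt_pvalue(fit1.log_likelihood, fit0.log_likelihood)
    return InteractionResult(snp1, snp2, gene, probe,
                             float(fit1.beta[-1]), stat, 1, p)


def expression_prep(raw_expr: np.ndarray, covariates: pd.DataFrame,
                    individuals: list[tuple[str, str]]) -> DerivedTrait:
    """Covariate-adjust and standardize a probe vector.

    Delegates to the longitudinal pipeline with a single "exam": least-squares
    adjustment for (age, smoking, medication), then z-standardization.
    ``covariates`` needs columns age, smoking, medication aligned to
    ``individuals``.
    """
    raw_expr = np.asarray(raw_expr, float)
    if np.nanstd(raw_expr) == 0:
        raise ValueError("constant probe: zero variance")
    rows = pd.DataFrame({
        "family_id": [f for f, _ in individuals],
        "individual_id": [i for _, i in individuals],
        "exam": 1,
        # carry the probe through the SBP/DBP slots so the invariant holds
        "SBP": raw_expr + 1.0, "DBP": raw_expr, "HTN": 0,
        "age": covariates["age"].to_numpy(dtype=float),
        "smoking": covariates["smoking"].to_numpy(dtype=float),
        "medication": covariates["medication"].to_numpy(dtype=float)})
    out = adjust_and_average(PhenotypeTable(rows), "DBP")
    return DerivedTrait(out.values, "expression", out.n_exams_used)


def run_pair_tests(genotypes: GenotypeMatrix, K: KinshipMatrix,
                   pairs: pd.DataFrame,
                   expression: dict[str, np.ndarray]) -> list[InteractionResult]:
    """Test every (gene, probe, snp1, snp2) row of ``pairs``.

    ``expression`` maps probe id to an adjusted trait vector in genotype row
    order. Probes reused across rows are tested once per row.
    """
    out = []
    for r in pairs.itertuples(index=False):
        expr = expression[str(r.probe)]
        d1 = genotypes.dosage_of(str(r.snp1))
        d2 = genotypes.dosage_of(str(r.snp2))
        out.append(interaction_test(expr, d1, d2, K,
                                    snp1=str(r.snp1), snp2=str(r.snp2),
                                    gene=str(r.gene), probe=str(r.probe)))
    return out
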