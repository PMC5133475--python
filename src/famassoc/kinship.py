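"""Relatedness matrices estimated from genotypes.

Two genotype-based estimators are provided: the realized relationship matrix
(RRM) built from variance-standardized dosages, and the centered kinship
matrix built from mean-centered (not variance-scaled) dosages. Both average
over the polymorphic SNPs; missing dosages are imputed to the SNP mean before
centering, so they contribute exactly zero. A pedigree-based expected kinship
(the coefficient-of-kinship matrix Phi) is provided as a simulation input and
test oracle, and an eigenvalue-clipping PSD repair guards the downstream
spectral mixed-model solver.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import GenotypeMatrix, KinshipMatrix, Pedigree

logger = logging.getLogger("famassoc")


def _imputed_centered(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages, center columns; return (C, column sd)."""
    D = genotypes.dosage.astype(float)
    mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), mean[None, :], D)
    C = D - mean[None, :]
    sd = C.std(axis=0, ddof=0)
    return C, sd


def rrm(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Realized relationship matrix K = W W^T / m over standardized dosages.

    Each SNP column is standardized to mean 0, variance 1 (missing values
    mean-imputed first, i.e. zero after standardization). Monomorphic SNPs
    are excluded from m; if none are polymorphic an error is raised.
    """
    C, sd = _imputed_centered(genotypes)
    poly = sd > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("rrm: excluded %d monomorphic SNP(s)", n_dropped)
    if not poly.any():
        raise ValueError("no polymorphic SNPs: RRM undefined")
    W = C[:, poly] / sd[poly][None, :]
    K = W @ W.T / poly.sum()
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(genotypes.individuals), estimator_tag="RRM")


def centered_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Centered kinship K = C C^T / m over mean-centered dosages."""
    C, sd = _imputed_centered(genotypes)
    poly = sd > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("centered_kinship: excluded %d monomorphic SNP(s)", n_dropped)
    if not poly.any():
        raise ValueError("no polymorphic SNPs: centered kinship undefined")
    C = C[:, poly]
    K = C @ C.T / poly.sum()
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(genotypes.individuals), estimator_tag="centered")


def repair_psd(matrix: KinshipMatrix | np.ndarray, floor: float = 0.0):
    """Clip eigenvalues at ``floor``; the Frobenius-nearest clipped PSD matrix.

    Accepts either a :class:`KinshipMatrix` (returned as the same type) or a
    bare symmetric ndarray (returned as ndarray). Inputs asymmetric beyond
    1e-8 are rejected.
    """
    if isinstance(matrix, KinshipMatrix):
        vals = matrix.values
    else:
        vals = np.asarray(matrix, dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("repair_psd requires a symmetric matrix (tol 1e-8)")
    w, V = np.linalg.eigh((vals + vals.T) / 2.0)
    if w.min() >= floor:
        out = (vals + vals.T) / 2.0
    else:
        out = (V * np.clip(w, floor, None)) @ V.T
        out = (out + out.T) / 2.0
    if isinstance(matrix, KinshipMatrix):
        return KinshipMatrix(out, matrix.individuals, matrix.estimator_tag)
    return out


def pedigree_kinship(pedigree: Pedigree) -> np.ndarray:
    """Expected kinship coefficients Phi from pedigree structure.

    Standard recursion: Phi(i,i) = (1 + Phi(f_i, m_i)) / 2 and
    Phi(i,j) = (Phi(f_i, j) + Phi(m_i, j)) / 2 with i not an ancestor of j.
    Returns Phi in pedigree row order (multiply by 2 for the expected RRM).
    """
    rows = pedigree.rows
    n = len(rows)
    idx = {(str(r.family_id), str(r.individual_id)): i
           for i, r in enumerate(rows.itertuples(index=False))}
    parents: list[tuple[int | None, int | None]] = []
    for r in rows.itertuples(index=False):
        fid = str(r.family_id)
        fa = idx[(fid, str(r.father_id))] if r.father_id is not None else None
        mo = idx[(fid, str(r.mother_id))] if r.mother_id is not None else None
        parents.append((fa, mo))

    # topological order: parents before children
    order: list[int] = []
    seen = [False] * n
    def visit(i: int) -> None:
        if seen[i]:
            return
        seen[i] = True
        for p in parents[i]:
            if p is not None:
                visit(p)
        order.append(i)
    for i in range(n):
        visit(i)

    phi = np.zeros((n, n))
    for pos, i in enumerate(order):
        fa, mo = parents[i]
        if fa is None and mo is None:
            phi[i, i] = 0.5
        else:
            pf = phi[fa, mo] if (fa is not None and mo is not None) else 0.0
            phi[i, i] = 0.5 * (1.0 + pf)
        for j in order[:pos]:
            if fa is None and mo is None:
                val = 0.0  # founders unrelated to everyone earlier
            else:
                val = 0.5 * ((phi[fa, j] if fa is not None else 0.0) +
                             (phi[mo, j] if mo is not None else 0.0))
            phi[i, j] = phi[j, i] = val
    return phi
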