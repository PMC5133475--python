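"""Collapse longitudinal phenotype records into one quantitative trait per
individual.

Derived blood-pressure phenotypes: median arterial pressure
MAP = 2/3 DBP + 1/3 SBP and pulse pressure PP = SBP - DBP. The longitudinal
reduction adjusts the trait for age, smoking and medication by least squares
within each exam, averages the residuals over each individual's available
exams, and z-standardizes the result; binary hypertension status passes
through the same pipeline as a 0/1 quantitative trait. An alternative order
(average raw values first, adjust once) is available behind a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import PhenotypeTable

logger = logging.getLogger("famassoc")


@dataclass
class DerivedTrait:
    """Per-individual single trait values, z-standardized.

    ``values`` is indexed by (family_id, individual_id); individuals with no
    non-missing exam are absent, never zero-filled.
    """

    values: pd.Series
    trait_name: str
    n_exams_used: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.rename(self.trait_name).reset_index()
        df.columns = ["family_id", "individual_id", self.trait_name]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DerivedTrait":
        df = pd.read_csv(path, sep="\t", dtype={"family_id": str,
                                                "individual_id": str})
        name = df.columns[-1]
        values = df.set_index(["family_id", "individual_id"])[name]
        n = pd.Series(1, index=values.index)
        return cls(values, name, n)


def derive_map(dbp, sbp):
    """Median arterial pressure, 2/3 DBP + 1/3 SBP (mmHg)."""
    dbp = np.asarray(dbp, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    valid = np.isnan(dbp) | np.isnan(sbp) | ((sbp > dbp) & (dbp > 0))
    if not valid.all():
        raise ValueError("derive_map requires SBP > DBP > 0")
    out = 2.0 / 3.0 * dbp + 1.0 / 3.0 * sbp
    return float(out) if out.ndim == 0 else out


def derive_pp(dbp, sbp):
    """Pulse pressure, SBP - DBP (mmHg, strictly positive)."""
    dbp = np.asarray(dbp, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    valid = np.isnan(dbp) | np.isnan(sbp) | (sbp > dbp)
    if not valid.all():
        raise ValueError("derive_pp requires SBP > DBP")
    out = sbp - dbp
    return float(out) if out.ndim == 0 else out


def _with_derived(rows: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    rows = rows.copy()
    if trait_name == "MAP":
        rows["MAP"] = derive_map(rows.DBP, rows.SBP)
    elif trait_name == "PP":
        rows["PP"] = derive_pp(rows.DBP, rows.SBP)
    return rows


def _adjust_exam(y: np.ndarray, cov: np.ndarray,
                 cov_names: list[str]) -> np.ndarray:
    """Residuals of y on [1, covariates] by least squares; constant covariate
    columns are dropped with a warning."""
    keep = []
    for j, name in enumerate(cov_names):
        if np.ptp(cov[:, j]) == 0:
            logger.warning("covariate %r is constant within exam; dropped", name)
        else:
            keep.append(j)
    X = np.column_stack([np.ones(len(y)), cov[:, keep]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def adjust_and_average(table: PhenotypeTable, trait_name: str,
                       order: str = "adjust_then_average") -> DerivedTrait:
    """Reduce longitudinal records to one standardized value per individual.

    ``order='adjust_then_average'`` (default): within each exam, replace the
    trait by its least-squares residual on (age, smoking, medication) across
    individuals; then average each individual's residuals over available
    exams; finally z-standardize. ``order='average_then_adjust'`` averages
    the raw trait (and covariates) per individual first and adjusts once.
    """
    if trait_name not in PhenotypeTable.TRAITS:
        raise ValueError(f"unknown trait {trait_name!r}")
    if order not in ("adjust_then_average", "average_then_adjust"):
        raise ValueError(f"unknown order {order!r}")
    rows = _with_derived(table.rows, trait_name)
    covs = PhenotypeTable.COVARIATES
    rows = rows.dropna(subset=[trait_name] + covs)
    if rows.empty:
        raise ValueError(f"trait {trait_name!r} entirely missing")

    if order == "adjust_then_average":
        parts = []
        for _, grp in rows.groupby("exam"):
            resid = _adjust_exam(grp[trait_name].to_numpy(dtype=float),
                                 grp[covs].to_numpy(dtype=float), covs)
            parts.append(pd.DataFrame({
                "family_id": grp.family_id, "individual_id": grp.individual_id,
                "resid": resid}))
        resid = pd.concat(parts)
        agg = resid.groupby(["family_id", "individual_id"])["resid"].agg(
            ["mean", "size"])
    else:
        per_ind = rows.groupby(["family_id", "individual_id"]).agg(
            trait=(trait_name, "mean"), n=("exam", "size"),
            age=("age", "mean"), smoking=("smoking", "mean"),
            medication=("medication", "mean"))
        resid = _adjust_exam(per_ind["trait"].to_numpy(dtype=float),
                             per_ind[covs].to_numpy(dtype=float), covs)
        agg = pd.DataFrame({"mean": resid, "size": per_ind["n"]},
                           index=per_ind.index)

    vals = agg["mean"]
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError(f"trait {trait_name!r} has zero variance after averaging")
    vals = (vals - vals.mean()) / sd
    return DerivedTrait(vals, trait_name, agg["size"].astype(int))
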