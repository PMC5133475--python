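"""Family-structured synthetic data with the statistical features the
analyses rely on: multi-generation pedigrees, block-LD genotypes transmitted
by gene dropping, longitudinal blood-pressure phenotypes with covariates and
a polygenic component, and expression traits carrying an additive x additive
two-SNP interaction.

Every stochastic operation derives its generator from ``SimConfig.seed``
through a named substream, so a single master seed makes the whole dataset
reproducible while keeping the operations independently re-runnable.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import GenotypeMatrix, Pedigree, PhenotypeTable, SNPRecord
from .kinship import pedigree_kinship

# base-pair layout of simulated markers: blocks sit far apart (> 2 Mb window),
# markers within a block sit 1 kb apart
_BLOCK_SPACING_BP = 5_000_000
_WITHIN_BLOCK_BP = 1_000


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the target design: 20 extended families of ~48 members
    (about 950-960 individuals), four annual exams with age, smoking and
    antihypertensive-medication covariates, and block-structured LD.
    """

    n_families: int = 20
    family_size_mean: int = 48
    n_generations: int = 3
    n_snps: int = 100
    block_size: int = 10
    within_block_r: float = 0.8     # latent AR(1) coefficient inside a block
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exams: int = 4
    trait_heritability: float = 0.3
    covariate_effects: tuple[float, float, float] = (0.4, 3.0, -5.0)  # age, smoking, medication
    interaction_effect: float = 0.5  # additive x additive coefficient (gamma)
    residual_sd: float = 8.0         # mmHg for blood pressure; trait units otherwise
    exam_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_generations < 2:
            raise ValueError("need n_families >= 1 and n_generations >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        if not (0 <= self.trait_heritability < 1):
            raise ValueError("trait_heritability must lie in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (deterministic, process-independent)."""
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _mean_children(cfg: SimConfig) -> float:
    """Mean offspring per couple so the expected family size matches config.

    With G generations, one founder couple, every pre-terminal child marrying
    a founder spouse: size(c) = 2 + 2*(c + ... + c^(G-2)) + c^(G-1).
    """
    G = cfg.n_generations

    def size(c: float) -> float:
        s = 2.0
        for g in range(2, G):
            s += 2.0 * c ** (g - 1)
        s += c ** (G - 1)
        return s

    target = float(cfg.family_size_mean)
    if size(0.01) >= target:
        return 0.01
    return float(optimize.brentq(lambda c: size(c) - target, 0.01, 60.0))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation families: founder couples, married-in spouses,
    Poisson numbers of children per couple. Rows are emitted parents-first."""
    rng = config.rng("pedigree")
    c = _mean_children(config)
    rows: list[tuple[str, str, str | None, str | None, int]] = []
    for f in range(1, config.n_families + 1):
        fid = f"F{f}"
        nxt = 1

        def new_id() -> str:
            nonlocal nxt
            iid = str(nxt)
            nxt += 1
            return iid

        pa, ma = new_id(), new_id()
        rows.append((fid, pa, None, None, 1))
        rows.append((fid, ma, None, None, 2))
        couples = [(pa, ma)]
        for g in range(2, config.n_generations + 1):
            next_couples = []
            for father, mother in couples:
                n_kids = rng.poisson(c)
                for _ in range(n_kids):
                    kid = new_id()
                    sex = int(rng.integers(1, 3))
                    rows.append((fid, kid, father, mother, sex))
                    if g < config.n_generations:
                        spouse = new_id()
                        rows.append((fid, spouse, None, None, 3 - sex))
                        pair = (kid, spouse) if sex == 1 else (spouse, kid)
                        next_couples.append(pair)
            couples = next_couples
    return Pedigree(pd.DataFrame(
        rows, columns=["family_id", "individual_id",
                       "father_id", "mother_id", "sex"]))


def _snp_map(config: SimConfig) -> list[SNPRecord]:
    snps = []
    for j in range(config.n_snps):
        b, k = divmod(j, config.block_size)
        pos = 1 + b * _BLOCK_SPACING_BP + k * _WITHIN_BLOCK_BP
        snps.append(SNPRecord(f"snp{j + 1}", 1, pos, "A", "G"))
    return snps


def _founder_haplotypes(n_hap: int, mafs: np.ndarray, config: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Population haplotypes with block LD via a latent Gaussian AR(1)
    threshold model: within a block z_j = r z_{j-1} + sqrt(1-r^2) e_j, and the
    minor allele is carried where z_j < Phi^-1(maf_j). Blocks independent."""
    m = len(mafs)
    r = config.within_block_r
    z = np.empty((n_hap, m))
    e = rng.standard_normal((n_hap, m))
    for j in range(m):
        if j % config.block_size == 0:
            z[:, j] = e[:, j]
        else:
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * e[:, j]
    thresh = stats.norm.ppf(mafs)
    return (z < thresh[None, :]).astype(np.int8)


def gene_drop(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Drop founder haplotypes down the pedigree.

    Founder haplotypes come from the block-LD population model; each child
    receives, from each parent, one of the parent's two haplotypes chosen
    independently per block (free recombination between blocks, none within).
    """
    rng = config.rng("gene_drop")
    mafs = config.rng("mafs").uniform(*config.maf_range, size=config.n_snps)
    snps = _snp_map(config)
    m = config.n_snps
    n_blocks = (m + config.block_size - 1) // config.block_size
    block_of = np.arange(m) // config.block_size

    rows = pedigree.rows
    n = len(rows)
    idx = {(str(r.family_id), str(r.individual_id)): i
           for i, r in enumerate(rows.itertuples(index=False))}
    parents: list[tuple[int | None, int | None]] = []
    for r in rows.itertuples(index=False):
        fid = str(r.family_id)
        parents.append((
            idx[(fid, str(r.father_id))] if r.father_id is not None else None,
            idx[(fid, str(r.mother_id))] if r.mother_id is not None else None))

    # topological order so parents are assigned before children
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

    founder_rows = [i for i in range(n) if parents[i] == (None, None)]
    fh = _founder_haplotypes(2 * len(founder_rows), mafs, config, rng)
    hap = np.empty((n, 2, m), dtype=np.int8)
    for k, i in enumerate(founder_rows):
        hap[i, 0] = fh[2 * k]
        hap[i, 1] = fh[2 * k + 1]

    for i in order:
        fa, mo = parents[i]
        if fa is None and mo is None:
            continue
        for slot, par in ((0, fa), (1, mo)):
            choice = rng.integers(0, 2, size=n_blocks)[block_of]
            hap[i, slot] = np.where(choice == 0, hap[par, 0], hap[par, 1])

    dosage = hap.sum(axis=1).astype(float)
    individuals = [(str(r.family_id), str(r.individual_id))
                   for r in rows.itertuples(index=False)]
    return GenotypeMatrix(individuals, snps, dosage)


def _generation_depth(pedigree: Pedigree) -> np.ndarray:
    rows = pedigree.rows
    n = len(rows)
    idx = {(str(r.family_id), str(r.individual_id)): i
           for i, r in enumerate(rows.itertuples(index=False))}
    depth = np.zeros(n, dtype=int)
    for _ in range(n):  # relax; pedigrees are shallow
        changed = False
        for i, r in enumerate(rows.itertuples(index=False)):
            fid = str(r.family_id)
            d = 0
            for par in (r.father_id, r.mother_id):
                if par is not None:
                    d = max(d, depth[idx[(fid, str(par))]] + 1)
            if d != depth[i]:
                depth[i] = d
                changed = True
        if not changed:
            break
    return depth


def _polygenic(pedigree: Pedigree, sigma_g: float,
               rng: np.random.Generator) -> np.ndarray:
    """Zero-mean polygenic values with covariance sigma_g^2 * 2*Phi."""
    n = len(pedigree.rows)
    if sigma_g == 0:
        return np.zeros(n)
    phi2 = 2.0 * pedigree_kinship(pedigree)
    L = np.linalg.cholesky(phi2 + 1e-10 * np.eye(n))
    return sigma_g * (L @ rng.standard_normal(n))


def _variance_split(config: SimConfig) -> tuple[float, float]:
    """(sigma_g, sigma_e) from heritability and residual_sd."""
    h2 = config.trait_heritability
    sigma_e = config.residual_sd
    sigma_g = sigma_e * np.sqrt(h2 / (1.0 - h2)) if h2 > 0 else 0.0
    return sigma_g, sigma_e


def simulate_longitudinal_phenotypes(
        genotypes: GenotypeMatrix, pedigree: Pedigree, config: SimConfig,
        causal_snps: list[tuple[str, float]] = ()) -> PhenotypeTable:
    """Blood-pressure records over ``n_exams`` annual exams.

    Diastolic pressure carries the full generative model
    ``DBP = mu + sum_j beta_j d_j + covariates + polygenic + noise``;
    systolic pressure adds a strictly positive pulse-pressure component, and
    hypertension is the indicator SBP >= 140 or on medication. Ages advance
    one year per exam from a generation-dependent baseline.
    """
    rng = config.rng("phenotypes")
    n = len(genotypes.individuals)
    for snp_id, _ in causal_snps:
        genotypes.snp_index(snp_id)  # raises KeyError if absent

    age_b, smoke_b, med_b = config.covariate_effects
    sigma_g, sigma_e = _variance_split(config)
    g = _polygenic(pedigree, sigma_g, config.rng("polygenic"))

    depth = _generation_depth(pedigree)
    age0 = np.maximum(rng.normal(62.0 - 24.0 * depth, 5.0), 18.0)
    smoking = (rng.random(n) < 0.2).astype(int)
    medication = (rng.random(n) < 0.2).astype(int)

    genetic = np.zeros(n)
    for snp_id, beta in causal_snps:
        d = genotypes.dosage_of(snp_id)
        genetic += beta * np.where(np.isnan(d), np.nanmean(d), d)

    records = []
    for i, (fid, iid) in enumerate(genotypes.individuals):
        for e in range(config.n_exams):
            if e > 0 and rng.random() < config.exam_missing_rate:
                continue
            age = age0[i] + e
            dbp = (75.0 + genetic[i] + age_b * age + smoke_b * smoking[i]
                   + med_b * medication[i] + g[i]
                   + sigma_e * rng.standard_normal())
            pp = 40.0 + abs(rng.normal(0.0, 8.0)) + 1.0
            sbp = dbp + pp
            htn = int(sbp >= 140.0 or medication[i] == 1)
            records.append((fid, iid, e + 1, sbp, dbp, htn,
                            age, smoking[i], medication[i]))
    return PhenotypeTable(pd.DataFrame(
        records, columns=["family_id", "individual_id", "exam",
                          "SBP", "DBP", "HTN", "age", "smoking", "medication"]))


def simulate_expression(genotypes: GenotypeMatrix, pedigree: Pedigree,
                        config: SimConfig, pair: tuple[str, str],
                        main_effects: tuple[float, float] = (0.0, 0.0),
                        expr_residual_sd: float = 1.0) -> np.ndarray:
    """Expression trait with an additive x additive interaction:
    expr = mu + a1 d1 + a2 d2 + gamma d1 d2 + polygenic + noise,
    gamma = ``config.interaction_effect``. Returns one value per individual
    in genotype row order."""
    rng = config.rng("expression")
    d1 = genotypes.dosage_of(pair[0])
    d2 = genotypes.dosage_of(pair[1])
    d1 = np.where(np.isnan(d1), np.nanmean(d1), d1)
    d2 = np.where(np.isnan(d2), np.nanmean(d2), d2)
    a1, a2 = main_effects
    h2 = config.trait_heritability
    sigma_e = expr_residual_sd
    sigma_g = sigma_e * np.sqrt(h2 / (1.0 - h2)) if h2 > 0 else 0.0
    g = _polygenic(pedigree, sigma_g, config.rng("expr_polygenic"))
    n = len(d1)
    return (5.0 + a1 * d1 + a2 * d2 + config.interaction_effect * d1 * d2
            + g + sigma_e * rng.standard_normal(n))


def write_truth(path: str | Path, config: SimConfig,
                causal_snps: list[tuple[str, float]] = (),
                pair: tuple[str, str] | None = None) -> None:
    """Ground-truth sidecar JSON: causal SNPs, variance components, gamma."""
    sigma_g, sigma_e = _variance_split(config)
    truth = {
        "causal_snps": [[s, b] for s, b in causal_snps],
        "sigma_g2": sigma_g ** 2,
        "sigma_e2": sigma_e ** 2,
        "heritability": config.trait_heritability,
        "interaction_pair": list(pair) if pair else None,
        "interaction_effect": config.interaction_effect,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(truth, indent=2))
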