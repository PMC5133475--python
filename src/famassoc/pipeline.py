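"""End-to-end orchestration: simulate -> prep -> kinship -> association /
interaction tests -> combined set tests -> report.

A run is a pure function of (config, seed): every stochastic stage derives
its generator from the master seed, so re-running a config reproduces every
output byte-for-byte. Stage boundaries follow the analysis modules; the
report echoes the per-test p-value tables, Bonferroni verdicts and overall
set p-values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datamodel as dm
from .datamodel import LDMatrix
from .kinship import repair_psd, rrm
from .lmm import assoc_scan
from .epistasis import interaction_test
from .phenotypes import adjust_and_average
from .settest import (PValueSet, TestEntry, bonferroni, build_test_correlation,
                      combined_statistic, fisher_independent, simulate_null)
from .simulate import (SimConfig, gene_drop, simulate_expression,
                       simulate_longitudinal_phenotypes, simulate_pedigree,
                       write_truth)

logger = logging.getLogger("famassoc")

DEFAULT_PHENOTYPES = ["DBP", "MAP", "PP", "SBP", "HTN"]


@dataclass
class RunConfig:
    """One nesting level of key/value settings for a full run."""

    seed: int = 0
    out_dir: str = "run_out"
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(seed=int(raw.get("seed", 0)),
                   out_dir=str(raw.get("out_dir", "run_out")),
                   simulate=dict(raw.get("simulate", {})),
                   analysis=dict(raw.get("analysis", {})))

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulate)
        kwargs.pop("causal_snps", None)
        if "maf_range" in kwargs:
            kwargs["maf_range"] = tuple(kwargs["maf_range"])
        if "covariate_effects" in kwargs:
            kwargs["covariate_effects"] = tuple(kwargs["covariate_effects"])
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)


def ld_from_genotypes(genotypes: dm.GenotypeMatrix) -> LDMatrix:
    """Empirical r-squared between dosage columns (mean-imputed)."""
    D = genotypes.dosage.astype(float)
    mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), mean[None, :], D)
    sd = D.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (D - D.mean(axis=0)) / sd
    r = Z.T @ Z / len(D)
    r2 = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix((r2 + r2.T) / 2.0, list(genotypes.snps))


def _assoc_pset(results, genotypes: dm.GenotypeMatrix,
                trait_name: str) -> PValueSet | None:
    tests = []
    for r in results:
        if np.isnan(r.p):
            continue
        s = genotypes.snps[genotypes.snp_index(r.snp_id)]
        tests.append(TestEntry(
            test_id=f"{trait_name}:{r.snp_id}", p=max(r.p, 1e-300),
            snps=((s.snp_id, s.chromosome, s.position),), trait=trait_name))
    return PValueSet(tests) if tests else None


def run_replication_study(config: RunConfig) -> dict:
    """Run the full synthetic replication study; returns a summary dict.

    Outputs under ``config.out_dir``: genotypes (.ped/.map), phenotype TSV,
    ground-truth JSON, kinship matrix, per-phenotype association TSVs,
    interaction TSV, per-set JSON summaries and ``report.txt``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    ana = config.analysis
    alpha = float(ana.get("alpha", 0.05))
    replicates = int(ana.get("replicates", 100_000))
    method = str(ana.get("method", "ML"))
    phenos = list(ana.get("phenotypes", DEFAULT_PHENOTYPES))
    causal = [(str(s), float(b))
              for s, b in (config.simulate.get("causal_snps") or [])]

    logger.info("stage simulate: %d families, %d SNPs, seed %d",
                sim.n_families, sim.n_snps, sim.seed)
    ped = simulate_pedigree(sim)
    geno = gene_drop(ped, sim)
    pheno = simulate_longitudinal_phenotypes(geno, ped, sim, causal)
    dm.write_ped_map(geno, ped, out / "genotypes.ped", out / "genotypes.map")
    pheno.to_tsv(out / "phenotypes.tsv")

    pair = ana.get("interaction_pair")
    if pair is None:
        pair = (geno.snp_ids[0], geno.snp_ids[-1])
    pair = (str(pair[0]), str(pair[1]))
    expr = simulate_expression(geno, ped, sim, pair)
    write_truth(out / "truth.json", sim, causal, pair)

    logger.info("stage kinship: RRM over %d SNPs", sim.n_snps)
    K = repair_psd(rrm(geno))
    dm.write_kinship(K, out / "kinship.txt")

    candidates = [str(s) for s in ana.get(
        "candidate_snps", geno.snp_ids[:: max(1, sim.n_snps // 20)])]
    ld = ld_from_genotypes(geno)

    report: list[str] = ["Synthetic family replication study",
                         f"seed={config.seed} individuals={len(geno.individuals)} "
                         f"snps={sim.n_snps} candidates={len(candidates)}", ""]
    summary: dict = {"seed": config.seed, "phenotypes": {}, "interaction": {}}
    thr = bonferroni(alpha, len(candidates))
    result_rows = []

    for trait_name in phenos:
        logger.info("stage assoc: %s", trait_name)
        trait = adjust_and_average(pheno, trait_name)
        results = assoc_scan(geno, trait, K, candidates, method=method)
        for r in results:
            s = geno.snps[geno.snp_index(r.snp_id)]
            result_rows.append({
                "test_id": f"{trait_name}:{r.snp_id}", "snp1": r.snp_id,
                "snp2": "", "chr1": s.chromosome, "chr2": "",
                "phenotype": trait_name, "beta": r.beta_snp, "se": r.se,
                "statistic": r.statistic, "df": r.df, "p": r.p})
        pset = _assoc_pset(results, geno, trait_name)
        report.append(f"[{trait_name}] single-SNP tests "
                      f"(Bonferroni {alpha}/{len(candidates)} = {thr:.2g}):")
        hits = []
        for r in results:
            mark = " *" if (not np.isnan(r.p) and r.p < thr) else ""
            report.append(f"  {r.snp_id:<10} p={r.p:.4g}{mark}")
            if mark:
                hits.append(r.snp_id)
        if pset is not None:
            corr = build_test_correlation(pset, ld)
            mc = simulate_null(pset, corr, replicates, seed=config.seed)
            summary["phenotypes"][trait_name] = {
                "T": mc.statistic, "n": mc.n_tests, "overall_p": mc.overall_p,
                "reps": mc.n_replicates, "bonferroni_hits": hits}
            report.append(f"  combined: T={mc.statistic:.3f} "
                          f"overall_p={mc.overall_p:.4g} "
                          f"({mc.n_replicates} replicates)")
        report.append("")

    logger.info("stage interact: %s x %s", *pair)
    ires = interaction_test(expr, geno.dosage_of(pair[0]),
                            geno.dosage_of(pair[1]), K,
                            snp1=pair[0], snp2=pair[1])
    s1 = geno.snps[geno.snp_index(pair[0])]
    s2 = geno.snps[geno.snp_index(pair[1])]
    result_rows.append({
        "test_id": f"interaction:{pair[0]}x{pair[1]}", "snp1": pair[0],
        "snp2": pair[1], "chr1": s1.chromosome, "chr2": s2.chromosome,
        "phenotype": "expression", "beta": ires.gamma, "se": "",
        "statistic": ires.lrt_statistic, "df": ires.df, "p": ires.p})
    summary["interaction"] = {"pair": list(pair), "gamma_hat": ires.gamma,
                              "lrt": ires.lrt_statistic, "p": ires.p}
    report.append(f"[expression] interaction {pair[0]} x {pair[1]}: "
                  f"LRT={ires.lrt_statistic:.3f} p={ires.p:.4g}")

    dm.write_results(result_rows, out / "results.tsv")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return summary
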