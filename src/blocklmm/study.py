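"""Simulation-study orchestration: replay the power comparison at configurable scale.

One iteration = simulate a genotype panel with haplotype blocks, plant the
three-QTN architecture, simulate the trait under each scenario, run each
GWAS method, and score it with the evaluation statistics.  Means over
iterations give the study summary.  Everything is reproducible from a
single master seed, fanned out to per-iteration seeds through
``numpy.random.SeedSequence`` spawn keys so iterations are independent and
individually re-runnable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from blocklmm.assoc import (
    AssociationResult,
    results_to_frame,
    single_snp_gwas,
    snpset_gwas,
)
from blocklmm.evaluate import (
    EvalConfig,
    auc_around_causals,
    causal_neighborhood,
    confusion_stats,
    inflator,
    ld_collapse,
    significance_threshold,
)
from blocklmm.genotype_io import MarkerGenotypes, SnpSet
from blocklmm.kernels import KernelSpec, additive_grm, structure_eigenvectors
from blocklmm.simulate import GenotypeSimSpec, PhenotypeSim, simulate_genotypes, simulate_phenotype

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of a full simulation study."""

    n_iterations: int = 20
    scenarios: tuple[str, ...] = ("coupling", "repulsion")
    methods: tuple[str, ...] = ("snpset", "single_snp")
    genotype: GenotypeSimSpec = field(default_factory=GenotypeSimSpec)
    h2_qtn: float = 0.3
    h2_polygenic: float = 0.3
    eval_config: EvalConfig = field(default_factory=EvalConfig)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    n_structure_eigenvectors: int = 2
    seed: int = 0
    max_failure_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.scenarios or not self.methods:
            raise ValueError("scenarios and methods must be nonempty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["methods"] = list(self.methods)
        d["genotype"]["snps_per_block"] = list(self.genotype.snps_per_block)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "genotype" in d:
            g = dict(d["genotype"])
            if "snps_per_block" in g:
                g["snps_per_block"] = tuple(g["snps_per_block"])
            d["genotype"] = GenotypeSimSpec(**g)
        if "eval_config" in d:
            d["eval_config"] = EvalConfig(**d["eval_config"])
        if "kernel" in d:
            d["kernel"] = KernelSpec(**d["kernel"])
        d["scenarios"] = tuple(d.get("scenarios", ("coupling", "repulsion")))
        d["methods"] = tuple(d.get("methods", ("snpset", "single_snp")))
        return cls(**d)


def evaluate_method_results(
    method: str,
    results: list[AssociationResult],
    geno: MarkerGenotypes,
    sets: list[SnpSet],
    sim: PhenotypeSim,
    config: EvalConfig | None = None,
) -> dict[str, float]:
    """Score one method's results against the planted truth.

    Returns the per-iteration summary statistics: inflator, raw and
    inflation-adjusted causal score (single-SNP scores are averaged over the
    QTN1/QTN2 pair), detected flag, recall/precision/F under BH-FDR and
    Bonferroni thresholds, and the causal-neighborhood AUC.
    """
    config = config or EvalConfig()
    if method == "snpset":
        unit_sets = sets
        qtn3_set = next(
            (s for s in sets if sim.qtn3_idx in s.marker_indices), None
        )
        causal_pair_units = [sim.causal_set_id]
        causal_units = {sim.causal_set_id}
        if qtn3_set is not None:
            causal_units.add(qtn3_set.set_id)
    elif method == "single_snp":
        unit_sets = None
        causal_pair_units = [geno.markers[sim.qtn1_idx], geno.markers[sim.qtn2_idx]]
        causal_units = set(causal_pair_units) | {geno.markers[sim.qtn3_idx]}
    else:
        raise ValueError(f"unknown method {method!r}")

    collapsed = ld_collapse(results, geno, config, sets=unit_sets, causal_units=causal_units)
    in_causal_ld = set()
    for s in collapsed:
        if s.is_causal:
            in_causal_ld.update(s.members)
    infl = inflator(results, causal_units, L=config.L, excluded_units=in_causal_ld)

    by_id = {r.unit_id: r for r in results}
    pair_scores = [by_id[u].neg_log10_p for u in causal_pair_units if u in by_id]
    score = float(np.mean(pair_scores)) if pair_scores else 0.0
    adj_score = score - infl
    detected = adj_score >= config.detected_threshold

    pvals = [r.p_value for r in results]
    cutoff_bh = significance_threshold(pvals, "BH", config.fdr)
    cutoff_bonf = significance_threshold(pvals, "bonferroni", config.bonferroni_alpha)
    recall_bh, precision_bh, f_bh = confusion_stats(collapsed, cutoff_bh)
    recall_bf, precision_bf, f_bf = confusion_stats(collapsed, cutoff_bonf)

    aucs = []
    for u in causal_pair_units:
        if u not in by_id:
            continue
        neigh = causal_neighborhood(results, geno, u, config, sets=unit_sets)
        a = auc_around_causals(results, u, neigh)
        if a is not None:
            aucs.append(a)
    auc = float(np.mean(aucs)) if aucs else np.nan

    return {
        "auc_detected": auc if detected else np.nan,
        "inflator": infl,
        "neg_log10_p_qtn12": score,
        "adj_neg_log10_p_qtn12": adj_score,
        "detected": float(detected),
        "recall_bh": recall_bh,
        "precision_bh": precision_bh,
        "f_measure_bh": f_bh,
        "recall_bonf": recall_bf,
        "precision_bonf": precision_bf,
        "f_measure_bonf": f_bf,
        "auc": auc,
    }


def _iteration_seeds(master_seed: int, iteration: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration,))
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def run_iteration(
    config: StudyConfig, iteration: int
) -> tuple[pd.DataFrame, dict[str, list[AssociationResult]]]:
    """One simulation iteration; returns the long-format stats table and raw results."""
    geno_seed, pheno_seed = _iteration_seeds(config.seed, iteration)
    gspec = GenotypeSimSpec(**{**asdict(config.genotype), "seed": geno_seed})
    gspec.snps_per_block = tuple(config.genotype.snps_per_block)
    geno, sets = simulate_genotypes(gspec)
    Kc = additive_grm(geno.codes, ids=geno.samples)
    structure = structure_eigenvectors(Kc, k=config.n_structure_eigenvectors)
    rows = []
    raw: dict[str, list[AssociationResult]] = {}
    for scenario in config.scenarios:
        sim = simulate_phenotype(
            geno,
            sets,
            scenario=scenario,
            h2_qtn=config.h2_qtn,
            h2_polygenic=config.h2_polygenic,
            seed=pheno_seed,
            grm=Kc,
        )
        for method in config.methods:
            t0 = time.perf_counter()
            if method == "snpset":
                res = snpset_gwas(
                    geno, sim.y, sets, spec=config.kernel, structure=structure, Kc=Kc
                )
            elif method == "single_snp":
                res = single_snp_gwas(geno, sim.y, structure=structure, Kc=Kc)
            else:
                raise ValueError(f"unknown method {method!r}")
            raw[f"{scenario}:{method}"] = res
            stats = evaluate_method_results(
                method, res, geno, sets, sim, config.eval_config
            )
            logger.info(
                "iter %d %s/%s: %.1fs, adj score %.2f",
                iteration, scenario, method,
                time.perf_counter() - t0, stats["adj_neg_log10_p_qtn12"],
            )
            for stat, value in stats.items():
                rows.append(
                    {
                        "iteration": iteration,
                        "scenario": scenario,
                        "method": method,
                        "statistic": stat,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows), raw


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Run the full study; returns mean statistics per (scenario, method, statistic).

    A failed iteration is logged and skipped; more than
    ``max_failure_fraction`` failures aborts the study.
    """
    tables = []
    failures = 0
    for it in range(config.n_iterations):
        try:
            tab, raw = run_iteration(config, it)
            tables.append(tab)
            if outdir is not None:
                resdir = Path(outdir) / "results"
                resdir.mkdir(parents=True, exist_ok=True)
                for key, res in raw.items():
                    name = key.replace(":", "_")
                    results_to_frame(res).to_csv(
                        resdir / f"iter{it:03d}_{name}.tsv", sep="\t", index=False
                    )
        except Exception:
            failures += 1
            logger.exception("iteration %d failed", it)
            if failures > config.max_failure_fraction * config.n_iterations:
                raise RuntimeError(
                    f"{failures} of {config.n_iterations} iterations failed; aborting"
                )
    long = pd.concat(tables, ignore_index=True)
    summary = (
        long.groupby(["scenario", "method", "statistic"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "summary").mkdir(parents=True, exist_ok=True)
        long.to_csv(outdir / "summary" / "per_iteration.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "summary" / "summary.tsv", sep="\t", index=False)
        summary.to_json(outdir / "summary" / "summary.json", orient="records", indent=2)
        with open(outdir / "summary" / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)
    return summary
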