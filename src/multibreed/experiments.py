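"""Replicated simulation experiments over the full pipeline.

Each function simulates data under stated study conditions, runs the
relevant estimator end to end and returns summary numbers.  They back
both the acceptance checks and exploratory use; all randomness flows
from one root seed through named substreams so results are reproducible.

Two architecture regimes are used deliberately:

* variance-component recovery (h2, rg) uses a *polygenic* architecture
  (many small QTL), under which the realized heritability and effect
  correlation concentrate tightly at their targets, so the experiments
  measure estimator error rather than architecture sampling noise;
* BayesR experiments use the *sparse* four-component mixture that the
  model is built for.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .bayesr import BayesRConfig, fit_bayesr
from .bayesr import predict as bayesr_predict
from .evaluate import Dataset, Scenario, cross_validate
from .gblup import ModelSpec, multitrait_reml, reml, solve_mme
from .grm import gunw, within_grm
from .io import qc_filter
from .ld import phase_persistence
from .panel import GenotypePanel, make_marker_map
from .simulate import (
    ArchitectureConfig,
    SimConfig,
    simulate_base_population,
    simulate_dataset,
    split_and_drift,
)

__all__ = [
    "h2_recovery",
    "rg_recovery",
    "simulate_bayesr_prior_dataset",
    "bayesr_prior_recovery",
    "bayesr_h2_coverage",
    "phase_persistence_by_divergence",
    "bayesr_vs_gblup_wins",
    "multibreed_reference_wins",
    "density_wins",
]

POLYGENIC_MIX = (0.2, 0.4, 0.3, 0.1)
STANDARD_EFFECTS = ["gender", "farm", "birth_year", "slaughter_age"]


def _seed_for(seed: int, name: str, i: int) -> int:
    return int(substream(seed, f"{name}-{i}").integers(2**31))


def h2_recovery(
    n_seeds: int = 10,
    n: int = 1200,
    m: int = 2000,
    h2: float = 0.40,
    seed: int = 0,
) -> dict:
    """Single-breed REML heritability recovery under a polygenic trait."""
    estimates = []
    for i in range(n_seeds):
        s = _seed_for(seed, "h2", i)
        cfg = SimConfig(
            n_base_haplotypes=2 * n, n_markers=m, n_chromosomes=10,
            base_generations=60, breed_sizes={"A": n},
            divergence_generations=0, seed=s,
        )
        arch = ArchitectureConfig(
            n_qtl=min(800, m // 2), mixture_proportions=POLYGENIC_MIX,
            h2_per_breed={"A": h2}, seed=s + 1,
        )
        panel, pheno, _ = simulate_dataset(cfg, arch)
        panel, _ = qc_filter(panel)
        grm = within_grm(panel)
        spec = ModelSpec(response="trait", fixed_effects=STANDARD_EFFECTS, grm=grm)
        estimates.append(reml(pheno, spec).h2["trait"])
    return {"mean_h2": float(np.mean(estimates)), "estimates": estimates,
            "target": h2, "n": n, "m": m}


def rg_recovery(
    n_seeds: int = 10,
    n_per_breed: int = 800,
    m: int = 3000,
    rg: float = 0.8,
    seed: int = 0,
) -> dict:
    """Bivariate (trait-per-breed) REML genetic-correlation recovery.

    Breeds split recently (2 generations) from a shared base so that
    cross-breed relatedness identifies the genetic covariance.
    """
    estimates = []
    for i in range(n_seeds):
        s = _seed_for(seed, "rg", i)
        cfg = SimConfig(
            n_base_haplotypes=2 * n_per_breed, n_markers=m, n_chromosomes=10,
            base_generations=80, breed_sizes={"A": n_per_breed, "B": n_per_breed},
            divergence_generations=2, seed=s,
        )
        arch = ArchitectureConfig(
            n_qtl=min(1000, m // 2), mixture_proportions=POLYGENIC_MIX,
            h2_per_breed={"A": 0.5, "B": 0.5}, rg_between_breeds=rg, seed=s + 1,
        )
        panel, pheno, _ = simulate_dataset(cfg, arch)
        panel, _ = qc_filter(panel)
        grm = gunw(panel.select_breed("A"), panel.select_breed("B"))
        spec = ModelSpec(response="trait", fixed_effects=STANDARD_EFFECTS,
                         grm=grm, breed_as_trait=True)
        estimates.append(float(multitrait_reml(pheno, spec).rg[0, 1]))
    return {"mean_rg": float(np.mean(estimates)), "estimates": estimates,
            "target": rg, "n_per_breed": n_per_breed, "m": m}


def simulate_bayesr_prior_dataset(
    n: int, m: int, P: tuple, h2: float, sigma_g2: float, rng: np.random.Generator
) -> tuple[GenotypePanel, pd.DataFrame, np.ndarray, np.ndarray]:
    """Phenotypes drawn exactly from the four-component mixture model.

    Genotypes are unlinked (linkage equilibrium), so the only structure in
    the data is the one the mixture prior describes.  Returns the panel,
    the phenotype table, the per-marker effects and the class indicators.
    """
    from .simulate import MIXTURE_VARIANCE_SCALES

    freq = rng.uniform(0.1, 0.9, m)
    dos = ((rng.random((n, m)) < freq).astype(float)
           + (rng.random((n, m)) < freq).astype(float))
    mm = make_marker_map(np.ones(m, dtype=int), (np.arange(m) + 1) * 1000)
    panel = GenotypePanel(
        dos,
        np.asarray([f"i{k}" for k in range(n)], dtype=object),
        np.asarray(["A"] * n, dtype=object),
        mm,
    )
    z = rng.choice(4, size=m, p=np.asarray(P))
    alpha = rng.standard_normal(m) * np.sqrt(
        MIXTURE_VARIANCE_SCALES[z] * sigma_g2
    )
    g = (dos - dos.mean(axis=0)) @ alpha
    var_g = float(np.var(g))
    e = rng.standard_normal(n) * np.sqrt(var_g * (1 - h2) / h2)
    pheno = pd.DataFrame(
        {
            "id": panel.individual_ids,
            "trait": 2.0 + g + e,
            "gender": np.where(rng.integers(0, 2, n) == 1, "m", "f"),
        }
    )
    return panel, pheno, alpha, z


def bayesr_prior_recovery(
    n_seeds: int = 4,
    n: int = 4000,
    m: int = 2000,
    P: tuple = (0.95, 0.03, 0.015, 0.005),
    h2: float = 0.5,
    n_iter: int = 5000,
    seed: int = 0,
) -> dict:
    """Posterior-mean mixture proportions on data drawn from the prior."""
    P = tuple(P)
    P_means = []
    for i in range(n_seeds):
        s = _seed_for(seed, "bayesr-P", i)
        rng = np.random.default_rng(s)
        panel, pheno, _, _ = simulate_bayesr_prior_dataset(n, m, P, h2, 1.0, rng)
        cfg = BayesRConfig(n_iter=n_iter, burn_in=n_iter // 4, thin=5, seed=s + 1)
        fit = fit_bayesr(pheno, panel, ["gender"], cfg)
        P_means.append(fit.P_mean)
    avg = np.mean(P_means, axis=0)
    return {
        "P_target": list(P),
        "P_posterior_mean": [float(v) for v in avg],
        "max_abs_error": float(np.max(np.abs(avg - np.asarray(P)))),
        "per_seed": [list(map(float, v)) for v in P_means],
        "n": n, "m": m,
    }


def bayesr_h2_coverage(
    n_seeds: int = 20,
    n: int = 800,
    m: int = 400,
    h2: float = 0.5,
    n_iter: int = 1500,
    level: float = 0.90,
    seed: int = 0,
) -> dict:
    """Fraction of nominal credible intervals covering the generating h2."""
    covered = 0
    for i in range(n_seeds):
        s = _seed_for(seed, "bayesr-cov", i)
        rng = np.random.default_rng(s)
        panel, pheno, alpha, _ = simulate_bayesr_prior_dataset(
            n, m, (0.95, 0.03, 0.015, 0.005), h2, 1.0, rng
        )
        dos = panel.dosages
        g = (dos - dos.mean(axis=0)) @ alpha
        e = pheno["trait"].to_numpy() - 2.0 - g
        h2_gen = float(np.var(g) / (np.var(g) + np.var(e)))
        cfg = BayesRConfig(n_iter=n_iter, burn_in=n_iter // 4, thin=5, seed=s + 1)
        fit = fit_bayesr(pheno, panel, ["gender"], cfg)
        lo, hi = fit.h2_interval(level)
        covered += lo <= h2_gen <= hi
    return {"coverage": covered / n_seeds, "n_seeds": n_seeds, "level": level,
            "n": n, "m": m}


def phase_persistence_by_divergence(
    divergence_levels: tuple = (0, 10, 40),
    n_seeds: int = 8,
    n_per_breed: int = 150,
    m: int = 800,
    seed: int = 0,
) -> dict:
    """Mean genome-average phase persistence at increasing divergence."""
    means = []
    for gens in divergence_levels:
        vals = []
        for i in range(n_seeds):
            s = _seed_for(seed, f"pp-{gens}", i)
            cfg = SimConfig(
                n_base_haplotypes=4 * n_per_breed, n_markers=m, n_chromosomes=4,
                base_generations=50, breed_sizes={"A": n_per_breed, "B": n_per_breed},
                divergence_generations=gens, seed=s,
            )
            base = simulate_base_population(cfg)
            panel = split_and_drift(base, cfg)
            pp = phase_persistence(panel.select_breed("A"), panel.select_breed("B"))
            vals.append(pp.genome_average)
        means.append(float(np.mean(vals)))
    return {"divergence_generations": list(divergence_levels),
            "mean_persistence": means}


def _sparse_within_breed_dataset(n: int, m: int, seed: int):
    cfg = SimConfig(
        n_base_haplotypes=2 * n, n_markers=m, n_chromosomes=6,
        base_generations=60, breed_sizes={"A": n},
        divergence_generations=0, seed=seed,
    )
    arch = ArchitectureConfig(
        n_qtl=20, mixture_proportions=(0.0, 0.0, 0.0, 1.0),
        h2_per_breed={"A": 0.5}, seed=seed + 1,
    )
    panel, pheno, truth = simulate_dataset(cfg, arch)
    panel, _ = qc_filter(panel)
    return panel, pheno, truth


def bayesr_vs_gblup_wins(
    n_seeds: int = 10,
    n: int = 800,
    m: int = 1500,
    n_validation: int = 160,
    n_iter: int = 2000,
    seed: int = 0,
) -> dict:
    """How often BayesR beats GBLUP in validation accuracy against true
    breeding values under a sparse (few moderate-QTL) architecture."""
    wins = 0
    pairs = []
    for i in range(n_seeds):
        s = _seed_for(seed, "bvg", i)
        panel, pheno, truth = _sparse_within_breed_dataset(n, m, s)
        rng = np.random.default_rng(s + 2)
        val = rng.choice(panel.n_individuals, n_validation, replace=False)
        train = np.setdiff1d(np.arange(panel.n_individuals), val)
        train_df = pheno.iloc[train].reset_index(drop=True)
        ids_val = [str(v) for v in panel.individual_ids[val]]
        tbv = truth.true_breeding_values.loc[ids_val].to_numpy()

        grm = within_grm(panel)
        spec = ModelSpec(response="trait", fixed_effects=STANDARD_EFFECTS, grm=grm)
        gfit = solve_mme(train_df, spec, reml(train_df, spec))
        acc_g = float(np.corrcoef(gfit.gebv.loc[ids_val], tbv)[0, 1])

        bcfg = BayesRConfig(n_iter=n_iter, burn_in=n_iter // 4, thin=5, seed=s + 3)
        bfit = fit_bayesr(train_df, panel, STANDARD_EFFECTS, bcfg)
        pred = bayesr_predict(bfit, panel.subset(individuals=val))
        acc_b = float(np.corrcoef(pred.to_numpy(), tbv)[0, 1])
        wins += acc_b >= acc_g
        pairs.append((acc_g, acc_b))
    return {"win_fraction": wins / n_seeds, "accuracies": pairs, "n": n, "m": m}


def multibreed_reference_wins(
    n_seeds: int = 10,
    n_large: int = 700,
    n_target: int = 250,
    m: int = 1200,
    rg: float = 0.8,
    seed: int = 0,
) -> dict:
    """How often a multi-breed reference beats the within-breed reference
    for a small target breed (GBLUP with the unweighted joint GRM)."""
    wins = 0
    pairs = []
    for i in range(n_seeds):
        s = _seed_for(seed, "mbr", i)
        cfg = SimConfig(
            n_base_haplotypes=2 * n_large, n_markers=m, n_chromosomes=6,
            base_generations=70, breed_sizes={"A": n_large, "B": n_target},
            divergence_generations=3, seed=s,
        )
        arch = ArchitectureConfig(
            n_qtl=min(600, m // 2), mixture_proportions=POLYGENIC_MIX,
            h2_per_breed={"A": 0.5, "B": 0.5}, rg_between_breeds=rg, seed=s + 1,
        )
        panel, pheno, _ = simulate_dataset(cfg, arch)
        panel, _ = qc_filter(panel)
        ds = Dataset(panel=panel, pheno=pheno)
        within = cross_validate(ds, Scenario(
            reference_breeds=["B"], target_breed="B", method="GBLUP-GUNW",
            k_folds=5, n_replicates=1, seed=s + 2))
        multi = cross_validate(ds, Scenario(
            reference_breeds=["A", "B"], target_breed="B", method="GBLUP-GUNW",
            k_folds=5, n_replicates=1, seed=s + 2))
        wins += multi.mean_accuracy >= within.mean_accuracy
        pairs.append((within.mean_accuracy, multi.mean_accuracy))
    return {"win_fraction": wins / n_seeds, "accuracies": pairs}


def density_wins(
    n_seeds: int = 10,
    n_large: int = 500,
    n_target: int = 250,
    m_dense: int = 1600,
    thin_factor: int = 4,
    n_iter: int = 1500,
    seed: int = 0,
) -> dict:
    """How often the dense ("WGS-like") marker set beats its nested sparse
    ("HD-like") subset for BayesR with a multi-breed reference."""
    wins = 0
    pairs = []
    for i in range(n_seeds):
        s = _seed_for(seed, "dens", i)
        cfg = SimConfig(
            n_base_haplotypes=2 * n_large + 2 * n_target, n_markers=m_dense,
            n_chromosomes=6, base_generations=60,
            breed_sizes={"A": n_large, "B": n_target},
            divergence_generations=3, seed=s,
        )
        arch = ArchitectureConfig(
            n_qtl=40, mixture_proportions=(0.0, 0.5, 0.3, 0.2),
            h2_per_breed={"A": 0.5, "B": 0.5}, rg_between_breeds=0.8, seed=s + 1,
        )
        panel, pheno, _ = simulate_dataset(cfg, arch)
        panel, _ = qc_filter(panel)
        ds = Dataset(
            panel=panel, pheno=pheno,
            marker_sets={
                "WGS-like": np.arange(panel.n_markers),
                "HD-like": np.arange(0, panel.n_markers, thin_factor),
            },
        )
        accs = {}
        for dens in ("HD-like", "WGS-like"):
            res = cross_validate(ds, Scenario(
                reference_breeds=["A", "B"], target_breed="B", method="BayesR",
                density=dens, n_replicates=1, holdout_size=max(60, n_target // 3),
                seed=s + 2,
                bayesr=BayesRConfig(n_iter=n_iter, burn_in=n_iter // 4, thin=5),
            ))
            accs[dens] = res.mean_accuracy
        wins += accs["WGS-like"] >= accs["HD-like"]
        pairs.append((accs["HD-like"], accs["WGS-like"]))
    return {"win_fraction": wins / n_seeds, "accuracies": pairs}
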