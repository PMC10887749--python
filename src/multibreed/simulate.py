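"""Forward-in-time multi-breed genotype and phenotype simulator.

Wright-Fisher random mating with Haldane (Poisson, no-interference)
recombination builds within-population LD over ``base_generations``; the
base population is then split into breeds that drift apart for a
controllable number of generations, producing realistic within-breed LD
decay and cross-breed LD-phase persistence that falls with divergence.
Phenotypes are generated under a four-component normal-mixture effect-size
architecture with per-breed heritabilities and a tunable cross-breed
genetic correlation, plus categorical fixed effects (gender, farm, birth
year) and a slaughter-age covariate, mirroring a beef-cattle slaughter
weight analysis design.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .panel import GenotypePanel, HaplotypePanel, make_marker_map, pair_haplotypes

__all__ = [
    "SimConfig",
    "ArchitectureConfig",
    "SimTruth",
    "simulate_base_population",
    "split_and_drift",
    "simulate_phenotypes",
    "simulate_dataset",
    "hudson_fst",
    "MIXTURE_VARIANCE_SCALES",
]

#: Relative variance of each effect-size mixture class (times sigma_g^2).
MIXTURE_VARIANCE_SCALES = np.array([0.0, 1e-4, 1e-3, 1e-2])


@dataclass
class SimConfig:
    """Demography knobs for the genotype simulator.

    Defaults emulate the three-breed beef-cattle design this package
    targets (a large main breed plus two small ones; 29 autosomes), at a
    marker density scaled to desk-size experiments.
    """

    n_base_haplotypes: int = 800
    n_markers: int = 5000
    n_chromosomes: int = 29
    chrom_length_morgans: float = 1.0
    base_generations: int = 100
    breed_sizes: dict[str, int] = field(
        default_factory=lambda: {"HX": 1478, "WG": 600, "YL": 400}
    )
    divergence_generations: int = 30
    target_fst: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, val in [
            ("n_base_haplotypes", self.n_base_haplotypes),
            ("n_markers", self.n_markers),
            ("n_chromosomes", self.n_chromosomes),
        ]:
            if int(val) <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.n_base_haplotypes % 2:
            raise ValueError("n_base_haplotypes must be even (diploid pool)")
        if self.chrom_length_morgans <= 0:
            raise ValueError("chrom_length_morgans must be positive")
        if self.base_generations < 0 or self.divergence_generations < 0:
            raise ValueError("generation counts must be nonnegative")
        if not self.breed_sizes:
            raise ValueError("breed_sizes must contain at least one breed")
        if any(int(n) <= 0 for n in self.breed_sizes.values()):
            raise ValueError("all breed sizes must be positive")
        if self.target_fst is not None and not (0.0 <= self.target_fst <= 0.5):
            raise ValueError("target_fst must lie in [0, 0.5]")


@dataclass
class ArchitectureConfig:
    """Genetic architecture and fixed-effect layout for phenotypes."""

    n_qtl: int = 200
    mixture_proportions: tuple[float, ...] = (0.95, 0.03, 0.015, 0.005)
    h2_per_breed: dict[str, float] = field(
        default_factory=lambda: {"HX": 0.40, "WG": 0.53, "YL": 0.49}
    )
    rg_between_breeds: float | np.ndarray = 0.8
    n_gender_levels: int = 2
    n_farm_levels: int = 5
    n_birth_years: int = 5
    slaughter_age_range: tuple[float, float] = (540.0, 960.0)
    fixed_effect_sd: float = 0.3  # per-factor effect SD in phenotype-SD units
    seed: int = 0

    def validate(self, breeds: list[str]) -> None:
        p = np.asarray(self.mixture_proportions, dtype=float)
        if p.size != 4 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("mixture_proportions must be 4 nonnegative values summing to 1")
        if self.n_qtl <= 0:
            raise ValueError("n_qtl must be positive")
        for b in breeds:
            h2 = self.h2_per_breed.get(b)
            if h2 is None:
                raise ValueError(f"h2_per_breed missing breed {b!r}")
            if not (0.0 <= h2 < 1.0):
                raise ValueError(f"h2 for breed {b!r} must lie in [0, 1)")
        R = self.rg_matrix(breeds)
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("rg matrix must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ValueError("rg matrix must be positive semidefinite")

    def rg_matrix(self, breeds: list[str]) -> np.ndarray:
        t = len(breeds)
        if np.isscalar(self.rg_between_breeds):
            r = float(self.rg_between_breeds)
            if not (-1.0 <= r <= 1.0):
                raise ValueError("rg must lie in [-1, 1]")
            R = np.full((t, t), r)
            np.fill_diagonal(R, 1.0)
            return R
        R = np.asarray(self.rg_between_breeds, dtype=float)
        if R.shape != (t, t):
            raise ValueError(f"rg matrix must be {t}x{t} for breeds {breeds}")
        return R


@dataclass
class SimTruth:
    """Everything a recovery test needs about the generating process."""

    qtl_indices: np.ndarray
    qtl_classes: np.ndarray  # mixture class 0..3 per QTL
    qtl_effects: np.ndarray  # (n_qtl, n_breeds) per-breed allele substitution
    true_breeding_values: pd.Series  # indexed by individual id
    realized_h2: dict[str, float]
    realized_fst: dict[tuple[str, str], float]
    breeds: list[str]
    fixed_effects: dict[str, np.ndarray]
    residual_sd: dict[str, float]


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _marker_layout(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Even marker placement: chromosome id, bp position, genetic position."""
    counts = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    counts[: cfg.n_markers % cfg.n_chromosomes] += 1
    chrom_bp = cfg.chrom_length_morgans * 1e8  # ~1 cM / Mb
    chroms, pos_bp, pos_m = [], [], []
    for c, mc in enumerate(counts, start=1):
        if mc == 0:
            continue
        frac = (np.arange(mc) + 1.0) / (mc + 1.0)
        chroms.append(np.full(mc, c))
        pos_bp.append(np.round(frac * chrom_bp).astype(np.int64))
        pos_m.append(frac * cfg.chrom_length_morgans)
    return np.concatenate(chroms), np.concatenate(pos_bp), np.concatenate(pos_m)


def _recomb_probs(chrom: np.ndarray, gpos: np.ndarray) -> np.ndarray:
    """Per-marker switch probability of the gamete-building Markov chain.

    Entry k is the probability that the template haplotype differs between
    markers k-1 and k (Haldane map function); the first marker of every
    chromosome gets 0.5, which doubles as the random template start.
    """
    m = chrom.size
    probs = np.empty(m)
    probs[0] = 0.5
    d = np.diff(gpos)
    newchrom = np.diff(chrom) != 0
    probs[1:] = np.where(newchrom, 0.5, 0.5 * (1.0 - np.exp(-2.0 * d)))
    return probs


def _make_gametes(
    hap: np.ndarray, parents: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Meiosis for a batch of gametes.

    hap: (2N, m) pool; parents: diploid parent index per gamete; probs: the
    per-interval switch probabilities from :func:`_recomb_probs`.
    """
    n_gam = parents.size
    switches = rng.random((n_gam, probs.size)) < probs[None, :]
    use_second = np.logical_xor.accumulate(switches, axis=1)
    h0 = hap[2 * parents]
    h1 = hap[2 * parents + 1]
    return np.where(use_second, h1, h0)


def _wright_fisher(
    hap: np.ndarray, n_offspring: int, generations: int, probs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a haplotype pool by random mating for the given generations."""
    for _ in range(generations):
        n_parents = hap.shape[0] // 2
        mothers = rng.integers(0, n_parents, size=n_offspring)
        fathers = rng.integers(0, n_parents, size=n_offspring)
        g1 = _make_gametes(hap, mothers, probs, rng)
        g2 = _make_gametes(hap, fathers, probs, rng)
        new = np.empty((2 * n_offspring, hap.shape[1]), dtype=np.int8)
        new[0::2] = g1
        new[1::2] = g2
        hap = new
    return hap


def simulate_base_population(cfg: SimConfig) -> HaplotypePanel:
    """Build the ancestral haplotype pool with burnt-in LD.

    Loci start in linkage equilibrium at uniform(0.05, 0.95) frequencies;
    ``base_generations`` of finite-size random mating then generate LD whose
    extent is governed by population size and map length.  Markers that end
    the burn-in with MAF < 0.01 (or monomorphic) are dropped so that the
    base panel is clean and QC violations downstream are always injected
    deliberately.
    """
    cfg.validate()
    rng = substream(cfg.seed, "haplotypes")
    chrom, pos_bp, pos_m = _marker_layout(cfg)
    m = chrom.size
    freqs = rng.uniform(0.05, 0.95, size=m)
    hap = (rng.random((cfg.n_base_haplotypes, m)) < freqs[None, :]).astype(np.int8)
    probs = _recomb_probs(chrom, pos_m)
    hap = _wright_fisher(hap, cfg.n_base_haplotypes // 2, cfg.base_generations, probs, rng)
    p = hap.mean(axis=0)
    keep = (p >= 0.01) & (p <= 0.99)
    if not keep.any():
        raise RuntimeError("all markers lost to drift; increase population size")
    mm = make_marker_map(chrom[keep], pos_bp[keep])
    return HaplotypePanel(hap[:, keep], mm, pos_m[keep])


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson's Fst (ratio-of-averages) from allele frequencies.

    n1, n2 are allele (haplotype) sample sizes.  Markers fixed in both
    populations contribute nothing to either sum.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    if not ok.any():
        return float("nan")
    return float(num[ok].sum() / den[ok].sum())


def _generations_for_fst(target: float, sizes: list[int]) -> int:
    """Drift generations so pairwise expected Fst tracks ``target``.

    Under pure drift, E[Fst] for a pair of populations of diploid sizes
    N1, N2 diverged t generations ago is approximately
    1 - (lam1^t + lam2^t)/2 with lam_i = 1 - 1/(2 N_i); solve for t using
    the harmonic-mean size across all breeds.
    """
    if target <= 0:
        return 0
    n_h = len(sizes) / sum(1.0 / n for n in sizes)
    lam = 1.0 - 1.0 / (2.0 * n_h)
    return max(1, round(math.log(1.0 - target) / math.log(lam)))


def split_and_drift(base: HaplotypePanel, cfg: SimConfig) -> GenotypePanel:
    """Split the base pool into breeds and let each drift independently.

    Each breed draws its founder haplotypes from the base pool (without
    replacement within a breed) and then random-mates at its own census
    size for ``divergence_generations`` (or the number implied by
    ``target_fst``).  Returns one merged diploid panel with breed labels,
    phased.
    """
    cfg.validate()
    rng = substream(cfg.seed, "split")
    sizes = {b: int(n) for b, n in cfg.breed_sizes.items()}
    largest = max(sizes.values())
    if 2 * largest > base.n_haplotypes:
        raise ValueError(
            f"breed of size {largest} needs {2 * largest} founder haplotypes; "
            f"base has only {base.n_haplotypes}"
        )
    if cfg.target_fst is not None:
        gens = _generations_for_fst(cfg.target_fst, list(sizes.values()))
    else:
        gens = int(cfg.divergence_generations)
    probs = _recomb_probs(base.marker_map["chrom"].to_numpy(), base.genetic_pos)

    parts, ids, labels = [], [], []
    for breed, n_b in sizes.items():
        founder_rows = rng.permutation(base.n_haplotypes)[: 2 * n_b]
        hap = base.haplotypes[founder_rows].copy()
        hap = _wright_fisher(hap, n_b, gens, probs, rng)
        parts.append(hap)
        ids.extend(f"{breed}_{i:05d}" for i in range(n_b))
        labels.extend([breed] * n_b)
    merged = np.vstack(parts)
    return pair_haplotypes(merged, base.marker_map, ids, labels)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel: GenotypePanel, arch: ArchitectureConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes under the four-component mixture architecture.

    QTL effects for the same locus in different breeds are drawn from a
    multivariate normal with cross-breed correlation ``rg`` and class
    variance 0 / 1e-4 / 1e-3 / 1e-2 (relative units); residual variances
    are then set per breed so that var(TBV)/var(TBV + e) matches the
    requested heritability.  Fixed effects: gender, farm, birth year
    (categorical) and slaughter age (uniform over the configured range,
    linear effect).
    """
    breeds = panel.breeds
    arch.validate(breeds)
    if arch.n_qtl > panel.n_markers:
        raise ValueError(
            f"n_qtl={arch.n_qtl} exceeds marker count {panel.n_markers}"
        )
    if np.isnan(panel.dosages).any():
        raise ValueError("phenotype simulation requires a complete (no-missing) panel")

    rng_qtl = substream(arch.seed, "qtl")
    rng_eff = substream(arch.seed, "effects")
    rng_fix = substream(arch.seed, "fixed")
    rng_res = substream(arch.seed, "residuals")

    n_qtl = int(arch.n_qtl)
    qtl_idx = np.sort(rng_qtl.choice(panel.n_markers, size=n_qtl, replace=False))
    classes = rng_qtl.choice(4, size=n_qtl, p=np.asarray(arch.mixture_proportions))

    t = len(breeds)
    R = arch.rg_matrix(breeds)
    vals, vecs = np.linalg.eigh(R)  # PSD factor; exact even for singular R
    L = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    z = rng_eff.standard_normal((n_qtl, t))
    effects = z @ L.T  # unit-variance, correlation R across breeds
    effects *= np.sqrt(MIXTURE_VARIANCE_SCALES[classes])[:, None]
    for j, b in enumerate(breeds):
        if arch.h2_per_breed[b] == 0.0:
            effects[:, j] = 0.0

    n = panel.n_individuals
    tbv = np.zeros(n)
    realized_h2: dict[str, float] = {}
    residual_sd: dict[str, float] = {}
    residual = np.zeros(n)
    for j, b in enumerate(breeds):
        rows = np.flatnonzero(np.asarray([str(x) == b for x in panel.breed_labels]))
        M = panel.dosages[np.ix_(rows, qtl_idx)]
        g = (M - M.mean(axis=0)) @ effects[:, j]
        tbv[rows] = g
        h2 = arch.h2_per_breed[b]
        var_g = float(np.var(g))
        if h2 == 0.0 or var_g == 0.0:
            sd_e = 1.0
        else:
            sd_e = math.sqrt(var_g * (1.0 - h2) / h2)
        e = rng_res.standard_normal(rows.size) * sd_e
        residual[rows] = e
        denom = float(np.var(g + e))
        realized_h2[b] = 0.0 if denom == 0 else float(np.var(g) / denom)
        residual_sd[b] = sd_e

    # phenotype scale for fixed-effect sizes: average phenotypic SD
    sd_p = float(np.std(tbv + residual))
    if sd_p == 0.0:
        sd_p = 1.0
    f_sd = arch.fixed_effect_sd * sd_p

    gender = rng_fix.integers(0, arch.n_gender_levels, size=n)
    farm = rng_fix.integers(0, arch.n_farm_levels, size=n)
    year = rng_fix.integers(0, arch.n_birth_years, size=n)
    lo, hi = arch.slaughter_age_range
    age = rng_fix.uniform(lo, hi, size=n)
    eff_gender = rng_fix.standard_normal(arch.n_gender_levels) * f_sd
    eff_farm = rng_fix.standard_normal(arch.n_farm_levels) * f_sd
    eff_year = rng_fix.standard_normal(arch.n_birth_years) * f_sd
    age_sd = (hi - lo) / math.sqrt(12.0) if hi > lo else 1.0
    beta_age = rng_fix.standard_normal() * f_sd / age_sd
    eff_breed = rng_fix.standard_normal(t) * f_sd
    breed_of = {b: j for j, b in enumerate(breeds)}
    breed_idx = np.asarray([breed_of[str(b)] for b in panel.breed_labels])

    fixed_part = (
        eff_gender[gender]
        + eff_farm[farm]
        + eff_year[year]
        + beta_age * age
        + eff_breed[breed_idx]
    )
    y = fixed_part + tbv + residual

    pheno = pd.DataFrame(
        {
            "id": panel.individual_ids,
            "breed": [str(b) for b in panel.breed_labels],
            "trait": y,
            "gender": [f"g{v}" for v in gender],
            "farm": [f"farm{v}" for v in farm],
            "birth_year": 2015 + year,
            "slaughter_age": age,
        }
    )

    realized_fst: dict[tuple[str, str], float] = {}
    by_breed = {b: panel.select_breed(b) for b in breeds}
    for i in range(t):
        for j in range(i + 1, t):
            b1, b2 = breeds[i], breeds[j]
            realized_fst[(b1, b2)] = hudson_fst(
                by_breed[b1].allele_freq(), by_breed[b2].allele_freq(),
                2 * by_breed[b1].n_individuals, 2 * by_breed[b2].n_individuals,
            )

    truth = SimTruth(
        qtl_indices=qtl_idx,
        qtl_classes=classes,
        qtl_effects=effects,
        true_breeding_values=pd.Series(tbv, index=[str(i) for i in panel.individual_ids]),
        realized_h2=realized_h2,
        realized_fst=realized_fst,
        breeds=breeds,
        fixed_effects={
            "gender": eff_gender, "farm": eff_farm, "birth_year": eff_year,
            "slaughter_age": np.asarray([beta_age]), "breed": eff_breed,
        },
        residual_sd=residual_sd,
    )
    return pheno, truth


def simulate_dataset(
    cfg: SimConfig, arch: ArchitectureConfig
) -> tuple[GenotypePanel, pd.DataFrame, SimTruth]:
    """Convenience: base population -> breed split -> phenotypes."""
    base = simulate_base_population(cfg)
    panel = split_and_drift(base, cfg)
    pheno, truth = simulate_phenotypes(panel, arch)
    return panel, pheno, truth


def export_dataset(
    panel: GenotypePanel, pheno: pd.DataFrame, truth: SimTruth, outdir: str
) -> None:
    """Write a simulated dataset to disk in interchange formats.

    Produces one PLINK bed/bim/fam fileset per breed plus a merged one
    (breed label in the fam FID column and in a breeds.tsv sidecar), the
    phenotype table as tab-separated text, and the simulation truth as a
    JSON sidecar.
    """
    import json
    from pathlib import Path

    from .io import write_plink

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_plink(panel, out / "merged")
    pd.DataFrame(
        {"id": panel.individual_ids, "breed": panel.breed_labels}
    ).to_csv(out / "breeds.tsv", sep="\t", index=False)
    for breed, sub in panel.split_by_breed().items():
        write_plink(sub, out / breed)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    payload = {
        "breeds": truth.breeds,
        "qtl_indices": truth.qtl_indices.tolist(),
        "qtl_classes": truth.qtl_classes.tolist(),
        "qtl_effects": truth.qtl_effects.tolist(),
        "true_breeding_values": {
            str(k): float(v) for k, v in truth.true_breeding_values.items()
        },
        "realized_h2": truth.realized_h2,
        "realized_fst": {f"{a}|{b}": v for (a, b), v in truth.realized_fst.items()},
        "residual_sd": truth.residual_sd,
    }
    (out / "truth.json").write_text(json.dumps(payload))
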