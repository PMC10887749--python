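"""Replicated cross-validation of genomic prediction accuracy.

The experimental design mirrors multi-breed reference-population studies:
a scenario names the breeds whose phenotyped animals train the model, the
target breed whose validation accuracy is reported, the method
(GBLUP with an unweighted or LD-weighted multi-breed GRM, or BayesR) and
a marker-density label.  The target breed's phenotyped individuals are
split into k folds; each fold's phenotypes are masked, the model is
refitted on the remaining records (variance components re-estimated per
fold — no leakage), and accuracy is the Pearson correlation between the
fold's GEBV and its fixed-effect-adjusted phenotypes.  Replicates redraw
the folds; the summary is the mean of replicate means with its standard
error over replicates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .bayesr import BayesRConfig, fit_bayesr, predict as bayesr_predict
from .design import FixedEffectDesign
from .gblup import ModelSpec, reml, solve_mme
from .grm import GrmResult, joint_grm, within_grm
from .ld import gld_weights, neighbor_profiles
from .panel import GenotypePanel

__all__ = [
    "Dataset",
    "Scenario",
    "CvResult",
    "adjust_phenotypes",
    "accuracy",
    "cross_validate",
    "run_experiment_grid",
    "format_grid",
]

logger = logging.getLogger(__name__)

METHODS = ("GBLUP-GUNW", "GBLUP-GLD", "BayesR")
DEFAULT_FIXED_EFFECTS = ["gender", "farm", "breed", "birth_year", "slaughter_age"]


@dataclass
class Dataset:
    """A QC'd multi-breed panel with its phenotype table.

    ``marker_sets`` optionally maps density labels (e.g. "HD-like",
    "WGS-like") to marker index arrays; densities are nested subsets of
    one simulation so density comparisons are paired.
    """

    panel: GenotypePanel
    pheno: pd.DataFrame
    marker_sets: dict[str, np.ndarray] | None = None


@dataclass
class Scenario:
    """One cell of the experiment grid."""

    reference_breeds: list[str]
    target_breed: str
    method: str = "GBLUP-GUNW"
    density: str | None = None
    k_folds: int = 5
    n_replicates: int = 10
    seed: int = 0
    fixed_effects: list[str] = field(default_factory=lambda: list(DEFAULT_FIXED_EFFECTS))
    bayesr: BayesRConfig | None = None
    ld_neighbors: int = 10
    ld_from_training_only: bool = False
    holdout_size: int | None = None  # fixed-size validation alternative

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    def describe(self) -> str:
        ref = "+".join(self.reference_breeds)
        dens = f", {self.density}" if self.density else ""
        return f"{ref} -> {self.target_breed} [{self.method}{dens}]"


@dataclass
class CvResult:
    """Per-replicate/per-fold accuracies with their summary."""

    scenario: Scenario
    accuracies: np.ndarray  # (n_replicates, n_folds)
    mean_accuracy: float
    se: float
    se_basis: str  # "replicates" or "folds"

    @property
    def replicate_means(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)


def make_folds(rows: np.ndarray, k_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Randomly partition ``rows`` into k disjoint folds covering all rows."""
    perm = rng.permutation(np.asarray(rows))
    return np.array_split(perm, k_folds)


def adjust_phenotypes(y: np.ndarray, X: np.ndarray, b_hat: np.ndarray) -> np.ndarray:
    """Residual phenotype after removing estimated fixed effects."""
    y = np.asarray(y, dtype=float)
    return y - np.asarray(X, dtype=float) @ np.asarray(b_hat, dtype=float)


def accuracy(gebv: np.ndarray, y_adjusted: np.ndarray) -> float:
    """Pearson correlation between GEBV and adjusted phenotypes."""
    g = np.asarray(gebv, dtype=float)
    y = np.asarray(y_adjusted, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("gebv and y_adjusted must be 1-D and aligned")
    if g.size < 3:
        raise ValueError("accuracy needs at least 3 paired values")
    if np.std(g) == 0.0 or np.std(y) == 0.0:
        raise ValueError("accuracy undefined: a vector is constant")
    return float(np.corrcoef(g, y)[0, 1])


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------

def _scenario_panel(dataset: Dataset, scenario: Scenario) -> GenotypePanel:
    breeds = list(dict.fromkeys([*scenario.reference_breeds, scenario.target_breed]))
    mask = np.isin(np.asarray([str(b) for b in dataset.panel.breed_labels]), breeds)
    panel = dataset.panel.subset(individuals=np.flatnonzero(mask))
    if scenario.density is not None:
        if not dataset.marker_sets or scenario.density not in dataset.marker_sets:
            raise KeyError(f"dataset has no marker set named {scenario.density!r}")
        panel = panel.subset(markers=dataset.marker_sets[scenario.density])
    return panel


def _effects_for(panel: GenotypePanel, effects: list[str]) -> list[str]:
    if len(panel.breeds) < 2:
        return [e for e in effects if e != "breed"]
    return list(effects)


def _build_grm(panel: GenotypePanel, scenario: Scenario,
               training_ids: np.ndarray | None = None) -> GrmResult:
    by_breed = panel.split_by_breed()
    panels = list(by_breed.values())
    if len(panels) == 1:
        return within_grm(panels[0])
    if scenario.method == "GBLUP-GLD":
        weight_source = panel
        if training_ids is not None:
            rows = weight_source.id_index(training_ids)
            weight_source = panel.subset(individuals=rows)
        profs = {
            b: neighbor_profiles(p, k=scenario.ld_neighbors)
            for b, p in weight_source.split_by_breed().items()
        }
        weights = {}
        names = list(by_breed)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                weights[(names[i], names[j])] = gld_weights(
                    profs[names[i]], profs[names[j]]
                )
        return joint_grm(panels, variant="GLD", weights_by_pair=weights)
    return joint_grm(panels, variant="GUNW")


def _fold_accuracy_gblup(
    train_df: pd.DataFrame, val_df: pd.DataFrame, grm: GrmResult,
    effects: list[str],
) -> float:
    spec = ModelSpec(response="trait", fixed_effects=effects, grm=grm)
    vc = reml(train_df, spec)
    fit = solve_mme(train_df, spec, vc)
    design = FixedEffectDesign(effects).fit(train_df)
    Xv, usable = design.transform(val_df)
    if not usable.all():
        val_df = val_df.loc[usable]
        Xv = Xv[usable]
    y_adj = adjust_phenotypes(val_df["trait"].to_numpy(), Xv, fit.b_hat.to_numpy())
    gebv = fit.gebv.loc[[str(v) for v in val_df["id"]]].to_numpy()
    return accuracy(gebv, y_adj)


def _fold_accuracy_bayesr(
    train_df: pd.DataFrame, val_df: pd.DataFrame, panel: GenotypePanel,
    effects: list[str], cfg: BayesRConfig,
) -> float:
    fit = fit_bayesr(train_df, panel, effects, cfg)
    design = FixedEffectDesign(effects).fit(train_df)
    Xv, usable = design.transform(val_df)
    if not usable.all():
        val_df = val_df.loc[usable]
        Xv = Xv[usable]
    y_adj = adjust_phenotypes(val_df["trait"].to_numpy(), Xv, fit.b_mean)
    rows = panel.id_index(val_df["id"])
    gebv = bayesr_predict(fit, panel.subset(individuals=rows)).to_numpy()
    return accuracy(gebv, y_adj)


def cross_validate(dataset: Dataset, scenario: Scenario) -> CvResult:
    """Replicated k-fold cross-validation of one scenario.

    Folds partition the target breed's phenotyped individuals.  The
    training set of a fold holds the target breed's remaining phenotyped
    individuals (when the target is part of the reference) plus all
    phenotyped individuals of the other reference breeds; the fold's
    phenotypes are masked everywhere, including variance-component
    estimation.  When ``holdout_size`` is set, each replicate instead
    holds out that many random target-breed individuals as validation.
    """
    scenario.validate()
    panel = _scenario_panel(dataset, scenario)
    breeds = panel.breeds
    pheno = dataset.pheno[dataset.pheno["breed"].isin(breeds)].reset_index(drop=True)
    effects = _effects_for(panel, scenario.fixed_effects)
    target = scenario.target_breed
    target_in_ref = target in scenario.reference_breeds
    target_rows = np.flatnonzero(pheno["breed"].to_numpy() == target)
    if target_rows.size == 0:
        raise ValueError(f"target breed {target!r} has no phenotyped individuals")
    other_rows = np.flatnonzero(
        pheno["breed"].isin([b for b in scenario.reference_breeds if b != target])
    )

    is_bayesr = scenario.method == "BayesR"
    grm_all = None
    if not is_bayesr and not scenario.ld_from_training_only:
        grm_all = _build_grm(panel, scenario)
    bcfg = scenario.bayesr or BayesRConfig(n_iter=3000, burn_in=600, thin=5)

    n_folds = 1 if scenario.holdout_size else scenario.k_folds
    acc = np.zeros((scenario.n_replicates, n_folds))
    for rep in range(scenario.n_replicates):
        rng = substream(scenario.seed, f"cv-rep{rep}")
        if scenario.holdout_size:
            if scenario.holdout_size >= target_rows.size:
                raise ValueError("holdout_size must leave training individuals")
            folds = [rng.permutation(target_rows)[: scenario.holdout_size]]
        else:
            folds = make_folds(target_rows, scenario.k_folds, rng)
        for f, fold in enumerate(folds):
            if fold.size < 3:
                raise ValueError(
                    f"fold of size {fold.size} is too small for accuracy"
                )
            train_target = np.setdiff1d(target_rows, fold) if target_in_ref else \
                np.empty(0, dtype=int)
            train_rows = np.concatenate([other_rows, train_target])
            if train_rows.size == 0:
                raise ValueError("empty training set for scenario "
                                 f"{scenario.describe()}")
            train_df = pheno.iloc[np.sort(train_rows)].reset_index(drop=True)
            val_df = pheno.iloc[np.sort(fold)].reset_index(drop=True)
            if is_bayesr:
                cfg = replace(bcfg, seed=int(
                    substream(scenario.seed, f"bayesr-{rep}-{f}").integers(2**31)
                ))
                acc[rep, f] = _fold_accuracy_bayesr(train_df, val_df, panel,
                                                    effects, cfg)
            else:
                grm = grm_all
                if grm is None:  # leakage-strict LD weights from training only
                    grm = _build_grm(panel, scenario,
                                     training_ids=train_df["id"].to_numpy())
                acc[rep, f] = _fold_accuracy_gblup(train_df, val_df, grm, effects)

    rep_means = acc.mean(axis=1)
    if scenario.n_replicates >= 2:
        se = float(np.std(rep_means, ddof=1) / np.sqrt(rep_means.size))
        basis = "replicates"
    elif acc.shape[1] >= 2:
        se = float(np.std(acc[0], ddof=1) / np.sqrt(acc[0].size))
        basis = "folds"
    else:
        se = float("nan")  # a single accuracy has no spread estimate
        basis = "undefined"
    return CvResult(
        scenario=scenario,
        accuracies=acc,
        mean_accuracy=float(rep_means.mean()),
        se=se,
        se_basis=basis,
    )


def run_experiment_grid(dataset: Dataset, scenarios: list[Scenario]) -> pd.DataFrame:
    """Run every scenario, collecting failures instead of aborting the grid."""
    rows = []
    for sc in scenarios:
        entry = {
            "refPop": "+".join(sc.reference_breeds),
            "target": sc.target_breed,
            "method": sc.method,
            "density": sc.density or "all",
        }
        try:
            res = cross_validate(dataset, sc)
            entry.update(
                mean_accuracy=res.mean_accuracy, se=res.se,
                n_replicates=sc.n_replicates, error="",
            )
        except Exception as exc:  # noqa: BLE001 - grid must continue
            logger.warning("scenario %s failed: %s", sc.describe(), exc)
            entry.update(mean_accuracy=np.nan, se=np.nan,
                         n_replicates=sc.n_replicates, error=str(exc))
        rows.append(entry)
    return pd.DataFrame(
        rows,
        columns=["refPop", "target", "method", "density", "mean_accuracy",
                 "se", "n_replicates", "error"],
    )


def format_grid(results: pd.DataFrame) -> str:
    """Text table, one row per (refPop, method), 'mean (se)' cells."""
    if results.empty:
        return "(no scenarios)"
    out = results.copy()
    out["cell"] = [
        "failed" if e else f"{m:.2f} ({s:.3f})"
        for m, s, e in zip(out["mean_accuracy"], out["se"], out["error"])
    ]
    pivot = out.pivot_table(
        index=["refPop", "method"], columns=["target", "density"],
        values="cell", aggfunc="first",
    )
    return pivot.to_string()
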