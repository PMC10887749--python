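"""Shared fixtures: small simulated datasets and hand-built panels."""
from __future__ import annotations

import numpy as np
import pytest

from multibreed import (
    ArchitectureConfig,
    GenotypePanel,
    SimConfig,
    qc_filter,
    simulate_dataset,
)
from multibreed.panel import make_marker_map


def build_panel(
    dosages,
    chrom=None,
    pos=None,
    breeds=None,
    phase=None,
    ids=None,
) -> GenotypePanel:
    """Hand-build a small panel from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = np.asarray(chrom if chrom is not None else np.ones(m, dtype=int))
    pos = np.asarray(pos if pos is not None else (np.arange(m) + 1) * 1000)
    breeds = list(breeds) if breeds is not None else ["X"] * n
    ids = list(ids) if ids is not None else [f"ind{i}" for i in range(n)]
    return GenotypePanel(
        dosages,
        np.asarray(ids, dtype=object),
        np.asarray(breeds, dtype=object),
        make_marker_map(chrom, pos),
        phase,
    )


def phased_panel_from_haplotypes(hap, chrom=None, pos=None, breeds=None) -> GenotypePanel:
    """Pair consecutive haplotype rows into a phased diploid panel."""
    hap = np.asarray(hap, dtype=np.int8)
    n2, m = hap.shape
    phase = hap.reshape(n2 // 2, 2, m)
    return build_panel(
        phase.sum(axis=1), chrom=chrom, pos=pos, breeds=breeds, phase=phase
    )


@pytest.fixture(scope="session")
def sim_two_breed():
    """Two diverged breeds (200 + 200) with phenotypes; raw and QC'd panels."""
    cfg = SimConfig(
        n_base_haplotypes=800,
        n_markers=600,
        n_chromosomes=3,
        base_generations=40,
        breed_sizes={"A": 200, "B": 200},
        divergence_generations=10,
        seed=11,
    )
    arch = ArchitectureConfig(
        n_qtl=60,
        h2_per_breed={"A": 0.4, "B": 0.5},
        rg_between_breeds=0.8,
        seed=12,
    )
    panel_raw, pheno, truth = simulate_dataset(cfg, arch)
    panel_qc, report = qc_filter(panel_raw)
    return {
        "cfg": cfg,
        "arch": arch,
        "panel_raw": panel_raw,
        "panel": panel_qc,
        "pheno": pheno,
        "truth": truth,
        "qc_report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
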