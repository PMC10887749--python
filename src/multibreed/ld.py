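"""Linkage-disequilibrium statistics and cross-breed LD-phase persistence.

Given phased haplotypes, the signed LD correlation between two markers is
r = D / sqrt(f(A)f(a)f(B)f(b)) with D = f(AB) - f(A)f(B) (Hill-Robertson),
which equals the Pearson correlation of the two haplotype indicator
columns; unphased panels fall back to the composite-LD dosage correlation.
Phase persistence between two populations is the Pearson correlation, per
autosome, of the LD statistic of adjacent marker pairs, averaged over
autosomes: a chip-era stand-in for the cross-population genetic
correlation of marker-QTL associations.  Per-marker weights for the
LD-weighted relationship matrix correlate the r^2 profile of each marker
with its ten nearest neighbours across the two breeds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "LdError",
    "LdProfile",
    "PhasePersistence",
    "pairwise_ld",
    "ld_decay",
    "phase_persistence",
    "neighbor_profiles",
    "gld_weights",
]

logger = logging.getLogger(__name__)


class LdError(ValueError):
    """Raised for LD requests that are undefined (e.g. monomorphic loci)."""


def _allele_columns(panel: GenotypePanel) -> tuple[np.ndarray, bool]:
    """(columns, phased_flag): haplotype indicators if phased, else dosages."""
    if panel.is_phased:
        return panel.haplotypes().astype(np.float64), True
    if np.isnan(panel.dosages).any():
        raise LdError("LD on unphased panels requires complete dosages")
    logger.info("panel unphased: using composite-LD dosage correlations")
    return panel.dosages, False


def pairwise_ld(panel: GenotypePanel, marker_a: int, marker_b: int) -> tuple[float, float, float]:
    """(D, r, r2) between two markers.

    Phased panels use exact haplotype frequencies; unphased panels the
    dosage correlation with D back-computed from r and the allele
    frequencies.  Monomorphic markers raise :class:`LdError`.
    """
    cols, phased = _allele_columns(panel)
    xa = cols[:, marker_a]
    xb = cols[:, marker_b]
    if phased:
        fA = xa.mean()
        fB = xb.mean()
        if fA in (0.0, 1.0) or fB in (0.0, 1.0):
            raise LdError(f"monomorphic marker in pair ({marker_a}, {marker_b})")
        fAB = (xa * xb).mean()
        D = fAB - fA * fB
        denom = fA * (1 - fA) * fB * (1 - fB)
        r = D / np.sqrt(denom)
    else:
        pa = xa.mean() / 2
        pb = xb.mean() / 2
        if xa.std() == 0.0 or xb.std() == 0.0:
            raise LdError(f"monomorphic marker in pair ({marker_a}, {marker_b})")
        r = float(np.corrcoef(xa, xb)[0, 1])
        D = r * np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    return float(D), float(r), float(r * r)


def _adjacent_r(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Signed r for every adjacent same-chromosome marker pair.

    Returns (r values with NaN where a member is monomorphic, chromosome
    of each pair).  Pair i couples map-order markers i and i+1.
    """
    cols, _ = _allele_columns(panel)
    chrom = panel.marker_map["chrom"].to_numpy()
    mu = cols.mean(axis=0)
    sd = cols.std(axis=0)
    centered = cols - mu
    cov = (centered[:, :-1] * centered[:, 1:]).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sd[:-1] * sd[1:])
    r[chrom[:-1] != chrom[1:]] = np.nan
    return r, chrom[:-1]


@dataclass
class PhasePersistence:
    """Per-autosome and genome-average LD-phase correlation."""

    per_chromosome: dict[int, float]
    genome_average: float
    scheme: str
    n_pairs: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, self.per_chromosome[c], self.n_pairs[c])
            for c in sorted(self.per_chromosome)
        ]
        return pd.DataFrame(rows, columns=["chrom", "correlation", "n_pairs"])


def phase_persistence(
    panel_1: GenotypePanel, panel_2: GenotypePanel, scheme: str = "signed_r"
) -> PhasePersistence:
    """Correlation across two populations of adjacent-pair LD, by autosome.

    scheme="signed_r" correlates signed r (keeps phase information and can
    range over [-1, 1]); scheme="r_squared" correlates r^2.  Pairs with a
    monomorphic member in either population are skipped; chromosomes with
    fewer than 3 usable pairs are skipped, and an error is raised if no
    chromosome is usable.
    """
    if scheme not in ("signed_r", "r_squared"):
        raise ValueError(f"unknown scheme {scheme!r}")
    mm1, mm2 = panel_1.marker_map, panel_2.marker_map
    if not (
        mm1["chrom"].to_numpy() == mm2["chrom"].to_numpy()
    ).all() or not (mm1["pos"].to_numpy() == mm2["pos"].to_numpy()).all():
        raise ValueError("panels must share one marker map")
    r1, chrom = _adjacent_r(panel_1)
    r2, _ = _adjacent_r(panel_2)
    if scheme == "r_squared":
        r1, r2 = r1**2, r2**2
    per_chrom: dict[int, float] = {}
    n_pairs: dict[int, int] = {}
    for c in np.unique(chrom):
        mask = (chrom == c) & ~np.isnan(r1) & ~np.isnan(r2)
        if mask.sum() < 3:
            continue
        a, b = r1[mask], r2[mask]
        if a.std() == 0.0 or b.std() == 0.0:
            continue
        per_chrom[int(c)] = float(np.corrcoef(a, b)[0, 1])
        n_pairs[int(c)] = int(mask.sum())
    if not per_chrom:
        raise LdError("no chromosome has 3+ usable adjacent pairs")
    return PhasePersistence(
        per_chromosome=per_chrom,
        genome_average=float(np.mean(list(per_chrom.values()))),
        scheme=scheme,
        n_pairs=n_pairs,
    )


def ld_decay(
    panel: GenotypePanel, max_distance_bp: int, n_bins: int
) -> pd.DataFrame:
    """Mean r^2 by distance bin over all within-chromosome marker pairs.

    Bins partition [0, max_distance_bp] evenly; empty bins carry NaN.
    """
    cols, phased = _allele_columns(panel)
    chrom = panel.marker_map["chrom"].to_numpy()
    pos = panel.marker_map["pos"].to_numpy().astype(np.int64)
    edges = np.linspace(0, max_distance_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    sd = cols.std(axis=0)
    centered = (cols - cols.mean(axis=0))
    for c in np.unique(chrom):
        idx = np.flatnonzero((chrom == c) & (sd > 0))
        if idx.size < 2:
            continue
        sub = centered[:, idx]
        n = sub.shape[0]
        corr = (sub.T @ sub) / n / np.outer(sd[idx], sd[idx])
        dist = np.abs(pos[idx][:, None] - pos[idx][None, :])
        iu = np.triu_indices(idx.size, k=1)
        d = dist[iu]
        r2 = corr[iu] ** 2
        ok = d <= max_distance_bp
        which = np.clip(np.digitize(d[ok], edges) - 1, 0, n_bins - 1)
        np.add.at(sums, which, r2[ok])
        np.add.at(counts, which, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


@dataclass
class LdProfile:
    """r^2 of one marker against its k nearest same-chromosome neighbours."""

    marker_index: int
    neighbor_indices: np.ndarray
    r2_values: np.ndarray  # NaN where a member is monomorphic
    r_values: np.ndarray


def neighbor_profiles(panel: GenotypePanel, k: int = 10) -> list[LdProfile]:
    """Per-locus LD profile: the k nearest markers by base-pair position.

    Neighbours never cross a chromosome boundary; on chromosomes with
    fewer than k+1 markers the profile is truncated.  Distance ties break
    toward the lower marker index.
    """
    cols, _ = _allele_columns(panel)
    chrom = panel.marker_map["chrom"].to_numpy()
    pos = panel.marker_map["pos"].to_numpy().astype(np.int64)
    mu = cols.mean(axis=0)
    sd = cols.std(axis=0)
    centered = cols - mu
    n = cols.shape[0]
    profiles: list[LdProfile] = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for local, gi in enumerate(idx):
            others = np.delete(idx, local)
            if others.size == 0:
                profiles.append(
                    LdProfile(int(gi), np.empty(0, int), np.empty(0), np.empty(0))
                )
                continue
            d = np.abs(pos[others] - pos[gi])
            order = np.lexsort((others, d))[: min(k, others.size)]
            nb = others[order]
            if sd[gi] == 0.0:
                r = np.full(nb.size, np.nan)
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = (centered[:, nb].T @ centered[:, gi]) / n / (sd[nb] * sd[gi])
                r[sd[nb] == 0.0] = np.nan
            profiles.append(LdProfile(int(gi), nb, r**2, r))
    profiles.sort(key=lambda p: p.marker_index)
    return profiles


def gld_weights(
    profiles_1: list[LdProfile], profiles_2: list[LdProfile]
) -> np.ndarray:
    """Per-marker weights: cross-breed correlation of neighbour r^2 profiles.

    Weight of marker k is the Pearson correlation between the two breeds'
    r^2 vectors over the neighbour pairs usable in both; markers with at
    most one shared usable pair, or a zero-variance profile, fall back to
    the mean of the defined raw weights.  Raw weights are finally floored
    at zero so a marker with opposite LD phase contributes no cross-breed
    covariance.
    """
    if len(profiles_1) != len(profiles_2):
        raise ValueError("profile lists must cover the same marker set")
    m = len(profiles_1)
    raw = np.full(m, np.nan)
    n_fallback = 0
    for k, (p1, p2) in enumerate(zip(profiles_1, profiles_2)):
        if p1.marker_index != p2.marker_index or not np.array_equal(
            p1.neighbor_indices, p2.neighbor_indices
        ):
            raise ValueError(
                f"neighbour definitions differ at marker {p1.marker_index}"
            )
        ok = ~np.isnan(p1.r2_values) & ~np.isnan(p2.r2_values)
        if ok.sum() <= 1:
            n_fallback += 1
            continue
        a, b = p1.r2_values[ok], p2.r2_values[ok]
        if a.std() == 0.0 or b.std() == 0.0:
            n_fallback += 1
            continue
        raw[k] = np.corrcoef(a, b)[0, 1]
    defined = ~np.isnan(raw)
    if not defined.any():
        raise LdError("no marker has a usable neighbour profile in both breeds")
    global_mean = float(raw[defined].mean())
    raw[~defined] = global_mean
    if n_fallback:
        logger.info("gld_weights: %d markers fell back to the global mean weight",
                    n_fallback)
    return np.maximum(raw, 0.0)
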