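"""In-memory genotype containers shared by every stage of the pipeline.

A :class:`GenotypePanel` is the individuals x markers dosage matrix (counts
of the A1 allele, 0/1/2, NaN for missing) together with breed labels and a
marker map sorted by (chromosome, position).  Phased panels additionally
carry the two haplotypes per individual, which LD computations use for
exact haplotype frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "HaplotypePanel", "make_marker_map"]

MAP_COLUMNS = ("chrom", "pos", "id", "a1", "a2")


def make_marker_map(
    chrom: np.ndarray,
    pos: np.ndarray,
    ids: Iterable[str] | None = None,
    a1: Iterable[str] | None = None,
    a2: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble a marker map DataFrame with the canonical columns."""
    chrom = np.asarray(chrom, dtype=int)
    pos = np.asarray(pos, dtype=int)
    m = chrom.size
    if ids is None:
        ids = [f"snp{c}_{p}" for c, p in zip(chrom, pos)]
    if a1 is None:
        a1 = ["A"] * m
    if a2 is None:
        a2 = ["B"] * m
    df = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": list(ids), "a1": list(a1), "a2": list(a2)}
    )
    return df


def _check_sorted(marker_map: pd.DataFrame) -> None:
    key = marker_map[["chrom", "pos"]].to_numpy()
    if key.shape[0] > 1:
        d = np.diff(key[:, 0]) * 10**12 + np.diff(key[:, 1].astype(np.int64))
        if np.any(d < 0):
            raise ValueError("marker_map must be sorted by (chrom, pos)")


@dataclass
class GenotypePanel:
    """Diploid dosage panel over one or more breeds.

    dosages[i, k] counts copies of allele A1 of marker k carried by
    individual i; NaN marks a missing call.  ``phase``, when present, is an
    int8 array of shape (n, 2, m) whose per-haplotype entries are 0/1
    counts of A1 and is kept consistent with ``dosages``.
    """

    dosages: np.ndarray
    individual_ids: np.ndarray
    breed_labels: np.ndarray
    marker_map: pd.DataFrame
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.breed_labels = np.asarray(self.breed_labels, dtype=object)
        n, m = self.dosages.shape
        if self.individual_ids.shape[0] != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if self.breed_labels.shape[0] != n:
            raise ValueError("breed_labels length does not match dosage rows")
        if len(self.marker_map) != m:
            raise ValueError("marker_map length does not match dosage columns")
        for col in MAP_COLUMNS:
            if col not in self.marker_map.columns:
                raise ValueError(f"marker_map missing column {col!r}")
        _check_sorted(self.marker_map)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (n, 2, m):
                raise ValueError("phase must have shape (n, 2, m)")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breed_labels:
            seen.setdefault(str(b))
        return list(seen)

    @property
    def is_phased(self) -> bool:
        return self.phase is not None

    # -- selection ------------------------------------------------------
    def subset(
        self,
        individuals: np.ndarray | None = None,
        markers: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Row/column subset by integer indices or boolean masks."""
        dos = self.dosages
        ids = self.individual_ids
        labels = self.breed_labels
        phase = self.phase
        mm = self.marker_map
        if individuals is not None:
            individuals = np.asarray(individuals)
            dos = dos[individuals]
            ids = ids[individuals]
            labels = labels[individuals]
            if phase is not None:
                phase = phase[individuals]
        if markers is not None:
            markers = np.asarray(markers)
            dos = dos[:, markers]
            mm = mm.iloc[markers].reset_index(drop=True)
            if phase is not None:
                phase = phase[:, :, markers]
        return GenotypePanel(dos.copy(), ids.copy(), labels.copy(), mm.copy(), None if phase is None else phase.copy())

    def select_breed(self, breed: str) -> "GenotypePanel":
        mask = np.asarray([str(b) == breed for b in self.breed_labels])
        if not mask.any():
            raise KeyError(f"no individuals with breed label {breed!r}")
        return self.subset(individuals=np.flatnonzero(mask))

    def split_by_breed(self) -> dict[str, "GenotypePanel"]:
        return {b: self.select_breed(b) for b in self.breeds}

    def id_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {str(v): i for i, v in enumerate(self.individual_ids)}
        try:
            return np.asarray([lookup[str(v)] for v in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"individual id {exc.args[0]!r} not in panel") from exc

    # -- summaries ------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (A1) allele per marker, NaN-aware."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def haplotypes(self) -> np.ndarray:
        """All haplotypes stacked (2n, m); requires a phased panel."""
        if self.phase is None:
            raise ValueError("panel is not phased")
        n, _, m = self.phase.shape
        return self.phase.reshape(n * 2, m)


@dataclass
class HaplotypePanel:
    """Phased haplotype pool (rows are haplotypes, not individuals)."""

    haplotypes: np.ndarray  # (n_hap, m) int8 of 0/1 (count of A1)
    marker_map: pd.DataFrame
    genetic_pos: np.ndarray = field(default=None)  # morgans within chromosome

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if len(self.marker_map) != self.haplotypes.shape[1]:
            raise ValueError("marker_map length does not match haplotype columns")
        if self.genetic_pos is None:
            raise ValueError("genetic_pos is required")
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=np.float64)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def subset_markers(self, markers: np.ndarray) -> "HaplotypePanel":
        markers = np.asarray(markers)
        return HaplotypePanel(
            self.haplotypes[:, markers].copy(),
            self.marker_map.iloc[markers].reset_index(drop=True).copy(),
            self.genetic_pos[markers].copy(),
        )

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def pair_haplotypes(
    hap: np.ndarray,
    marker_map: pd.DataFrame,
    ids: Iterable[str],
    breed_labels: Iterable[str],
) -> GenotypePanel:
    """Pair consecutive haplotype rows (0,1), (2,3), ... into diploids."""
    hap = np.asarray(hap, dtype=np.int8)
    n2, m = hap.shape
    if n2 % 2:
        raise ValueError("odd number of haplotypes cannot be paired")
    phase = hap.reshape(n2 // 2, 2, m)
    dos = phase.sum(axis=1).astype(np.float64)
    return GenotypePanel(dos, np.asarray(list(ids), dtype=object),
                         np.asarray(list(breed_labels), dtype=object),
                         marker_map.reset_index(drop=True), phase)
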