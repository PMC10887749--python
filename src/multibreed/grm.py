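"""Genomic relationship matrices: within-breed, GUNW and GLD variants.

Within a breed the VanRaden form is used: G = M M' / sum_k 2 p_k (1-p_k)
with M the dosage matrix centered by twice the breed's own allele
frequency.  The multi-breed matrices keep each breed's within block and
join breeds through a between block whose numerator multiplies the two
breeds' (own-frequency-centered) genotypes and whose denominator is the
geometric mean of the two breeds' 2p(1-p) sums; the LD-weighted variant
(GLD) additionally multiplies marker k's contribution to the between
block by a weight w_k in [0, 1] measuring cross-breed LD-phase
consistency, leaving within blocks untouched.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = ["GrmResult", "within_grm", "gunw", "gld", "joint_grm",
           "write_gcta_grm", "read_gcta_grm"]


@dataclass
class GrmResult:
    """Symmetric relationship matrix with breed-block metadata."""

    matrix: np.ndarray
    individual_ids: np.ndarray
    breed_labels: np.ndarray
    variant: str  # within | GUNW | GLD
    blocks: dict[str, slice]
    weights_used: dict[tuple[str, str], np.ndarray] | None = None
    psd_adjustment: dict | None = None
    n_markers: int = 0

    def __post_init__(self) -> None:
        M = self.matrix
        if M.shape[0] != M.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("GRM must be symmetric (1e-10)")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {str(v): i for i, v in enumerate(self.individual_ids)}
        idx = np.asarray([lookup[str(v)] for v in ids])
        return self.matrix[np.ix_(idx, idx)]


def _centered(panel: GenotypePanel) -> tuple[np.ndarray, float]:
    """Own-frequency-centered dosages and the 2p(1-p) scaling sum."""
    if np.isnan(panel.dosages).any():
        raise ValueError("GRM construction requires complete dosages (impute first)")
    p = panel.allele_freq()
    if np.any((p == 0.0) | (p == 1.0)):
        bad = panel.marker_map["id"].to_numpy()[(p == 0.0) | (p == 1.0)]
        raise ValueError(
            f"monomorphic markers present (QC first): {list(bad[:5])}..."
            if bad.size > 5 else f"monomorphic markers present (QC first): {list(bad)}"
        )
    M = panel.dosages - 2.0 * p[None, :]
    scale = float(np.sum(2.0 * p * (1.0 - p)))
    return M, scale


def _require_single_breed(panel: GenotypePanel) -> str:
    breeds = panel.breeds
    if len(breeds) != 1:
        raise ValueError(f"expected a single-breed panel, got breeds {breeds}")
    return breeds[0]


def _check_shared_markers(p1: GenotypePanel, p2: GenotypePanel) -> None:
    id1 = p1.marker_map["id"].to_numpy()
    id2 = p2.marker_map["id"].to_numpy()
    if id1.shape == id2.shape and (id1 == id2).all():
        return
    s1, s2 = set(id1), set(id2)
    diff = sorted(s1.symmetric_difference(s2))
    raise ValueError(
        f"marker sets differ between panels; symmetric difference has "
        f"{len(diff)} markers, e.g. {diff[:5]}"
    )


def within_grm(panel: GenotypePanel) -> GrmResult:
    """VanRaden GRM of a single breed (allele frequencies from this breed)."""
    breed = _require_single_breed(panel)
    M, scale = _centered(panel)
    G = (M @ M.T) / scale
    return GrmResult(
        matrix=G,
        individual_ids=panel.individual_ids.copy(),
        breed_labels=panel.breed_labels.copy(),
        variant="within",
        blocks={breed: slice(0, panel.n_individuals)},
        n_markers=panel.n_markers,
    )


def _between_block(
    p1: GenotypePanel, p2: GenotypePanel, weights: np.ndarray | None
) -> np.ndarray:
    M1, s1 = _centered(p1)
    M2, s2 = _centered(p2)
    if weights is None:
        num = M1 @ M2.T
    else:
        num = (M1 * weights[None, :]) @ M2.T
    return num / np.sqrt(s1 * s2)


def _validate_weights(weights: np.ndarray, m: int) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (m,):
        raise ValueError(f"weights must have length {m}, got shape {w.shape}")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("weights must be finite and nonnegative")
    return w


def gunw(panel_1: GenotypePanel, panel_2: GenotypePanel) -> GrmResult:
    """Two-breed joint GRM with an unweighted between block."""
    return joint_grm([panel_1, panel_2], variant="GUNW")


def gld(
    panel_1: GenotypePanel, panel_2: GenotypePanel, weights: np.ndarray
) -> GrmResult:
    """Two-breed joint GRM with the LD-consistency-weighted between block."""
    key = (_require_single_breed(panel_1), _require_single_breed(panel_2))
    return joint_grm(
        [panel_1, panel_2], variant="GLD", weights_by_pair={key: weights}
    )


def joint_grm(
    panels: list[GenotypePanel],
    variant: str = "GUNW",
    weights_by_pair: dict[tuple[str, str], np.ndarray] | None = None,
    psd_tol: float = 1e-8,
) -> GrmResult:
    """Assemble the block GRM over two or more breeds.

    Within blocks are each breed's own VanRaden GRM; between blocks follow
    the geometric-mean-denominator cross product, weighted per marker when
    variant="GLD".  The assembled matrix is checked for positive
    semidefiniteness and repaired by eigenvalue bending when the minimum
    eigenvalue falls below -psd_tol (negative eigenvalues raised to
    psd_tol; the repair is recorded in ``psd_adjustment``).
    """
    if variant not in ("GUNW", "GLD"):
        raise ValueError(f"unknown variant {variant!r}")
    if len(panels) < 2:
        raise ValueError("joint_grm needs at least two panels")
    breeds = [_require_single_breed(p) for p in panels]
    if len(set(breeds)) != len(breeds):
        raise ValueError(f"duplicate breed labels in panels: {breeds}")
    for other in panels[1:]:
        _check_shared_markers(panels[0], other)
    m = panels[0].n_markers

    sizes = [p.n_individuals for p in panels]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    G = np.zeros((n, n))
    blocks = {
        b: slice(int(offsets[i]), int(offsets[i + 1])) for i, b in enumerate(breeds)
    }
    weights_used: dict[tuple[str, str], np.ndarray] = {}
    for i, pi in enumerate(panels):
        G[blocks[breeds[i]], blocks[breeds[i]]] = within_grm(pi).matrix
        for j in range(i + 1, len(panels)):
            pj = panels[j]
            w = None
            if variant == "GLD":
                if weights_by_pair is None:
                    raise ValueError("variant='GLD' requires weights_by_pair")
                key = (breeds[i], breeds[j])
                if key in weights_by_pair:
                    w = weights_by_pair[key]
                elif key[::-1] in weights_by_pair:
                    w = weights_by_pair[key[::-1]]
                else:
                    raise ValueError(f"missing weight vector for breed pair {key}")
                w = _validate_weights(w, m)
                weights_used[key] = w
            B = _between_block(pi, pj, w)
            G[blocks[breeds[i]], blocks[breeds[j]]] = B
            G[blocks[breeds[j]], blocks[breeds[i]]] = B.T

    psd_adjustment = None
    min_eig = float(np.linalg.eigvalsh(G).min())
    if min_eig < -psd_tol:
        vals, vecs = np.linalg.eigh(G)
        bent = np.maximum(vals, psd_tol)
        G = (vecs * bent[None, :]) @ vecs.T
        G = 0.5 * (G + G.T)
        psd_adjustment = {
            "method": "eigenvalue_bending",
            "min_eigenvalue_before": min_eig,
            "n_bent": int((vals < psd_tol).sum()),
        }

    ids = np.concatenate([p.individual_ids for p in panels])
    labels = np.concatenate([p.breed_labels for p in panels])
    return GrmResult(
        matrix=G,
        individual_ids=ids,
        breed_labels=labels,
        variant=variant,
        blocks=blocks,
        weights_used=weights_used or None,
        psd_adjustment=psd_adjustment,
        n_markers=m,
    )


# ---------------------------------------------------------------------------
# GCTA binary GRM convention
# ---------------------------------------------------------------------------

def write_gcta_grm(grm: GrmResult, prefix: str | Path) -> None:
    """Write <prefix>.grm.bin / .grm.N.bin / .grm.id (GCTA convention:
    float32 lower triangle row by row, diagonal included)."""
    prefix = Path(prefix)
    n = grm.n
    iu = np.tril_indices(n)
    vals = grm.matrix[iu].astype("<f4")
    vals.tofile(str(prefix) + ".grm.bin")
    np.full(vals.size, grm.n_markers, dtype="<f4").tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for fid, iid in zip(grm.breed_labels, grm.individual_ids):
            fh.write(f"{fid}\t{iid}\n")


def read_gcta_grm(prefix: str | Path) -> GrmResult:
    """Read a GCTA binary GRM back into a :class:`GrmResult`."""
    prefix = Path(prefix)
    ids = pd.read_csv(str(prefix) + ".grm.id", sep="\t", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    vals = np.fromfile(str(prefix) + ".grm.bin", dtype="<f4").astype(np.float64)
    if vals.size != n * (n + 1) // 2:
        raise ValueError(
            f"{prefix}.grm.bin holds {vals.size} values, expected {n*(n+1)//2}"
        )
    G = np.zeros((n, n))
    iu = np.tril_indices(n)
    G[iu] = vals
    G = G + G.T - np.diag(np.diag(G))
    nmark = np.fromfile(str(prefix) + ".grm.N.bin", dtype="<f4")
    labels = ids["fid"].to_numpy(dtype=object)
    blocks: dict[str, slice] = {}
    start = 0
    for b in pd.unique(ids["fid"]):
        cnt = int((ids["fid"] == b).sum())
        blocks[str(b)] = slice(start, start + cnt)
        start += cnt
    return GrmResult(
        matrix=G,
        individual_ids=ids["iid"].to_numpy(dtype=object),
        breed_labels=labels,
        variant="within" if len(blocks) == 1 else "GUNW",
        blocks=blocks,
        n_markers=int(nmark[0]) if nmark.size else 0,
    )
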