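"""PLINK/VCF genotype input-output and marker quality control.

The binary PLINK layout (bed v1.00, SNP-major) is decoded/encoded at byte
level: two bits per genotype, four genotypes per byte, low bits first,
with 00 = homozygous A1 (dosage 2), 10 = heterozygous, 11 = homozygous A2
(dosage 0) and 01 = missing.  QC applies the standard marker filters in a
fixed order (autosome, call rate, minor allele frequency, Hardy-Weinberg
exact test), per breed with intersection of survivors, so that multi-breed
relationship matrices are built on one shared marker set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel, make_marker_map

__all__ = [
    "PlinkFormatError",
    "QcReport",
    "read_plink",
    "write_plink",
    "read_vcf",
    "qc_filter",
    "hwe_exact_test",
    "impute_missing",
]

logger = logging.getLogger(__name__)

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit code -> dosage of A1; 0b01 is the missing sentinel
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
AUTOSOMES = range(1, 30)


class PlinkFormatError(ValueError):
    """Raised for malformed or inconsistent bed/bim/fam filesets."""


def _decode_table() -> np.ndarray:
    """(256, 4) lookup: byte -> dosages of its four packed genotypes."""
    table = np.empty((256, 4))
    for byte in range(256):
        for slot in range(4):
            table[byte, slot] = _CODE_TO_DOSAGE[(byte >> (2 * slot)) & 0b11]
    return table


_DECODE = _decode_table()


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a bed/bim/fam triple into a :class:`GenotypePanel`.

    Dosages count the A1 allele of the bim file (PLINK's minor-allele
    convention); missing genotypes are preserved as NaN.  The fam FID
    column is used as the breed label.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "id": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3]!r} (want SNP-major v1.00)"
        )
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: payload is {len(raw) - 3} bytes, expected "
            f"{expected - 3} for {n} individuals x {m} markers"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    dosages = _DECODE[payload].reshape(m, bytes_per_marker * 4)[:, :n].T.copy()
    mm = make_marker_map(bim["chrom"], bim["pos"], bim["id"], bim["a1"], bim["a2"])
    return GenotypePanel(
        dosages,
        fam["iid"].to_numpy(dtype=object),
        fam["fid"].to_numpy(dtype=object),
        mm,
    )


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as bed/bim/fam (breed label stored in the fam FID)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mm = panel.marker_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in mm.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid, fid in zip(panel.individual_ids, panel.breed_labels):
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")
    n, m = panel.n_individuals, panel.n_markers
    dos = panel.dosages
    codes = np.where(np.isnan(dos), 1, np.where(dos == 2, 0, np.where(dos == 1, 2, 3)))
    codes = codes.astype(np.uint8).T  # (m, n)
    bytes_per_marker = (n + 3) // 4
    padded = np.ones((m, bytes_per_marker * 4), dtype=np.uint8) * 0  # pad with code 00
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | Path, breed_map: dict[str, str] | None = None) -> GenotypePanel:
    """Read biallelic SNPs from a VCF into a panel (dosages count ALT).

    ``breed_map`` maps sample id -> breed label; unlisted samples get
    breed "unknown".
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, a1s, a2s, rows = [], [], [], [], [], []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        try:
            chrom = int(str(var.CHROM).removeprefix("chr"))
        except ValueError:
            continue
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(np.nansum(gt, axis=1) + np.where(np.isnan(gt).all(axis=1), np.nan, 0.0))
        chroms.append(chrom)
        poss.append(var.POS)
        ids.append(var.ID or f"{chrom}:{var.POS}")
        a1s.append(var.ALT[0])
        a2s.append(var.REF)
    if not rows:
        raise ValueError(f"{path}: no biallelic autosomal SNPs found")
    dosages = np.asarray(rows).T
    mm = make_marker_map(np.asarray(chroms), np.asarray(poss), ids, a1s, a2s)
    order = np.lexsort((mm["pos"], mm["chrom"]))
    breeds = [
        (breed_map or {}).get(s, "unknown") for s in samples
    ]
    return GenotypePanel(
        dosages[:, order],
        np.asarray(samples, dtype=object),
        np.asarray(breeds, dtype=object),
        mm.iloc[order].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (the standard exact-test construction for genotype data).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa  # rarer allele bookkeeping below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    # possible heterozygote counts share the parity of the rare allele count
    het_min = rare % 2
    hets = np.arange(het_min, rare + 1, 2)
    # unnormalized probabilities by recurrence from the smallest het count
    logp = np.zeros(hets.size)
    for i in range(1, hets.size):
        h = hets[i]
        # P(h) / P(h-2) = ( (rare-h+2)(2n-rare-h+2) ) / ( h (h-1) )
        num = (rare - h + 2) * (2 * n - rare - h + 2)
        logp[i] = logp[i - 1] + np.log(num) - np.log(h * (h - 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    pval = float(p[p <= p_obs[0] * (1 + 1e-12)].sum())
    return min(1.0, pval)


@dataclass
class QcReport:
    """Accounting of marker removals, one marker counted at its first
    failing filter in the fixed order autosome -> call rate -> MAF -> HWE."""

    n_markers_in: int
    n_removed_nonautosomal: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_markers_out: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_removed_nonautosomal + self.n_removed_callrate
            + self.n_removed_maf + self.n_removed_hwe + self.n_markers_out
        )
        if total != self.n_markers_in:
            raise ValueError("QC accounting does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_markers_in),
            ("removed_nonautosomal", self.n_removed_nonautosomal),
            ("removed_callrate", self.n_removed_callrate),
            ("removed_maf", self.n_removed_maf),
            ("removed_hwe", self.n_removed_hwe),
            ("output", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["filter", "n_markers"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(col)
    c = col[ok]
    return int((c == 2).sum()), int((c == 1).sum()), int((c == 0).sum())


def qc_filter(
    panel: GenotypePanel,
    cr_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    autosomes: range = AUTOSOMES,
) -> tuple[GenotypePanel, QcReport]:
    """Marker QC: autosome, call-rate, MAF and HWE filters.

    With several breeds in the panel, call rate, MAF and HWE are evaluated
    per breed and a marker survives only if it passes in every breed (the
    per-breed HWE avoids Wahlund-effect false failures on pooled data and
    the intersection keeps one marker set for all relationship-matrix
    blocks).
    """
    for name, val in (("cr_min", cr_min), ("maf_min", maf_min), ("hwe_alpha", hwe_alpha)):
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    if panel.n_markers == 0 or panel.n_individuals == 0:
        raise ValueError("cannot QC an empty panel")

    chrom = panel.marker_map["chrom"].to_numpy()
    ok_autosome = np.isin(chrom, np.asarray(list(autosomes)))

    sub = [panel.select_breed(b) for b in panel.breeds]
    m = panel.n_markers
    ok_cr = np.ones(m, dtype=bool)
    ok_maf = np.ones(m, dtype=bool)
    ok_hwe = np.ones(m, dtype=bool)
    for bp in sub:
        ok_cr &= bp.call_rate() >= cr_min
        p = bp.allele_freq()
        with np.errstate(invalid="ignore"):
            maf = np.minimum(p, 1.0 - p)
        ok_maf &= ~np.isnan(maf) & (maf >= maf_min)
        for k in range(m):
            if not ok_hwe[k]:
                continue
            nAA, nAa, naa = _genotype_counts(bp.dosages[:, k])
            if nAA + nAa + naa == 0:
                ok_hwe[k] = False
                continue
            if hwe_exact_test(nAA, nAa, naa) < hwe_alpha:
                ok_hwe[k] = False

    fail_auto = ~ok_autosome
    fail_cr = ok_autosome & ~ok_cr
    fail_maf = ok_autosome & ok_cr & ~ok_maf
    fail_hwe = ok_autosome & ok_cr & ok_maf & ~ok_hwe
    keep = ok_autosome & ok_cr & ok_maf & ok_hwe

    ids = panel.marker_map["id"].to_numpy()
    report = QcReport(
        n_markers_in=m,
        n_removed_nonautosomal=int(fail_auto.sum()),
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_markers_out=int(keep.sum()),
        removed={
            "nonautosomal": list(ids[fail_auto]),
            "callrate": list(ids[fail_cr]),
            "maf": list(ids[fail_maf]),
            "hwe": list(ids[fail_hwe]),
        },
    )
    return panel.subset(markers=np.flatnonzero(keep)), report


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the breed mean dosage 2p of the marker."""
    if not np.isnan(panel.dosages).any():
        return panel
    dos = panel.dosages.copy()
    for b in panel.breeds:
        rows = np.flatnonzero(np.asarray([str(x) == b for x in panel.breed_labels]))
        block = dos[rows]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(block, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        nan_r, nan_c = np.nonzero(np.isnan(block))
        block[nan_r, nan_c] = mean[nan_c]
        dos[rows] = block
    logger.info("imputed %d missing genotypes with breed-mean dosage",
                int(np.isnan(panel.dosages).sum()))
    return GenotypePanel(dos, panel.individual_ids, panel.breed_labels,
                         panel.marker_map, panel.phase)
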