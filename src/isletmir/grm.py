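"""Genetic relationship matrices, LD, and cis/trans variant partitioning.

The GRM is the standard standardized-dosage kinship ``K = Z Z' / M`` with
``z = (g - 2f) / sqrt(2 f (1 - f))`` and in-sample allele frequencies.
The cis window (default +/- 250 kb, alternate 20 Mb) is anchored on the
full feature interval for miRNAs and on the strand-aware TSS for mRNAs;
variants on the same chromosome with ``window_start <= pos < window_end``
are cis, everything else trans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureRecord, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "cis_window",
    "compute_grm",
    "partition_cis_trans",
    "ld_r2",
    "psd_repair",
]

DEFAULT_WINDOW = 250_000
WIDE_WINDOW = 20_000_000


@dataclass
class KinshipMatrix:
    """Symmetric n x n genetic relatedness matrix over ``n_variants`` SNPs."""

    values: np.ndarray
    sample_ids: list[str]
    n_variants: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_variants: int) -> "KinshipMatrix":
        return cls(frame.to_numpy(dtype=float), [str(s) for s in frame.index], n_variants)


def standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    """Center and scale dosage columns by sqrt(2 f (1-f)), f in-sample."""
    f = dosages.mean(axis=0) / 2.0
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("monomorphic variant: in-sample frequency must be in (0, 1)")
    return (dosages - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def compute_grm(
    genotypes: GenotypeMatrix, variant_subset: list[str] | None = None
) -> KinshipMatrix:
    """GRM over exactly ``variant_subset`` (all variants when None)."""
    gm = genotypes if variant_subset is None else genotypes.subset_variants(variant_subset)
    if gm.n_variants == 0:
        raise ValueError("empty variant subset: cannot compute a GRM")
    z = standardize_dosages(gm.dosages)
    k = z @ z.T / gm.n_variants
    return KinshipMatrix(k, list(gm.sample_ids), gm.n_variants)


def cis_window(
    feature: FeatureRecord, window_size: int = DEFAULT_WINDOW
) -> tuple[str, int, int]:
    """Half-open cis window around a feature, clipped at 0.

    miRNAs anchor on the full mature-transcript interval; mRNAs on the
    TSS point (interval start for '+' strand, end for '-').
    """
    if feature.biotype == "mRNA":
        tss = feature.start if feature.strand == "+" else feature.end
        anchor_start, anchor_end = tss, tss + 1
    else:
        anchor_start, anchor_end = feature.start, feature.end
    if not np.isfinite(window_size):
        return feature.chrom, 0, np.inf  # type: ignore[return-value]
    return (
        feature.chrom,
        max(0, anchor_start - int(window_size)),
        anchor_end + int(window_size),
    )


def partition_cis_trans(
    variants: pd.DataFrame,
    feature: FeatureRecord,
    window_size: int = DEFAULT_WINDOW,
) -> tuple[list[str], list[str]]:
    """Split variant ids into (cis, trans) relative to a feature's window.

    The partition is exhaustive and disjoint: cis = same chromosome and
    ``window_start <= pos < window_end``; trans = complement.
    """
    chrom, wstart, wend = cis_window(feature, window_size)
    pos = variants["pos"].to_numpy()
    is_cis = (
        (variants["chrom"].to_numpy() == chrom) & (pos >= wstart) & (pos < wend)
    )
    ids = variants["variant_id"].to_numpy()
    return list(ids[is_cis]), list(ids[~is_cis])


def ld_r2(genotypes: GenotypeMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    ga = genotypes.dosage_vector(variant_a)
    gb = genotypes.dosage_vector(variant_b)
    if np.std(ga) == 0 or np.std(gb) == 0:
        raise ValueError("monomorphic variant: LD undefined")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def psd_repair(k: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Return K + eps*I with eps = max(0, -lambda_min) + jitter."""
    lam_min = np.linalg.eigvalsh(k)[0]
    eps = max(0.0, -lam_min) + jitter
    return k + eps * np.eye(k.shape[0])
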