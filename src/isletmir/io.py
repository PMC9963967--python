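"""Readers/writers for the on-disk formats shared by all pipeline stages.

Conventions
-----------
* Feature intervals are 0-based half-open internally (BED convention);
  GFF3 1-based closed coordinates are converted on read.
* Variant positions are kept 1-based (VCF convention), as carried in the
  genotype input.  A variant overlaps a half-open interval ``[s, e)`` iff
  ``s <= pos < e``.
* Counts are features x samples, non-negative integers.
* All tabular outputs are TSV with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FeatureRecord",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_dosage_tsv",
    "read_intervals",
    "write_intervals",
    "read_counts",
    "write_counts",
    "read_summary_stats",
    "write_summary_stats",
]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]

SUMMARY_STAT_COLUMNS = ["variant_id", "chrom", "pos", "beta", "se", "p", "n", "maf"]


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    ``dosages`` is an (n_samples, n_variants) float array in [0, 2];
    ``variants`` is a DataFrame with columns ``variant_id, chrom, pos,
    ref, alt, maf`` (pos 1-based, maf folded to the minor allele).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate variant_id(s): {list(dups)}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not present")
        return self.dosages[:, idx[0]]

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        wanted = set(variant_ids)
        mask = self.variants["variant_id"].isin(wanted).to_numpy()
        return GenotypeMatrix(
            self.dosages[:, mask],
            list(self.sample_ids),
            self.variants.loc[mask].reset_index(drop=True),
        )


@dataclass
class FeatureRecord:
    """Genomic feature (miRNA or mRNA) on 0-based half-open coordinates."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "miRNA"
    confidence: str = "canonical"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.feature_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def high_confidence(self) -> bool:
        return self.confidence in {"canonical", "isomiR_shift_le2"}


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _finalize_genotypes(
    dosages: np.ndarray,
    sample_ids: list[str],
    variants: pd.DataFrame,
    maf_min: float,
    max_missing: float,
) -> GenotypeMatrix:
    """Impute missingness, fold MAF, apply filters. dosages: samples x variants."""
    keep_cols = []
    mafs = []
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        miss = np.isnan(col)
        if miss.all():
            warnings.warn(
                f"variant {variants['variant_id'].iloc[j]!r} has no observed "
                "genotypes; dropped"
            )
            continue
        if miss.mean() > max_missing:
            warnings.warn(
                f"variant {variants['variant_id'].iloc[j]!r} exceeds "
                f"missingness cap ({miss.mean():.2f} > {max_missing}); dropped"
            )
            continue
        if miss.any():
            col = col.copy()
            col[miss] = col[~miss].mean()
            dosages[:, j] = col
        f = col.mean() / 2.0
        maf = min(f, 1.0 - f)
        if maf < maf_min:
            continue
        keep_cols.append(j)
        mafs.append(maf)
    variants = variants.iloc[keep_cols].copy()
    variants["maf"] = mafs
    return GenotypeMatrix(dosages[:, keep_cols], sample_ids, variants)


def _read_genotypes_vcf(path: Path, maf_min: float, max_missing: float) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = []
    meta = []
    has_ds = "DS" in {f.strip() for line in vcf.raw_header.splitlines()
                      for f in ([line.split("ID=")[1].split(",")[0]]
                                if line.startswith("##FORMAT=") and "ID=" in line else [])}
    for rec in vcf:
        if has_ds:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        else:
            gt = rec.gt_types  # 0=hom_ref,1=het,2=hom_alt? cyvcf2: 3=hom_alt,2=unknown
            ds = np.full(len(sample_ids), np.nan)
            ds[gt == 0] = 0.0
            ds[gt == 1] = 1.0
            ds[gt == 3] = 2.0
        rows.append(ds)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        alt = rec.ALT[0] if rec.ALT else "."
        meta.append((vid, rec.CHROM, rec.POS, rec.REF, alt, np.nan))
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    if variants["variant_id"].duplicated().any():
        dups = variants.loc[variants["variant_id"].duplicated(), "variant_id"].unique()
        raise ValueError(f"duplicate variant_id(s) in {path}: {list(dups[:5])}")
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return _finalize_genotypes(dosages, sample_ids, variants, maf_min, max_missing)


def _read_genotypes_tsv(path: Path, maf_min: float, max_missing: float) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if table.columns[0] != "variant_id":
        raise ValueError("dosage TSV must have 'variant_id' as first column")
    if table["variant_id"].duplicated().any():
        dups = table.loc[table["variant_id"].duplicated(), "variant_id"].unique()
        raise ValueError(f"duplicate variant_id(s) in {path}: {list(dups[:5])}")
    sample_ids = [str(c) for c in table.columns[1:]]
    dosages = table.iloc[:, 1:].to_numpy(dtype=float).T
    if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    sidecar = path.with_suffix(".variants.tsv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t", dtype={"variant_id": str, "chrom": str})
        meta = (
            table[["variant_id"]]
            .merge(meta, on="variant_id", how="left")
            .reindex(columns=VARIANT_COLUMNS)
        )
    else:
        meta = pd.DataFrame({"variant_id": table["variant_id"]})
        for col in VARIANT_COLUMNS[1:]:
            meta[col] = np.nan
    return _finalize_genotypes(dosages, sample_ids, meta, maf_min, max_missing)


def read_genotypes(
    path: str | Path, maf_min: float = 0.0, max_missing: float = 0.1
) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT or DS) or a dosage TSV.

    Variants with folded MAF < ``maf_min`` are dropped; missing dosages are
    mean-imputed per variant, and variants with a missing fraction above
    ``max_missing`` (or no observed calls) are dropped with a warning.
    Sample ids are returned in file order.  MAF is always recomputed
    in-sample on the imputed dosages and folded to the minor allele.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix in {".vcf"}:
        return _read_genotypes_vcf(path, maf_min, max_missing)
    return _read_genotypes_tsv(path, maf_min, max_missing)


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2.  Integral dosages become GT, otherwise DS."""
    path = Path(path)
    integral = np.all(np.isclose(gm.dosages, np.round(gm.dosages)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        if integral:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in gm.variants.iterrows():
            ref = row["ref"] if isinstance(row["ref"], str) else "A"
            alt = row["alt"] if isinstance(row["alt"], str) else "G"
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["variant_id"]),
                ref,
                alt,
                ".",
                "PASS",
                ".",
                "GT" if integral else "DS",
            ]
            col = gm.dosages[:, j]
            if integral:
                fields += [gt_codes[int(round(d))] for d in col]
            else:
                fields += [f"{d:.4f}" for d in col]
            fh.write("\t".join(fields) + "\n")


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write dosage TSV (variants x samples) plus the variant-metadata sidecar."""
    path = Path(path)
    table = pd.DataFrame(gm.dosages.T, columns=gm.sample_ids)
    table.insert(0, "variant_id", gm.variants["variant_id"].to_numpy())
    table.to_csv(path, sep="\t", index=False)
    gm.variants.to_csv(path.with_suffix(".variants.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

_GFF_SUFFIXES = {".gff", ".gff3"}


def read_intervals(path: str | Path, dialect: str | None = None) -> list[FeatureRecord]:
    """Read BED6(+2) or GFF3 feature intervals.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    BED may carry two optional extra columns (biotype, confidence).
    """
    path = Path(path)
    if dialect is None:
        dialect = "gff3" if path.suffix.lower() in _GFF_SUFFIXES else "bed"
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "bed":
                    chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                    strand = parts[5] if len(parts) > 5 else "+"
                    biotype = parts[6] if len(parts) > 6 else "miRNA"
                    confidence = parts[7] if len(parts) > 7 else "canonical"
                else:  # gff3: 1-based closed -> 0-based half-open
                    chrom, ftype = parts[0], parts[2]
                    start, end = int(parts[3]) - 1, int(parts[4])
                    strand = parts[6] if parts[6] in {"+", "-"} else "+"
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    name = attrs.get("ID") or attrs.get("Name") or f"{chrom}:{start}-{end}"
                    biotype = attrs.get("biotype", ftype if ftype in {"miRNA", "mRNA"} else "miRNA")
                    confidence = attrs.get("confidence", "canonical")
                if start >= end:
                    raise ValueError("empty interval")
                records.append(
                    FeatureRecord(name, chrom, start, end, strand, biotype, confidence)
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid {dialect} line: {exc}") from exc
    return records


def write_intervals(records: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write features as BED6+2 (biotype, confidence extra columns)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.feature_id}\t0\t{r.strand}"
                f"\t{r.biotype}\t{r.confidence}\n"
            )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a features x samples count TSV into an integer DataFrame."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicated feature id(s): {list(dups[:5])}")
    try:
        values = table.to_numpy().astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    bad = ~np.isfinite(values) | (values < 0) | (values != np.round(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid count at feature {table.index[i]!r}, "
            f"sample {table.columns[j]!r}: {table.iat[i, j]!r}"
        )
    return pd.DataFrame(values.astype(np.int64), index=table.index, columns=table.columns)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read GWAS/eQTL summary statistics TSV.

    Required columns: variant_id, chrom, pos, beta, se, p, n, maf.
    Optional: trait_type ('quantitative'/'case_control'), case_fraction.
    Validation checks se > 0, p in (0, 1], and warns when |beta/se| is
    inconsistent with p under a normal approximation (>10% relative).
    """
    stats = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if validate:
        if (stats["se"] <= 0).any():
            raise ValueError(f"{path}: se must be > 0")
        if ((stats["p"] <= 0) | (stats["p"] > 1)).any():
            raise ValueError(f"{path}: p must lie in (0, 1]")
        from scipy.stats import norm

        z = (stats["beta"] / stats["se"]).abs().to_numpy()
        z_from_p = norm.isf(np.clip(stats["p"].to_numpy(), 1e-300, 1.0) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(z - z_from_p) / np.maximum(z_from_p, 1e-12)
        inconsistent = (z_from_p > 0.5) & (rel > 0.10)
        if inconsistent.any():
            warnings.warn(
                f"{path}: {int(inconsistent.sum())} record(s) with |beta/se| "
                "inconsistent with p (>10% relative) under the normal approximation"
            )
    return stats


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)
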