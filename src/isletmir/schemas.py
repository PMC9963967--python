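"""Column contracts for every TSV the pipeline writes, plus a validator
used by the end-to-end tests and the CLI."""

from __future__ import annotations

import pandas as pd

SCHEMAS: dict[str, list[str]] = {
    "kinship": [],  # square matrix: sample ids as header and index
    "heritability": ["feature_id", "sigma2_g", "sigma2_e", "hg2", "loglik", "converged", "heritable"],
    "decomposition": [
        "feature_id", "sigma2_cis", "sigma2_trans", "sigma2_e",
        "hg2", "h_cis", "h_trans", "loglik", "converged", "window_size",
    ],
    "assoc": ["variant_id", "feature_id", "beta", "se", "p", "q", "n", "scan_type"],
    "sumstats": ["variant_id", "chrom", "pos", "beta", "se", "p", "n", "maf"],
    "coloc": ["region_id", "pp0", "pp1", "pp2", "pp3", "pp4", "n_snps"],
    "credset": ["signal_id", "variant_id", "posterior", "cumulative", "rank"],
    "overlap": [
        "variant_id", "signal_id", "chrom", "pos", "interval_kind",
        "site_start", "site_end", "mirna_id", "gene_id",
        "mirna_expressed", "mrna_expressed",
    ],
    "de": ["feature_id", "phenotype", "log2fc", "se", "p", "stratum"],
    "meta": ["feature_id", "phenotype", "log2fc", "se", "p", "q", "n_strata"],
    "fractions": ["sample_id", "alpha", "beta", "residual_norm"],
    "sensitivity": ["beta_without", "beta_with"],
}


def validate_table(kind: str, frame: pd.DataFrame) -> None:
    """Raise ValueError when ``frame`` misses the contract columns of ``kind``."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown output kind {kind!r}")
    if kind == "kinship":
        if frame.shape[0] != frame.shape[1] or list(frame.index.astype(str)) != [
            str(c) for c in frame.columns
        ]:
            raise ValueError("kinship TSV must be square with matching sample ids")
        return
    missing = [c for c in SCHEMAS[kind] if c not in frame.columns]
    if missing:
        raise ValueError(f"{kind} output missing column(s): {missing}")


def validate_file(kind: str, path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0 if kind == "kinship" else None)
    validate_table(kind, frame)
    return frame
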