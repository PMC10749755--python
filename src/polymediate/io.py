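"""Readers for phenotype tables, dosage matrices, weight tables and VCFs."""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grs import GRSError, validate_weight_table

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeError",
    "read_phenotypes",
    "read_dosage_csv",
    "read_weight_table",
    "read_dosage_vcf",
]


class PhenotypeError(ValueError):
    """Raised for malformed phenotype files."""


def read_phenotypes(
    path: str | Path,
    required_columns: Sequence[str] = (),
    numeric_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a one-row-per-individual phenotype CSV.

    ``required_columns`` must all be present (hard error naming the
    missing ones). ``numeric_columns`` are validated: a non-numeric value
    raises with the offending row number. Row count and per-column
    missingness are logged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise PhenotypeError(f"{path.name}: missing required columns {missing}")
    for col in numeric_columns:
        if col not in df.columns:
            raise PhenotypeError(f"{path.name}: missing numeric column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise PhenotypeError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = coerced
    logger.info(
        "read %d rows from %s; missingness per column: %s",
        len(df),
        path.name,
        {c: int(df[c].isna().sum()) for c in df.columns if df[c].isna().any()} or "none",
    )
    return df


def read_dosage_csv(path: str | Path, index_col: str = "individual_id") -> pd.DataFrame:
    """Read an individuals x variants dosage matrix (header = variant ids)."""
    df = pd.read_csv(path, index_col=index_col)
    mat = df.to_numpy(dtype=float)
    finite = mat[np.isfinite(mat)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise GRSError(f"{Path(path).name}: dosages outside [0, 2]")
    return df


def read_weight_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a 4-column tab-separated variant-weight table."""
    df = pd.read_csv(path, sep="\t")
    return validate_weight_table(df)


def read_dosage_vcf(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read per-genotype dosages from a VCF.

    Uses the ``DS`` FORMAT field when present, otherwise counts ALT
    alleles in ``GT``. Returns the individuals x variants dosage matrix and
    a map variant id -> counted allele (the ALT allele), suitable for
    allele alignment in :func:`polymediate.grs.compute_grs`.
    """
    import pysam

    path = str(path)
    dosages: dict[str, list[float]] = {}
    counted: dict[str, str] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            if len(rec.alts or ()) != 1:
                raise GRSError(f"variant {vid}: exactly one ALT allele required")
            counted[vid] = rec.alts[0]
            row = []
            for s in samples:
                fmt = rec.samples[s]
                if "DS" in fmt and fmt["DS"] is not None:
                    row.append(float(fmt["DS"]))
                elif fmt.get("GT") is not None:
                    alleles = [g for g in fmt["GT"] if g is not None]
                    row.append(float(sum(1 for g in alleles if g > 0)) if alleles else np.nan)
                else:
                    row.append(np.nan)
            dosages[vid] = row
    df = pd.DataFrame(dosages, index=pd.Index(samples, name="individual_id"))
    return df, counted
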