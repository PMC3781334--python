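"""Reading, writing and validation of expression matrices and sample tables.

The on-disk dialect is tab-separated UTF-8; lines starting with ``#`` are
comments.  Expression matrices are genes/probesets x samples of non-negative
linear-scale values, first column the gene identifier, header row the sample
identifiers.  Sample tables describe a factorial design with columns
``sample_id``, ``genotype`` (WT/KO), ``treatment`` (vehicle/TM), ``time``
(hours) and ``replicate``.

Also hosts housekeeping-normalized relative expression for qPCR-style data:
each sample is divided by the geometric mean of its housekeeping genes, then
expressed on a log2 scale relative to a reference condition.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, StressclustError

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
TREATMENTS = ("vehicle", "TM")

SAMPLE_COLUMNS = ("sample_id", "genotype", "treatment", "time", "replicate")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       na_values=["", "."], keep_default_na=False)


def read_samples(path) -> pd.DataFrame:
    """Read and validate a sample table TSV."""
    df = _read_tsv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample table missing columns {missing}")
    df = df[list(SAMPLE_COLUMNS)].copy()
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    if df[["time", "replicate"]].isna().any().any():
        bad = df.index[df[["time", "replicate"]].isna().any(axis=1)][0]
        raise ParseError(f"{path}: non-numeric time/replicate at data row {bad + 1}")
    validate_samples(df, source=str(path))
    return df


def validate_samples(samples: pd.DataFrame, source: str = "sample table") -> None:
    bad_geno = set(samples["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise ParseError(f"{source}: unknown genotype level(s) {sorted(bad_geno)}")
    bad_trt = set(samples["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise ParseError(f"{source}: unknown treatment level(s) {sorted(bad_trt)}")
    if (samples["time"] <= 0).any():
        raise ParseError(f"{source}: non-positive time value")
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{source}: duplicate sample_id {dup!r}")
    key = samples[["genotype", "treatment", "time", "replicate"]]
    if key.duplicated().any():
        row = key.index[key.duplicated()][0]
        raise ParseError(
            f"{source}: duplicate (genotype, treatment, time, replicate) at data row {row + 1}")


def read_expression(matrix_path, samples_path):
    """Read a (matrix TSV, sample TSV) pair and cross-validate them.

    Returns ``(matrix, samples)`` where ``matrix`` is a genes x samples
    DataFrame of floats and ``samples`` the validated design table.
    """
    samples = read_samples(samples_path)
    raw = _read_tsv(matrix_path)
    if raw.shape[1] < 2:
        raise ParseError(f"{matrix_path}: expected gene column plus >=1 sample column")
    gene_col = raw.columns[0]
    if raw[gene_col].duplicated().any():
        dup = raw[gene_col][raw[gene_col].duplicated()].iloc[0]
        raise ParseError(f"{matrix_path}: duplicate gene id {dup!r}")
    matrix = raw.set_index(gene_col)
    for j, col in enumerate(matrix.columns):
        vals = pd.to_numeric(matrix[col], errors="coerce")
        if vals.isna().any():
            i = int(np.where(vals.isna())[0][0])
            raise ParseError(
                f"{matrix_path}: non-numeric or missing value at gene row {i + 1}, "
                f"column {j + 2} (sample {col!r})")
        matrix[col] = vals
    if (matrix.values < 0).any():
        raise ParseError(f"{matrix_path}: negative expression value")
    unknown = [s for s in matrix.columns if s not in set(samples["sample_id"])]
    if unknown:
        raise ParseError(
            f"{matrix_path}: sample(s) absent from the sample table: {unknown}")
    matrix.index.name = "gene"
    logger.info("read expression matrix: %d genes x %d samples", *matrix.shape)
    return matrix, samples


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")
    logger.info("wrote %d expression rows to %s", len(out), path)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d sample rows to %s", len(samples), path)


def read_probeset_map(path) -> pd.Series:
    """Read a probeset -> gene symbol map (two-column TSV)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (probeset, gene)")
    df = df.iloc[:, :2]
    df.columns = ["probeset", "gene"]
    if df["probeset"].duplicated().any():
        dup = df["probeset"][df["probeset"].duplicated()].iloc[0]
        raise ParseError(f"{path}: probeset {dup!r} maps to more than one gene")
    return df.set_index("probeset")["gene"]


def select_samples(samples: pd.DataFrame, genotype=None, treatment=None,
                   time=None) -> list[str]:
    """Sample ids matching the given factor levels (None = no constraint)."""
    mask = pd.Series(True, index=samples.index)
    if genotype is not None:
        mask &= samples["genotype"] == genotype
    if treatment is not None:
        mask &= samples["treatment"] == treatment
    if time is not None:
        mask &= samples["time"] == time
    return samples.loc[mask, "sample_id"].tolist()


def relative_expression(expr: pd.DataFrame, housekeeping: Sequence[str],
                        reference_samples: Iterable[str],
                        mean: str = "geometric") -> pd.DataFrame:
    """Housekeeping-normalized log2 relative expression.

    Per sample, each gene's linear value is divided by the mean of the
    housekeeping genes' linear values in that sample (geometric mean by
    default, the standard delta-delta-Ct convention; ``mean='arithmetic'``
    uses the linear-scale arithmetic mean instead).  The result is log2 of
    the normalized value over the mean normalized value across the
    reference-condition samples.
    """
    housekeeping = list(housekeeping)
    reference_samples = list(reference_samples)
    if not housekeeping:
        raise StressclustError("at least one housekeeping gene is required")
    if not reference_samples:
        raise StressclustError("reference condition selects no samples")
    missing = [g for g in housekeeping if g not in expr.index]
    if missing:
        raise StressclustError(f"housekeeping gene(s) not in matrix: {missing}")
    hk = expr.loc[housekeeping]
    if (hk.values <= 0).any():
        raise StressclustError("housekeeping expression must be strictly positive")
    if mean == "geometric":
        divisor = np.exp(np.log(hk).mean(axis=0))
    elif mean == "arithmetic":
        divisor = hk.mean(axis=0)
    else:
        raise StressclustError(f"unknown mean mode {mean!r}")
    norm = expr.div(divisor, axis=1)
    ref = norm[reference_samples].mean(axis=1)
    if (ref <= 0).any():
        raise StressclustError("zero normalized expression in reference condition")
    return np.log2(norm.div(ref, axis=0))
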