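"""Tabular input/output and the core data containers.

Everything tabular is tab-delimited text. Expression values are assumed to
be on the log2(FPKM+1) scale, genes in rows and samples in columns. Floats
are serialized with 9 significant digits throughout, so a write/read
round-trip preserves every table at that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pairrisk")

FLOAT_FORMAT = "%.9g"

GROUP_LABELS = ("tumor", "normal")

BIOTYPES = ("lncRNA", "protein_coding", "other")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression on the log2(FPKM+1) scale.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``group`` is a Series over the same samples with labels in
    {"tumor", "normal"}.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicated sample id: {dup!r}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()][0]
            raise ValueError(f"sample {missing!r} has no group label")
        bad = set(self.group.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("log2(FPKM+1) expression values must be >= 0")
        counts = self.group.value_counts()
        if len(counts) == 2 and counts.min() < 2:
            raise ValueError("need at least 2 samples per group when both present")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)

    @property
    def n_samples(self):
        return self.values.shape[1]

    def samples_in_group(self, label: str) -> list:
        return list(self.group.index[self.group == label])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.group.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)],
                                self.group.loc[list(sample_ids)])


def read_expression(path, group_label: str) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix, labelling all samples.

    First column holds gene ids, header row holds sample ids. Duplicated
    gene rows are collapsed by their arithmetic mean on the log2 scale
    (deterministic and order-independent). Non-numeric cells are an error.
    """
    if group_label not in GROUP_LABELS:
        raise ValueError(f"group_label must be one of {GROUP_LABELS}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for col in header:
        if col in seen:
            raise ValueError(f"duplicate sample id in {path}: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    df.columns = header
    cols = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise ValueError(
                f"non-numeric expression value at gene {row!r}, sample {col!r} "
                f"in {path}: {df.loc[row, col]!r}")
        cols[col] = converted.astype(float)
    numeric = pd.DataFrame(cols, index=df.index)
    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicated gene rows by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    group = pd.Series(group_label, index=numeric.columns)
    return ExpressionMatrix(numeric, group)


def merge_cohorts(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Join two cohorts on their shared genes, concatenating samples."""
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"overlapping sample ids: {sorted(overlap)[:5]}")
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between the two cohorts")
    values = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    group = pd.concat([a.group, b.group])
    return ExpressionMatrix(values, group)


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table: gene_id, biotype, is_immune.

    Stands in for an Ensembl GTF biotype map plus an immune-gene list.
    Returns a DataFrame indexed by gene_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "biotype"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing mandatory column {col!r}")
    if "is_immune" not in df.columns:
        df["is_immune"] = False
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene_id in annotation: {dup!r}")
    bad = set(df["biotype"].unique()) - set(BIOTYPES)
    if bad:
        raise ValueError(f"unknown biotypes: {sorted(bad)}")
    df["is_immune"] = df["is_immune"].astype(bool)
    return df.set_index("gene_id")


CLINICAL_REQUIRED = ("sample_id", "time", "event")
CLINICAL_OPTIONAL = ("age", "grade", "stage")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table: sample_id, time, event, age, grade, stage.

    Time is in the unit declared by the pipeline config. ``grade``/``stage``
    are ordinal integers; missing clinical covariates are NaN.
    """
    df = pd.read_csv(path, sep="\t")
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"clinical table missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id in clinical table: {dup!r}")
    df = df.set_index("sample_id")
    df["time"] = pd.to_numeric(df["time"])
    if (df["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    df["event"] = pd.to_numeric(df["event"])
    if not df["event"].isin((0, 1)).all():
        bad = df.loc[~df["event"].isin((0, 1)), "event"].iloc[0]
        raise ValueError(f"event indicator must be 0 or 1; got {bad!r}")
    df["event"] = df["event"].astype(int)
    for col in CLINICAL_OPTIONAL:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def align_samples(expr: ExpressionMatrix, clinical: pd.DataFrame):
    """Inner-join expression samples with clinical rows.

    Samples lacking clinical information are dropped (with a logged count),
    mirroring cohort curation on real registries.
    """
    keep = [s for s in expr.sample_ids if s in clinical.index]
    dropped = expr.n_samples - len(keep)
    if dropped:
        logger.info("dropping %d samples without clinical information", dropped)
    if not keep:
        raise ValueError("no samples shared between expression and clinical tables")
    return expr.subset_samples(keep), clinical.loc[keep]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Single serialization point: TSV, floats at 9 significant digits."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
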