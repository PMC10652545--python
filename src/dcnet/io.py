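"""Tabular input/output and sample alignment.

Canonical in-memory containers are pandas objects: an expression matrix is a
``DataFrame`` with samples as the index and genes as the columns; phenotype
data is wrapped in :class:`PhenotypeTable`, which records which columns are
numeric versus categorical and which column carries the binary condition.
All gene identifiers are opaque strings — NCBI Entrez IDs are numerals and
must never be parsed as integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "GroupAssignment",
    "read_expression",
    "read_phenotype",
    "read_id_map",
    "align_and_split",
    "rename_genes",
    "write_expression",
]


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    p = str(path).lower()
    if p.endswith(".csv"):
        return ","
    return "\t"


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()].astype(str)))
        raise ValueError(f"duplicate {what} identifiers: {dups}")


def _validate_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce all cells to float; raise naming the first bad cell."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ValueError(
            f"non-numeric expression value {df.iat[r, c]!r} at "
            f"sample {df.index[r]!r}, gene {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any() or not np.isfinite(coerced.to_numpy()).all():
        raise ValueError("expression matrix contains missing or non-finite values")
    return coerced.astype(float)


def read_expression(
    path,
    orientation: str = "samples_by_genes",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read an expression table into canonical samples × genes orientation.

    Parameters
    ----------
    path
        TSV/CSV file whose first column holds identifiers. Delimiter is
        inferred from the extension (.csv → comma, otherwise tab) unless
        ``delimiter`` is given.
    orientation
        ``"samples_by_genes"`` (the canonical layout) or
        ``"genes_by_samples"``, in which case the table is transposed on
        read.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    # pandas silently renames duplicated header fields, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    what = "gene" if orientation == "samples_by_genes" else "sample"
    _check_unique(header, what)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression table: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "genes_by_samples":
        df = df.T
    _check_unique(df.index, "sample")
    _check_unique(df.columns, "gene")
    df = _validate_numeric(df)
    if df.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 genes")
    return df


def write_expression(df: pd.DataFrame, path, delimiter: str | None = None) -> None:
    """Write samples × genes TSV/CSV with full-precision floats."""
    sep = _delimiter_for(path, delimiter)
    df.to_csv(path, sep=sep, index_label="sample", float_format="%.17g")


@dataclass
class PhenotypeTable:
    """Phenotype/clinical table with a designated binary grouping column.

    ``data`` is samples × variables; ``group_variable`` names the binary
    condition column; numeric vs. categorical covariates are recorded at
    construction time so the design matrix is built deterministically.
    """

    data: pd.DataFrame
    group_variable: str
    numeric_columns: list[str] = field(default_factory=list)
    categorical_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.group_variable not in self.data.columns:
            raise ValueError(
                f"group variable {self.group_variable!r} not among columns "
                f"{list(self.data.columns)}"
            )
        if not self.numeric_columns and not self.categorical_columns:
            for col in self.data.columns:
                if col == self.group_variable:
                    continue
                if pd.api.types.is_numeric_dtype(self.data[col]):
                    self.numeric_columns.append(col)
                else:
                    self.categorical_columns.append(col)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def group_levels(self) -> list:
        return sorted(self.data[self.group_variable].dropna().unique(), key=str)


def read_phenotype(
    path, group_variable: str, delimiter: str | None = None
) -> PhenotypeTable:
    """Read a phenotype table and validate the binary grouping column."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"empty phenotype table: {path}")
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample")
    if group_variable not in df.columns:
        raise ValueError(
            f"group variable {group_variable!r} not found; columns are "
            f"{list(df.columns)}"
        )
    grp = df[group_variable]
    if grp.isna().any():
        missing = list(df.index[grp.isna()].astype(str))
        raise ValueError(
            f"missing values in group variable {group_variable!r} for samples {missing}"
        )
    levels = grp.unique()
    if len(levels) != 2:
        raise ValueError(
            f"group variable {group_variable!r} must have exactly 2 observed "
            f"levels, found {len(levels)}: {sorted(levels, key=str)}"
        )
    return PhenotypeTable(data=df, group_variable=group_variable)


@dataclass(frozen=True)
class GroupAssignment:
    """Row positions of the two condition groups in the aligned tables.

    Group A is the reference level (coded 0 in the regression); Group B is
    coded 1. Index sets are asserted disjoint and exhaustive on construction.
    """

    group_a_indices: np.ndarray
    group_b_indices: np.ndarray
    level_labels: tuple

    def __post_init__(self):
        a = np.asarray(self.group_a_indices, dtype=int)
        b = np.asarray(self.group_b_indices, dtype=int)
        object.__setattr__(self, "group_a_indices", a)
        object.__setattr__(self, "group_b_indices", b)
        if np.intersect1d(a, b).size:
            raise ValueError("group index sets overlap")
        n = a.size + b.size
        if not np.array_equal(np.sort(np.concatenate([a, b])), np.arange(n)):
            raise ValueError("group index sets do not cover all samples")
        if a.size < 4 or b.size < 4:
            raise ValueError(
                "each group needs >= 4 samples for leave-one-out re-estimation "
                f"(got {a.size} and {b.size})"
            )

    @property
    def n_samples(self) -> int:
        return self.group_a_indices.size + self.group_b_indices.size

    def indicator(self) -> np.ndarray:
        """0/1 vector over the aligned sample order (1 = Group B)."""
        out = np.zeros(self.n_samples, dtype=float)
        out[self.group_b_indices] = 1.0
        return out


def align_and_split(
    expr: pd.DataFrame,
    pheno: PhenotypeTable,
    group_a_level=None,
    group_b_level=None,
) -> tuple[pd.DataFrame, PhenotypeTable, GroupAssignment]:
    """Restrict both tables to common samples and build the group split.

    Samples with a missing value in any covariate are dropped
    (complete-case), with the count logged. Unless levels are named
    explicitly, the lexicographically smaller level of the group variable
    becomes Group A (the regression reference), so the sign of the group
    coefficient is deterministic.
    """
    common = expr.index.intersection(pheno.sample_ids)
    if common.empty:
        raise ValueError("no overlapping sample identifiers between tables")
    dropped_overlap = (len(expr) - len(common)) + (len(pheno.sample_ids) - len(common))
    if dropped_overlap:
        logger.warning(
            "dropped %d sample(s) absent from one of the two tables", dropped_overlap
        )
    # preserve expression-table order
    keep = expr.index[expr.index.isin(common)]
    pdat = pheno.data.loc[keep]
    complete = ~pdat.isna().any(axis=1)
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.warning("dropped %d sample(s) with missing covariate values", n_incomplete)
    keep = keep[complete.to_numpy()]

    expr2 = expr.loc[keep]
    pdat = pheno.data.loc[keep]
    grp = pdat[pheno.group_variable]
    levels = sorted(grp.unique(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"group variable has {len(levels)} observed level(s) after filtering"
        )
    if group_a_level is None and group_b_level is None:
        a_level, b_level = levels
    else:
        a_level = group_a_level if group_a_level is not None else next(
            l for l in levels if l != group_b_level
        )
        b_level = group_b_level if group_b_level is not None else next(
            l for l in levels if l != group_a_level
        )
        if {a_level, b_level} != set(levels):
            raise ValueError(
                f"requested levels ({a_level!r}, {b_level!r}) do not match "
                f"observed levels {levels}"
            )
    a_idx = np.flatnonzero((grp == a_level).to_numpy())
    b_idx = np.flatnonzero((grp == b_level).to_numpy())
    if a_idx.size < 4 or b_idx.size < 4:
        raise ValueError(
            "each group needs >= 4 samples after filtering "
            f"(got {a_idx.size} for {a_level!r} and {b_idx.size} for {b_level!r})"
        )
    assignment = GroupAssignment(a_idx, b_idx, (a_level, b_level))

    pheno2 = PhenotypeTable(
        data=pdat,
        group_variable=pheno.group_variable,
        numeric_columns=list(pheno.numeric_columns),
        categorical_columns=list(pheno.categorical_columns),
    )
    # warn on categorical levels observed in only one group (confounded design)
    for col in pheno2.categorical_columns:
        la = set(pdat[col].iloc[a_idx].unique())
        lb = set(pdat[col].iloc[b_idx].unique())
        only = (la - lb) | (lb - la)
        if only:
            logger.warning(
                "covariate %r has level(s) %s present in only one group; the "
                "group effect is partially confounded with it",
                col,
                sorted(map(str, only)),
            )
    return expr2, pheno2, assignment


def read_id_map(path, delimiter: str | None = None) -> dict:
    """Read a two-column (source_id, target_id) mapping table."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("id-map table needs two columns (source, target)")
    src = df.iloc[:, 0].astype(str)
    _check_unique(src, "source")
    return dict(zip(src, df.iloc[:, 1].astype(str)))


def rename_genes(ids, mapping: dict) -> list:
    """Map gene ids through ``mapping``; unmapped ids pass through unchanged."""
    out, missing = [], 0
    for g in ids:
        g = str(g)
        if g in mapping:
            out.append(str(mapping[g]))
        else:
            out.append(g)
            missing += 1
    if missing:
        logger.warning("%d gene id(s) had no mapping and were passed through", missing)
    return out
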