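"""Readers and writers for expression matrices, sample annotations and gene-sets.

All tabular formats are plain UTF-8 TSV with a ``.`` decimal separator and no
quoting.  Expression matrices are genes-by-samples with a header row of sample
identifiers and the gene identifier in the first column.  Gene identifiers are
opaque, case-sensitive strings; no symbol aliasing is performed.  Malformed
input is rejected with an error naming the offending coordinate rather than
silently repaired.  Missing values are not supported: every matrix cell must
be a finite number.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ANNOTATION_COLUMNS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "read_gmt",
    "write_gmt",
    "shared_genes",
    "read_de_results",
    "write_de_results",
]

#: Fixed column layout for sample annotation tables.  The three tissue
#: percentages are optional (blank when no histopathology is available).
ANNOTATION_COLUMNS = (
    "sample_id",
    "class",
    "cohort_id",
    "stroma_pct",
    "cancer_pct",
    "epithelium_pct",
)

_CLASSES = frozenset({"cancer", "normal"})


def _first_duplicate(values: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            return v
        seen.add(v)
    return None


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """A gene-by-sample expression matrix on a log-like scale for one cohort.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Values must be finite floats; identifiers must be unique.
    cohort_id
        Label of the cohort the matrix belongs to.
    """

    data: pd.DataFrame
    cohort_id: str

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.data.index)
        if dup is not None:
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        dup = _first_duplicate(self.data.columns)
        if dup is not None:
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at "
                f"gene {self.data.index[gi]!r}, sample {self.data.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]!r}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.cohort_id)


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene identifiers."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene-set {self.name!r} is empty")
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"gene-set {self.name!r} has duplicate gene {dup!r}")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, k: int) -> "GeneSet":
        """The first ``k`` genes, preserving rank order."""
        if not 1 <= k <= len(self.genes):
            raise ValueError(f"k={k} outside 1..{len(self.genes)}")
        return GeneSet(f"{self.name}_top{k}", self.description, self.genes[:k])


def read_expression_matrix(path: str | Path, cohort_id: str) -> ExpressionMatrix:
    """Read a genes-by-samples TSV into an :class:`ExpressionMatrix`.

    Row and column order is preserved from the file.  Duplicate identifiers
    and non-numeric cells raise ``ValueError`` with coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    raw.index = raw.index.astype(str)
    dup = _first_duplicate(raw.index)
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    dup = _first_duplicate(raw.columns)
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample identifier {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[gi, si]!r} at "
            f"gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), cohort_id)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.10g"
) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV (columns :data:`ANNOTATION_COLUMNS`)."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort_id": str})
    missing = [c for c in ANNOTATION_COLUMNS[:3] if c not in ann.columns]
    if missing:
        raise ValueError(f"{path}: annotation lacks required columns {missing}")
    for col in ANNOTATION_COLUMNS[3:]:
        if col not in ann.columns:
            ann[col] = np.nan
    ann = ann[list(ANNOTATION_COLUMNS)]
    _check_annotation_frame(ann, str(path))
    return ann


def _check_annotation_frame(ann: pd.DataFrame, origin: str) -> None:
    dup = _first_duplicate(ann["sample_id"])
    if dup is not None:
        raise ValueError(f"{origin}: duplicate sample_id {dup!r}")
    bad = set(ann["class"]) - _CLASSES
    if bad:
        raise ValueError(f"{origin}: unknown sample class values {sorted(bad)!r}")
    pct = ann[["stroma_pct", "cancer_pct", "epithelium_pct"]].to_numpy(float)
    has_histo = ~np.isnan(pct).any(axis=1)
    if has_histo.any():
        totals = pct[has_histo].sum(axis=1)
        off = np.abs(totals - 100.0) > 0.5
        if off.any():
            sid = ann.loc[has_histo, "sample_id"].to_numpy()[off][0]
            raise ValueError(
                f"{origin}: tissue percentages for sample {sid!r} sum to "
                f"{totals[off][0]:.2f}, expected 100 +/- 0.5"
            )
        neg = (pct[has_histo] < 0) | (pct[has_histo] > 100)
        if neg.any():
            raise ValueError(f"{origin}: tissue percentage outside [0, 100]")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.10g")


def validate_annotation(ann: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    """Check that every annotated sample exists in the cohort's matrix."""
    _check_annotation_frame(ann, f"annotation for cohort {matrix.cohort_id!r}")
    missing = set(ann["sample_id"]) - set(matrix.sample_ids)
    if missing:
        raise ValueError(
            f"annotated samples absent from matrix {matrix.cohort_id!r}: "
            f"{sorted(missing)[:5]!r}"
        )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            dup = _first_duplicate(genes)
            if dup is not None:
                raise ValueError(
                    f"{path}: line {lineno} ({name!r}) lists gene {dup!r} twice"
                )
            sets.append(GeneSet(name, desc, tuple(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def shared_genes(matrices: Sequence[ExpressionMatrix]) -> list[str]:
    """Genes present in every cohort, sorted lexicographically.

    The shared universe is what makes enrichment scores comparable across
    cohorts measured on different platforms.
    """
    if len(matrices) == 0:
        raise ValueError("shared_genes requires at least one matrix")
    common: set[str] = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no genes shared by all matrices")
    return sorted(common)


_DE_COLUMNS = ("gene_id", "direction", "p_value", "q_value", "rank", "log_fold_change")


def write_de_results(de: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a differential-expression result table as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        de[list(_DE_COLUMNS)].to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_de_results(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = [c for c in _DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"{path}: DE table lacks columns {missing}")
    return de
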