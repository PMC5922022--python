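"""Rank-based multi-cohort meta-analysis of differential expression.

Cohorts measured on different platforms are made comparable in three steps:

1. Within each cohort, each gene's expression values are rank-normalized to
   a 0-100 score (average ranks for ties; the lowest-expressing sample maps
   to 0, the highest to 100).
2. The scores are mean-centered per gene within each cohort.  With weighted
   centering the subtracted center is the unweighted average of the cancer
   and normal class means, which makes the centering invariant to the often
   huge class imbalance; plain centering subtracts the grand mean and is
   used for cohorts that lack one of the classes.
3. The centered scores of all cohorts are merged; the cancer-vs-normal
   contrast (unstratified, balanced or unbalanced) is tested per gene with a
   single pooled Mann-Whitney test.  A gene absent from some cohorts is
   tested on the cohorts that contain it.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix
from .stats import assign_ranks, bh_fdr, mann_whitney_de

__all__ = ["rank_normalize", "weighted_mean_center", "build_meta_matrix", "meta_de", "MetaMatrix"]


def rank_normalize(values) -> np.ndarray:
    """Map values to 0-100 by rank (1-D), or each row of a 2-D array.

    Average ranks are used for ties and mapped affinely so that rank 1 -> 0
    and rank n -> 100; e.g. [5, 5, 9] -> [25, 25, 100].  A single sample has
    no rank range and raises.
    """
    arr = np.asarray(values, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    n = arr.shape[1]
    if n < 2:
        raise ValueError("rank normalization needs >= 2 samples")
    ranks = rankdata(arr, axis=1)
    scores = (ranks - 1.0) / (n - 1.0) * 100.0
    return scores[0] if one_d else scores


def weighted_mean_center(
    scores: pd.DataFrame,
    classes: pd.Series,
    weighted: bool = True,
) -> pd.DataFrame:
    """Center each gene's scores within a cohort.

    With ``weighted=True`` the center is (mean over cancer + mean over
    normal) / 2, so duplicating samples of one class leaves the other
    class's centered values unchanged; both classes must be present.  With
    ``weighted=False`` the plain grand mean is subtracted.
    """
    classes = classes.reindex(scores.columns)
    if weighted:
        cancer = classes[classes == "cancer"].index
        normal = classes[classes == "normal"].index
        if len(cancer) == 0 or len(normal) == 0:
            raise ValueError("weighted centering requires both cancer and normal samples")
        center = (scores[cancer].mean(axis=1) + scores[normal].mean(axis=1)) / 2.0
    else:
        center = scores.mean(axis=1)
    return scores.sub(center, axis=0)


@dataclasses.dataclass(frozen=True)
class MetaMatrix:
    """Merged rank-normalized, centered scores from several cohorts.

    ``data`` holds genes (union over cohorts) by samples; entries for genes
    a cohort does not measure are NaN.  ``sample_meta`` carries cohort_id
    and class per sample; ``coverage`` is a genes x cohorts boolean frame.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    coverage: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def cohorts_of(self, gene_id: str) -> list[str]:
        row = self.coverage.loc[gene_id]
        return list(row.index[row])


def build_meta_matrix(
    cohorts: Sequence[tuple[ExpressionMatrix, pd.Series]],
    weighted: bool = True,
) -> MetaMatrix:
    """Rank-normalize and center each cohort, then merge on the gene union.

    Parameters
    ----------
    cohorts
        (matrix, classes) pairs; ``classes`` maps the matrix's sample ids to
        "cancer"/"normal".  Sample ids must be unique across cohorts.
    weighted
        Use class-balanced centering (requires both classes per cohort).
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    blocks: list[pd.DataFrame] = []
    meta_rows: list[pd.DataFrame] = []
    cohort_ids: list[str] = []
    for matrix, classes in cohorts:
        classes = pd.Series(classes)
        scores = pd.DataFrame(
            rank_normalize(matrix.data.to_numpy(float)),
            index=matrix.data.index,
            columns=matrix.data.columns,
        )
        centered = weighted_mean_center(scores, classes, weighted=weighted)
        blocks.append(centered)
        cohort_ids.append(matrix.cohort_id)
        meta_rows.append(
            pd.DataFrame(
                {
                    "sample_id": matrix.sample_ids,
                    "cohort_id": matrix.cohort_id,
                    "class": classes.reindex(matrix.sample_ids).to_numpy(),
                }
            )
        )
    if len(set(cohort_ids)) != len(cohort_ids):
        raise ValueError("cohort ids must be unique")
    sample_meta = pd.concat(meta_rows, ignore_index=True)
    dup = sample_meta["sample_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"sample id {sample_meta.loc[dup, 'sample_id'].iloc[0]!r} occurs in "
            "more than one cohort"
        )
    all_genes = sorted(set().union(*[set(b.index) for b in blocks]))
    data = pd.concat([b.reindex(all_genes) for b in blocks], axis=1)
    coverage = pd.DataFrame(
        {cid: [g in set(b.index) for g in all_genes] for cid, b in zip(cohort_ids, blocks)},
        index=all_genes,
    )
    sample_meta = sample_meta.set_index("sample_id", drop=False)
    return MetaMatrix(data, sample_meta, coverage)


def meta_de(
    meta: MetaMatrix,
    contrast_samples: Sequence[str] | None = None,
    m_total: int | None = None,
) -> pd.DataFrame:
    """Pooled Mann-Whitney differential expression over the merged cohorts.

    Parameters
    ----------
    meta
        Output of :func:`build_meta_matrix`.
    contrast_samples
        Sample ids making up the contrast (e.g. a balanced meta-dataset);
        ``None`` uses every sample (the unstratified contrast).  Class
        labels come from ``meta.sample_meta``.
    m_total
        BH correction gene count; defaults to the gene union size.

    Genes not covered by any cohort contributing contrast samples are
    excluded with a warning.  Each gene's test pools the centered scores of
    exactly the cohorts that measured it.
    """
    if contrast_samples is None:
        contrast_samples = list(meta.sample_meta["sample_id"])
    contrast_samples = [s for s in meta.data.columns if s in set(contrast_samples)]
    classes = meta.sample_meta.loc[contrast_samples, "class"]
    n_cancer = int((classes == "cancer").sum())
    n_normal = int((classes == "normal").sum())
    if n_cancer < 2 or n_normal < 2:
        raise ValueError(
            f"contrast needs >= 2 samples per class (got {n_cancer} cancer, "
            f"{n_normal} normal)"
        )
    sub = meta.data[contrast_samples]
    covered = sub.notna()
    sample_cohort = meta.sample_meta.loc[contrast_samples, "cohort_id"].to_numpy()

    # Genes sharing a coverage pattern over the contrast samples are tested
    # together through one vectorized Mann-Whitney call.
    pattern_key = covered.to_numpy().astype(np.uint8)
    patterns: dict[bytes, list[str]] = {}
    for gene, row in zip(sub.index, pattern_key):
        patterns.setdefault(row.tobytes(), []).append(gene)

    pieces: list[pd.DataFrame] = []
    dropped: list[str] = []
    for key, genes in patterns.items():
        mask = np.frombuffer(key, dtype=np.uint8).astype(bool)
        cols = [s for s, keep in zip(contrast_samples, mask) if keep]
        cls = classes.loc[cols]
        if (cls == "cancer").sum() < 2 or (cls == "normal").sum() < 2:
            dropped.extend(genes)
            continue
        block = ExpressionMatrix(sub.loc[genes, cols], cohort_id="meta")
        de = mann_whitney_de(block, cls, m_total=None)
        de = de.drop(columns=["q_value", "rank"])
        pieces.append(de)
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes dropped from meta-DE: no covering cohort in "
            "the contrast",
            stacklevel=2,
        )
    if not pieces:
        raise ValueError("no genes testable in the requested contrast")
    out = pd.concat(pieces, ignore_index=True)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy(), m_total or len(meta.gene_ids))
    out = assign_ranks(out)
    return out[["gene_id", "direction", "p_value", "q_value", "rank", "log_fold_change"]]
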