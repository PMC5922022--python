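"""Single-sample enrichment scoring of stroma content.

Each sample's genes are ranked by descending expression within the sample
(ties broken by gene id) and scored against a stroma gene-set with the
classic unweighted Kolmogorov-Smirnov running sum: walking down the ranked
universe, a gene in the set steps the sum up by 1/|S| and a gene outside it
steps down by 1/(N - |S|); the enrichment score (ES) is the signed maximum
deviation from zero.  The unweighted statistic depends on ranks only, which
makes it comparable across microarray and RNA-seq platforms.

A sample's stroma score combines the up- and down-regulated stroma sets as
ES(up) - ES(down), computed at several gene-set sizes (by default the top
100, 150, ..., 500 and 1000 genes of each set); each size's scores are
normalized affinely to 0-100 across the cohort's samples and averaged.
Scores are therefore *relative within a cohort*: cohorts show prominent
baseline differences in raw enrichment, so no cross-cohort absolute stroma
percentage is provided.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .genesets import StromaGeneSets
from .io import ExpressionMatrix, GeneSet

__all__ = [
    "DEFAULT_SIZES",
    "single_sample_es",
    "stroma_score_cohort",
    "calibrate_to_histopathology",
    "score_stability",
    "StromaScoreTable",
    "CalibrationModel",
]

#: Gene-set size ladder used for multi-size scoring of full-scale cohorts.
DEFAULT_SIZES = (100, 150, 200, 250, 300, 350, 400, 450, 500, 1000)


def _ranked_universe(sample_expression: pd.Series) -> np.ndarray:
    """Gene ids sorted by descending expression, ties broken by gene id."""
    genes = sample_expression.index.to_numpy(dtype=object)
    values = sample_expression.to_numpy(dtype=float)
    order = np.lexsort((genes, -values))
    return genes[order]


def _es_from_order(ordered_genes: np.ndarray, hit: np.ndarray) -> float:
    """KS running-sum ES given the ranked universe and a hit indicator."""
    n = len(ordered_genes)
    n_hit = int(hit.sum())
    steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def single_sample_es(sample_expression: pd.Series, gene_set: GeneSet | Sequence[str]) -> float:
    """Unweighted KS enrichment score of one sample against one gene-set.

    ``sample_expression`` must already be restricted to the gene universe;
    the gene-set must be a non-empty strict subset of that universe (the
    miss step is undefined otherwise).  The score lies in [-1, 1]: +1 when
    every set gene outranks every other gene, -1 in the reversed case.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    universe = set(sample_expression.index)
    members = set(genes)
    if not members:
        raise ValueError("gene-set is empty")
    if not members <= universe:
        missing = sorted(members - universe)
        raise ValueError(f"gene-set genes absent from universe: {missing[:5]!r}")
    if members == universe:
        raise ValueError("gene-set equals the whole universe; miss step undefined")
    ordered = _ranked_universe(sample_expression)
    hit = np.isin(ordered, list(members))
    return _es_from_order(ordered, hit)


@dataclasses.dataclass(frozen=True)
class StromaScoreTable:
    """Per-sample multi-size enrichment scores and the averaged stroma score.

    Attributes
    ----------
    raw
        samples x sizes frame of ES(up_k) - ES(down_k).
    normalized
        Same shape, each size affinely mapped to 0-100 over the samples.
    stroma_score
        Per-sample mean of the normalized columns (0-100).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    stroma_score: pd.Series
    geneset_source: str
    universe_size: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.stroma_score.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.stroma_score.index, "stroma_score": self.stroma_score.to_numpy()})
        for k in self.normalized.columns:
            out[f"norm_{k}"] = self.normalized[k].to_numpy()
        for k in self.raw.columns:
            out[f"raw_{k}"] = self.raw[k].to_numpy()
        return out


def stroma_score_cohort(
    matrix: ExpressionMatrix,
    sets: StromaGeneSets,
    sizes: Sequence[int] = DEFAULT_SIZES,
    universe: Sequence[str] | None = None,
) -> StromaScoreTable:
    """Score every sample of a cohort for stroma content.

    Per sample and size ``k`` the raw score is ES(top-k stroma-up set) minus
    ES(top-k stroma-down set) on the universe-restricted expression profile.
    Per size, raw scores are normalized to [0, 100] over the cohort's
    samples; the stroma score is the mean of the normalized columns.  A
    single-sample cohort has no normalization range: its score is defined as
    50 with a warning.
    """
    sizes = tuple(int(k) for k in sizes)
    if len(sizes) == 0 or any(k < 1 for k in sizes):
        raise ValueError("sizes must be positive integers")
    universe = list(universe) if universe is not None else sorted(matrix.gene_ids)
    missing = set(universe) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"universe genes absent from matrix: {sorted(missing)[:5]!r}")
    up = [g for g in sets.up.genes if g in set(universe)]
    down = [g for g in sets.down.genes if g in set(universe)]
    for k in sizes:
        if k > len(up) or k > len(down):
            raise ValueError(
                f"size {k} exceeds universe-restricted set sizes "
                f"(up={len(up)}, down={len(down)})"
            )
    if len(universe) < 2 * max(sizes):
        raise ValueError(
            f"universe of {len(universe)} genes smaller than twice the largest "
            f"gene-set size ({max(sizes)})"
        )

    sub = matrix.data.loc[universe]
    genes = sub.index.to_numpy(dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    up_masks = {}
    down_masks = {}
    for k in sizes:
        m = np.zeros(n, dtype=bool)
        m[[gene_pos[g] for g in up[:k]]] = True
        up_masks[k] = m
        m = np.zeros(n, dtype=bool)
        m[[gene_pos[g] for g in down[:k]]] = True
        down_masks[k] = m

    values = sub.to_numpy(float)
    raw = np.empty((matrix.n_samples, len(sizes)))
    for j in range(matrix.n_samples):
        order = np.lexsort((genes, -values[:, j]))
        for i, k in enumerate(sizes):
            es_up = _es_from_order(genes[order], up_masks[k][order])
            es_down = _es_from_order(genes[order], down_masks[k][order])
            raw[j, i] = es_up - es_down

    raw_df = pd.DataFrame(raw, index=matrix.sample_ids, columns=list(sizes))
    if matrix.n_samples == 1:
        warnings.warn(
            "single-sample cohort: 0-100 normalization is degenerate, "
            "stroma score set to 50",
            stacklevel=2,
        )
        norm_df = raw_df * 0.0 + 50.0
    else:
        lo = raw_df.min(axis=0)
        span = raw_df.max(axis=0) - lo
        degenerate = span == 0
        if degenerate.any():
            warnings.warn("constant raw scores at some sizes; normalized to 50", stacklevel=2)
        span = span.where(~degenerate, 1.0)
        norm_df = (raw_df - lo) / span * 100.0
        for k in norm_df.columns[degenerate.to_numpy()]:
            norm_df[k] = 50.0
    score = norm_df.mean(axis=1)
    score.name = "stroma_score"
    return StromaScoreTable(raw_df, norm_df, score, sets.source, len(universe))


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """Linear least-squares map from enrichment score to stroma percentage."""

    slope: float
    intercept: float
    pearson_r: float
    mean_abs_deviation: float

    def predict(self, scores) -> np.ndarray:
        pred = self.slope * np.asarray(scores, dtype=float) + self.intercept
        return np.clip(pred, 0.0, 100.0)


def calibrate_to_histopathology(
    scores: StromaScoreTable | pd.Series,
    histo_stroma_pct: pd.Series,
) -> CalibrationModel:
    """Fit histopathology stroma percentage on the enrichment stroma score.

    Ordinary least squares of ``histo ~ score`` over the samples present in
    both inputs.  Reports the slope, intercept, Pearson r, and the mean
    absolute deviation (percentage points) of fitted vs observed stroma.
    """
    score = scores.stroma_score if isinstance(scores, StromaScoreTable) else scores
    common = score.index.intersection(histo_stroma_pct.dropna().index)
    if len(common) < 3:
        raise ValueError("calibration needs >= 3 samples with score and histopathology")
    x = score.loc[common].to_numpy(float)
    y = histo_stroma_pct.loc[common].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("scores are constant; calibration undefined")
    fit = linregress(x, y)
    fitted = fit.slope * x + fit.intercept
    mad = float(np.mean(np.abs(fitted - y)))
    return CalibrationModel(float(fit.slope), float(fit.intercept), float(fit.rvalue), mad)


def score_stability(
    matrix: ExpressionMatrix,
    sets: StromaGeneSets,
    sizes: Sequence[int] = DEFAULT_SIZES,
    universe: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-sample SD of the normalized scores across gene-set sizes.

    Returns the per-sample sample standard deviations and their cohort mean,
    a descriptive measure of how robust the stroma assessment is to the
    choice of gene-set size.
    """
    table = stroma_score_cohort(matrix, sets, sizes, universe)
    sd = table.normalized.std(axis=1, ddof=1)
    sd.name = "score_sd"
    return sd, float(sd.mean())
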