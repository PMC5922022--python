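"""Rank-based per-gene statistics.

The differential-expression test is the two-sided Mann-Whitney-Wilcoxon
rank-sum test, applied gene by gene.  For groups of at least eight samples
each the tie-corrected normal approximation is used; smaller layouts are
tested by exact enumeration of all group assignments, which handles ties
correctly.  Multiple-testing correction is Benjamini-Hochberg, optionally at
a global gene count larger than the number of genes actually tested (the
conservative convention of correcting every display at the full cross-cohort
gene universe).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = ["mann_whitney_de", "bh_fdr", "collapse_probes", "assign_ranks"]

#: Largest number of group assignments enumerated by the exact test before
#: falling back to the normal approximation.
EXACT_ENUMERATION_LIMIT = 200_000


def _mw_u_statistics(values: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Per-row U statistic of the masked group (genes x samples input)."""
    n1 = int(group_mask.sum())
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, group_mask].sum(axis=1)
    return r1 - n1 * (n1 + 1) / 2.0


def _asymptotic_p(values: np.ndarray, group_mask: np.ndarray, u1: np.ndarray) -> np.ndarray:
    """Two-sided p from the tie-corrected normal approximation (no continuity
    correction).  Constant rows get p = 1."""
    n = values.shape[1]
    n1 = int(group_mask.sum())
    n2 = n - n1
    mu = n1 * n2 / 2.0
    # tie correction: sum over tied groups of (t^3 - t), per gene
    sorted_vals = np.sort(values, axis=1)
    tie_term = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        _, counts = np.unique(sorted_vals[g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma_sq, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (u1 - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def _exact_p(values: np.ndarray, group_mask: np.ndarray, u1: np.ndarray) -> np.ndarray:
    """Two-sided exact p by enumerating every assignment of samples to the
    first group.  The two-sided p-value of gene g is the fraction of
    assignments whose U deviates from the null mean by at least as much as
    the observed U.  Ties need no special treatment: the permutation
    distribution is computed on the actual (tied) ranks."""
    n = values.shape[1]
    n1 = int(group_mask.sum())
    n2 = n - n1
    mu = n1 * n2 / 2.0
    ranks = rankdata(values, axis=1)
    combos = np.array(list(combinations(range(n), n1)))  # (n_combo, n1)
    # rank sums of every candidate group-1 assignment, per gene
    r1_all = ranks[:, combos].sum(axis=2)  # (genes, n_combo)
    u_all = r1_all - n1 * (n1 + 1) / 2.0
    obs_dev = np.abs(u1 - mu)[:, None]
    # small tolerance so equal deviations (up to float noise) count as extreme
    p = (np.abs(u_all - mu) >= obs_dev - 1e-9).mean(axis=1)
    return p


def mann_whitney_de(
    matrix: ExpressionMatrix,
    classes: Mapping[str, str] | pd.Series,
    group: str = "cancer",
    reference: str = "normal",
    m_total: int | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney test of ``group`` vs ``reference``.

    Parameters
    ----------
    matrix
        Expression matrix; only samples labelled ``group`` or ``reference``
        in ``classes`` are used.
    classes
        Mapping from sample id to class label.
    m_total
        Gene count used for the BH correction; defaults to the number of
        genes in the matrix.

    Returns
    -------
    DataFrame with columns gene_id, direction, p_value, q_value, rank and
    log_fold_change, sorted by ascending rank.  ``direction`` is "up" when
    the group's values are located above the reference's (rank-biserial
    shift >= 0; constant genes report p = 1 and "up" by convention).
    ``log_fold_change`` is the difference of class means on the matrix's
    (log-like) scale.  Ranks are 1..n_genes by ascending p, ties broken by
    gene id.
    """
    classes = pd.Series(dict(classes)) if not isinstance(classes, pd.Series) else classes
    g_samples = [s for s in matrix.sample_ids if classes.get(s) == group]
    r_samples = [s for s in matrix.sample_ids if classes.get(s) == reference]
    if len(g_samples) < 2 or len(r_samples) < 2:
        raise ValueError(
            f"each class needs >= 2 samples (got {len(g_samples)} {group!r}, "
            f"{len(r_samples)} {reference!r})"
        )
    ordered = g_samples + r_samples
    values = matrix.data[ordered].to_numpy(float)
    mask = np.zeros(len(ordered), dtype=bool)
    mask[: len(g_samples)] = True

    n1, n2 = len(g_samples), len(r_samples)
    u1 = _mw_u_statistics(values, mask)
    if min(n1, n2) >= 8 or comb(n1 + n2, n1) > EXACT_ENUMERATION_LIMIT:
        p = _asymptotic_p(values, mask, u1)
    else:
        p = _exact_p(values, mask, u1)

    direction = np.where(u1 >= n1 * n2 / 2.0, "up", "down")
    lfc = values[:, mask].mean(axis=1) - values[:, ~mask].mean(axis=1)

    de = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "direction": direction,
            "p_value": p,
            "log_fold_change": lfc,
        }
    )
    de["q_value"] = bh_fdr(de["p_value"].to_numpy(), m_total or matrix.n_genes)
    de = assign_ranks(de)
    return de[["gene_id", "direction", "p_value", "q_value", "rank", "log_fold_change"]]


def assign_ranks(de: pd.DataFrame) -> pd.DataFrame:
    """Assign significance ranks 1..n by ascending p, ties broken by gene id."""
    order = np.lexsort((de["gene_id"].to_numpy(), de["p_value"].to_numpy()))
    ranks = np.empty(len(de), dtype=int)
    ranks[order] = np.arange(1, len(de) + 1)
    de = de.copy()
    de["rank"] = ranks
    return de.sort_values("rank").reset_index(drop=True)


def bh_fdr(p_values: Sequence[float] | np.ndarray, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values at a global test count.

    ``q_(i) = min_{j >= i} p_(j) * m_total / j`` (ascending order, capped at
    1), with the result returned in the original order.  ``m_total`` may
    exceed the number of supplied p-values, e.g. when correcting a
    per-cohort analysis at the full cross-cohort gene universe.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError(f"m_total={m} smaller than number of p-values ({len(p)})")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, len(p) + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    strategy: str = "best_avg_de_rank",
    de_context: Sequence[Mapping[str, float]] | None = None,
) -> ExpressionMatrix:
    """Keep one representative probe per gene on multi-probe platforms.

    Strategies
    ----------
    ``best_avg_de_rank``
        Keep the probe with the most significant (numerically smallest)
        average p-value rank over several differential analyses, e.g. the
        unstratified, balanced and unbalanced comparisons.  Requires
        ``de_context``: one probe-to-rank mapping per analysis.
    ``best_de_rank``
        Same with a single analysis.
    ``max_expression``
        Keep the probe with the highest mean expression (used on platforms
        where almost every gene has one probe).

    Probes with no gene mapping are dropped.  Ties are broken by probe id.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    if strategy not in {"best_de_rank", "best_avg_de_rank", "max_expression"}:
        raise ValueError(f"unknown collapse strategy {strategy!r}")
    if strategy in {"best_de_rank", "best_avg_de_rank"}:
        if not de_context:
            raise ValueError(f"strategy {strategy!r} requires de_context rank lists")
        if strategy == "best_de_rank" and len(de_context) != 1:
            raise ValueError("best_de_rank expects exactly one rank list")

    mean_expr = probe_matrix.data.mean(axis=1)

    def score(probe: str) -> float:
        if strategy == "max_expression":
            # negate so that "smallest score wins" applies uniformly
            return -float(mean_expr[probe])
        ranks = [float(ctx[probe]) for ctx in de_context if probe in ctx]
        if not ranks:
            raise KeyError(f"probe {probe!r} missing from de_context ranks")
        return float(np.mean(ranks))

    by_gene: dict[str, list[str]] = {}
    for probe in probe_matrix.gene_ids:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        by_gene.setdefault(gene, []).append(probe)

    if not by_gene:
        raise ValueError("no probe maps to any gene")

    kept: list[str] = []
    genes: list[str] = []
    for gene, probes in by_gene.items():
        best = min(probes, key=lambda pr: (score(pr), pr))
        kept.append(best)
        genes.append(gene)

    collapsed = probe_matrix.data.loc[kept]
    collapsed.index = pd.Index(genes, name="gene_id")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, probe_matrix.cohort_id)
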