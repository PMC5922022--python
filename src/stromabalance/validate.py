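"""Validation utilities: gene-set overlap vs random baselines, and recovery
of planted gene classes from ranked results.

Overlap between stroma gene-sets derived from independent cohorts is the
primary evidence that the sets capture tissue biology rather than platform
noise: the observed percentage of shared top-N genes is contrasted with the
average overlap of random same-size draws from each cohort's own measured
gene universe.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["geneset_overlap", "random_overlap_baseline", "recovery_report", "overlap_report"]


def geneset_overlap(a: Sequence[str], b: Sequence[str], n_top: int) -> float:
    """Percentage of ``a``'s top ``n_top`` genes found in ``b``'s top ``n_top``."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > len(a) or n_top > len(b):
        raise ValueError(f"n_top={n_top} exceeds a list length ({len(a)}, {len(b)})")
    top_a = list(a)[:n_top]
    top_b = set(list(b)[:n_top])
    return 100.0 * sum(g in top_b for g in top_a) / n_top


def random_overlap_baseline(
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    n_top: int,
    n_draws: int = 50,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean overlap percentage of random same-size selections.

    Draws ``n_draws`` pairs of uniform random ``n_top``-subsets, one from
    each universe, and averages their overlap percentage.  With a shared
    universe of size N the expectation is ``n_top / N * 100``
    (hypergeometric).
    """
    ua = list(dict.fromkeys(universe_a))
    ub = list(dict.fromkeys(universe_b))
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > len(ua) or n_top > len(ub):
        raise ValueError("n_top exceeds a universe size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_draws):
        pick_a = rng.choice(len(ua), size=n_top, replace=False)
        pick_b = rng.choice(len(ub), size=n_top, replace=False)
        sel_b = {ub[i] for i in pick_b}
        total += 100.0 * sum(ua[i] in sel_b for i in pick_a) / n_top
    return total / n_draws


def overlap_report(
    a: Sequence[str],
    b: Sequence[str],
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    n_top: int,
    n_draws: int = 50,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Observed top-N overlap of two ranked gene lists plus its random baseline."""
    return {
        "n_top": n_top,
        "observed_overlap_pct": geneset_overlap(a, b, n_top),
        "random_overlap_pct": random_overlap_baseline(
            universe_a, universe_b, n_top, n_draws, seed
        ),
        "n_random_draws": n_draws,
        "universe_sizes": (len(set(universe_a)), len(set(universe_b))),
    }


def recovery_report(
    ranked_genes: Sequence[str] | pd.DataFrame,
    gene_class: Mapping[str, str] | pd.Series,
    k: int,
) -> pd.DataFrame:
    """Precision/recall of planted gene classes in a ranked gene list.

    Parameters
    ----------
    ranked_genes
        Either an ordered gene-id sequence (best first) or a DE table with
        ``gene_id`` and ``rank`` columns.
    gene_class
        Mapping gene id -> planted class ("stroma_up", "cancer_de_down",
        ..., "null"); must cover every ranked gene.
    k
        Cutoff for the recovered-in-top-k fraction.

    Returns
    -------
    One row per non-null planted class with columns n_planted,
    recall_top_k, precision_top_k (share of the top-k belonging to the
    class) and mean_rank (1 = best).  Classes without planted genes are
    simply absent.
    """
    if isinstance(ranked_genes, pd.DataFrame):
        ordered = ranked_genes.sort_values("rank")["gene_id"].tolist()
    else:
        ordered = list(ranked_genes)
    if k < 1 or k > len(ordered):
        raise ValueError(f"k={k} outside 1..{len(ordered)}")
    gene_class = pd.Series(dict(gene_class)) if not isinstance(gene_class, pd.Series) else gene_class
    unknown = [g for g in ordered if g not in gene_class.index]
    if unknown:
        raise ValueError(f"ranked genes missing from truth: {unknown[:5]!r}")
    rank_of = {g: i + 1 for i, g in enumerate(ordered)}
    top_k = set(ordered[:k])
    rows = []
    for cls in sorted(set(gene_class[gene_class != "null"])):
        members = [g for g in gene_class.index[gene_class == cls] if g in rank_of]
        if not members:
            continue
        in_top = sum(g in top_k for g in members)
        rows.append(
            {
                "gene_class": cls,
                "n_planted": len(members),
                "recall_top_k": in_top / len(members),
                "precision_top_k": in_top / k,
                "mean_rank": float(np.mean([rank_of[g] for g in members])),
            }
        )
    return pd.DataFrame(rows, columns=["gene_class", "n_planted", "recall_top_k", "precision_top_k", "mean_rank"])
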