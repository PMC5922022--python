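"""Derivation of stroma gene-sets from a histopathology-stratified cohort.

A gene that is characteristic of stroma tissue is strongly differentially
expressed when the cancer and normal groups differ in stroma content (the
*unbalanced* contrast) but not when their stroma content is matched (the
*balanced* contrast).  Genes are ranked by

    p_score = p_unbal / p_bal**2

where smaller is better.  The squared denominator demands a larger p-value
gap from genes that are highly significant in both contrasts: a gene at
p = 1e-5 unbalanced and non-significant balanced is a better stroma-marker
candidate than one at 1e-20 unbalanced and 1e-15 balanced, even though the
plain ratio is the same.  p-values enter the formula uncorrected.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .io import GeneSet

__all__ = ["p_score", "pscore_table", "build_stroma_genesets", "StromaGeneSets"]


def p_score(p_unbal, p_bal):
    """The stroma-marker ranking score ``p_unbal / p_bal**2`` (lower = better).

    Accepts scalars or arrays; both p-values must lie in (0, 1].
    """
    p_unbal = np.asarray(p_unbal, dtype=float)
    p_bal = np.asarray(p_bal, dtype=float)
    if ((p_unbal <= 0) | (p_unbal > 1)).any() or ((p_bal <= 0) | (p_bal > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    out = p_unbal / p_bal**2
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class StromaGeneSets:
    """Ranked stroma-enriched (up) and stroma-depleted (down) gene-sets."""

    up: GeneSet
    down: GeneSet
    n_top: int
    excluded: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.excluded) & (set(self.up.genes) | set(self.down.genes))
        if overlap:
            raise ValueError(f"excluded genes present in gene-sets: {sorted(overlap)[:5]}")


def pscore_table(
    de_balanced: pd.DataFrame,
    de_unbalanced: pd.DataFrame,
    high_stroma_direction: str = "down",
) -> pd.DataFrame:
    """Join balanced and unbalanced DE results into a per-gene p_score table.

    Parameters
    ----------
    de_balanced, de_unbalanced
        DE tables (as produced by :func:`stromabalance.stats.mann_whitney_de`)
        over the same gene universe.
    high_stroma_direction
        The DE ``direction`` value that corresponds to higher expression in
        the high-stroma group of the unbalanced contrast.  In the standard
        design the normal samples are the high-stroma group and DE direction
        is cancer-vs-normal, so genes up in stroma appear "down"; hence the
        default.

    Returns
    -------
    DataFrame with columns gene_id, p_unbal, p_bal, p_score and
    stroma_direction ("up" = enriched in stroma), sorted by ascending
    p_score (ties broken by gene id).
    """
    if high_stroma_direction not in {"up", "down"}:
        raise ValueError("high_stroma_direction must be 'up' or 'down'")
    bal = de_balanced.set_index("gene_id")
    unbal = de_unbalanced.set_index("gene_id")
    if set(bal.index) != set(unbal.index):
        raise ValueError("balanced and unbalanced DE cover different gene universes")
    unbal = unbal.loc[bal.index]
    table = pd.DataFrame(
        {
            "gene_id": bal.index,
            "p_unbal": unbal["p_value"].to_numpy(),
            "p_bal": bal["p_value"].to_numpy(),
        }
    )
    # Mann-Whitney p-values of constant genes are exactly 1; a p of 0 cannot
    # occur, but clip defensively against subnormal underflow.
    table["p_unbal"] = table["p_unbal"].clip(lower=np.nextafter(0, 1))
    table["p_bal"] = table["p_bal"].clip(lower=np.nextafter(0, 1))
    table["p_score"] = p_score(table["p_unbal"], table["p_bal"])
    toward_high = unbal["direction"].to_numpy() == high_stroma_direction
    table["stroma_direction"] = np.where(toward_high, "up", "down")
    order = np.lexsort((table["gene_id"].to_numpy(), table["p_score"].to_numpy()))
    return table.iloc[order].reset_index(drop=True)


def build_stroma_genesets(
    de_balanced: pd.DataFrame,
    de_unbalanced: pd.DataFrame,
    n_top: int = 1000,
    exclude: Iterable[str] = (),
    high_stroma_direction: str = "down",
    source: str = "",
) -> StromaGeneSets:
    """Build the top-``n_top`` stroma-up and stroma-down gene-sets.

    Genes are partitioned by the direction of their unbalanced shift toward
    the high-stroma group, each partition is sorted by ascending p_score,
    excluded genes (e.g. the pathway under study, to avoid circularity) are
    removed before truncation, and the top ``n_top`` per direction are
    retained.  Genes more significant balanced than unbalanced are not
    filtered, only down-ranked by the formula.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    excluded = tuple(dict.fromkeys(exclude))
    table = pscore_table(de_balanced, de_unbalanced, high_stroma_direction)
    table = table[~table["gene_id"].isin(excluded)]
    if table.empty:
        raise ValueError("no genes left after exclusion")
    sets: dict[str, GeneSet] = {}
    for direction in ("up", "down"):
        part = table[table["stroma_direction"] == direction]
        if part.empty:
            raise ValueError(f"no stroma-{direction} genes available")
        genes = tuple(part["gene_id"].head(n_top))
        label = source or "stroma"
        sets[direction] = GeneSet(
            f"{label}_{direction}",
            f"top {len(genes)} stroma-{direction} genes by p_score",
            genes,
        )
    return StromaGeneSets(sets["up"], sets["down"], n_top, excluded, source)
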