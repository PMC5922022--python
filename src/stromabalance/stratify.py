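"""Stratification of a cohort into stroma-balanced and unbalanced datasets.

Normal prostate samples systematically contain more stroma than cancer
samples (cancer samples carry a third tissue type), so a conventional
cancer-vs-normal contrast partly measures cancer-vs-stroma.  Stratification
counters this: the *balanced* dataset joins the cancer samples with the
highest stroma content to the normal samples with the lowest, matching the
groups' average stroma; the *unbalanced* dataset joins the complementary
halves, maximizing the stroma difference.  Both datasets have the same
cancer and normal group sizes, so p-values are directly comparable between
them gene by gene.

The stroma values driving the split may come from histopathology percentages
or from enrichment-score assessment; only the within-cohort ordering
matters, so any strictly increasing transform of the values yields the same
assignment.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["Stratification", "split_by_stroma", "split_high_low"]


@dataclasses.dataclass(frozen=True)
class Stratification:
    """Per-cohort assignment of samples to balanced and unbalanced datasets."""

    balanced_cancer: tuple[str, ...]
    balanced_normal: tuple[str, ...]
    unbalanced_cancer: tuple[str, ...]
    unbalanced_normal: tuple[str, ...]
    stroma_source: str = "histopathology"

    def __post_init__(self) -> None:
        if len(self.balanced_cancer) != len(self.unbalanced_cancer):
            raise ValueError("balanced and unbalanced cancer groups differ in size")
        if len(self.balanced_normal) != len(self.unbalanced_normal):
            raise ValueError("balanced and unbalanced normal groups differ in size")
        if set(self.balanced_cancer) & set(self.unbalanced_cancer):
            raise ValueError("cancer sample assigned to both datasets")
        if set(self.balanced_normal) & set(self.unbalanced_normal):
            raise ValueError("normal sample assigned to both datasets")

    @property
    def balanced(self) -> tuple[str, ...]:
        return self.balanced_cancer + self.balanced_normal

    @property
    def unbalanced(self) -> tuple[str, ...]:
        return self.unbalanced_cancer + self.unbalanced_normal

    def dataset_of(self) -> pd.Series:
        """sample_id -> dataset label ('balanced' / 'unbalanced')."""
        labels = {}
        for s in self.balanced:
            labels[s] = "balanced"
        for s in self.unbalanced:
            labels[s] = "unbalanced"
        return pd.Series(labels, name="dataset")

    def to_frame(self, all_samples=None) -> pd.DataFrame:
        """Tidy table (sample_id, dataset); unassigned samples -> 'excluded'."""
        assigned = self.dataset_of()
        if all_samples is None:
            all_samples = list(assigned.index)
        rows = [(s, assigned.get(s, "excluded")) for s in all_samples]
        return pd.DataFrame(rows, columns=["sample_id", "dataset"])


def _sorted_by_stroma(sample_ids: np.ndarray, stroma: np.ndarray, descending: bool) -> np.ndarray:
    """Sample ids sorted by stroma value, ties broken by sample id."""
    key = -stroma if descending else stroma
    order = np.lexsort((sample_ids, key))
    return sample_ids[order]


def _check_values(sample_ids, stroma_values: pd.Series) -> np.ndarray:
    vals = []
    for s in sample_ids:
        if s not in stroma_values.index or pd.isna(stroma_values[s]):
            raise ValueError(f"missing stroma value for sample {s!r}")
        vals.append(float(stroma_values[s]))
    return np.asarray(vals)


def split_by_stroma(
    annotation: pd.DataFrame,
    stroma_values: pd.Series,
    fraction: float = 0.5,
    stroma_source: str = "histopathology",
) -> Stratification:
    """Assign each class's high/low-stroma halves to balanced/unbalanced sets.

    Cancer samples are sorted by stroma content: the top half goes to the
    balanced dataset, the bottom half to the unbalanced one.  Normal samples
    are assigned the other way around.  With an odd class count the median
    sample is dropped so the two datasets keep equal group sizes.

    ``fraction`` (0 < fraction <= 0.5) sets the share of each class assigned
    to *each* dataset; samples between the two tails are excluded.  Stroma
    ties are broken by sample id.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    out: dict[str, tuple[str, ...]] = {}
    for cls in ("cancer", "normal"):
        ids = annotation.loc[annotation["class"] == cls, "sample_id"].to_numpy(dtype=object)
        if len(ids) < 2:
            raise ValueError(f"need >= 2 {cls} samples to stratify (got {len(ids)})")
        stroma = _check_values(ids, stroma_values)
        k = int(len(ids) * fraction)
        if k < 1:
            raise ValueError(f"fraction {fraction} selects no {cls} samples")
        ranked = _sorted_by_stroma(ids, stroma, descending=True)  # high stroma first
        high, low = ranked[:k], ranked[len(ranked) - k :]
        if cls == "cancer":
            out["balanced_cancer"] = tuple(sorted(high))
            out["unbalanced_cancer"] = tuple(sorted(low))
        else:
            out["balanced_normal"] = tuple(sorted(low))
            out["unbalanced_normal"] = tuple(sorted(high))
    return Stratification(stroma_source=stroma_source, **out)


def split_high_low(
    sample_ids,
    stroma_values: pd.Series,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Median-split one group of samples into (low, high) stroma halves.

    Used for cancer-only cohorts where no cancer-vs-normal contrast can be
    built.  With an odd count the median sample is dropped; when every
    stroma value ties, the split is deterministic by sample id and a warning
    is emitted.
    """
    ids = np.asarray(list(sample_ids), dtype=object)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples to split")
    stroma = _check_values(ids, stroma_values)
    if np.ptp(stroma) == 0:
        warnings.warn(
            "all stroma values tied; splitting deterministically by sample id",
            stacklevel=2,
        )
    k = len(ids) // 2
    ranked = _sorted_by_stroma(ids, stroma, descending=False)  # low stroma first
    low, high = ranked[:k], ranked[len(ranked) - k :]
    return tuple(sorted(low)), tuple(sorted(high))
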