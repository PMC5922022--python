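"""Synthetic prostate-tissue cohort generator.

Bulk prostate samples are modelled as convex mixtures of three latent tissue
expression profiles — cancer, stroma and benign epithelium.  Cancer samples
mix all three tissues; normal samples contain no cancer tissue and mix only
stroma and epithelium.  Normal samples draw systematically more stroma than
cancer samples (mean 0.50 vs 0.25 by default), reproducing the documented
sampling bias that confounds conventional cancer-vs-normal comparisons.

Latent profiles live on a log2 scale; mixing happens in linear scale (bulk
RNA from different tissue compartments adds physically in linear space) and
the mixture is logged again, then Gaussian noise and an optional
cohort-level baseline offset are added.

Planted gene classes
--------------------
``stroma_up`` / ``stroma_down``
    The stroma profile is shifted by +/- ``stroma_shift`` log2 units.
``cancer_de_down``
    The confounded cancer-vs-epithelium pattern: highly expressed in benign
    epithelium, intermediate in cancer, weakly expressed in stroma
    (profile shifts +``cancer_de_epi_shift`` / 0 / -``cancer_de_stroma_shift``).
``cancer_de_up``
    The mirrored pattern: weak in epithelium, intermediate in cancer,
    elevated in stroma (-``cancer_de_epi_shift`` / 0 /
    +``cancer_de_up_stroma_shift``).

The default gap magnitudes are chosen so that, at the default tissue-
fraction means, the stroma gradient approximately offsets the true
cancer-vs-epithelium difference in the pooled (unstratified) contrast:
planted cancer genes are genuinely hidden until the stroma content of the
compared groups is balanced, while remaining clearly detectable in a
stroma-balanced contrast at the default cohort size and noise level.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import ANNOTATION_COLUMNS, ExpressionMatrix

__all__ = [
    "TissueProfileConfig",
    "PlantedTruth",
    "generate_cohort",
    "generate_suite",
    "planted_de_table",
    "SyntheticCohort",
]

_TISSUES = ("cancer", "stroma", "epithelium")
_CLASSES = ("stroma_up", "stroma_down", "cancer_de_down", "cancer_de_up", "null")


@dataclasses.dataclass(frozen=True)
class TissueProfileConfig:
    """Generative settings for one synthetic cohort.

    Fractions of planted genes must sum to at most 1; stroma means encode
    the sampling bias and must satisfy ``mean_stroma_cancer <
    mean_stroma_normal``.  ``noise_sd`` is the SD of additive Gaussian noise
    on the log2 scale; ``baseline_shift`` is a constant cohort offset.
    """

    n_genes: int = 2000
    n_cancer_samples: int = 100
    n_normal_samples: int = 50
    frac_stroma_up: float = 0.10
    frac_stroma_down: float = 0.10
    frac_cancer_de: float = 0.10
    frac_cancer_de_up: float = 0.5  # share of cancer_de genes with the up-mirrored pattern
    mean_stroma_normal: float = 0.50
    mean_stroma_cancer: float = 0.25
    proportion_concentration: float = 10.0
    noise_sd: float = 0.5
    baseline_shift: float = 0.0
    seed: int = 0
    # effect sizes (log2)
    stroma_shift: float = 2.0
    cancer_de_epi_shift: float = 1.0
    cancer_de_stroma_shift: float = 2.0
    cancer_de_up_stroma_shift: float = 0.5
    base_mean: float = 7.0
    base_sd: float = 1.0
    cancer_tissue_share: float = 0.6  # share of the non-stroma fraction that is cancer tissue

    def validate(self) -> None:
        for name in (
            "frac_stroma_up",
            "frac_stroma_down",
            "frac_cancer_de",
            "frac_cancer_de_up",
            "mean_stroma_normal",
            "mean_stroma_cancer",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.frac_stroma_up + self.frac_stroma_down + self.frac_cancer_de > 1.0:
            raise ValueError("planted gene fractions sum to more than 1")
        if not 0.0 < self.mean_stroma_cancer < self.mean_stroma_normal < 1.0:
            raise ValueError(
                "need 0 < mean_stroma_cancer < mean_stroma_normal < 1 "
                "(the stroma sampling bias)"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_cancer_samples < 1 or self.n_normal_samples < 1:
            raise ValueError("both sample classes need at least one sample")
        for name in ("proportion_concentration",):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive real")
        for name in ("noise_sd", "base_sd"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("baseline_shift", "base_mean", "stroma_shift", "cancer_de_epi_shift",
                     "cancer_de_stroma_shift", "cancer_de_up_stroma_shift"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 < self.cancer_tissue_share < 1.0:
            raise ValueError("cancer_tissue_share must lie in (0, 1)")

    def replace(self, **kwargs) -> "TissueProfileConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping) -> "TissueProfileConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        cfg.validate()
        return cfg


@dataclasses.dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    gene_class: pd.Series  # gene id -> planted class
    tissue_fractions: pd.DataFrame  # sample x (cancer, stroma, epithelium)
    latent_profiles: pd.DataFrame  # gene x (cancer, stroma, epithelium), log2


@dataclasses.dataclass(frozen=True)
class SyntheticCohort:
    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    truth: PlantedTruth


def _draw_gene_classes_and_profiles(
    config: TissueProfileConfig, rng: np.random.Generator
) -> tuple[pd.Series, pd.DataFrame]:
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    n_up = round(config.frac_stroma_up * n)
    n_down = round(config.frac_stroma_down * n)
    n_cd = round(config.frac_cancer_de * n)
    n_cd_up = round(config.frac_cancer_de_up * n_cd)
    n_cd_down = n_cd - n_cd_up

    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    cursor = 0
    for cls, count in (
        ("stroma_up", n_up),
        ("stroma_down", n_down),
        ("cancer_de_down", n_cd_down),
        ("cancer_de_up", n_cd_up),
    ):
        labels[perm[cursor : cursor + count]] = cls
        cursor += count
    gene_class = pd.Series(labels, index=gene_ids, name="gene_class")

    base = rng.normal(config.base_mean, config.base_sd, size=n)
    profiles = pd.DataFrame(
        {t: base.copy() for t in _TISSUES}, index=gene_ids, columns=list(_TISSUES)
    )
    is_up = labels == "stroma_up"
    is_down = labels == "stroma_down"
    is_cdd = labels == "cancer_de_down"
    is_cdu = labels == "cancer_de_up"
    profiles.loc[is_up, "stroma"] += config.stroma_shift
    profiles.loc[is_down, "stroma"] -= config.stroma_shift
    profiles.loc[is_cdd, "epithelium"] += config.cancer_de_epi_shift
    profiles.loc[is_cdd, "stroma"] -= config.cancer_de_stroma_shift
    profiles.loc[is_cdu, "epithelium"] -= config.cancer_de_epi_shift
    profiles.loc[is_cdu, "stroma"] += config.cancer_de_up_stroma_shift
    return gene_class, profiles


def _draw_fractions(config: TissueProfileConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Dirichlet tissue fractions; normals carry exactly zero cancer tissue."""
    conc = config.proportion_concentration
    s_c = config.mean_stroma_cancer
    mean_cancer = np.array(
        [
            (1 - s_c) * config.cancer_tissue_share,
            s_c,
            (1 - s_c) * (1 - config.cancer_tissue_share),
        ]
    )
    frac_cancer = rng.dirichlet(conc * mean_cancer, size=config.n_cancer_samples)
    s_n = config.mean_stroma_normal
    frac_norm_2d = rng.dirichlet(conc * np.array([s_n, 1 - s_n]), size=config.n_normal_samples)
    frac_normal = np.column_stack(
        [np.zeros(config.n_normal_samples), frac_norm_2d[:, 0], frac_norm_2d[:, 1]]
    )
    sample_ids = [f"C{i:04d}" for i in range(config.n_cancer_samples)] + [
        f"N{i:04d}" for i in range(config.n_normal_samples)
    ]
    return pd.DataFrame(
        np.vstack([frac_cancer, frac_normal]), index=sample_ids, columns=list(_TISSUES)
    )


def _mix_expression(
    profiles: pd.DataFrame,
    fractions: pd.DataFrame,
    config: TissueProfileConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    linear = np.power(2.0, profiles.to_numpy(float))  # genes x tissues
    mixture = linear @ fractions.to_numpy(float).T  # genes x samples
    log_mix = np.log2(mixture)
    if config.noise_sd > 0:
        log_mix = log_mix + rng.normal(0.0, config.noise_sd, size=log_mix.shape)
    log_mix = log_mix + config.baseline_shift
    return pd.DataFrame(log_mix, index=profiles.index, columns=fractions.index)


def generate_cohort(
    config: TissueProfileConfig,
    cohort_id: str = "sim",
    _shared: tuple[pd.Series, pd.DataFrame] | None = None,
    _rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Generate one cohort: expression matrix, annotation, planted truth.

    Deterministic given the config (all randomness flows from
    ``config.seed``).  The annotation carries the true tissue fractions as
    histopathology percentages.
    """
    config.validate()
    rng = _rng if _rng is not None else np.random.default_rng(config.seed)
    gene_class, profiles = _shared if _shared is not None else _draw_gene_classes_and_profiles(config, rng)
    fractions = _draw_fractions(config, rng)
    fractions.index = [f"{cohort_id}_{s}" for s in fractions.index]
    expr = _mix_expression(profiles, fractions, config, rng)
    matrix = ExpressionMatrix(expr, cohort_id)
    ann = pd.DataFrame(
        {
            "sample_id": fractions.index,
            "class": ["cancer"] * config.n_cancer_samples + ["normal"] * config.n_normal_samples,
            "cohort_id": cohort_id,
            "stroma_pct": fractions["stroma"].to_numpy() * 100.0,
            "cancer_pct": fractions["cancer"].to_numpy() * 100.0,
            "epithelium_pct": fractions["epithelium"].to_numpy() * 100.0,
        }
    )[list(ANNOTATION_COLUMNS)]
    truth = PlantedTruth(gene_class, fractions, profiles)
    return SyntheticCohort(matrix, ann, truth)


def generate_suite(
    config: TissueProfileConfig,
    n_cohorts: int = 5,
    histopathology: Sequence[bool] | None = None,
    cohort_sizes: Sequence[tuple[int, int]] | None = None,
    baseline_shifts: Sequence[float] | None = None,
    cohort_ids: Sequence[str] | None = None,
) -> list[SyntheticCohort]:
    """Generate several cohorts sharing one set of latent tissue profiles.

    All cohorts plant the same genes with the same latent profiles (as if
    measuring the same biology on different platforms/populations) but draw
    their samples, noise and cohort baseline offsets independently.

    Parameters
    ----------
    histopathology
        Which cohorts keep their histopathology percentages in the
        annotation (others get them blanked, emulating public cohorts
        without histopathology).  Default: first two cohorts only.
    cohort_sizes
        Per-cohort (n_cancer, n_normal); default: the config's sizes.
    baseline_shifts
        Per-cohort constant offsets (emulating cohort baseline differences);
        default: 0.5 * (index - (n_cohorts-1)/2).
    """
    config.validate()
    if histopathology is None:
        histopathology = [i < 2 for i in range(n_cohorts)]
    if cohort_ids is None:
        cohort_ids = [f"cohort{i + 1}" for i in range(n_cohorts)]
    if baseline_shifts is None:
        baseline_shifts = [0.5 * (i - (n_cohorts - 1) / 2.0) for i in range(n_cohorts)]
    if not (len(histopathology) == len(cohort_ids) == len(baseline_shifts) == n_cohorts):
        raise ValueError("per-cohort argument lengths must equal n_cohorts")
    if cohort_sizes is not None and len(cohort_sizes) != n_cohorts:
        raise ValueError("cohort_sizes length must equal n_cohorts")

    master = np.random.default_rng(config.seed)
    shared = _draw_gene_classes_and_profiles(config, master)
    cohorts: list[SyntheticCohort] = []
    for i in range(n_cohorts):
        sizes = cohort_sizes[i] if cohort_sizes is not None else (
            config.n_cancer_samples,
            config.n_normal_samples,
        )
        sub = config.replace(
            n_cancer_samples=sizes[0],
            n_normal_samples=sizes[1],
            baseline_shift=baseline_shifts[i],
        )
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        cohort = generate_cohort(sub, cohort_ids[i], _shared=shared, _rng=rng)
        if not histopathology[i]:
            ann = cohort.annotation.copy()
            ann[["stroma_pct", "cancer_pct", "epithelium_pct"]] = np.nan
            cohort = SyntheticCohort(cohort.matrix, ann, cohort.truth)
        cohorts.append(cohort)
    return cohorts


#: Study design of the default five-cohort synthetic suite: two
#: histopathology cohorts sized like a radical-prostatectomy series with
#: full pathology review (116 cancer / 40 normal), three score-only cohorts
#: of 100/50.
DEFAULT_SUITE_COHORT_SIZES: tuple[tuple[int, int], ...] = (
    (116, 40),
    (116, 40),
    (100, 50),
    (100, 50),
    (100, 50),
)
#: Gene-set size ladder used when scoring the synthetic suite: the standard
#: full-scale ladder (100..500, 1000) scaled to the 2000-gene synthetic
#: universe and a 200-gene per-direction stroma set.
DEFAULT_SUITE_GSEA_SIZES: tuple[int, ...] = (20, 30, 40, 50, 60, 70, 80, 90, 100, 200)
#: Genes retained per stroma direction when deriving sets from the suite.
DEFAULT_SUITE_N_TOP: int = 200


def default_study_suite(seed: int = 0) -> list[SyntheticCohort]:
    """The standard five-cohort synthetic study used for end-to-end checks.

    Five cohorts share one set of latent profiles and planted gene classes;
    the first two carry histopathology, all five have cohort-specific
    baseline offsets.  All other settings are the
    :class:`TissueProfileConfig` defaults.
    """
    config = TissueProfileConfig(seed=seed)
    return generate_suite(
        config,
        n_cohorts=len(DEFAULT_SUITE_COHORT_SIZES),
        cohort_sizes=DEFAULT_SUITE_COHORT_SIZES,
    )


def write_suite(suite: Sequence[SyntheticCohort], out_dir) -> list[dict]:
    """Write a suite's matrices/annotations as TSV; return cohort spec dicts
    suitable for :class:`stromabalance.pipeline.CohortSpec`."""
    from pathlib import Path

    from .io import write_annotation, write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = []
    for cohort in suite:
        cid = cohort.matrix.cohort_id
        mat = out / f"{cid}_matrix.tsv"
        ann = out / f"{cid}_annotation.tsv"
        write_expression_matrix(cohort.matrix, mat)
        write_annotation(cohort.annotation, ann)
        has_histo = not cohort.annotation["stroma_pct"].isna().any()
        specs.append(
            {
                "cohort_id": cid,
                "matrix": str(mat),
                "annotation": str(ann),
                "histopathology": bool(has_histo),
            }
        )
    return specs


def planted_de_table(truth: PlantedTruth) -> pd.DataFrame:
    """One row per planted (non-null) gene with its true cancer-vs-epithelium
    direction, derived from the latent profiles ("down" when the epithelium
    profile exceeds the cancer profile, "flat" when they are equal)."""
    planted = truth.gene_class[truth.gene_class != "null"]
    diff = (
        truth.latent_profiles.loc[planted.index, "cancer"]
        - truth.latent_profiles.loc[planted.index, "epithelium"]
    )
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "gene_id": planted.index,
            "gene_class": planted.to_numpy(),
            "direction": direction,
        }
    ).reset_index(drop=True)
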