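"""End-to-end orchestration of the stroma-balancing workflow.

Steps, in order:

1. Stratify each histopathology cohort into balanced/unbalanced datasets
   from its pathologist-assessed stroma percentages.
2. Run the rank-based differential-expression test on both datasets.
3. Derive a stroma gene-set (top-N up and down by p_score) independently
   per histopathology cohort; gene-sets are never combined across cohorts.
4. Score every sample of every cohort for stroma content by single-sample
   enrichment on the shared gene universe.
5. Stratify every cohort (including the histopathology ones) into
   balanced/unbalanced datasets from the enrichment scores; cohorts with
   only cancer samples are split into high/low-stroma groups instead.
6. Per-cohort differential expression for the unstratified, balanced and
   unbalanced contrasts.
7. Merge the cohorts with both classes into one rank-normalized,
   mean-centered meta-matrix and run the pooled meta-DE for all three
   contrasts.
8. Validation: overlap of the independently derived stroma gene-sets
   against a random-draw baseline.

Every intermediate is written to the output directory as TSV/GMT; result
tables carry a header comment with the configuration hash, and re-running
with an identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .genesets import StromaGeneSets, build_stroma_genesets, pscore_table
from .meta import build_meta_matrix, meta_de
from .scoring import DEFAULT_SIZES, StromaScoreTable, stroma_score_cohort
from .stats import mann_whitney_de
from .stratify import Stratification, split_by_stroma, split_high_low
from .validate import overlap_report

__all__ = ["CohortSpec", "PipelineConfig", "PipelineResult", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("stromabalance")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """One cohort's input files and whether it carries histopathology."""

    cohort_id: str
    matrix: str
    annotation: str
    histopathology: bool = False


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    cohorts: tuple[CohortSpec, ...]
    out_dir: str
    n_top: int = 1000
    gsea_sizes: tuple[int, ...] = DEFAULT_SIZES
    exclude: str | None = None  # path to a one-gene-per-line exclusion list
    m_total: int | None = None  # default: union gene count over cohorts
    split_fraction: float = 0.5
    weighted: bool = True
    seed: int = 0
    geneset_cohort: str | None = None  # histo cohort whose set drives scoring
    overlap_n_top: int | None = None  # default: n_top
    n_random_draws: int = 50

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("pipeline needs at least one cohort")
        if not any(c.histopathology for c in self.cohorts):
            raise ValueError("at least one cohort must carry histopathology")
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ValueError("cohort ids must be unique")
        if list(self.gsea_sizes) != sorted(self.gsea_sizes):
            raise ValueError("gsea_sizes must be sorted ascending")
        for spec in self.cohorts:
            for p in (spec.matrix, spec.annotation):
                if not Path(p).exists():
                    raise FileNotFoundError(f"cohort {spec.cohort_id!r}: missing file {p}")
        if self.exclude is not None and not Path(self.exclude).exists():
            raise FileNotFoundError(f"exclusion list not found: {self.exclude}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    cohorts = tuple(CohortSpec(**c) for c in raw.pop("cohorts"))
    if "gsea_sizes" in raw:
        raw["gsea_sizes"] = tuple(int(k) for k in raw["gsea_sizes"])
    return PipelineConfig(cohorts=cohorts, **raw)


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    universe: list[str]
    genesets: dict[str, StromaGeneSets]
    pscore_tables: dict[str, pd.DataFrame]
    hp_stratifications: dict[str, Stratification]
    score_tables: dict[str, StromaScoreTable]
    stratifications: dict[str, Stratification]
    high_low: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]
    cohort_de: dict[str, dict[str, pd.DataFrame]]
    meta_de: dict[str, pd.DataFrame]
    overlap: list[dict]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _step(name: str, cohort: str | None = None):
    where = f"step {name!r}" + (f" (cohort {cohort!r})" if cohort else "")
    log.info("running %s", where)
    return where


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; see the module docstring for the steps."""
    config.validate()
    cfg_hash = config.config_hash()
    out = Path(config.out_dir)
    for sub in ("genesets", "scores", "stratification", "de", "meta", "validation"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    log.info("pipeline start: %d cohorts, config_hash=%s, seed=%d",
             len(config.cohorts), cfg_hash, config.seed)

    exclude: tuple[str, ...] = ()
    if config.exclude:
        exclude = tuple(
            line.strip()
            for line in Path(config.exclude).read_text(encoding="utf-8").splitlines()
            if line.strip()
        )

    # -- load inputs -------------------------------------------------------
    matrices: dict[str, sio.ExpressionMatrix] = {}
    annotations: dict[str, pd.DataFrame] = {}
    for spec in config.cohorts:
        where = _step("load", spec.cohort_id)
        try:
            m = sio.read_expression_matrix(spec.matrix, spec.cohort_id)
            ann = sio.read_annotation(spec.annotation)
            sio.validate_annotation(ann, m)
        except Exception as exc:
            raise RuntimeError(f"{where} failed: {exc}") from exc
        matrices[spec.cohort_id] = m
        annotations[spec.cohort_id] = ann
        log.info("cohort %s: %d genes x %d samples", spec.cohort_id, m.n_genes, m.n_samples)

    universe = sio.shared_genes(list(matrices.values()))
    union_genes = sorted(set().union(*[set(m.gene_ids) for m in matrices.values()]))
    m_total = config.m_total or len(union_genes)
    log.info("shared universe: %d genes; union: %d genes; m_total=%d",
             len(universe), len(union_genes), m_total)

    classes_of = {
        cid: ann.set_index("sample_id")["class"] for cid, ann in annotations.items()
    }

    # -- steps 1-3: histopathology stratification, DE, gene-sets -----------
    genesets: dict[str, StromaGeneSets] = {}
    pscores: dict[str, pd.DataFrame] = {}
    hp_strats: dict[str, Stratification] = {}
    for spec in config.cohorts:
        if not spec.histopathology:
            continue
        cid = spec.cohort_id
        where = _step("derive-stroma-genes", cid)
        try:
            ann = annotations[cid]
            histo = ann.set_index("sample_id")["stroma_pct"]
            strat = split_by_stroma(ann, histo, config.split_fraction, "histopathology")
            hp_strats[cid] = strat
            m = matrices[cid]
            cls = classes_of[cid]
            de_bal = mann_whitney_de(
                sio.ExpressionMatrix(m.data[list(strat.balanced)], cid), cls, m_total=m_total
            )
            de_unbal = mann_whitney_de(
                sio.ExpressionMatrix(m.data[list(strat.unbalanced)], cid), cls, m_total=m_total
            )
            pscores[cid] = pscore_table(de_bal, de_unbal)
            genesets[cid] = build_stroma_genesets(
                de_bal, de_unbal, config.n_top, exclude=exclude, source=cid
            )
        except Exception as exc:
            raise RuntimeError(f"{where} failed: {exc}") from exc
        sio.write_gmt(
            [genesets[cid].up, genesets[cid].down], out / "genesets" / f"{cid}_stroma.gmt"
        )
        _write_table(pscores[cid], out / "genesets" / f"{cid}_pscore.tsv", cfg_hash)
        sio.write_de_results(de_bal, out / "genesets" / f"{cid}_hp_balanced_de.tsv",
                             f"config_hash={cfg_hash}")
        sio.write_de_results(de_unbal, out / "genesets" / f"{cid}_hp_unbalanced_de.tsv",
                             f"config_hash={cfg_hash}")

    # -- step 4: enrichment scoring on the shared universe ------------------
    source_cid = config.geneset_cohort or next(
        c.cohort_id for c in config.cohorts if c.histopathology
    )
    if source_cid not in genesets:
        raise ValueError(f"geneset_cohort {source_cid!r} is not a histopathology cohort")
    active_sets = genesets[source_cid]
    scores: dict[str, StromaScoreTable] = {}
    for spec in config.cohorts:
        where = _step("score-stroma", spec.cohort_id)
        try:
            scores[spec.cohort_id] = stroma_score_cohort(
                matrices[spec.cohort_id], active_sets, config.gsea_sizes, universe
            )
        except Exception as exc:
            raise RuntimeError(f"{where} failed: {exc}") from exc
        _write_table(
            scores[spec.cohort_id].to_frame(),
            out / "scores" / f"{spec.cohort_id}.tsv",
            cfg_hash,
        )

    # -- step 5: score-based stratification ---------------------------------
    strats: dict[str, Stratification] = {}
    high_low: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for spec in config.cohorts:
        cid = spec.cohort_id
        where = _step("stratify", cid)
        try:
            ann = annotations[cid]
            score = scores[cid].stroma_score
            has_both = set(ann["class"]) == {"cancer", "normal"}
            if has_both:
                strats[cid] = split_by_stroma(ann, score, config.split_fraction, "gsea")
                table = strats[cid].to_frame(matrices[cid].sample_ids)
            else:
                low, high = split_high_low(ann["sample_id"], score)
                high_low[cid] = (low, high)
                labels = {s: "low_stroma" for s in low} | {s: "high_stroma" for s in high}
                table = pd.DataFrame(
                    {
                        "sample_id": matrices[cid].sample_ids,
                        "dataset": [labels.get(s, "excluded") for s in matrices[cid].sample_ids],
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"{where} failed: {exc}") from exc
        _write_table(table, out / "stratification" / f"{cid}.tsv", cfg_hash)

    # -- step 6: per-cohort DE ----------------------------------------------
    cohort_de: dict[str, dict[str, pd.DataFrame]] = {}
    for spec in config.cohorts:
        cid = spec.cohort_id
        if cid not in strats:
            continue
        where = _step("diffexpr", cid)
        try:
            m = matrices[cid]
            cls = classes_of[cid]
            strat = strats[cid]
            cohort_de[cid] = {
                "unstratified": mann_whitney_de(m, cls, m_total=m_total),
                "balanced": mann_whitney_de(
                    sio.ExpressionMatrix(m.data[list(strat.balanced)], cid), cls, m_total=m_total
                ),
                "unbalanced": mann_whitney_de(
                    sio.ExpressionMatrix(m.data[list(strat.unbalanced)], cid), cls, m_total=m_total
                ),
            }
        except Exception as exc:
            raise RuntimeError(f"{where} failed: {exc}") from exc
        for contrast, de in cohort_de[cid].items():
            sio.write_de_results(de, out / "de" / f"{cid}_{contrast}.tsv",
                                 f"config_hash={cfg_hash}")

    # -- step 7: meta-analysis ----------------------------------------------
    meta_cohorts = [
        (matrices[cid], classes_of[cid]) for cid in strats  # cohorts with both classes
    ]
    meta_results: dict[str, pd.DataFrame] = {}
    if meta_cohorts:
        where = _step("meta")
        try:
            meta = build_meta_matrix(meta_cohorts, weighted=config.weighted)
            contrasts = {
                "unstratified": None,
                "balanced": [s for cid in strats for s in strats[cid].balanced],
                "unbalanced": [s for cid in strats for s in strats[cid].unbalanced],
            }
            for name, samples in contrasts.items():
                meta_results[name] = meta_de(meta, samples, m_total=m_total)
        except Exception as exc:
            raise RuntimeError(f"{where} failed: {exc}") from exc
        for name, de in meta_results.items():
            sio.write_de_results(de, out / "meta" / f"{name}.tsv", f"config_hash={cfg_hash}")

    # -- step 8: gene-set overlap validation --------------------------------
    overlaps: list[dict] = []
    histo_ids = [c.cohort_id for c in config.cohorts if c.histopathology]
    if len(histo_ids) >= 2:
        where = _step("validate")
        rng = np.random.default_rng(config.seed)
        a, b = histo_ids[0], histo_ids[1]
        n_top = config.overlap_n_top or min(
            config.n_top, len(genesets[a].up), len(genesets[b].up)
        )
        for direction in ("up", "down"):
            ga = getattr(genesets[a], direction).genes
            gb = getattr(genesets[b], direction).genes
            rep = overlap_report(
                ga, gb, matrices[a].gene_ids, matrices[b].gene_ids,
                min(n_top, len(ga), len(gb)), config.n_random_draws, rng,
            )
            rep["direction"] = direction
            rep["cohort_a"], rep["cohort_b"] = a, b
            overlaps.append(rep)
        _write_table(pd.DataFrame(overlaps), out / "validation" / "overlap.tsv", cfg_hash)

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_cohorts": len(config.cohorts),
        "universe_size": len(universe),
        "union_genes": len(union_genes),
        "m_total": m_total,
        "geneset_cohort": source_cid,
        "cohort_samples": {cid: m.n_samples for cid, m in matrices.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline done: outputs in %s", out)

    return PipelineResult(
        config=config,
        universe=universe,
        genesets=genesets,
        pscore_tables=pscores,
        hp_stratifications=hp_strats,
        score_tables=scores,
        stratifications=strats,
        high_low=high_low,
        cohort_de=cohort_de,
        meta_de=meta_results,
        overlap=overlaps,
    )
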