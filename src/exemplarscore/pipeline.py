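"""End-to-end orchestration of the two analysis steps.

Step 1 (clinical): PESO prediction matrix → exemplar scores → quartile
strata → univariate best/poor characterization.  Step 2 (genomic): build
ALL / POOR / BEST subject conditions from the exemplar table, run stratified
cross-validated L2-logistic classification per condition, compare conditions
on fold-wise MCC, and run gene-set enrichment on the sign-consistent
coefficients of the BEST (and optionally POOR) condition.

The two steps share no features: Step 1 sees only clinical variables, Step 2
only SNP dosages; the exemplar table passes nothing between them except
subject ids, labels and stratum assignments.  A single global seed fans out
to per-stage substreams so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_compare import ComparisonResult, compare_strata, comparison_report
from .data_model import ClinicalDataset, GeneAnnotation, GeneSetCollection, GenotypeDataset
from .enrichment import (
    EnrichmentResult,
    enrichment_report,
    gene_scores,
    map_variants_to_genes,
    set_enrichment_test,
    sign_consistent_variants,
)
from .errors import ValidationError
from .exemplar import exemplar_score, stratify_quartiles, stratum_members, write_exemplar_table
from .genomic_classify import (
    ConditionComparison,
    FoldResults,
    coefficient_matrix,
    compare_conditions,
    stratified_kfold_eval,
)
from .peso import PesoConfig, PredictionMatrix, run_peso

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "peso", "compare", "genomic", "enrichment")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the protocol's stated settings."""

    n_trees: int = 100
    m_draws: int = 10
    k_neighbors: int = 5
    q: float = 0.25
    n_permutations: int = 10000
    k_folds: int = 10
    C: float = 1.0
    alpha: float = 0.05
    alpha_fdr: float = 0.05
    seed: int = 0
    stratum_scope: str = "within_subsample"  # or "inherited"
    enrich_conditions: tuple[str, ...] = ("BEST",)
    gene_score_statistic: str = "max"

    def __post_init__(self) -> None:
        if self.stratum_scope not in ("within_subsample", "inherited"):
            raise ValidationError("stratum_scope must be within_subsample or inherited")

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.seed), _STAGES.index(stage)])

    def stage_seed_int(self, stage: str) -> int:
        return int(self.stage_seed(stage).generate_state(1)[0] % 2**31)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ValidationError(f"config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "enrich_conditions" in payload:
            payload["enrich_conditions"] = tuple(payload["enrich_conditions"])
        return cls(**payload)

    def peso_config(self) -> PesoConfig:
        return PesoConfig(
            n_trees=self.n_trees, m_draws=self.m_draws,
            k_neighbors=self.k_neighbors, seed=self.stage_seed_int("peso"),
        )


@dataclass
class Step1Result:
    predictions: PredictionMatrix
    exemplar_table: pd.DataFrame
    comparisons_best: list[ComparisonResult]
    comparisons_poor: list[ComparisonResult]


@dataclass
class Step2Result:
    fold_results: dict[str, list[FoldResults]]
    comparison: ConditionComparison
    enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)


def run_manifest(config: PipelineConfig) -> dict:
    import pandas
    import sklearn

    return {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }


def run_step1(
    data: ClinicalDataset,
    config: PipelineConfig | None = None,
    subjects: pd.Index | None = None,
    compare: bool = True,
    outdir: str | Path | None = None,
) -> Step1Result:
    """PESO → exemplar scores → strata → univariate best/poor comparisons."""
    config = config or PipelineConfig()
    predictions = run_peso(data, config.peso_config(), subjects=subjects)
    table = stratify_quartiles(exemplar_score(predictions), q=config.q)
    best: list[ComparisonResult] = []
    poor: list[ComparisonResult] = []
    if compare:
        seeds = config.stage_seed("compare").spawn(2)
        best = compare_strata(data, table, "best", B=config.n_permutations,
                              alpha=config.alpha, seed=seeds[0])
        poor = compare_strata(data, table, "poor", B=config.n_permutations,
                              alpha=config.alpha, seed=seeds[1])
    result = Step1Result(predictions, table, best, poor)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        predictions.write(outdir / "prediction_matrix.tsv")
        write_exemplar_table(table, outdir / "exemplar_table.tsv")
        if compare:
            comparison_report(best).to_csv(outdir / "compare_best.tsv", sep="\t", index=False)
            comparison_report(poor).to_csv(outdir / "compare_poor.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(run_manifest(config), indent=1))
    return result


def build_conditions(
    exemplar_table: pd.DataFrame,
    genotyped_ids: pd.Index,
    config: PipelineConfig,
) -> dict[str, pd.Index]:
    """ALL / POOR / BEST genotyped subject sets.

    Under the default within-subsample scope, exemplar scores of the
    genotyped subjects are re-stratified into quartiles inside the subsample;
    under "inherited", the full-cohort stratum labels are reused.
    """
    missing = genotyped_ids.difference(exemplar_table.index)
    if len(missing):
        raise ValidationError(
            f"genotyped subjects absent from exemplar table: {list(missing[:10])}"
        )
    sub = exemplar_table.loc[genotyped_ids]
    if config.stratum_scope == "within_subsample":
        sub = stratify_quartiles(sub, q=config.q)
    return {
        "ALL": genotyped_ids,
        "POOR": stratum_members(sub, "POOR"),
        "BEST": stratum_members(sub, "BEST"),
    }


def run_step2(
    config: PipelineConfig,
    exemplar_table: pd.DataFrame,
    genotypes: GenotypeDataset,
    annotation: GeneAnnotation | None = None,
    gene_sets: GeneSetCollection | None = None,
    outdir: str | Path | None = None,
) -> Step2Result:
    """Condition-stratified genomic classification, comparison and enrichment."""
    genotyped_ids = pd.Index(genotypes.subject_ids)
    conditions = build_conditions(exemplar_table, genotyped_ids, config)
    labels = exemplar_table["y"].astype(int)

    seed = config.stage_seed_int("genomic")
    fold_results: dict[str, list[FoldResults]] = {}
    for name, ids in conditions.items():
        fold_results[name] = stratified_kfold_eval(
            genotypes, labels.loc[ids], name,
            k=config.k_folds, seed=seed, C=config.C,
        )
    comparison = compare_conditions(fold_results, alpha=config.alpha)

    enrichment: dict[str, list[EnrichmentResult]] = {}
    if annotation is not None and gene_sets is not None:
        for name in config.enrich_conditions:
            selection = sign_consistent_variants(coefficient_matrix(fold_results[name]))
            mapping = map_variants_to_genes(genotypes.variants, annotation)
            scores = gene_scores(selection, mapping, statistic=config.gene_score_statistic)
            if len(scores) < 2:
                logger.warning("condition %s: <2 scored genes, enrichment skipped", name)
                continue
            enrichment[name] = set_enrichment_test(
                scores, gene_sets, alpha_fdr=config.alpha_fdr
            )

    result = Step2Result(fold_results, comparison, enrichment)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_step2(result, config, outdir)
    return result


def _write_step2(result: Step2Result, config: PipelineConfig, outdir: Path) -> None:
    rows = []
    for name, folds in result.fold_results.items():
        for r in folds:
            rows.append({"condition": name, "fold": r.fold,
                         "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
                         **r.metrics})
    pd.DataFrame(rows).to_csv(outdir / "fold_metrics.tsv", sep="\t", index=False)
    summary = {
        "omnibus_h": result.comparison.omnibus_h,
        "omnibus_p": result.comparison.omnibus_p,
        "corrected_alpha": result.comparison.corrected_alpha,
        "pairwise": {f"{a}_vs_{b}": {"U": u, "p": p}
                     for (a, b), (u, p) in result.comparison.pairwise.items()},
        "summaries": result.comparison.summaries.to_dict(orient="records"),
    }
    (outdir / "comparison.json").write_text(json.dumps(summary, indent=1))
    for name, res in result.enrichment.items():
        enrichment_report(res).to_csv(
            outdir / f"enrichment_{name.lower()}.tsv", sep="\t", index=False
        )
    (outdir / "manifest.json").write_text(json.dumps(run_manifest(config), indent=1))
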