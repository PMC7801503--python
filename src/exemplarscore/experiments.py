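"""Replicate-level experiment drivers for the headline simulation studies.

These wrap the full pipeline — simulate a multi-site study, score clinical
exemplars with PESO, stratify the genotyped subsample, classify response from
genotypes per condition — into single calls that return the per-condition
summary numbers.  Both the acceptance checks and the analysis scripts drive
the pipeline through this module so the quantities they report are computed
identically.

Problem sizes: each replicate runs the generator's default study (6 sites ×
200 subjects, 30% genotyped, 500 SNPs).  Replicate studies use a single
marginalization draw per fit (m_draws = 1); at the default 5% missingness the
draw-to-draw variance is negligible and the saving makes replicate studies
tractable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exemplar import exemplar_score, stratify_quartiles
from .genomic_classify import fold_metric, stratified_kfold_eval
from .peso import PesoConfig, run_peso
from .pipeline import PipelineConfig, run_step2
from .synthetic_data import SimulationConfig, simulate_full_study


@dataclass
class HeadlineReplicate:
    """Per-condition medians from one full-pipeline replicate."""

    seed: int
    scenario: str
    median_auc: dict[str, float]
    median_mcc: dict[str, float]
    omnibus_p: float
    n_genotyped: int
    core_enrichment_best: float
    peso_leakage_violations: int

    @property
    def best_minus_poor_auc(self) -> float:
        return self.median_auc["BEST"] - self.median_auc["POOR"]

    @property
    def ordering_holds(self) -> bool:
        a = self.median_auc
        return a["BEST"] > a["ALL"] > a["POOR"]


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([int(seed), salt]).generate_state(1)[0] % 2**31)


def run_headline_replicate(
    seed: int,
    scenario: str = "concentrated",
    m_draws: int = 1,
    n_trees: int = 100,
) -> HeadlineReplicate:
    """One full replicate: simulate → PESO → stratify → genomic conditions.

    ``scenario`` is "concentrated" (SNP effects only in core subjects) or
    "uniform" (equal effects — the matched null).  Exemplar scores are
    computed for the genotyped subsample, whose strata Step 2 uses under the
    default within-subsample scope.
    """
    if scenario not in ("concentrated", "uniform"):
        raise ValueError(scenario)
    sim = SimulationConfig(seed=_derive_seed(seed, 1))
    if scenario == "uniform":
        sim = sim.uniform_null()
    clinical, genotypes, profiles = simulate_full_study(sim)
    genotyped = pd.Index(genotypes.subject_ids)

    peso_cfg = PesoConfig(n_trees=n_trees, m_draws=m_draws,
                          seed=_derive_seed(seed, 2))
    predictions = run_peso(clinical, peso_cfg, subjects=genotyped)
    table = stratify_quartiles(exemplar_score(predictions))

    pipe_cfg = PipelineConfig(seed=_derive_seed(seed, 3),
                              n_trees=n_trees, m_draws=m_draws)
    step2 = run_step2(pipe_cfg, table, genotypes)

    summaries = step2.comparison.summaries
    med = lambda cond, metric: float(
        summaries.query("condition == @cond and metric == @metric")["median"].iloc[0]
    )
    best_ids = table.index[table["stratum"].isin(["LRBest", "NRBest"])]
    core = profiles["L"]
    enrichment = (
        float(core.loc[best_ids].mean() / core.loc[genotyped].mean())
        if core.loc[genotyped].mean() > 0 else np.nan
    )
    return HeadlineReplicate(
        seed=seed,
        scenario=scenario,
        median_auc={c: med(c, "auc") for c in ("ALL", "POOR", "BEST")},
        median_mcc={c: med(c, "mcc") for c in ("ALL", "POOR", "BEST")},
        omnibus_p=step2.comparison.omnibus_p,
        n_genotyped=len(genotyped),
        core_enrichment_best=enrichment,
        peso_leakage_violations=predictions.audit.leakage_violations,
    )


def permuted_label_mcc(seed: int, n_permutations: int = 10, k: int = 10) -> float:
    """Mean fold MCC of genomic classification after label permutation.

    A leakage-free pipeline must score at chance (MCC ≈ 0) when the response
    labels are shuffled; returns the mean over folds and permutations on one
    default-size genotyped subsample.
    """
    sim = SimulationConfig(seed=_derive_seed(seed, 11))
    _clinical, genotypes, _profiles = simulate_full_study(sim)
    labels = _clinical.response.loc[genotypes.subject_ids].astype(int)
    rng = np.random.default_rng(_derive_seed(seed, 12))
    mccs = []
    for i in range(n_permutations):
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        results = stratified_kfold_eval(
            genotypes, shuffled, "NULL", k=k, seed=_derive_seed(seed, 13 + i)
        )
        mccs.extend(fold_metric(results, "mcc"))
    return float(np.mean(mccs))
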