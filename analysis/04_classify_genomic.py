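#!/usr/bin/env python
"""Exemplar-stratified genomic classification of lithium response.

Restricts to the genotyped subsample, re-stratifies its exemplar scores into
within-subsample quartiles, and classifies response from SNP dosages with
L2 logistic regression (C=1) under stratified 10-fold cross-validation in
three conditions: ALL genotyped subjects, the POOR exemplars, and the BEST
exemplars.  Reports median (IQR) MCC and ROC-AUC per condition with the
Kruskal–Wallis / Mann–Whitney comparison, and writes fold-level metrics,
the comparison JSON, and per-fold coefficient matrices for the enrichment
stage.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from exemplarscore.data_model import read_genotypes_tsv
from exemplarscore.exemplar import read_exemplar_table
from exemplarscore.genomic_classify import coefficient_matrix
from exemplarscore.pipeline import PipelineConfig, run_step2

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=4)
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--step1dir", type=Path, default=Path("results/step1"))
parser.add_argument("--outdir", type=Path, default=Path("results/step2"))
args = parser.parse_args()

genotypes = read_genotypes_tsv(args.datadir / "dosages.tsv", args.datadir / "variants.tsv")
table = read_exemplar_table(args.step1dir / "exemplar_table.tsv")

config = PipelineConfig(seed=args.seed)
result = run_step2(config, table, genotypes, outdir=args.outdir)

summary = result.comparison.summaries
for metric in ("mcc", "auc"):
    rows = summary[summary["metric"] == metric]
    pretty = ", ".join(
        f"{r.condition} {r.median:.2f} [{r.iqr_low:.2f}, {r.iqr_high:.2f}]"
        for r in rows.itertuples()
    )
    print(f"median {metric.upper()} (IQR): {pretty}")
print(f"Kruskal-Wallis on fold MCC: H = {result.comparison.omnibus_h:.2f}, "
      f"p = {result.comparison.omnibus_p:.4f}")
for (a, b), (u, p) in result.comparison.pairwise.items():
    flag = "*" if p < result.comparison.corrected_alpha else ""
    print(f"  {a} vs {b}: U = {u:.0f}, p = {p:.4f}{flag}")

for condition, folds in result.fold_results.items():
    cm = coefficient_matrix(folds)
    cm.to_csv(args.outdir / f"coefficients_{condition.lower()}.tsv", sep="\t")
print(f"fold metrics, comparison and coefficients -> {args.outdir}/")
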