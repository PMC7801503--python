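"""Sign-consistent variant selection, nearest-gene mapping, gene-set enrichment.

Variants whose logistic-regression coefficients keep one strict sign across
every cross-validation fold are treated as stably informative.  Each selected
variant is mapped to its nearest gene (containment first, then minimal
base-pair distance on the same chromosome); each gene's score is the largest
absolute mean coefficient among its selected variants.  Gene sets are then
tested for enrichment with a one-sided Mann–Whitney U comparing member vs
non-member gene scores (exact for small products without ties, tie-corrected
normal approximation otherwise), with Benjamini–Hochberg FDR control across
the tested sets at q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import GeneAnnotation, GeneSetCollection
from .errors import ValidationError

logger = logging.getLogger(__name__)

EXACT_PRODUCT_LIMIT = 400  # exact Mann–Whitney when n_member * n_nonmember <= this


@dataclass
class VariantSelection:
    variant_id: str
    fold_coefficients: np.ndarray
    selected: bool
    summary_coefficient: float  # mean over folds


@dataclass
class EnrichmentResult:
    set_id: str
    n_members_scored: int
    u_statistic: float
    p: float
    q: float = np.nan
    significant: bool = False


def sign_consistent_variants(fold_coefficients: pd.DataFrame) -> list[VariantSelection]:
    """Select variants whose coefficients share one strict sign in all folds.

    ``fold_coefficients`` is folds × variants.  An exact zero in any fold
    breaks consistency (a zero carries no sign).
    """
    if fold_coefficients.shape[0] < 2:
        raise ValidationError("sign consistency needs >= 2 folds")
    values = fold_coefficients.to_numpy(dtype=float)
    all_pos = (values > 0).all(axis=0)
    all_neg = (values < 0).all(axis=0)
    selected = all_pos | all_neg
    means = values.mean(axis=0)
    return [
        VariantSelection(vid, values[:, j].copy(), bool(selected[j]), float(means[j]))
        for j, vid in enumerate(fold_coefficients.columns)
    ]


def map_variants_to_genes(
    variants: pd.DataFrame,
    annotation: GeneAnnotation,
) -> dict[str, str]:
    """Nearest-gene assignment for each variant (variant_id → gene_id).

    ``variants`` needs columns variant_id / chrom / pos (1-based).  A variant
    inside a gene's [start, end) interval maps to that gene; otherwise to the
    gene at minimal distance d = max(0, start − pos, pos − end) on the same
    chromosome, ties broken by smaller gene start then lexicographic gene_id.
    Variants on chromosomes absent from the annotation are left unmapped
    (logged).
    """
    genes_by_chrom = {
        str(chrom): g.sort_values(["start", "gene_id"]).reset_index(drop=True)
        for chrom, g in annotation.genes.groupby("chrom")
    }
    mapping: dict[str, str] = {}
    for row in variants.itertuples():
        chrom = str(row.chrom)
        genes = genes_by_chrom.get(chrom)
        if genes is None:
            logger.warning("variant %s: chromosome %s absent from annotation",
                           row.variant_id, chrom)
            continue
        pos = int(row.pos)
        pos0 = pos - 1  # VCF 1-based -> annotation 0-based frame
        inside = genes[(genes["start"] <= pos0) & (pos0 < genes["end"])]
        if len(inside):
            pick = inside.sort_values(["start", "gene_id"]).iloc[0]
        else:
            d = np.maximum(0, np.maximum(genes["start"] - pos, pos - genes["end"]))
            order = genes.assign(_d=d).sort_values(["_d", "start", "gene_id"])
            pick = order.iloc[0]
        mapping[row.variant_id] = pick["gene_id"]
    return mapping


def gene_scores(
    selection: list[VariantSelection],
    mapping: dict[str, str],
    statistic: str = "max",
) -> dict[str, float]:
    """Gene score from its selected variants' |mean coefficient| (max or mean)."""
    if statistic not in ("max", "mean"):
        raise ValidationError("statistic must be 'max' or 'mean'")
    per_gene: dict[str, list[float]] = {}
    for v in selection:
        if not v.selected or v.variant_id not in mapping:
            continue
        per_gene.setdefault(mapping[v.variant_id], []).append(abs(v.summary_coefficient))
    agg = max if statistic == "max" else (lambda xs: sum(xs) / len(xs))
    return {gene: float(agg(xs)) for gene, xs in per_gene.items()}


def _mannwhitney_greater(members: np.ndarray, others: np.ndarray) -> tuple[float, float]:
    """One-sided (members rank higher) U test; exact when small and tie-free."""
    use_exact = (
        len(members) * len(others) <= EXACT_PRODUCT_LIMIT
        and len(np.unique(np.concatenate([members, others])))
        == len(members) + len(others)
    )
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(members, others, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def set_enrichment_test(
    scores: dict[str, float],
    sets: GeneSetCollection,
    alpha_fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Rank-based enrichment of each gene set among the scored genes.

    For each set with at least one scored member and one scored non-member, a
    one-sided Mann–Whitney U asks whether member scores rank above
    non-member scores; BH-FDR is applied across the tested sets.
    """
    if len(scores) < 2:
        raise ValidationError("enrichment needs >= 2 scored genes")
    universe = pd.Series(scores, dtype=float)
    results: list[EnrichmentResult] = []
    for set_id, (_desc, members) in sets.items():
        member_mask = universe.index.isin(members)
        n_members = int(member_mask.sum())
        n_others = int((~member_mask).sum())
        if n_members == 0 or n_others == 0:
            logger.warning("gene set %s skipped (%d scored members, %d non-members)",
                           set_id, n_members, n_others)
            continue
        u, p = _mannwhitney_greater(
            universe[member_mask].to_numpy(), universe[~member_mask].to_numpy()
        )
        results.append(EnrichmentResult(set_id, n_members, u, p))
    if results:
        q = bh_fdr([r.p for r in results])
        for r, qv in zip(results, q):
            r.q = float(qv)
            r.significant = bool(qv < alpha_fdr)
    return results


def enrichment_report(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"set_id": r.set_id, "n": r.n_members_scored, "U": r.u_statistic,
         "p": r.p, "q": r.q, "significant": r.significant}
        for r in results
    ])
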