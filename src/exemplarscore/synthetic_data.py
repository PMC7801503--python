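"""Synthetic multi-site clinical and genotype data with latent exemplar structure.

The generator emulates the study design the pipeline targets: a multi-centre
clinical cohort of lithium-treated bipolar-disorder patients whose
feature–response relationship is heterogeneous across sites, plus a genotyped
subsample in which SNP effects are concentrated in a latent "classical
phenotype" subgroup.

Generative model
----------------
Each subject carries a site label, a binary response ``y`` (per-site responder
prevalence), and a latent binary core indicator ``L`` (probability
``core_fraction``).  Latent feature vectors are standard normal with a
class-dependent mean shift:

* core subjects (L = 1) are shifted along one *shared* direction
  (``core_alignment`` · sign(y)), so every site's classifier places them on
  the same side of its boundary;
* non-core subjects are shifted along a *site-specific* direction (the shared
  weight vector plus a site perturbation of magnitude ``site_effect_sd``), so
  their features predict response mostly under their own site's model.

Both the shared effect and the site perturbations are *sparse* (roughly a
quarter of the features each, unit weights of random sign): clinical
prediction is typically carried by a handful of informative variables, and
sparse axis-aligned structure is what tree ensembles can actually recover.

Equivalently (Gaussian class-conditionals, shared covariance), each site's
response is logistic in its own weight vector shared_effect + perturbation.
Half of the latent coordinates are released as continuous variables; the rest
are discretised into binary / three-level categorical / five-level ordinal
variables so both imputation branches downstream are exercised.  Missingness
is completely at random at ``missing_rate``.

Genotypes are independent biallelic SNPs, dosage ~ Binomial(2, MAF).  For the
``n_causal`` causal SNPs each subject's dosage is redrawn from an allele
frequency tilted on the logit scale by ±β/2, where β is ``causal_effect`` for
core subjects and ``causal_effect_noncore`` otherwise — the "concentrated"
scenario has the latter at 0, the "uniform" null sets both equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ClinicalDataset, DataDictionary, GenotypeDataset, Variable
from .errors import ValidationError

_CAT3 = ["A", "B", "C"]
_BIN = ["no", "yes"]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults are the generator's canonical conditions: 6 sites of 200
    subjects, 34.7% responder prevalence, 20 mixed-type clinical features,
    35% core subjects, 5% MCAR missingness, and a genotyped subsample of 30%
    with 500 SNPs of which 40 are causal only in core subjects.
    """

    n_sites: int = 6
    site_sizes: Sequence[int] | int = 200
    responder_prevalence: Sequence[float] | float = 0.347
    n_clinical_features: int = 20
    shared_effect: Sequence[float] | None = None
    site_effect_sd: float = 3.0
    core_fraction: float = 0.35
    core_alignment: float = 3.0
    noncore_alignment: float | None = None  # defaults to core_alignment
    missing_rate: float = 0.05
    n_snps: int = 500
    n_causal: int = 40
    causal_effect: float = 2.0
    causal_effect_noncore: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    genotyped_fraction: float = 0.3
    genotyped_sites: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_clinical_features < 1 or self.n_snps < 1:
            raise ValidationError("counts must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValidationError("n_causal must lie in [0, n_snps]")
        for p in (*np.atleast_1d(self.responder_prevalence),
                  self.core_fraction, self.missing_rate, self.genotyped_fraction):
            if not 0.0 <= float(p) <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi < 1")

    @property
    def sizes(self) -> list[int]:
        if np.isscalar(self.site_sizes):
            return [int(self.site_sizes)] * self.n_sites
        sizes = [int(s) for s in self.site_sizes]
        if len(sizes) != self.n_sites:
            raise ValidationError("site_sizes length must equal n_sites")
        return sizes

    @property
    def prevalences(self) -> list[float]:
        if np.isscalar(self.responder_prevalence):
            return [float(self.responder_prevalence)] * self.n_sites
        prevs = [float(p) for p in self.responder_prevalence]
        if len(prevs) != self.n_sites:
            raise ValidationError("responder_prevalence length must equal n_sites")
        return prevs

    def uniform_null(self) -> "SimulationConfig":
        """The matched null in which SNP effects are equal in core and non-core."""
        return replace(self, causal_effect_noncore=self.causal_effect)


@dataclass
class LatentProfile:
    """Per-subject latent state: the core indicator and realized genetic tilt."""

    subject_id: str
    L: int
    genetic_liability: float = 0.0


def _feature_plan(d: int) -> list[tuple[str, str]]:
    """Deterministic type mix: alternating continuous and discrete variables.

    Produces 50% continuous, with the remainder split between binary,
    three-level categorical and five-level ordinal.
    """
    plan: list[tuple[str, str]] = []
    discrete_cycle = ["binary", "categorical", "ordinal", "binary", "categorical"]
    j = 0
    for i in range(d):
        if i % 2 == 0:
            plan.append((f"x{i:03d}", "continuous"))
        else:
            plan.append((f"x{i:03d}", discrete_cycle[j % len(discrete_cycle)]))
            j += 1
    return plan


def _build_dictionary(plan: list[tuple[str, str]]) -> DataDictionary:
    variables = []
    for name, vartype in plan:
        if vartype == "continuous":
            variables.append(Variable(name, "continuous", None))
        elif vartype == "ordinal":
            variables.append(Variable(name, "ordinal", (0, 4)))
        elif vartype == "binary":
            variables.append(Variable(name, "binary", _BIN))
        else:
            variables.append(Variable(name, "categorical", _CAT3))
    return DataDictionary(variables)


def _discretize(z: np.ndarray, vartype: str) -> np.ndarray:
    if vartype == "binary":
        return np.where(z > 0, _BIN[1], _BIN[0])
    if vartype == "categorical":
        return np.asarray(_CAT3)[np.digitize(z, [-0.6, 0.6])]
    if vartype == "ordinal":
        return np.clip(np.digitize(z, [-1.2, -0.4, 0.4, 1.2]), 0, 4).astype(float)
    raise ValueError(vartype)


def _sparse_effect(d: int, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Sparse weight vector: ~d/4 features carry unit weights of random sign."""
    if scale == 0:
        return np.zeros(d)
    k = max(2, d // 4)
    w = np.zeros(d)
    idx = rng.choice(d, size=min(k, d), replace=False)
    w[idx] = scale * rng.choice([-1.0, 1.0], size=len(idx))
    return w


def simulate_multisite_clinical(
    config: SimulationConfig,
) -> tuple[ClinicalDataset, pd.DataFrame]:
    """Generate the clinical cohort; returns the dataset and latent profiles.

    The profile table is indexed by subject_id with columns ``L`` (core
    indicator) and ``genetic_liability`` (0 until genotypes are simulated).
    Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence([int(config.seed), 0x51])
    rng_global, rng_sites = [np.random.default_rng(s) for s in root.spawn(2)]
    d = config.n_clinical_features
    plan = _feature_plan(d)
    dictionary = _build_dictionary(plan)

    if config.shared_effect is not None:
        w_shared = np.asarray(config.shared_effect, dtype=float)
        if w_shared.shape != (d,):
            raise ValidationError("shared_effect length must equal n_clinical_features")
    else:
        w_shared = _sparse_effect(d, rng_global, 1.0)
    u_shared = w_shared / np.linalg.norm(w_shared)
    noncore_scale = (
        config.core_alignment if config.noncore_alignment is None
        else config.noncore_alignment
    )

    frames, profiles = [], []
    for s, (size, prev) in enumerate(zip(config.sizes, config.prevalences)):
        rng = rng_sites
        site_name = f"site{s + 1}"
        w_site = w_shared + _sparse_effect(d, rng, config.site_effect_sd)
        u_site = w_site / np.linalg.norm(w_site)

        for attempt in range(20):
            y = (rng.random(size) < prev).astype(int)
            if 0 < y.sum() < size or size == 1:
                break
        else:
            raise ValidationError(
                f"site {site_name}: could not generate both classes in 20 attempts"
            )
        L = (rng.random(size) < config.core_fraction).astype(int)
        z = rng.normal(size=(size, d))
        sign = (2 * y - 1)[:, None]
        shift = np.where(
            L[:, None] == 1,
            config.core_alignment * sign * u_shared[None, :],
            noncore_scale * sign * u_site[None, :],
        )
        z = z + shift

        sids = [f"S{s + 1}-{i + 1:04d}" for i in range(size)]
        cols: dict[str, np.ndarray] = {}
        for j, (name, vartype) in enumerate(plan):
            cols[name] = z[:, j] if vartype == "continuous" else _discretize(z[:, j], vartype)
        frame = pd.DataFrame(cols, index=pd.Index(sids, name="subject_id"))

        alda = np.where(
            y == 1,
            7 + rng.binomial(3, 0.5, size),
            np.minimum(6, rng.binomial(8, 0.35, size)),
        )
        frame.insert(0, "response", y)
        frame.insert(0, "alda_total", alda.astype(float))
        frame.insert(0, "site", site_name)

        if config.missing_rate > 0:
            mask = rng.random((size, d)) < config.missing_rate
            for j, (name, _vt) in enumerate(plan):
                col = frame[name].astype(object)
                col[mask[:, j]] = np.nan
                frame[name] = (
                    col.astype(float) if dictionary[name].is_numeric else col
                )

        frames.append(frame)
        profiles.append(pd.DataFrame(
            {"L": L, "genetic_liability": 0.0},
            index=pd.Index(sids, name="subject_id"),
        ))

    subjects = pd.concat(frames)
    profile_table = pd.concat(profiles)
    return ClinicalDataset(subjects, dictionary), profile_table


def simulate_genotypes(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    responses: pd.Series,
) -> GenotypeDataset:
    """Generate SNP dosages for the subjects in ``profiles``.

    Dosages are Binomial(2, MAF) draws; at causal SNPs each subject's dosage
    is redrawn from a logit-tilted allele frequency (±β/2 by response class),
    with β depending on the subject's core status.  Deterministic given
    ``config.seed``.
    """
    if not profiles.index.equals(responses.index):
        raise ValidationError("profiles and responses must cover the same subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x6E]))
    n, m = len(profiles), config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    beta = np.where(
        profiles["L"].to_numpy() == 1,
        config.causal_effect,
        config.causal_effect_noncore,
    )
    sign = 2 * responses.to_numpy(dtype=float) - 1
    tilt = (beta * sign)[:, None] / 2.0  # per-subject logit shift at causal SNPs
    if len(causal_idx):
        logit_maf = np.log(maf[causal_idx] / (1 - maf[causal_idx]))
        p = 1.0 / (1.0 + np.exp(-(logit_maf[None, :] + tilt)))
        dosages[:, causal_idx] = rng.binomial(2, p)

    variants = pd.DataFrame({
        "variant_id": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": (np.arange(m) % 22 + 1).astype(str),
        "pos": (np.arange(m) // 22 + 1) * 1000 + 1,
        "ref": "A",
        "alt": "G",
    })
    dosage_df = pd.DataFrame(
        dosages, index=profiles.index.copy(), columns=list(variants["variant_id"])
    )
    geno = GenotypeDataset(variants, dosage_df)
    geno.causal_variant_ids = [variants["variant_id"].iloc[j] for j in causal_idx]
    return geno


def simulate_full_study(
    config: SimulationConfig,
) -> tuple[ClinicalDataset, GenotypeDataset, pd.DataFrame]:
    """Clinical cohort plus a genotyped subsample drawn from selected sites.

    The genotyped subsample is a simple random draw of ``genotyped_fraction``
    of the subjects belonging to ``genotyped_sites`` (all sites by default).
    The returned profile table gains a boolean ``genotyped`` column and the
    realized per-subject genetic tilt in ``genetic_liability``.
    """
    clinical, profiles = simulate_multisite_clinical(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x75]))

    eligible = clinical.subjects.index
    if config.genotyped_sites is not None:
        keep = clinical.site.isin(list(config.genotyped_sites))
        eligible = clinical.subjects.index[keep]
    n_geno = int(round(config.genotyped_fraction * len(eligible)))
    chosen = np.sort(rng.choice(len(eligible), size=n_geno, replace=False))
    geno_ids = eligible[chosen]

    geno_profiles = profiles.loc[geno_ids]
    responses = clinical.response.loc[geno_ids].astype(float)
    genotypes = simulate_genotypes(geno_profiles, config, responses)

    profiles = profiles.copy()
    profiles["genotyped"] = profiles.index.isin(geno_ids)
    beta = np.where(
        profiles["L"] == 1, config.causal_effect, config.causal_effect_noncore
    )
    sign = 2 * clinical.response.reindex(profiles.index).to_numpy(dtype=float) - 1
    profiles["genetic_liability"] = np.where(
        profiles["genotyped"], beta * sign, 0.0
    )
    return clinical, genotypes, profiles


def simulate_gene_annotation(genotypes: GenotypeDataset) -> "GeneAnnotation":
    """Synthetic gene annotation tiling the synthetic variant coordinates.

    Each chromosome present in the variant map is tiled with 1-kb genes
    ([k·1000+500, (k+1)·1000+500) in 0-based half-open coordinates) so every
    synthetic variant falls inside exactly one gene.  This is a synthetic
    stand-in for a real annotation, usable only with the synthetic variant
    grid.
    """
    from .data_model import GeneAnnotation

    rows = []
    for chrom, group in genotypes.variants.groupby("chrom"):
        max_tile = int((group["pos"].max() - 1) // 1000)
        for k in range(-1, max_tile + 1):
            start = k * 1000 + 500
            if start < 0:
                start = 0
            rows.append({"gene_id": f"G{chrom}_{k + 1}", "chrom": str(chrom),
                         "start": start, "end": (k + 1) * 1000 + 500})
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_gene_sets(
    annotation,
    target_genes: Sequence[str],
    n_sets: int = 20,
    set_size: int = 15,
    seed: int = 0,
) -> "GeneSetCollection":
    """Random gene sets plus one set concentrated on ``target_genes``.

    The first set (``SET_TARGET``) holds the target genes padded with random
    fillers; the remaining sets are uniform draws from the annotation, giving
    the enrichment stage a planted positive and a null background.
    """
    from .data_model import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = list(annotation.genes["gene_id"])
    target = list(dict.fromkeys(target_genes))
    sets: dict[str, tuple[str, list[str]]] = {}
    fillers = [g for g in universe if g not in target]
    pad = list(rng.choice(fillers, size=max(0, set_size - len(target)), replace=False))
    sets["SET_TARGET"] = ("planted causal pathway", target + pad)
    for i in range(1, n_sets):
        members = list(rng.choice(universe, size=min(set_size, len(universe)), replace=False))
        sets[f"SET{i:03d}"] = (f"random set {i}", members)
    return GeneSetCollection(sets)
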