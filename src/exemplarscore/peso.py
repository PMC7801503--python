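"""Predict-every-subject-out (PESO): one out-of-sample prediction per site model.

For each site the protocol (i) runs leave-one-out cross-validation within the
site so its own subjects get out-of-sample predictions, then (ii) trains on
the full site and predicts every other site's subjects.  Every subject thus
receives one predicted probability of lithium response from each site's
classifier, with their own record never present in any training set used to
predict them.

The classifier is a random forest (100 trees by default, no hyperparameter
search).  Inside every fit the training partition is completed by
marginalization (M draws) and rebalanced with SMOTE–Tomek; the held-out or
cross-site subjects are completed using the *training* partition's observed
ranges, and predicted probabilities are averaged over the M draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .data_model import ClinicalDataset
from .errors import ValidationError
from .preprocess import FeatureEncoder, marginalize_missing, smote_tomek

logger = logging.getLogger(__name__)


@dataclass
class PesoConfig:
    n_trees: int = 100
    m_draws: int = 10
    k_neighbors: int = 5
    seed: int = 0


@dataclass
class PesoAudit:
    """Leakage bookkeeping: every fit asserts its targets are outside training."""

    n_fits: int = 0
    n_predictions: int = 0
    leakage_violations: int = 0
    skipped_sites: list[str] = field(default_factory=list)


@dataclass
class PredictionMatrix:
    """Subjects × site-models matrix of out-of-sample responder probabilities."""

    probabilities: pd.DataFrame  # index subject_id, one column per site model
    y: pd.Series
    site_of_origin: pd.Series
    audit: PesoAudit = field(default_factory=PesoAudit)

    def __post_init__(self) -> None:
        values = self.probabilities.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("prediction matrix has missing entries")
        if ((values < 0) | (values > 1)).any():
            raise ValidationError("predicted probabilities must lie in [0, 1]")

    def write(self, path) -> None:
        out = self.probabilities.copy()
        out.insert(0, "y", self.y)
        out.insert(0, "site", self.site_of_origin)
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "PredictionMatrix":
        df = pd.read_csv(path, sep="\t").set_index("subject_id")
        return cls(
            probabilities=df.drop(columns=["site", "y"]),
            y=df["y"].astype(int),
            site_of_origin=df["site"],
        )


def fit_site_model(
    X: np.ndarray, y: np.ndarray, n_trees: int = 100, seed=None
) -> RandomForestClassifier:
    """Fit the fixed-specification random forest (no hyperparameter search)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    rs = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    model = RandomForestClassifier(n_estimators=n_trees, random_state=rs, n_jobs=1)
    model.fit(X, y)
    return model


def _positive_proba(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return proba[:, classes.index(1)]


def _fit_predict(
    train_features: pd.DataFrame,
    train_y: np.ndarray,
    target_features: pd.DataFrame,
    data: ClinicalDataset,
    config: PesoConfig,
    seed_seq: np.random.SeedSequence,
    audit: PesoAudit,
) -> np.ndarray:
    """Average predicted responder probability over M marginalization draws.

    Target rows are completed using the training partition's observed ranges;
    their ids are asserted disjoint from training (leakage audit).
    """
    overlap = train_features.index.intersection(target_features.index)
    if len(overlap):
        audit.leakage_violations += len(overlap)
        raise ValidationError(f"target subjects present in training set: {list(overlap)}")

    encoder = FeatureEncoder(data.dictionary, list(train_features.columns))
    seeds = seed_seq.spawn(config.m_draws)
    total = np.zeros(len(target_features))
    for m in range(config.m_draws):
        rng = np.random.default_rng(seeds[m])
        train_draw = marginalize_missing(
            train_features, data.dictionary, 1, rng.spawn(1)[0]
        )[0].frame
        target_draw = marginalize_missing(
            target_features, data.dictionary, 1, rng.spawn(1)[0],
            reference=train_features,
        )[0].frame
        X_train = encoder.transform(train_draw)
        if np.unique(train_y, return_counts=True)[1].min() >= 2:
            X_bal, y_bal = smote_tomek(
                X_train, train_y, k_neighbors=config.k_neighbors,
                seed=rng.spawn(1)[0],
            )
            X_bal = encoder.harden(X_bal)
        else:
            # a singleton minority (e.g. LOO on a 2-per-class site) cannot be
            # SMOTE-rebalanced; train on the raw partition instead
            X_bal, y_bal = X_train, train_y
        model = fit_site_model(
            X_bal, y_bal, n_trees=config.n_trees, seed=rng.spawn(1)[0],
        )
        audit.n_fits += 1
        total += _positive_proba(model, encoder.transform(target_draw))
    audit.n_predictions += len(target_features)
    return total / config.m_draws


def site_eligible(y: pd.Series) -> bool:
    """A site can contribute a model iff both classes have >= 2 subjects."""
    counts = y.value_counts()
    return len(counts) == 2 and counts.min() >= 2


def loo_within_site(
    data: ClinicalDataset,
    site: str,
    config: PesoConfig,
    seed_seq: np.random.SeedSequence | None = None,
    targets: pd.Index | None = None,
    audit: PesoAudit | None = None,
) -> pd.Series:
    """Leave-one-out out-of-sample probabilities for a site's own subjects.

    ``targets`` restricts which of the site's subjects are scored (all by
    default); the training remainder always spans the whole site minus the
    held-out subject.
    """
    audit = audit if audit is not None else PesoAudit()
    seed_seq = seed_seq if seed_seq is not None else np.random.SeedSequence(config.seed)
    members = data.subjects.index[data.site == site]
    y = data.response.loc[members].astype(int)
    if not site_eligible(y):
        raise ValidationError(f"site {site!r} needs >= 2 subjects per class for LOO")
    if targets is None:
        targets = members
    features = data.features.loc[members]

    out = pd.Series(index=targets, dtype=float)
    child_seeds = seed_seq.spawn(len(targets))
    for child, sid in zip(child_seeds, targets):
        train = features.drop(index=sid)
        out.loc[sid] = _fit_predict(
            train, y.drop(index=sid).to_numpy(),
            features.loc[[sid]], data, config, child, audit,
        )[0]
    return out


def cross_site_predict(
    data: ClinicalDataset,
    source_site: str,
    target_ids: pd.Index,
    config: PesoConfig,
    seed_seq: np.random.SeedSequence | None = None,
    audit: PesoAudit | None = None,
) -> pd.Series:
    """Train on the full source site and predict the given non-source subjects."""
    audit = audit if audit is not None else PesoAudit()
    seed_seq = seed_seq if seed_seq is not None else np.random.SeedSequence(config.seed)
    members = data.subjects.index[data.site == source_site]
    y = data.response.loc[members].astype(int)
    if not site_eligible(y):
        raise ValidationError(f"site {source_site!r} ineligible for model fitting")
    if len(pd.Index(target_ids).intersection(members)):
        raise ValidationError("cross-site targets must come from other sites")
    probs = _fit_predict(
        data.features.loc[members], y.to_numpy(),
        data.features.loc[target_ids], data, config, seed_seq, audit,
    )
    return pd.Series(probs, index=target_ids)


def run_peso(
    data: ClinicalDataset,
    config: PesoConfig | None = None,
    subjects: pd.Index | None = None,
) -> PredictionMatrix:
    """Assemble the full subjects × site-models prediction matrix.

    Sites whose minority class has < 2 subjects are skipped as models (logged;
    their subjects are still predicted by the other sites).  ``subjects``
    restricts the scored rows — e.g. to a genotyped subsample — without
    changing any training set.
    """
    config = config or PesoConfig()
    if data.response.isna().any():
        raise ValidationError("all subjects need a binary response label for PESO")
    subjects = data.subjects.index if subjects is None else pd.Index(subjects)
    missing = subjects.difference(data.subjects.index)
    if len(missing):
        raise ValidationError(f"unknown subjects requested: {list(missing[:5])}")

    audit = PesoAudit()
    sites = list(dict.fromkeys(data.site))
    eligible = []
    for site in sites:
        if site_eligible(data.response[data.site == site].astype(int)):
            eligible.append(site)
        else:
            audit.skipped_sites.append(site)
            logger.warning("site %s skipped as model (needs >= 2 subjects per class)", site)
    if len(eligible) < 2:
        raise ValidationError("PESO needs at least 2 eligible sites")

    root = np.random.SeedSequence([int(config.seed), 0xBE50])
    site_seeds = dict(zip(sites, root.spawn(len(sites))))

    columns: dict[str, pd.Series] = {}
    for site in eligible:
        loo_seed, cross_seed = site_seeds[site].spawn(2)
        members = data.subjects.index[data.site == site]
        own_targets = subjects.intersection(members)
        cross_targets = subjects.difference(members)
        parts = []
        if len(own_targets):
            parts.append(loo_within_site(
                data, site, config, loo_seed, targets=own_targets, audit=audit,
            ))
        if len(cross_targets):
            parts.append(cross_site_predict(
                data, site, cross_targets, config, cross_seed, audit=audit,
            ))
        column = pd.concat(parts).reindex(subjects)
        acc = 1 - (column - data.response.loc[subjects]).abs()
        logger.info(
            "site %s: mean per-subject accuracy %.3f (median %.3f)",
            site, acc.mean(), acc.median(),
        )
        columns[site] = column

    matrix = pd.DataFrame(columns, index=subjects)
    return PredictionMatrix(
        probabilities=matrix,
        y=data.response.loc[subjects].astype(int),
        site_of_origin=data.site.loc[subjects],
        audit=audit,
    )
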