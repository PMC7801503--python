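"""Training-time preparation: missing-data marginalization, encoding, SMOTE–Tomek.

Missing clinical values are *marginalized* rather than imputed to a point
estimate: each missing cell is filled by a draw from an uninformative prior on
the variable's domain — uniform over the dictionary's category list for
binary/categorical variables, uniform over the observed training range for
continuous/ordinal variables (falling back to the dictionary bounds when a
variable has no observed training values).  M independent completed copies
are produced and downstream predictions are averaged over them.

Class imbalance is handled by SMOTE followed by Tomek-link cleaning, applied
to training partitions only.  Both are implemented here directly from their
definitions: SMOTE interpolates synthetic minority points between minority
nearest neighbours; a Tomek link is a mutual-nearest-neighbour pair of
opposite classes, whose majority-class member is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .data_model import DataDictionary
from .errors import ValidationError


@dataclass
class ImputedSample:
    """One completed copy of a feature table (draw ``draw_index`` of M)."""

    frame: pd.DataFrame
    draw_index: int


def _observed_range(values: pd.Series) -> tuple[float, float] | None:
    observed = values.dropna()
    if observed.empty:
        return None
    return float(observed.min()), float(observed.max())


def marginalize_missing(
    features: pd.DataFrame,
    dictionary: DataDictionary,
    m_draws: int,
    seed,
    reference: pd.DataFrame | None = None,
) -> list[ImputedSample]:
    """Fill missing cells by sampling from uninformative priors on each domain.

    ``reference`` supplies the observed values defining continuous/ordinal
    ranges (defaults to ``features`` itself); passing the training partition
    here lets held-out subjects be completed without touching their own data.
    Observed cells are never altered.
    """
    if m_draws < 1:
        raise ValidationError("m_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = features

    draws = [features.copy() for _ in range(m_draws)]
    for name in features.columns:
        var = dictionary[name]
        missing = features[name].isna() if var.is_numeric else features[name].isnull()
        n_missing = int(missing.sum())
        if n_missing == 0:
            continue
        if var.is_numeric:
            rng_range = _observed_range(reference[name])
            if rng_range is None:
                if var.domain is None:
                    raise ValidationError(
                        f"variable {name!r}: no observed values and unbounded domain"
                    )
                rng_range = var.domain
            lo, hi = rng_range
            for m in range(m_draws):
                if var.vartype == "ordinal":
                    fill = rng.integers(int(np.floor(lo)), int(np.ceil(hi)) + 1,
                                        size=n_missing).astype(float)
                else:
                    fill = rng.uniform(lo, hi, size=n_missing)
                draws[m].loc[missing, name] = fill
        else:
            cats = np.asarray(var.domain, dtype=object)
            for m in range(m_draws):
                draws[m].loc[missing, name] = cats[
                    rng.integers(0, len(cats), size=n_missing)
                ]
    return [ImputedSample(frame, m) for m, frame in enumerate(draws)]


class FeatureEncoder:
    """Fixed numeric encoding of a mixed-type feature table.

    Continuous/ordinal variables pass through as single float columns;
    binary/categorical variables become one-hot blocks with the column order
    fixed by the data dictionary, so matrices from different partitions are
    always column-compatible.
    """

    def __init__(self, dictionary: DataDictionary, feature_names: list[str]):
        self.dictionary = dictionary
        self.feature_names = list(feature_names)
        self.blocks: list[tuple[str, str, list[str] | None]] = []
        self.columns: list[str] = []
        for name in self.feature_names:
            var = dictionary[name]
            if var.is_numeric:
                self.blocks.append((name, "numeric", None))
                self.columns.append(name)
            else:
                cats = list(var.domain)
                self.blocks.append((name, "onehot", cats))
                self.columns.extend(f"{name}={c}" for c in cats)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, kind, cats in self.blocks:
            if kind == "numeric":
                cols.append(frame[name].to_numpy(dtype=float)[:, None])
            else:
                values = frame[name].astype(str).to_numpy()
                cols.append((values[:, None] == np.asarray(cats)).astype(float))
        return np.hstack(cols)

    def harden(self, X: np.ndarray) -> np.ndarray:
        """Snap interpolated one-hot blocks back to valid indicators (arg-max)."""
        X = X.copy()
        j = 0
        for _name, kind, cats in self.blocks:
            if kind == "numeric":
                j += 1
                continue
            block = X[:, j:j + len(cats)]
            winners = block.argmax(axis=1)
            block[:] = 0.0
            block[np.arange(len(block)), winners] = 1.0
            j += len(cats)
        return X


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed=None,
    return_origin: bool = False,
):
    """Augment the minority class to the majority count by interpolation.

    Each synthetic point is ``x_i + λ (x_nn − x_i)`` with λ ~ U(0, 1) and
    ``x_nn`` one of the ``k_neighbors`` nearest minority neighbours of a
    randomly chosen minority point (Euclidean metric).  Balanced input is
    returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("smote_oversample requires exactly two classes")
    minority = classes[counts.argmin()]
    n_min, n_maj = counts.min(), counts.max()
    origin = np.arange(len(y))
    if n_min == n_maj:
        out = (X.copy(), y.copy())
        return (*out, origin) if return_origin else out
    if n_min < 2:
        raise ValidationError("minority class has a single sample; SMOTE needs >= 2")

    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(y == minority)
    Xmin = X[minority_idx]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neighbors = nn.kneighbors(Xmin, return_distance=False)[:, 1:]

    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = neighbors[base, rng.integers(0, k, size=n_new)]
    lam = rng.random(n_new)[:, None]
    synthetic = Xmin[base] + lam * (Xmin[pick] - Xmin[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    if return_origin:
        return X_out, y_out, np.concatenate([origin, np.full(n_new, -1)])
    return X_out, y_out


def tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Indices (a, b) of opposite-class pairs that are mutual 1-nearest neighbours."""
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        return []
    nn = NearestNeighbors(n_neighbors=min(3, len(X))).fit(X)
    candidates = nn.kneighbors(X, return_distance=False)
    # with zero-distance duplicates, "self" need not come first in the list
    nearest = np.array([
        next(j for j in row if j != i) for i, row in enumerate(candidates)
    ])
    links = []
    for a in range(len(X)):
        b = nearest[a]
        if a < b and nearest[b] == a and y[a] != y[b]:
            links.append((a, int(b)))
    return links


def tomek_remove(
    X: np.ndarray,
    y: np.ndarray,
    majority_class=None,
    return_kept: bool = False,
):
    """Remove the majority-class member of every Tomek link.

    ``majority_class`` overrides the majority (used after SMOTE, when counts
    are balanced and the relevant majority is the pre-resampling one).  With
    balanced counts and no override, nothing is removed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("tomek_remove requires both classes present")
    if majority_class is None:
        if counts[0] == counts[1]:
            kept = np.arange(len(y))
            out = (X.copy(), y.copy())
            return (*out, kept) if return_kept else out
        majority_class = classes[counts.argmax()]

    drop = {a if y[a] == majority_class else b
            for a, b in tomek_links(X, y)
            if majority_class in (y[a], y[b])}
    kept = np.array([i for i in range(len(y)) if i not in drop])
    out = (X[kept], y[kept])
    return (*out, kept) if return_kept else out


def smote_tomek(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed=None,
    return_origin: bool = False,
):
    """SMOTE oversampling followed by Tomek-link cleaning of the original majority.

    Returns the rebalanced training matrix; with ``return_origin``, also the
    per-row provenance (original row index, or −1 for synthetic points) so
    callers can audit that no held-out subject leaked into training.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("smote_tomek requires exactly two classes")
    majority = classes[counts.argmax()] if counts[0] != counts[1] else None
    X1, y1, origin = smote_oversample(
        X, y, k_neighbors=k_neighbors, seed=seed, return_origin=True
    )
    X2, y2, kept = tomek_remove(X1, y1, majority_class=majority, return_kept=True)
    if return_origin:
        return X2, y2, origin[kept]
    return X2, y2
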