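"""Clinical exemplar score and best/poor stratification.

For subject *i* with true label ``y_i`` and per-site predicted probabilities
``p_is`` (from PESO):

* per-site accuracy ``a_is = 1 − |y_i − p_is|`` (a bounded, order-preserving
  accuracy in [0, 1]);
* accuracy component ``A_i = mean_s a_is``;
* agreement component ``G_i = 1 − 2 · mean_s |p_is − p̄_i|`` — one minus twice
  the mean absolute deviation of the site probabilities, so unanimity gives
  G = 1 and maximal split gives G = 0;
* exemplar score ``E_i = (A_i + G_i) / 2``.

E = 1 only when every site predicts the subject's class exactly; a subject
predicted wrongly but unanimously, or accurately but with maximal
disagreement, lands at intermediate values (0.5 and 0.25 respectively in the
canonical two extremes).  Strata are assigned within each response class:
the top quartile of scores are the *best* exemplars (LRBest among responders,
NRBest among non-responders), the bottom quartile the *poor* exemplars
(LRPoor / NRPoor); everyone else is "middle".
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peso import PredictionMatrix

STRATA = ("LRBest", "LRPoor", "NRBest", "NRPoor", "middle")


def canonical_score(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (A, G, E) for an n × s probability matrix and label vector."""
    err = np.abs(y[:, None] - p)
    A = 1.0 - err.mean(axis=1)
    p_bar = p.mean(axis=1, keepdims=True)
    G = 1.0 - 2.0 * np.abs(p - p_bar).mean(axis=1)
    E = 0.5 * (A + G)
    return A, G, E


def exemplar_score(
    predictions: PredictionMatrix,
    score_fn: Callable[[np.ndarray, np.ndarray], tuple] = canonical_score,
) -> pd.DataFrame:
    """Per-subject exemplar table: y, per-component scores, E (no strata yet)."""
    p = predictions.probabilities.to_numpy(dtype=float)
    if p.shape[1] < 2:
        raise ValidationError("exemplar score needs >= 2 site columns")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    y = predictions.y.to_numpy(dtype=float)
    A, G, E = score_fn(p, y)
    return pd.DataFrame(
        {
            "y": predictions.y.astype(int),
            "site": predictions.site_of_origin,
            "A": A,
            "G": G,
            "E": E,
            "stratum": "middle",
        },
        index=predictions.probabilities.index,
    )


def quartile_count(n_class: int, q: float = 0.25) -> int:
    """Stratum size: round-half-up of q · n (e.g. 439 → 110, 827 → 207 at q = 0.25)."""
    return int(math.floor(q * n_class + 0.5))


def stratify_quartiles(scores: pd.DataFrame, q: float = 0.25) -> pd.DataFrame:
    """Assign best/poor strata within each response class.

    Within a class of size n, the k = round_half_up(q·n) highest-scoring
    subjects become the Best stratum and the k lowest the Poor stratum; ties
    at a boundary are broken by ascending subject_id, so the assignment is
    deterministic.  Requires >= 4 subjects per class and non-overlapping
    strata (2k <= n).
    """
    if not 0 < q <= 0.5:
        raise ValidationError("q must lie in (0, 0.5]")
    out = scores.copy()
    out["stratum"] = "middle"
    for label, best_name, poor_name in ((1, "LRBest", "LRPoor"), (0, "NRBest", "NRPoor")):
        members = out.index[out["y"] == label]
        n_class = len(members)
        if n_class < 4:
            raise ValidationError(
                f"class y={label} has {n_class} subjects; stratification needs >= 4"
            )
        k = quartile_count(n_class, q)
        if 2 * k > n_class:
            raise ValidationError(
                f"class y={label}: strata of size {k} would overlap (n={n_class})"
            )
        ranked = (
            out.loc[members, ["E"]]
            .assign(_sid=members.astype(str))
            .sort_values(["E", "_sid"], ascending=[False, True], kind="mergesort")
        )
        best = ranked.index[:k]
        # Poor drawn from the complement of Best so heavy ties can never overlap.
        poor = (
            ranked.drop(index=best)
            .sort_values(["E", "_sid"], ascending=[True, True], kind="mergesort")
            .index[:k]
        )
        out.loc[best, "stratum"] = best_name
        out.loc[poor, "stratum"] = poor_name
    return out


def stratum_members(table: pd.DataFrame, which: str) -> pd.Index:
    """Subject ids in a named stratum, or the BEST/POOR unions across classes."""
    which = which.upper() if which.lower() in ("best", "poor") else which
    if which == "BEST":
        mask = table["stratum"].isin(["LRBest", "NRBest"])
    elif which == "POOR":
        mask = table["stratum"].isin(["LRPoor", "NRPoor"])
    elif which in STRATA:
        mask = table["stratum"] == which
    else:
        raise ValidationError(f"unknown stratum {which!r}")
    return table.index[mask]


def write_exemplar_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.insert(0, "subject_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_exemplar_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("subject_id")
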