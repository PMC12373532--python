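"""Covariate conversions and analysis-ready variables.

The analyses use fixed conversion rules for the self-report scales:

* income-shock Likert (1-6): 1-3 -> 0, 4-6 -> 1 (binarised at the midpoint);
* emotion ratings (0-100): < 33.33 -> 0, > 66.66 -> 1, else 0.5 (values
  exactly at a boundary fall in the middle bin by default — the published
  rule uses strict inequalities and leaves them unassigned);
* negative affect: mean of the three converted fear/sad/anger values
  (convert-then-average by default; average-then-convert is available);
* all regression inputs are z-scored with the sample (n-1) SD;
* two-wave change scores difference log k and binarised shock within
  participant, carry demographics from wave 1, and by default exclude
  participants flagged as reporting a positive shock at wave 2.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .instrument import ValidationError

__all__ = [
    "binarize_income_shock",
    "trichotomize_emotion",
    "negative_affect_score",
    "standardize",
    "build_encoded",
    "change_scores",
]

DEMOGRAPHICS = ("age", "gender", "education", "income")

_EMOTION_LOW = 100.0 / 3.0   # 33.33...
_EMOTION_HIGH = 200.0 / 3.0  # 66.66...


def _maybe_scalar(out, inp):
    return out.item() if np.ndim(inp) == 0 else out


def binarize_income_shock(likert):
    """Map Likert 1-3 -> 0 and 4-6 -> 1; anything else is an error."""
    arr = np.asarray(likert)
    if arr.size and (not np.issubdtype(arr.dtype, np.number) or np.any((arr < 1) | (arr > 6))
                     or np.any(arr != np.round(arr))):
        raise ValidationError(f"income-shock Likert values must be integers in 1..6")
    out = (arr >= 4).astype(int)
    return _maybe_scalar(out, likert)


def trichotomize_emotion(rating, boundary_policy: str = "middle"):
    """Convert a 0-100 emotion rating to {0, 0.5, 1}.

    ``boundary_policy`` decides where a rating exactly at 33.33 or 66.66
    lands: ``"middle"`` (default) puts both in the 0.5 bin, ``"down"`` in the
    lower bin, ``"up"`` in the upper bin.
    """
    arr = np.asarray(rating, dtype=float)
    if np.any(np.isnan(arr)) or np.any((arr < 0) | (arr > 100)):
        raise ValidationError("emotion ratings must lie in [0, 100]")
    if boundary_policy not in ("middle", "down", "up"):
        raise ValidationError(f"unknown boundary_policy {boundary_policy!r}")
    lo, hi = _EMOTION_LOW, _EMOTION_HIGH
    if boundary_policy == "middle":
        low = arr < lo
        high = arr > hi
    elif boundary_policy == "down":
        low = arr <= lo
        high = arr > hi
    else:
        low = arr < lo
        high = arr >= hi
    out = np.where(low, 0.0, np.where(high, 1.0, 0.5))
    return _maybe_scalar(out, rating)


def negative_affect_score(fear, sad, angry, order: str = "convert_first",
                          boundary_policy: str = "middle"):
    """Composite negative-affect score in [0, 1] from three emotion ratings.

    ``order="convert_first"`` (default) trichotomises each rating then
    averages; ``"average_first"`` averages the raw ratings then trichotomises.
    Missing components are an error — no partial averaging.
    """
    parts = [np.asarray(v, dtype=float) for v in (fear, sad, angry)]
    if any(np.any(np.isnan(p)) for p in parts):
        raise ValidationError("negative_affect_score: missing emotion component")
    if order == "convert_first":
        conv = [trichotomize_emotion(p, boundary_policy) for p in parts]
        out = np.mean(np.broadcast_arrays(*conv), axis=0)
    elif order == "average_first":
        out = trichotomize_emotion(np.mean(np.broadcast_arrays(*parts), axis=0),
                                   boundary_policy)
    else:
        raise ValidationError(f"unknown order {order!r}")
    return _maybe_scalar(np.asarray(out), fear)


def standardize(x):
    """z-score with the sample (n-1) standard deviation.

    Preserves a pandas index if given a Series; a constant column is an
    error (its z-score is undefined).
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValidationError("standardize needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("cannot standardize a constant column")
    out = (arr - arr.mean()) / sd
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def build_encoded(
    df: pd.DataFrame,
    order: str = "convert_first",
    boundary_policy: str = "middle",
) -> pd.DataFrame:
    """Add ``shock01`` and ``affect_score`` columns to a covariate table.

    Expects columns ``income_shock_likert`` and ``fear``/``sad``/``angry``;
    demographic and log_k columns pass through untouched.
    """
    out = df.copy()
    out["shock01"] = binarize_income_shock(df["income_shock_likert"].to_numpy())
    out["affect_score"] = negative_affect_score(
        df["fear"].to_numpy(), df["sad"].to_numpy(), df["angry"].to_numpy(),
        order=order, boundary_policy=boundary_policy,
    )
    return out


def change_scores(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    exclude_positive_shock: bool = True,
    delta_shock_scale: str = "binary",
) -> pd.DataFrame:
    """Two-wave change scores, one row per participant present at both waves.

    Both inputs need ``participant_id``, ``log_k``, ``income_shock_likert``
    and the demographic columns; ``t2`` may carry a boolean
    ``positive_shock`` column.  Output columns: the wave-1 demographics,
    ``delta_log_k`` (wave 2 minus wave 1), ``delta_shock`` (binarised by
    default, in {-1, 0, 1}; raw Likert differencing with
    ``delta_shock_scale="likert"``), and ``delta_affect`` when emotion
    columns are present.  Participants flagged positive-shock at wave 2 are
    excluded unless ``exclude_positive_shock=False``; participants missing a
    wave are dropped with a warning.  Row-accounting lives in
    ``result.attrs`` (n_t1, n_t2, n_matched, n_excluded_positive, n_analyzed).
    """
    if delta_shock_scale not in ("binary", "likert"):
        raise ValidationError(f"unknown delta_shock_scale {delta_shock_scale!r}")
    a = t1.set_index("participant_id")
    b = t2.set_index("participant_id")
    common = a.index.intersection(b.index)
    n_unmatched = (len(a) - len(common)) + (len(b) - len(common))
    if n_unmatched:
        warnings.warn(
            f"change_scores: dropped {n_unmatched} rows without both timepoints",
            stacklevel=2,
        )
    a, b = a.loc[common], b.loc[common]

    out = pd.DataFrame(index=common)
    for col in DEMOGRAPHICS:
        if col in a.columns:
            out[col] = a[col]
    out["delta_log_k"] = b["log_k"] - a["log_k"]
    if delta_shock_scale == "binary":
        out["delta_shock"] = (
            binarize_income_shock(b["income_shock_likert"].to_numpy())
            - binarize_income_shock(a["income_shock_likert"].to_numpy())
        )
    else:
        out["delta_shock"] = b["income_shock_likert"] - a["income_shock_likert"]
    if all(c in a.columns and c in b.columns for c in ("fear", "sad", "angry")):
        out["delta_affect"] = negative_affect_score(
            b["fear"].to_numpy(), b["sad"].to_numpy(), b["angry"].to_numpy()
        ) - negative_affect_score(
            a["fear"].to_numpy(), a["sad"].to_numpy(), a["angry"].to_numpy()
        )

    n_matched = len(out)
    n_excluded = 0
    if exclude_positive_shock and "positive_shock" in b.columns:
        keep = ~b["positive_shock"].fillna(False).astype(bool)
        n_excluded = int((~keep).sum())
        out = out[keep]
    out = out.reset_index().rename(columns={"index": "participant_id"})
    out.attrs.update(
        n_t1=len(t1), n_t2=len(t2), n_matched=n_matched,
        n_excluded_positive=n_excluded, n_analyzed=len(out),
    )
    return out
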