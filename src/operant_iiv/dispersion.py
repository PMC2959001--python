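"""Individual phenotypic dispersion (PD_i) — the core IIV statistic.

For one rat, one session and one trait, let ``x_1..x_K`` be the per-segment
counts.  The individual phenotypic dispersion is the mean absolute deviation
from the session mean::

    PD = (1/K) * sum_k |x_k - mean(x)|

computed with the plain ``1/K`` divisor (no ``n-1`` correction) on raw
counts.  One PD value exists per (rat, session, trait); ``PD = 0`` iff all
segment counts in the session are equal.

The within-session trend analysis uses a per-segment variant: for each rat,
trait and segment ``k``, the absolute deviation ``|x_{s,k} - mean_k(x_s)|``
of that segment from its own session's mean, averaged over sessions.
Averaging this quantity over segments recovers the rat's mean PD over
sessions, so the two views are consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from .traits import TRAITS

__all__ = [
    "pd_session",
    "dispersion_table",
    "segment_deviation_table",
    "SessionDispersion",
    "SegmentDeviations",
]

PD_COLUMNS = ["rat_id", "strain", "session", "trait", "pd", "session_mean"]
SEGDEV_COLUMNS = ["rat_id", "strain", "trait", "segment", "mean_abs_dev"]


def pd_session(segment_values) -> tuple[float, float]:
    """Phenotypic dispersion of one session.

    Parameters
    ----------
    segment_values
        The per-segment values of one trait for one rat-session (length >= 2).

    Returns
    -------
    (pd, session_mean)
        Mean absolute deviation from the session mean, and the session mean.
    """
    x = np.asarray(segment_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d list of at least 2 segment values")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment values must all be finite")
    m = float(x.mean())
    return float(np.abs(x - m).mean()), m


def _check_complete(traits: pd.DataFrame, n_segments: int | None) -> int:
    if n_segments is None:
        n_segments = traits["segment"].nunique()
    counts = traits.groupby(["rat_id", "session"])["segment"].agg(["size", "nunique"])
    bad = counts[(counts["size"] != n_segments) | (counts["nunique"] != n_segments)]
    if len(bad):
        rat, session = bad.index[0]
        raise ValueError(
            f"incomplete trait table: rat {rat!r} session {session} has "
            f"{bad.iloc[0]['nunique']} distinct segments, expected {n_segments}"
        )
    return n_segments


def dispersion_table(traits: pd.DataFrame, n_segments: int | None = None) -> pd.DataFrame:
    """One PD record per (rat, session, trait) from a complete trait table.

    ``n_segments`` defaults to the number of distinct segments in the table;
    a rat-session missing a segment raises ``ValueError`` naming it.
    Returns columns ``rat_id, strain, session, trait, pd, session_mean``.
    """
    _check_complete(traits, n_segments)
    key = ["rat_id", "strain", "session"]
    frames = []
    for trait in TRAITS:
        g = traits.groupby(key, sort=False)[trait]
        mean = g.transform("mean")
        adev = (traits[trait] - mean).abs()
        agg = traits[key].assign(pd=adev, session_mean=mean).groupby(key, sort=False).mean()
        agg = agg.reset_index()
        agg.insert(3, "trait", trait)
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out[PD_COLUMNS].sort_values(["rat_id", "session", "trait"],
                                       kind="stable").reset_index(drop=True)


def segment_deviation_table(traits: pd.DataFrame,
                            n_segments: int | None = None) -> pd.DataFrame:
    """Per-segment absolute deviations from the session mean, averaged over sessions.

    For each (rat, trait, segment), the mean over sessions of
    ``|x_{session,segment} - session mean|``.  Returns columns
    ``rat_id, strain, trait, segment, mean_abs_dev`` with ``segment`` 1-based.
    """
    _check_complete(traits, n_segments)
    key = ["rat_id", "strain", "session"]
    frames = []
    for trait in TRAITS:
        mean = traits.groupby(key, sort=False)[trait].transform("mean")
        adev = (traits[trait] - mean).abs()
        agg = (traits[["rat_id", "strain", "segment"]]
               .assign(mean_abs_dev=adev)
               .groupby(["rat_id", "strain", "segment"], sort=False)["mean_abs_dev"]
               .mean().reset_index())
        agg.insert(2, "trait", trait)
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out[SEGDEV_COLUMNS].sort_values(["rat_id", "trait", "segment"],
                                           kind="stable").reset_index(drop=True)


class SessionDispersion(BaseEstimator, TransformerMixin):
    """Transformer: per-segment trait table -> per-session PD table."""

    def __init__(self, n_segments: int | None = None):
        self.n_segments = n_segments

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return dispersion_table(X, n_segments=self.n_segments)


class SegmentDeviations(BaseEstimator, TransformerMixin):
    """Transformer: trait table -> per-segment mean absolute deviations."""

    def __init__(self, n_segments: int | None = None):
        self.n_segments = n_segments

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return segment_deviation_table(X, n_segments=self.n_segments)
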