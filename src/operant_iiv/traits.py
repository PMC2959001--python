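"""Per-segment operant trait counts: hyperactivity, impulsiveness, inattention.

Trait operationalization
------------------------
* **Impulsiveness** — number of correct lever presses whose inter-response
  time (IRT, the time since the previous correct lever press in the same
  session) is defined and shorter than the threshold (default 0.67 s).
* **Hyperactivity** — total lever presses (correct + incorrect by default)
  *minus* the impulsive presses.  Excluding the short-IRT presses decouples
  the hyperactivity dispersion estimate from the impulsiveness one, so for
  every segment ``impulsiveness + hyperactivity == total lever presses``.
* **Inattention** — number of incorrect door openings (door opened with no
  water present).

IRTs exist only between consecutive *correct* lever presses within one
session: incorrect presses neither carry IRTs nor reset the clock, the first
press of a session has no IRT (never impulsive, always counted in
hyperactivity), and a press pair spanning a segment boundary yields an IRT
attributed to the segment of the *later* press.
"""

from __future__ import annotations

import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from .events import EVENT_COLUMNS, SessionStructure, assign_segment

__all__ = [
    "TRAITS",
    "TRAIT_COLUMNS",
    "compute_irts",
    "extract_traits",
    "TraitExtractor",
]

TRAITS = ("hyperactivity", "impulsiveness", "inattention")
TRAIT_COLUMNS = ["rat_id", "strain", "session", "segment",
                 "hyperactivity", "impulsiveness", "inattention"]


def compute_irts(events: pd.DataFrame) -> pd.DataFrame:
    """Inter-response times between consecutive correct lever presses.

    Parameters
    ----------
    events
        Validated event table, time-sorted within each (rat, session).

    Returns
    -------
    DataFrame with columns ``rat_id, strain, session, time_s, irt_s`` holding
    one row per correct lever press in time order; ``irt_s`` is NaN for the
    first press of each rat-session (its IRT is undefined) and strictly
    positive otherwise.  IRTs never span sessions; segment boundaries are not
    breaks.
    """
    presses = events.loc[events["event_type"] == "correct_lever",
                         ["rat_id", "strain", "session", "time_s"]].copy()
    presses["irt_s"] = presses.groupby(["rat_id", "session"], sort=False)["time_s"].diff()
    return presses.reset_index(drop=True)


def extract_traits(events: pd.DataFrame,
                   structure: SessionStructure | None = None,
                   irt_threshold_s: float = 0.67,
                   hyperactivity_levers: str = "both") -> pd.DataFrame:
    """Count the three traits per (rat, session, segment).

    Every (rat, session) observed in ``events`` contributes exactly
    ``structure.n_segments`` rows, with explicit zeros for empty segments.
    ``segment`` is 1-based in the output, matching the reported "segment
    (1-5)" convention.

    ``hyperactivity_levers`` selects whether hyperactivity counts presses on
    both levers (``"both"``, default) or correct-lever presses only
    (``"correct"``); impulsive (short-IRT) correct presses are excluded from
    hyperactivity in either case.
    """
    if not irt_threshold_s > 0:
        raise ValueError(f"irt_threshold_s must be > 0, got {irt_threshold_s}")
    if hyperactivity_levers not in ("both", "correct"):
        raise ValueError("hyperactivity_levers must be 'both' or 'correct'")
    structure = structure or SessionStructure()

    ev = events.loc[:, EVENT_COLUMNS].reset_index(drop=True)
    ev["segment"] = assign_segment(ev["time_s"].to_numpy(), structure) + 1

    keys = ["rat_id", "strain", "session", "segment"]

    def seg_counts(mask, name):
        return (ev.loc[mask].groupby(keys, sort=False).size().rename(name))

    is_correct = ev["event_type"] == "correct_lever"
    is_lever = is_correct | (ev["event_type"] == "incorrect_lever")

    irt = ev.loc[is_correct].groupby(["rat_id", "session"], sort=False)["time_s"].diff()
    impulsive_idx = irt.index[irt.notna() & (irt < irt_threshold_s)]
    impulsive_mask = ev.index.isin(impulsive_idx)

    lever_mask = is_lever if hyperactivity_levers == "both" else is_correct
    counts = pd.concat(
        [
            seg_counts(lever_mask, "lever_total"),
            seg_counts(impulsive_mask, "impulsiveness"),
            seg_counts(ev["event_type"] == "incorrect_door", "inattention"),
        ],
        axis=1,
    )

    # complete grid: all segments for every observed (rat, strain, session)
    rat_sessions = ev[["rat_id", "strain", "session"]].drop_duplicates()
    grid = rat_sessions.merge(
        pd.DataFrame({"segment": range(1, structure.n_segments + 1)}), how="cross")
    table = grid.merge(counts.reset_index(), on=keys, how="left").fillna(0)
    for col in ("lever_total", "impulsiveness", "inattention"):
        table[col] = table[col].astype(int)
    table["hyperactivity"] = table["lever_total"] - table["impulsiveness"]
    return (table[TRAIT_COLUMNS]
            .sort_values(["rat_id", "session", "segment"], kind="stable")
            .reset_index(drop=True))


class TraitExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer from event tables to per-segment trait tables.

    Parameters mirror :func:`extract_traits`.  ``fit`` is a no-op; the class
    exists so trait extraction composes with scikit-learn pipelines and
    parameter search.
    """

    def __init__(self, session_duration_s: float = 5400.0, n_segments: int = 5,
                 irt_threshold_s: float = 0.67, hyperactivity_levers: str = "both"):
        self.session_duration_s = session_duration_s
        self.n_segments = n_segments
        self.irt_threshold_s = irt_threshold_s
        self.hyperactivity_levers = hyperactivity_levers

    @property
    def structure_(self) -> SessionStructure:
        return SessionStructure(self.session_duration_s, self.n_segments)

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return extract_traits(X, self.structure_,
                              irt_threshold_s=self.irt_threshold_s,
                              hyperactivity_levers=self.hyperactivity_levers)
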