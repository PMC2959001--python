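"""operant_iiv — intra-individual variability analysis of operant behavior.

Pipeline: time-stamped operant-chamber event streams -> per-segment trait
counts (hyperactivity, impulsiveness, inattention) -> per-session phenotypic
dispersion (PD, the mean absolute deviation of segment counts from the
session mean) -> two-group comparison (Kruskal-Wallis, log-scale GLM with
95% CIs, variance proportion) and temporal-trend models (among sessions,
within sessions).  A synthetic-data generator emulating a two-strain
(SHR-like vs WKY-like) study design makes every stage testable end to end.
"""

from __future__ import annotations

from dataclasses import asdict

import pandas as pd

from .events import (EVENT_COLUMNS, EVENT_TYPES, EventFileError,
                     SessionStructure, assign_segment, read_events,
                     validate_events, write_events)
from .simulate import (IMPULSIVE_IRT_THRESHOLD_S, SimulationDesign,
                       StrainParams, irt_mixture_sample, simulate_experiment)
from .presets import default_config, default_design, default_strain_params, load_config
from .traits import TRAITS, TraitExtractor, compute_irts, extract_traits
from .dispersion import (SegmentDeviations, SessionDispersion,
                         dispersion_table, pd_session, segment_deviation_table)
from .inference import (AmongSessionsTrend, StrainComparison,
                        StrainDispersionComparison, TrendFit,
                        WithinSessionsTrend, among_sessions_model,
                        glm_log_pd, kruskal_wallis, strain_comparison,
                        variance_proportion, within_sessions_model)

__version__ = "0.1.0"

__all__ = [
    "EVENT_COLUMNS", "EVENT_TYPES", "EventFileError", "SessionStructure",
    "assign_segment", "read_events", "validate_events", "write_events",
    "IMPULSIVE_IRT_THRESHOLD_S", "SimulationDesign", "StrainParams",
    "irt_mixture_sample", "simulate_experiment",
    "default_config", "default_design", "default_strain_params", "load_config",
    "TRAITS", "TraitExtractor", "compute_irts", "extract_traits",
    "SegmentDeviations", "SessionDispersion", "dispersion_table",
    "pd_session", "segment_deviation_table",
    "AmongSessionsTrend", "StrainComparison", "StrainDispersionComparison",
    "TrendFit", "WithinSessionsTrend", "among_sessions_model", "glm_log_pd",
    "kruskal_wallis", "strain_comparison", "variance_proportion",
    "within_sessions_model",
    "analyze_events", "full_report",
]


def analyze_events(events: pd.DataFrame,
                   structure: SessionStructure | None = None,
                   irt_threshold_s: float = 0.67,
                   hyperactivity_levers: str = "both",
                   log_offset: float = 1.0,
                   kw_unit: str = "rat",
                   slope_scale: str = "raw",
                   sphericity_correction: bool = False) -> dict:
    """Run the full pipeline on an event table and return a report dict.

    The report holds the per-trait strain comparison (``comparison``), the
    among-sessions and within-sessions trend fits (``trends``), the
    intermediate PD and segment-deviation tables, and a ``config`` block
    echoing every interpretive setting in force.
    """
    structure = structure or SessionStructure()
    traits = extract_traits(events, structure, irt_threshold_s=irt_threshold_s,
                            hyperactivity_levers=hyperactivity_levers)
    pd_table = dispersion_table(traits, n_segments=structure.n_segments)
    segdev = segment_deviation_table(traits, n_segments=structure.n_segments)

    comparison = StrainDispersionComparison(log_offset=log_offset,
                                            kw_unit=kw_unit).fit(pd_table)
    n_sessions = pd_table["session"].nunique()
    trends: dict[str, dict] = {"among_sessions": {}, "within_sessions": {}}
    if n_sessions >= 2:
        among = AmongSessionsTrend(log_offset=log_offset,
                                   sphericity_correction=sphericity_correction
                                   ).fit(pd_table)
        trends["among_sessions"] = {t: asdict(f) for t, f in among.fits_.items()}
    within = WithinSessionsTrend(log_offset=log_offset, slope_scale=slope_scale,
                                 sphericity_correction=sphericity_correction
                                 ).fit(segdev)
    trends["within_sessions"] = {t: asdict(f) for t, f in within.fits_.items()}

    return {
        "comparison": {t: asdict(r) for t, r in comparison.results_.items()},
        "comparison_table": comparison.comparison_table_,
        "trends": trends,
        "pd_table": pd_table,
        "segment_deviations": segdev,
        "config": {
            "session_duration_s": structure.session_duration_s,
            "n_segments": structure.n_segments,
            "irt_threshold_s": irt_threshold_s,
            "hyperactivity_levers": hyperactivity_levers,
            "log_offset": log_offset,
            "kw_unit": kw_unit,
            "slope_scale": slope_scale,
            "sphericity_correction": sphericity_correction,
            "segment_convention": "half-open [start, end); 1-based in output",
            "segment_deviation_definition":
                "|segment count - own session mean|, averaged over sessions",
        },
    }


def full_report(pd_table: pd.DataFrame, segdev: pd.DataFrame,
                log_offset: float = 1.0, kw_unit: str = "rat",
                slope_scale: str = "raw",
                sphericity_correction: bool = False) -> dict:
    """Comparison + trend report from precomputed PD and segment-deviation tables."""
    comparison = StrainDispersionComparison(log_offset=log_offset,
                                            kw_unit=kw_unit).fit(pd_table)
    trends: dict[str, dict] = {"among_sessions": {}, "within_sessions": {}}
    if pd_table["session"].nunique() >= 2:
        among = AmongSessionsTrend(log_offset=log_offset,
                                   sphericity_correction=sphericity_correction
                                   ).fit(pd_table)
        trends["among_sessions"] = {t: asdict(f) for t, f in among.fits_.items()}
    within = WithinSessionsTrend(log_offset=log_offset, slope_scale=slope_scale,
                                 sphericity_correction=sphericity_correction
                                 ).fit(segdev)
    trends["within_sessions"] = {t: asdict(f) for t, f in within.fits_.items()}
    return {
        "comparison": {t: asdict(r) for t, r in comparison.results_.items()},
        "comparison_table": comparison.comparison_table_,
        "trends": trends,
        "config": {
            "log_offset": log_offset,
            "kw_unit": kw_unit,
            "slope_scale": slope_scale,
            "sphericity_correction": sphericity_correction,
            "segment_deviation_definition":
                "|segment count - own session mean|, averaged over sessions",
        },
    }
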