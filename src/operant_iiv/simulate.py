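"""Synthetic operant event streams with controllable intra-individual variability.

The generator emulates the design of a two-strain operant study: each rat
performs ``n_sessions`` daily 90-min sessions split into five 18-min
segments, pressing a correct lever reinforced on a variable-interval (VI)
schedule, occasionally pressing an unreinforced incorrect lever, and opening
the reinforcer-cubicle door both when water is present (after a reinforcer)
and when it is not ("incorrect" openings, the inattention trait).

Three statistical structures matter downstream and are explicit knobs:

* **between-rat level** — a per-rat lognormal random effect on all rates
  (``rat_rate_sd_log``);
* **segment-to-segment dispersion** — each (session, segment) draws a
  multiplicative lognormal noise ``exp(N(0, sigma_k^2))`` applied to all of
  that segment's rates.  ``sigma_k = segment_dispersion_sd_log +
  dispersion_trend_per_segment * k`` (floored at 0), so
  ``segment_dispersion_sd_log`` is the intra-individual-variability knob and
  ``dispersion_trend_per_segment`` injects a within-session dispersion trend;
* **burst structure** — lever-press inter-response times (IRTs) come from a
  two-component exponential mixture: with probability ``burst_prob`` a short
  "burst" IRT (mean below the 0.67-s impulsiveness threshold), otherwise a
  long IRT, scaled so the mixture mean matches the segment's target rate.

Determinism: a single experiment seed deterministically derives one RNG
substream per rat (keyed by strain index and rat index), so adding rats or
strains never perturbs the events of existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .events import EVENT_COLUMNS, SessionStructure

__all__ = [
    "IMPULSIVE_IRT_THRESHOLD_S",
    "StrainParams",
    "SimulationDesign",
    "irt_mixture_sample",
    "simulate_experiment",
]

#: IRT below this (seconds) defines an impulsive response; the mixture's
#: burst component must sit below it and the non-burst component above it.
IMPULSIVE_IRT_THRESHOLD_S = 0.67


@dataclass(frozen=True)
class StrainParams:
    """Generative parameters for one strain (group) of rats.

    Rates are per minute; log-scale SDs are natural-log.
    """

    base_lever_rate: float = 3.0            # mean lever presses/min across rats
    rat_rate_sd_log: float = 0.25           # SD of the per-rat log-rate effect
    segment_dispersion_sd_log: float = 0.3  # SD of segment-level log-noise (IIV knob)
    dispersion_trend_per_segment: float = 0.0  # change in that SD per segment index
    burst_prob: float = 0.25                # P(an IRT comes from the burst component)
    burst_irt_mean_s: float = 0.25          # burst-component mean IRT (< 0.67 s)
    nonburst_irt_mean_s: float = 3.0        # non-burst component mean IRT (> 0.67 s)
    incorrect_door_rate: float = 1.0        # incorrect door openings/min
    incorrect_lever_frac: float = 0.2       # fraction of presses on the wrong lever

    def __post_init__(self) -> None:
        for name in ("base_lever_rate", "rat_rate_sd_log",
                     "segment_dispersion_sd_log", "incorrect_door_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("dispersion_trend_per_segment", "burst_irt_mean_s",
                     "nonburst_irt_mean_s", "burst_prob", "incorrect_lever_frac"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.burst_prob <= 1:
            raise ValueError("burst_prob must be in [0, 1]")
        if not 0 <= self.incorrect_lever_frac <= 1:
            raise ValueError("incorrect_lever_frac must be in [0, 1]")
        if not (0 < self.burst_irt_mean_s < IMPULSIVE_IRT_THRESHOLD_S
                < self.nonburst_irt_mean_s):
            raise ValueError(
                "need burst_irt_mean_s < "
                f"{IMPULSIVE_IRT_THRESHOLD_S} < nonburst_irt_mean_s "
                "so the impulsiveness threshold separates the components"
            )


@dataclass(frozen=True)
class SimulationDesign:
    """Study design: group sizes, sessions, session layout, VI schedule, seed."""

    n_rats_per_strain: Mapping[str, int] = field(
        default_factory=lambda: {"SHR": 16, "WKY": 15})
    n_sessions: int = 5
    structure: SessionStructure = field(default_factory=SessionStructure)
    vi_mean_s: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if not np.isfinite(self.vi_mean_s) or self.vi_mean_s <= 0:
            raise ValueError("vi_mean_s must be positive and finite")
        if len(self.n_rats_per_strain) == 0:
            raise ValueError("at least one strain required")
        for strain, n in self.n_rats_per_strain.items():
            if n < 1:
                raise ValueError(f"strain {strain!r} has zero rats")


def _mixture_component_means(params: StrainParams, target_rate: float) -> tuple[float, float]:
    """Component means (burst, non-burst) of the IRT mixture at a target rate.

    The non-burst mean is chosen so the mixture mean equals ``60/target_rate``;
    if that would push it below ``nonburst_irt_mean_s`` (its floor), both
    component means are instead rescaled by a common factor, which also makes
    the mixture mean exact.  ``burst_prob`` 0 or 1 degenerate to a single
    exponential.
    """
    if not np.isfinite(target_rate) or target_rate <= 0:
        raise ValueError(f"target_rate must be positive and finite, got {target_rate}")
    target_mean = 60.0 / target_rate
    p = params.burst_prob
    b, nb = params.burst_irt_mean_s, params.nonburst_irt_mean_s
    if p >= 1.0:
        return b, b
    if p <= 0.0:
        return target_mean, target_mean
    m_req = (target_mean - p * b) / (1.0 - p)
    if m_req >= nb:
        return b, m_req
    f = target_mean / (p * b + (1.0 - p) * nb)
    if f <= 0:
        raise ValueError(
            f"target rate {target_rate}/min is unattainable: the burst component "
            f"alone exceeds the requested mean IRT {target_mean:.4f} s"
        )
    return f * b, f * nb


def _irt_mixture_batch(params: StrainParams, target_rate: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    mb, mnb = _mixture_component_means(params, target_rate)
    burst = rng.random(size) < params.burst_prob
    out = np.empty(size)
    out[burst] = rng.exponential(mb, burst.sum())
    out[~burst] = rng.exponential(mnb, size - burst.sum())
    return out


def irt_mixture_sample(params: StrainParams, target_rate: float,
                       rng: np.random.Generator) -> float:
    """Draw one inter-response time (seconds) from the burst/non-burst mixture.

    The mixture mean equals ``60/target_rate`` (responses/min) exactly, except
    in the degenerate ``burst_prob = 1`` case where every IRT is a burst IRT.
    """
    return float(_irt_mixture_batch(params, target_rate, 1, rng)[0])


def _renewal_times(params: StrainParams, target_rate: float, start: float,
                   end: float, rng: np.random.Generator) -> np.ndarray:
    """Event times of a renewal process with mixture IRTs on [start, end)."""
    duration = end - start
    mean_irt = 60.0 / target_rate
    expected = duration / mean_irt
    times: list[np.ndarray] = []
    t = start
    # oversample in batches; a couple of iterations almost always suffice
    while t < end:
        n = int(expected + 5.0 * np.sqrt(expected + 1.0) + 20)
        irts = _irt_mixture_batch(params, target_rate, n, rng)
        # 1 ms refractory floor: keeps successive presses distinct even after
        # timestamps are rounded to 4 decimals for file output
        np.maximum(irts, 1e-3, out=irts)
        ts = t + np.cumsum(irts)
        inside = ts < end
        times.append(ts[inside])
        if not inside.all():
            break
        t = ts[-1]
    return np.concatenate(times) if times else np.empty(0)


def _simulate_rat(rat_id: str, strain: str, params: StrainParams,
                  design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    st = design.structure
    seg_d = st.segment_duration_s
    dur = st.session_duration_s
    rat_effect = rng.normal(0.0, params.rat_rate_sd_log) if params.rat_rate_sd_log > 0 else 0.0

    rows_time: list[np.ndarray] = []
    rows_type: list[np.ndarray] = []
    rows_session: list[np.ndarray] = []

    for session in range(1, design.n_sessions + 1):
        press_times: list[np.ndarray] = []
        door_times: list[np.ndarray] = []
        for k in range(st.n_segments):
            sigma = max(0.0, params.segment_dispersion_sd_log
                        + params.dispersion_trend_per_segment * k)
            mult = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            lever_rate = params.base_lever_rate * np.exp(rat_effect) * mult
            if lever_rate > 0:
                press_times.append(
                    _renewal_times(params, lever_rate, k * seg_d, (k + 1) * seg_d, rng))
            door_rate = params.incorrect_door_rate * mult  # per min
            if door_rate > 0:
                n_door = rng.poisson(door_rate * seg_d / 60.0)
                if n_door:
                    door_times.append(
                        np.sort(k * seg_d + rng.random(n_door) * seg_d))

        presses = np.concatenate(press_times) if press_times else np.empty(0)
        incorrect = rng.random(presses.size) < params.incorrect_lever_frac
        correct_times = presses[~incorrect]

        # VI schedule: reinforcer available after an exponential wait
        # (mean vi_mean_s, clipped to [1 s, 3*vi_mean_s]); the first correct
        # press at/after availability triggers a reinforcer, then one correct
        # door opening after a lognormal latency (median 1.5 s, sigma_log 0.4).
        reinf_times: list[float] = []
        cdoor_times: list[float] = []
        avail = float(np.clip(rng.exponential(design.vi_mean_s), 1.0,
                              3.0 * design.vi_mean_s))
        while avail < dur and correct_times.size:
            i = int(np.searchsorted(correct_times, avail, side="left"))
            if i >= correct_times.size:
                break
            t_r = float(correct_times[i])
            reinf_times.append(t_r)
            latency = float(np.exp(np.log(1.5) + 0.4 * rng.normal()))
            if t_r + latency < dur:
                cdoor_times.append(t_r + latency)
            avail = t_r + float(np.clip(rng.exponential(design.vi_mean_s), 1.0,
                                        3.0 * design.vi_mean_s))

        idoor = np.concatenate(door_times) if door_times else np.empty(0)
        # order of appending matters only for equal-time ties: a reinforcer
        # shares its timestamp with the triggering press and must follow it
        chunks = [
            (presses[~incorrect], "correct_lever"),
            (presses[incorrect], "incorrect_lever"),
            (np.asarray(reinf_times), "reinforcer"),
            (np.asarray(cdoor_times), "correct_door"),
            (idoor, "incorrect_door"),
        ]
        for ts, label in chunks:
            if ts.size:
                rows_time.append(ts)
                rows_type.append(np.full(ts.size, label, dtype=object))
                rows_session.append(np.full(ts.size, session, dtype=int))

    if not rows_time:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    time = np.round(np.concatenate(rows_time), 4)
    df = pd.DataFrame({
        "rat_id": rat_id,
        "strain": strain,
        "session": np.concatenate(rows_session),
        "time_s": time,
        "event_type": np.concatenate(rows_type),
    })
    # rounding can push an event in the last 50 microseconds onto the session
    # boundary; the interval is half-open, so drop it
    df = df[df["time_s"] < dur]
    # stable sort keeps press-before-reinforcer order at equal timestamps
    return df.sort_values(["session", "time_s"], kind="stable").reset_index(drop=True)


def simulate_experiment(design: SimulationDesign,
                        params_by_strain: Mapping[str, StrainParams],
                        seed: int | None = None) -> pd.DataFrame:
    """Simulate a full multi-rat, multi-session experiment.

    Returns an event table (``rat_id, strain, session, time_s, event_type``)
    sorted by rat, session and time, satisfying every event-model invariant.
    Times are rounded to 4 decimals so event files round-trip exactly.

    ``seed`` overrides ``design.seed``; identical seed and configuration
    produce a bit-identical table (and file).
    """
    missing = set(design.n_rats_per_strain) - set(params_by_strain)
    if missing:
        raise ValueError(f"no StrainParams for strain(s): {sorted(missing)}")
    seed = design.seed if seed is None else seed

    frames = []
    for s_idx, (strain, n_rats) in enumerate(design.n_rats_per_strain.items()):
        params = params_by_strain[strain]
        for r_idx in range(n_rats):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(s_idx, r_idx))
            rng = np.random.default_rng(ss)
            rat_id = f"{strain}{r_idx + 1:02d}"
            frames.append(_simulate_rat(rat_id, strain, params, design, rng))
    events = pd.concat(frames, ignore_index=True)
    return (events.sort_values(["rat_id", "session", "time_s"], kind="stable")
            .reset_index(drop=True))
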