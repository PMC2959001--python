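"""Shipped simulation presets and config-file parsing.

The default configuration (``data/default_config.toml``) defines an
"SHR-like" high-dispersion group and a "WKY-like" control group: the SHR-like
preset has higher base response rate, burst probability, incorrect-door rate
and segment-to-segment dispersion, and a positive within-session dispersion
trend, while the WKY-like preset has a mild negative trend.  These are
modelling choices that give the generator the qualitative structure the
analysis is designed to detect; they are not fitted to any real dataset.

Config files are TOML with a ``[design]`` table and one ``[strain.<label>]``
table per group; each strain table holds ``n_rats`` plus the
:class:`~operant_iiv.simulate.StrainParams` fields.
"""

from __future__ import annotations

import dataclasses
import tomllib
from importlib import resources

from .events import SessionStructure
from .simulate import SimulationDesign, StrainParams

__all__ = [
    "load_config",
    "default_config",
    "default_design",
    "default_strain_params",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(StrainParams)}


def _parse_config(cfg: dict, seed: int = 0) -> tuple[SimulationDesign, dict[str, StrainParams]]:
    design_cfg = dict(cfg.get("design", {}))
    strains = cfg.get("strain", {})
    if not strains:
        raise ValueError("config has no [strain.<label>] sections")
    structure = SessionStructure(
        session_duration_s=float(design_cfg.pop("session_duration_s", 5400.0)),
        n_segments=int(design_cfg.pop("n_segments", 5)),
    )
    n_rats = {}
    params = {}
    for label, entry in strains.items():
        entry = dict(entry)
        n_rats[label] = int(entry.pop("n_rats"))
        unknown = set(entry) - _PARAM_FIELDS
        if unknown:
            raise ValueError(f"[strain.{label}] has unknown key(s): {sorted(unknown)}")
        params[label] = StrainParams(**entry)
    design = SimulationDesign(
        n_rats_per_strain=n_rats,
        n_sessions=int(design_cfg.pop("n_sessions", 5)),
        structure=structure,
        vi_mean_s=float(design_cfg.pop("vi_mean_s", 180.0)),
        seed=seed,
    )
    if design_cfg:
        raise ValueError(f"[design] has unknown key(s): {sorted(design_cfg)}")
    return design, params


def load_config(path, seed: int = 0) -> tuple[SimulationDesign, dict[str, StrainParams]]:
    """Parse a TOML simulation config into a design and per-strain parameters."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return _parse_config(cfg, seed=seed)


def default_config(seed: int = 0) -> tuple[SimulationDesign, dict[str, StrainParams]]:
    """The shipped SHR-like vs WKY-like default configuration."""
    text = resources.files("operant_iiv").joinpath("data/default_config.toml").read_bytes()
    return _parse_config(tomllib.loads(text.decode("utf-8")), seed=seed)


def default_design(seed: int = 0) -> SimulationDesign:
    return default_config(seed=seed)[0]


def default_strain_params() -> dict[str, StrainParams]:
    return default_config()[1]
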