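"""Run configuration: one YAML file with a section per pipeline stage.

Unknown keys are rejected on load so typos surface immediately; every value
has a documented default, so an empty file is a valid configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .dielectrics import DEFAULT_DEBYE, DebyeParameters

__all__ = ["RunConfig", "load_config", "DEFAULTS"]


@dataclass(frozen=True)
class RunConfig:
    """Validated flat configuration for `stomadry run` and the library."""

    # schedule
    period_h: float = 24.0
    bright_h: float = 12.0
    t0_h: float = 0.0
    # extraction band (THz) and slab geometry
    band_lo_thz: float = 0.1
    band_hi_thz: float = 0.3
    thickness_um: float = 185.0
    dry_air_ratio: float = 1.0
    thickness_slope_um_per_wtpct: float = 0.0
    thickness_intercept_um: float = 0.0
    density_dry_g_cm3: float = 1.5
    fabry_perot: bool = False
    # double Debye water defaults (documented literature values)
    debye_eps_static: float = DEFAULT_DEBYE.eps_static
    debye_eps_intermediate: float = DEFAULT_DEBYE.eps_intermediate
    debye_eps_inf: float = DEFAULT_DEBYE.eps_inf
    debye_tau1_ps: float = DEFAULT_DEBYE.tau1_ps
    debye_tau2_ps: float = DEFAULT_DEBYE.tau2_ps
    drymat_band_lo_thz: float = 0.1
    drymat_band_hi_thz: float = 2.0
    # fitting
    gamma_bright_dark: float = 0.92
    m_dry: float = 17.5
    k3: float = 1e-3
    n_starts: int = 8
    master_seed: int = 20250923
    r2_threshold: float = 0.99
    test: str = "welch"
    # generation
    n_wildtype: int = 10
    n_mutant: int = 10
    seed: int = 42
    jitter_cv: float = 0.15
    horizon_days: float = 12.0
    cadence_min: float = 25.0
    # output
    out_dir: str = "stomadry_out"
    verbosity: str = "INFO"

    def debye(self) -> DebyeParameters:
        return DebyeParameters(
            eps_static=self.debye_eps_static,
            eps_intermediate=self.debye_eps_intermediate,
            eps_inf=self.debye_eps_inf,
            tau1_ps=self.debye_tau1_ps,
            tau2_ps=self.debye_tau2_ps,
        )

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_lo_thz, self.band_hi_thz)


DEFAULTS = RunConfig()

# YAML section -> config-field prefix mapping
_SECTIONS = {
    "schedule": ("period_h", "bright_h", "t0_h"),
    "band": ("band_lo_thz", "band_hi_thz"),
    "geometry": ("thickness_um", "dry_air_ratio",
                 "thickness_slope_um_per_wtpct", "thickness_intercept_um",
                 "density_dry_g_cm3", "fabry_perot"),
    "debye": ("debye_eps_static", "debye_eps_intermediate", "debye_eps_inf",
              "debye_tau1_ps", "debye_tau2_ps"),
    "drymat": ("drymat_band_lo_thz", "drymat_band_hi_thz"),
    "fit": ("gamma_bright_dark", "m_dry", "k3", "n_starts", "master_seed",
            "r2_threshold", "test"),
    "generate": ("n_wildtype", "n_mutant", "seed", "jitter_cv",
                 "horizon_days", "cadence_min"),
    "output": ("out_dir", "verbosity"),
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML config; keyword overrides win.

    The file is organised in sections (schedule, band, geometry, debye,
    drymat, fit, generate, output); keys inside a section map onto the flat
    :class:`RunConfig` fields.  Unknown sections or keys raise.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        for section, content in raw.items():
            if section not in _SECTIONS:
                raise ValueError(f"unknown config section {section!r}")
            if not isinstance(content, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            allowed = _SECTIONS[section]
            for key, val in content.items():
                matches = [f for f in allowed
                           if f == key or f == f"{section}_{key}"
                           or f.removeprefix(f"{section}_") == key]
                if not matches:
                    raise ValueError(
                        f"unknown key {key!r} in section {section!r}")
                values[matches[0]] = val
    values.update(overrides)
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    cfg = replace(DEFAULTS, **values)
    if cfg.band_lo_thz >= cfg.band_hi_thz:
        raise ValueError("band_lo_thz must be below band_hi_thz")
    cfg.debye()  # validates ordering
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)
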