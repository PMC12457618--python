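"""Synthetic plants and synthetic THz trace pairs.

Real drying campaigns are long (8-14 days per plant) and raw measurement
series are not bundled with the package, so every stage of the pipeline is
exercised against synthetic data with the statistical structure the analysis
assumes: 25-minute sampling, a 12 h / 12 h photoperiod, an initial plateau
at 80-85 wt%, a genotype-dependent phase I duration (about seven days for
the wildtype, four for the ost1-2 mutant), day-night oscillations in phase
II, collapse near 50 wt% at the wilting event, and additive Gaussian
measurement noise.

The preset parameter values are a package calibration: they were chosen once
so that the noise-free forward simulation reproduces those anchor features,
and they are fixed in version control.  The closure half-lives implied by
the presets are 12.3 h (wildtype) and 3.4 h (mutant), and the mutant's
open-stomata coefficient is 2.8 times the wildtype's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    DryingParams,
    LightSchedule,
    Trajectory,
    simulate_drying,
)
from .series import WaterContentSeries
from .thz import (
    LeafGeometry,
    TimeTrace,
    leaf_transfer_function,
    to_frequency_domain,
    weight_percent_to_volumetric,
)

__all__ = [
    "GenotypePreset",
    "PulseModel",
    "PRESETS",
    "WILDTYPE",
    "OST1_2",
    "generate_drying_series",
    "generate_cohort",
    "synthesize_thz_traces",
]

LN2 = math.log(2.0)

#: Parameters jittered per plant by :func:`generate_cohort`, in draw order.
#: k2_os is jittered through the positive increment over k2_cs so the
#: ordering k2_os >= k2_cs survives any jitter amplitude.
JITTERED_FIELDS = ("k1_max", "k3", "k2_cs", "dk2", "tau_h", "theta_wilt", "a_s0")


@dataclass(frozen=True)
class GenotypePreset:
    """Calibrated parameter set emulating one genotype."""

    name: str
    params: DryingParams
    m_dry: float
    noise_sd_wtpct: float = 1.0

    @property
    def t_half_h(self) -> float:
        return self.params.tau_h * LN2


WILDTYPE = GenotypePreset(
    name="wildtype",
    params=DryingParams(
        k1_max=0.047,
        k3=0.001,
        k2_os=0.068,
        k2_cs=0.004,
        tau_h=12.3 / LN2,          # closure half-life 12.3 h
        gamma_bright_dark=0.92,
        theta_wilt=33.0,
        a_l0=82.5,
        a_s0=505.0,
    ),
    m_dry=17.5,                    # maps a_l0 to an 82.5 wt% plateau
)

OST1_2 = GenotypePreset(
    name="ost1-2",
    params=WILDTYPE.params.with_(
        k2_os=2.8 * 0.068,         # 2.8x wider maximal stomatal opening
        tau_h=3.4 / LN2,           # closure half-life 3.4 h
    ),
    m_dry=17.5,
)

PRESETS: dict[str, GenotypePreset] = {"wildtype": WILDTYPE, "ost1-2": OST1_2}


@dataclass(frozen=True)
class PulseModel:
    """Analytic single-cycle reference pulse (Gaussian first derivative).

    The spectral envelope peaks near 1/(2 pi width_ps) THz, so the default
    0.5 ps width gives strong power across the 0.1-0.3 THz fit band.
    """

    center_ps: float = 10.0
    width_ps: float = 0.5
    amplitude: float = 1.0
    duration_ps: float = 50.0
    dt_ps: float = 0.05
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.center_ps < self.duration_ps):
            raise ValueError("pulse centre must lie inside the trace window")

    def times(self) -> np.ndarray:
        n = int(round(self.duration_ps / self.dt_ps))
        return np.arange(n) * self.dt_ps

    def field(self) -> np.ndarray:
        t = self.times()
        u = (t - self.center_ps) / self.width_ps
        return -self.amplitude * u * np.exp(-0.5 * u**2)


def generate_drying_series(
    preset: GenotypePreset,
    seed: int,
    horizon_days: float = 12.0,
    schedule: LightSchedule = LightSchedule(),
    cadence_min: float = 25.0,
    params: DryingParams | None = None,
    plant_id: str | None = None,
) -> WaterContentSeries:
    """One synthetic drying curve: forward simulation plus seeded noise.

    With ``noise_sd_wtpct = 0`` the series equals the deterministic
    simulation exactly; identical (preset, seed, horizon) inputs give
    byte-identical output.
    """
    p = params if params is not None else preset.params
    traj = simulate_drying(p, schedule, horizon_h=horizon_days * 24.0,
                           cadence_min=cadence_min, m_dry=preset.m_dry)
    wt = traj.water_wt_pct.copy()
    if preset.noise_sd_wtpct > 0:
        rng = np.random.default_rng(seed)
        wt = wt + rng.normal(0.0, preset.noise_sd_wtpct, size=wt.size)
        np.clip(wt, 0.0, 100.0, out=wt)
    return WaterContentSeries(
        traj.times_h, wt, traj.light,
        plant_id=plant_id or f"{preset.name}-{seed}",
        genotype=preset.name,
        meta={"seed": int(seed), "noise_sd_wtpct": preset.noise_sd_wtpct,
              "wilt_time_h": traj.wilt_time_h},
    )


def jitter_params(base: DryingParams, rng: np.random.Generator,
                  jitter_cv: float) -> DryingParams:
    """Lognormal per-plant jitter with the preset values as medians.

    Each field in :data:`JITTERED_FIELDS` is multiplied by
    exp(sigma * z) with sigma = sqrt(ln(1 + cv^2)) and z standard normal,
    drawn in the fixed field order.  k2_os is reconstructed as
    k2_cs + dk2.
    """
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be non-negative")
    sigma = math.sqrt(math.log(1.0 + jitter_cv**2))
    z = rng.standard_normal(len(JITTERED_FIELDS))
    factors = dict(zip(JITTERED_FIELDS, np.exp(sigma * z)))
    dk2 = (base.k2_os - base.k2_cs) * factors["dk2"]
    k2_cs = base.k2_cs * factors["k2_cs"]
    return base.with_(
        k1_max=base.k1_max * factors["k1_max"],
        k3=base.k3 * factors["k3"],
        k2_cs=k2_cs,
        k2_os=k2_cs + dk2,
        tau_h=base.tau_h * factors["tau_h"],
        theta_wilt=base.theta_wilt * factors["theta_wilt"],
        a_s0=base.a_s0 * factors["a_s0"],
    )


def generate_cohort(
    n_wildtype: int,
    n_mutant: int,
    seed: int,
    jitter_cv: float = 0.15,
    horizon_days: float = 12.0,
    schedule: LightSchedule = LightSchedule(),
    cadence_min: float = 25.0,
) -> list[WaterContentSeries]:
    """Synthetic cohort with per-plant lognormal parameter jitter.

    For each plant the parameter draw and an independent noise seed are
    taken from one master generator, so the full cohort is deterministic
    given ``seed``.
    """
    if n_wildtype < 1 or n_mutant < 1:
        raise ValueError("need at least one plant per genotype")
    rng = np.random.default_rng(seed)
    out: list[WaterContentSeries] = []
    for preset, n in ((WILDTYPE, n_wildtype), (OST1_2, n_mutant)):
        for i in range(n):
            p = jitter_params(preset.params, rng, jitter_cv)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            s = generate_drying_series(
                preset, noise_seed, horizon_days, schedule, cadence_min,
                params=p, plant_id=f"{preset.name}-{i:02d}")
            s.meta["true_params"] = p
            out.append(s)
    return out


def synthesize_thz_traces(
    water_wt_pct: float,
    geometry: LeafGeometry = LeafGeometry(),
    pulse: PulseModel = PulseModel(),
    seed: int | None = None,
) -> tuple[TimeTrace, TimeTrace]:
    """(reference, sample) trace pair for a leaf of given water content.

    The reference is the analytic pulse; the sample is the inverse Fourier
    transform of the reference spectrum multiplied by the theoretical
    Looyenga-slab transfer function at the matching water volume fraction.
    Independent Gaussian noise of ``pulse.noise_sd`` is added to both traces
    when a seed is given and the noise level is positive.
    """
    if not (0.0 <= water_wt_pct <= 100.0):
        raise ValueError("water content must lie in [0, 100] wt%")
    times = pulse.times()
    ref_field = pulse.field()
    ref_trace = TimeTrace(times, ref_field)
    spec = to_frequency_domain(ref_trace, window=None)

    x_water = weight_percent_to_volumetric(
        water_wt_pct, geometry.dry_air_ratio, geometry.density_dry_g_cm3)
    h = leaf_transfer_function(x_water, spec.grid, geometry).h
    # back to the numpy FFT convention before inverting
    sample_field = np.fft.irfft(np.conj(spec.amp * h), n=ref_field.size)

    if seed is not None and pulse.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ref_field = ref_field + rng.normal(0, pulse.noise_sd, ref_field.size)
        sample_field = sample_field + rng.normal(0, pulse.noise_sd,
                                                 sample_field.size)
        ref_trace = TimeTrace(times, ref_field)
    return ref_trace, TimeTrace(times, sample_field)
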