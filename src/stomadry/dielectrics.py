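"""Frequency-domain material models for leaf tissue in the terahertz band.

A fresh leaf is treated as an effective medium of liquid water, dry organic
matter and air.  This module provides the three ingredient permittivities and
the Landau-Lifshitz-Looyenga mixing rule that combines them into a single
complex dielectric function.

Sign convention
---------------
All spectra use ``eps = eps' + 1j*eps''`` with ``eps'' >= 0`` meaning loss
(physics time convention ``e^{-i omega t}``).  The transfer-function code in
:mod:`stomadry.thz` uses the same convention throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "DielectricSpectrum",
    "DebyeParameters",
    "MixingFractions",
    "water_permittivity",
    "dry_material_permittivity",
    "air_permittivity",
    "looyenga_mix",
    "DEFAULT_DEBYE",
    "DRY_MATTER_VALIDITY_BAND_THZ",
]

logger = logging.getLogger(__name__)

# Validity band of the measured dry-matter polynomial fit (THz); evaluation
# outside this band is extrapolation and is logged as a warning.
DRY_MATTER_VALIDITY_BAND_THZ: tuple[float, float] = (0.1, 2.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies in THz."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(freqs < 0):
            raise ValueError("frequencies must be non-negative")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)

    def __len__(self) -> int:
        return self.freqs.size

    def band_mask(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Boolean mask selecting frequencies in the closed band [f_lo, f_hi]."""
        return (self.freqs >= f_lo) & (self.freqs <= f_hi)


@dataclass(frozen=True)
class DielectricSpectrum:
    """Complex relative permittivity sampled on a :class:`FrequencyGrid`."""

    grid: FrequencyGrid
    eps: np.ndarray

    def __post_init__(self) -> None:
        eps = np.atleast_1d(np.asarray(self.eps, dtype=complex))
        if eps.shape != self.grid.freqs.shape:
            raise ValueError("eps must have the same length as the frequency grid")
        object.__setattr__(self, "eps", eps)

    @property
    def real(self) -> np.ndarray:
        return self.eps.real

    @property
    def imag(self) -> np.ndarray:
        return self.eps.imag


@dataclass(frozen=True)
class DebyeParameters:
    """Two-relaxation (double Debye) parameters for liquid water.

    ``eps_static > eps_intermediate > eps_inf > 0`` and ``tau1 > tau2 > 0``
    (relaxation times in picoseconds).
    """

    eps_static: float
    eps_intermediate: float
    eps_inf: float
    tau1_ps: float
    tau2_ps: float

    def __post_init__(self) -> None:
        if not (self.eps_static > self.eps_intermediate > self.eps_inf > 0):
            raise ValueError(
                "Debye limits must satisfy eps_static > eps_intermediate > eps_inf > 0"
            )
        if not (self.tau1_ps > self.tau2_ps > 0):
            raise ValueError("relaxation times must satisfy tau1 > tau2 > 0")


#: Room-temperature double-Debye parameters for liquid water, taken from the
#: THz spectroscopy literature (slow relaxation ~8.2 ps, fast ~0.18 ps).
#: Overridable through the ``debye.*`` config keys.
DEFAULT_DEBYE = DebyeParameters(
    eps_static=78.36,
    eps_intermediate=4.93,
    eps_inf=3.48,
    tau1_ps=8.24,
    tau2_ps=0.18,
)


@dataclass(frozen=True)
class MixingFractions:
    """Volume fractions of water, dry matter and air; must sum to one."""

    x_water: float
    x_dry: float
    x_air: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("x_water", "x_dry", "x_air"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.x_water + self.x_dry + self.x_air
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions sum to {total}, expected 1")


def water_permittivity(
    grid: FrequencyGrid, params: DebyeParameters = DEFAULT_DEBYE
) -> DielectricSpectrum:
    """Double Debye relaxation spectrum of liquid water.

    eps(f) = eps_inf + (eps_s - eps_1)/(1 - i 2 pi f tau1)
                     + (eps_1 - eps_inf)/(1 - i 2 pi f tau2)

    with f in THz and tau in ps (the product f*tau is dimensionless).  The
    minus sign in the denominators follows the package loss convention so
    that eps'' >= 0.
    """
    f = grid.freqs
    w1 = 2.0 * np.pi * f * params.tau1_ps
    w2 = 2.0 * np.pi * f * params.tau2_ps
    eps = (
        params.eps_inf
        + (params.eps_static - params.eps_intermediate) / (1.0 - 1j * w1)
        + (params.eps_intermediate - params.eps_inf) / (1.0 - 1j * w2)
    )
    return DielectricSpectrum(grid, eps)


def dry_material_permittivity(grid: FrequencyGrid) -> DielectricSpectrum:
    """Measured permittivity of dried, pressed leaf matter.

    Quadratic fits to transmission measurements on pressed pellets of dried
    Arabidopsis leaf powder, with f in THz:

        eps'(f)  = -0.01 f^2 - 0.18 f + 3.7
        eps''(f) = -0.08 f^2 + 0.43 f + 0.04

    Outside the measured band the polynomial is extrapolated (logged).  Where
    the eps'' quadratic dips below zero it is clamped to zero, since negative
    loss is unphysical for a passive material.
    """
    f = grid.freqs
    lo, hi = DRY_MATTER_VALIDITY_BAND_THZ
    if f[0] < lo or f[-1] > hi:
        logger.warning(
            "dry-matter polynomial evaluated outside its validity band "
            "%.2f-%.2f THz (grid spans %.3f-%.3f THz); extrapolating",
            lo, hi, f[0], f[-1],
        )
    eps_re = -0.01 * f**2 - 0.18 * f + 3.7
    eps_im = -0.08 * f**2 + 0.43 * f + 0.04
    if np.any(eps_im < 0):
        logger.warning("dry-matter eps'' < 0 at %d frequencies; clamping to 0",
                       int(np.sum(eps_im < 0)))
        eps_im = np.clip(eps_im, 0.0, None)
    return DielectricSpectrum(grid, eps_re + 1j * eps_im)


def air_permittivity(grid: FrequencyGrid) -> DielectricSpectrum:
    """Vacuum/air permittivity, eps = 1 at all frequencies."""
    return DielectricSpectrum(grid, np.ones(len(grid), dtype=complex))


def looyenga_mix(
    fractions: MixingFractions,
    eps_water: DielectricSpectrum,
    eps_dry: DielectricSpectrum,
    eps_air: DielectricSpectrum,
) -> DielectricSpectrum:
    """Landau-Lifshitz-Looyenga effective-medium mixing.

    eps_res^(1/3) = x_water eps_water^(1/3) + x_dry eps_dry^(1/3)
                    + x_air eps_air^(1/3)

    Cube roots use the principal complex branch.  All passive constituents
    have arguments in [0, pi), so the principal branch keeps Im(eps^(1/3))
    >= 0 and there is no branch ambiguity; this is asserted at runtime.
    """
    spectra = (eps_water, eps_dry, eps_air)
    grids = {id(s.grid): s.grid for s in spectra}
    ref = eps_water.grid.freqs
    for s in spectra[1:]:
        if s.grid.freqs.shape != ref.shape or not np.array_equal(s.grid.freqs, ref):
            raise ValueError("all constituent spectra must share one frequency grid")
    del grids

    roots = []
    for s in spectra:
        root = np.asarray(s.eps, dtype=complex) ** (1.0 / 3.0)
        if np.any(root.imag < -1e-12):
            raise FloatingPointError(
                "principal cube root left the physical half-plane; "
                "constituent permittivity has eps'' < 0"
            )
        roots.append(root)

    mixed_root = (
        fractions.x_water * roots[0]
        + fractions.x_dry * roots[1]
        + fractions.x_air * roots[2]
    )
    return DielectricSpectrum(eps_water.grid, mixed_root**3)
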