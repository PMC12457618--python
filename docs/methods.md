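# Methods

This note records the modelling assumptions, numerical choices and
calibration decisions behind stomadry, and what its synthetic-data tests do
and do not demonstrate about real measurements.

## Water-transport model

Two well-mixed pools (soil `A_s`, leaf `A_l`, arbitrary amount units) are
coupled by gradient-driven uptake `k1 (A_s - A_l)`; the leaf loses water by
stomatal transpiration `k2 A_l` and the soil by direct evaporation
`k3 A_s`. The model deliberately ignores root/xylem and xylem/leaf
interface resistances and any spatial structure: transpiration is treated as
the dominant driver of uptake, so a single series resistance (expressed
through `k1`) suffices.

`k1` is not a free function: while uptake demand is below the soil-retention
ceiling `k1_max`, it takes the equilibrium value `k2 A_l / (A_s - A_l)` that
keeps `dA_l/dt = 0` exactly — this is what produces the phase-I plateau. When
demand exceeds `k1_max` the coefficient is clamped and the leaf starts to
lose water (phase II). When `A_s` crosses the permanent wilting point
`theta_wilt`, `k1` drops to zero and stays there (a latching event): a step,
not a smooth roll-off, because only an abrupt interruption of uptake
reproduces the observed fast terminal decay. After the step the leaf pool
follows `exp(-∫k2 dt)` exactly, which the test suite checks against the
closed form to 1%.

`k2` is piecewise in the light cycle: an exponential decay from the
open-stomata level `k2_os` to the closed-stomata level `k2_cs` with time
constant `tau` during light, restarting at every dawn, and the constant
`Gamma * k2_cs` in darkness. `Gamma = 0.92` is a single empirical constant —
residual cuticular/hydathode loss makes bright closed-stomata loss slightly
exceed dark loss — and is configuration, not a per-plant parameter. The
closure half-life `t_1/2 = tau ln 2` is the headline physiological readout.
Hooks exist for a per-day multiplier on `k2_os` and a post-wilt multiplier
on `k2` (default 1; real phase-III loss can exceed the open-stomata level,
but no calibrated value is available, so the default keeps the plain
dynamics).

The observable is `wt% = 100 A_l / (A_l + m_dry)` with a fixed dry mass
`m_dry` per preset. Whether laboratories fit wt% directly or an internal
amount variable is a modelling choice; this package fits wt%.

## Integration

The ODEs are integrated with a fixed-step classical Runge-Kutta scheme
(default ceiling 0.0125 h = 45 s), restarted at every light/dark transition
so no step straddles a `k2` discontinuity; the wilting crossing is located
by linear interpolation inside the step that contains it and the step is
split there. Two cumulative loss integrals ride along as extra states, so
`A_l + A_s + losses` closes to solver accuracy (measured ~1e-14 relative;
the tests require 1e-3). A fixed-step kernel (numba-compiled, ~1 ms per
two-week simulation) was chosen over an adaptive library solver because the
fitting engine needs of the order of 10^5 simulations per cohort; the
piecewise-linear structure of the system makes fixed small steps both cheap
and accurate, and in the unclamped regime the leaf equation is satisfied
identically at every stage, so the plateau is exact rather than
tolerance-limited.

## Per-plant fitting

Weighted (uniform by default) least squares of the simulated wt% against the
observed series, via a trust-region-reflective solver on log10-transformed
rate parameters. Free parameters: `k1_max, k2_os, k2_cs, tau, theta_wilt,
a_s0`. `k2_os` is parametrised as `k2_cs + dk2` with `dk2 > 0` so the
open-stomata level cannot cross below the closed-stomata level. `a_l0` is
anchored to the observed initial plateau. `k3` is a configuration constant
by default rather than a free parameter: the leaf water content is almost
uninformative about soil-side evaporation (in phase I the observable is
exactly flat whatever `k3`), and freeing it opens a flat `k3`–`a_s0`
likelihood ridge that measurably degrades every other estimate; in a real
campaign `k3` comes from plant-free gravimetric soil controls. Set
`vary_k3=True` to free it.

Starts: the first start is data-driven (plateau → `a_l0`; the log-slope of
the last dark period after phase I → `k2_cs`; the first phase-II morning
slope → `dk2`, bumped adaptively until the guess curve actually leaves
phase I, since a guess that never leaves phase I produces an exactly
constant model curve with a zero jacobian); seven further starts perturb it
log-normally (0.2 dex) from a seeded generator. Best final objective wins.
Finite-difference steps of 1e-3 in log10 space keep the numerical gradient
above the interpolation noise of the fixed-step kernel.

Standard errors come from the linearized covariance, delta-transformed back
to natural units. They are reliable for the well-conditioned parameters
(`k1_max`, `k2_os`, `k2_cs`) but optimistic along the sloppy
`tau`–`theta_wilt`–`a_s0` valley; profile or bootstrap errors would be
needed there. Identifiability at the default study conditions (1 wt% noise,
12/10-day records): `k2_os` recovers with median bias below 5%; `tau`,
`theta_wilt`, `a_s0`, `k1_max` land within ~15%; `k2_cs`, whose only direct
signature is a ~0.03 wt%/h dark slope, scatters within ~50%. Cohort means
are correspondingly tighter (the acceptance run recovers the generating
half-lives and the k2_os ratio within the published spreads).

Fits are screened at R² > 0.99 before cohort statistics, mirroring the
screening used for real campaigns (plants that die early or detach never
reach the informative phases; note that an otherwise perfect fit of a
record that ends before the wilting event can sit below the threshold
simply because its total variance is small). Group comparisons use Welch's
unequal-variance t-test by default (Mann-Whitney optional) and the headline
ratio is the ratio of group means of `k2_os` with first-order error
propagation from the standard errors of the means; a parametric bootstrap
agrees with the propagated error to 10% in the tests.

## THz extraction chain

Spectra use the physics convention `e^{-i omega t}` with
`eps = eps' + i eps''`, `eps'' >= 0` meaning loss. Water follows a two-term
Debye model; the shipped parameters (eps_static 78.36, eps_intermediate
4.93, eps_inf 3.48, tau1 8.24 ps, tau2 0.18 ps) are literature-typical
room-temperature values and are overridable in config — any absolute wt%
comparison between laboratories hinges on this choice. Dry leaf matter uses
the measured quadratic fits (valid 0.1–2 THz; extrapolation is logged, and
the slightly negative eps'' the quadratic produces far outside the band is
clamped to zero). Mixing uses the Looyenga cube-root rule with principal
complex cube roots; all passive constituents have spectra in the upper
half-plane, so the principal branch is unambiguous (asserted at runtime).

The slab transfer function is single-pass Fresnel transmission referenced to
air; Fabry-Perot echoes are off by default (thin wet leaves are lossy
enough that echoes are negligible within a 50 ps window) and can be enabled
in config. A zero-thickness slab returns the identity by definition.
Extraction minimises the summed squared complex residual between the
experimental and theoretical transfer functions over 0.1–0.3 THz
(inclusive band edges) with the water volume fraction as the only free
parameter; the non-water volume is split by a fixed dry-matter/air ratio
(default 1.0, configurable — the true value is sample-dependent). The
drying leaf thins; a linear thickness law `d = intercept + slope * wt%` is
evaluated inside the objective at each candidate water fraction, which
keeps the problem one-dimensional and deterministic while avoiding the
truncation error of a separate thickness-update pass. The objective is
unimodal over the band for the default materials (checked against a
50-point grid scan), so a bounded scalar minimiser suffices. Volume-to-mass
conversion assumes water density 1 g/cm³ and dry-matter density 1.5 g/cm³.

## Synthetic data and calibration

The generator emulates the study conditions: 25-minute sampling, 12 h/12 h
photoperiod, additive Gaussian noise of SD 1 wt% (chosen so that clean
records clear the R² > 0.99 screen, matching the selection regime of real
campaigns), records of 8–14 days. Genotype presets were calibrated once
against the published anchors — initial plateau 80–85 wt%, phase I of about
7 days (wildtype) and 4 days (mutant) from irrigation stop, collapse near
50 wt%, closure half-lives 12.3 h and 3.4 h, k2_os ratio 2.8, Gamma 0.92 —
and are fixed in version control:

| parameter | wildtype | ost1-2 |
|---|---|---|
| k1_max (1/h) | 0.047 | 0.047 |
| k3 (1/h) | 0.001 | 0.001 |
| k2_os (1/h) | 0.068 | 0.1904 |
| k2_cs (1/h) | 0.004 | 0.004 |
| tau (h) | 12.3/ln 2 | 3.4/ln 2 |
| theta_wilt | 33 | 33 |
| a_l0 / a_s0 / m_dry | 82.5 / 505 / 17.5 | same |

`k1_max` and `theta_wilt` are genotype-independent by construction (the
mutation affects stomatal regulation, not root-soil transfer or the soil's
wilting threshold). Cohorts add per-plant lognormal jitter (CV 0.15 by
default) to the physiological parameters, drawn from a single master seed;
the draw algorithm is simple enough to reimplement independently, and a test
does exactly that.

What the synthetic data do **not** emulate: correlated (drift-like)
measurement noise, leaf-fixation artifacts, premature plant death (an
optional contamination hook is deliberately left off by default),
day-to-day modulation of the dawn opening, and any disagreement between the
true leaf optics and the Looyenga slab. Passing tests therefore demonstrate
internal consistency of the chain and recoverability under the stated noise
model, not absolute calibration of real spectrometer data — in particular
the absolute wt% scale of the THz chain depends on the Debye parameters,
the dry/air ratio and the thickness law, none of which are printed to full
precision in the public record.

## Problem sizes used in the checks

The reference recovery runs use 10 plants per genotype (12-day wildtype,
10-day mutant records, seeds fixed per run), the jittered-cohort check uses
4 + 4 plants over 14 days, and the extraction Monte Carlo uses 100 seeded
repeats; these sizes give sampling errors comfortably inside the asserted
tolerances while keeping a full suite run in the minutes range.
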