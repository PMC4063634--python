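# Methods

`runtumble` couples a single-cell signaling model of the *E. coli*
chemotaxis pathway to 1D run-and-tumble population dynamics and solves for
the steady-state distribution of a closed population analytically, with a
stochastic agent-based simulator as an independent check. This note
records the model, the choices that were genuinely open, the numerical
conventions, and what the shipped defaults do and do not establish.

## Model

**Receptor cluster (MWC).** The receptor-kinase cluster is a two-state
allosteric unit of cooperativity N whose activity (proportional to CheY-P)
is

    a = 1 / (1 + exp(F)),
    F = N * [ alpha(T) * (m0 - m) + f_signal ],        (kT units)

where m is the average methylation level and `f_signal` collects the
ligand and/or pH terms:

* attractant: `ln((1 + L/KI)/(1 + L/KA))` with KI < KA — rising attractant
  raises F and lowers activity;
* pH: per receptor type `ln((1 + 10^(pH-pKI))/(1 + 10^(pH-pKA)))`,
  weighted by the Tar and Tsr fractions f_a, f_s.  Tar's pK ordering
  (pKI > pKA) makes its term *fall* with pH (attractant response to
  acidification), Tsr's the opposite.  The base-10 form mirrors the pH
  scale; it reduces to the ligand form with 10^pH playing the role of a
  concentration.  A convention had to be chosen here (natural-log
  concentration forms are equally defensible); every result in the package
  depends only on the signs and magnitudes of the slopes, which are
  regime parameters.

**Adaptation.** Methylation relaxes the activity to an adapted level a0
with rate dm/dt = k_m (a0 - a).  k_m = 1/(tau_m · N · alpha · a0(1-a0)) so
that the *linearized activity* relaxation time is exactly `tau_m`; the
spec of the package is the activity-restoration timescale, not the raw
methylation rate.  Adaptation is perfect: the fixed point is a = a0
independent of the signal, giving the adapted methylation closed form

    m_ss = m0 + (f_signal - ln(1/a0 - 1)/N) / alpha(T),

which the implementation cross-checks against a bracketed root to 1e-10 on
every call.

**Temperature.** alpha(T) = alpha0 + (dalpha/dT)(T - T0) with
dalpha/dT > 0, and a0(T) = a0_ref + (da0/dT)(T - T0) with da0/dT > 0 (the
adapted CheY-P level rises with temperature).  The thermal response at
fixed m is proportional to (m0 - m): a cell adapted below the critical
methylation level m_c = m0 is a warm sensor, above it a cold sensor.  The
critical temperature solves m_ss(T_c) = m_c, equivalently a0(T_c) = 1/2;
it depends only on receptor kinetics, never on motor parameters.  The
positive sign of dalpha/dT is forced by the inversion logic (warm sensing
at sub-critical methylation requires ∂F/∂T > 0 when m < m0).

**Motor.** CW bias is a Hill function `a^H / (a^H + K(T)^H)` with H = 10
(ultrasensitive).  The rate of entering the tumble state is
z_m = bias/tau_tumble; a tumble redraws the direction uniformly from
{+1, −1} (half of tumbles reverse).  Rotational diffusion reverses the
direction at rate 2·D_r in the 1D two-direction reduction.  Tumbles are
instantaneous; tau_tumble only normalizes the rate.

**Steady state.** For the two-direction master equation with reversal
rates nu± the zero-flux steady state obeys exactly

    d ln(v P) / dx = -(nu+ - nu-) / v.

The direction-conditioned mean activities split by
Δa = a+ − a− = −v·a0(1−a0)·(∂F/∂x|m) / (nu + 1/(2·tau_m)) with
nu = z_m/2 + 2·D_r the total reversal rate: Δa is proportional to the run
length v/nu (older memories, larger split) and is cut off by adaptation
itself (the 1/(2 tau_m) term).  Using Δnu = ½ (dz_m/da) Δa,

    P_s(x) ∝ v(x)^{-1} · exp( ∫ (chi(x')/N) ∂F/∂x'|m dx' ),
    chi = N·a0(1-a0) · [H(1-B0)/a0] · z_m / (z_m + 4·D_r + 1/tau_m),

the product of the receptor gain, the motor gain (B0 = adapted CW bias)
and a damping factor collecting everything that erases directional
memory.  For a single attractant at constant speed this is exactly
P_s ∝ [(1+L/KI)/(1+L/KA)]^chi; the package's permanent self-consistency
test requires the general solver to match this closed form to 1e-8, which
pins every constant above.  The same machinery specialized to pH,
temperature, or mixed signals yields the preferred-point condition
(d ln vP/dx = 0), the Gaussian near-T_c approximation
P ∝ v^{-1} exp(−β (T−T_c)²) with β = 2 chi (dalpha/dT)(da0/dT)/(N alpha),
and the combined-gradient interference (the ligand term loads the
methylation set point, shifting where the thermal drift changes sign).

These derivation constants are *this package's* — they are exact for the
reorientation conventions of its own simulator (tumble randomization,
reversal at 2·D_r), and they are enforced by two permanent tests: the
closed-form identity above and simulator↔theory agreement (KL < 0.01) in
all four scenario families.

## Parameters (defaults) and why

| parameter | default | note |
|---|---|---|
| N | 6 | receptor cooperativity (MeAsp/Tar cluster scale) |
| KI, KA | 18, 3000 µM | MeAsp/Tar dissociation constants |
| alpha0 | 2 kT/methyl | methylation free energy at T0 |
| m0 (= m_c) | 1 | reference/critical methylation |
| a0_ref | 0.5 | adapted activity at T0; receptor gain maximal |
| tau_m | 10 s | activity relaxation time |
| H | 10 | motor Hill coefficient |
| K_ref | 0.5 | motor threshold = a0_ref: adapted CW bias 1/2 |
| kappa | 0.01 /°C | K(T) slope; = (da0/dT)/a0_ref, motor tracks set point |
| tau_tumble | 0.2 s | tumble duration (rate normalization only) |
| D_r | 0.062 /s | rotational diffusion |
| v0 | 20 µm/s | swimming speed |
| T0 | 25 °C | reference temperature; T_c = 25 °C with these slopes |
| dalpha/dT | 0.35 kT/°C/methyl | keeps alpha > 0 down to 19.3 °C |
| da0/dT | 0.005 /°C | gentle set-point drift (see below) |

Two defaults deserve comment, because they were revised during
development and the reasons are substantive:

* **Motor operating point (K_ref = a0_ref).**  With H = 10, an adapted
  bias far from 1/2 places the motor on a strongly convex part of the
  Hill curve.  Run-history fluctuations of the activity (standard
  deviation ~ v·|∂F/∂x|·sqrt(tau_m/2 nu), which the ultrasensitive motor
  amplifies by H/a0) then renormalize the mean tumbling rates beyond the
  leading-order theory, and the simulated density tilt falls ~10% short
  of chi at *any* gradient steepness.  At the half-max point the
  curvature term vanishes and simulator and theory agree to a few
  percent.  The leading-order framework is self-consistent only with the
  motor near its sensitive midpoint — which is also where a
  narrow-operating-range motor is supposed to sit.

* **Thermal slopes and kappa.**  Three published claims compete
  quantitatively: visible accumulation at T_c, insensitivity of the
  density to kappa (< 5% sup-norm), and interior preferred temperatures
  under opposing attractant gradients.  With H = 10, the kappa = 0
  comparator saturates the motor wherever a0(T) drifts more than ~1/H
  from K, so insensitivity requires a gentle set-point drift
  (da0/dT = 0.005/°C) with K(T) tracking it (kappa = da0/dT / a0_ref,
  the "balanced" thermal robustness of the pathway).  Within that
  constraint the accumulation contrast is maximized by the largest
  admissible dalpha/dT (bounded by alpha > 0 at the cold wall), giving a
  contrast of 1.43 over 20–30 °C.  The combined-gradient scenario then
  requires sub-µM attractant scales (midpoint 0.1 µM, gradients in
  nM/mm): the set point absorbs N·f_L, which must stay inside the narrow
  range of ln(1/a0(T) − 1) across the chamber for the preference to
  remain interior.

## The simulator (what a green oracle test establishes)

Each agent carries (x, direction, m); activity follows deterministically
from (m, x).  Per step (dt = 8 ms, bounding dt·z_max < 0.05): Euler
update of m (signaling sub-sampled 4:1 against motion), tumble with
probability z_m dt, rotational reversal with probability 2 D_r dt,
advection by ±v dt with reflective walls.  Cells start uniform in space
with locally adapted memories; burn-in (350 s ≥ 10 tau_m and ≥ 3 spatial
relaxation times) is discarded; the histogram is the time-and-ensemble
occupancy of 64 bins over ~1150 s; a stationarity diagnostic compares the
third and fourth quarters of the averaging window.  A single seeded
generator drives everything; runs are bit-reproducible.

The simulator emulates an ideal 1D chamber: no cell–cell interactions, no
consumption or secretion, no growth, no finite tumble time, no
hydrodynamics, and 1D reorientation statistics rather than 3D angle
distributions.  Agreement therefore validates the steady-state
*derivation* (memory-driven tumbling asymmetry plus speed effects), not
the realism of any particular parameter value.

Known systematic in thermal scenarios: when the adapted activity a0(T)
varies along the channel, a moving cell's activity lags behind the
*drifting set point*, adding a direction-dependent source ~ -v·da0/dx to
the activity split that the published steady-state expressions (and this
package's analytic layer, which follows them) do not include.  With any
linear alpha(T) this warm-pushing term is comparable to the near-T_c
restoring drift, so the simulated thermal accumulation sits somewhat warm
of T_c while the analytic profile peaks exactly at T_c; at the shipped
shallow contrasts the two stay within the KL < 0.01 oracle band.  Treat
the analytic thermal peak location as the leading-order (published)
result, and the simulator as the model's full answer.

Known systematic at the walls: reflective boundaries carry
memory-length (sqrt(2 D tau_m) ≈ 50 µm) layers where the bulk
exponential-tilt form does not hold; `fit_chi` therefore excludes one
memory length per wall when motor parameters are supplied.  The KL
criterion integrates over these layers and passes without exclusions.

## Numerical conventions

* Drift exponent accumulated by cumulative Simpson quadrature on an
  8-fold refined grid, in log space, normalized by the trapezoid rule on
  the reporting grid (512 cells by default; halving the spacing moves
  densities by < 1e-6).
* Preferred points by sign-change bracketing of d ln(vP)/dx on the grid
  followed by Brent's method; multiple maxima are all reported, with a
  warning, and the first is returned.
* Adapted methylation closed form cross-checked against `brentq` at
  1e-10 on every call; adapted activities outside (0,1) and motor
  thresholds outside (0,1) raise instead of clipping (they indicate
  misconfiguration, not physics).
* Dispersion is computed on the signal axis (pH or °C), not the spatial
  axis.
* The near-T_c Gaussian form is exposed for diagnostics only; all shipped
  results use the full solver.

## pH regimes

The three shipped dissociation-constant regimes realize the tunability
trichotomy by window geometry, and were frozen after a one-time numeric
survey: `separated` (windows disjoint; the preference sits on both
exponential tails; eta ≈ 0.55, weak restoring force), `balanced` (windows
meet at the preference; eta ≈ 0.98; steepest well, minimal dispersion —
the accuracy optimum, at the price of modest tunability), `overlapping`
(broad overlap; eta ≈ 2.1; most tunable, least accurate).  eta is defined
against log10 of the Tar/Tsr ratio.  The wild-type default is the
`balanced` regime.

## Limitations

Closed (zero-flux) chambers only — open geometries with through-flux have
a different steady state.  Linear/exponential signal profiles in the
simulator (the analytic layer also accepts tabulated profiles).  The
leading-order theory degrades for steep gradients (fitted sensitivity
falls with steepness — a real closed-chamber effect, not an artifact),
near walls (memory layers), and for motors biased far from half-max
(Hill-curvature renormalization).  Receptor-type-specific methylation
kinetics are deliberately averaged into a single m.
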