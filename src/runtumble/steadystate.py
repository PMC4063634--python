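"""Analytic steady-state cell distributions in 1D closed chambers.

For a run-and-tumble population with internal adaptation, the zero-flux
steady state of the two-direction master equation is

    P_s(x)  ∝  v(x)^{-1} · exp( ∫ (χ(x')/N) · ∂F/∂x'|_m  dx' ),

where F is the total receptor free energy (kT, including the cooperativity
factor N), the derivative is taken at fixed methylation and evaluated at
the locally adapted state, and χ is the effective population sensitivity

    χ = N·a0(1-a0) · [H(1-B0)/a0] · z_m / (z_m + 4·D_r + 1/τ_m),

the product of the receptor gain, the motor gain (B0 is the adapted CW
bias, z_m the adapted motor tumbling rate) and a damping factor collecting
every process that erases directional memory: tumbling, rotational
diffusion and adaptation itself.  Specialized to a single attractant with
constant speed this reduces to the closed form
P_s ∝ [(1+L/KI)/(1+L/KA)]^χ.

The agent-based simulator in :mod:`runtumble.abm` is the independent
oracle for every formula in this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, trapezoid
from scipy.optimize import brentq

from .params import ReceptorParams, MotorParams
from .environments import Environment1D
from .motility import SpeedProfile, cw_bias, motor_K
from . import signaling as sig

__all__ = [
    "DensityProfile",
    "SensitivitySummary",
    "sensitivity_chi",
    "activity_difference",
    "tumbling_rate_difference",
    "steady_state_density",
    "chemotaxis_closed_form",
    "fit_chi",
    "effective_potential",
    "preferred_point",
    "ph_tunability",
    "dispersion",
    "thermo_density",
    "thermo_density_leading_order",
    "combined_density",
    "infer_mode",
]

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Steady-state population profile on a spatial grid.

    density integrates to one over the grid (trapezoid rule); potential is
    U(x) = -ln P_s(x) shifted so min U = 0.
    """

    grid: np.ndarray
    density: np.ndarray
    activity: np.ndarray
    methylation: np.ndarray
    potential: np.ndarray
    signals: Dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = ""

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        norm = trapezoid(self.density, self.grid)
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"density normalization off by {norm - 1.0:.2e}")

    def to_frame(self) -> pd.DataFrame:
        cols = {"x": self.grid}
        for name, arr in self.signals.items():
            cols[name] = arr
        cols.update(
            density=self.density,
            activity=self.activity,
            methylation=self.methylation,
            potential=self.potential,
        )
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class SensitivitySummary:
    """Effective population sensitivity χ and its factors."""

    chi: float
    receptor_gain: float  # N*a0*(1-a0)
    motor_gain: float  # d ln z_m / da at a0 = H*(1-B0)/a0
    damping: float  # z_m / (z_m + 4*D_r + 1/tau_m)
    z_motor: float  # adapted motor tumbling rate, 1/s
    reversal_rate: float  # direction reversal rate nu = z_m/2 + 2*D_r, 1/s


# ---------------------------------------------------------------------------
# adapted state and drift ingredients
# ---------------------------------------------------------------------------

def infer_mode(env: Environment1D) -> str:
    """Scenario family implied by which profiles the environment carries."""
    has_L = env.ligand is not None
    has_T = env.temperature is not None
    has_pH = env.ph is not None
    if has_pH and not (has_L or has_T):
        return "ph"
    if has_L and has_T:
        return "mixed"
    if has_T:
        return "thermo"
    if has_L:
        return "chemo"
    raise ValueError("environment carries no signal profile")


def _adapted_state(x: np.ndarray, env: Environment1D, rp: ReceptorParams, mode: str):
    """Vectorized adapted state along the grid.

    Returns (a0, m_ss, T, alpha) arrays; T is None for isothermal modes.
    """
    if mode in ("thermo", "mixed"):
        T = np.asarray(env.signal_at(x, "temperature"), dtype=float)
        a0 = sig.adapted_activity(T, rp)
        alpha = rp.alpha0 + rp.thermo.dalpha_dT * (T - rp.thermo.T0)
        if np.any(alpha <= 0):
            raise ValueError("alpha(T) must stay positive on the domain")
    else:
        T = None
        a0 = np.full_like(x, rp.a0_ref, dtype=float)
        alpha = np.full_like(x, rp.alpha0, dtype=float)
    f0 = np.log(1.0 / a0 - 1.0)
    if mode == "chemo":
        f_sig = rp.N * sig.ligand_term(env.signal_at(x, "ligand"), rp.KI, rp.KA)
    elif mode == "ph":
        pH = env.signal_at(x, "ph")
        ph = rp.ph
        f_sig = rp.N * (
            ph.f_a * sig.ph_term(pH, ph.pKI_tar, ph.pKA_tar)
            + ph.f_s * sig.ph_term(pH, ph.pKI_tsr, ph.pKA_tsr)
        )
    elif mode == "thermo":
        f_sig = np.zeros_like(x, dtype=float)
    else:  # mixed
        f_sig = rp.N * sig.ligand_term(env.signal_at(x, "ligand"), rp.KI, rp.KA)
    m_ss = rp.m0 + (np.asarray(f_sig) - f0) / (rp.N * alpha)
    return a0, m_ss, T, alpha


def _free_energy_slope(x: np.ndarray, env: Environment1D, rp: ReceptorParams,
                       mode: str, m_ss: np.ndarray, alpha: np.ndarray):
    """∂F/∂x at fixed methylation, evaluated at the locally adapted state."""
    Fx = np.zeros_like(x, dtype=float)
    if mode in ("chemo", "mixed"):
        L = np.asarray(env.signal_at(x, "ligand"), dtype=float)
        dL = np.asarray(env.signal_slope(x, "ligand"), dtype=float)
        Fx += rp.N * (1.0 / (L + rp.KI) - 1.0 / (L + rp.KA)) * dL
    if mode == "ph":
        pH = np.asarray(env.signal_at(x, "ph"), dtype=float)
        dpH = np.asarray(env.signal_slope(x, "ph"), dtype=float)
        ph = rp.ph

        def dterm(pK_I, pK_A):
            uI = 10.0 ** (pH - pK_I)
            uA = 10.0 ** (pH - pK_A)
            return _LN10 * (uI / (1.0 + uI) - uA / (1.0 + uA))

        Fx += rp.N * (ph.f_a * dterm(ph.pKI_tar, ph.pKA_tar)
                      + ph.f_s * dterm(ph.pKI_tsr, ph.pKA_tsr)) * dpH
    if mode in ("thermo", "mixed"):
        dT = np.asarray(env.signal_slope(x, "temperature"), dtype=float)
        Fx += rp.N * rp.thermo.dalpha_dT * (rp.m0 - m_ss) * dT
    return Fx


def sensitivity_chi(rp: ReceptorParams, mp: MotorParams,
                    T: Optional[float] = None) -> SensitivitySummary:
    """Effective population sensitivity χ at the adapted state.

    χ is proportional to the receptor gain N·a0(1-a0) and the motor gain
    H(1-B0)/a0 and is damped by rotational diffusion (χ → 0 as D_r → ∞).
    The damping denominator z_m + 4·D_r + 1/τ_m collects the loss of
    directional memory by tumbling, rotational diffusion and adaptation.
    """
    Tq = rp.thermo.T0 if T is None else float(T)
    a0 = float(sig.adapted_activity(Tq, rp))
    B0 = float(cw_bias(a0, mp, Tq))
    z_m = B0 / mp.tau_tumble
    receptor_gain = rp.N * a0 * (1.0 - a0)
    motor_gain = mp.H * (1.0 - B0) / a0
    damping = z_m / (z_m + 4.0 * mp.D_r + 1.0 / rp.tau_m)
    nu = 0.5 * z_m + 2.0 * mp.D_r
    return SensitivitySummary(
        chi=receptor_gain * motor_gain * damping,
        receptor_gain=receptor_gain,
        motor_gain=motor_gain,
        damping=damping,
        z_motor=z_m,
        reversal_rate=nu,
    )


def _chi_profile(x: np.ndarray, env: Environment1D, rp: ReceptorParams,
                 mp: MotorParams, mode: str, a0: np.ndarray, T):
    """Pointwise χ(x) along the grid (varies only through a0(T) and K(T))."""
    if T is None:
        s = sensitivity_chi(rp, mp)
        return np.full_like(x, s.chi, dtype=float)
    K = np.asarray(motor_K(T, mp), dtype=float)
    r = np.exp(mp.H * (np.log(a0) - np.log(K)))
    B0 = r / (1.0 + r)
    z_m = B0 / mp.tau_tumble
    receptor_gain = rp.N * a0 * (1.0 - a0)
    motor_gain = mp.H * (1.0 - B0) / a0
    damping = z_m / (z_m + 4.0 * mp.D_r + 1.0 / rp.tau_m)
    return receptor_gain * motor_gain * damping


def activity_difference(x, env: Environment1D, rp: ReceptorParams,
                        mp: MotorParams, mode: Optional[str] = None):
    """Mean-activity split Δa(x) = a₊(x) - a₋(x) between direction classes.

    Δa = -v·a0(1-a0)·(∂F/∂x|_m) / (ν + 1/(2τ_m)),  ν = z_m/2 + 2·D_r,

    proportional to the run length v/ν: longer runs carry older memories and
    widen the split.  Negative where an attractant increases to the right
    (right-movers are less active and tumble less).
    """
    mode = mode or infer_mode(env)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    a0, m_ss, T, alpha = _adapted_state(xs, env, rp, mode)
    Fx = _free_energy_slope(xs, env, rp, mode, m_ss, alpha)
    v = np.asarray(env.speed_at(xs), dtype=float)
    Tq = rp.thermo.T0 if T is None else T
    K = np.asarray(motor_K(Tq, mp), dtype=float)
    r = np.exp(mp.H * (np.log(a0) - np.log(K)))
    B0 = r / (1.0 + r)
    z_m = B0 / mp.tau_tumble
    nu = 0.5 * z_m + 2.0 * mp.D_r
    out = -v * a0 * (1.0 - a0) * Fx / (nu + 0.5 / rp.tau_m)
    return float(out[0]) if np.isscalar(x) else out


def tumbling_rate_difference(x, env: Environment1D, rp: ReceptorParams,
                             mp: MotorParams, mode: Optional[str] = None):
    """Δz(x) = (dz_m/da at a0) · Δa(x); same sign as Δa (1/s)."""
    mode = mode or infer_mode(env)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    a0, m_ss, T, _ = _adapted_state(xs, env, rp, mode)
    Tq = rp.thermo.T0 if T is None else T
    K = np.asarray(motor_K(Tq, mp), dtype=float)
    r = np.exp(mp.H * (np.log(a0) - np.log(K)))
    B0 = r / (1.0 + r)
    z_m = B0 / mp.tau_tumble
    dz_da = z_m * mp.H * (1.0 - B0) / a0
    da = activity_difference(xs, env, rp, mp, mode)
    out = dz_da * np.atleast_1d(da)
    return float(out[0]) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# the general solver and its specializations
# ---------------------------------------------------------------------------

def _log_density_unnorm(xf: np.ndarray, env: Environment1D, rp: ReceptorParams,
                        mp: MotorParams, mode: str):
    """ln(P) up to a constant on the fine grid xf."""
    a0, m_ss, T, alpha = _adapted_state(xf, env, rp, mode)
    Fx = _free_energy_slope(xf, env, rp, mode, m_ss, alpha)
    chi = _chi_profile(xf, env, rp, mp, mode, a0, T)
    integrand = chi / rp.N * Fx
    E = cumulative_simpson(integrand, x=xf, initial=0.0)
    v = np.asarray(env.speed_at(xf), dtype=float)
    lnP = E - np.log(v)
    if not np.all(np.isfinite(lnP)):
        raise FloatingPointError("non-normalizable density (overflow in exponent)")
    return lnP, a0, m_ss


def steady_state_density(env: Environment1D, rp: ReceptorParams, mp: MotorParams,
                         mode: Optional[str] = None, refine: int = 8) -> DensityProfile:
    """General steady-state density P_s(x) on the environment grid.

    The drift exponent is accumulated by cumulative Simpson quadrature on a
    grid refined ``refine``-fold (log-domain accumulation, normalized by the
    trapezoid rule on the reporting grid).
    """
    mode = mode or infer_mode(env)
    centers = env.grid
    xf = np.union1d(
        np.linspace(env.x_min, env.x_max, refine * env.n_grid + 1), centers
    )
    lnP_f, _, _ = _log_density_unnorm(xf, env, rp, mp, mode)
    idx = np.searchsorted(xf, centers)
    lnP = lnP_f[idx]
    a0, m_ss, T, alpha = _adapted_state(centers, env, rp, mode)
    lnP -= lnP.max()
    dens = np.exp(lnP)
    dens /= trapezoid(dens, centers)
    U = -np.log(dens)
    signals = {}
    for kind, col in (("ligand", "ligand"), ("ph", "pH"), ("temperature", "T")):
        try:
            signals[col] = np.asarray(env.signal_at(centers, kind), dtype=float)
        except ValueError:
            pass
    return DensityProfile(
        grid=centers, density=dens, activity=a0, methylation=m_ss,
        potential=U - U.min(), signals=signals, mode=mode,
    )


def chemotaxis_closed_form(env: Environment1D, chi: float,
                           rp: ReceptorParams) -> DensityProfile:
    """Closed-form chemotaxis profile P_s ∝ [(1+L/KI)/(1+L/KA)]^χ."""
    x = env.grid
    L = np.asarray(env.signal_at(x, "ligand"), dtype=float)
    lnP = chi * np.asarray(sig.ligand_term(L, rp.KI, rp.KA))
    lnP -= lnP.max()
    dens = np.exp(lnP)
    dens /= trapezoid(dens, x)
    a0 = np.full_like(x, rp.a0_ref)
    m_ss = rp.m0 + (rp.N * sig.ligand_term(L, rp.KI, rp.KA)
                    - math.log(1.0 / rp.a0_ref - 1.0)) / (rp.N * rp.alpha0)
    U = -np.log(dens)
    return DensityProfile(grid=x, density=dens, activity=a0, methylation=m_ss,
                          potential=U - U.min(), signals={"ligand": L}, mode="chemo")


def fit_chi(profile: DensityProfile, env: Environment1D, rp: ReceptorParams,
            mp: Optional[MotorParams] = None):
    """Least-squares estimate of χ from a density profile.

    Regresses ln(density) on the closed-form kernel ln((1+L/KI)/(1+L/KA));
    returns (chi_hat, r_squared).  When motor parameters are supplied, a
    boundary margin of one directional memory length sqrt(2·D·τ_m)
    (D = v²/2ν the run-and-tumble diffusivity) is excluded at each wall:
    the exponential-tilt form is a bulk result and reflective walls carry
    memory-length boundary layers outside its validity.
    """
    x = profile.grid
    L = np.asarray(env.signal_at(x, "ligand"), dtype=float)
    kernel = np.asarray(sig.ligand_term(L, rp.KI, rp.KA), dtype=float)
    if np.ptp(kernel) < 1e-12:
        raise ValueError("degenerate (constant) ligand kernel; cannot fit chi")
    mask = profile.density > 0
    if mp is not None:
        s = sensitivity_chi(rp, mp)
        v = float(np.mean(np.asarray(env.speed_at(x), dtype=float)))
        D = v**2 / (2.0 * s.reversal_rate)
        margin = math.sqrt(2.0 * D * rp.tau_m)
        mask &= (x > env.x_min + margin) & (x < env.x_max - margin)
        if mask.sum() < 8:
            raise ValueError("domain too short for the boundary margin")
    y = np.log(profile.density[mask])
    A = np.vstack([kernel[mask], np.ones(mask.sum())]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), r2


def effective_potential(profile: DensityProfile) -> np.ndarray:
    """U(x) = -ln P_s(x), shifted so the minimum is zero."""
    if np.any(profile.density <= 0):
        raise ValueError("density must be positive to define the potential")
    U = -np.log(profile.density)
    return U - U.min()


# ---------------------------------------------------------------------------
# preferred points, tunability, dispersion
# ---------------------------------------------------------------------------

def _drift_integrand_fn(env: Environment1D, rp: ReceptorParams, mp: MotorParams,
                        mode: str):
    """d ln P_s / dx as a callable of position."""

    def f(x):
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        a0, m_ss, T, alpha = _adapted_state(xs, env, rp, mode)
        Fx = _free_energy_slope(xs, env, rp, mode, m_ss, alpha)
        chi = _chi_profile(xs, env, rp, mp, mode, a0, T)
        term = chi / rp.N * Fx
        # speed term -dlnv/dx by center difference (analytic for constant v)
        h = env.length * 1e-7
        lo = np.maximum(xs - h, env.x_min)
        hi = np.minimum(xs + h, env.x_max)
        v_lo = np.asarray(env.speed_at(lo), dtype=float)
        v_hi = np.asarray(env.speed_at(hi), dtype=float)
        dlnv = (np.log(v_hi) - np.log(v_lo)) / (hi - lo)
        out = term - dlnv
        return out if out.size > 1 else float(out[0])

    return f


def preferred_point(env: Environment1D, rp: ReceptorParams, mp: MotorParams,
                    mode: Optional[str] = None) -> dict:
    """Interior accumulation point, where d ln P_s/dx crosses zero.

    Returns a dict with ``x_star``, the signal value there (``pH_star`` or
    ``T_star`` as applicable), and ``interior`` (False when the drift never
    changes sign, in which case the reported point is the denser boundary).
    """
    mode = mode or infer_mode(env)
    f = _drift_integrand_fn(env, rp, mp, mode)
    x = env.grid
    vals = np.atleast_1d(f(x))
    s = np.sign(vals)
    crossings = np.nonzero(np.diff(s) != 0)[0]
    out: dict = {"mode": mode, "interior": False, "roots": []}
    if crossings.size == 0:
        x_star = x[0] if vals.mean() < 0 else x[-1]
        out["x_star"] = float(x_star)
    else:
        roots = [brentq(lambda q: np.atleast_1d(f(q))[0], x[i], x[i + 1], xtol=1e-10)
                 for i in crossings]
        # keep maxima (drift + -> -); report all roots for diagnostics
        maxima = [r for i, r in zip(crossings, roots) if s[i] > 0]
        out["roots"] = [float(r) for r in roots]
        out["interior"] = bool(maxima)
        out["x_star"] = float(maxima[0]) if maxima else float(
            x[0] if vals.mean() < 0 else x[-1])
        if len(maxima) > 1:
            warnings.warn("multiple interior accumulation points; reporting the first")
    if env.ph is not None:
        out["pH_star"] = float(env.signal_at(out["x_star"], "ph"))
    if env.temperature is not None:
        out["T_star"] = float(env.signal_at(out["x_star"], "temperature"))
    return out


def ph_tunability(ratios: Sequence[float], env: Environment1D,
                  rp: ReceptorParams, mp: MotorParams) -> dict:
    """Tunability of the preferred pH with the Tar/Tsr abundance ratio.

    Computes pH* for each ratio, regresses pH* on log10(ratio) and returns
    eta = -slope (positive when more Tar shifts the preference to lower pH),
    the regression R², the intercept (pH* at ratio 1) and the per-ratio
    table.  Ratios whose preferred point hits the boundary are excluded
    with a warning.
    """
    from dataclasses import replace

    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size < 4 or np.log10(ratios.max() / ratios.min()) < 1.0 - 1e-9:
        raise ValueError("need >= 4 ratios spanning at least one decade")
    rows = []
    for r in ratios:
        rp_r = replace(rp, ph=rp.ph.with_ratio(float(r)))
        pt = preferred_point(env, rp_r, mp, mode="ph")
        if not pt["interior"]:
            warnings.warn(f"ratio {r:g}: preferred point at boundary; excluded")
            continue
        rows.append((float(r), pt["pH_star"]))
    if len(rows) < 3:
        raise ValueError("too few interior preferred points to regress")
    logr = np.log10([r for r, _ in rows])
    ph_star = np.array([p for _, p in rows])
    A = np.vstack([logr, np.ones_like(logr)]).T
    coef, *_ = np.linalg.lstsq(A, ph_star, rcond=None)
    resid = ph_star - A @ coef
    ss_tot = float(np.sum((ph_star - ph_star.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return {
        "eta": float(-coef[0]),
        "intercept": float(coef[1]),
        "r_squared": r2,
        "ratios": [r for r, _ in rows],
        "ph_star": ph_star.tolist(),
    }


def dispersion(profile: DensityProfile, signal: str) -> float:
    """Density-weighted standard deviation on a signal axis (e.g. pH units)."""
    s = profile.signals[signal]
    w = profile.density
    mu = trapezoid(w * s, profile.grid)
    var = trapezoid(w * (s - mu) ** 2, profile.grid)
    return float(math.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# thermotaxis and combined gradients
# ---------------------------------------------------------------------------

def thermo_density(env: Environment1D, rp: ReceptorParams,
                   mp: MotorParams) -> DensityProfile:
    """Steady state in a linear temperature gradient (general machinery)."""
    return steady_state_density(env, rp, mp, mode="thermo")


def thermo_density_leading_order(env: Environment1D, rp: ReceptorParams,
                                 mp: MotorParams) -> DensityProfile:
    """Leading-order (near-T_c) Gaussian approximation, for diagnostics.

    Expanding the adapted methylation offset to first order in T - T_c gives
    P ∝ v^{-1} exp(-β (T - T_c)^2) with
    β = 2 χ(T_c) dalpha_dT da0_dT / (N alpha(T_c)).
    """
    T_c = sig.critical_temperature(rp)
    chi_c = sensitivity_chi(rp, mp, T=T_c).chi
    alpha_c = rp.alpha(T_c)
    beta = 2.0 * chi_c * rp.thermo.dalpha_dT * rp.thermo.da0_dT / (rp.N * alpha_c)
    x = env.grid
    T = np.asarray(env.signal_at(x, "temperature"), dtype=float)
    v = np.asarray(env.speed_at(x), dtype=float)
    lnP = -beta * (T - T_c) ** 2 - np.log(v)
    lnP -= lnP.max()
    dens = np.exp(lnP)
    dens /= trapezoid(dens, x)
    a0 = sig.adapted_activity(T, rp)
    m_ss = rp.m0 - np.log(1.0 / a0 - 1.0) / (
        rp.N * (rp.alpha0 + rp.thermo.dalpha_dT * (T - rp.thermo.T0)))
    U = -np.log(dens)
    return DensityProfile(grid=x, density=dens, activity=a0, methylation=m_ss,
                          potential=U - U.min(), signals={"T": T}, mode="thermo")


def combined_density(env: Environment1D, rp: ReceptorParams,
                     mp: MotorParams) -> DensityProfile:
    """Steady state under simultaneous attractant and temperature gradients.

    Reduces exactly to :func:`thermo_density` when the ligand profile is
    identically zero.
    """
    return steady_state_density(env, rp, mp, mode="mixed")
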