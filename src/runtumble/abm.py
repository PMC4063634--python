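"""Stochastic agent-based 1D run-and-tumble simulator.

Each cell carries a position, a swimming direction (±1) and its own
methylation level; the kinase activity follows instantaneously from the
MWC free energy at the local signal.  Per time step a cell (i) relaxes its
methylation toward the adapted level, (ii) tumbles with probability
z_motor(a)·dt — a tumble redraws the direction uniformly from {+1, -1}, so
only half of tumbles reverse — (iii) reverses by rotational diffusion with
probability 2·D_r·dt, and (iv) advances by ±v·dt with reflective walls.

This simulator is the independent oracle for every analytic result in
:mod:`runtumble.steadystate`: it shares the signaling model but none of
the steady-state derivation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import trapezoid

from .params import ReceptorParams, MotorParams
from .environments import Environment1D
from .steadystate import DensityProfile
from . import signaling as sig

__all__ = ["SimConfig", "Cells", "init_cells", "step", "simulate", "compare_profiles"]

# parameter-vector layout for the numba kernel
_NP = 40
(_N, _ALPHA0, _M0, _A0REF, _TAUM, _KI, _KA,
 _PKI_A, _PKA_A, _PKI_S, _PKA_S, _FA, _FS,
 _DALPHA, _DA0, _T0R,
 _H, _KREF, _KAPPA, _TAUT, _DR, _T0M,
 _XMIN, _XMAX,
 _LKIND, _LA, _LB,
 _PHKIND, _PHA, _PHB,
 _TKIND, _TA, _TB,
 _SPKIND, _V0, _VSLOPE, _VTREF, _VCURV, _VTPEAK,
 _MODE) = range(40)


@dataclass(frozen=True)
class SimConfig:
    """Agent-based run configuration.

    dt must satisfy dt·z_max < 0.05 with z_max = 1/tau_tumble + 2·D_r, and
    the burn-in must cover at least ten adaptation times; both are enforced
    at simulation time.  ``signal_every`` sub-samples the (slow) signaling
    update relative to the motion step.
    """

    n_cells: int = 10_000
    dt: float = 0.008
    t_end: float = 1500.0
    t_burnin: float = 350.0
    seed: int = 0
    n_bins: int = 64
    signal_every: int = 4

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.dt <= 0 or self.t_end <= self.t_burnin:
            raise ValueError("invalid simulation configuration")
        if self.signal_every < 1:
            raise ValueError("signal_every must be >= 1")


@dataclass
class Cells:
    """Per-agent state arrays: position, direction (±1), methylation, activity."""

    x: np.ndarray
    direction: np.ndarray
    m: np.ndarray
    a: np.ndarray


def _mode_code(mode: str) -> int:
    return {"chemo": 0, "ph": 1, "thermo": 2, "mixed": 3}[mode]


def _pack_params(env: Environment1D, rp: ReceptorParams, mp: MotorParams,
                 mode: str) -> np.ndarray:
    P = np.zeros(_NP)
    ph, th = rp.ph, rp.thermo
    P[_N], P[_ALPHA0], P[_M0], P[_A0REF], P[_TAUM] = rp.N, rp.alpha0, rp.m0, rp.a0_ref, rp.tau_m
    P[_KI], P[_KA] = rp.KI, rp.KA
    P[_PKI_A], P[_PKA_A], P[_PKI_S], P[_PKA_S] = ph.pKI_tar, ph.pKA_tar, ph.pKI_tsr, ph.pKA_tsr
    P[_FA], P[_FS] = ph.f_a, ph.f_s
    P[_DALPHA], P[_DA0], P[_T0R] = th.dalpha_dT, th.da0_dT, th.T0
    P[_H], P[_KREF], P[_KAPPA], P[_TAUT], P[_DR], P[_T0M] = (
        mp.H, mp.K_ref, mp.kappa, mp.tau_tumble, mp.D_r, mp.T0)
    P[_XMIN], P[_XMAX] = env.x_min, env.x_max

    def lin(prof, slot_kind, slot_a, slot_b):
        if prof is None:
            P[slot_kind] = 0.0
        elif prof["kind"] == "linear":
            P[slot_kind] = 1.0
            P[slot_a], P[slot_b] = prof["value_at_min"], prof["value_at_max"]
        elif prof["kind"] == "exponential":
            P[slot_kind] = 2.0
            P[slot_a], P[slot_b] = prof["L0"], prof["g"]
        else:
            raise ValueError(
                "the agent-based kernel supports linear/exponential profiles only")

    lin(env.ligand, _LKIND, _LA, _LB)
    lin(env.ph, _PHKIND, _PHA, _PHB)
    lin(env.temperature, _TKIND, _TA, _TB)
    sp = env.speed
    P[_SPKIND] = {"constant": 0.0, "linear_in_T": 1.0, "quadratic_in_T": 2.0}.get(sp.kind, -1.0)
    if P[_SPKIND] < 0:
        raise ValueError("the agent-based kernel supports constant/linear_in_T/"
                         "quadratic_in_T speed profiles only")
    P[_V0], P[_VSLOPE], P[_VTREF], P[_VCURV], P[_VTPEAK] = (
        sp.v0, sp.slope, sp.T_ref, sp.curv, sp.T_peak)
    P[_MODE] = float(_mode_code(mode))
    return P


@njit(cache=True, fastmath=False)
def _signal_eval(P, x):
    """Local (L, pH, T, v) at position x."""
    xmin, xmax = P[_XMIN], P[_XMAX]
    t = (x - xmin) / (xmax - xmin)
    L = 0.0
    if P[_LKIND] == 1.0:
        L = P[_LA] * (1.0 - t) + P[_LB] * t
    elif P[_LKIND] == 2.0:
        L = P[_LA] * math.exp(P[_LB] * (x - xmin))
    pH = 0.0
    if P[_PHKIND] == 1.0:
        pH = P[_PHA] * (1.0 - t) + P[_PHB] * t
    T = P[_T0R]
    if P[_TKIND] == 1.0:
        T = P[_TA] * (1.0 - t) + P[_TB] * t
    if P[_SPKIND] == 0.0:
        v = P[_V0]
    elif P[_SPKIND] == 1.0:
        v = P[_V0] * (1.0 + P[_VSLOPE] * (T - P[_VTREF]))
    else:
        v = P[_V0] - P[_VCURV] * (T - P[_VTPEAK]) ** 2
    return L, pH, T, v


@njit(cache=True, fastmath=False)
def _local_signaling(P, x, m):
    """Activity, adapted activity, methylation rate constant and z_m at x."""
    L, pH, T, v = _signal_eval(P, x)
    mode = P[_MODE]
    alpha = P[_ALPHA0]
    a0 = P[_A0REF]
    if mode >= 2.0:  # thermo or mixed
        alpha = P[_ALPHA0] + P[_DALPHA] * (T - P[_T0R])
        a0 = P[_A0REF] + P[_DA0] * (T - P[_T0R])
    F = P[_N] * alpha * (P[_M0] - m)
    if mode == 0.0 or mode == 3.0:  # chemo or mixed
        F += P[_N] * (math.log(1.0 + L / P[_KI]) - math.log(1.0 + L / P[_KA]))
    elif mode == 1.0:  # ph
        ga = (math.log(1.0 + 10.0 ** (pH - P[_PKI_A]))
              - math.log(1.0 + 10.0 ** (pH - P[_PKA_A])))
        gs = (math.log(1.0 + 10.0 ** (pH - P[_PKI_S]))
              - math.log(1.0 + 10.0 ** (pH - P[_PKA_S])))
        F += P[_N] * (P[_FA] * ga + P[_FS] * gs)
    if F > 0.0:
        a = math.exp(-F) / (1.0 + math.exp(-F))
    else:
        a = 1.0 / (1.0 + math.exp(F))
    k_m = 1.0 / (P[_TAUM] * P[_N] * alpha * a0 * (1.0 - a0))
    K = P[_KREF] * (1.0 + P[_KAPPA] * (T - P[_T0M]))
    r = math.exp(P[_H] * (math.log(a) - math.log(K)))
    z_m = (r / (1.0 + r)) / P[_TAUT]
    return a, a0, k_m, z_m, v


@njit(cache=True, fastmath=False)
def _run_kernel(P, x, dirn, m, n_steps, burn_steps, sub, dt, seed, nbins):
    """Advance all cells; accumulate occupancy and per-direction statistics.

    Returns (occ, a_sum, m_sum, tumbles, occA, occB): occ/a_sum/m_sum/tumbles
    are (2, nbins) arrays indexed by direction (0 = left, 1 = right); occA
    and occB are direction-summed occupancies over the third and fourth
    quarters of the post-burn-in window, for a stationarity check.
    """
    np.random.seed(seed)
    n = x.shape[0]
    xmin, xmax = P[_XMIN], P[_XMAX]
    inv_bw = nbins / (xmax - xmin)
    prot = 2.0 * P[_DR] * dt
    dt_sub = dt * sub

    occ = np.zeros((2, nbins))
    a_sum = np.zeros((2, nbins))
    m_sum = np.zeros((2, nbins))
    tumbles = np.zeros((2, nbins))
    occA = np.zeros(nbins)
    occB = np.zeros(nbins)

    a = np.empty(n)
    ptum = np.empty(n)
    vloc = np.empty(n)
    for i in range(n):
        ai, a0i, kmi, zmi, vi = _local_signaling(P, x[i], m[i])
        a[i] = ai
        ptum[i] = zmi * dt
        vloc[i] = vi

    qmark = burn_steps + (n_steps - burn_steps) // 2
    qmark2 = burn_steps + 3 * (n_steps - burn_steps) // 4

    for s in range(n_steps):
        update_sig = (s % sub) == 0
        record = s >= burn_steps
        for i in range(n):
            xi = x[i]
            if update_sig:
                ai, a0i, kmi, zmi, vi = _local_signaling(P, xi, m[i])
                m[i] += dt_sub * kmi * (a0i - ai)
                a[i] = ai
                ptum[i] = zmi * dt
                vloc[i] = vi
            di = dirn[i]
            if record:
                b = int((xi - xmin) * inv_bw)
                if b >= nbins:
                    b = nbins - 1
                d = 1 if di > 0 else 0
                occ[d, b] += 1.0
                a_sum[d, b] += a[i]
                m_sum[d, b] += m[i]
                if s >= qmark2:
                    occB[b] += 1.0
                elif s >= qmark:
                    occA[b] += 1.0
            u = np.random.random()
            if u < ptum[i]:
                if record:
                    b = int((xi - xmin) * inv_bw)
                    if b >= nbins:
                        b = nbins - 1
                    tumbles[1 if di > 0 else 0, b] += 1.0
                di = 1 if np.random.random() < 0.5 else -1
            elif u < ptum[i] + prot:
                di = -di
            xn = xi + di * vloc[i] * dt
            if xn < xmin:
                xn = 2.0 * xmin - xn
                di = -di
            elif xn > xmax:
                xn = 2.0 * xmax - xn
                di = -di
            x[i] = xn
            dirn[i] = di
    return occ, a_sum, m_sum, tumbles, occA, occB


def init_cells(env: Environment1D, rp: ReceptorParams, n: int,
               rng: np.random.Generator, mode: str) -> Cells:
    """Cells uniform in x with random direction and locally adapted memory."""
    x = rng.uniform(env.x_min, env.x_max, size=n)
    direction = np.where(rng.random(n) < 0.5, -1, 1).astype(np.int64)
    # vectorized closed-form adapted state (same formula adapted_methylation
    # cross-checks against its root finder)
    if mode in ("thermo", "mixed"):
        T = np.asarray(env.signal_at(x, "temperature"), dtype=float)
        a0 = sig.adapted_activity(T, rp)
        alpha = rp.alpha0 + rp.thermo.dalpha_dT * (T - rp.thermo.T0)
    else:
        a0 = np.full(n, rp.a0_ref)
        alpha = np.full(n, rp.alpha0)
    if mode in ("chemo", "mixed"):
        L = np.asarray(env.signal_at(x, "ligand"), dtype=float)
        f_sig = rp.N * sig.ligand_term(L, rp.KI, rp.KA)
    elif mode == "ph":
        pH = np.asarray(env.signal_at(x, "ph"), dtype=float)
        ph = rp.ph
        f_sig = rp.N * (ph.f_a * sig.ph_term(pH, ph.pKI_tar, ph.pKA_tar)
                        + ph.f_s * sig.ph_term(pH, ph.pKI_tsr, ph.pKA_tsr))
    else:
        f_sig = np.zeros(n)
    f0 = np.log(1.0 / a0 - 1.0)
    m = rp.m0 + (f_sig - f0) / (rp.N * alpha)
    return Cells(x=x, direction=direction, m=m, a=a0.copy())


def step(cells: Cells, env: Environment1D, rp: ReceptorParams, mp: MotorParams,
         dt: float, rng: np.random.Generator, mode: str | None = None) -> Cells:
    """Single vectorized update of a cell ensemble (reference implementation).

    Mirrors the kernel semantics; used for small-scale unit checks.
    """
    from .steadystate import infer_mode

    mode = mode or infer_mode(env)
    z_max = 1.0 / mp.tau_tumble + 2.0 * mp.D_r
    if dt * z_max >= 0.05:
        raise ValueError("time step too large: dt * z_max must stay below 0.05")
    P = _pack_params(env, rp, mp, mode)
    n = cells.x.shape[0]
    a = np.empty(n)
    ptum = np.empty(n)
    v = np.empty(n)
    for i in range(n):
        ai, a0i, kmi, zmi, vi = _local_signaling(P, cells.x[i], cells.m[i])
        cells.m[i] += dt * kmi * (a0i - ai)
        a[i] = ai
        ptum[i] = zmi * dt
        v[i] = vi
    u = rng.random(n)
    tumble = u < ptum
    new_dir = np.where(rng.random(n) < 0.5, 1, -1)
    cells.direction = np.where(tumble, new_dir, cells.direction)
    rot = (~tumble) & (u < ptum + 2.0 * mp.D_r * dt)
    cells.direction = np.where(rot, -cells.direction, cells.direction)
    xn = cells.x + cells.direction * v * dt
    low, high = xn < env.x_min, xn > env.x_max
    xn = np.where(low, 2 * env.x_min - xn, xn)
    xn = np.where(high, 2 * env.x_max - xn, xn)
    cells.direction = np.where(low | high, -cells.direction, cells.direction)
    cells.x = xn
    cells.a = a
    return cells


def simulate(env: Environment1D, rp: ReceptorParams, mp: MotorParams,
             cfg: SimConfig, mode: str | None = None):
    """Run the ABM and return (DensityProfile, summary).

    The density is the time-and-ensemble occupancy histogram after burn-in.
    The summary carries per-direction mean activity ``a_plus``/``a_minus``,
    empirical motor tumbling rates ``z_plus``/``z_minus`` on the bin grid,
    and a stationarity diagnostic comparing the third and fourth quarters
    of the averaging window.
    """
    from .steadystate import infer_mode

    mode = mode or infer_mode(env)
    z_max = 1.0 / mp.tau_tumble + 2.0 * mp.D_r
    if cfg.dt * z_max >= 0.05:
        raise ValueError("time step too large: dt * z_max must stay below 0.05")
    if cfg.t_burnin < 10.0 * rp.tau_m:
        raise ValueError("burn-in must cover at least 10 adaptation times")
    # adapted activity must stay in (0,1) across the domain (raises if not)
    if env.temperature is not None:
        sig.adapted_activity(
            np.array([env.signal_at(env.x_min, "temperature"),
                      env.signal_at(env.x_max, "temperature")]), rp)

    rng = np.random.default_rng(cfg.seed)
    cells = init_cells(env, rp, cfg.n_cells, rng, mode)
    P = _pack_params(env, rp, mp, mode)
    n_steps = int(round(cfg.t_end / cfg.dt))
    burn_steps = int(round(cfg.t_burnin / cfg.dt))
    kseed = (cfg.seed * 2654435761 + 1) % (2**31 - 1)
    occ, a_sum, m_sum, tumbles, occA, occB = _run_kernel(
        P, cells.x, cells.direction.astype(np.int64), cells.m,
        n_steps, burn_steps, cfg.signal_every, cfg.dt, kseed, cfg.n_bins)

    edges = np.linspace(env.x_min, env.x_max, cfg.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bw = edges[1] - edges[0]
    tot = occ.sum(axis=0)
    dens = tot / tot.sum() / bw
    dens /= trapezoid(dens, centers)  # consistent with DensityProfile norm
    with np.errstate(divide="ignore"):
        act = np.where(tot > 0, (a_sum.sum(axis=0)) / np.maximum(tot, 1), np.nan)
        meth = np.where(tot > 0, (m_sum.sum(axis=0)) / np.maximum(tot, 1), np.nan)
        a_minus = np.where(occ[0] > 0, a_sum[0] / np.maximum(occ[0], 1), np.nan)
        a_plus = np.where(occ[1] > 0, a_sum[1] / np.maximum(occ[1], 1), np.nan)
        z_minus = np.where(occ[0] > 0, tumbles[0] / (np.maximum(occ[0], 1) * cfg.dt), np.nan)
        z_plus = np.where(occ[1] > 0, tumbles[1] / (np.maximum(occ[1], 1) * cfg.dt), np.nan)
    U = -np.log(np.maximum(dens, 1e-300))
    signals = {}
    for kind, col in (("ligand", "ligand"), ("ph", "pH"), ("temperature", "T")):
        try:
            signals[col] = np.asarray(env.signal_at(centers, kind), dtype=float)
        except ValueError:
            pass
    profile = DensityProfile(grid=centers, density=dens, activity=act,
                             methylation=meth, potential=U - U.min(),
                             signals=signals, mode=mode)

    pA = occA / max(occA.sum(), 1.0)
    pB = occB / max(occB.sum(), 1.0)
    stat_diff = float(np.max(np.abs(pA - pB)))
    # rough per-bin Monte-Carlo floor: independent-snapshot binomial scale
    n_eff = max(cfg.n_cells, 1)
    floor = 4.0 * float(np.sqrt(pB.max() / n_eff))
    stationary = stat_diff < max(2.0 * floor, 0.02 * pB.max())
    if not stationary:
        warnings.warn("histogram still drifting between late-time windows; "
                      "consider a longer horizon")
    summary = {
        "a_plus": a_plus, "a_minus": a_minus,
        "z_plus": z_plus, "z_minus": z_minus,
        "occupancy": occ, "tumbles": tumbles,
        "stationarity_supnorm": stat_diff,
        "stationary": bool(stationary),
        "mode": mode,
    }
    return profile, summary


def compare_profiles(hist: DensityProfile, analytic: DensityProfile) -> dict:
    """Divergence metrics between a simulated and an analytic profile.

    Returns KL divergence (nats, simulated vs analytic), the sup-norm of the
    relative difference, and the earth-mover (1-Wasserstein) distance in
    grid units.  Requires a shared grid.
    """
    if hist.grid.shape != analytic.grid.shape or not np.allclose(
            hist.grid, analytic.grid):
        raise ValueError("profiles must share a grid")
    x = hist.grid
    w = np.gradient(x)
    p = hist.density * w
    q = analytic.density * w
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    kl = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    sup_rel = float(np.max(np.abs(hist.density - analytic.density))
                    / np.max(analytic.density))
    emd = float(np.sum(np.abs(np.cumsum(p - q))[:-1] * np.diff(x)))
    return {"kl": kl, "sup_rel": sup_rel, "emd": emd}
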