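"""Receptor-cluster signaling: MWC activity, free energies and adaptation.

The receptor cluster is a two-state (MWC) unit whose activity is

    a = 1 / (1 + exp(F)),

where ``F`` is the total free-energy difference between the active and
inactive conformations in kT.  By package convention ``F`` already carries
the cooperativity factor N, so every free-energy builder here returns
``N * (...)``.  Attractant-like stimuli *raise* F and hence lower the
activity; methylation lowers F and restores activity during adaptation.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .params import ReceptorParams

Mode = Literal["chemo", "ph", "thermo", "mixed"]

__all__ = [
    "activity",
    "free_energy_chemo",
    "free_energy_ph",
    "free_energy_thermo",
    "free_energy_mixed",
    "adapted_activity",
    "adapted_methylation",
    "methylation_rate",
    "critical_temperature",
    "ligand_term",
    "ph_term",
    "signal_free_energy",
]


def activity(f_total):
    """MWC activity a = 1/(1 + exp(f_total)); f_total in kT, including N."""
    f = np.asarray(f_total, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("free energy must be finite")
    out = expit(-f)  # numerically stable 1/(1+e^f)
    return float(out) if np.isscalar(f_total) else out


def ligand_term(L, KI: float, KA: float):
    """Per-receptor ligand free energy ln((1+L/KI)/(1+L/KA)), kT."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    out = np.log1p(L / KI) - np.log1p(L / KA)
    return float(out) if out.ndim == 0 else out


def ph_term(pH, pKI: float, pKA: float):
    """MWC log-ratio pH term ln((1+10^(pH-pKI))/(1+10^(pH-pKA))), kT.

    10^pH plays the role of the ligand concentration, so the slope in pH is
    positive iff pKI < pKA.
    """
    pH = np.asarray(pH, dtype=float)
    out = np.log1p(10.0 ** (pH - pKI)) - np.log1p(10.0 ** (pH - pKA))
    return float(out) if out.ndim == 0 else out


def free_energy_chemo(m, L, p: ReceptorParams):
    """Total free energy N*[alpha0*(m0-m) + ln((1+L/KI)/(1+L/KA))], kT."""
    return p.N * (p.alpha0 * (p.m0 - np.asarray(m, dtype=float)) + ligand_term(L, p.KI, p.KA))


def free_energy_ph(m, pH, p: ReceptorParams):
    """Total free energy of a Tar/Tsr mixture in a pH environment, kT.

    The Tar contribution decreases with pH (attractant response to
    acidification) and the Tsr contribution increases, so a wild-type
    mixture has an interior free-energy maximum where cells accumulate.
    """
    ph = p.ph
    if abs(ph.f_a + ph.f_s - 1.0) > 1e-9:
        raise ValueError("Tar and Tsr fractions must sum to 1")
    sig = ph.f_a * ph_term(pH, ph.pKI_tar, ph.pKA_tar) + ph.f_s * ph_term(
        pH, ph.pKI_tsr, ph.pKA_tsr
    )
    return p.N * (p.alpha0 * (p.m0 - np.asarray(m, dtype=float)) + sig)


def free_energy_thermo(m, T, p: ReceptorParams):
    """Total free energy N*alpha(T)*(m0-m) of a Tar-only thermosensor, kT."""
    T = np.asarray(T, dtype=float)
    alpha = p.alpha0 + p.thermo.dalpha_dT * (T - p.thermo.T0)
    if np.any(alpha <= 0):
        raise ValueError("alpha(T) must stay positive on the requested range")
    out = p.N * alpha * (p.m0 - np.asarray(m, dtype=float))
    return float(out) if out.ndim == 0 else out


def free_energy_mixed(m, T, L, p: ReceptorParams):
    """Thermal free energy plus the attractant ligand term (Tar-only), kT."""
    return free_energy_thermo(m, T, p) + p.N * ligand_term(L, p.KI, p.KA)


def adapted_activity(T, p: ReceptorParams):
    """Adapted activity a0(T) = a0_ref + da0_dT*(T - T0).

    Raises if the linear form leaves (0, 1): that is a parameter
    misconfiguration rather than a physical regime.
    """
    T = np.asarray(T, dtype=float)
    a0 = p.a0_ref + p.thermo.da0_dT * (T - p.thermo.T0)
    if np.any(a0 <= 0.0) or np.any(a0 >= 1.0):
        raise ValueError("adapted activity a0(T) left the interval (0, 1)")
    return float(a0) if a0.ndim == 0 else a0


def signal_free_energy(s: dict, p: ReceptorParams, mode: Mode):
    """Signal-dependent (methylation-independent) part of F, including N.

    ``s`` may contain 'ligand', 'pH' and 'T' entries as the mode requires.
    """
    if mode == "chemo":
        return p.N * ligand_term(s["ligand"], p.KI, p.KA)
    if mode == "ph":
        ph = p.ph
        return p.N * (
            ph.f_a * ph_term(s["pH"], ph.pKI_tar, ph.pKA_tar)
            + ph.f_s * ph_term(s["pH"], ph.pKI_tsr, ph.pKA_tsr)
        )
    if mode == "thermo":
        return np.zeros_like(np.asarray(s["T"], dtype=float)) + 0.0
    if mode == "mixed":
        return p.N * ligand_term(s["ligand"], p.KI, p.KA)
    raise ValueError(f"unknown mode {mode!r}")


def _mode_free_energy(m, s: dict, p: ReceptorParams, mode: Mode):
    if mode == "chemo":
        return free_energy_chemo(m, s["ligand"], p)
    if mode == "ph":
        return free_energy_ph(m, s["pH"], p)
    if mode == "thermo":
        return free_energy_thermo(m, s["T"], p)
    if mode == "mixed":
        return free_energy_mixed(m, s["T"], s["ligand"], p)
    raise ValueError(f"unknown mode {mode!r}")


def adapted_methylation(s: dict, p: ReceptorParams, mode: Mode = "chemo") -> float:
    """Steady-state methylation m_ss at which activity equals a0.

    Solves activity(F(m_ss, s)) = a0(T).  For the linear methylation free
    energy the closed form is

        m_ss = m0 + (f_signal/N - f0/N) / alpha(T),   f0 = ln(1/a0 - 1),

    where f_signal is the N-scaled signal term.  The closed form is
    cross-checked against a bracketed root to 1e-10.
    """
    T = float(s.get("T", p.thermo.T0))
    a0 = adapted_activity(T, p) if mode in ("thermo", "mixed") else p.a0_ref
    alpha = p.alpha(T) if mode in ("thermo", "mixed") else p.alpha0
    f0 = math.log(1.0 / a0 - 1.0)
    # f_sig includes the factor N; f0 does not. Solve N*alpha*(m0-m) + f_sig = f0.
    f_sig = float(signal_free_energy(s, p, mode))
    m_closed = p.m0 + (f_sig - f0) / (p.N * alpha)

    lo, hi = p.m_bounds
    if not (lo <= m_closed <= hi):
        raise ValueError(
            f"adapted methylation {m_closed:.4f} outside bounds {p.m_bounds}"
        )

    def g(m):
        return activity(_mode_free_energy(m, s, p, mode)) - a0

    # activity is increasing in m, so bracket around the closed form.
    eps = 1e-3
    a, b = m_closed - eps, m_closed + eps
    if g(a) * g(b) > 0:  # widen if the tiny bracket misses (should not happen)
        a, b = lo, hi
        if g(a) * g(b) > 0:
            raise ValueError("no adapted-methylation root in configured bounds")
    m_root = brentq(g, a, b, xtol=1e-13, rtol=8.9e-16)
    if abs(m_root - m_closed) > 1e-10:
        raise RuntimeError(
            f"closed form ({m_closed!r}) and root ({m_root!r}) disagree beyond 1e-10"
        )
    return m_closed


def methylation_rate(a, a0, p: ReceptorParams, T: float | None = None):
    """dm/dt = k_m * (a0 - a); linear in activity, restoring a toward a0.

    k_m is set so that the linearized activity relaxation time equals
    tau_m (see :meth:`ReceptorParams.k_m`).
    """
    a = np.asarray(a, dtype=float)
    if np.any((a <= 0) | (a >= 1)) or not 0 < a0 < 1:
        raise ValueError("activities must lie in (0, 1)")
    out = p.k_m(T) * (a0 - a)
    return float(out) if out.ndim == 0 else out


def critical_temperature(p: ReceptorParams, T_range=(10.0, 50.0)) -> float:
    """Temperature at which the Tar thermal response inverts.

    Defined by m_ss(T_c) = m_c.  Under the linear alpha(T) form with
    m_c = m0 this reduces to a0(T_c) = 1/2, but the implementation solves
    the defining condition directly so that configured m_c != m0 also works.
    """

    def h(T):
        return adapted_methylation({"T": T}, p, mode="thermo") - p.m_c

    lo, hi = T_range
    # clip to where alpha(T) > 0 and a0(T) in (0, 1)
    th = p.thermo
    if th.dalpha_dT > 0:
        lo = max(lo, th.T0 - p.alpha0 / th.dalpha_dT + 1e-6)
    elif th.dalpha_dT < 0:
        hi = min(hi, th.T0 + p.alpha0 / (-th.dalpha_dT) - 1e-6)
    if th.da0_dT > 0:
        lo = max(lo, th.T0 - p.a0_ref / th.da0_dT + 1e-6)
        hi = min(hi, th.T0 + (1.0 - p.a0_ref) / th.da0_dT - 1e-6)
    elif th.da0_dT < 0:
        hi = min(hi, th.T0 + p.a0_ref / (-th.da0_dT) - 1e-6)
        lo = max(lo, th.T0 - (1.0 - p.a0_ref) / (-th.da0_dT) + 1e-6)
    if not lo < hi:
        raise ValueError("empty admissible temperature range")
    # probe on a grid: m_ss may still blow up where alpha(T) ~ 0
    Ts, hs = [], []
    for T in np.linspace(lo, hi, 81):
        try:
            hs.append(h(float(T)))
            Ts.append(float(T))
        except (ValueError, RuntimeError):
            continue
    if len(Ts) < 2:
        raise ValueError("adapted methylation undefined across the range")
    hs = np.asarray(hs)
    if np.all(np.abs(hs) < 1e-13):
        raise ValueError(
            "degenerate configuration: m_ss(T) == m_c over the whole range "
            "(no thermal-response inversion)"
        )
    sign_change = np.nonzero(np.diff(np.sign(hs)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError(f"m_ss(T) - m_c does not change sign on {T_range}")
    i = sign_change[0]
    return brentq(h, Ts[i], Ts[i + 1], xtol=1e-12)
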