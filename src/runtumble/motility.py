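"""Motor response and swimming-speed profiles.

The flagellar motor switches to clockwise rotation (a tumble) with an
ultrasensitive Hill dependence on the kinase activity ``a`` (a proxy for
CheY-P).  The rate of entering the tumble state is ``cw_bias(a)/tau_tumble``;
passive rotational diffusion additionally decorrelates the swimming
direction at rate ``2*D_r`` in the 1D two-direction reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np

from .params import MotorParams

__all__ = [
    "cw_bias",
    "motor_K",
    "tumbling_rate",
    "motor_tumbling_rate",
    "rotational_rate",
    "SpeedProfile",
    "speed",
]


def motor_K(T, mp: MotorParams):
    """Motor switching threshold K(T) = K_ref*(1 + kappa*(T - T0)).

    K is the activity at which the CW bias is one half; it is observed to
    increase with temperature (kappa > 0).
    """
    T = np.asarray(T, dtype=float)
    K = mp.K_ref * (1.0 + mp.kappa * (T - mp.T0))
    if np.any(K <= 0.0) or np.any(K >= 1.0):
        raise ValueError("motor threshold K(T) left the interval (0, 1)")
    return float(K) if K.ndim == 0 else K


def cw_bias(a, mp: MotorParams, T: Optional[float] = None):
    """CW bias a^H/(a^H + K(T)^H); equals 1/2 at a = K(T)."""
    a = np.asarray(a, dtype=float)
    if np.any((a <= 0.0) | (a >= 1.0)):
        raise ValueError("activity must lie in (0, 1)")
    K = motor_K(mp.T0 if T is None else T, mp)
    # (a/K)^H / (1 + (a/K)^H), computed in log space for large H
    r = np.exp(mp.H * (np.log(a) - np.log(K)))
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def motor_tumbling_rate(a, mp: MotorParams, T: Optional[float] = None):
    """Rate of entering the tumble state, z_motor = cw_bias/tau_tumble (1/s)."""
    out = np.asarray(cw_bias(a, mp, T)) / mp.tau_tumble
    return float(out) if out.ndim == 0 else out


def rotational_rate(mp: MotorParams) -> float:
    """Direction-reversal rate contributed by rotational diffusion, 2*D_r."""
    return 2.0 * mp.D_r


def tumbling_rate(a, mp: MotorParams, T: Optional[float] = None):
    """Effective direction-changing rate z_eff = z_motor + 2*D_r (1/s).

    Monotone increasing in the activity; bounded below by the rotational
    term, which is motor-independent.
    """
    out = np.asarray(motor_tumbling_rate(a, mp, T)) + rotational_rate(mp)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpeedProfile:
    """Swimming-speed profile, optionally temperature dependent.

    kinds
    -----
    constant : v = v0 everywhere.
    linear_in_T : v(T) = v0*(1 + slope*(T - T_ref)).
    quadratic_in_T : v(T) = v0 - curv*(T - T_peak)^2, maximal at T_peak.
    custom : tabulated (coordinate, speed) pairs, linearly interpolated.

    Units: µm/s; slope 1/degC; curv µm/s/degC^2.
    """

    kind: str = "constant"
    v0: float = 20.0
    slope: float = 0.0
    T_ref: float = 25.0
    curv: float = 0.0
    T_peak: float = 37.0
    table: Optional[tuple] = None  # (coords, speeds) for kind='custom'

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_in_T", "quadratic_in_T", "custom"):
            raise ValueError(f"unknown speed profile kind {self.kind!r}")
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.kind == "custom":
            if self.table is None:
                raise ValueError("custom profile requires a table")
            coords, speeds = self.table
            if np.any(np.asarray(speeds) <= 0):
                raise ValueError("custom speed profile must be positive everywhere")

    def __call__(self, x_or_T):
        return speed(x_or_T, self)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["table"] is not None:
            d["table"] = [list(map(float, c)) for c in d["table"]]
        return d


def speed(x_or_T, sp: SpeedProfile):
    """Evaluate the speed profile at a position or temperature (µm/s)."""
    q = np.asarray(x_or_T, dtype=float)
    if sp.kind == "constant":
        v = np.full_like(q, sp.v0, dtype=float)
    elif sp.kind == "linear_in_T":
        v = sp.v0 * (1.0 + sp.slope * (q - sp.T_ref))
    elif sp.kind == "quadratic_in_T":
        v = sp.v0 - sp.curv * (q - sp.T_peak) ** 2
    else:  # custom
        coords, speeds = sp.table
        v = np.interp(q, np.asarray(coords, dtype=float), np.asarray(speeds, dtype=float))
    if np.any(v <= 0.0):
        raise ValueError("speed profile evaluated non-positive")
    return float(v) if v.ndim == 0 else v
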