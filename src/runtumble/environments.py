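"""1D closed-chamber environments: signal profiles, grids and fixtures.

An :class:`Environment1D` is a finite interval with zero-flux (reflective)
boundaries carrying any subset of three signal profiles — attractant
concentration L(x), pH(x) and temperature T(x) — plus a swimming-speed
profile.  All profiles used by the shipped scenarios are generated
programmatically here; linear and exponential forms are evaluated in closed
form (including their spatial derivatives), custom profiles by linear
interpolation.

Positions are in µm, concentrations in µM, temperatures in degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .params import PHParams, ReceptorParams, MotorParams
from .motility import SpeedProfile

__all__ = [
    "Environment1D",
    "make_linear_gradient",
    "signal_at",
    "chemo_fixture",
    "ph_fixture",
    "thermo_fixture",
    "combined_fixture",
    "speed_channel_fixture",
    "custom_profile_from_csv",
    "PH_REGIMES",
]

_SIGNAL_KINDS = ("ligand", "ph", "temperature")


@dataclass(frozen=True)
class Environment1D:
    """Closed 1D chamber with signal and speed profiles.

    Each profile is a dict: ``{"kind": "linear", "value_at_min": a,
    "value_at_max": b}``, ``{"kind": "exponential", "L0": L0, "g": g}``
    (ligand only, L(x) = L0*exp(g*(x - x_min))) or ``{"kind": "custom",
    "x": [...], "y": [...]}``.
    """

    x_min: float = 0.0
    x_max: float = 600.0
    n_grid: int = 512
    ligand: Optional[dict] = None
    ph: Optional[dict] = None
    temperature: Optional[dict] = None
    speed: SpeedProfile = field(default_factory=SpeedProfile)

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.n_grid < 64:
            raise ValueError("grid must have at least 64 points")
        if self.ligand is not None and self.ligand["kind"] == "linear":
            if min(self.ligand["value_at_min"], self.ligand["value_at_max"]) < 0:
                raise ValueError("ligand endpoints must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        """Cell-centered grid used for histogramming and reporting."""
        edges = np.linspace(self.x_min, self.x_max, self.n_grid + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def length(self) -> float:
        return self.x_max - self.x_min

    def _profile(self, kind: str) -> dict:
        prof = {"ligand": self.ligand, "ph": self.ph, "temperature": self.temperature}[kind]
        if prof is None:
            raise ValueError(f"environment has no {kind} profile")
        return prof

    def signal_at(self, x, kind: str):
        """Evaluate a signal profile at position(s) x."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x_min - 1e-9) or np.any(x > self.x_max + 1e-9):
            raise ValueError("position outside the domain")
        prof = self._profile(kind)
        if prof["kind"] == "linear":
            t = (x - self.x_min) / self.length
            out = prof["value_at_min"] * (1.0 - t) + prof["value_at_max"] * t
        elif prof["kind"] == "exponential":
            out = prof["L0"] * np.exp(prof["g"] * (x - self.x_min))
        elif prof["kind"] == "custom":
            out = np.interp(x, np.asarray(prof["x"]), np.asarray(prof["y"]))
        else:
            raise ValueError(f"unknown profile kind {prof['kind']!r}")
        return float(out) if out.ndim == 0 else out

    def signal_slope(self, x, kind: str):
        """Spatial derivative of a signal profile at position(s) x."""
        x = np.asarray(x, dtype=float)
        prof = self._profile(kind)
        if prof["kind"] == "linear":
            out = np.full_like(x, (prof["value_at_max"] - prof["value_at_min"]) / self.length)
        elif prof["kind"] == "exponential":
            out = prof["g"] * prof["L0"] * np.exp(prof["g"] * (x - self.x_min))
        elif prof["kind"] == "custom":
            xs, ys = np.asarray(prof["x"], dtype=float), np.asarray(prof["y"], dtype=float)
            mid = np.interp(x, xs, ys)
            h = (xs[-1] - xs[0]) / (10.0 * len(xs))
            out = (np.interp(np.minimum(x + h, xs[-1]), xs, ys)
                   - np.interp(np.maximum(x - h, xs[0]), xs, ys)) / (
                np.minimum(x + h, xs[-1]) - np.maximum(x - h, xs[0]))
        else:
            raise ValueError(f"unknown profile kind {prof['kind']!r}")
        return float(out) if out.ndim == 0 else out

    def speed_at(self, x):
        """Swimming speed at position(s) x (µm/s)."""
        if self.speed.kind in ("linear_in_T", "quadratic_in_T"):
            return self.speed(self.signal_at(x, "temperature"))
        return self.speed(x)

    def gradient_steepness(self, kind: str) -> float:
        prof = self._profile(kind)
        if prof["kind"] != "linear":
            raise ValueError("steepness is defined for linear profiles")
        return (prof["value_at_max"] - prof["value_at_min"]) / self.length

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "n_grid": self.n_grid,
            "ligand": self.ligand,
            "ph": self.ph,
            "temperature": self.temperature,
            "speed": self.speed.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment1D":
        d = dict(d)
        sp = d.pop("speed", None)
        if isinstance(sp, dict):
            if sp.get("table") is not None:
                sp["table"] = tuple(tuple(c) for c in sp["table"])
            sp = SpeedProfile(**sp)
        return cls(speed=sp or SpeedProfile(), **d)


def make_linear_gradient(
    kind: str,
    value_at_min: float,
    value_at_max: float,
    x_min: float = 0.0,
    x_max: float = 600.0,
    n_grid: int = 512,
    speed: Optional[SpeedProfile] = None,
) -> Environment1D:
    """Environment with a single linear signal profile."""
    if kind not in _SIGNAL_KINDS:
        raise ValueError(f"kind must be one of {_SIGNAL_KINDS}")
    if kind == "ligand" and min(value_at_min, value_at_max) < 0:
        raise ValueError("ligand endpoints must be non-negative")
    prof = {"kind": "linear", "value_at_min": float(value_at_min),
            "value_at_max": float(value_at_max)}
    kw = {kind if kind != "temperature" else "temperature": prof}
    if kind == "ph":
        kw = {"ph": prof}
    elif kind == "ligand":
        kw = {"ligand": prof}
    return Environment1D(
        x_min=x_min, x_max=x_max, n_grid=n_grid,
        speed=speed or SpeedProfile(), **kw,
    )


def signal_at(env: Environment1D, x, kind: str):
    """Module-level alias of :meth:`Environment1D.signal_at`."""
    return env.signal_at(x, kind)


def custom_profile_from_csv(path) -> dict:
    """Two-column CSV (coordinate, value) -> custom profile dict.

    Usable as any of Environment1D's signal profiles, or as the table of a
    custom :class:`~runtumble.motility.SpeedProfile`.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError("custom profile CSV must have exactly two columns")
    xs = df.iloc[:, 0].to_numpy(dtype=float)
    ys = df.iloc[:, 1].to_numpy(dtype=float)
    if not np.all(np.diff(xs) > 0):
        raise ValueError("custom profile coordinates must be strictly increasing")
    return {"kind": "custom", "x": xs.tolist(), "y": ys.tolist()}


# ---------------------------------------------------------------------------
# Shipped scenario fixtures (the configurations exercised by the tests and
# examples; every profile is generated here, no data files).
# ---------------------------------------------------------------------------

#: Three pH dissociation-constant regimes realizing distinct tunability
#: classes (see docs/methods.md).  "separated": Tar and Tsr response windows
#: disjoint, the preferred pH sits on both exponential tails (eta < 1, weak
#: restoring force).  "balanced": windows meet at the preferred pH where both
#: responses are strong (eta ~ 1, steepest potential well).  "overlapping":
#: broad overlapping windows (eta > 1, most tunable, shallow well).
PH_REGIMES: Dict[str, PHParams] = {
    "separated": PHParams(pKI_tar=9.5, pKA_tar=8.0, pKI_tsr=4.5, pKA_tsr=6.0),
    "balanced": PHParams(pKI_tar=9.0, pKA_tar=6.6, pKI_tsr=5.0, pKA_tsr=6.5),
    "overlapping": PHParams(pKI_tar=8.5, pKA_tar=6.5, pKI_tsr=5.5, pKA_tsr=7.5),
}

#: Regime with minimal population dispersion ("optimal accuracy"): both
#: sensors respond strongly at the preferred pH, giving the steepest
#: effective-potential well; the tradeoff is a modest tunability (eta ~ 1).
OPTIMAL_ACCURACY_REGIME = "balanced"


def chemo_fixture(L_min: float = 17.0, L_max: float = 20.0,
                  length: float = 600.0, n_grid: int = 512) -> Environment1D:
    """Shallow linear MeAsp-like gradient in a closed channel."""
    return make_linear_gradient("ligand", L_min, L_max, 0.0, length, n_grid)


def ph_fixture(pH_min: float = 5.9, pH_max: float = 7.1,
               length: float = 600.0, n_grid: int = 512) -> Environment1D:
    """Linear pH gradient spanning the preferred point of the wild type."""
    return make_linear_gradient("ph", pH_min, pH_max, 0.0, length, n_grid)


def thermo_fixture(T1: float = 20.0, T2: float = 30.0,
                   length: float = 600.0, n_grid: int = 512,
                   speed: Optional[SpeedProfile] = None) -> Environment1D:
    """Linear temperature gradient bracketing the critical temperature."""
    return make_linear_gradient("temperature", T1, T2, 0.0, length, n_grid,
                                speed=speed)


def combined_fixture(attr_gradient: float = 0.0, L_mid: float = 0.1,
                     T1: float = 20.0, T2: float = 30.0,
                     length: float = 1000.0, n_grid: int = 512) -> Environment1D:
    """Opposing chemical and thermal gradients.

    Temperature rises left to right; the attractant falls at
    ``attr_gradient`` (nM per mm) around a concentration ``L_mid`` (µM)
    fixed at the channel midpoint, so steepening the chemical gradient
    pulls cells toward the cold end.  Sub-µM scales keep the adapted
    free-energy balance (and hence the preferred temperature) inside the
    chamber: the methylation set point absorbs N·f_L, which must stay
    within the narrow range spanned by ln(1/a0(T) - 1) across the domain.
    """
    half_span = 0.5 * attr_gradient * 1e-3 * length / 1000.0  # nM/mm
    L_lo, L_hi = L_mid + half_span, L_mid - half_span
    if min(L_lo, L_hi) < 0:
        raise ValueError("attractant gradient too steep for the midpoint concentration")
    return Environment1D(
        x_min=0.0, x_max=length, n_grid=n_grid,
        ligand={"kind": "linear", "value_at_min": L_lo, "value_at_max": L_hi},
        temperature={"kind": "linear", "value_at_min": T1, "value_at_max": T2},
    )


def speed_channel_fixture(T1: float = 20.0, T2: float = 30.0,
                          v0: float = 20.0, slope: float = 0.03,
                          length: float = 600.0, n_grid: int = 512) -> Environment1D:
    """Temperature gradient driving only the speed channel.

    Combined with a receptor configuration whose gain is zero (see
    :func:`runtumble.steadystate.receptorless`), the density is the pure
    inverse-speed profile — the mutant-strain limit lacking chemoreceptors.
    """
    sp = SpeedProfile(kind="linear_in_T", v0=v0, slope=slope, T_ref=0.5 * (T1 + T2))
    return thermo_fixture(T1, T2, length, n_grid, speed=sp)


def receptorless(p: Optional[ReceptorParams] = None) -> ReceptorParams:
    """Receptor parameters with all sensory gains silenced.

    KI = KA kills the ligand term and zero thermal slopes kill temperature
    sensing; adaptation still runs but produces no spatial drift.
    """
    from dataclasses import replace
    from .params import ThermoParams

    base = p or ReceptorParams()
    return replace(
        base,
        KI=100.0, KA=100.0000001,  # ~zero ligand gain while keeping KI < KA
        thermo=ThermoParams(dalpha_dT=0.0, da0_dT=0.0, T0=base.thermo.T0),
    )
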