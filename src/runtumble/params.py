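"""Parameter containers for the receptor cluster and the flagellar motor.

All free energies are in units of kT, temperatures in degrees Celsius,
concentrations in the same units as the dissociation constants (µM by
convention), times in seconds and lengths in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class PHParams:
    """pH-sensing parameters of the Tar/Tsr receptor mixture.

    Dissociation constants are expressed on the pH scale.  Tar shows an
    attractant response to a pH decrease, so its free-energy contribution
    falls with rising pH, which requires ``pKI_tar > pKA_tar``; Tsr responds
    oppositely (``pKI_tsr < pKA_tsr``).  ``f_a`` and ``f_s`` are the Tar and
    Tsr fractions of the cluster and must sum to one.
    """

    pKI_tar: float = 9.0
    pKA_tar: float = 6.6
    pKI_tsr: float = 5.0
    pKA_tsr: float = 6.5
    f_a: float = 0.5
    f_s: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_a <= 1.0 and 0.0 <= self.f_s <= 1.0):
            raise ValueError("receptor fractions must lie in [0, 1]")
        if abs(self.f_a + self.f_s - 1.0) > 1e-9:
            raise ValueError("Tar and Tsr fractions must sum to 1")
        if self.f_a > 0.0 and not self.pKI_tar > self.pKA_tar:
            raise ValueError(
                "Tar convention requires pKI_tar > pKA_tar "
                "(free energy decreasing in pH)"
            )
        if self.f_s > 0.0 and not self.pKI_tsr < self.pKA_tsr:
            raise ValueError(
                "Tsr convention requires pKI_tsr < pKA_tsr "
                "(free energy increasing in pH)"
            )

    def with_ratio(self, ratio: float) -> "PHParams":
        """Return a copy with Tar/Tsr abundance ratio ``f_a/f_s = ratio``."""
        if ratio <= 0:
            raise ValueError("Tar/Tsr ratio must be positive")
        f_a = ratio / (1.0 + ratio)
        return PHParams(
            pKI_tar=self.pKI_tar,
            pKA_tar=self.pKA_tar,
            pKI_tsr=self.pKI_tsr,
            pKA_tsr=self.pKA_tsr,
            f_a=f_a,
            f_s=1.0 - f_a,
        )


@dataclass(frozen=True)
class ThermoParams:
    """Temperature dependence of the receptor free energy and set point.

    ``dalpha_dT`` is the slope of the methylation free energy per methyl
    group, alpha(T) = alpha0 + dalpha_dT*(T - T0).  A positive slope makes a
    sub-critically methylated receptor (m < m_c) a warm sensor, as required
    for thermal-response inversion at the critical temperature.  ``da0_dT``
    is the slope of the adapted activity with temperature (the adapted
    CheY-P level rises with temperature).
    """

    dalpha_dT: float = 0.35  # kT / degC / methyl
    da0_dT: float = 0.005  # 1 / degC
    T0: float = 25.0  # degC


@dataclass(frozen=True)
class ReceptorParams:
    """MWC receptor-cluster parameters.

    The activity of the cluster is a = 1/(1 + exp(F)) where the total free
    energy F carries the cooperativity factor N internally:
    F = N * [alpha(T)*(m0 - m) + ligand and/or pH terms].

    Attributes
    ----------
    N : receptor cooperativity (cluster size), > 0.
    alpha0 : free-energy change per added methyl group at T0, kT.
    m0 : reference methylation level; also the critical level m_c for
        thermal-response inversion under the linear alpha(T) form.
    a0_ref : adapted activity at the reference temperature, in (0, 1).
    tau_m : adaptation timescale of the *activity* relaxation, seconds.
    KI, KA : dissociation constants of the inactive/active conformations
        for the chemoattractant; KI < KA for an attractant.
    ph : pH-sensing parameters (Tar/Tsr mixture).
    thermo : temperature-sensing parameters.
    m_c : critical methylation level; defaults to m0.
    m_bounds : admissible methylation range used by root bracketing.
    """

    N: float = 6.0
    alpha0: float = 2.0
    m0: float = 1.0
    a0_ref: float = 0.5
    tau_m: float = 10.0
    KI: float = 18.0
    KA: float = 3000.0
    ph: PHParams = field(default_factory=PHParams)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    m_c: Optional[float] = None
    m_bounds: tuple = (-2.0, 10.0)

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError("N must be positive")
        if not 0.0 < self.a0_ref < 1.0:
            raise ValueError("a0_ref must lie in (0, 1)")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if not self.KI < self.KA:
            raise ValueError("attractant convention requires KI < KA")
        if self.m_c is None:
            object.__setattr__(self, "m_c", self.m0)

    def alpha(self, T: float) -> float:
        """Methylation free energy per methyl group at temperature T, kT."""
        a = self.alpha0 + self.thermo.dalpha_dT * (T - self.thermo.T0)
        if a <= 0:
            raise ValueError(f"alpha(T={T}) = {a} must stay positive")
        return a

    def k_m(self, T: Optional[float] = None) -> float:
        """Methylation rate constant.

        Chosen so the linearized relaxation time of the *activity* equals
        tau_m:  1/tau_m = k_m * N * alpha(T) * a0(1-a0).
        """
        from .signaling import adapted_activity

        if T is None:
            a0, alpha = self.a0_ref, self.alpha0
        else:
            a0, alpha = adapted_activity(T, self), self.alpha(T)
        return 1.0 / (self.tau_m * self.N * alpha * a0 * (1.0 - a0))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MotorParams:
    """Flagellar motor response parameters.

    The CW bias follows a Hill function of the kinase activity,
    bias = a^H / (a^H + K(T)^H), with K(T) = K_ref*(1 + kappa*(T - T0)).
    The rate of entering the tumble state is bias/tau_tumble, and passive
    rotational diffusion reverses the 1D direction at rate 2*D_r.
    """

    H: float = 10.0
    K_ref: float = 0.5
    kappa: float = 0.01  # fractional slope of K with temperature, 1/degC
    tau_tumble: float = 0.2  # s
    D_r: float = 0.062  # 1/s
    T0: float = 25.0  # degC

    def __post_init__(self) -> None:
        if not self.H > 0:
            raise ValueError("H must be positive")
        if not 0.0 < self.K_ref < 1.0:
            raise ValueError("K_ref must lie in (0, 1)")
        if not self.tau_tumble > 0:
            raise ValueError("tau_tumble must be positive")
        if self.D_r < 0:
            raise ValueError("D_r must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)
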