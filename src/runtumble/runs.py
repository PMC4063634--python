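"""Configuration layer and file-producing run entry points.

A run is described by a schema-validated configuration (YAML or dict) with
one block per model component.  Unknown keys are rejected and all defaults
are materialized into the manifest that every run writes next to its
outputs, so any output file is regenerable from its manifest alone
(plus the seed for stochastic runs).

Physical quantities carry unit suffixes in their key names (``tau_m_s``,
``T0_C``, ...) to prevent unit drift in config files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .params import ReceptorParams, MotorParams, PHParams, ThermoParams
from .motility import SpeedProfile
from .environments import Environment1D, PH_REGIMES
from . import steadystate as ss
from . import signaling as sig

__all__ = ["RunConfig", "load_config", "run_steady_state", "run_simulation", "run_scan"]

_VERSION = "0.1.0"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReceptorBlock(_Block):
    N: float = 6.0
    alpha0_kT: float = 2.0
    m0: float = 1.0
    a0_ref: float = 0.5
    tau_m_s: float = 10.0
    KI_uM: float = 18.0
    KA_uM: float = 3000.0
    ph_regime: Optional[str] = None  # one of PH_REGIMES, or explicit pK keys
    pKI_tar: Optional[float] = None
    pKA_tar: Optional[float] = None
    pKI_tsr: Optional[float] = None
    pKA_tsr: Optional[float] = None
    tar_fraction: float = 0.5
    dalpha_dT_kT_per_C: float = 0.35
    da0_dT_per_C: float = 0.005
    T0_C: float = 25.0

    def build(self) -> ReceptorParams:
        if self.ph_regime is not None:
            base = PH_REGIMES[self.ph_regime]
        else:
            base = PHParams()
        pk = {
            "pKI_tar": self.pKI_tar if self.pKI_tar is not None else base.pKI_tar,
            "pKA_tar": self.pKA_tar if self.pKA_tar is not None else base.pKA_tar,
            "pKI_tsr": self.pKI_tsr if self.pKI_tsr is not None else base.pKI_tsr,
            "pKA_tsr": self.pKA_tsr if self.pKA_tsr is not None else base.pKA_tsr,
        }
        ph = PHParams(f_a=self.tar_fraction, f_s=1.0 - self.tar_fraction, **pk)
        thermo = ThermoParams(dalpha_dT=self.dalpha_dT_kT_per_C,
                              da0_dT=self.da0_dT_per_C, T0=self.T0_C)
        return ReceptorParams(N=self.N, alpha0=self.alpha0_kT, m0=self.m0,
                              a0_ref=self.a0_ref, tau_m=self.tau_m_s,
                              KI=self.KI_uM, KA=self.KA_uM, ph=ph, thermo=thermo)


class MotorBlock(_Block):
    H: float = 10.0
    K_ref: float = 0.5
    kappa_per_C: float = 0.01
    tau_tumble_s: float = 0.2
    D_r_per_s: float = 0.062
    T0_C: float = 25.0

    def build(self) -> MotorParams:
        return MotorParams(H=self.H, K_ref=self.K_ref, kappa=self.kappa_per_C,
                           tau_tumble=self.tau_tumble_s, D_r=self.D_r_per_s,
                           T0=self.T0_C)


class SpeedBlock(_Block):
    kind: Literal["constant", "linear_in_T", "quadratic_in_T"] = "constant"
    v0_um_s: float = 20.0
    slope_per_C: float = 0.0
    T_ref_C: float = 25.0
    curv_um_s_per_C2: float = 0.0
    T_peak_C: float = 37.0

    def build(self) -> SpeedProfile:
        return SpeedProfile(kind=self.kind, v0=self.v0_um_s, slope=self.slope_per_C,
                            T_ref=self.T_ref_C, curv=self.curv_um_s_per_C2,
                            T_peak=self.T_peak_C)


class ProfileBlock(_Block):
    kind: Literal["linear", "exponential"] = "linear"
    value_at_min: Optional[float] = None
    value_at_max: Optional[float] = None
    L0: Optional[float] = None
    g: Optional[float] = None

    def build(self) -> dict:
        if self.kind == "linear":
            if self.value_at_min is None or self.value_at_max is None:
                raise ValueError("linear profile needs value_at_min/value_at_max")
            return {"kind": "linear", "value_at_min": self.value_at_min,
                    "value_at_max": self.value_at_max}
        if self.L0 is None or self.g is None:
            raise ValueError("exponential profile needs L0 and g")
        return {"kind": "exponential", "L0": self.L0, "g": self.g}


class EnvironmentBlock(_Block):
    x_min_um: float = 0.0
    x_max_um: float = 600.0
    n_grid: int = 512
    ligand_uM: Optional[ProfileBlock] = None
    ph: Optional[ProfileBlock] = None
    temperature_C: Optional[ProfileBlock] = None

    def build(self, speed: SpeedProfile) -> Environment1D:
        return Environment1D(
            x_min=self.x_min_um, x_max=self.x_max_um, n_grid=self.n_grid,
            ligand=self.ligand_uM.build() if self.ligand_uM else None,
            ph=self.ph.build() if self.ph else None,
            temperature=self.temperature_C.build() if self.temperature_C else None,
            speed=speed,
        )


class AbmBlock(_Block):
    n_cells: int = 10_000
    dt_s: float = 0.008
    t_end_s: float = 1500.0
    t_burnin_s: float = 350.0
    seed: int = 0
    n_bins: int = 64
    signal_every: int = 4
    kl_threshold: float = 0.01

    def build(self):
        from .abm import SimConfig

        return SimConfig(n_cells=self.n_cells, dt=self.dt_s, t_end=self.t_end_s,
                         t_burnin=self.t_burnin_s, seed=self.seed,
                         n_bins=self.n_bins, signal_every=self.signal_every)


class ScanBlock(_Block):
    axis: Literal["tar_tsr_ratio", "gradient_steepness", "speed_slope",
                  "kappa", "attractant_gradient"]
    values: list[float]


class RunConfig(_Block):
    scenario: Literal["chemo", "ph", "thermo", "mixed"]
    receptor: ReceptorBlock = Field(default_factory=ReceptorBlock)
    motor: MotorBlock = Field(default_factory=MotorBlock)
    speed: SpeedBlock = Field(default_factory=SpeedBlock)
    environment: EnvironmentBlock = Field(default_factory=EnvironmentBlock)
    abm: Optional[AbmBlock] = None
    scan: Optional[ScanBlock] = None

    def build(self):
        sp = self.speed.build()
        return (self.environment.build(sp), self.receptor.build(),
                self.motor.build())


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON path or dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh)
    else:
        data = path_or_dict
    return RunConfig.model_validate(data)


def _derived_quantities(cfg: RunConfig, env, rp, mp) -> dict:
    out = {"chi": ss.sensitivity_chi(rp, mp).chi}
    if cfg.scenario in ("thermo", "mixed"):
        try:
            out["T_c"] = sig.critical_temperature(rp)
        except ValueError:
            out["T_c"] = None
    if cfg.scenario in ("ph", "thermo", "mixed"):
        pt = ss.preferred_point(env, rp, mp, mode=cfg.scenario)
        out.update({k: v for k, v in pt.items() if k in ("x_star", "pH_star", "T_star")})
        out["interior"] = pt["interior"]
    return out


def _write_manifest(path: Path, cfg: RunConfig, derived: dict, extra: dict | None = None):
    manifest = {
        "version": _VERSION,
        "config": json.loads(cfg.model_dump_json()),
        "derived": derived,
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_steady_state(config, out_dir) -> dict:
    """Compute the analytic steady state; write density CSV + manifest JSON."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env, rp, mp = cfg.build()
    profile = ss.steady_state_density(env, rp, mp, mode=cfg.scenario)
    csv_path = out / "density.csv"
    profile.to_csv(csv_path)
    derived = _derived_quantities(cfg, env, rp, mp)
    if cfg.scenario == "ph":
        derived["dispersion_pH"] = ss.dispersion(profile, "pH")
    if cfg.scenario in ("thermo", "mixed"):
        derived["dispersion_T"] = ss.dispersion(profile, "T")
    _write_manifest(out / "manifest.json", cfg, derived)
    return {"density_csv": str(csv_path), "manifest": str(out / "manifest.json"),
            "derived": derived}


def run_simulation(config, out_dir) -> dict:
    """Run the ABM against the matching analytic density; write both + report."""
    from .abm import simulate, compare_profiles

    cfg = load_config(config)
    if cfg.abm is None:
        raise ValueError("configuration has no abm block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env, rp, mp = cfg.build()
    sim_cfg = cfg.abm.build()
    hist, summary = simulate(env, rp, mp, sim_cfg, mode=cfg.scenario)
    # analytic density evaluated on the histogram grid
    env_hist = Environment1D(
        x_min=env.x_min, x_max=env.x_max, n_grid=sim_cfg.n_bins,
        ligand=env.ligand, ph=env.ph, temperature=env.temperature, speed=env.speed)
    analytic = ss.steady_state_density(env_hist, rp, mp, mode=cfg.scenario)
    metrics = compare_profiles(hist, analytic)
    hist.to_csv(out / "histogram.csv")
    analytic.to_csv(out / "analytic.csv")
    passed = metrics["kl"] < cfg.abm.kl_threshold
    report = {
        "metrics": metrics,
        "kl_threshold": cfg.abm.kl_threshold,
        "passed": bool(passed),
        "stationary": summary["stationary"],
    }
    derived = _derived_quantities(cfg, env, rp, mp)
    _write_manifest(out / "manifest.json", cfg, derived, extra={"divergence": report})
    return {"histogram_csv": str(out / "histogram.csv"),
            "analytic_csv": str(out / "analytic.csv"),
            "report": report}


def run_scan(config, out_dir) -> pd.DataFrame:
    """Scan one parameter axis; write a TSV with one row per value."""
    from dataclasses import replace

    cfg = load_config(config)
    if cfg.scan is None:
        raise ValueError("configuration has no scan block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for val in cfg.scan.values:
        env, rp, mp = cfg.build()
        if cfg.scan.axis == "tar_tsr_ratio":
            rp = replace(rp, ph=rp.ph.with_ratio(val))
        elif cfg.scan.axis == "gradient_steepness":
            lig = dict(env.ligand)
            mid = 0.5 * (lig["value_at_min"] + lig["value_at_max"])
            half = 0.5 * val * env.length / 1000.0
            lig.update(value_at_min=mid - half, value_at_max=mid + half)
            env = replace(env, ligand=lig)
        elif cfg.scan.axis == "attractant_gradient":
            # opposing-gradient scan: value in nM/mm, midpoint fixed
            lig = dict(env.ligand)
            mid = 0.5 * (lig["value_at_min"] + lig["value_at_max"])
            half = 0.5 * val * 1e-3 * env.length / 1000.0
            lig.update(value_at_min=mid + half, value_at_max=mid - half)
            env = replace(env, ligand=lig)
        elif cfg.scan.axis == "speed_slope":
            env = replace(env, speed=replace(env.speed, kind="linear_in_T", slope=val))
        elif cfg.scan.axis == "kappa":
            mp = replace(mp, kappa=val)
        profile = ss.steady_state_density(env, rp, mp, mode=cfg.scenario)
        row = {"value": val, "chi": ss.sensitivity_chi(rp, mp).chi}
        if cfg.scenario == "chemo":
            chi_hat, r2 = ss.fit_chi(profile, env, rp)
            row.update(chi_hat=chi_hat, fit_r2=r2)
        if cfg.scenario in ("ph", "thermo", "mixed"):
            pt = ss.preferred_point(env, rp, mp, mode=cfg.scenario)
            row.update({k: pt.get(k) for k in ("pH_star", "T_star") if k in pt})
            row["interior"] = pt["interior"]
            if cfg.scenario == "ph":
                row["tar_tsr_ratio"] = rp.ph.f_a / rp.ph.f_s
                row["dispersion_pH"] = ss.dispersion(profile, "pH")
            else:
                row["dispersion_T"] = ss.dispersion(profile, "T")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "scan.tsv", sep="\t", index=False, lineterminator="\n")
    return df
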