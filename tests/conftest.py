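"""Shared fixtures.

The agent-based runs are expensive (10^4 cells, 1500 s horizon), so each
scenario family is simulated once per session and shared between the
simulator unit tests and the acceptance suite.  Seeds are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import runtumble as rt
from runtumble.abm import SimConfig, simulate
from runtumble.environments import Environment1D
from runtumble.steadystate import steady_state_density


@dataclass
class AbmRun:
    env: Environment1D
    rp: rt.ReceptorParams
    mp: rt.MotorParams
    mode: str
    hist: rt.DensityProfile
    summary: dict
    analytic: rt.DensityProfile  # on the histogram grid


def _run(env, rp, mp, mode, seed) -> AbmRun:
    cfg = SimConfig(n_cells=10_000, t_end=1500.0, t_burnin=350.0, seed=seed)
    hist, summary = simulate(env, rp, mp, cfg, mode=mode)
    env_h = Environment1D(
        x_min=env.x_min, x_max=env.x_max, n_grid=cfg.n_bins,
        ligand=env.ligand, ph=env.ph, temperature=env.temperature,
        speed=env.speed,
    )
    analytic = steady_state_density(env_h, rp, mp, mode=mode)
    return AbmRun(env=env_h, rp=rp, mp=mp, mode=mode, hist=hist,
                  summary=summary, analytic=analytic)


@pytest.fixture(scope="session")
def default_params():
    return rt.ReceptorParams(), rt.MotorParams()


@pytest.fixture(scope="session")
def chemo_run(default_params) -> AbmRun:
    rp, mp = default_params
    return _run(rt.chemo_fixture(), rp, mp, "chemo", seed=1)


@pytest.fixture(scope="session")
def ph_run(default_params) -> AbmRun:
    rp, mp = default_params
    return _run(rt.ph_fixture(), rp, mp, "ph", seed=2)


@pytest.fixture(scope="session")
def thermo_run(default_params) -> AbmRun:
    rp, mp = default_params
    return _run(rt.thermo_fixture(), rp, mp, "thermo", seed=2)


@pytest.fixture(scope="session")
def combined_run(default_params) -> AbmRun:
    rp, mp = default_params
    return _run(rt.combined_fixture(attr_gradient=3.0), rp, mp, "mixed", seed=2)


@pytest.fixture(scope="session")
def speed_run(default_params) -> AbmRun:
    rp, mp = default_params
    return _run(rt.speed_channel_fixture(), rt.receptorless(rp), mp,
                "thermo", seed=2)
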