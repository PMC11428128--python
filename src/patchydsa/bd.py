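"""Brownian (Langevin) dynamics with a square-wave modulated patch potential.

The discontinuous Kern-Frenkel well has no forces, so the dynamics engine
uses a continuous analogue: a purely repulsive WCA core plus an attraction

    E_att = -eps(t) * exp(-(r - sigma)^2 / (2 rw^2)) * A(th_i) * A(th_j),
    A(th) = exp(-th^2 / (2 aw^2)),

evaluated over the best-aligned patch pairing permitted by the bond rule,
where th is the angle between a patch direction and the interparticle axis.
The nonequilibrium drive modulates the well depth globally as a square wave,
eps(t) = baseline +/- amplitude with a fixed period (floored at zero), the
dynamics analogue of the MC acceptance bias.

Integration is Langevin BAOAB for translations plus a spherical-top
rotational Langevin scheme on lab-frame angular velocities.  Units follow
the kJ/mol - ps - amu convention in which kJ/mol / amu = (sigma/ps)^2, so a
unit mass at 65 K moves at thermal speed ~0.7 sigma/ps.  Target detection
applies the square-well geometric bonding criterion of the MC engine to the
instantaneous geometry (without the hard lower distance bound, since the
soft core permits slight interpenetration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .mc import DriveSpec, RunResult, SquareWave, StopMode, _STATUS_MESSAGES
from .model import (
    BondRule,
    InteractionModel,
    InvalidStateError,
    ParameterError,
    PatchGeometry,
    PatchyConfiguration,
    SimulationBox,
    ThermoState,
)
from .observables import AssemblyResult


@dataclass(frozen=True)
class ContinuousPatchModel:
    """Smooth patchy potential used by the dynamics engine.

    eps_base       attraction depth at zero drive amplitude, kJ/mol
    radial_width   Gaussian radial width of the well, sigma units
    angular_width  Gaussian angular width of a patch, radians
    eps_core       WCA core strength, kJ/mol (cutoff at 2^(1/6) sigma)
    """

    eps_base: float
    sigma: float = 1.0
    radial_width: float = 0.15
    angular_width: float = 0.5
    eps_core: float = 5.0
    bond_rule: BondRule = BondRule.ONE_STATE
    geometry: PatchGeometry = field(default_factory=PatchGeometry)

    def __post_init__(self):
        if self.radial_width <= 0 or self.angular_width <= 0:
            raise ParameterError("widths must be > 0")
        if self.eps_base < 0 or self.eps_core <= 0:
            raise ParameterError("eps_base >= 0 and eps_core > 0 required")


@dataclass(frozen=True)
class BDParams:
    """Integrator parameters (kJ/mol - ps - amu unit system)."""

    timestep: float = 0.005  # ps
    friction: float = 1.0  # 1/ps
    mass: float = 1.0  # amu-like reduced mass
    inertia: float = 0.4  # spherical top, ~ (2/5) m (sigma/2)^2 * 4
    temperature: float = 65.0  # K
    budget_time: float = 1000.0  # ps

    def __post_init__(self):
        if self.timestep <= 0:
            raise ParameterError("timestep must be > 0")
        if self.budget_time < self.timestep:
            raise ParameterError("budget_time must be >= timestep")
        if self.mass <= 0 or self.inertia <= 0 or self.friction <= 0:
            raise ParameterError("mass, inertia and friction must be > 0")


def square_wave_eps(t: float, drive: DriveSpec) -> float:
    """Instantaneous well depth eps(t) of the square-wave drive, kJ/mol.

    baseline + amplitude on the first half-period, baseline - amplitude on
    the second, floored at zero.  With no waveform the baseline is returned
    unmodulated (amplitude 0 is the equilibrium case).
    """
    wf = drive.waveform
    if wf is None:
        raise ParameterError("drive has no waveform")
    if wf.period <= 0:
        raise ParameterError("period must be > 0")
    return float(_kernels._square_wave(float(t), wf.baseline, wf.amplitude, wf.period))


def pair_force_energy(
    pi,
    pj,
    model: ContinuousPatchModel,
    eps_t: float,
    box: SimulationBox,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Energy, forces (2,3) and torques (2,3) of one pair at well depth eps_t.

    Forces and torques are the exact analytic gradients of the continuous
    potential (validated against central differences in the test suite).
    """
    pos = np.stack([pi.position, pj.position])
    quat = np.stack([pi.orientation, pj.orientation])
    species = np.array([int(pi.species), int(pj.species)], dtype=np.int64)
    config = PatchyConfiguration(pos, quat, species)
    pdirs = config.patch_directions_lab(model.geometry)
    F = np.zeros((2, 3))
    T = np.zeros((2, 3))
    rule = 0 if model.bond_rule is BondRule.ONE_STATE else 1
    E = _kernels._bd_forces(
        config.positions,
        np.ascontiguousarray(pdirs),
        config.species,
        np.ascontiguousarray(box.edge),
        float(eps_t),
        model.sigma,
        model.radial_width,
        model.angular_width,
        model.eps_core,
        rule,
        F,
        T,
    )
    if not np.isfinite(E):
        raise InvalidStateError("singular pair geometry (r = 0)")
    return float(E), F, T


def run_bd(
    initial: PatchyConfiguration,
    model: ContinuousPatchModel,
    drive: DriveSpec,
    bd_params: BDParams,
    box: SimulationBox,
    stop_mode: StopMode = StopMode.FIXED_BUDGET,
    seed: int = 0,
    record_every_ps: float = 1.0,
    check_every_ps: float = 0.25,
    detection: Optional[InteractionModel] = None,
    n_target_bonds: Optional[int] = None,
) -> RunResult:
    """Integrate Langevin dynamics under the square-wave drive.

    Velocities and angular velocities are drawn from the Maxwell-Boltzmann
    distribution at the thermostat temperature.  T_fas is reported in ps at
    the detection resolution ``check_every_ps``.
    """
    wf = drive.waveform or SquareWave(baseline=model.eps_base, amplitude=0.0, period=20.0)
    if detection is None:
        detection = InteractionModel(eps_patch=model.eps_base, sigma=model.sigma,
                                     bond_rule=model.bond_rule, geometry=model.geometry)
    if n_target_bonds is None:
        n_target_bonds = initial.n_patchy

    config = initial.copy()
    thermo = ThermoState(bd_params.temperature)
    rng = np.random.default_rng(seed)
    n = config.n_particles
    vel = rng.standard_normal((n, 3)) * np.sqrt(thermo.kT / bd_params.mass)
    omega = rng.standard_normal((n, 3)) * np.sqrt(thermo.kT / bd_params.inertia)

    n_steps = int(round(bd_params.budget_time / bd_params.timestep))
    record_every = max(1, int(round(record_every_ps / bd_params.timestep)))
    check_every = max(1, int(round(check_every_ps / bd_params.timestep)))
    rule = 0 if model.bond_rule is BondRule.ONE_STATE else 1

    (status, rec_count, rec_t, rec_E, rec_nb, rec_KE,
     event_time, censored, final_time) = _kernels.run_bd_kernel(
        config.positions,
        config.quaternions,
        vel,
        omega,
        config.species,
        np.ascontiguousarray(model.geometry.patch_directions),
        float(wf.baseline),
        float(wf.amplitude),
        float(wf.period),
        float(model.sigma),
        float(model.radial_width),
        float(model.angular_width),
        float(model.eps_core),
        rule,
        float(thermo.kT),
        float(bd_params.mass),
        float(bd_params.inertia),
        float(bd_params.friction),
        float(bd_params.timestep),
        np.ascontiguousarray(box.edge),
        np.int64(n_steps),
        np.int64(record_every),
        np.int64(check_every),
        stop_mode.value,
        float(detection.lambda_range * detection.sigma),
        float(detection.cos_theta_max),
        np.int64(n_target_bonds),
        np.int64(int(rng.integers(2**31 - 1))),
    )
    if status != _kernels.OK:
        raise InvalidStateError(_STATUS_MESSAGES[status])

    t = rec_t[:rec_count].copy()
    nb = rec_nb[:rec_count].copy()
    energy = rec_E[:rec_count].copy()
    R = np.minimum(1.0, nb / float(n_target_bonds))

    assembly = AssemblyResult()
    if stop_mode is StopMode.FIRST_ASSEMBLY:
        if censored:
            assembly.t_fas, assembly.t_fas_censored = bd_params.budget_time, True
        else:
            assembly.t_fas, assembly.t_fas_censored = float(event_time), False
    elif stop_mode is StopMode.FIRST_DISASSEMBLY:
        if censored:
            assembly.t_stable, assembly.t_stable_censored = bd_params.budget_time, True
        else:
            assembly.t_stable, assembly.t_stable_censored = float(event_time), False

    result = RunResult(
        steps=t,
        total_energy=energy,
        order_parameter=R,
        entropy=np.zeros_like(t),
        n_bonds=nb,
        assembly=assembly,
        final_configuration=config,
        seed=seed,
        acceptance_rate=1.0,
    )
    # kinetic-energy series for thermostat diagnostics
    result.kinetic_energy = rec_KE[:rec_count].copy()
    return result
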