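"""Metropolis Monte Carlo with a nonequilibrium target-bond acceptance bias.

One MC step is one attempted single-particle move: a random particle is
chosen, then with probability ``translation_probability`` a uniform
displacement in a cube of half-width ``max_translation`` is proposed,
otherwise a rotation about a uniformly random axis by an angle uniform in
[0, max_rotation) (crowders only translate).  The move is accepted with

    p = min(1, exp(-(dE - eps_drive * dn) / kT))

where dn is the change in target-bond count incident to the moved particle.
The drive modifies the acceptance ratio only: the stored configurational
energy remains the undriven Kern-Frenkel energy, which is what breaks
detailed balance with respect to the physical energy and makes the process
dissipative.  Each accepted bond-count-changing move contributes
``eps_drive * |dn| / kT`` (in k_B units) to the housekeeping entropy
production S, so S is non-decreasing and identically zero in equilibrium
(eps_drive = 0).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .model import (
    BondRule,
    HARD_CORE_ENERGY,
    InteractionModel,
    InvalidStateError,
    ParameterError,
    PatchyConfiguration,
    PatchyParticle,
    SimulationBox,
    Species,
    ThermoState,
    pair_interaction,
    quat_rotate,
    rotation_to_quat,
)
from .observables import AssemblyResult
from scipy.spatial.transform import Rotation


class StopMode(enum.Enum):
    FIXED_BUDGET = 0
    FIRST_ASSEMBLY = 1
    FIRST_DISASSEMBLY = 2


@dataclass(frozen=True)
class MoveParams:
    """Single-particle move sizes.

    Defaults are calibrated so that the 8-particle system at 65 K shows the
    three assembly regimes (censored / fast / kinetically trapped) within a
    10^7-step budget; smaller moves freeze chain rearrangement and push
    first-assembly times beyond any practical budget.
    """

    max_translation: float = 0.3  # sigma
    max_rotation: float = 0.4  # rad
    translation_probability: float = 0.5

    def __post_init__(self):
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ParameterError("move sizes must be >= 0")
        if not (0.0 <= self.translation_probability <= 1.0):
            raise ParameterError("translation_probability must lie in [0, 1]")


@dataclass(frozen=True)
class SquareWave:
    """Square-wave modulation of the patch well depth (BD drive)."""

    baseline: float  # kJ/mol
    amplitude: float  # kJ/mol
    period: float  # ps
    shape: str = "SQUARE"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.period <= 0:
            raise ParameterError("period must be > 0")
        if self.shape != "SQUARE":
            raise ParameterError("only SQUARE waveforms are supported")


@dataclass(frozen=True)
class DriveSpec:
    """Nonequilibrium drive: MC acceptance bias and/or BD waveform."""

    eps_drive: float = 0.0  # kJ/mol, MC acceptance bias
    waveform: Optional[SquareWave] = None  # BD only

    def __post_init__(self):
        if self.eps_drive < 0:
            raise ParameterError("eps_drive must be >= 0")


@dataclass
class MoveRecord:
    """Bookkeeping of one attempted move."""

    step_index: int
    accepted: bool
    delta_E: float
    delta_n_target_bonds: int
    entropy_increment: float  # k_B units


@dataclass
class RunResult:
    """Time series plus outcome of one MC or BD run."""

    steps: np.ndarray  # step index (MC) or time in ps (BD)
    total_energy: np.ndarray  # kJ/mol
    order_parameter: np.ndarray
    entropy: np.ndarray  # cumulative S, k_B units
    n_bonds: np.ndarray
    assembly: AssemblyResult
    final_configuration: PatchyConfiguration
    seed: int
    acceptance_rate: float
    n_accepted: int = 0
    sum_abs_dn: int = 0  # sum of |dn| over accepted bond-changing moves
    entropy_final: float = 0.0


# ---------------------------------------------------------------------------
# elementary operations (reference implementations)
# ---------------------------------------------------------------------------

def acceptance_probability(
    delta_E: float, delta_n: int, eps_drive: float, kT: float
) -> float:
    """min(1, exp(-(dE - eps_drive*dn)/kT)); hard-core overlap (dE = +inf) -> 0."""
    if kT <= 0:
        raise ParameterError("kT must be > 0")
    if math.isinf(delta_E):
        return 0.0
    arg = (delta_E - eps_drive * delta_n) / kT
    return 1.0 if arg <= 0 else math.exp(-arg)


def entropy_increment(
    accepted: bool, delta_n: int, eps_drive: float, kT: float
) -> float:
    """Housekeeping entropy of one move, k_B units."""
    if accepted and delta_n != 0:
        return eps_drive * abs(delta_n) / kT
    return 0.0


def propose_move(
    config: PatchyConfiguration,
    particle_index: int,
    move_params: MoveParams,
    rng: np.random.Generator,
) -> PatchyParticle:
    """Trial state for one particle (crowders: translation only)."""
    if not (0 <= particle_index < config.n_particles):
        raise ParameterError("particle index out of range")
    sp = Species(int(config.species[particle_index]))
    pos = config.positions[particle_index].copy()
    quat = config.quaternions[particle_index].copy()
    translate = sp is Species.CROWDER or rng.random() < move_params.translation_probability
    if translate:
        pos = pos + (2.0 * rng.random(3) - 1.0) * move_params.max_translation
    else:
        axis = rng.standard_normal(3)
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 1e-12 else np.array([1.0, 0.0, 0.0])
        angle = rng.random() * move_params.max_rotation
        dq = rotation_to_quat(Rotation.from_rotvec(angle * axis))
        quat = _quat_multiply(dq, quat)
        quat = quat / np.linalg.norm(quat)
    return PatchyParticle(position=pos, orientation=quat, species=sp)


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def _particle_env(
    config: PatchyConfiguration,
    i: int,
    trial: Optional[PatchyParticle],
    model: InteractionModel,
    box: SimulationBox,
):
    """(energy, n_bonds, overlap) of particle i against all others."""
    pi = trial if trial is not None else config.particle(i)
    energy, nb = 0.0, 0
    for j in range(config.n_particles):
        if j == i:
            continue
        res = pair_interaction(pi, config.particle(j), model, box)
        if res.overlap:
            return HARD_CORE_ENERGY, 0, True
        energy += res.energy
        if res.bonded_patch_pair is not None:
            nb += 1
    return energy, nb, False


def mc_step(
    config: PatchyConfiguration,
    model: InteractionModel,
    thermo: ThermoState,
    drive: DriveSpec,
    move_params: MoveParams,
    rng: np.random.Generator,
    step_index: int = 0,
):
    """One attempted move (pure-python reference path; the production run
    uses the compiled kernel).  Returns (new_config, MoveRecord); the input
    configuration is not modified."""
    i = int(rng.integers(config.n_particles))
    old_E, old_nb, _ = _particle_env(config, i, None, model, box=_require_box(config))
    trial = propose_move(config, i, move_params, rng)
    new_E, new_nb, overlap = _particle_env(config, i, trial, model, _require_box(config))
    if overlap:
        delta_E, delta_n = HARD_CORE_ENERGY, 0
    else:
        delta_E = new_E - old_E
        delta_n = new_nb - old_nb
    p = acceptance_probability(delta_E, delta_n, drive.eps_drive, thermo.kT)
    accepted = rng.random() < p if p < 1.0 else True
    out = config
    if accepted:
        out = config.copy()
        box = _require_box(config)
        out.positions[i] = box.wrap(trial.position)
        out.quaternions[i] = trial.orientation
    rec = MoveRecord(
        step_index=step_index,
        accepted=accepted,
        delta_E=delta_E,
        delta_n_target_bonds=delta_n,
        entropy_increment=entropy_increment(accepted, delta_n, drive.eps_drive, thermo.kT),
    )
    return out, rec


_BOX_ATTR = "_box"


def attach_box(config: PatchyConfiguration, box: SimulationBox) -> PatchyConfiguration:
    """Associate a box with a configuration for the reference step path."""
    setattr(config, _BOX_ATTR, box)
    return config


def _require_box(config: PatchyConfiguration) -> SimulationBox:
    box = getattr(config, _BOX_ATTR, None)
    if box is None:
        raise InvalidStateError("configuration has no attached box; use attach_box()")
    return box


# ---------------------------------------------------------------------------
# production run (compiled kernel)
# ---------------------------------------------------------------------------

_STATUS_MESSAGES = {
    _kernels.ERR_INITIAL_OVERLAP: "initial configuration contains a hard-core overlap",
    _kernels.ERR_ENERGY_DRIFT: "incremental bond bookkeeping drifted from full recompute",
    _kernels.ERR_BAD_INITIAL: "FIRST_DISASSEMBLY requires starting at the target structure",
    _kernels.ERR_NONFINITE: "non-finite energy; reduce the timestep",
}


def run_mc(
    initial: PatchyConfiguration,
    model: InteractionModel,
    thermo: ThermoState,
    drive: DriveSpec,
    move_params: MoveParams,
    box: SimulationBox,
    budget_steps: int,
    record_every: int = 10_000,
    stop_mode: StopMode = StopMode.FIXED_BUDGET,
    seed: int = 0,
    n_target_bonds: Optional[int] = None,
) -> RunResult:
    """Run the driven Metropolis chain and collect observables.

    FIRST_ASSEMBLY stops at the step where the target detector first fires
    (T_fas, censored at the budget); FIRST_DISASSEMBLY requires a target
    initial state and stops when the bond count first drops below the target
    bond count (T_stable, no grace window).
    """
    if budget_steps < 1:
        raise ParameterError("budget_steps must be >= 1")
    if record_every < 1:
        raise ParameterError("record_every must be >= 1")
    if n_target_bonds is None:
        n_target_bonds = initial.n_patchy
    config = initial.copy()
    rule = 0 if model.bond_rule is BondRule.ONE_STATE else 1

    (status, rec_count, rec_step, rec_nb, rec_S, event_step, censored,
     n_accepted, sum_abs_dn, S_final, nb_final) = _kernels.run_mc_kernel(
        config.positions,
        config.quaternions,
        config.species,
        np.ascontiguousarray(model.geometry.patch_directions),
        float(model.eps_patch),
        float(model.sigma),
        float(model.lambda_range * model.sigma),
        float(model.cos_theta_max),
        rule,
        float(thermo.kT),
        float(drive.eps_drive),
        float(move_params.max_translation),
        float(move_params.max_rotation),
        float(move_params.translation_probability),
        np.ascontiguousarray(box.edge),
        np.int64(budget_steps),
        np.int64(record_every),
        stop_mode.value,
        np.int64(n_target_bonds),
        np.int64(min(budget_steps, 2_000_000)),
        np.int64(seed),
    )
    if status != _kernels.OK:
        raise InvalidStateError(_STATUS_MESSAGES[status])

    steps = rec_step[:rec_count].copy()
    n_bonds = rec_nb[:rec_count].copy()
    S = rec_S[:rec_count].copy()
    energy = -model.eps_patch * n_bonds.astype(float)
    R = np.minimum(1.0, n_bonds / float(n_target_bonds))

    assembly = AssemblyResult()
    last_step = int(steps[-1]) if rec_count else budget_steps
    if stop_mode is StopMode.FIRST_ASSEMBLY:
        if censored:
            assembly.t_fas, assembly.t_fas_censored = float(budget_steps), True
        else:
            assembly.t_fas, assembly.t_fas_censored = float(event_step), False
    elif stop_mode is StopMode.FIRST_DISASSEMBLY:
        if censored:
            assembly.t_stable, assembly.t_stable_censored = float(budget_steps), True
        else:
            assembly.t_stable, assembly.t_stable_censored = float(event_step), False

    return RunResult(
        steps=steps,
        total_energy=energy,
        order_parameter=R,
        entropy=S,
        n_bonds=n_bonds,
        assembly=assembly,
        final_configuration=config,
        seed=seed,
        acceptance_rate=n_accepted / max(1, last_step),
        n_accepted=int(n_accepted),
        sum_abs_dn=int(sum_abs_dn),
        entropy_final=float(S_final),
    )
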