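"""Replicated sweeps over interaction and drive strength, region segmentation,
system presets (bare / crowded / large), and the normalized-entropy curve.

Medians follow the censored-at-budget convention: a replicate whose stopping
event did not occur within the budget enters the median at the budget value,
so a grid cell where more than half the replicates are censored reports the
budget itself as its median (the region-I plateau at the total step count).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .mc import DriveSpec, MoveParams, StopMode, run_mc
from .model import (
    BondRule,
    InteractionModel,
    ParameterError,
    PatchyConfiguration,
    SimulationBox,
    ThermoState,
    random_configuration,
    target_configuration,
)


class SystemPreset(enum.Enum):
    BARE_8 = "bare_8"  # 8 patchy particles, 4.5 sigma box ("gaseous-like")
    CROWDED_8_48 = "crowded_8_48"  # 8 patchy + 48 crowders, 6 sigma box
    LARGE_1000 = "large_1000"  # 1000 patchy at the BARE_8 number density


class SweepMode(enum.Enum):
    TFAS = "tfas"
    TSTABLE = "tstable"


@dataclass
class SweepSpec:
    """Grid of (eps_patch, eps_drive) cells with replicate runs per cell."""

    eps_patch_values: Sequence[float]
    eps_drive_values: Sequence[float] = (0.0,)
    replicates: int = 20
    budget: int = 10_000_000
    start_mode: SweepMode = SweepMode.TFAS
    preset: SystemPreset = SystemPreset.BARE_8
    bond_rule: BondRule = BondRule.ONE_STATE
    temperature: float = 65.0
    seed: int = 0
    record_every: int = 100_000

    def __post_init__(self):
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if len(self.eps_patch_values) == 0 or len(self.eps_drive_values) == 0:
            raise ParameterError("grid must be non-empty")


@dataclass
class SweepResult:
    """Per-cell replicate values with censoring, medians and region labels."""

    spec: SweepSpec
    # keyed by (eps_patch, eps_drive)
    values: Dict[Tuple[float, float], np.ndarray]
    censored: Dict[Tuple[float, float], np.ndarray]
    medians: Dict[Tuple[float, float], float]
    regions: Dict[float, str] = field(default_factory=dict)  # eps_patch -> label


def preset_system(
    name: SystemPreset,
    bond_rule: BondRule = BondRule.ONE_STATE,
    seed: int = 0,
    start_at_target: bool = False,
) -> Tuple[PatchyConfiguration, SimulationBox]:
    """Initial configuration and box for one of the study systems.

    LARGE_1000 uses the BARE_8 number density (8 particles in a 4.5-sigma box
    -> 1000 particles in a 22.5-sigma box); two-state variants split species
    half and half.
    """
    if name is SystemPreset.BARE_8:
        box = SimulationBox.cubic(4.5)
        if start_at_target:
            model = InteractionModel(eps_patch=1.0, bond_rule=bond_rule)
            return target_configuration(8, model, box), box
        return random_configuration(8, 0, bond_rule, box, seed), box
    if name is SystemPreset.CROWDED_8_48:
        box = SimulationBox.cubic(6.0)
        if start_at_target:
            raise ParameterError("crowded preset starts from random configurations")
        return random_configuration(8, 48, bond_rule, box, seed), box
    if name is SystemPreset.LARGE_1000:
        box = SimulationBox.cubic(22.5)
        return random_configuration(1000, 0, bond_rule, box, seed), box
    raise ParameterError(f"unknown preset {name}")


def median_with_censoring(values: np.ndarray, censored: np.ndarray, budget: float) -> float:
    """Median over all replicates, censored values entered at the budget."""
    vals = np.where(censored, budget, values)
    return float(np.median(vals))


def run_sweep(
    spec: SweepSpec,
    model_defaults: Optional[InteractionModel] = None,
    move_params: MoveParams = MoveParams(),
) -> SweepResult:
    """Run ``replicates`` independent chains per grid cell and collect medians.

    Replicate r of a cell uses seed = root_seed + r (one root per cell,
    derived deterministically from the sweep seed and the cell index).
    """
    if model_defaults is None:
        model_defaults = InteractionModel(eps_patch=0.0, bond_rule=spec.bond_rule)
    thermo = ThermoState(spec.temperature)
    values: Dict[Tuple[float, float], np.ndarray] = {}
    censored: Dict[Tuple[float, float], np.ndarray] = {}
    medians: Dict[Tuple[float, float], float] = {}
    cell_index = 0
    for eps_patch in spec.eps_patch_values:
        for eps_drive in spec.eps_drive_values:
            cell_index += 1
            root = (spec.seed + 100_000 * cell_index) % (2**31 - 1)
            model = model_defaults.with_eps(float(eps_patch))
            vals = np.empty(spec.replicates)
            cens = np.zeros(spec.replicates, dtype=bool)
            for r in range(spec.replicates):
                run_seed = root + r
                try:
                    if spec.start_mode is SweepMode.TFAS:
                        config, box = preset_system(
                            spec.preset, spec.bond_rule, seed=run_seed
                        )
                        res = run_mc(
                            config, model, thermo, DriveSpec(eps_drive=float(eps_drive)),
                            move_params, box, spec.budget,
                            record_every=spec.record_every,
                            stop_mode=StopMode.FIRST_ASSEMBLY, seed=run_seed,
                            n_target_bonds=8,
                        )
                        vals[r] = res.assembly.t_fas
                        cens[r] = res.assembly.t_fas_censored
                    else:
                        config, box = preset_system(
                            spec.preset, spec.bond_rule, seed=run_seed,
                            start_at_target=True,
                        )
                        res = run_mc(
                            config, model, thermo, DriveSpec(eps_drive=float(eps_drive)),
                            move_params, box, spec.budget,
                            record_every=spec.record_every,
                            stop_mode=StopMode.FIRST_DISASSEMBLY, seed=run_seed,
                            n_target_bonds=8,
                        )
                        vals[r] = res.assembly.t_stable
                        cens[r] = res.assembly.t_stable_censored
                except Exception as exc:
                    raise RuntimeError(
                        f"sweep cell eps_patch={eps_patch}, eps_drive={eps_drive}, "
                        f"replicate {r} failed"
                    ) from exc
            key = (float(eps_patch), float(eps_drive))
            values[key] = vals
            censored[key] = cens
            medians[key] = median_with_censoring(vals, cens, spec.budget)
    result = SweepResult(spec=spec, values=values, censored=censored, medians=medians)
    if len(spec.eps_patch_values) >= 4 and len(spec.eps_drive_values) == 1:
        mode = spec.start_mode
        result.regions = segment_regions(result, mode)
    return result


def segment_regions(result: SweepResult, mode: SweepMode) -> Dict[float, str]:
    """Label the eps_patch axis with assembly/stability regimes.

    TFAS: region I is the maximal low-eps prefix where at least half the
    replicates are censored; region III is the maximal high-eps suffix whose
    median exceeds the global minimum median by a factor >= 1.3; region II is
    the remainder.  TSTABLE: region B starts at the first eps whose median
    exceeds twice the low-eps plateau (median of the replicate values pooled
    over the lowest two grid points); region A is the prefix.
    """
    spec = result.spec
    eps_values = [float(e) for e in spec.eps_patch_values]
    if len(eps_values) < 4:
        raise ParameterError("region segmentation needs >= 4 eps_patch grid points")
    if any(b <= a for a, b in zip(eps_values[:-1], eps_values[1:])):
        raise ParameterError("eps_patch grid must be strictly increasing")
    drive = float(spec.eps_drive_values[0])
    meds = np.array([result.medians[(e, drive)] for e in eps_values])
    labels: Dict[float, str] = {}
    if mode is SweepMode.TFAS:
        cens_frac = np.array(
            [np.mean(result.censored[(e, drive)]) for e in eps_values]
        )
        i_end = 0
        while i_end < len(eps_values) and cens_frac[i_end] >= 0.5:
            i_end += 1
        if i_end == len(eps_values):
            return {e: "I" for e in eps_values}
        global_min = float(np.min(meds[i_end:])) if i_end < len(meds) else float(np.min(meds))
        iii_start = len(eps_values)
        while iii_start - 1 >= i_end and meds[iii_start - 1] >= 1.3 * global_min:
            iii_start -= 1
        for k, e in enumerate(eps_values):
            labels[e] = "I" if k < i_end else ("III" if k >= iii_start else "II")
    else:
        pooled = np.concatenate(
            [
                np.where(result.censored[(e, drive)], spec.budget,
                         result.values[(e, drive)])
                for e in eps_values[:2]
            ]
        )
        plateau = float(np.median(pooled))
        b_start = len(eps_values)
        for k, e in enumerate(eps_values):
            if meds[k] > 2.0 * plateau:
                b_start = k
                break
        for k, e in enumerate(eps_values):
            labels[e] = "A" if k < b_start else "B"
    return labels


def region_boundary(regions: Dict[float, str], first_label: str) -> Optional[float]:
    """Smallest eps_patch not carrying ``first_label`` (the I/II or A/B edge)."""
    for eps, lab in sorted(regions.items()):
        if lab != first_label:
            return eps
    return None


def normalized_entropy_vs_drive(
    eps_patch: float,
    drive_values: Sequence[float],
    replicates: int = 5,
    seed: int = 0,
    bond_rule: BondRule = BondRule.ONE_STATE,
    temperature: float = 65.0,
    budget: int = 10_000_000,
    move_params: MoveParams = MoveParams(),
) -> Dict[float, dict]:
    """Total entropy production up to T_fas normalized by the drive.

    For each eps_drive > 0 the cumulative S at first assembly is divided by
    eps_drive/kT, which equals the number of accepted drive-affected events
    weighted by |dn| -- a proxy for the number of entropy-producing cycles.
    Censored replicates are flagged and excluded from the summary median.
    """
    if any(d <= 0 for d in drive_values):
        raise ParameterError("all drive values must be > 0")
    thermo = ThermoState(temperature)
    model = InteractionModel(eps_patch=eps_patch, bond_rule=bond_rule)
    out: Dict[float, dict] = {}
    for k, eps_drive in enumerate(drive_values):
        per_rep = []
        censored_flags = []
        for r in range(replicates):
            run_seed = (seed + 977 * (k + 1) + r) % (2**31 - 1)
            config, box = preset_system(SystemPreset.BARE_8, bond_rule, seed=run_seed)
            res = run_mc(
                config, model, thermo, DriveSpec(eps_drive=float(eps_drive)),
                move_params, box, budget, stop_mode=StopMode.FIRST_ASSEMBLY,
                seed=run_seed, n_target_bonds=8,
            )
            norm = res.entropy_final / (eps_drive / thermo.kT)
            per_rep.append(norm)
            censored_flags.append(res.assembly.t_fas_censored)
        per_rep = np.array(per_rep)
        flags = np.array(censored_flags)
        ok = ~flags
        out[float(eps_drive)] = {
            "normalized_entropy": per_rep,
            "censored": flags,
            "median": float(np.median(per_rep[ok])) if np.any(ok) else float("nan"),
        }
    return out
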