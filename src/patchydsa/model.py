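"""Kern-Frenkel patchy particles: types, pair potential, canonical configurations.

The particle is a hard sphere of diameter ``sigma`` decorated with two
attractive surface patches whose directions subtend a fixed opening angle
(135 degrees by default, the interior angle of a regular octagon, so that
eight particles can close into an unstrained ring).  A pair of particles
attracts with a square well of depth ``eps_patch`` when their centres lie
inside the radial well ``sigma <= r < lambda_range * sigma`` and one patch on
each particle points at the other particle to within the angular half-width
(``cos theta >= cos_theta_max``) -- the Kern-Frenkel criterion.

Two bond-specificity rules are supported: a one-state system in which any
pair of patchy (alpha) particles may bond, and a two-state system of alpha
and beta particles in which only alpha-beta contacts carry energy.  Inert
crowding particles interact through the hard core only.

Units: lengths in units of the core diameter sigma, energies in kJ/mol,
temperature in kelvin with kT = R_gas * T.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

R_GAS = 0.0083145  # kJ/(mol K)

#: Sentinel energy for a hard-core overlap; treated as +inf by acceptance rules.
HARD_CORE_ENERGY = np.inf


class SimulationError(Exception):
    """Base class for simulator errors."""


class InvalidStateError(SimulationError):
    """A particle or configuration violates its invariants."""


class OverlapError(SimulationError):
    """Hard-core overlap where none is allowed."""

    def __init__(self, i: int, j: int, r: float):
        self.pair = (i, j)
        super().__init__(f"hard-core overlap between particles {i} and {j} (r = {r:.6f} sigma)")


class PackingError(SimulationError):
    """Rejection sampling failed to place all particles without overlap."""


class GeometryError(SimulationError):
    """A requested construction does not fit the simulation box."""


class ParameterError(SimulationError):
    """Invalid physical parameter."""


class Species(enum.IntEnum):
    ALPHA = 0
    BETA = 1
    CROWDER = 2


class BondRule(enum.Enum):
    #: identical particles; any patch-patch contact between two ALPHA particles bonds
    ONE_STATE = "one_state"
    #: alternating alpha/beta ring; only ALPHA-BETA contacts carry energy
    TWO_STATE = "two_state"


SPECIES_LABELS = {Species.ALPHA: "A", Species.BETA: "B", Species.CROWDER: "C"}
LABEL_SPECIES = {v: k for k, v in SPECIES_LABELS.items()}


# ---------------------------------------------------------------------------
# geometry of the two patches
# ---------------------------------------------------------------------------

def _default_patch_directions(opening_angle_deg: float) -> np.ndarray:
    """Two unit vectors in the body x-z plane, symmetric about +z."""
    half = np.deg2rad(opening_angle_deg) / 2.0
    return np.array(
        [
            [np.sin(half), 0.0, np.cos(half)],
            [-np.sin(half), 0.0, np.cos(half)],
        ]
    )


@dataclass(frozen=True)
class PatchGeometry:
    """Body-frame directions of the two patches and their opening angle."""

    opening_angle_deg: float = 135.0
    patch_directions: np.ndarray = None  # (2, 3), set in __post_init__ if omitted

    def __post_init__(self):
        if self.patch_directions is None:
            object.__setattr__(
                self, "patch_directions", _default_patch_directions(self.opening_angle_deg)
            )
        dirs = np.asarray(self.patch_directions, dtype=float)
        if dirs.shape != (2, 3):
            raise InvalidStateError("patch_directions must have shape (2, 3)")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise InvalidStateError("patch directions must be unit vectors (tol 1e-12)")
        angle = np.degrees(np.arccos(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0)))
        if abs(angle - self.opening_angle_deg) > 1e-9:
            raise InvalidStateError(
                f"angle between patches is {angle:.12f} deg, expected {self.opening_angle_deg}"
            )
        object.__setattr__(self, "patch_directions", dirs)


@dataclass(frozen=True)
class InteractionModel:
    """Kern-Frenkel parameters plus the bond-specificity rule.

    eps_patch       square-well depth, kJ/mol
    sigma           hard-core diameter (the length unit; 1 by construction)
    lambda_range    outer edge of the radial well in units of sigma
    cos_theta_max   cosine of the patch angular half-width
    bond_rule       ONE_STATE or TWO_STATE specificity
    """

    eps_patch: float
    sigma: float = 1.0
    lambda_range: float = 1.1
    cos_theta_max: float = 0.95
    bond_rule: BondRule = BondRule.ONE_STATE
    geometry: PatchGeometry = field(default_factory=PatchGeometry)

    def __post_init__(self):
        if self.eps_patch < 0:
            raise ParameterError("eps_patch must be >= 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.lambda_range <= 1:
            raise ParameterError("lambda_range must exceed 1")
        if not (0.0 < self.cos_theta_max < 1.0):
            raise ParameterError("cos_theta_max must lie in (0, 1)")

    def with_eps(self, eps_patch: float) -> "InteractionModel":
        return replace(self, eps_patch=eps_patch)


@dataclass(frozen=True)
class ThermoState:
    """Temperature in kelvin; kT derived in kJ/mol."""

    temperature: float

    def __post_init__(self):
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")

    @property
    def kT(self) -> float:
        return R_GAS * self.temperature


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box with edges in sigma units."""

    edge: np.ndarray
    periodic: Tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        edge = np.atleast_1d(np.asarray(self.edge, dtype=float))
        if edge.size == 1:
            edge = np.repeat(edge, 3)
        if edge.shape != (3,) or np.any(edge <= 0):
            raise ParameterError("box edges must be three positive lengths")
        object.__setattr__(self, "edge", edge)

    @classmethod
    def cubic(cls, edge: float) -> "SimulationBox":
        return cls(edge=np.full(3, float(edge)))

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement(s); supports (..., 3) arrays."""
        d = np.asarray(d, dtype=float)
        per = np.asarray(self.periodic)
        wrapped = d - self.edge * np.round(d / self.edge)
        return np.where(per, wrapped, d)

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        per = np.asarray(self.periodic)
        return np.where(per, np.mod(pos, self.edge), pos)

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge))


@dataclass
class PatchyParticle:
    """Single-particle view: position (sigma units), scalar-first unit quaternion, species."""

    position: np.ndarray
    orientation: np.ndarray
    species: Species = Species.ALPHA

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if not np.all(np.isfinite(self.position)) or self.position.shape != (3,):
            raise InvalidStateError("position must be a finite 3-vector")
        if self.orientation.shape != (4,) or abs(np.linalg.norm(self.orientation) - 1.0) > 1e-10:
            raise InvalidStateError("orientation must be a unit quaternion (tol 1e-10)")

    def patch_directions_lab(self, geometry: PatchGeometry) -> np.ndarray:
        return quat_rotate(self.orientation, geometry.patch_directions)


@dataclass
class PairInteraction:
    """Outcome of evaluating one unordered pair."""

    energy: float
    overlap: bool
    bonded_patch_pair: Optional[Tuple[int, int]] = None


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention)
# ---------------------------------------------------------------------------

def quat_to_rotation(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.concatenate([q[..., 1:4], q[..., 0:1]], axis=-1))


def rotation_to_quat(rot: Rotation) -> np.ndarray:
    xyzw = rot.as_quat()
    q = np.concatenate([xyzw[..., 3:4], xyzw[..., 0:3]], axis=-1)
    # canonical sign: non-negative scalar part
    sign = np.where(q[..., 0:1] < 0, -1.0, 1.0)
    return q * sign


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate row vector(s) v by the unit quaternion q."""
    return quat_to_rotation(q).apply(v)


def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed unit quaternions (scalar-first), n x 4."""
    rots = Rotation.random(n, random_state=rng)
    q = rotation_to_quat(rots)
    return q.reshape(n, 4)


# ---------------------------------------------------------------------------
# configuration container
# ---------------------------------------------------------------------------

@dataclass
class PatchyConfiguration:
    """State of the simulation: positions, orientations and species of all particles.

    positions    (N, 3) float, sigma units
    quaternions  (N, 4) float, scalar-first unit quaternions
    species      (N,)   int (Species codes)
    """

    positions: np.ndarray
    quaternions: np.ndarray
    species: np.ndarray

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.quaternions = np.ascontiguousarray(self.quaternions, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.quaternions.shape != (n, 4):
            raise InvalidStateError("positions must be (N,3) and quaternions (N,4)")
        if self.species.shape != (n,):
            raise InvalidStateError("species must be (N,)")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise InvalidStateError("non-finite position")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise InvalidStateError("non-unit quaternion (tol 1e-10)")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def patchy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species != Species.CROWDER)

    @property
    def n_patchy(self) -> int:
        return int(np.sum(self.species != Species.CROWDER))

    @property
    def n_crowders(self) -> int:
        return int(np.sum(self.species == Species.CROWDER))

    def particle(self, i: int) -> PatchyParticle:
        return PatchyParticle(
            position=self.positions[i].copy(),
            orientation=self.quaternions[i].copy(),
            species=Species(int(self.species[i])),
        )

    def copy(self) -> "PatchyConfiguration":
        return PatchyConfiguration(
            self.positions.copy(), self.quaternions.copy(), self.species.copy()
        )

    def patch_directions_lab(self, geometry: PatchGeometry) -> np.ndarray:
        """Lab-frame patch directions, shape (N, 2, 3). Crowders get zeros."""
        n = self.n_particles
        out = np.zeros((n, 2, 3))
        mask = self.species != Species.CROWDER
        if np.any(mask):
            rots = quat_to_rotation(self.quaternions[mask])
            mats = rots.as_matrix()  # (m, 3, 3)
            out[mask] = np.einsum("nij,pj->npi", mats, geometry.patch_directions)
        return out


def _rule_permits(si: int, sj: int, rule: BondRule) -> bool:
    if si == Species.CROWDER or sj == Species.CROWDER:
        return False
    if rule is BondRule.ONE_STATE:
        return si == Species.ALPHA and sj == Species.ALPHA
    return {si, sj} == {int(Species.ALPHA), int(Species.BETA)}


# ---------------------------------------------------------------------------
# pair potential and total energy
# ---------------------------------------------------------------------------

def pair_interaction(
    pi: PatchyParticle,
    pj: PatchyParticle,
    model: InteractionModel,
    box: SimulationBox,
) -> PairInteraction:
    """Evaluate the Kern-Frenkel interaction of one unordered pair.

    Overlap iff the minimum-image distance is below sigma.  The pair is bonded
    (energy -eps_patch) iff the centre distance lies in the square well and a
    patch on each particle aligns with the interparticle axis to within the
    angular half-width, and the bond rule permits the species pair.
    """
    d = box.minimum_image(pj.position - pi.position)
    r = float(np.linalg.norm(d))
    if r < model.sigma:
        return PairInteraction(energy=HARD_CORE_ENERGY, overlap=True)
    if r >= model.lambda_range * model.sigma:
        return PairInteraction(energy=0.0, overlap=False)
    if not _rule_permits(int(pi.species), int(pj.species), model.bond_rule):
        return PairInteraction(energy=0.0, overlap=False)
    rhat = d / r
    di = pi.patch_directions_lab(model.geometry)
    dj = pj.patch_directions_lab(model.geometry)
    ci = di @ rhat          # patch on i must point toward j
    cj = dj @ (-rhat)       # patch on j must point toward i
    ok_i = np.flatnonzero(ci >= model.cos_theta_max)
    ok_j = np.flatnonzero(cj >= model.cos_theta_max)
    if ok_i.size and ok_j.size:
        # narrow patches: at most one patch per particle can align; pick the
        # best-aligned pairing deterministically
        a = int(ok_i[np.argmax(ci[ok_i])])
        b = int(ok_j[np.argmax(cj[ok_j])])
        return PairInteraction(
            energy=-model.eps_patch, overlap=False, bonded_patch_pair=(a, b)
        )
    return PairInteraction(energy=0.0, overlap=False)


def geometric_bond_candidates(
    config: PatchyConfiguration, model: InteractionModel, box: SimulationBox
):
    """All patch-pair contacts satisfying the bonding criterion.

    Returns (candidates, overlaps): candidates is a list of
    (distance, i, patch_a, j, patch_b) tuples with i < j; overlaps a list of
    (i, j, r) hard-core violations.  Vectorized over all pairs.
    """
    pos = config.positions
    n = config.n_particles
    if n < 2:
        return [], []
    iu, ju = np.triu_indices(n, k=1)
    d = box.minimum_image(pos[ju] - pos[iu])
    r = np.linalg.norm(d, axis=1)
    overlaps = [
        (int(i), int(j), float(rr))
        for i, j, rr in zip(iu[r < model.sigma], ju[r < model.sigma], r[r < model.sigma])
    ]
    in_well = (r >= model.sigma) & (r < model.lambda_range * model.sigma)
    if not np.any(in_well):
        return [], overlaps
    iw, jw, dw, rw = iu[in_well], ju[in_well], d[in_well], r[in_well]
    rhat = dw / rw[:, None]
    dirs = config.patch_directions_lab(model.geometry)
    candidates = []
    spec = config.species
    for k in range(iw.size):
        i, j = int(iw[k]), int(jw[k])
        if not _rule_permits(int(spec[i]), int(spec[j]), model.bond_rule):
            continue
        ci = dirs[i] @ rhat[k]
        cj = dirs[j] @ (-rhat[k])
        ok_i = np.flatnonzero(ci >= model.cos_theta_max)
        ok_j = np.flatnonzero(cj >= model.cos_theta_max)
        if ok_i.size and ok_j.size:
            a = int(ok_i[np.argmax(ci[ok_i])])
            b = int(ok_j[np.argmax(cj[ok_j])])
            candidates.append((float(rw[k]), i, a, j, b))
    return candidates, overlaps


def total_energy(
    config: PatchyConfiguration, model: InteractionModel, box: SimulationBox
) -> float:
    """Sum of pair energies over all unordered pairs; raises on overlap."""
    candidates, overlaps = geometric_bond_candidates(config, model, box)
    if overlaps:
        i, j, r = overlaps[0]
        raise OverlapError(i, j, r)
    # resolve patch-slot exclusivity exactly as build_bond_graph does
    from .observables import _resolve_bonds

    edges = _resolve_bonds(candidates)
    return -model.eps_patch * len(edges)


# ---------------------------------------------------------------------------
# canonical configurations
# ---------------------------------------------------------------------------

def _assign_species(n_patchy: int, bond_rule: BondRule) -> np.ndarray:
    if bond_rule is BondRule.TWO_STATE:
        if n_patchy % 2:
            raise ParameterError("two-state systems need an even particle count")
        sp = np.empty(n_patchy, dtype=np.int64)
        sp[0::2] = Species.ALPHA
        sp[1::2] = Species.BETA
        return sp
    return np.full(n_patchy, int(Species.ALPHA), dtype=np.int64)


def random_configuration(
    n_patchy: int,
    n_crowders: int = 0,
    bond_rule: BondRule = BondRule.ONE_STATE,
    box: SimulationBox = None,
    seed=None,
    sigma: float = 1.0,
    max_attempts: int = 20_000,
) -> PatchyConfiguration:
    """Non-overlapping uniformly random positions with uniform random orientations.

    Two-state systems get alternating species (n/2 alpha, n/2 beta).  Placement
    is sequential rejection sampling against the hard core; a PackingError is
    raised if a particle cannot be placed within ``max_attempts`` draws.
    """
    if box is None:
        box = SimulationBox.cubic(4.5)
    rng = np.random.default_rng(seed)
    n = n_patchy + n_crowders
    positions = np.empty((n, 3))
    placed = 0
    for k in range(n):
        for _ in range(max_attempts):
            trial = rng.random(3) * box.edge
            if placed == 0:
                break
            d = box.minimum_image(positions[:placed] - trial)
            if np.all(np.linalg.norm(d, axis=1) >= sigma):
                break
        else:
            raise PackingError(
                f"could not place particle {k + 1}/{n} after {max_attempts} attempts"
            )
        positions[k] = trial
        placed += 1
    quats = random_quaternions(n, rng)
    species = np.concatenate(
        [_assign_species(n_patchy, bond_rule), np.full(n_crowders, int(Species.CROWDER))]
    )
    return PatchyConfiguration(positions, quats, species)


def target_configuration(
    n: int = 8,
    model: InteractionModel = None,
    box: SimulationBox = None,
    bond_length: float = 1.05,
) -> PatchyConfiguration:
    """Regular octagonal ring with every patch engaged in a bond.

    Particles sit at the vertices of a regular n-gon with side ``bond_length``
    (inside the square well), each oriented so that its two patches point
    exactly at its two ring neighbours.  With the default 135-degree patch
    opening this is unstrained only for n = 8.
    """
    if model is None:
        model = InteractionModel(eps_patch=4.0)
    if box is None:
        box = SimulationBox.cubic(4.5)
    if n != 8:
        raise ParameterError("the ring builder supports n = 8 (regular octagon)")
    if not (model.sigma <= bond_length < model.lambda_range * model.sigma):
        raise GeometryError("bond_length must lie inside the square well")
    circumradius = bond_length / (2.0 * np.sin(np.pi / n))
    if 2.0 * circumradius >= np.min(box.edge):
        raise GeometryError("octagon does not fit the periodic box")
    center = box.edge / 2.0
    phis = 2.0 * np.pi * np.arange(n) / n
    positions = center + circumradius * np.stack(
        [np.cos(phis), np.sin(phis), np.zeros(n)], axis=1
    )
    quats = np.empty((n, 4))
    for i in range(n):
        to_next = positions[(i + 1) % n] - positions[i]
        to_prev = positions[(i - 1) % n] - positions[i]
        u_next = to_next / np.linalg.norm(to_next)
        u_prev = to_prev / np.linalg.norm(to_prev)
        x_img = (u_next - u_prev) / np.linalg.norm(u_next - u_prev)
        z_img = (u_next + u_prev) / np.linalg.norm(u_next + u_prev)
        y_img = np.cross(z_img, x_img)
        # columns are the lab-frame images of the body axes; body patches are
        # symmetric about +z in the x-z plane, so patch 0 -> u_next, patch 1 -> u_prev
        mat = np.stack([x_img, y_img, z_img], axis=1)
        quats[i] = rotation_to_quat(Rotation.from_matrix(mat))
    species = _assign_species(n, model.bond_rule)
    return PatchyConfiguration(positions, quats, species)
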