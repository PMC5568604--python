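"""Replica-exchange Monte Carlo docking.

Ten (by default) copies of the receptor-peptide system evolve at
different temperatures on a geometric ladder.  The peptide is fully
flexible (rigid translations/rotations plus local backbone moves); the
receptor fluctuates around its input conformation under flat-bottom
restraints.  Adjacent replicas periodically attempt to swap
temperatures.  Acceptance uses the sampling energy, i.e. including the
soft contact restraint, which is excluded again when models are scored.

Snapshots collected evenly along each replica form the model pool
(default 10 replicas x 1000 snapshots = 10,000 models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .cg import (BOND_MAX, BOND_MIN, CGChain, ComplexModel, LatticeConfig,
                 snap_to_lattice)
from .energy import EnergyModel, EnergyParams

__all__ = [
    "SimulationConfig",
    "ReplicaState",
    "Trajectory",
    "DockingSystem",
    "MoveWeights",
    "scatter_peptide",
    "propose_move",
    "metropolis_accept",
    "attempt_exchange",
    "run_remc",
]

PEPTIDE_BOND = 3.8  # Angstrom, CA-CA virtual bond
SURFACE_RADIUS = 2.0  # pseudoatom radius defining the molecular surface


@dataclass(frozen=True)
class MoveWeights:
    """Relative frequencies of the Monte Carlo move types."""

    translation: float = 0.15
    rotation: float = 0.15
    kink: float = 0.25
    crankshaft: float = 0.15
    end_flip: float = 0.10
    receptor: float = 0.20

    def as_arrays(self):
        names = ("translation", "rotation", "kink", "crankshaft",
                 "end_flip", "receptor")
        w = np.array([getattr(self, n) for n in names], dtype=float)
        return names, w / w.sum()


@dataclass(frozen=True)
class SimulationConfig:
    n_replicas: int = 10
    t_min: float = 1.0
    t_max: float = 2.0
    n_cycles: int = 1000
    snapshots_per_replica: int = 1000
    exchange_period: int = 50
    max_scatter_distance: float = 20.0
    seed: int = 0
    move_weights: MoveWeights = field(default_factory=MoveWeights)
    translation_step: float = 1.0  # A, Gaussian sigma
    rotation_step: float = 15.0  # degrees, Gaussian sigma
    receptor_step: float = 0.3  # A, Gaussian sigma
    scatter_retries: int = 2000

    def __post_init__(self):
        if self.n_replicas < 2:
            raise ValueError("need at least two replicas")
        if not (0 < self.t_min <= self.t_max):
            raise ValueError("require 0 < t_min <= t_max")

    @property
    def pool_size(self) -> int:
        return self.n_replicas * self.snapshots_per_replica

    def temperature_ladder(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


@dataclass
class ReplicaState:
    """One replica: configuration plus its current ladder position.

    ``replica_id`` (and the attached RNG stream) are permanent; on an
    accepted exchange two states trade ``temperature`` and
    ``ladder_index``, never their identities.
    """

    model: ComplexModel
    temperature: float
    replica_id: int
    rng_stream: np.random.Generator
    ladder_index: int = 0
    energy: float = 0.0  # cached sampling energy
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class Trajectory:
    """Ordered snapshot pool from all replicas."""

    snapshots: list

    def __len__(self):
        return len(self.snapshots)

    def scoring_energies(self) -> np.ndarray:
        return np.array([m.energy.scoring_energy for m in self.snapshots])


@dataclass
class DockingSystem:
    """Prepared inputs for a docking run."""

    receptor: CGChain
    peptide_spec: object  # PeptideSpec
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    params: EnergyParams = field(default_factory=EnergyParams)


# ---------------------------------------------------------------------------
# initial peptide placement

def _self_avoiding_walk(n: int, rng, min_sep: float = 3.6,
                        max_tries: int = 200) -> np.ndarray:
    """Random CA walk with fixed 3.8 A bonds, avoiding self-overlap."""
    for _ in range(max_tries):
        pts = [np.zeros(3)]
        ok = True
        for _i in range(n - 1):
            placed = False
            for _t in range(40):
                v = rng.normal(size=3)
                v *= PEPTIDE_BOND / np.linalg.norm(v)
                cand = pts[-1] + v
                prior = np.asarray(pts[:-1]) if len(pts) > 1 else None
                if prior is None or np.min(
                        np.linalg.norm(prior - cand, axis=1)) >= min_sep:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise RuntimeError("failed to draw a self-avoiding peptide conformation")


def _attach_side_centers(ca: np.ndarray, toward: np.ndarray | None = None):
    """Place CB/SC off the backbone, pointing away from the local trace
    (or toward an external point when given)."""
    n = len(ca)
    cb = np.empty_like(ca)
    sc = np.empty_like(ca)
    centroid = ca.mean(axis=0)
    for i in range(n):
        if toward is not None:
            v = toward - ca[i]
        else:
            v = ca[i] - centroid
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            v = np.array([0.0, 0.0, 1.0])
            norm = 1.0
        u = v / norm
        cb[i] = ca[i] + 1.1 * u
        sc[i] = ca[i] + 2.2 * u
    return cb, sc


def peptide_chain_from_spec(spec, ca: np.ndarray,
                            lattice: LatticeConfig | None = None) -> CGChain:
    """Build a peptide CGChain on the given CA trace."""
    lattice = lattice or LatticeConfig()
    ca = snap_to_lattice(ca, lattice)
    cb, sc = _attach_side_centers(ca)
    return CGChain(spec.names3, np.arange(1, len(spec) + 1), ca, cb, sc,
                   chain_id="P", role="peptide")


def surface_distance(peptide: CGChain, receptor: CGChain) -> float:
    """Minimum peptide-pseudoatom distance to the receptor molecular
    surface (pseudoatom centres inflated by 2 A), clamped at zero."""
    pa, _ = peptide.pseudoatoms()
    ra, _ = receptor.pseudoatoms()
    d = float(cdist(pa, ra).min())
    return max(0.0, d - SURFACE_RADIUS)


def scatter_peptide(receptor: CGChain, spec, max_dist: float = 20.0,
                    rng: np.random.Generator | None = None,
                    lattice: LatticeConfig | None = None,
                    params: EnergyParams | None = None,
                    max_retries: int = 2000) -> CGChain:
    """Place a random-conformation peptide near the receptor.

    The pose is drawn as a self-avoiding CA walk, randomly oriented and
    positioned so that its distance to the receptor molecular surface is
    at most ``max_dist`` and it has no excluded-volume overlap with the
    receptor.
    """
    from .energy import excluded_volume_energy

    if len(receptor) == 0:
        raise ValueError("empty receptor")
    rng = rng if rng is not None else np.random.default_rng()
    lattice = lattice or LatticeConfig()
    params = params or EnergyParams()
    ra, _ = receptor.pseudoatoms()
    center = ra.mean(axis=0)
    r_rec = float(np.linalg.norm(ra - center, axis=1).max())

    for _try in range(max_retries):
        ca = _self_avoiding_walk(len(spec), rng)
        rot = Rotation.random(random_state=rng)
        ca = ca @ rot.as_matrix().T
        ca -= ca.mean(axis=0)
        # aim point: random direction, radius between surface and max_dist
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        radius = r_rec + SURFACE_RADIUS + rng.uniform(0.0, max_dist)
        ca += center + radius * u
        peptide = peptide_chain_from_spec(spec, ca, lattice)
        d = surface_distance(peptide, receptor)
        if d > max_dist:
            # the receptor is not spherical: pull the pose inward along
            # the placement direction until it re-enters the shell
            pull = snap_to_lattice(-u * (d - 0.5 * max_dist), lattice)
            for arr in (peptide.ca, peptide.cb, peptide.sc):
                arr += pull
            d = surface_distance(peptide, receptor)
            if d > max_dist:
                continue
        probe = ComplexModel(receptor, peptide)
        if excluded_volume_energy(probe, params.hard_radius,
                                  params.ev_penalty) > 0:
            continue
        return peptide
    raise RuntimeError(
        f"could not place the peptide within {max_dist} A of the receptor "
        "surface; consider a larger max_dist")


# ---------------------------------------------------------------------------
# move set

def _bonds_ok(ca: np.ndarray) -> bool:
    if len(ca) < 2:
        return True
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    return bool(np.all((d >= BOND_MIN) & (d <= BOND_MAX)))


def _rotate_about(points, axis_point, axis_dir, angle_deg):
    """Rodrigues rotation of point(s) about an axis through axis_point."""
    th = np.radians(angle_deg)
    k = axis_dir
    p = np.atleast_2d(points - axis_point)
    kxp = np.empty_like(p)  # explicit cross product: np.cross is slow here
    kxp[:, 0] = k[1] * p[:, 2] - k[2] * p[:, 1]
    kxp[:, 1] = k[2] * p[:, 0] - k[0] * p[:, 2]
    kxp[:, 2] = k[0] * p[:, 1] - k[1] * p[:, 0]
    cos_t = np.cos(th)
    rot = p * cos_t + kxp * np.sin(th) + np.outer(p @ k, k) * (1.0 - cos_t)
    out = rot + axis_point
    return out if np.ndim(points) == 2 else out[0]


def _peptide_candidate(model):
    """Candidate for a peptide move: the receptor is shared, not copied."""
    return ComplexModel(model.receptor, model.peptide.copy())


def _receptor_candidate(model):
    return ComplexModel(model.receptor.copy(), model.peptide)


def _move_translation(model, cfg, lattice, rng):
    delta = rng.normal(scale=cfg.translation_step, size=3)
    delta = snap_to_lattice(delta, lattice)
    cand = _peptide_candidate(model)
    for arr in (cand.peptide.ca, cand.peptide.cb, cand.peptide.sc):
        arr += delta
    return cand, EnergyModel.PEPTIDE_RIGID

def _move_rotation(model, cfg, lattice, rng):
    angle = rng.normal(scale=cfg.rotation_step)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    cand = _peptide_candidate(model)
    pivot = cand.peptide.ca.mean(axis=0)
    for arr in (cand.peptide.ca, cand.peptide.cb, cand.peptide.sc):
        arr[:] = _rotate_about(arr, pivot, axis, angle)
    cand.peptide.ca[:] = snap_to_lattice(cand.peptide.ca, lattice)
    if not _bonds_ok(cand.peptide.ca):
        return None, EnergyModel.PEPTIDE_RIGID
    return cand, EnergyModel.PEPTIDE_RIGID

def _move_kink(model, cfg, lattice, rng):
    n = len(model.peptide)
    if n < 3:
        return None, EnergyModel.PEPTIDE_LOCAL
    i = int(rng.integers(1, n - 1))
    axis = model.peptide.ca[i + 1] - model.peptide.ca[i - 1]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None, EnergyModel.PEPTIDE_LOCAL
    axis /= norm
    angle = rng.uniform(-60.0, 60.0)
    cand = _peptide_candidate(model)
    pivot = cand.peptide.ca[i - 1]
    for arr in (cand.peptide.ca, cand.peptide.cb, cand.peptide.sc):
        arr[i] = _rotate_about(arr[i], pivot, axis, angle)
    cand.peptide.ca[i] = snap_to_lattice(cand.peptide.ca[i], lattice)
    if not _bonds_ok(cand.peptide.ca):
        return None, EnergyModel.PEPTIDE_LOCAL
    return cand, EnergyModel.PEPTIDE_LOCAL

def _move_crankshaft(model, cfg, lattice, rng):
    n = len(model.peptide)
    if n < 4:
        return None, EnergyModel.PEPTIDE_LOCAL
    i = int(rng.integers(1, n - 2))  # rotate residues i, i+1
    axis = model.peptide.ca[i + 2] - model.peptide.ca[i - 1]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None, EnergyModel.PEPTIDE_LOCAL
    axis /= norm
    angle = rng.uniform(-60.0, 60.0)
    cand = _peptide_candidate(model)
    pivot = cand.peptide.ca[i - 1]
    for arr in (cand.peptide.ca, cand.peptide.cb, cand.peptide.sc):
        arr[i:i + 2] = _rotate_about(arr[i:i + 2], pivot, axis, angle)
    cand.peptide.ca[i:i + 2] = snap_to_lattice(cand.peptide.ca[i:i + 2],
                                               lattice)
    if not _bonds_ok(cand.peptide.ca):
        return None, EnergyModel.PEPTIDE_LOCAL
    return cand, EnergyModel.PEPTIDE_LOCAL

def _move_end_flip(model, cfg, lattice, rng):
    n = len(model.peptide)
    i = 0 if rng.random() < 0.5 else n - 1
    j = 1 if i == 0 else n - 2
    v = rng.normal(size=3)
    v *= PEPTIDE_BOND / np.linalg.norm(v)
    cand = _peptide_candidate(model)
    new_ca = snap_to_lattice(cand.peptide.ca[j] + v, lattice)
    shift = new_ca - cand.peptide.ca[i]
    cand.peptide.ca[i] = new_ca
    cand.peptide.cb[i] += shift
    cand.peptide.sc[i] += shift
    if not _bonds_ok(cand.peptide.ca):
        return None, EnergyModel.PEPTIDE_LOCAL
    return cand, EnergyModel.PEPTIDE_LOCAL

def _move_receptor(model, cfg, lattice, rng):
    n = len(model.receptor)
    i = int(rng.integers(0, n))
    delta = rng.normal(scale=cfg.receptor_step, size=3)
    cand = _receptor_candidate(model)
    new_ca = snap_to_lattice(cand.receptor.ca[i] + delta, lattice)
    shift = new_ca - cand.receptor.ca[i]
    cand.receptor.ca[i] = new_ca
    cand.receptor.cb[i] += shift
    cand.receptor.sc[i] += shift
    if not _bonds_ok(cand.receptor.ca):
        return None, EnergyModel.RECEPTOR_LOCAL
    return cand, EnergyModel.RECEPTOR_LOCAL


_MOVES = {
    "translation": _move_translation,
    "rotation": _move_rotation,
    "kink": _move_kink,
    "crankshaft": _move_crankshaft,
    "end_flip": _move_end_flip,
    "receptor": _move_receptor,
}


def propose_move(state: ReplicaState, rng: np.random.Generator,
                 cfg: SimulationConfig | None = None,
                 lattice: LatticeConfig | None = None):
    """Draw a move type by its configured weight and apply it.

    Returns ``(candidate, affected_groups, move_name)``; ``candidate``
    is None when the move is geometrically infeasible (counted as a
    rejection by the caller).
    """
    cfg = cfg or SimulationConfig()
    lattice = lattice or LatticeConfig()
    names, w = cfg.move_weights.as_arrays()
    name = names[int(rng.choice(len(names), p=w))]
    cand, groups = _MOVES[name](state.model, cfg, lattice, rng)
    return cand, groups, name


# ---------------------------------------------------------------------------
# acceptance and exchange

def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis rule: accept with min(1, exp(-dE/T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def attempt_exchange(a: ReplicaState, b: ReplicaState,
                     rng: np.random.Generator) -> bool:
    """Attempt a temperature swap between ladder-adjacent replicas.

    Acceptance probability min(1, exp((1/Ta - 1/Tb) (Ea - Eb))) on the
    cached sampling energies; a success trades temperatures (and ladder
    positions), leaving configurations with their replica identities.
    """
    if abs(a.ladder_index - b.ladder_index) != 1:
        raise ValueError("replica exchange requires ladder-adjacent pairs")
    arg = (1.0 / a.temperature - 1.0 / b.temperature) * (a.energy - b.energy)
    accept = arg >= 0 or rng.random() < math.exp(arg)
    if accept:
        a.temperature, b.temperature = b.temperature, a.temperature
        a.ladder_index, b.ladder_index = b.ladder_index, a.ladder_index
    return accept


# ---------------------------------------------------------------------------
# main driver

def _snapshot_cycles(n_cycles: int, n_snapshots: int) -> np.ndarray:
    """Evenly spaced snapshot cycles in [1, n_cycles] (with repeats when
    there are more snapshots than cycles)."""
    if n_cycles <= 0:
        return np.zeros(n_snapshots, dtype=int)
    return np.linspace(1, n_cycles, n_snapshots).round().astype(int)


def run_remc(system: DockingSystem, restraints=(),
             config: SimulationConfig | None = None) -> Trajectory:
    """Run the replica-exchange docking simulation.

    One cycle attempts one move per mobile residue (peptide plus
    receptor).  Adjacent-pair exchanges alternate odd/even pairings
    every ``exchange_period`` cycles.  Snapshots are taken at evenly
    spaced cycles; the pool holds ``n_replicas x snapshots_per_replica``
    models with full energy breakdowns.  The run is a pure function of
    the seed.
    """
    config = config or SimulationConfig()
    emodel = EnergyModel(system.receptor, system.peptide_spec.names3,
                         system.params, restraints, system.peptide_spec)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicas + 2)
    exchange_rng = np.random.default_rng(seeds[-1])
    scatter_rng = np.random.default_rng(seeds[-2])

    ladder = config.temperature_ladder()
    states = []
    for r in range(config.n_replicas):
        peptide = scatter_peptide(system.receptor, system.peptide_spec,
                                  config.max_scatter_distance, scatter_rng,
                                  system.lattice, system.params,
                                  config.scatter_retries)
        model = ComplexModel(system.receptor.copy(), peptide,
                             replica_id=r, temperature=float(ladder[r]))
        comp = emodel.components(model)
        states.append(ReplicaState(
            model=model, temperature=float(ladder[r]), replica_id=r,
            rng_stream=np.random.default_rng(seeds[r]), ladder_index=r,
            energy=EnergyModel.sampling_from_components(comp),
            components=comp))

    snap_at = _snapshot_cycles(config.n_cycles,
                               config.snapshots_per_replica)
    snapshots: list[ComplexModel] = []
    model_id = 0

    def take_snapshot(state: ReplicaState, cycle: int):
        nonlocal model_id
        bd = emodel.breakdown(state.model)
        snap = state.model.copy()
        snap.energy = bd
        snap.model_id = model_id
        snap.replica_id = state.replica_id
        snap.cycle = cycle
        snap.temperature = state.temperature
        snapshots.append(snap)
        # resync the cached components against drift
        state.components = emodel.components(state.model)
        state.energy = EnergyModel.sampling_from_components(state.components)
        model_id += 1

    if config.n_cycles == 0:
        for st in states:
            for _ in range(config.snapshots_per_replica):
                take_snapshot(st, 0)
        return Trajectory(snapshots)

    n_mobile = len(system.receptor) + len(system.peptide_spec)
    exchange_parity = 0
    # the sampling shell is fixed by the *input* receptor surface
    ra0, _ = system.receptor.pseudoatoms()
    for cycle in range(1, config.n_cycles + 1):
        for st in states:
            for _ in range(n_mobile):
                cand, groups, _name = propose_move(st, st.rng_stream, config,
                                                   system.lattice)
                if cand is None:
                    continue
                # the search stays inside the scattering shell: reject
                # peptide moves that leave it (bounded-box sampling)
                if groups is not EnergyModel.RECEPTOR_LOCAL:
                    pa, _ = cand.peptide.pseudoatoms()
                    if cdist(pa, ra0).min() - SURFACE_RADIUS \
                            > config.max_scatter_distance:
                        continue
                d_e, new_comp = emodel.delta(st.components, cand, groups)
                if metropolis_accept(d_e, st.temperature, st.rng_stream):
                    st.model = cand
                    st.components = new_comp
                    st.energy += d_e

        if config.exchange_period > 0 and cycle % config.exchange_period == 0:
            by_ladder = sorted(states, key=lambda s: s.ladder_index)
            start = exchange_parity % 2
            for k in range(start, config.n_replicas - 1, 2):
                attempt_exchange(by_ladder[k], by_ladder[k + 1], exchange_rng)
            exchange_parity += 1

        for st in states:
            for _ in range(int(np.sum(snap_at == cycle))):
                take_snapshot(st, cycle)

    return Trajectory(snapshots)
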