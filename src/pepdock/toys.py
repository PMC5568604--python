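"""Synthetic receptor-peptide systems with known native poses.

Every downstream stage is testable without external structures: the
generator builds a compact lattice receptor with a concave surface
pocket lined by hydrophobic residues, lays a hydrophobic peptide into
the pocket, and records the native contacts.  Because the shipped
contact matrix rewards hydrophobic side-chain pairs, the native pose
sits in a genuine energy funnel (verified at construction against
random surface placements).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .cg import CGChain, ComplexModel, LatticeConfig, snap_to_lattice
from .energy import EnergyParams, pair_contact_energy, excluded_volume_energy
from .io import ContactSpec, PeptideSpec
from .remc import PEPTIDE_BOND, scatter_peptide
from .selection import ligand_rmsd, native_contacts

__all__ = ["ToyComplex", "make_toy_complex", "make_decoy_set",
           "write_fixture"]

POCKET_RESIDUES = ["ILE", "LEU", "PHE", "VAL", "MET"]
SURFACE_RESIDUES = ["SER", "GLU", "LYS", "ASN", "THR", "ASP", "GLN"]
PEPTIDE_PATTERN = "LFIVLM"  # hydrophobic peptide, cycled to length

# receptor CA may not come closer than this to any native peptide
# pseudoatom: keeps the native pose clash-free with ~2.2 A side centres
PEPTIDE_CLEARANCE = 5.5


@dataclass
class ToyComplex:
    receptor: CGChain
    native_peptide: CGChain
    native_contacts: list  # of ContactSpec
    pocket_center: np.ndarray
    peptide_spec: PeptideSpec = None
    seed: int | None = None

    @property
    def native_model(self) -> ComplexModel:
        return ComplexModel(self.receptor.copy(), self.native_peptide.copy())


def _lattice_bond_vectors(lattice: LatticeConfig) -> np.ndarray:
    """All lattice vectors whose length is a valid CA-CA bond."""
    kmax = int(np.ceil(4.3 / lattice.spacing))
    rng_ = np.arange(-kmax, kmax + 1)
    grid = np.stack(np.meshgrid(rng_, rng_, rng_, indexing="ij"), -1).reshape(-1, 3)
    vecs = grid * lattice.spacing
    norms = np.linalg.norm(vecs, axis=1)
    return vecs[(norms >= 3.4) & (norms <= 4.2)]


def _build_receptor_walk(n: int, forbidden_pts: np.ndarray, r_max: float,
                         lattice: LatticeConfig, rng,
                         min_sep: float = 4.2) -> np.ndarray | None:
    """Compact self-avoiding CA walk on the lattice avoiding the pocket."""
    bonds = _lattice_bond_vectors(lattice)

    def allowed(cand, placed):
        if np.linalg.norm(cand) > r_max:
            return False
        if cdist(cand[None], forbidden_pts).min() < PEPTIDE_CLEARANCE:
            return False
        if len(placed) > 1:
            prior = np.asarray(placed[:-1])
            if cdist(cand[None], prior).min() < min_sep:
                return False
        return True

    start = snap_to_lattice(np.array([-r_max * 0.4, 0.0, 0.0]), lattice)
    pts = [start]
    stuck = 0
    while len(pts) < n:
        cands = pts[-1] + bonds[rng.permutation(len(bonds))[:40]]
        # prefer steps that keep the globule compact
        order = np.argsort(np.linalg.norm(cands, axis=1)
                           + rng.uniform(0, 4.0, size=len(cands)))
        placed = False
        for idx in order:
            if allowed(cands[idx], pts):
                pts.append(cands[idx])
                placed = True
                break
        if not placed:
            # backtrack a few residues and retry
            stuck += 1
            if stuck > 50 * n:
                return None
            drop = min(len(pts) - 1, int(rng.integers(1, 4)))
            if drop > 0:
                del pts[-drop:]
            if not pts:
                pts = [start]
    return np.asarray(pts)


def _native_peptide(spec: PeptideSpec, pocket_center: np.ndarray,
                    lattice: LatticeConfig) -> CGChain:
    """Lay the peptide through the pocket along z, side centres facing
    the receptor interior (-x)."""
    L = len(spec)
    ca = np.zeros((L, 3))
    ca[:, 2] = (np.arange(L) - (L - 1) / 2.0) * PEPTIDE_BOND
    ca += pocket_center
    ca = snap_to_lattice(ca, lattice)
    u = np.array([-1.0, 0.0, 0.0])
    cb = ca + 1.1 * u
    sc = ca + 2.2 * u
    return CGChain(spec.names3, np.arange(1, L + 1), ca, cb, sc,
                   chain_id="P", role="peptide")


def _receptor_side_centers(ca: np.ndarray, hard_radius: float):
    """CB/SC along the local free-space direction, shrunk until the
    receptor is internally clash-free."""
    n = len(ca)
    centroid = ca.mean(axis=0)
    u = np.empty_like(ca)
    d_all = cdist(ca, ca)
    for i in range(n):
        near = (d_all[i] < 7.0) & (d_all[i] > 1e-9)
        if near.any():
            v = ca[i] - ca[near].mean(axis=0)
        else:
            v = ca[i] - centroid
        norm = np.linalg.norm(v)
        u[i] = v / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])

    cn = 0.5 * (ca[:-1] + ca[1:]) if n > 1 else np.empty((0, 3))
    cb_off = np.full(n, 1.1)
    sc_off = np.full(n, 2.2)
    for _ in range(30):
        cb = ca + cb_off[:, None] * u
        sc = ca + sc_off[:, None] * u
        pts = np.concatenate([ca, cb, sc, cn])
        owner = np.concatenate([np.tile(np.arange(n, dtype=float), 3),
                                np.arange(n - 1, dtype=float) + 0.5])
        d = cdist(pts, pts)
        sep = np.abs(owner[:, None] - owner[None, :])
        rows, cols = np.nonzero(np.triu((d < hard_radius) & (sep >= 2), 1))
        if len(rows) == 0:
            return cb, sc
        offenders = np.unique(np.floor(np.concatenate(
            [owner[rows], owner[cols]])).astype(int))
        for i in offenders:
            cb_off[i] *= 0.7
            sc_off[i] *= 0.7
            if 0 < sc_off[i] < 0.2:  # give up: collapse onto CA
                cb_off[i] = sc_off[i] = 0.0
    return ca + cb_off[:, None] * u, ca + sc_off[:, None] * u


def make_toy_complex(receptor_size: int = 40, peptide_length: int = 6,
                     pocket_depth: float = 4.0,
                     rng: np.random.Generator | int | None = None,
                     lattice: LatticeConfig | None = None,
                     params: EnergyParams | None = None,
                     max_rebuilds: int = 25,
                     decoy_patch: bool = True) -> ToyComplex:
    """Build a toy complex with a hydrophobic pocket and a known pose.

    The funnel guarantee is enforced at construction: the native pose's
    pairwise contact energy must be lower than at least 95 of 100 random
    surface placements, otherwise the build is retried with fresh
    randomness.

    ``decoy_patch`` additionally makes the surface opposite the pocket
    hydrophobic.  Real receptors offer competing attractive sites;
    without one, unguided docking on a toy this small almost always
    finds the single funnel and the default vs contact-driven comparison
    loses its discriminating power.
    """
    if receptor_size < 20:
        raise ValueError("receptor_size must be at least 20")
    if peptide_length < 3:
        raise ValueError("peptide_length must be at least 3")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    lattice = lattice or LatticeConfig()
    params = params or EnergyParams()

    seq = "".join(PEPTIDE_PATTERN[i % len(PEPTIDE_PATTERN)]
                  for i in range(peptide_length))
    spec = PeptideSpec(seq, ss_pref="C" * peptide_length)

    # receptor envelope radius from a typical packing volume per residue
    r_max = (3.0 * 115.0 * receptor_size / (4.0 * np.pi)) ** (1.0 / 3.0) + 2.0
    pocket_center = np.array([r_max - pocket_depth, 0.0, 0.0])

    last_err = "construction failed"
    for _attempt in range(max_rebuilds):
        peptide = _native_peptide(spec, pocket_center, lattice)
        ppts, _ = peptide.pseudoatoms()
        ca = _build_receptor_walk(receptor_size, ppts, r_max, lattice, rng)
        if ca is None:
            last_err = "receptor walk failed"
            continue

        # hydrophobic lining near the pocket, polar elsewhere; optionally
        # a competing hydrophobic patch on the opposite surface
        names = []
        dist_to_pocket = np.linalg.norm(ca - pocket_center, axis=1)
        decoy_center = -pocket_center
        dist_to_decoy = np.linalg.norm(ca - decoy_center, axis=1)
        for i in range(receptor_size):
            hydrophobic = dist_to_pocket[i] <= 9.0 or (
                decoy_patch and dist_to_decoy[i] <= 8.0)
            pool = POCKET_RESIDUES if hydrophobic else SURFACE_RESIDUES
            names.append(pool[int(rng.integers(len(pool)))])

        cb, sc = _receptor_side_centers(ca, params.hard_radius)
        receptor = CGChain(names, np.arange(1, receptor_size + 1), ca, cb, sc,
                           chain_id="A", role="receptor")

        native = ComplexModel(receptor, peptide)
        if excluded_volume_energy(native, params.hard_radius,
                                  params.ev_penalty) > 0:
            last_err = "native pose clashes with the receptor"
            continue
        # at least one true side-chain contact
        sc_d = cdist(receptor.sc, peptide.sc)
        if sc_d.min() > 5.0:
            last_err = "no SC-SC contact at 5 A in the native pose"
            continue
        contacts = native_contacts(receptor, peptide, cutoff=5.0)
        if not contacts:
            last_err = "no native contacts at 5 A"
            continue

        # funnel guarantee vs random surface placements
        e_native = pair_contact_energy(native, params.contact_matrix,
                                       params.r_on)
        worse = 0
        for _ in range(100):
            try:
                decoy_pep = scatter_peptide(receptor, spec, max_dist=5.0,
                                            rng=rng, lattice=lattice,
                                            params=params)
            except RuntimeError:
                worse += 1
                continue
            e = pair_contact_energy(ComplexModel(receptor, decoy_pep),
                                    params.contact_matrix, params.r_on)
            if e_native < e:
                worse += 1
        if worse < 95:
            last_err = f"funnel check failed ({worse}/100 placements worse)"
            continue

        return ToyComplex(receptor=receptor, native_peptide=peptide,
                          native_contacts=contacts,
                          pocket_center=pocket_center, peptide_spec=spec,
                          seed=seed)
    raise RuntimeError(f"make_toy_complex: {last_err} after "
                       f"{max_rebuilds} attempts")


def make_decoy_set(toy: ToyComplex, n: int, rmsd_targets,
                   rng: np.random.Generator | int | None = None,
                   jitter: float = 0.10, max_adjust: int = 25):
    """Perturbed peptide poses at prescribed ligand RMSDs from native.

    Targets are assigned round-robin over ``n`` decoys.  Each decoy is a
    rigid translation (random direction) plus small internal noise,
    rescaled until the achieved ligand RMSD is within 15% of the target
    (a zero target returns the native pose exactly).  Returns a list of
    ``(model, target, achieved, reached)`` tuples.
    """
    rmsd_targets = list(rmsd_targets)
    if n < len(rmsd_targets):
        raise ValueError("n must cover every RMSD target at least once")
    rng = np.random.default_rng(rng)
    native = toy.native_model
    # one displacement direction per target so each target forms a tight
    # bundle (a planted cluster), with small within-bundle noise
    directions = {}
    for t in rmsd_targets:
        u = rng.normal(size=3)
        directions[float(t)] = u / np.linalg.norm(u)
    out = []
    for i in range(n):
        target = float(rmsd_targets[i % len(rmsd_targets)])
        if target == 0.0:
            out.append((native.copy(), 0.0, 0.0, True))
            continue
        u = directions[target]
        noise = rng.normal(scale=jitter * target,
                           size=toy.native_peptide.ca.shape)
        scale = 1.0
        achieved = np.inf
        model = None
        reached = False
        for _ in range(max_adjust):
            cand = native.copy()
            shift = scale * target * u
            for arr in (cand.peptide.ca, cand.peptide.cb, cand.peptide.sc):
                arr += shift
            cand.peptide.ca += noise
            cand.peptide.cb += noise
            cand.peptide.sc += noise
            achieved = ligand_rmsd(cand, native)
            model = cand
            if abs(achieved - target) <= 0.15 * target:
                reached = True
                break
            scale *= target / max(achieved, 1e-9)
        out.append((model, target, achieved, reached))
    return out


def write_fixture(toy: ToyComplex, directory) -> dict:
    """Persist a toy complex: CG PDB, minimal all-atom PDB, JSON sidecar."""
    from .io import write_models_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cg_path = directory / "toy_cg.pdb"
    write_models_pdb([toy.native_model], cg_path)
    aa_path = directory / "toy_allatom.pdb"
    _write_minimal_allatom(toy, aa_path)
    sidecar = {
        "seed": toy.seed,
        "pocket_center": [float(x) for x in toy.pocket_center],
        "peptide_sequence": toy.peptide_spec.sequence,
        "ss_pref": toy.peptide_spec.ss_pref,
        "native_contacts": [
            {"receptor_chain": c.receptor_chain,
             "receptor_residue": c.receptor_residue,
             "peptide_residue": c.peptide_residue}
            for c in toy.native_contacts],
    }
    json_path = directory / "toy.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    return {"cg_pdb": cg_path, "allatom_pdb": aa_path, "json": json_path}


def _write_minimal_allatom(toy: ToyComplex, path) -> None:
    """Synthetic backbone+CB rendering of the toy (N/C placed along the
    trace, O off the C): enough structure to exercise all-atom readers,
    not real stereochemistry."""
    def chain_lines(chain: CGChain, chain_id, serial):
        lines = []
        n = len(chain)
        for i in range(n):
            prev_u = (chain.ca[i - 1] - chain.ca[i]) if i > 0 else \
                (chain.ca[i] - chain.ca[min(i + 1, n - 1)])
            next_u = (chain.ca[i + 1] - chain.ca[i]) if i < n - 1 else \
                (chain.ca[i] - chain.ca[max(i - 1, 0)])
            for v in (prev_u, next_u):
                nv = np.linalg.norm(v)
                if nv > 1e-9:
                    v /= nv
            atoms = [("N", chain.ca[i] + 1.45 * prev_u),
                     ("CA", chain.ca[i]),
                     ("C", chain.ca[i] + 1.52 * next_u),
                     ("O", chain.ca[i] + 1.52 * next_u
                      + np.array([0.0, 1.23, 0.0]))]
            if chain.names[i] != "GLY":
                atoms.append(("CB", chain.cb[i]))
            for name, xyz in atoms:
                lines.append(
                    f"ATOM  {serial:>5d}  {name:<3s}{chain.names[i]:>4s} "
                    f"{chain_id}{int(chain.indices[i]):>4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n")
                serial += 1
        lines.append(f"TER   {serial:>5d}      {chain.names[-1]:>3s} "
                     f"{chain_id}{int(chain.indices[-1]):>4d}\n")
        return lines, serial + 1

    with Path(path).open("w") as fh:
        serial = 1
        lines, serial = chain_lines(toy.receptor, "A", serial)
        fh.writelines(lines)
        lines, _ = chain_lines(toy.native_peptide, "P", serial)
        fh.writelines(lines)
        fh.write("END\n")
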