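"""Coarse-grained chain representation.

Each amino-acid residue is reduced to three interaction centres -- the
C-alpha (CA), the C-beta (CB) and a single side-chain centre (SC) -- plus
one pseudoatom per backbone bond (CN) placed at the geometric centre of
the virtual CA-CA bond.  CA positions may be restricted to a cubic
lattice; CB, SC and CN sit off-lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LatticeConfig",
    "CGResidue",
    "CGChain",
    "ComplexModel",
    "snap_to_lattice",
    "coarse_grain",
    "AtomicResidue",
]

#: residues ordered as in the shipped contact-matrix data file
AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# CA-CA virtual bond limits (Angstrom) enforced after lattice snapping
BOND_MIN = 3.3
BOND_MAX = 4.3
CHAIN_BREAK_DIST = 4.5


@dataclass(frozen=True)
class LatticeConfig:
    """Cubic lattice for CA positions.

    ``spacing`` is the lattice constant in Angstrom.  The conventional
    value for this family of models is 0.61 A; set ``enabled=False`` for
    continuous-space work.
    """

    spacing: float = 0.61
    enabled: bool = True

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")


@dataclass
class AtomicResidue:
    """Minimal all-atom residue: heavy-atom name -> coordinate map."""

    residue_index: int
    residue_name: str
    chain_id: str
    atoms: dict  # atom name -> (3,) float array

    def side_chain_atoms(self, include_cb: bool = False) -> dict:
        out = {}
        for name, xyz in self.atoms.items():
            if name in BACKBONE_ATOMS:
                continue
            if name == "CB" and not include_cb:
                continue
            if name.startswith("H"):
                continue
            out[name] = xyz
        return out


@dataclass
class CGResidue:
    """One coarse-grained residue (all coordinates in Angstrom)."""

    residue_index: int
    residue_name: str
    ca: np.ndarray
    cb: np.ndarray
    sc: np.ndarray
    chain_id: str = "A"


class CGChain:
    """Array-backed chain of coarse-grained residues.

    Coordinates are stored as ``(N, 3)`` float arrays (``ca``, ``cb``,
    ``sc``); ``bond_centers`` are derived midpoints of consecutive CA
    pairs, so the midpoint invariant holds by construction.
    """

    def __init__(self, names, indices, ca, cb, sc, chain_id="A",
                 role="receptor", chain_breaks=()):
        self.names = list(names)
        self.indices = np.asarray(indices, dtype=int)
        self.ca = np.atleast_2d(np.asarray(ca, dtype=float))
        self.cb = np.atleast_2d(np.asarray(cb, dtype=float))
        self.sc = np.atleast_2d(np.asarray(sc, dtype=float))
        self.chain_id = chain_id
        self.role = role
        self.chain_breaks = tuple(chain_breaks)
        n = len(self.names)
        if not (self.ca.shape == self.cb.shape == self.sc.shape == (n, 3)):
            raise ValueError("coordinate arrays must all be (N, 3)")
        if len(self.indices) != n:
            raise ValueError("indices length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def bond_centers(self) -> np.ndarray:
        """Midpoints of consecutive CA pairs, shape (N-1, 3)."""
        return 0.5 * (self.ca[:-1] + self.ca[1:])

    @property
    def residues(self) -> list:
        return [
            CGResidue(int(self.indices[i]), self.names[i],
                      self.ca[i].copy(), self.cb[i].copy(),
                      self.sc[i].copy(), self.chain_id)
            for i in range(len(self))
        ]

    @property
    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(n, "X") for n in self.names)

    def pseudoatoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All pseudoatoms (CA, CB, SC, CN) and their residue positions.

        CN pseudoatoms get half-integer positions so that a sequence
        separation test ``|pos_i - pos_j| >= 2`` treats them as sitting
        between their flanking residues.
        """
        n = len(self)
        coords = [self.ca, self.cb, self.sc]
        pos = [np.arange(n, dtype=float)] * 3
        if n > 1:
            coords.append(self.bond_centers)
            pos.append(np.arange(n - 1, dtype=float) + 0.5)
        return np.concatenate(coords), np.concatenate(pos)

    def copy(self) -> "CGChain":
        # hot path in the sampler: bypass __init__ validation and share
        # the immutable name/index metadata
        new = object.__new__(CGChain)
        new.names = self.names
        new.indices = self.indices
        new.ca = self.ca.copy()
        new.cb = self.cb.copy()
        new.sc = self.sc.copy()
        new.chain_id = self.chain_id
        new.role = self.role
        new.chain_breaks = self.chain_breaks
        return new

    def transformed(self, rotation=None, translation=None) -> "CGChain":
        """Rigidly transformed copy: x -> R x + t."""
        out = self.copy()
        for arr in (out.ca, out.cb, out.sc):
            if rotation is not None:
                arr[:] = arr @ np.asarray(rotation).T
            if translation is not None:
                arr += np.asarray(translation)
        return out


@dataclass
class ComplexModel:
    """A receptor+peptide snapshot with its energy breakdown."""

    receptor: CGChain
    peptide: CGChain
    energy: object = None  # EnergyBreakdown, filled by the energy model
    model_id: int = -1
    replica_id: int = -1
    cycle: int = -1
    temperature: float = float("nan")

    def copy(self) -> "ComplexModel":
        return ComplexModel(self.receptor.copy(), self.peptide.copy(),
                            self.energy, self.model_id, self.replica_id,
                            self.cycle, self.temperature)


def snap_to_lattice(coords, lattice: LatticeConfig) -> np.ndarray:
    """Snap coordinates to the nearest cubic-lattice node.

    Pass-through when the lattice is disabled.  Per-axis displacement is
    bounded by ``spacing / 2``.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate passed to snap_to_lattice")
    if not lattice.enabled:
        return coords.copy()
    return lattice.spacing * np.round(coords / lattice.spacing)


def _gly_fallback(ca: np.ndarray, i: int, n: int, all_ca: np.ndarray) -> np.ndarray:
    """Glycine CB/SC placement: 1 A from CA along the bisector normal of
    the CA(i-1)..CA(i+1) segment; terminal glycines keep SC at CA."""
    if i == 0 or i == n - 1:
        return ca.copy()
    mid = 0.5 * (all_ca[i - 1] + all_ca[i + 1])
    v = ca - mid
    norm = np.linalg.norm(v)
    if norm < 1e-9:  # colinear trace: no defined normal
        return ca.copy()
    return ca + v / norm


def coarse_grain(atomic_chain, lattice: LatticeConfig | None = None) -> CGChain:
    """Convert an ordered all-atom chain into the three-centre model.

    ``atomic_chain`` is a sequence of :class:`AtomicResidue`.  The SC
    centre is the centroid of side-chain heavy atoms beyond CB; when only
    CB exists (alanine) SC coincides with CB; glycine uses a CA-based
    fallback for both.  CA positions are snapped to the lattice when
    enabled.  A CA-CA gap above 4.5 A (before snapping) is flagged as a
    chain break and kept with a warning.
    """
    lattice = lattice or LatticeConfig()
    residues = list(atomic_chain)
    if not residues:
        raise ValueError("empty chain passed to coarse_grain")

    ca = []
    for res in residues:
        if "CA" not in res.atoms:
            raise ValueError(
                f"residue {res.residue_name} {res.chain_id}{res.residue_index} "
                "has no CA atom")
        ca.append(np.asarray(res.atoms["CA"], dtype=float))
    ca = np.asarray(ca)

    breaks = []
    if len(ca) > 1:
        gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        for i in np.nonzero(gaps > CHAIN_BREAK_DIST)[0]:
            breaks.append(int(i))
        if breaks:
            warnings.warn(
                f"chain {residues[0].chain_id}: {len(breaks)} CA-CA gap(s) "
                "above 4.5 A; keeping the chain with a break flag",
                stacklevel=2)

    ca_snapped = snap_to_lattice(ca, lattice)

    names, indices, cbs, scs = [], [], [], []
    n = len(residues)
    for i, res in enumerate(residues):
        names.append(res.residue_name)
        indices.append(res.residue_index)
        if res.residue_name == "GLY" or ("CB" not in res.atoms and
                                         not res.side_chain_atoms()):
            fb = _gly_fallback(ca_snapped[i], i, n, ca_snapped)
            cbs.append(fb)
            scs.append(fb.copy())
            continue
        if "CB" in res.atoms:
            cb = np.asarray(res.atoms["CB"], dtype=float)
        else:  # missing CB but side chain present: use its centroid
            cb = np.mean(list(res.side_chain_atoms(include_cb=True).values()),
                         axis=0)
        side = res.side_chain_atoms(include_cb=False)
        if side:
            sc = np.mean(list(side.values()), axis=0)
        else:  # alanine-like: the side chain is just CB
            sc = cb.copy()
        cbs.append(cb)
        scs.append(sc)

    return CGChain(names, indices, ca_snapped, np.asarray(cbs),
                   np.asarray(scs), chain_id=residues[0].chain_id,
                   chain_breaks=breaks)
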