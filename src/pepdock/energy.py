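"""Energy terms for coarse-grained docking.

The total conformational energy is a sum of pluggable surrogate terms
(excluded volume, pairwise side-chain contact energies, secondary-
structure bias), a flat-bottom restraint keeping the receptor near its
input conformation, and the soft side-chain contact restraint used to
drive contact-guided docking:

    E(D) = 0            if D <= D0
         = s * (D - D0) if D >  D0

where D is the SC-SC pseudoatom distance of the restrained pair.  The
contact restraint biases *sampling* only: the scoring energy used to
rank models excludes it.  All energies are in reduced units (k_B = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from .cg import AA3_TO_1, CGChain, ComplexModel

logger = logging.getLogger("pepdock")

__all__ = [
    "ContactRestraint",
    "EnergyBreakdown",
    "EnergyParams",
    "EnergyModel",
    "contact_restraint_energy",
    "receptor_restraint_energy",
    "excluded_volume_energy",
    "pair_contact_energy",
    "ss_bias_energy",
    "total_energy",
    "native_ca_distance_map",
    "load_contact_matrix",
    "default_contact_matrix",
]

# protocol defaults for the contact restraint
DEFAULT_D0 = 5.0  # Angstrom
DEFAULT_SLOPE = 1.0  # reduced energy per Angstrom


@dataclass(frozen=True)
class ContactRestraint:
    """One restrained receptor-peptide side-chain pair.

    ``receptor_pos`` / ``peptide_pos`` are 0-based positions into the
    respective chains (resolved from user-facing residue identifiers by
    :func:`pepdock.io.build_restraints`).
    """

    receptor_pos: int
    peptide_pos: int
    d0: float = DEFAULT_D0
    s: float = DEFAULT_SLOPE

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("D0 must be positive")
        if self.s < 0:
            raise ValueError("slope must be non-negative")


@dataclass
class EnergyBreakdown:
    excluded_volume: float = 0.0
    pair_contact: float = 0.0
    ss_bias: float = 0.0
    receptor_restraint: float = 0.0
    contact_restraint: float = 0.0

    @property
    def scoring_energy(self) -> float:
        """Conformational energy used for ranking (restraint excluded)."""
        return (self.excluded_volume + self.pair_contact + self.ss_bias
                + self.receptor_restraint)

    @property
    def sampling_energy(self) -> float:
        """Energy driving Monte Carlo acceptance (restraint included)."""
        return self.scoring_energy + self.contact_restraint


@dataclass
class EnergyParams:
    """Tunable parameters of the surrogate force field.

    hard_radius / ev_penalty: soft-core excluded volume -- each
        non-bonded pseudoatom pair closer than ``hard_radius`` costs
        ``ev_penalty``.
    r_on: SC-SC distance below which a pairwise contact energy applies.
    ss_weight: per-residue penalty for violating the secondary-structure
        preference.
    rr_tolerance / rr_weight: flat-bottom width and slope of the
        receptor near-native restraints.
    rr_max_native / rr_min_sep: which CA pairs of the input receptor are
        restrained (native distance <= 8 A, sequence separation >= 3).
    """

    hard_radius: float = 3.0
    ev_penalty: float = 5.0
    r_on: float = 6.0
    ss_weight: float = 0.5
    rr_tolerance: float = 1.0
    rr_weight: float = 1.0
    rr_max_native: float = 8.0
    rr_min_sep: int = 3
    contact_matrix: dict = field(default_factory=lambda: default_contact_matrix())


# ---------------------------------------------------------------------------
# contact matrix

def load_contact_matrix(path_or_buf) -> dict:
    """Read a 20x20 whitespace table with one-letter header row/column.

    Returns a dict mapping ('X', 'Y') residue-letter pairs to energies;
    the table must be symmetric.
    """
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep=r"\s+", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not np.allclose(df.values, df.values.T, atol=1e-9):
        raise ValueError("contact matrix must be symmetric")
    return {(a, b): float(df.loc[a, b]) for a in df.index for b in df.columns}


def default_contact_matrix() -> dict:
    """The shipped hydrophobicity-derived SC-SC contact matrix."""
    ref = resources.files("pepdock").joinpath("data/contact_matrix.tsv")
    with ref.open("r") as fh:
        return load_contact_matrix(fh)


# ---------------------------------------------------------------------------
# individual terms (reference implementations)

def contact_restraint_energy(D: float, D0: float = DEFAULT_D0,
                             s: float = DEFAULT_SLOPE) -> float:
    """Soft one-sided contact restraint: zero up to D0, slope s beyond."""
    D = float(D)
    if D < 0:
        raise ValueError("distance must be non-negative")
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if s < 0:
        raise ValueError("slope must be non-negative")
    return 0.0 if D <= D0 else s * (D - D0)


def native_ca_distance_map(receptor: CGChain, max_native: float = 8.0,
                           min_sep: int = 3) -> dict:
    """Native CA-CA distances to restrain: (i, j) -> Angstrom.

    Positions are 0-based into the receptor chain; pairs satisfy
    ``j - i >= min_sep`` and native distance ``<= max_native``.
    """
    d = cdist(receptor.ca, receptor.ca)
    n = len(receptor)
    out = {}
    for i in range(n):
        for j in range(i + min_sep, n):
            if d[i, j] <= max_native:
                out[(i, j)] = float(d[i, j])
    return out


def receptor_restraint_energy(model: ComplexModel, native_ca_distances: dict,
                              tolerance: float = 1.0,
                              weight: float = 1.0) -> float:
    """Flat-bottom restraints keeping the receptor near-native.

    Each restrained pair contributes ``weight * max(0, |d - d_nat| -
    tolerance)``; the unperturbed receptor scores exactly zero.
    """
    ca = model.receptor.ca
    n = len(model.receptor)
    e = 0.0
    for (i, j), d_nat in native_ca_distances.items():
        if i >= n or j >= n:
            raise KeyError(f"restrained pair ({i}, {j}) absent from model")
        d = float(np.linalg.norm(ca[i] - ca[j]))
        e += weight * max(0.0, abs(d - d_nat) - tolerance)
    return e


def excluded_volume_energy(model: ComplexModel, hard_radius: float = 3.0,
                           penalty: float = 5.0) -> float:
    """Soft-core overlap penalty over all non-bonded pseudoatom pairs."""
    if hard_radius <= 0:
        raise ValueError("hard_radius must be positive")
    e = 0.0
    chains = [model.receptor, model.peptide]
    tables = [c.pseudoatoms() for c in chains]
    for coords, pos in tables:  # intra-chain
        d = cdist(coords, coords)
        sep_ok = np.abs(pos[:, None] - pos[None, :]) >= 2
        pairs = np.triu(sep_ok & (d < hard_radius), 1)
        e += penalty * int(pairs.sum())
    (ra, _), (pa, _) = tables  # inter-chain: every pair counts
    e += penalty * int((cdist(ra, pa) < hard_radius).sum())
    return e


def _type_energy_matrix(names_a, names_b, matrix: dict) -> np.ndarray:
    """Per-pair energies by residue type; unknown types use the row mean."""
    letters = sorted({a for a, _ in matrix})
    row_mean = {a: np.mean([matrix[(a, b)] for b in letters]) for a in letters}
    grand_mean = float(np.mean(list(matrix.values())))

    def energy(na, nb):
        a = AA3_TO_1.get(na, "?")
        b = AA3_TO_1.get(nb, "?")
        if (a, b) in matrix:
            return matrix[(a, b)]
        logger.warning("unknown residue pair (%s, %s): using average energy",
                       na, nb)
        if a in row_mean:
            return row_mean[a]
        if b in row_mean:
            return row_mean[b]
        return grand_mean

    return np.array([[energy(na, nb) for nb in names_b] for na in names_a])


def pair_contact_energy(model: ComplexModel, contact_matrix: dict,
                        r_on: float = 6.0) -> float:
    """Knowledge-based SC-SC contact energies.

    Sums matrix energies over side-chain pairs closer than ``r_on``,
    inter-chain plus intra-chain with sequence separation >= 2.
    """
    e = 0.0
    for chain in (model.receptor, model.peptide):
        d = cdist(chain.sc, chain.sc)
        pos = np.arange(len(chain))
        sep_ok = np.abs(pos[:, None] - pos[None, :]) >= 2
        mask = np.triu(sep_ok & (d <= r_on), 1)
        if mask.any():
            em = _type_energy_matrix(chain.names, chain.names, contact_matrix)
            e += float(em[mask].sum())
    d = cdist(model.receptor.sc, model.peptide.sc)
    mask = d <= r_on
    if mask.any():
        em = _type_energy_matrix(model.receptor.names, model.peptide.names,
                                 contact_matrix)
        e += float(em[mask].sum())
    return e


def _pseudo_angles(ca: np.ndarray) -> np.ndarray:
    """Vertex angle (degrees) at each internal CA; NaN at the termini."""
    n = len(ca)
    ang = np.full(n, np.nan)
    if n < 3:
        return ang
    u = ca[:-2] - ca[1:-1]
    v = ca[2:] - ca[1:-1]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    ang[1:-1] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang


#: pseudo-angle windows for helix / extended preference
SS_BINS = {"H": (80.0, 105.0), "E": (105.0, 145.0)}


def ss_bias_energy(peptide: CGChain, spec, weight: float = 0.5) -> float:
    """Penalty for deviating from the per-residue H/E/C preference.

    A residue matches 'H' when its CA pseudo-angle falls in [80, 105]
    degrees, 'E' in [105, 145]; 'C' (and chain termini, which have no
    defined angle) always match.  Missing preference -> zero energy.
    """
    ss = getattr(spec, "ss_pref", None)
    if not ss:
        return 0.0
    if len(ss) != len(peptide):
        raise ValueError("ss preference length does not match the peptide")
    ang = _pseudo_angles(peptide.ca)
    e = 0.0
    for i, code in enumerate(ss):
        if code == "C" or np.isnan(ang[i]):
            continue
        lo, hi = SS_BINS[code]
        if not (lo <= ang[i] <= hi):
            e += weight
    return e


def total_energy(model: ComplexModel, restraints=(), params: EnergyParams | None = None,
                 native_ca_distances: dict | None = None,
                 peptide_spec=None) -> EnergyBreakdown:
    """Full energy breakdown of a complex model (reference path).

    The contact restraint is evaluated on SC-SC distances and kept out
    of the scoring energy.  ``native_ca_distances`` defaults to the map
    built from the model's own receptor (then the receptor-restraint
    term is zero by construction); pass the map built from the *input*
    receptor to restrain against it.
    """
    params = params or EnergyParams()
    if native_ca_distances is None:
        native_ca_distances = native_ca_distance_map(
            model.receptor, params.rr_max_native, params.rr_min_sep)
    bd = EnergyBreakdown(
        excluded_volume=excluded_volume_energy(
            model, params.hard_radius, params.ev_penalty),
        pair_contact=pair_contact_energy(
            model, params.contact_matrix, params.r_on),
        ss_bias=ss_bias_energy(model.peptide, peptide_spec, params.ss_weight),
        receptor_restraint=receptor_restraint_energy(
            model, native_ca_distances, params.rr_tolerance, params.rr_weight),
    )
    cr = 0.0
    for r in restraints:
        d = float(np.linalg.norm(model.receptor.sc[r.receptor_pos]
                                 - model.peptide.sc[r.peptide_pos]))
        cr += contact_restraint_energy(d, r.d0, r.s)
    bd.contact_restraint = cr
    return bd


# ---------------------------------------------------------------------------
# fast evaluator used by the sampler

class EnergyModel:
    """Precomputed evaluator bound to one receptor/peptide system.

    Splits each term into receptor-receptor, receptor-peptide and
    peptide-peptide blocks so the Monte Carlo loop can skip blocks that
    a move cannot change.  Results agree with :func:`total_energy` to
    numerical precision (exercised in the test suite).
    """

    def __init__(self, receptor: CGChain, peptide_names, params: EnergyParams,
                 restraints=(), peptide_spec=None):
        self.params = params
        self.restraints = tuple(restraints)
        self.peptide_spec = peptide_spec
        self.native_map = native_ca_distance_map(
            receptor, params.rr_max_native, params.rr_min_sep)
        self._rr_pairs = np.array(list(self.native_map.keys()), dtype=int).reshape(-1, 2)
        self._rr_dn = np.array(list(self.native_map.values()))
        # per-pair contact energies, fixed once residue types are known
        self._em_rr = _type_energy_matrix(receptor.names, receptor.names,
                                          params.contact_matrix)
        self._em_rp = _type_energy_matrix(receptor.names, peptide_names,
                                          params.contact_matrix)
        self._em_pp = _type_energy_matrix(peptide_names, peptide_names,
                                          params.contact_matrix)
        n_r, n_p = len(receptor), len(peptide_names)
        self._sep_rr = self._intra_sep_mask(n_r)
        self._sep_pp = self._intra_sep_mask(n_p)
        # pseudoatom separation masks (computed lazily: needs CN count)
        self._ev_intra_masks = {}

    @staticmethod
    def _intra_sep_mask(n: int) -> np.ndarray:
        pos = np.arange(n)
        return np.triu(np.abs(pos[:, None] - pos[None, :]) >= 2, 1)

    def _ev_intra(self, chain: CGChain) -> float:
        coords, pos = chain.pseudoatoms()
        key = (len(chain), chain.role)
        mask = self._ev_intra_masks.get(key)
        if mask is None:
            sep_ok = np.abs(pos[:, None] - pos[None, :]) >= 2
            mask = np.triu(sep_ok, 1)
            self._ev_intra_masks[key] = mask
        d2 = cdist(coords, coords)
        return self.params.ev_penalty * int((mask & (d2 < self.params.hard_radius)).sum())

    def ev_rr(self, model):  # receptor internal clashes
        return self._ev_intra(model.receptor)

    def ev_pp(self, model):
        return self._ev_intra(model.peptide)

    def ev_rp(self, model):
        ra, _ = model.receptor.pseudoatoms()
        pa, _ = model.peptide.pseudoatoms()
        n = int((cdist(ra, pa) < self.params.hard_radius).sum())
        return self.params.ev_penalty * n

    def pc_rr(self, model):
        d = cdist(model.receptor.sc, model.receptor.sc)
        mask = self._sep_rr & (d <= self.params.r_on)
        return float(self._em_rr[mask].sum())

    def pc_pp(self, model):
        d = cdist(model.peptide.sc, model.peptide.sc)
        mask = self._sep_pp & (d <= self.params.r_on)
        return float(self._em_pp[mask].sum())

    def pc_rp(self, model):
        d = cdist(model.receptor.sc, model.peptide.sc)
        return float(self._em_rp[d <= self.params.r_on].sum())

    def rr_term(self, model):
        if len(self._rr_pairs) == 0:
            return 0.0
        ca = model.receptor.ca
        d = np.linalg.norm(ca[self._rr_pairs[:, 0]] - ca[self._rr_pairs[:, 1]],
                           axis=1)
        excess = np.abs(d - self._rr_dn) - self.params.rr_tolerance
        return self.params.rr_weight * float(np.clip(excess, 0.0, None).sum())

    def ss_term(self, model):
        return ss_bias_energy(model.peptide, self.peptide_spec,
                              self.params.ss_weight)

    def cr_term(self, model):
        e = 0.0
        for r in self.restraints:
            d = float(np.linalg.norm(model.receptor.sc[r.receptor_pos]
                                     - model.peptide.sc[r.peptide_pos]))
            e += contact_restraint_energy(d, r.d0, r.s)
        return e

    def breakdown(self, model: ComplexModel) -> EnergyBreakdown:
        return EnergyBreakdown(
            excluded_volume=self.ev_rr(model) + self.ev_pp(model) + self.ev_rp(model),
            pair_contact=self.pc_rr(model) + self.pc_pp(model) + self.pc_rp(model),
            ss_bias=self.ss_term(model),
            receptor_restraint=self.rr_term(model),
            contact_restraint=self.cr_term(model),
        )

    def components(self, model: ComplexModel) -> dict:
        return {
            "ev_rr": self.ev_rr(model), "ev_pp": self.ev_pp(model),
            "ev_rp": self.ev_rp(model), "pc_rr": self.pc_rr(model),
            "pc_pp": self.pc_pp(model), "pc_rp": self.pc_rp(model),
            "ss": self.ss_term(model), "rr": self.rr_term(model),
            "cr": self.cr_term(model),
        }

    # component groups a move can change
    PEPTIDE_RIGID = ("ev_rp", "pc_rp", "cr")
    PEPTIDE_LOCAL = ("ev_rp", "ev_pp", "pc_rp", "pc_pp", "ss", "cr")
    RECEPTOR_LOCAL = ("ev_rp", "ev_rr", "pc_rp", "pc_rr", "rr", "cr")

    def _component_fn(self, name):
        return {"ss": self.ss_term, "rr": self.rr_term,
                "cr": self.cr_term}.get(name) or getattr(self, name)

    def delta(self, old_comp: dict, candidate: ComplexModel,
              groups: tuple) -> tuple[float, dict]:
        """Sampling-energy change when only ``groups`` may differ."""
        new_comp = dict(old_comp)
        for g in groups:
            new_comp[g] = self._component_fn(g)(candidate)
        d = sum(new_comp[g] - old_comp[g] for g in groups)
        return d, new_comp

    @staticmethod
    def sampling_from_components(comp: dict) -> float:
        return sum(comp.values())

    @staticmethod
    def scoring_from_components(comp: dict) -> float:
        return sum(v for k, v in comp.items() if k != "cr")
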