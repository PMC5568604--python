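"""Reading and writing of structures and user inputs.

PDB reading goes through Bio.PDB; writing of coarse-grained models uses
plain fixed-width ATOM records (pseudoatoms named CA, CB, SC and CN for
the backbone bond centre) in multi-MODEL files so a trajectory or a
ranked model set round-trips through standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .cg import AA1_TO_3, AtomicResidue, CGChain, ComplexModel

__all__ = [
    "PeptideSpec",
    "ContactSpec",
    "read_receptor_pdb",
    "read_models_pdb",
    "write_models_pdb",
    "parse_contacts",
    "build_restraints",
    "write_ranking_tsv",
    "write_trajectory_tsv",
]


@dataclass(frozen=True)
class PeptideSpec:
    """Peptide to dock: one-letter sequence plus optional H/E/C
    per-residue secondary-structure preference."""

    sequence: str
    ss_pref: str | None = None

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise ValueError("peptide sequence must have at least 3 residues")
        bad = set(self.sequence) - set(AA1_TO_3)
        if bad:
            raise ValueError(f"unknown amino-acid letters: {sorted(bad)}")
        if self.ss_pref is not None:
            if len(self.ss_pref) != len(self.sequence):
                raise ValueError("ss preference length must match the sequence")
            if set(self.ss_pref) - set("HEC"):
                raise ValueError("ss preference must use only H, E, C")

    def __len__(self):
        return len(self.sequence)

    @property
    def names3(self) -> list[str]:
        return [AA1_TO_3[a] for a in self.sequence]


@dataclass(frozen=True)
class ContactSpec:
    """One receptor residue <-> peptide residue contact.

    The receptor residue is addressed by (chain id, author residue
    number); the peptide residue by its 1-based sequence position.
    """

    receptor_chain: str
    receptor_residue: int
    peptide_residue: int
    d0: float | None = None  # per-contact restraint overrides
    s: float | None = None

    def __post_init__(self):
        if self.peptide_residue < 1:
            raise ValueError("peptide residue index is 1-based and positive")
        if self.receptor_residue < 1:
            raise ValueError("receptor residue index must be positive")
        if self.d0 is not None and self.d0 <= 0:
            raise ValueError("D0 override must be positive")
        if self.s is not None and self.s < 0:
            raise ValueError("slope override must be non-negative")


# ---------------------------------------------------------------------------
# PDB reading

def _pick_altloc(atom):
    """Collapse a disordered atom to altloc A (or the first altloc)."""
    if atom.is_disordered():
        ids = sorted(atom.disordered_get_id_list())
        return atom.disordered_get("A" if "A" in ids else ids[0])
    return atom


def read_receptor_pdb(path, chain: str | None = None,
                      keep_het: tuple = ()) -> dict:
    """Parse a PDB file into {chain_id: [AtomicResidue, ...]}.

    Waters and HETATM records are skipped unless whitelisted via
    ``keep_het``; for disordered atoms altloc A (or the first altloc) is
    kept; an insertion code is appended to the residue key.  Only the
    first MODEL of multi-model files is read.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no models found in {path}") from None

    chains = {}
    for ch in model:
        residues = []
        for res in ch:
            hetflag, resseq, icode = res.get_id()
            if hetflag != " " and res.get_resname() not in keep_het:
                continue  # waters and non-whitelisted HETATM
            atoms = {}
            for atom in res:  # packed list: one entry per atom name
                picked = _pick_altloc(atom)
                atoms[picked.get_name()] = np.asarray(picked.get_coord(),
                                                      dtype=float)
            residues.append(AtomicResidue(
                residue_index=int(resseq),
                residue_name=res.get_resname(),
                chain_id=ch.id,
                atoms=atoms))
        if residues:
            chains[ch.id] = residues

    if not chains:
        raise ValueError(f"no protein chains parsed from {path}")
    if chain is not None:
        if chain not in chains or not chains[chain]:
            raise ValueError(f"chain {chain!r} empty or absent in {path}")
        return {chain: chains[chain]}
    return chains


def _cg_chain_from_atomic(residues: list[AtomicResidue], role: str) -> CGChain:
    """Rebuild a CGChain from pseudoatom records (CA/CB/SC)."""
    names, indices, ca, cb, sc = [], [], [], [], []
    for res in residues:
        if "CA" not in res.atoms:
            raise ValueError(f"pseudoatom residue {res.residue_index} lacks CA")
        names.append(res.residue_name)
        indices.append(res.residue_index)
        ca.append(res.atoms["CA"])
        cb.append(res.atoms.get("CB", res.atoms["CA"]))
        sc.append(res.atoms.get("SC", res.atoms.get("CB", res.atoms["CA"])))
    return CGChain(names, indices, np.asarray(ca), np.asarray(cb),
                   np.asarray(sc), chain_id=residues[0].chain_id, role=role)


def read_models_pdb(path, receptor_chain: str = "R",
                    peptide_chain: str = "P") -> list[ComplexModel]:
    """Read a multi-MODEL coarse-grained PDB written by write_models_pdb."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))
    models = []
    for i, model in enumerate(structure.get_models()):
        chains = {}
        for ch in model:
            residues = []
            for res in ch:
                atoms = {a.get_name(): np.asarray(a.get_coord(), dtype=float)
                         for a in res.get_unpacked_list()}
                residues.append(AtomicResidue(int(res.get_id()[1]),
                                              res.get_resname(), ch.id, atoms))
            chains[ch.id] = residues
        if receptor_chain not in chains or peptide_chain not in chains:
            raise ValueError(
                f"model {i} lacks chain {receptor_chain!r} or {peptide_chain!r}")
        models.append(ComplexModel(
            receptor=_cg_chain_from_atomic(chains[receptor_chain], "receptor"),
            peptide=_cg_chain_from_atomic(chains[peptide_chain], "peptide"),
            model_id=i))
    if not models:
        raise ValueError(f"no models found in {path}")
    return models


# ---------------------------------------------------------------------------
# PDB writing

def _atom_record(serial, name, resname, chain_id, resseq, xyz):
    # PDB v3.3 fixed-width ATOM record; pseudoatom names are left-padded
    # to the element column convention used for CA.
    return (f"ATOM  {serial:>5d}  {name:<3s}{resname:>4s} {chain_id}"
            f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00\n")


def _write_cg_chain(fh, chain: CGChain, chain_id: str, serial: int) -> int:
    for i in range(len(chain)):
        resname = chain.names[i]
        resseq = int(chain.indices[i])
        for name, xyz in (("CA", chain.ca[i]), ("CB", chain.cb[i]),
                          ("SC", chain.sc[i])):
            fh.write(_atom_record(serial, name, resname, chain_id, resseq, xyz))
            serial += 1
        if i < len(chain) - 1:
            fh.write(_atom_record(serial, "CN", resname, chain_id, resseq,
                                  chain.bond_centers[i]))
            serial += 1
    fh.write(f"TER   {serial:>5d}      {chain.names[-1]:>3s} {chain_id}"
             f"{int(chain.indices[-1]):>4d}\n")
    return serial + 1


def write_models_pdb(models, path, receptor_chain: str = "R",
                     peptide_chain: str = "P") -> None:
    """Write complex models as a multi-MODEL pseudoatom PDB file."""
    models = list(models)
    if not models:
        raise ValueError("no models to write")
    path = Path(path)
    with path.open("w") as fh:
        for k, m in enumerate(models, start=1):
            fh.write(f"MODEL     {k:>4d}\n")
            serial = 1
            serial = _write_cg_chain(fh, m.receptor, receptor_chain, serial)
            _write_cg_chain(fh, m.peptide, peptide_chain, serial)
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# contact lists and reports

def parse_contacts(source, peptide: PeptideSpec,
                   receptor: CGChain | None = None) -> list[ContactSpec]:
    """Parse a contact table: ``chain resid pep_index`` per row.

    Accepts a path, file object or string; '#' comments and blank lines
    are skipped; commas are treated as whitespace.  Rows may carry two
    trailing numbers (per-contact D0 and slope overrides) which are
    validated here and consumed by :func:`build_restraints`.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source and Path(source).is_file():
        text = Path(source).read_text()
    elif isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)

    specs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].replace(",", " ").strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (3, 5):
            raise ValueError(f"contact row {lineno}: expected 3 or 5 fields, "
                             f"got {len(fields)} in {raw!r}")
        chain_id = fields[0]
        try:
            resid = int(fields[1])
            pep_idx = int(fields[2])
            overrides = tuple(float(x) for x in fields[3:])
        except ValueError as exc:
            raise ValueError(f"contact row {lineno}: {exc}") from None
        if pep_idx < 1 or pep_idx > len(peptide):
            raise ValueError(
                f"contact row {lineno}: peptide index {pep_idx} out of range "
                f"for a {len(peptide)}-residue peptide")
        try:
            spec = ContactSpec(chain_id, resid, pep_idx,
                               d0=overrides[0] if overrides else None,
                               s=overrides[1] if overrides else None)
        except ValueError as exc:
            raise ValueError(f"contact row {lineno}: {exc}") from None
        if receptor is not None:
            _resolve_receptor_pos(receptor, spec, lineno)
        specs.append(spec)
    return specs


def _resolve_receptor_pos(receptor: CGChain, spec: ContactSpec,
                          row: int | None = None) -> int:
    if receptor.chain_id != spec.receptor_chain:
        raise ValueError(
            f"contact{'' if row is None else f' row {row}'}: receptor chain "
            f"{spec.receptor_chain!r} does not match parsed chain "
            f"{receptor.chain_id!r}")
    hits = np.nonzero(receptor.indices == spec.receptor_residue)[0]
    if len(hits) == 0:
        raise ValueError(
            f"contact{'' if row is None else f' row {row}'}: receptor residue "
            f"{spec.receptor_residue} absent from the structure")
    return int(hits[0])


def build_restraints(receptor: CGChain, contacts, d0: float = 5.0,
                     s: float = 1.0):
    """Resolve ContactSpecs into ContactRestraints (0-based positions)."""
    from .energy import ContactRestraint

    out = []
    for c in contacts:
        pos = _resolve_receptor_pos(receptor, c)
        out.append(ContactRestraint(
            receptor_pos=pos,
            peptide_pos=c.peptide_residue - 1,
            d0=c.d0 if c.d0 is not None else d0,
            s=c.s if c.s is not None else s))
    return out


def write_ranking_tsv(report, models_by_id: dict, path) -> None:
    """Ranking table: rank, cluster_size, density, energy, medoid_model_id."""
    import pandas as pd

    rows = []
    for rank, cluster in enumerate(report.ranked_clusters(), start=1):
        medoid = models_by_id[cluster.medoid_id]
        rows.append({
            "rank": rank,
            "cluster_size": len(cluster.member_ids),
            "density": cluster.density,
            "energy": medoid.energy.scoring_energy,
            "medoid_model_id": cluster.medoid_id,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def write_trajectory_tsv(trajectory, path) -> None:
    """Sidecar table with one row per snapshot and its energy terms."""
    import pandas as pd

    rows = []
    for m in trajectory.snapshots:
        rows.append({
            "model_id": m.model_id, "replica": m.replica_id,
            "cycle": m.cycle, "temperature": m.temperature,
            "excluded_volume": m.energy.excluded_volume,
            "pair_contact": m.energy.pair_contact,
            "ss_bias": m.energy.ss_bias,
            "receptor_restraint": m.energy.receptor_restraint,
            "contact_restraint": m.energy.contact_restraint,
            "scoring_energy": m.energy.scoring_energy,
            "sampling_energy": m.energy.sampling_energy,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
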