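"""Protein–DNA complex structures and DNA-contact shells.

The mutation-design workflow starts from the set of protein residues close
to the DNA duplex: residues within 6 Å of the DNA are generally the ones
that matter for the polymerase/DNA interaction, so they seed the candidate
list.  This module parses complex structures (PDB or mmCIF), classifies
chains as protein or nucleic from residue-name vocabulary, and computes
minimum heavy-atom residue–DNA distances and the resulting contact shell.

Conventions
-----------
* Distances use heavy atoms only; hydrogens are ignored so that structures
  with and without explicit hydrogens give identical shells.
* The cutoff comparison is inclusive (``min_dist <= cutoff``).
* For disordered atoms the highest-occupancy conformer is kept, ties broken
  alphabetically by altloc id.
* Waters are excluded at parse time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, ParseError, ResidueLookupError, RoleError

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
NUCLEIC_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U"}
WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass(frozen=True)
class Atom:
    chain: str
    resi: int
    resname: str
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class StructureModel:
    """Atoms grouped into residues and chains, with protein/nucleic roles."""

    atoms: list[Atom]
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chain_roles:
            self.chain_roles = _assign_roles(self.atoms)
        coords = np.array([a.coord for a in self.atoms], dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ContractError("non-finite coordinates in structure")
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain)
            if prev is not None and a.resi < prev:
                raise ContractError(
                    f"residue indices not increasing in chain {a.chain}"
                )
            last[a.chain] = a.resi

    # -- convenience views ------------------------------------------------
    def chains(self, role: str | None = None) -> list[str]:
        ids = sorted({a.chain for a in self.atoms})
        if role is None:
            return ids
        return [c for c in ids if self.chain_roles.get(c) == role]

    def residues(self, chain: str) -> list[tuple[int, str]]:
        seen: dict[int, str] = {}
        for a in self.atoms:
            if a.chain == chain:
                seen.setdefault(a.resi, a.resname)
        return sorted(seen.items())

    def residue_atoms(self, chain: str, resi: int, heavy_only: bool = True) -> list[Atom]:
        out = [
            a for a in self.atoms
            if a.chain == chain and a.resi == resi and (a.is_heavy or not heavy_only)
        ]
        return out

    def chain_coords(self, chains: set[str], heavy_only: bool = True) -> np.ndarray:
        sel = [
            a.coord for a in self.atoms
            if a.chain in chains and (a.is_heavy or not heavy_only)
        ]
        return np.array(sel, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            Atom(a.chain, a.resi, a.resname, a.name, a.element,
                 tuple(R @ np.asarray(a.coord) + t))
            for a in self.atoms
        ]
        return StructureModel(atoms, dict(self.chain_roles))


@dataclass
class ContactShell:
    """Protein residues within ``cutoff`` Å of any DNA heavy atom."""

    entries: list[tuple[str, int, str, float]]  # (chain, resi, resname, min_dist)
    cutoff: float

    @property
    def positions(self) -> list[int]:
        return [e[1] for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["chain", "resi", "resn", "min_dist_A"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff: float = float("nan")) -> "ContactShell":
        df = pd.read_csv(path, sep="\t")
        entries = [
            (str(r.chain), int(r.resi), str(r.resn), float(r.min_dist_A))
            for r in df.itertuples()
        ]
        return cls(entries, cutoff)


def _classify_resname(resname: str) -> str:
    if resname in PROTEIN_RESNAMES:
        return "protein"
    if resname in NUCLEIC_RESNAMES:
        return "nucleic"
    return "other"


def _assign_roles(atoms: list[Atom]) -> dict[str, str]:
    """Chain role by majority vote over its residues; ties fall to 'other'."""
    per_chain: dict[str, dict[str, set[int]]] = {}
    for a in atoms:
        per_chain.setdefault(a.chain, {}).setdefault(
            _classify_resname(a.resname), set()
        ).add(a.resi)
    roles = {}
    for chain, groups in per_chain.items():
        counts = {role: len(resis) for role, resis in groups.items()}
        best = max(counts.values())
        winners = sorted(r for r, c in counts.items() if c == best)
        roles[chain] = winners[0] if len(winners) == 1 else "other"
    return roles


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a protein–DNA complex from a PDB or mmCIF file.

    Waters are dropped; for disordered atoms the highest-occupancy altloc is
    kept (ties alphabetical).  Chain roles are assigned from residue names:
    the 20 standard amino acids mark protein chains, DA/DC/DG/DT (and ribo
    variants) mark nucleic chains, anything else is ``other``.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ContractError(f"unknown structure format {format!r}")
    parser = PDBParser(QUIET=True) if format == "pdb" else MMCIFParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises several concrete types
        raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise ParseError(f"no structure models found in {path}")
    atoms: list[Atom] = []
    model = models[0]
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in WATER_RESNAMES:
                continue
            resi = residue.get_id()[1]
            for atom in residue:
                if atom.is_disordered():
                    children = atom.disordered_get_list()
                    atom = sorted(
                        children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc())
                    )[0]
                element = (atom.element or "").strip() or atom.get_name()[0]
                atoms.append(
                    Atom(
                        chain=chain.get_id().strip() or "A",
                        resi=int(resi),
                        resname=resname,
                        name=atom.get_name().strip(),
                        element=element,
                        # PDB/mmCIF text carries 3 decimals; rounding removes
                        # the parser's float32 representation error
                        coord=tuple(round(float(x), 3) for x in atom.get_coord()),
                    )
                )
    if not atoms:
        raise ParseError(f"no atoms read from {path}")
    return StructureModel(atoms)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB text (round-trips through :func:`read_structure`)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("model")
    builder.init_model(0)
    serial = 1
    current_chain = None
    current_res = None
    builder.init_seg("    ")
    for a in model.atoms:
        if a.chain != current_chain:
            builder.init_chain(a.chain)
            current_chain = a.chain
            current_res = None
        if a.resi != current_res:
            builder.init_residue(a.resname, " ", a.resi, " ")
            current_res = a.resi
        builder.init_atom(
            a.name,
            np.asarray(a.coord, dtype=float),
            0.0,
            1.0,
            " ",
            a.name.center(4) if len(a.name) < 4 else a.name,
            serial,
            element=a.element,
        )
        serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def min_residue_distance(
    model: StructureModel,
    residue: tuple[str, int],
    target_chains: set[str],
) -> float:
    """Minimum heavy-atom distance from one residue to a set of chains."""
    if not target_chains:
        raise ContractError("target chain set is empty")
    chain, resi = residue
    res_atoms = model.residue_atoms(chain, resi)
    if not res_atoms:
        raise ResidueLookupError(f"residue {chain}:{resi} not found")
    targets = model.chain_coords(set(target_chains))
    if targets.size == 0:
        raise ContractError(f"no heavy atoms in target chains {sorted(target_chains)}")
    source = np.array([a.coord for a in res_atoms], dtype=float)
    diff = source[:, None, :] - targets[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def contact_shell(model: StructureModel, cutoff: float = 6.0,
                  numbering: dict[int, int] | None = None) -> ContactShell:
    """Protein residues whose min heavy-atom distance to DNA is ≤ ``cutoff``.

    ``numbering`` optionally maps structure residue numbers onto reference
    sequence coordinates (1-based); the identity map is used by default.
    """
    protein_chains = model.chains("protein")
    nucleic_chains = model.chains("nucleic")
    if not protein_chains:
        raise RoleError("structure has no protein chain")
    if not nucleic_chains:
        raise RoleError("structure has no nucleic (DNA) chain")
    dna = set(nucleic_chains)
    entries = []
    for chain in protein_chains:
        for resi, resname in model.residues(chain):
            d = min_residue_distance(model, (chain, resi), dna)
            if d <= cutoff:
                ref_pos = numbering.get(resi, resi) if numbering else resi
                entries.append((chain, ref_pos, resname, d))
    entries.sort(key=lambda e: (e[0], e[1]))
    return ContactShell(entries, cutoff)
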