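"""Surrogate protein–DNA binding-energy scoring and ΔΔG bookkeeping.

Binding free energies are decomposed MM-PBSA-style,

    ΔG_bind = E_elec + E_vdW + G_polar_solv + G_nonpolar_solv,

with the entropic −TΔS term identically zero (it is ignored, as is common
when ranking closely related variants).  The scorer here is a deterministic
single-conformation molecular-mechanics surrogate, not a Poisson–Boltzmann
ensemble average: absolute magnitudes are not comparable to MD/PB results,
but the per-chain bookkeeping, the mutant − wild-type aggregation, and the
ranking logic are exact and are what this module exists to test.

Functional form (pair sums over protein × DNA heavy atoms within a 12 Å
cutoff):

* electrostatics with a distance-dependent dielectric ε(r) = ε₀·r, giving
  E_elec = Σ k·q_i·q_j / (ε₀·r²) with k = 332.06 kcal·Å/(mol·e²);
* Lennard-Jones 12-6 with per-element σ/ε and Lorentz–Berthelot mixing;
* polar solvation 0 by default — a strategy seam (any callable returning an
  :class:`EnergyDecomposition`) lets users plug in an external PB solver;
* nonpolar solvation γ × a buried-contact-area surrogate, off by default.

Charges are integer formal charges applied at carrier atoms: Asp/Glu −1 and
Lys/Arg +1 at Cβ (Cα for Gly), His neutral, and −1 per nucleotide at the
backbone phosphate P atom.  The table ships as a plain-text file so it is
versioned with the package.

The duplex strands are labeled P (primer, the strand being extended) and T
(template); every variant is scored against each strand separately and the
difference column ΔΔG = Σ_chain (ΔG_mut − ΔG_wt) ranks the designs —
negative means strengthened binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .design import MutationSpec
from .errors import ContractError, ParameterizationError, RoleError, ValidationError
from .structure import AA1_TO_3, Atom, StructureModel

COULOMB_K = 332.06  # kcal·Å/(mol·e²)
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "CB"}


@dataclass
class ForceField:
    """Residue formal charges, per-element LJ parameters, and constants."""

    residue_charges: dict[str, float]
    element_lj: dict[str, tuple[float, float]]  # element -> (sigma, epsilon)
    eps0: float = 4.0
    cutoff: float = 12.0
    gamma: float = 0.0
    contact_radius: float = 4.5  # Å, for the buried-area surrogate

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceField":
        charges: dict[str, float] = {}
        lj: dict[str, tuple[float, float]] = {}
        consts: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            kind = parts[0]
            if kind == "charge":
                charges[parts[1]] = float(parts[2])
            elif kind == "lj":
                lj[parts[1]] = (float(parts[2]), float(parts[3]))
            elif kind == "const":
                consts[parts[1]] = float(parts[2])
            else:
                raise ParameterizationError(f"unknown parameter line: {raw!r}")
        return cls(
            charges,
            lj,
            eps0=consts.get("eps0", 4.0),
            cutoff=consts.get("cutoff", 12.0),
            gamma=consts.get("gamma", 0.0),
        )

    @classmethod
    def default(cls) -> "ForceField":
        with resources.as_file(
            resources.files("polbind.data").joinpath("forcefield.txt")
        ) as p:
            return cls.from_file(p)


@dataclass
class EnergyDecomposition:
    """Per-component interaction energy, kcal/mol; −TΔS is identically 0."""

    e_elec: float
    e_vdw: float
    g_polar: float = 0.0
    g_nonpolar: float = 0.0
    chain: str = "complex"

    @property
    def total(self) -> float:
        return self.e_elec + self.e_vdw + self.g_polar + self.g_nonpolar


@dataclass
class DdgRecord:
    """Mutant − wild-type binding-energy difference, summed over P and T."""

    label: str
    wt: dict[str, float]       # chain -> ΔG_bind
    mut: dict[str, float]
    ddg_total: float = field(init=False)

    def __post_init__(self) -> None:
        for chains in (self.wt, self.mut):
            missing = {"P", "T"} - set(chains)
            if missing:
                raise ContractError(f"per-chain ΔG missing chain(s) {sorted(missing)}")
        self.ddg_total = sum(self.mut[c] - self.wt[c] for c in ("P", "T"))


# A scorer maps (model, protein chains, dna chain) to an EnergyDecomposition.
# interaction_energy below is the default; an external PB solver can be
# wired in through this seam.
Scorer = Callable[[StructureModel, set, str], EnergyDecomposition]


def _carrier_charges(model: StructureModel, chains: set[str],
                     ff: ForceField) -> tuple[list[Atom], np.ndarray]:
    """Heavy atoms of ``chains`` with their formal charges.

    The residue's formal charge sits on its carrier atom: Cβ for amino acids
    (Cα for glycine, or when no Cβ is present), the phosphate P for
    nucleotides.  All other atoms carry zero charge.
    """
    atoms = [a for a in model.atoms if a.chain in chains and a.is_heavy]
    charges = np.zeros(len(atoms))
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(atoms):
        by_residue.setdefault((a.chain, a.resi), []).append(i)
    for (chain, resi), idxs in by_residue.items():
        resname = atoms[idxs[0]].resname
        if resname not in ff.residue_charges:
            raise ParameterizationError(
                f"no charge parameter for residue {resname} ({chain}:{resi})"
            )
        q = ff.residue_charges[resname]
        if q == 0:
            continue
        names = {atoms[i].name: i for i in idxs}
        role = model.chain_roles.get(chain)
        if role == "nucleic":
            carrier = names.get("P")
        else:
            carrier = names.get("CB", names.get("CA"))
        if carrier is None:
            raise ParameterizationError(
                f"no charge-carrier atom in residue {resname} {chain}:{resi}"
            )
        charges[carrier] = q
    return atoms, charges


def _lj_params(atoms: list[Atom], ff: ForceField) -> tuple[np.ndarray, np.ndarray]:
    sigma = np.empty(len(atoms))
    eps = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in ff.element_lj:
            raise ParameterizationError(
                f"no LJ parameters for element {el} (atom {a.name} in {a.resname})"
            )
        sigma[i], eps[i] = ff.element_lj[el]
    return sigma, eps


def interaction_energy(
    model: StructureModel,
    protein_chains: set[str],
    dna_chains: set[str] | str,
    ff: ForceField | None = None,
    chain_label: str = "complex",
) -> EnergyDecomposition:
    """Protein–DNA interaction energy for one protein/strand pairing.

    Pair sums run over protein × DNA heavy-atom pairs within the cutoff
    (default 12 Å); beyond it the energy is exactly zero.
    """
    ff = ff or ForceField.default()
    if isinstance(dna_chains, str):
        dna_chains = {dna_chains}
    protein_chains = set(protein_chains)
    if protein_chains & dna_chains:
        raise ContractError(
            f"protein and DNA chain sets overlap: {sorted(protein_chains & dna_chains)}"
        )
    p_atoms, p_q = _carrier_charges(model, protein_chains, ff)
    d_atoms, d_q = _carrier_charges(model, dna_chains, ff)
    if not p_atoms or not d_atoms:
        raise ContractError("empty protein or DNA atom selection")
    p_xyz = np.array([a.coord for a in p_atoms])
    d_xyz = np.array([a.coord for a in d_atoms])
    r = np.sqrt(((p_xyz[:, None, :] - d_xyz[None, :, :]) ** 2).sum(axis=2))
    within = r <= ff.cutoff
    if not within.any():
        return EnergyDecomposition(0.0, 0.0, 0.0, 0.0, chain_label)

    # electrostatics with distance-dependent dielectric eps(r) = eps0 * r
    qq = np.outer(p_q, d_q)
    with np.errstate(divide="ignore", invalid="ignore"):
        elec = np.where(within, COULOMB_K * qq / (ff.eps0 * r ** 2), 0.0)
    e_elec = float(elec.sum())

    p_sig, p_eps = _lj_params(p_atoms, ff)
    d_sig, d_eps = _lj_params(d_atoms, ff)
    sig_ij = 0.5 * (p_sig[:, None] + d_sig[None, :])
    eps_ij = np.sqrt(np.outer(p_eps, d_eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (sig_ij / r) ** 6
        vdw = np.where(within, 4.0 * eps_ij * (sr6 ** 2 - sr6), 0.0)
    e_vdw = float(vdw.sum())

    g_nonpolar = 0.0
    if ff.gamma != 0.0:
        # buried-contact-area surrogate: linear ramp inside the contact radius
        buried = np.where(
            r < ff.contact_radius, 1.0 - r / ff.contact_radius, 0.0
        ).sum()
        g_nonpolar = float(ff.gamma * buried)

    return EnergyDecomposition(e_elec, e_vdw, 0.0, g_nonpolar, chain_label)


def coarse_mutant_model(model: StructureModel, spec: MutationSpec) -> StructureModel:
    """Relabel residues per the spec and drop side-chain atoms beyond Cβ.

    A deliberately coarse mutant representation: the backbone is the
    wild-type backbone, the residue identity (and hence its formal charge)
    changes, and no side chain is rebuilt.  Suited to the carrier-atom
    charge model above.
    """
    targets = {pos: (wt, new) for pos, wt, new in spec.substitutions}
    protein_chains = set(model.chains("protein"))
    seen: set[int] = set()
    atoms: list[Atom] = []
    for a in model.atoms:
        if a.chain in protein_chains and a.resi in targets:
            wt, new = targets[a.resi]
            if a.resname != AA1_TO_3[wt]:
                raise ValidationError(
                    f"position {a.resi}: structure has {a.resname}, spec expects {AA1_TO_3[wt]}"
                )
            if a.name not in BACKBONE_ATOMS:
                continue
            atoms.append(replace(a, resname=AA1_TO_3[new]))
            seen.add(a.resi)
        else:
            atoms.append(a)
    missing = set(targets) - seen
    if missing:
        raise ValidationError(f"mutated position(s) {sorted(missing)} not in structure")
    return StructureModel(atoms, dict(model.chain_roles))


def per_chain_binding(
    model: StructureModel,
    mutant: MutationSpec | None = None,
    ff: ForceField | None = None,
    scorer: Scorer | None = None,
    chain_map: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """ΔG_bind of the protein against each DNA strand separately.

    The two nucleic chains must be identifiable as primer (P) and template
    (T): either they are literally named P and T, or ``chain_map`` supplies
    {"P": <chain id>, "T": <chain id>}.  A mutant spec is scored on the
    coarse relabeled model.
    """
    nucleic = model.chains("nucleic")
    if chain_map is None:
        if set(nucleic) == {"P", "T"}:
            chain_map = {"P": "P", "T": "T"}
        else:
            raise RoleError(
                f"cannot identify primer/template strands among chains {nucleic}; "
                "provide chain_map"
            )
    protein = set(model.chains("protein"))
    if not protein:
        raise RoleError("no protein chain to score")
    if mutant is not None:
        model = coarse_mutant_model(model, mutant)
    ff = ff or ForceField.default()
    if scorer is None:
        def scorer(m, pc, dc):  # default surrogate MM scorer
            return interaction_energy(m, pc, dc, ff)
    out = {}
    for strand in ("P", "T"):
        decomp = scorer(model, protein, chain_map[strand])
        out[strand] = decomp.total
    return out


def aggregate_ddg(
    wt: Mapping[str, float], mut: Mapping[str, float], label: str
) -> DdgRecord:
    """ΔΔG = Σ_{chain ∈ {P,T}} (ΔG_mut − ΔG_wt); negative = strengthened."""
    return DdgRecord(label, dict(wt), dict(mut))


def rank_mutants(records: list[DdgRecord]) -> list[DdgRecord]:
    """Ascending by ΔΔG (most strengthening first), ties by label."""
    return sorted(records, key=lambda r: (r.ddg_total, r.label))
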