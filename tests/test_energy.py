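import math

import numpy as np
import pytest

from polbind import (
    ForceField,
    aggregate_ddg,
    coarse_mutant_model,
    interaction_energy,
    make_bdna_duplex,
    make_toy_complex,
    parse_mutation_label,
    per_chain_binding,
    rank_mutants,
)
from polbind.energy import COULOMB_K
from polbind.errors import ContractError, ParameterizationError, RoleError
from polbind.structure import Atom, StructureModel

from conftest import random_rigid_transform

NO_VDW = ForceField(
    residue_charges={"LYS": 1.0, "ALA": 0.0, "ARG": 1.0, "ASP": -1.0,
                     "DG": -1.0, "DC": -1.0, "DA": -1.0, "DT": -1.0,
                     "SER": 0.0, "THR": 0.0},
    element_lj={"C": (3.4, 0.0), "P": (3.74, 0.0)},
    eps0=4.0,
)


def two_charge_model(r=3.5):
    return StructureModel([
        Atom("A", 1, "LYS", "CB", "C", (0.0, 0.0, 0.0)),
        Atom("B", 1, "DG", "P", "P", (r, 0.0, 0.0)),
    ])


def reference_energy(model, protein_chains, dna_chains, ff):
    """Unoptimized all-pairs reference: explicit double loop, same physics."""
    def charges(chains):
        atoms = [a for a in model.atoms if a.chain in chains and a.is_heavy]
        qs = []
        by_res = {}
        for a in atoms:
            by_res.setdefault((a.chain, a.resi), []).append(a)
        q_of = {}
        for (chain, resi), group in by_res.items():
            q = ff.residue_charges[group[0].resname]
            names = {a.name: a for a in group}
            if model.chain_roles[chain] == "nucleic":
                carrier = names.get("P")
            else:
                carrier = names.get("CB", names.get("CA"))
            for a in group:
                q_of[id(a)] = q if (carrier is not None and a is carrier) else 0.0
        return atoms, q_of

    p_atoms, p_q = charges(protein_chains)
    d_atoms, d_q = charges(dna_chains)
    e_elec = e_vdw = 0.0
    for a in p_atoms:
        for b in d_atoms:
            r = math.dist(a.coord, b.coord)
            if r > ff.cutoff:
                continue
            e_elec += COULOMB_K * p_q[id(a)] * d_q[id(b)] / (ff.eps0 * r ** 2)
            sig = 0.5 * (ff.element_lj[a.element][0] + ff.element_lj[b.element][0])
            eps = math.sqrt(ff.element_lj[a.element][1] * ff.element_lj[b.element][1])
            sr6 = (sig / r) ** 6
            e_vdw += 4.0 * eps * (sr6 ** 2 - sr6)
    return e_elec, e_vdw


class TestInteractionEnergy:
    def test_closed_form_two_opposite_unit_charges(self):
        decomp = interaction_energy(two_charge_model(3.5), {"A"}, "B", NO_VDW)
        expected = COULOMB_K * (-1.0) / (4.0 * 3.5 ** 2)
        assert decomp.e_elec == pytest.approx(expected, rel=1e-12)
        assert decomp.e_elec == pytest.approx(-6.78, abs=0.005)
        assert decomp.e_vdw == 0.0

    def test_zero_beyond_cutoff(self):
        decomp = interaction_energy(two_charge_model(100.0), {"A"}, "B", NO_VDW)
        assert decomp.total == 0.0

    def test_separated_complex_scores_exactly_zero(self, duplex):
        model = make_toy_complex(duplex, [("LYS", 3.0, "P"), ("ASP", 5.0, "T")])
        far = StructureModel(
            [
                Atom(a.chain, a.resi, a.resname, a.name, a.element,
                     (a.coord[0] + 500, a.coord[1], a.coord[2]))
                if a.chain == "A" else a
                for a in model.atoms
            ]
        )
        decomp = interaction_energy(far, {"A"}, {"P", "T"})
        assert abs(decomp.total) < 1e-6

    def test_matches_all_pairs_reference(self, duplex):
        ff = ForceField.default()
        model = make_toy_complex(
            make_bdna_duplex("GAAGC"),
            [("LYS", 3.0, "P"), ("ASP", 4.0, "T"), ("SER", 5.0, "P"),
             ("ARG", 6.0, "T"), ("ALA", 8.0, "P")],
        )
        assert len(model.atoms) == 30
        decomp = interaction_energy(model, {"A"}, {"P", "T"}, ff)
        ref_elec, ref_vdw = reference_energy(model, {"A"}, {"P", "T"}, ff)
        assert decomp.e_elec == pytest.approx(ref_elec, abs=1e-9)
        assert decomp.e_vdw == pytest.approx(ref_vdw, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_complex):
        ff = ForceField.default()
        base = interaction_energy(toy_complex, {"A"}, {"P", "T"}, ff)
        rng = np.random.default_rng(3)
        R, t = random_rigid_transform(rng)
        moved = interaction_energy(toy_complex.transformed(R, t), {"A"}, {"P", "T"}, ff)
        assert moved.e_elec == pytest.approx(base.e_elec, rel=1e-9)
        assert moved.e_vdw == pytest.approx(base.e_vdw, rel=1e-9)

    def test_decomposition_identity_exact(self, toy_complex):
        decomp = interaction_energy(toy_complex, {"A"}, {"P", "T"})
        assert decomp.total == decomp.e_elec + decomp.e_vdw + decomp.g_polar + decomp.g_nonpolar

    def test_overlapping_chain_sets_rejected(self, toy_complex):
        with pytest.raises(ContractError):
            interaction_energy(toy_complex, {"A", "P"}, {"P"})

    def test_missing_parameter_names_residue(self):
        model = StructureModel([
            Atom("A", 1, "XXX", "CB", "C", (0.0, 0.0, 0.0)),
            Atom("B", 1, "DG", "P", "P", (3.0, 0.0, 0.0)),
        ])
        with pytest.raises(ParameterizationError, match="XXX"):
            interaction_energy(model, {"A"}, "B")


def symmetric_model():
    """Protein on the mirror plane between two identical strands."""
    atoms = []
    for i in range(1, 4):
        z = 3.4 * i
        atoms.append(Atom("P", i, "DG", "P", "P", (5.0, 0.0, z)))
        atoms.append(Atom("P", i, "DG", "BC", "C", (3.0, 0.0, z)))
        atoms.append(Atom("T", i, "DG", "P", "P", (-5.0, 0.0, z)))
        atoms.append(Atom("T", i, "DG", "BC", "C", (-3.0, 0.0, z)))
    atoms.append(Atom("A", 1, "LYS", "CA", "C", (0.0, 7.5, 3.4)))
    atoms.append(Atom("A", 1, "LYS", "CB", "C", (0.0, 6.0, 3.4)))
    return StructureModel(atoms)


class TestPerChainBinding:
    def test_symmetric_complex_scores_equal(self):
        dg = per_chain_binding(symmetric_model())
        assert dg["P"] == pytest.approx(dg["T"], rel=1e-12)

    def test_label_swap_swaps_values(self, toy_complex):
        dg = per_chain_binding(toy_complex)
        swap = {"P": "T", "T": "P"}
        swapped = StructureModel(
            [
                Atom(swap.get(a.chain, a.chain), a.resi, a.resname, a.name,
                     a.element, a.coord)
                for a in sorted(toy_complex.atoms, key=lambda a: (swap.get(a.chain, a.chain), a.resi))
            ]
        )
        dg2 = per_chain_binding(swapped)
        assert dg2["P"] == pytest.approx(dg["T"], rel=1e-12)
        assert dg2["T"] == pytest.approx(dg["P"], rel=1e-12)

    def test_positive_charge_near_primer_strengthens_p_binding(self, duplex):
        model = make_toy_complex(duplex, [("ALA", 3.0, "P")])
        spec = parse_mutation_label("A1R")
        wt = per_chain_binding(model)
        mut = per_chain_binding(model, mutant=spec)
        dP = mut["P"] - wt["P"]
        dT = mut["T"] - wt["T"]
        assert dP < 0            # more negative: strengthened binding
        assert abs(dT) < abs(dP)  # far strand barely changes

    def test_unidentifiable_strands_role_error(self):
        atoms = [
            Atom("X", 1, "DG", "P", "P", (0.0, 0.0, 0.0)),
            Atom("Y", 1, "DG", "P", "P", (5.0, 0.0, 0.0)),
            Atom("A", 1, "LYS", "CB", "C", (2.0, 3.0, 0.0)),
        ]
        with pytest.raises(RoleError):
            per_chain_binding(StructureModel(atoms))

    def test_coarse_mutant_drops_side_chain_beyond_cb(self):
        atoms = [
            Atom("A", 1, "LYS", "N", "N", (0.0, 0.0, 0.0)),
            Atom("A", 1, "LYS", "CA", "C", (1.5, 0.0, 0.0)),
            Atom("A", 1, "LYS", "CB", "C", (2.0, 1.0, 0.0)),
            Atom("A", 1, "LYS", "NZ", "N", (3.0, 3.0, 0.0)),
            Atom("B", 1, "DG", "P", "P", (8.0, 0.0, 0.0)),
        ]
        model = StructureModel(atoms)
        mut = coarse_mutant_model(model, parse_mutation_label("K1A"))
        names = [a.name for a in mut.atoms if a.chain == "A"]
        assert names == ["N", "CA", "CB"]
        assert all(a.resname == "ALA" for a in mut.atoms if a.chain == "A")


class TestDdgBookkeeping:
    WT = {"P": -2251.8, "T": -3465.7}

    def test_block_mutant_difference(self):
        rec = aggregate_ddg(self.WT, {"P": -2579.5, "T": -3670.2}, "KSKIP(241–245)RVRKS")
        assert rec.ddg_total == pytest.approx(-532.2, abs=1e-9)

    def test_weakened_binder_difference(self):
        rec = aggregate_ddg(self.WT, {"P": -2554.6, "T": -3120.5}, "K337R")
        assert rec.ddg_total == pytest.approx(42.4, abs=1e-9)

    def test_identity_gives_zero(self):
        assert aggregate_ddg(self.WT, dict(self.WT), "wt").ddg_total == pytest.approx(0.0, abs=1e-12)

    def test_missing_chain_key(self):
        with pytest.raises(ContractError):
            aggregate_ddg({"P": -1.0}, self.WT, "bad")


class TestRankMutants:
    PER_CHAIN = {
        "KSKIP(241–245)RVRKS": {"P": -2579.5, "T": -3670.2},
        "M76I": {"P": -2414.7, "T": -3682.8},
        "L250V": {"P": -2422.1, "T": -3603.7},
        "T37F": {"P": -2313.6, "T": -3562.9},
        "A221S": {"P": -2344.03, "T": -3473.91},
        "I62V": {"P": -2145.6, "T": -3632.2},
        "K337R": {"P": -2554.6, "T": -3120.5},
        "Y249I": {"P": -2305.0, "T": -3118.9},
    }
    WT = {"P": -2251.8, "T": -3465.7}

    def _records(self):
        return [
            aggregate_ddg(self.WT, chains, label)
            for label, chains in self.PER_CHAIN.items()
        ]

    def test_published_variants_rank_by_strengthening(self):
        ranked = rank_mutants(self._records())
        assert [r.label for r in ranked] == [
            "KSKIP(241–245)RVRKS", "M76I", "L250V", "T37F",
            "A221S", "I62V", "K337R", "Y249I",
        ]

    def test_permutation_invariance_and_singleton(self):
        records = self._records()
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(len(records)))
        ranked_a = rank_mutants(records)
        ranked_b = rank_mutants([records[i] for i in shuffled])
        assert [r.label for r in ranked_a] == [r.label for r in ranked_b]
        assert rank_mutants([records[0]]) == [records[0]]
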