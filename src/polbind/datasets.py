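"""Literature-reported reference datasets for Dbh and its designed variants.

Two small tables ship with the package:

* ``load_binding_energies`` — MM-PBSA per-chain binding free energies
  (kcal/mol) of wild-type Dbh and eight designed variants against the
  primer (P) and template (T) strands, the reported mutant − WT difference
  column, and the experimentally measured equilibrium dissociation
  constants (nM) of the corresponding Sso7d-fusion variants;
* ``load_kinetics`` — steady-state Michaelis–Menten parameters (K_m in µM,
  V_max in nM·min⁻¹, each with SD) for single-nucleotide insertion of dCTP
  (correct) and dATP (incorrect) opposite G and 8-oxoG template bases, with
  the reported V_max/K_m efficiency column.

These are inputs to the bookkeeping/report operations (difference and
efficiency columns are always recomputed, never copied through).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("polbind.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t")


def load_binding_energies() -> pd.DataFrame:
    """Per-chain ΔG_bind, reported ΔΔG, and measured K_d per variant."""
    return _read("dbh_binding_energies.tsv")


def load_kinetics() -> pd.DataFrame:
    """Reported K_m/V_max (±SD) and efficiency per variant and condition."""
    return _read("dbh_kinetics.tsv")
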