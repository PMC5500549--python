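"""Synthetic-data generators for every pipeline stage.

No structures, alignments, titrations, or gel images from the original
study are available as files, so each analysis stage is exercised on
generated inputs that have the statistical and geometric structure the
stage assumes:

* a coarse ideal B-form DNA duplex (one phosphate + one base-centroid
  pseudo-atom per nucleotide, 3.4 Å rise, 36° twist per step) with strands
  labeled P (primer) and T (template); the default fixture sequence is the
  13-mer template 5′-GAAGCCGGCGGAA-3′;
* toy protein–DNA complexes with residues placed at controlled minimum
  distances from the duplex;
* alignments with exact per-column residue compositions;
* hyperbolic binding titrations and Michaelis–Menten velocity curves with
  Gaussian noise;
* gel lanes with log-length band mobility, a marker ladder, and a
  fluorophore mobility offset.

All generators are deterministic under a fixed seed.  Coordinates are
rounded to 0.001 Å so structures round-trip exactly through PDB text.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .errors import AlphabetError, ContractError, GeometryError, SpecError
from .gel import LaneTrace
from .kinetics import AssayCondition, VelocityDataset
from .msa import AA_ALPHABET, GAP, Alignment
from .structure import AA1_TO_3, Atom, StructureModel
from .titration import TitrationDataset

DEFAULT_TEMPLATE_13MER = "GAAGCCGGCGGAA"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# coarse B-form geometry
RISE = 3.4            # Å per base step
TWIST = 36.0          # degrees per base step
BACKBONE_RADIUS = 8.9  # Å, phosphate distance from the helix axis
BASE_RADIUS = 2.5      # Å, base centroid distance from the helix axis
STRAND_PHASE = 154.0   # degrees between paired phosphates (minor-groove offset)


def _round3(x: float) -> float:
    return round(float(x), 3)


def make_bdna_duplex(sequence: str = DEFAULT_TEMPLATE_13MER) -> StructureModel:
    """Coarse ideal B-form duplex for a given strand sequence.

    The given sequence becomes chain P (5′→3′); its complement becomes
    chain T.  Each nucleotide carries two pseudo-atoms: the backbone
    phosphate P (the charge carrier) and a base centroid BC.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ContractError("duplex needs at least 2 base pairs")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise AlphabetError(f"invalid DNA bases {sorted(bad)}")

    atoms: list[Atom] = []

    def add_nucleotide(chain: str, resi: int, base: str, theta_deg: float, z: float) -> None:
        theta = np.deg2rad(theta_deg)
        for name, element, radius in (("P", "P", BACKBONE_RADIUS),
                                      ("BC", "C", BASE_RADIUS)):
            atoms.append(
                Atom(
                    chain=chain, resi=resi, resname="D" + base,
                    name=name, element=element,
                    coord=(
                        _round3(radius * np.cos(theta)),
                        _round3(radius * np.sin(theta)),
                        _round3(z),
                    ),
                )
            )

    for i, base in enumerate(sequence):
        add_nucleotide("P", i + 1, base, i * TWIST, i * RISE)
    for i, base in enumerate(sequence):
        add_nucleotide("T", i + 1, _COMPLEMENT[base], i * TWIST + STRAND_PHASE, i * RISE)
    return StructureModel(atoms)


def make_toy_complex(
    duplex: StructureModel,
    placements: list[tuple],
) -> StructureModel:
    """Add protein pseudo-residues at controlled distances from the duplex.

    Each placement is ``(residue name, nominal distance Å, strand side)``
    with an optional 4th element giving the residue index (sequential by
    default).  Residues are two pseudo-atoms (Cα, Cβ) placed radially
    outward from the helix axis so that the minimum heavy-atom distance to
    the duplex equals the nominal distance to within 0.01 Å.
    """
    dna_xyz = np.array([a.coord for a in duplex.atoms if a.is_heavy])
    if dna_xyz.size == 0:
        raise ContractError("duplex has no atoms")

    def min_dist(point: np.ndarray) -> float:
        return float(np.sqrt(((dna_xyz - point) ** 2).sum(axis=1)).min())

    anchors = {
        chain: [a for a in duplex.atoms if a.chain == chain and a.name == "P"]
        for chain in duplex.chains()
    }
    atoms = list(duplex.atoms)
    new_atoms: list[Atom] = []
    for k, placement in enumerate(placements):
        if len(placement) == 4:
            resname, dist, side, resi = placement
        else:
            resname, dist, side = placement
            resi = k + 1
        if len(resname) == 1:
            resname = AA1_TO_3.get(resname, resname)
        if dist <= 0:
            raise GeometryError(f"placement distance must be positive, got {dist}")
        strand_anchors = anchors.get(side)
        if not strand_anchors:
            raise ContractError(f"no strand {side!r} in duplex")
        anchor = np.asarray(strand_anchors[(k * 3) % len(strand_anchors)].coord)
        radial = np.array([anchor[0], anchor[1], 0.0])
        norm = np.linalg.norm(radial)
        if norm == 0:
            raise GeometryError("anchor lies on the helix axis")
        u = radial / norm

        # Aim 0.002 Å inside the nominal distance: coordinate rounding then
        # keeps the realized minimum distance strictly below the nominal
        # value (so "within d" placements land inside a cutoff of d) while
        # staying well inside the 0.01 Å placement tolerance.
        target = dist - 0.002 if dist > 0.01 else dist

        def f(t: float) -> float:
            return min_dist(anchor + u * t) - target

        t_star = brentq(f, 0.0, dist + 30.0, xtol=1e-10)
        cb = anchor + u * t_star
        ca = cb + u * 1.5
        for name, xyz in (("CA", ca), ("CB", cb)):
            new_atoms.append(
                Atom(
                    chain="A", resi=int(resi), resname=resname, name=name,
                    element="C",
                    coord=(_round3(xyz[0]), _round3(xyz[1]), _round3(xyz[2])),
                )
            )
    new_atoms.sort(key=lambda a: a.resi)
    return StructureModel(new_atoms + atoms)


def make_alignment(
    reference: str,
    column_specs: dict[int, dict[str, int]] | None = None,
    n_sequences: int = 34,
    seed: int = 0,
    gap_fraction: float = 0.0,
    reference_id: str = "ref",
) -> Alignment:
    """Alignment with exact per-column residue compositions.

    ``column_specs`` maps 1-based reference positions to residue→count
    compositions over the n−1 non-reference sequences; rows not covered by
    a composition at a specified column receive a gap, so the resulting
    column profile equals the composition exactly.  Unspecified columns copy
    the reference (optionally gapped at ``gap_fraction``).
    """
    column_specs = column_specs or {}
    reference = reference.upper()
    bad = set(reference) - AA_ALPHABET
    if bad:
        raise AlphabetError(f"reference contains invalid residues {sorted(bad)}")
    n_hom = n_sequences - 1
    if n_hom < 1:
        raise SpecError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    rows = [list(reference) for _ in range(n_hom)]
    for pos, comp in sorted(column_specs.items()):
        if not 1 <= pos <= len(reference):
            raise SpecError(f"column spec position {pos} outside reference")
        total = sum(comp.values())
        if total > n_hom:
            raise SpecError(
                f"composition at position {pos} needs {total} sequences, "
                f"only {n_hom} available"
            )
        bad = set(comp) - AA_ALPHABET
        if bad:
            raise SpecError(f"invalid residues {sorted(bad)} at position {pos}")
        order = rng.permutation(n_hom)
        cursor = 0
        for res, count in sorted(comp.items()):
            for _ in range(count):
                rows[order[cursor]][pos - 1] = res
                cursor += 1
        for i in range(cursor, n_hom):
            rows[order[i]][pos - 1] = GAP
    if gap_fraction > 0:
        specified = set(column_specs)
        for i in range(n_hom):
            for j in range(len(reference)):
                if (j + 1) not in specified and rng.random() < gap_fraction:
                    rows[i][j] = GAP
    records = [(reference_id, reference)] + [
        (f"hom{i + 1:03d}", "".join(row)) for i, row in enumerate(rows)
    ]
    return Alignment(records, reference_id)


def _noise(rng: np.random.Generator, sd: float, model_values: np.ndarray,
           noise_model: str) -> np.ndarray:
    """Gaussian measurement noise: homoscedastic (sd in signal units) or
    proportional (sd as a coefficient of variation of the model value)."""
    if noise_model == "homoscedastic":
        scale = np.full_like(model_values, sd)
    elif noise_model == "proportional":
        scale = sd * np.abs(model_values)
    else:
        raise ContractError(f"unknown noise model {noise_model!r}")
    return rng.normal(0.0, 1.0, len(model_values)) * scale


def simulate_titration(
    kd: float,
    fmax: float = 1000.0,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    background_slope: float = 0.0,
    probe_concentration: float = 100.0,
    replicates: int = 4,
    noise_model: str = "homoscedastic",
) -> TitrationDataset:
    """Hyperbolic binding curve plus Gaussian noise and optional linear
    protein background (present in both signal and control series).

    Each recorded point is the mean of ``replicates`` noisy measurements
    (four by default, matching how such titrations are recorded); the
    matched control series is averaged the same way.
    """
    if kd <= 0:
        raise ContractError("K_d must be positive")
    if replicates < 1:
        raise ContractError("need at least 1 replicate")
    if concentrations is None:
        concentrations = np.array(
            [0, 2.5, 5, 10, 15, 20, 30, 40, 60, 80, 100, 150, 200,
             300, 500, 750, 1000], dtype=float
        )
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    background = background_slope * c
    model = fmax * c / (kd + c) + background
    signal = np.mean(
        [model + _noise(rng, noise_sd, model, noise_model) for _ in range(replicates)],
        axis=0,
    )
    control = np.mean(
        [background + _noise(rng, noise_sd, model, noise_model) for _ in range(replicates)],
        axis=0,
    )
    return TitrationDataset(c, signal, control, probe_concentration)


def simulate_velocities(
    km: float,
    vmax: float,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 2,
    seed: int = 0,
    condition: AssayCondition | None = None,
    noise_model: str = "homoscedastic",
) -> VelocityDataset:
    """Michaelis–Menten velocity curve with Gaussian noise, measured in
    replicate (duplicate by default) at each concentration."""
    if km <= 0:
        raise ContractError("K_m must be positive")
    if concentrations is None:
        concentrations = np.array(
            [2.5, 5, 10, 25, 50, 100, 200, 400, 600, 800], dtype=float
        )
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    model = vmax * c / (km + c)
    conc_all, v_all, rep_all = [], [], []
    for rep in range(replicates):
        v = model + _noise(rng, noise_sd, model, noise_model)
        conc_all.append(c)
        v_all.append(np.clip(v, 0.0, None))
        rep_all.append(np.full(len(c), rep + 1))
    return VelocityDataset(
        np.concatenate(conc_all),
        np.concatenate(v_all),
        condition or AssayCondition(),
        replicate=np.concatenate(rep_all),
    )


def simulate_gel_lanes(
    extension_spec: dict[int, float],
    primer_length: int = 36,
    ladder_lengths: tuple = (50, 100, 200, 300, 400, 500, 600, 700, 800),
    a: float = 600.0,
    b: float = 80.0,
    mobility_offset: float = 44.0,
    primer_fraction: float = 0.3,
    band_sigma: float = 0.5,
    noise_sd: float = 0.0,
    migration_step: float = 0.2,
    seed: int = 0,
) -> tuple[LaneTrace, LaneTrace]:
    """Render a sample lane and a marker-ladder lane.

    Bands are Gaussians in migration coordinate.  Fluorophore-labeled
    products (primer and extensions) run at their apparent length
    (true + ``mobility_offset``) through migration = a − b·log(length);
    unlabeled ladder markers run at their true length.

    ``extension_spec`` maps extension length (nt beyond the primer) to a
    relative intensity; ``primer_fraction`` of the total lane intensity is
    placed in the unextended primer band.
    """
    if not extension_spec:
        raise SpecError("empty extension spec")
    if any(e <= 0 for e in extension_spec):
        raise SpecError("extension lengths must be positive")
    if b <= 0:
        raise ContractError("mobility slope b must be positive")
    rng = np.random.default_rng(seed)

    def migration(length: float) -> float:
        return a - b * np.log(length)

    total_w = sum(extension_spec.values())
    bands = [
        (migration(primer_length + ext + mobility_offset),
         (1 - primer_fraction) * w / total_w)
        for ext, w in sorted(extension_spec.items())
    ]
    if primer_fraction > 0:
        bands.append((migration(primer_length + mobility_offset), primer_fraction))
    ladder_bands = [(migration(L), 1.0) for L in ladder_lengths]

    centers = [m for m, _ in bands] + [m for m, _ in ladder_bands]
    grid = np.arange(min(centers) - 10.0, max(centers) + 10.0, migration_step)

    def render(band_list):
        intensity = np.zeros_like(grid)
        for center, weight in band_list:
            intensity += weight * np.exp(-((grid - center) ** 2) / (2 * band_sigma ** 2))
        if noise_sd > 0:
            intensity += np.abs(rng.normal(0, noise_sd, len(grid)))
        return intensity

    sample = LaneTrace(grid, render(bands), label="sample", role="sample")
    ladder = LaneTrace(grid, render(ladder_bands), label="ladder", role="ladder")
    return sample, ladder
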