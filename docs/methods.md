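# Methods

This note documents the models behind each `polbind` module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Contact shell

Protein residues are scored by their minimum Euclidean distance to any DNA
atom, heavy atoms only on both sides. Hydrogens are excluded because
crystal structures usually lack them; a heavy-atom convention gives the
same shell whether or not a model was protonated. The cutoff comparison is
inclusive (`min_dist ≤ cutoff`, default 6.0 Å), reading "within 6 Å" in
its inclusive sense; boundary ties are therefore in the shell. Residue
numbers are reported in 1-based reference-sequence coordinates through an
explicit mapping table (identity by default). For disordered atoms the
highest-occupancy altloc is kept, ties broken alphabetically. Chain roles
come from residue-name vocabulary (standard amino acids → protein;
DA/DC/DG/DT and ribo variants → nucleic; anything else → other), decided
per chain by majority over its residues.

## Conservation and mutability

Pairwise identity is computed over alignment columns where neither
sequence is gapped; a record with no comparable column scores 0. Homolog
inclusion is strictly greater than the threshold (default 40%), and the
filter is idempotent. Column profiles cover each ungapped reference
position: residue counts over the non-reference sequences plus a separate
gap tally, so counts + gaps always equal n − 1.

A position is *non-conserved* when more than `max_nonref_fraction`
(default 5%) of the non-gap homolog residues differ from the reference
residue. The 5% default is a deliberate operationalization — small enough
that a single divergent homolog in a set of ~30 does not flip a position,
large enough to catch genuinely variable columns; it is configurable
everywhere it is used. Columns with only gaps among homologs carry no
evidence of variation and count as conserved. Substitution frequencies
are reported as raw counts (`R/28`), not fractions, matching how such
mutability tables are usually printed.

## Mutation design

Candidates are exactly the positions that are simultaneously in the
contact shell and non-conserved; each carries its ranked substitutions
(count descending, ties alphabetical, the reference residue never listed)
and its minimum DNA distance. Maximal runs of ≥ 2 consecutive candidate
positions become block mutations labeled `WTRUN(start–end)NEWRUN`; the en
dash is display-only and the parser accepts ASCII hyphens. Applying a
spec validates the stated wild-type residue at every position, which
guards against coordinate drift between the structure and the alignment.

Mutants are represented at sequence level plus a relabeled copy of the
wild-type backbone: the residue name changes and side-chain atoms beyond
Cβ are dropped. No side-chain rebuilding or repacking is attempted; the
energy model below is designed so that this coarse representation is
scoreable (the charge carrier is Cβ).

Linker notation `PREFIX(UNIT)_k_SUFFIX` expands to prefix + k × unit +
suffix; `SS(GGGGS)_3_GM` gives the 19-residue flexible linker used to
tether Sso7d to the polymerase N-terminus.

## Surrogate binding-energy scorer

The scorer is a deterministic, single-conformation molecular-mechanics
surrogate for an MM-PBSA ensemble calculation:

* ΔG_bind = E_elec + E_vdW + G_polar_solv + G_nonpolar_solv, with the
  −TΔS term identically zero (entropy is ignored, as is common when
  ranking closely related variants);
* electrostatics over protein × DNA heavy-atom pairs within 12 Å with a
  distance-dependent dielectric ε(r) = ε₀·r, so
  E_elec = Σ 332.06·q_i·q_j/(ε₀·r²) kcal/mol; ε₀ defaults to 4.0, a
  common protein-interior choice, and is configurable;
* Lennard-Jones 12-6 with per-element σ/ε and Lorentz–Berthelot mixing;
* polar solvation 0 by default; any callable implementing the scorer
  signature can be plugged in to supply a Poisson–Boltzmann term;
* nonpolar solvation γ × a buried-contact-area surrogate (a linear ramp
  inside a 4.5 Å contact radius), with γ = 0 by default.

Charges are integer formal charges at carrier atoms: Asp/Glu −1 and
Lys/Arg +1 at Cβ (Cα for glycine), His neutral, termini neutral, and −1
per nucleotide at the backbone phosphate P atom. The table ships as a
plain-text parameter file versioned with the package; a missing parameter
raises an error naming the residue or element rather than defaulting
silently.

Absolute magnitudes from this scorer are **not** comparable to MD-ensemble
MM-PBSA values — no solvent, no minimization, no trajectory averaging.
What the module does reproduce exactly is the bookkeeping: per-strand
scoring (primer P and template T separately), the mutant − wild-type
difference ΔΔG = Σ_chain (ΔG_mut − ΔG_wt), and ranking (ascending ΔΔG,
most strengthening first, ties by label). When a table of published
per-chain energies also carries a printed difference column, the report
builder recomputes the column and flags disagreements beyond 0.05
kcal/mol instead of copying; one published row (L250V) fails this check
by 10 kcal/mol and is reported with the recomputed value and a flag.

## Equilibrium titration fits

The corrected signal (pointwise signal − matched control) is fit to
F = F_max·[pol]/(K_d + [pol]) by unweighted nonlinear least squares,
initialized with F_max at the maximum signal and K_d at the concentration
nearest half-max; standard errors come from the fit covariance.
[pol] is total added polymerase — no free-ligand depletion correction —
because that is the form in which such titrations are reported, even
though the probe (100 nM) is comparable to the K_d values of interest; an
exact 1:1-binding quadratic model is available via `model="quadratic"`
for users who want the depletion-corrected estimate. Whether binding
enhances or quenches the fluorophore is inferred from the data (sign of
the linear trend); quenched signals are fit with the sign flipped and
flagged as such. Non-convergence returns a flagged fit with diagnostics;
an all-zero signal is a degenerate-data error.

## Insertion kinetics

Duplicate measurements are averaged per concentration before an
unweighted Michaelis–Menten fit. Catalytic efficiency is
V_max/K_m with K_m converted to mM — the only convention consistent with
published efficiency columns of this form (e.g. V_max = 1.0 nM·min⁻¹,
K_m = 88.2 µM → 11); the occasional "(min)" unit seen in such column
headers is treated as a typographical artifact. Efficiencies are shown at
two significant figures but retained at full precision internally.
Fold-changes compare a quantity between two fits with matched template
base and dNTP (an override flag permits deliberate cross-condition
comparisons); misinsertion fidelity is efficiency(incorrect dNTP) /
efficiency(correct dCTP) opposite the same template base. Two published
efficiency cells are 10× larger than V_max/K_m computed from their own
row's parameters; the report builder flags them and reports the computed
values.

## Gel processivity

Migration is modeled as affine in log(length), the standard behaviour for
denaturing PAGE in this size range. Ladder peaks (local maxima above 10%
of the lane maximum) are matched in migration order to the known marker
lengths and fit by least squares; the fit must be monotone decreasing in
length. Sample lanes are mapped through the inverse calibration to
apparent lengths, shifted by the fluorophore mobility offset (default
44 nt, from a 36-nt labeled primer running at ~80 nt), and re-binned to
integer nucleotides conserving total intensity; samples outside the
calibrated range are extrapolated and recorded as warnings.

Processivity is the intensity-weighted percentile (default 85th) of
extension length over products *above* the primer band; the unextended
primer is excluded because including it would conflate binding
efficiency with extension length. The percentile convention is the
smallest extension whose cumulative normalized intensity reaches the
target — no interpolation, so estimates are integer nucleotides. A lane
with no intensity above the primer band yields estimate 0 with a note,
not an exception. The single-hit check flags a lane as single-hit only
with limiting enzyme (below the primer-template concentration) and a
≥ 400-fold competitor trap.

## Synthetic-data generators

The generators produce inputs with the statistical and geometric
structure each stage assumes, not realistic molecules:

* **Duplex**: one phosphate and one base-centroid pseudo-atom per
  nucleotide on an ideal helix (3.4 Å rise, 36°/step twist, phosphates at
  8.9 Å radius, 154° inter-strand phase), strands labeled P and T. The
  default sequence is the 13-mer 5′-GAAGCCGGCGGAA-3′ used throughout the
  tests. Coordinates are rounded to 0.001 Å so structures round-trip
  exactly through PDB text.
* **Toy complexes**: two-pseudo-atom residues placed radially so the
  minimum heavy-atom distance to the duplex matches the request within
  0.01 Å (aimed 0.002 Å inside the nominal value so that
  coordinate rounding never pushes a boundary placement outside an
  equal-valued cutoff).
* **Alignments**: exact per-column compositions; rows not covered by a
  specified composition receive gaps at that column, so profiles equal
  the specification exactly.
* **Titrations and velocities**: the hyperbolic/Michaelis–Menten model
  plus Gaussian noise, homoscedastic by default with a proportional
  (constant-CV) option, which is the natural reading of "x% noise" for
  plate-reader and gel-quantified measurements. Titration points are
  means of four replicate draws (titrations of this kind are recorded as
  averages of repeated measurements); velocities are duplicated.
  Defaults: K_d in the 30–60 nM range against a 0–1000 nM titration with
  points concentrated below ~5×K_d; K_m in the 30–220 µM range against a
  2.5–800 µM dNTP series of ten concentrations.
* **Gel lanes**: Gaussian bands (σ = 0.5 migration units on a 0.2-unit
  grid) at migration a − b·log(length), a = 600, b = 80; labeled
  products run at true length + offset, ladder markers at true length;
  optional non-negative baseline noise.

What passing tests on these fixtures shows is that the *analysis* is
correct: counting, intersection, aggregation, fitting, calibration, and
percentile logic. They say nothing about force-field realism, about
alignment quality on real homolog sets, or about image-to-trace
extraction from real gels (traces are inputs here).

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small inputs:
toy complexes of ≤ 500 atoms (checked against an O(N²) brute-force
distance oracle), 34-sequence designed alignments, 200 seeded replicates
for parameter-recovery statistics, and single simulated lanes per gel
scenario. Fits use `scipy.optimize.curve_fit` with non-negative bounds
and data-driven initialization; grid-search oracles in the tests confirm
the optimizer lands in the global basin. Tie-breaks are alphabetical
throughout (substitution ranking, variant ranking, altloc choice) so all
outputs are deterministic.

## Known limitations

* The energy scorer ranks variants by electrostatics-dominated interface
  changes; it cannot capture packing, solvation shifts, or conformational
  relaxation, and its absolute values are not physical binding energies.
* The coarse mutant representation ignores side-chain geometry beyond Cβ;
  mutations whose effect is steric rather than electrostatic score near
  zero.
* The hyperbolic K_d model ignores ligand depletion; with probe ≈ K_d the
  fitted K_d is an apparent value (the quadratic option addresses this).
* Percentile processivity depends on the primer-band exclusion rule and
  on the no-interpolation convention; both are configurable, and
  estimates are only as good as the ladder calibration in the relevant
  size range.
* Conservation classification depends on the homolog set; the same
  threshold on a different alignment yields a different candidate list.
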