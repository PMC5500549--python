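# polbind coarse force-field parameter table.
#
# charge <RESNAME> <formal charge, e>
#   Protein residue charges are applied at the Cbeta carrier atom (Calpha
#   for Gly); nucleotide charges model the backbone phosphate and are
#   applied at the P atom.  Termini are neutral.
# lj <ELEMENT> <sigma, Angstrom> <epsilon, kcal/mol>
#   Lennard-Jones parameters per element, combined with Lorentz-Berthelot
#   rules.
# const <name> <value>
#   eps0      reference dielectric for the distance-dependent model e(r)=eps0*r
#   cutoff    pair-interaction cutoff, Angstrom
#   gamma     nonpolar solvation coefficient (0 disables the term)

charge ALA 0
charge ARG +1
charge ASN 0
charge ASP -1
charge CYS 0
charge GLN 0
charge GLU -1
charge GLY 0
charge HIS 0
charge ILE 0
charge LEU 0
charge LYS +1
charge MET 0
charge PHE 0
charge PRO 0
charge SER 0
charge THR 0
charge TRP 0
charge TYR 0
charge VAL 0
charge DA -1
charge DC -1
charge DG -1
charge DT -1

lj C 3.40 0.086
lj N 3.25 0.170
lj O 2.96 0.210
lj P 3.74 0.200
lj S 3.56 0.250

const eps0 4.0
const cutoff 12.0
const gamma 0.0
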