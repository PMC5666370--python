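# Mass-constant and modification table for venompep.
# Monoisotopic atomic masses are fixed so that reported peptide masses are
# auditable and stable across releases; the version string below is echoed
# in every report the pipeline writes.
version: "1.0"

atomic_masses:
  monoisotopic:
    C: 12.0
    H: 1.0078250319
    N: 14.0030740052
    O: 15.9949146221
    S: 31.97207069
  average:
    C: 12.011
    H: 1.008
    N: 14.007
    O: 15.999
    S: 32.06

proton_mass: 1.00727646

# Residue (amino-acid minus water) formulas and monoisotopic masses for the
# 20 standard residues.  The numeric masses are deliberately stored as
# independent literals: they are validated against the formulas at load time
# (to 1e-9 Da) and give peptide_mass a second code path that does not go
# through formula arithmetic.  Leu and Ile are distinct letters with
# identical composition.
residues:
  A: {formula: "C3H5NO",     mass: 71.0371137868}
  C: {formula: "C3H5NOS",    mass: 103.0091844768}
  D: {formula: "C4H5NO3",    mass: 115.0269430310}
  E: {formula: "C5H7NO3",    mass: 129.0425930948}
  F: {formula: "C9H9NO",     mass: 147.0684139144}
  G: {formula: "C2H3NO",     mass: 57.0214637230}
  H: {formula: "C6H7N3O",    mass: 137.0589118610}
  I: {formula: "C6H11NO",    mass: 113.0840639782}
  K: {formula: "C6H12N2O",   mass: 128.0949630153}
  L: {formula: "C6H11NO",    mass: 113.0840639782}
  M: {formula: "C5H9NOS",    mass: 131.0404846044}
  N: {formula: "C4H6N2O2",   mass: 114.0429274460}
  P: {formula: "C5H7NO",     mass: 97.0527638506}
  Q: {formula: "C5H8N2O2",   mass: 128.0585775098}
  R: {formula: "C6H12N4O",   mass: 156.1011110257}
  S: {formula: "C3H5NO2",    mass: 87.0320284089}
  T: {formula: "C4H7NO2",    mass: 101.0476784727}
  V: {formula: "C5H9NO",     mass: 99.0684139144}
  W: {formula: "C11H10N2O",  mass: 186.0793129515}
  Y: {formula: "C9H9NO2",    mass: 163.0633285365}

# Post-translational modifications used by the maturation model.
#   amidation:      C-terminal amide in place of the free acid (-OH +NH2)
#   met_oxide:      methionine S-oxide (+O at a Met residue)
#   disulfide_dimer: two identical chains joined by one S-S bond (-2H on the
#                    doubled formula); applied at the whole-molecule level
modifications:
  amidation:
    delta: {O: -1, N: 1, H: 1}
    constraint: C-term
  met_oxide:
    delta: {O: 1}
    constraint: "residue:M"
  disulfide_dimer:
    delta: {H: -2}
    constraint: whole-molecule
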