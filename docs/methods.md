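# Methods

## Mass model

All masses are monoisotopic daltons computed from a fixed atomic-mass table
(C 12.000000, H 1.0078250319, N 14.0030740052, O 15.9949146221,
S 31.97207069; proton 1.00727646), stored with the package in
`data/constants.yaml` and versioned so every report can cite the constants
it used. Average masses are available as a secondary mode but nothing in
the pipeline depends on them.

A peptide free acid is the sum of its residue formulas plus one water.
Terminal and residue modifications are signed element deltas:

| modification | delta | mass shift (Da) | placement |
|---|---|---|---|
| C-terminal amidation | −O +N +H | −0.98402 | C-terminus |
| methionine S-oxide | +O | +15.99491 | Met residues |
| disulfide homodimer | ×2 then −2H | 2M − 2.01565 | whole molecule |

Masses are computed twice, by independent routes: element counts × atomic
masses, and a sum of per-residue mass literals frozen in the constants
file. The literals are validated against the formulas at load (1e-9 Da)
and the two peptide-level routes are required to agree to 1e-6 Da in the
test suite, which also cross-checks against pyteomics as an external
oracle. Reports round to 3 decimals; full precision is kept internally.
Nonstandard letters (B, J, O, U, X, Z) are rejected rather than
approximated. Leu and Ile are distinct letters with identical composition,
so intact-mass assignments can never distinguish them.

## Maturation rules

A precursor record carries its sequence and an annotated signal-peptidase
boundary (0-based, half-open; 1-based only in human-readable output).
Signal cleavage sites are required annotations — no predictor is bundled,
because curated venom precursors come with the boundary known and silently
predicting one would move an error source inside the pipeline. The
propeptide boundary may be annotated or derived by the dipeptidyl-peptidase
rule: X-Pro/X-Ala dipeptides are removed iteratively from the N-terminus
while the leading pair ends in P or A, stopping at the first violating
pair.

From the remaining mature region the engine emits every species the enzyme
cascade allows:

* the untrimmed free acid (unprocessed C-terminus);
* …G-K terminus: the des-K free acid (carboxypeptidase intermediate, Gly
  retained), the des-GK amide (amidating-lyase product), and the des-GK
  free acid;
* …G terminus: the des-G amide and des-G free acid;
* …E-K terminus: the des-K free acid. K-removal requires the preceding Glu
  by default (the motif carboxypeptidase acts on in these precursors); a
  flag relaxes it to any C-terminal Lys;
* a disulfide homodimer of every monomeric form whose sequence has exactly
  one cysteine. Two or more cysteines make the inter-chain topology
  ambiguous, so no dimer is generated and a warning is recorded.
  Heterodimers between different chains are not generated.

The des-GK/des-G *free acids* deserve a note: enzymatically, incomplete
amidation leaves the glycine-retaining intermediate, not the glycine-less
free acid. They are nevertheless emitted, tagged `des-GK-unamidated`,
because venom surveys report species at exactly that mass (the amide
+0.98402), and carrying them as explicitly tagged candidates lets the
matcher flag such peaks instead of leaving them orphaned. Amidation is
only ever generated from a Gly donor.

Truncation ladders model the ragged N/C-terminally shortened peptides seen
in venom (whether from gland processing or in-venom proteolysis is not
resolved; the provenance tag records the form without claiming a
mechanism). Ladders are terminal-anchored only — every observed fragment
in the motivating data is a prefix or suffix of a full form — with
prefixes as free acids, suffixes inheriting the parent's C-terminal state,
and a default minimum length of 5 (the shortest reported fragment is 7
residues; the margin of 2 admits slightly shorter real fragments without
flooding the candidate list). Methionine S-oxide variants are generated
one per Met on demand rather than combinatorially.

## Mass matching

ESI deconvolution uses the proton mass (not the hydrogen atom), per the
protonation convention: M = z·(m/z − 1.00727646). Observed neutral masses
are matched to candidates within max(10 ppm, 0.02 Da) by default. The ppm
term reflects instrument calibration (typically 1–3 ppm on an Orbitrap);
the absolute floor absorbs the few-mDa gaps that intact-mass tables show on
small peptides. An optional loose window (0.1 Da) admits and *flags*
near-misses — assignments made only by the loose window are marked
`loose_only` and never silently mixed with strict matches. A mass with one
in-tolerance candidate is `unique`, with several `ambiguous` (all listed,
sorted by |ppm error|, then modification count, then sequence — a
deterministic tie-break), otherwise `unassigned`; no fit is ever forced.
Retention time is carried through and used only to sort and bin output
("virtual fractionation" is plain retention-time binning), never as a
matching feature.

Fragment confirmation uses b/y ions only: b_i = (Σ first i residues) + z
protons over z, y_i likewise plus water — or plus NH₃ when the parent is
amidated, since the C-terminal state rides exclusively on y ions. The
score is the fraction of theoretical ions found within 0.02 Da; no
probabilistic model is claimed. The fragment model is monomer-only;
homodimers must be scored per chain.

## Synthetic venoms

The generator emulates the precursor architecture above: a Met-initiated
hydrophobic leader (15–22 residues), a spacer of 2–8 X-P/X-A dipeptide
repeats with X ∈ {D, E}, and a 20–40-residue mature region drawn from a
distribution enriched in K, A, G, I, L (basic, amphiphilic, like the real
peptides — deliberately producing realistic near-collisions in mass space),
ending in one of …GK (p=0.3), …G (0.1), …EK (0.2), a single-cysteine chain
(0.2) or a plain terminus (0.2). Ground truth records the exact candidate
set the rules should emit and which species is "secreted"; observed masses
perturb the secreted species by Gaussian noise at a 3 ppm default scale
(the calibration class of the instruments being emulated), and decoys are
rejection-sampled to sit further than max(25 ppm, 5× the noise scale,
0.05 Da) from every candidate so that recovery rates measure the matcher,
not decoy luck. MS/MS peak lists come from the fragment model with a
configurable ion-dropout probability. Everything is a pure function of the
seed; the same seed gives bit-identical output.

What the generator does **not** emulate: isotope envelopes and
deconvolution artifacts, chromatographic co-elution and peak-shape effects,
in-venom proteolysis products, chemical noise, and sequence homology
between precursors (each is sampled independently). Passing the synthetic
end-to-end tests therefore demonstrates the rule engine and matcher are
correct and calibrated, not that real spectra are this clean; real data
adds upstream error sources the pipeline's tolerances must absorb.

At 3 ppm noise the strict 10 ppm window is ±3.3σ, so ≥99% recovery is the
expected operating point; losses come from the Gaussian tail and from
genuine cross-precursor mass collisions inside the tolerance window, which
are reported as `ambiguous` rather than guessed. Test and acceptance runs
use 6–20 precursors per seed and ≤20 seeds, sizes chosen to exercise every
motif and collision mode while keeping the whole suite around a few
seconds.

## Degenerate inputs and numerical choices

Zero spacer repeats, zero removals, and empty observed lists are valid
(warned, not fatal); an empty candidate list leaves everything unassigned
with a warning; a zero-total count table and a signal boundary of 0 are
errors. Formula subtraction below zero, modifications on the wrong
residue, homodimers without cysteine, and fragment generation on dimers
are errors. Duplicate candidates are deduplicated by molecular identity
(sequence, terminal state, modifications, multimer), keeping the first
provenance tag. Tolerance monotonicity (shrinking the window never assigns
more) is property-tested.

## Known inconsistencies handled explicitly

Published intact-mass tables for these peptides contain two internal
inconsistencies that the package reproduces *and flags* rather than
resolving silently (`chem.check_reported_formula`): an amidated PLP5
sequence paired with the formula (and mass, 1837.071) of its free acid —
the amide computes to 1836.087 — and a PLP2 formula whose hydrogen count
disagrees with the sequence route that reproduces the printed mass
3361.753. In both cases the sequence-derived arithmetic is treated as
authoritative for candidates, and reconciliation output shows both values.
Similarly, the printed PLP4 monomer mass (3166.810) is 0.01 Da below the
sequence/dimer-consistent value (3166.820); the dimer mass 6331.625, which
both routes agree on, is used.

## Limitations

Intact mass cannot distinguish Leu/Ile or localize modifications; the
matcher reports species, not sites. No isotope-envelope deconvolution, no
de novo sequencing, no retention-time prediction, no signal-peptide
prediction, and no read mapping/assembly — the expression module starts
from a mapped-count table and deliberately skips length (RPKM)
normalization, since the relative profile of short, highly expressed venom
transcripts is the target quantity.
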