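# venompep

Venom peptidome prediction and LC-ESI-MS mass matching for linear ant venom
peptides (pilosulin-like peptides and relatives).

Ant venom glands transcribe precursor proteins that are far from the
peptides actually injected: a hydrophobic signal peptide is removed by
signal peptidase, an acidic spacer of X-Pro/X-Ala dipeptide repeats is
trimmed two residues at a time by dipeptidyl peptidase 4, a carboxypeptidase
removes C-terminal lysines, an amidating lyase converts a C-terminal glycine
donor into an amide (−0.98402 Da versus the glycine-less free acid), and
single-cysteine chains can pair into disulfide homodimers (2M − 2.01565 Da).
`venompep` turns annotated precursor sequences into the complete set of
candidate molecular species these rules allow — each with its exact
elemental formula and monoisotopic mass — and assigns deconvoluted
LC-ESI-MS neutral masses (M = z·(m/z − m_p)) and b/y MS/MS fragment spectra
to those candidates within a configurable ppm/Da tolerance. It is written
for venomics groups integrating a venom-gland transcriptome with an
intact-mass peptidome survey.

## Worked example

The mature region of pilosulin-like peptide 1 ends in a Gly-Lys amidation
motif, so four species are possible:

```python
from venompep import (PrecursorRecord, enumerate_mature_forms,
                      match_masses, MatchTolerance, ObservedMass)

rec = PrecursorRecord(
    id="PLP1",
    sequence="MKPSVLVLAIVFVLAIV" + "EAEPEAEPDA" + "GILDWGKKVMDWIKDKMGK",
    signal_end=17,          # 0-based end of the signal peptide
    propeptide_end=27,      # end of the X-P/X-A spacer
)
candidates = enumerate_mature_forms(rec)
for c in candidates:
    print(f"{c.label():30s} {c.mass:9.3f} Da  ({c.provenance})")
```

```
GILDWGKKVMDWIKDKM-NH2           2061.090 Da  (full)
GILDWGKKVMDWIKDKM               2062.074 Da  (des-GK-unamidated)
GILDWGKKVMDWIKDKMG              2119.096 Da  (full)
GILDWGKKVMDWIKDKMGK             2247.191 Da  (full)
```

The amidated 17-mer (glycine consumed as the amide donor, lysine removed by
carboxypeptidase), the des-K intermediate still carrying the glycine, and
the unprocessed precursor terminus each get a theoretical mass; an observed
venom peak then resolves against them:

```python
observed = [ObservedMass(mass=2061.089, rt=29.76, area=27.41, label="Om2061")]
[a] = match_masses(observed, candidates, MatchTolerance(ppm=10, da_floor=0.02))
best = a.best
print(f"{a.observed.label}: {a.status} -> {best.candidate.label()} "
      f"({best.theoretical_mass:.3f} Da, {best.error_da:+.3f} Da, {best.error_ppm:+.2f} ppm)")
```

```
Om2061: unique -> GILDWGKKVMDWIKDKM-NH2 (2061.090 Da, -0.001 Da, -0.66 ppm)
```

The dominant venom peak is the amidated mature peptide, 0.001 Da from
theory. The same candidates, their terminal truncation ladders
(`truncation_ladder`), methionine S-oxide variants and b/y fragment tables
(`fragment_ions`, `score_msms`) drive MS/MS confirmation.

## Command line

```bash
venompep simulate  --out-dir sim --seed 7        # ground-truthed synthetic venom
venompep process   --fasta sim/precursors.fasta --annotations sim/annotations.tsv \
                   --out sim/candidates.tsv
venompep match     --candidates sim/candidates.tsv --observed sim/observed.csv \
                   --out sim/assignments.tsv
venompep fragments --sequence GWGSLFK
venompep profile   --counts counts.tsv --out profile.tsv
```

Each report carries the package version and the mass-constant table version
so numbers stay auditable; `venompep.example_data` ships reconstructed
precursor records for the six *Odontomachus monticola* pilosulin-like
peptides plus the whole-venom LC-MS peak list as a regression example.

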