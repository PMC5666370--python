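"""Maturation rules: precursor sequences → mature-peptide candidates.

Pilosulin-like venom peptide precursors are organized as

    signal peptide | propeptide spacer | mature peptide (+ optional C-tail)

and are matured by a cascade of enzymes: a signal peptidase removes the
leader, dipeptidyl peptidase 4 trims the acidic spacer two residues at a
time (X-Pro / X-Ala dipeptides), a carboxypeptidase removes C-terminal
lysines, and an amidating lyase converts a C-terminal glycine donor into an
amide.  Single-cysteine monomers can pair into disulfide homodimers.  This
module turns an annotated precursor into the concrete set of candidate
molecular species those rules allow, each carrying its elemental formula and
theoretical monoisotopic mass.

Coordinates are 0-based, half-open throughout; human-readable reports
convert to 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from . import chem
from .chem import CTerm, ElementalFormula, ModificationSpec, Multimer

__all__ = [
    "PrecursorRecord",
    "MaturePeptideCandidate",
    "EnumerationOptions",
    "AmbiguousTopologyWarning",
    "strip_signal",
    "process_propeptide",
    "mature_region",
    "enumerate_mature_forms",
    "truncation_ladder",
    "oxidation_variants",
]


class AmbiguousTopologyWarning(UserWarning):
    """Raised when a multi-cysteine sequence makes dimer topology ambiguous."""


@dataclass(frozen=True)
class PrecursorRecord:
    """An annotated precursor sequence.

    ``signal_end`` is the 0-based index one past the last signal-peptide
    residue (the mature-side boundary of signal peptidase cleavage);
    ``propeptide_end``, if given, is one past the last spacer residue.  When
    ``propeptide_end`` is ``None`` the spacer boundary is found by the
    dipeptidyl-peptidase rule (:func:`process_propeptide`).
    """

    id: str
    sequence: str
    signal_end: int
    propeptide_end: Optional[int] = None
    source: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty precursor sequence")
        if not 0 < self.signal_end < len(self.sequence):
            raise ValueError(
                f"{self.id}: signal_end={self.signal_end} must lie strictly inside "
                f"the sequence (length {len(self.sequence)}); provide a signal "
                f"cleavage annotation — no signal-peptide predictor is bundled"
            )
        if self.propeptide_end is not None and not (
            self.signal_end <= self.propeptide_end <= len(self.sequence)
        ):
            raise ValueError(
                f"{self.id}: propeptide_end={self.propeptide_end} outside "
                f"[signal_end, sequence length]"
            )


@dataclass(frozen=True)
class MaturePeptideCandidate:
    """A concrete candidate molecular species derived from one precursor.

    ``trimmed`` records which C-terminal residues of the precursor's mature
    region were removed ('' | 'K' | 'G' | 'GK'); ``provenance`` distinguishes
    full-length rule products from truncation-ladder fragments.
    """

    parent_id: str
    sequence: str
    c_term: CTerm = "free_acid"
    trimmed: str = ""
    multimer: Multimer = "monomer"
    provenance: str = "full"
    residue_mods: tuple[tuple[int, ModificationSpec], ...] = ()

    def __post_init__(self):
        if self.multimer == "disulfide_homodimer" and self.sequence.count("C") < 1:
            raise ValueError(f"{self.parent_id}: homodimer candidate without cysteine")

    @property
    def formula(self) -> ElementalFormula:
        return chem.peptide_formula(
            self.sequence, self.c_term, self.residue_mods, self.multimer
        )

    @property
    def mass(self) -> float:
        return chem.peptide_mass(
            self.sequence, self.c_term, self.residue_mods, self.multimer
        )

    def key(self) -> tuple:
        """Identity of the molecular species (ignores provenance labels)."""
        return (self.sequence, self.c_term, self.multimer, self.residue_mods)

    def label(self) -> str:
        suffix = "-NH2" if self.c_term == "amide" else ""
        dimer = " (S-S homodimer)" if self.multimer == "disulfide_homodimer" else ""
        return f"{self.sequence}{suffix}{dimer}"


@dataclass(frozen=True)
class EnumerationOptions:
    """Rule toggles for :func:`enumerate_mature_forms`.

    ``des_k_requires_e``: carboxypeptidase K-removal only fires on an E-K
    C-terminal motif (set False to allow any C-terminal Lys).
    ``emit_des_gk_free_acid``: for a Gly/Gly-Lys terminus, also emit the
    glycine-removed *free acid* alongside the amide; venom surveys report
    such unamidated species, so keeping them as explicitly tagged candidates
    lets the matcher flag them instead of leaving the mass orphaned.
    """

    amidation: bool = True
    des_k: bool = True
    des_k_requires_e: bool = True
    dimers: bool = True
    emit_des_gk_free_acid: bool = True


def strip_signal(precursor: PrecursorRecord) -> str:
    """Sequence downstream of the signal-peptidase cleavage site."""
    return precursor.sequence[precursor.signal_end :]


def process_propeptide(pro_sequence: str) -> tuple[int, list[str]]:
    """Trim X-Pro / X-Ala dipeptides from the N-terminus.

    Emulates dipeptidyl peptidase 4, which removes dipeptides whose second
    residue is Pro or Ala.  Removal proceeds from the N-terminus while the
    leading pair ends in P or A and stops at the first pair that does not.
    Returns the 0-based start of the remaining (mature) sequence and the
    ordered list of removed dipeptides.
    """
    if not pro_sequence:
        raise ValueError("empty pro-peptide sequence")
    start = 0
    removed: list[str] = []
    while start + 2 <= len(pro_sequence) and pro_sequence[start + 1] in ("P", "A"):
        removed.append(pro_sequence[start : start + 2])
        start += 2
    return start, removed


def mature_region(precursor: PrecursorRecord) -> str:
    """Mature region (with any C-terminal extension still attached).

    Uses the annotated propeptide boundary when present, otherwise the
    dipeptidyl-peptidase rule on the post-signal sequence.
    """
    if precursor.propeptide_end is not None:
        return precursor.sequence[precursor.propeptide_end :]
    pro = strip_signal(precursor)
    start, _ = process_propeptide(pro)
    return pro[start:]


def enumerate_mature_forms(
    precursor: PrecursorRecord,
    options: EnumerationOptions = EnumerationOptions(),
) -> list[MaturePeptideCandidate]:
    """All candidate mature species a precursor can yield under the rules.

    Emits, as applicable to the mature region's C-terminus:

    * the untrimmed free acid;
    * Gly-Lys terminus: the des-K free acid (carboxypeptidase product, Gly
      still attached), the des-GK amide (amidating-lyase product) and,
      optionally, the des-GK free acid;
    * Gly terminus: the des-G amide (and optional des-G free acid);
    * Glu-Lys terminus: the des-K free acid;
    * for every monomeric form of a sequence with exactly one cysteine, the
      disulfide homodimer.  Sequences with more than one cysteine get no
      dimer and an :class:`AmbiguousTopologyWarning` is recorded.

    Output is deterministic and sorted; duplicates (by molecular identity)
    are removed.
    """
    region = mature_region(precursor)
    if not region:
        raise ValueError(f"{precursor.id}: empty mature region")

    forms: list[MaturePeptideCandidate] = []

    def add(sequence: str, c_term: CTerm, trimmed: str, provenance: str = "full"):
        if sequence:
            forms.append(
                MaturePeptideCandidate(
                    parent_id=precursor.id,
                    sequence=sequence,
                    c_term=c_term,
                    trimmed=trimmed,
                    provenance=provenance,
                )
            )

    add(region, "free_acid", "")

    if region.endswith("GK"):
        add(region[:-1], "free_acid", "K")
        if options.amidation:
            add(region[:-2], "amide", "GK")
        if options.emit_des_gk_free_acid:
            add(region[:-2], "free_acid", "GK", provenance="des-GK-unamidated")
    elif region.endswith("G"):
        if options.amidation:
            add(region[:-1], "amide", "G")
        if options.emit_des_gk_free_acid:
            add(region[:-1], "free_acid", "G", provenance="des-G-unamidated")
    elif region.endswith("K") and options.des_k:
        if not options.des_k_requires_e or (len(region) >= 2 and region[-2] == "E"):
            add(region[:-1], "free_acid", "K")

    if options.dimers:
        for cand in list(forms):
            n_cys = cand.sequence.count("C")
            if n_cys == 1:
                forms.append(replace(cand, multimer="disulfide_homodimer"))
            elif n_cys > 1:
                warnings.warn(
                    f"{precursor.id}: {n_cys} cysteines in {cand.sequence!r}; "
                    f"inter-chain topology ambiguous, homodimer not generated",
                    AmbiguousTopologyWarning,
                    stacklevel=2,
                )

    return _dedupe(forms)


def truncation_ladder(
    candidate: MaturePeptideCandidate, min_length: int = 5
) -> list[MaturePeptideCandidate]:
    """Terminal-anchored truncation series of a monomeric candidate.

    Venom peptidomes contain ragged N- and C-terminally shortened forms of
    the full peptides (whether from in-gland processing or in-venom
    proteolysis is not resolved here; the provenance tag records the form).
    Emits every prefix as a free acid and every suffix inheriting the
    parent's C-terminal state, for lengths ≥ ``min_length``, including the
    parent itself, deduplicated by molecular identity.
    """
    if candidate.multimer != "monomer":
        raise ValueError("truncation ladder is defined for monomers only")
    if min_length < 3:
        raise ValueError("min_length must be ≥ 3")
    if candidate.residue_mods:
        raise ValueError("truncation ladder does not propagate residue modifications")
    seq = candidate.sequence
    n = len(seq)
    forms = [candidate]
    for length in range(min_length, n):
        forms.append(
            replace(
                candidate,
                sequence=seq[:length],
                c_term="free_acid",
                trimmed="",
                provenance="prefix-truncation",
            )
        )
        forms.append(
            replace(candidate, sequence=seq[n - length :], provenance="suffix-truncation")
        )
    return _dedupe(forms)


def oxidation_variants(candidate: MaturePeptideCandidate) -> list[MaturePeptideCandidate]:
    """Methionine S-oxide variants, one per Met position (monomers only)."""
    if candidate.multimer != "monomer":
        raise ValueError("oxidation variants are generated for monomers only")
    variants = []
    for pos, letter in enumerate(candidate.sequence):
        if letter == "M":
            variants.append(
                replace(
                    candidate,
                    residue_mods=candidate.residue_mods + ((pos, chem.MET_OXIDE),),
                    provenance=candidate.provenance + "+met-oxide",
                )
            )
    return variants


def _dedupe(forms: Iterable[MaturePeptideCandidate]) -> list[MaturePeptideCandidate]:
    seen: dict[tuple, MaturePeptideCandidate] = {}
    for cand in forms:
        seen.setdefault(cand.key(), cand)
    return sorted(
        seen.values(), key=lambda c: (c.sequence, c.c_term, c.multimer, c.provenance)
    )
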