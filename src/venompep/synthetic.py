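"""Ground-truthed synthetic venoms for end-to-end pipeline testing.

The generator emulates the architecture of pilosulin-like venom peptide
precursors — a hydrophobic signal peptide, an acidic spacer of X-Pro/X-Ala
dipeptide repeats (X mostly Asp/Glu), and a basic amphiphilic mature region
ending in one of the maturation motifs (…G, …GK, …EK, a single-cysteine
chain, or a plain terminus) — together with the LC-MS observables those
peptides would produce: neutral-mass lists with ppm-scale Gaussian noise,
identifiable decoy masses, and b/y MS/MS peak lists with configurable ion
dropout.  Every output is a pure function of the spec's seed.

Ground truth records, for every precursor, the exact candidate set the
maturation rules should emit and which species was "secreted" into the
simulated venom, so recovery rates can be measured without circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .chem import CTerm
from .precursor import MaturePeptideCandidate, PrecursorRecord
from .spectrum import (
    MatchTolerance,
    ObservedMass,
    PeakList,
    charge_project,
    fragment_ions,
    match_masses,
)

__all__ = [
    "SyntheticVenomSpec",
    "SyntheticVenom",
    "ObservedBundle",
    "generate_precursors",
    "generate_observed",
    "evaluate_recovery",
]

# Residue alphabet for mature regions, enriched in Lys/Ala/Gly/Ile/Leu to
# resemble basic amphiphilic venom peptides; no Cys (inserted explicitly for
# the single-cysteine motif) and no Pro (would extend dipeptidyl trimming).
_MATURE_ALPHABET = "KAGILVFSTWEDNQMH"
_MATURE_WEIGHTS = np.array(
    [3.0, 2.5, 2.0, 2.0, 2.0, 1.5, 1.0, 1.0, 1.0, 0.5, 0.7, 0.7, 0.7, 0.7, 0.7, 0.4]
)
_SIGNAL_ALPHABET = "LIVFAMSTW"

MOTIFS = ("GK", "G", "EK", "cys", "plain")


@dataclass(frozen=True)
class SyntheticVenomSpec:
    """Study conditions for one synthetic venom.

    ``spacer_repeats`` and ``mature_length`` are inclusive uniform ranges;
    ``motif_mix`` gives sampling probabilities over the C-terminal motifs
    (must sum to 1); ``mass_noise_ppm`` is the 1-sigma relative calibration
    noise applied to observed masses (instrument-typical: 1–3 ppm);
    ``msms_dropout`` is the probability that any one theoretical fragment
    ion is missing from a simulated MS/MS peak list.
    """

    n_precursors: int = 6
    spacer_repeats: tuple[int, int] = (2, 8)
    mature_length: tuple[int, int] = (20, 40)
    motif_mix: Mapping[str, float] = field(
        default_factory=lambda: {"GK": 0.3, "G": 0.1, "EK": 0.2, "cys": 0.2, "plain": 0.2}
    )
    mass_noise_ppm: float = 3.0
    n_decoys: int = 12
    msms_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_precursors < 1:
            raise ValueError("need at least one precursor")
        unknown = set(self.motif_mix) - set(MOTIFS)
        if unknown:
            raise ValueError(f"unknown motif(s) {sorted(unknown)}; valid: {MOTIFS}")
        total = sum(self.motif_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"motif probabilities must sum to 1, got {total}")
        if not 0 <= self.msms_dropout < 1:
            raise ValueError("msms_dropout must be in [0, 1)")
        if self.mass_noise_ppm < 0:
            raise ValueError("mass_noise_ppm must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What one synthetic precursor should yield."""

    motif: str
    spacer_dipeptides: tuple[str, ...]
    mature_region: str
    candidates: tuple[MaturePeptideCandidate, ...]
    principal: MaturePeptideCandidate


@dataclass(frozen=True)
class SyntheticVenom:
    spec: SyntheticVenomSpec
    precursors: tuple[PrecursorRecord, ...]
    truth: Mapping[str, GroundTruth]

    def all_candidates(self) -> list[MaturePeptideCandidate]:
        return [c for gt in self.truth.values() for c in gt.candidates]


@dataclass(frozen=True)
class ObservedBundle:
    """Simulated LC-MS observables plus the true assignment table."""

    observed: tuple[ObservedMass, ...]
    truth: Mapping[str, tuple]  # observed label -> true candidate key
    peaklists: tuple[PeakList, ...]
    peaklist_truth: Mapping[str, tuple]  # peak list id -> candidate key


def _sample_mature(rng: np.random.Generator, length: int, motif: str) -> str:
    p = _MATURE_WEIGHTS / _MATURE_WEIGHTS.sum()
    letters = list(rng.choice(list(_MATURE_ALPHABET), size=length, p=p))
    # second residue must not re-trigger dipeptidyl trimming
    while letters[1] in ("P", "A"):
        letters[1] = rng.choice(list(_MATURE_ALPHABET.replace("A", "")))
    # keep the core terminus neutral so only the assigned motif fires
    while letters[-1] in ("G", "K"):
        letters[-1] = rng.choice(list("ILVFSTNQMH"))
    if motif == "cys":
        pos = int(rng.integers(2, length - 1))
        letters[pos] = "C"
    core = "".join(letters)
    if motif == "GK":
        return core + "GK"
    if motif == "G":
        return core + "G"
    if motif == "EK":
        return core + "EK"
    return core  # cys, plain


def _truth_for_region(pid: str, region: str, motif: str) -> tuple[tuple[MaturePeptideCandidate, ...], MaturePeptideCandidate]:
    def cand(seq: str, c_term: CTerm, trimmed: str, prov: str = "full") -> MaturePeptideCandidate:
        return MaturePeptideCandidate(
            parent_id=pid, sequence=seq, c_term=c_term, trimmed=trimmed, provenance=prov
        )

    forms = [cand(region, "free_acid", "")]
    principal = forms[0]
    if motif == "GK":
        forms.append(cand(region[:-1], "free_acid", "K"))
        principal = cand(region[:-2], "amide", "GK")
        forms.append(principal)
        forms.append(cand(region[:-2], "free_acid", "GK", "des-GK-unamidated"))
    elif motif == "G":
        principal = cand(region[:-1], "amide", "G")
        forms.append(principal)
        forms.append(cand(region[:-1], "free_acid", "G", "des-G-unamidated"))
    elif motif == "EK":
        principal = cand(region[:-1], "free_acid", "K")
        forms.append(principal)
    elif motif == "cys":
        dimers = [replace(c, multimer="disulfide_homodimer") for c in forms]
        principal = dimers[0]
        forms.extend(dimers)
    return tuple(forms), principal


def generate_precursors(spec: SyntheticVenomSpec) -> SyntheticVenom:
    """Sample precursor records and their ground-truth mature forms."""
    rng = np.random.default_rng(spec.seed)
    motifs = list(spec.motif_mix)
    probs = np.array([spec.motif_mix[m] for m in motifs])

    precursors = []
    truth: dict[str, GroundTruth] = {}
    for i in range(spec.n_precursors):
        pid = f"syn{i:03d}"
        motif = str(rng.choice(motifs, p=probs))
        sig_len = int(rng.integers(15, 23))
        signal = "M" + "".join(rng.choice(list(_SIGNAL_ALPHABET), size=sig_len - 1))
        n_rep = int(rng.integers(spec.spacer_repeats[0], spec.spacer_repeats[1] + 1))
        dipeptides = tuple(
            str(rng.choice(["D", "E"])) + str(rng.choice(["P", "A"]))
            for _ in range(n_rep)
        )
        length = int(rng.integers(spec.mature_length[0], spec.mature_length[1] + 1))
        region = _sample_mature(rng, length, motif)
        spacer = "".join(dipeptides)
        record = PrecursorRecord(
            id=pid,
            sequence=signal + spacer + region,
            signal_end=len(signal),
            propeptide_end=len(signal) + len(spacer),
            source="synthetic",
        )
        candidates, principal = _truth_for_region(pid, region, motif)
        precursors.append(record)
        truth[pid] = GroundTruth(
            motif=motif,
            spacer_dipeptides=dipeptides,
            mature_region=region,
            candidates=candidates,
            principal=principal,
        )
    return SyntheticVenom(spec=spec, precursors=tuple(precursors), truth=truth)


def generate_observed(venom: SyntheticVenom, spec: SyntheticVenomSpec | None = None) -> ObservedBundle:
    """Simulate the LC-MS view of a synthetic venom.

    One observed neutral mass per precursor (its principal secreted species,
    perturbed by Gaussian ppm noise) plus decoy masses placed away from
    every candidate mass by a margin that guarantees identifiability at the
    default matching tolerance; b/y MS/MS peak lists (charge 2 precursors)
    with the spec's ion dropout.
    """
    spec = spec or venom.spec
    rng = np.random.default_rng([spec.seed, 104729])
    noise = spec.mass_noise_ppm * 1e-6

    observed: list[ObservedMass] = []
    truth: dict[str, tuple] = {}
    all_masses = [c.mass for c in venom.all_candidates()]

    rts = np.sort(rng.uniform(5.0, 40.0, size=len(venom.precursors) + spec.n_decoys))
    areas = rng.dirichlet(np.ones(len(venom.precursors) + spec.n_decoys)) * 100.0
    slot = 0
    for record in venom.precursors:
        gt = venom.truth[record.id]
        m = gt.principal.mass * (1.0 + rng.normal(0.0, noise)) if noise else gt.principal.mass
        label = f"T-{record.id}"
        observed.append(
            ObservedMass(mass=m, rt=float(rts[slot]), area=float(areas[slot]), label=label)
        )
        truth[label] = gt.principal.key()
        slot += 1

    lo = 0.8 * min(all_masses)
    hi = 1.2 * max(all_masses)
    n_placed = 0
    while n_placed < spec.n_decoys:
        m = float(rng.uniform(lo, hi))
        margin = max(25e-6 * m, 5 * noise * m, 0.05)
        if all(abs(m - c) > margin for c in all_masses):
            label = f"D{n_placed:03d}"
            observed.append(
                ObservedMass(mass=m, rt=float(rts[slot]), area=float(areas[slot]), label=label)
            )
            slot += 1
            n_placed += 1

    peaklists: list[PeakList] = []
    pl_truth: dict[str, tuple] = {}
    for record in venom.precursors:
        gt = venom.truth[record.id]
        chain = gt.principal
        if chain.multimer != "monomer":
            chain = replace(chain, multimer="monomer")
        ions = fragment_ions(chain)
        keep = [
            (mz, float(rng.uniform(10.0, 100.0)))
            for _lbl, mz in ions
            if spec.msms_dropout == 0.0 or rng.random() >= spec.msms_dropout
        ]
        pl_id = f"msms-{record.id}"
        peaklists.append(
            PeakList(
                peaks=tuple(keep),
                precursor_mz=charge_project(chain.mass, 2),
                precursor_charge=2,
                rt=float(rng.uniform(5.0, 40.0)),
                id=pl_id,
            )
        )
        pl_truth[pl_id] = chain.key()

    return ObservedBundle(
        observed=tuple(observed),
        truth=truth,
        peaklists=tuple(peaklists),
        peaklist_truth=pl_truth,
    )


def evaluate_recovery(
    bundle: ObservedBundle,
    candidates: list[MaturePeptideCandidate],
    tolerance: MatchTolerance = MatchTolerance(),
) -> tuple[float, float]:
    """(true-assignment recovery, decoy false-assignment rate).

    A true observed mass counts as recovered when its assignment is a strict
    unique match to the ground-truth species; a decoy counts as a false
    assignment when it is anything but unassigned.
    """
    assignments = match_masses(bundle.observed, candidates, tolerance)
    n_true = n_recovered = n_decoy = n_false = 0
    for a in assignments:
        if a.observed.label.startswith("T-"):
            n_true += 1
            if (
                a.status == "unique"
                and not a.loose_only
                and a.best is not None
                and a.best.candidate.key() == bundle.truth[a.observed.label]
            ):
                n_recovered += 1
        else:
            n_decoy += 1
            if a.status != "unassigned":
                n_false += 1
    recovery = n_recovered / n_true if n_true else 1.0
    false_rate = n_false / n_decoy if n_decoy else 0.0
    return recovery, false_rate
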