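"""ESI deconvolution, observed-mass assignment and b/y fragment confirmation.

Positive-mode electrospray produces multiply protonated ions; the neutral
monoisotopic mass follows from M = z × (m/z − m_proton).  Observed neutral
masses are assigned to theoretical candidates within a relative (ppm)
tolerance with an absolute floor, with an optional *loose* absolute window
for flagging near-misses; MS/MS peak lists are confirmed against theoretical
b/y fragment series.  No probabilistic score is claimed — the matched-ion
fraction is reported as-is.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from . import chem
from .precursor import MaturePeptideCandidate

__all__ = [
    "ObservedMass",
    "PeakList",
    "Assignment",
    "MatchTolerance",
    "deconvolute",
    "charge_project",
    "match_masses",
    "fragment_ions",
    "score_msms",
    "bin_by_retention_time",
]

PROTON = chem.PROTON_MASS
_WATER_MASS = chem.formula_mass(chem.WATER)
_AMIDE_SHIFT = sum(
    n * chem.MONOISOTOPIC[el] for el, n in chem.AMIDATION.delta.items()
)  # -0.98402 Da

Status = Literal["unique", "ambiguous", "unassigned"]


@dataclass(frozen=True)
class ObservedMass:
    """A deconvoluted neutral monoisotopic mass from an LC-MS run."""

    mass: float
    rt: Optional[float] = None
    area: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"observed mass must be positive, got {self.mass}")
        if self.area is not None and not 0 <= self.area <= 100:
            raise ValueError(f"relative area must be in [0, 100], got {self.area}")


@dataclass(frozen=True)
class PeakList:
    """An MS/MS spectrum: fragment peaks plus precursor ion descriptors."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float
    precursor_charge: int
    rt: Optional[float] = None
    id: str = ""

    def __post_init__(self):
        for mz, intensity in self.peaks:
            if mz <= 0:
                raise ValueError(f"{self.id}: non-positive fragment m/z {mz}")
            if intensity < 0:
                raise ValueError(f"{self.id}: negative intensity {intensity}")

    @property
    def precursor_neutral_mass(self) -> float:
        return deconvolute(self.precursor_mz, self.precursor_charge)


@dataclass(frozen=True)
class CandidateHit:
    """One candidate within tolerance of an observed mass."""

    candidate: MaturePeptideCandidate
    theoretical_mass: float
    error_da: float
    error_ppm: float
    loose: bool  # True when only the loose absolute window admits the hit


@dataclass(frozen=True)
class Assignment:
    """Link between an observed mass (or spectrum) and candidate peptides."""

    observed: ObservedMass
    status: Status
    hits: tuple[CandidateHit, ...] = ()
    loose_only: bool = False
    matched_ions: Optional[int] = None
    total_ions: Optional[int] = None

    @property
    def best(self) -> Optional[CandidateHit]:
        return self.hits[0] if self.hits else None

    @property
    def matched_fraction(self) -> Optional[float]:
        if self.matched_ions is None or not self.total_ions:
            return None
        return self.matched_ions / self.total_ions


@dataclass(frozen=True)
class MatchTolerance:
    """Relative tolerance with an absolute floor, plus a loose window.

    The effective strict tolerance at mass M is max(ppm × 1e-6 × M, da_floor).
    Instrument calibration is typically 1–3 ppm but peptide tables routinely
    show absolute gaps of a few mDa on small peptides, hence the floor.  When
    ``loose_da`` is set, masses that miss the strict window but fall within
    ``loose_da`` are still reported, flagged as loose-only.
    """

    ppm: float = 10.0
    da_floor: float = 0.02
    loose_da: Optional[float] = None

    def __post_init__(self):
        if self.ppm <= 0 or self.da_floor < 0:
            raise ValueError("tolerance must be positive")

    def strict_window(self, mass: float) -> float:
        return max(self.ppm * 1e-6 * mass, self.da_floor)


def deconvolute(mz: float, z: int) -> float:
    """Neutral monoisotopic mass of a [M + zH]^z+ ion: M = z(m/z − m_p)."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if mz <= PROTON:
        raise ValueError(f"m/z {mz} not above the proton mass")
    return z * (mz - PROTON)


def charge_project(neutral_mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion of a neutral mass (inverse of deconvolute)."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (neutral_mass + z * PROTON) / z


def match_masses(
    observed: Sequence[ObservedMass],
    candidates: Sequence[MaturePeptideCandidate],
    tolerance: MatchTolerance = MatchTolerance(),
) -> list[Assignment]:
    """Assign each observed neutral mass to candidate peptides.

    Every observed mass receives exactly one :class:`Assignment`: ``unique``
    when a single candidate species lies within tolerance, ``ambiguous`` when
    several do (all recorded, sorted by |ppm error| then modification count
    then sequence), ``unassigned`` otherwise.  Candidates admitted only by
    the loose absolute window are flagged, and an assignment whose every hit
    is loose is marked ``loose_only``.  Output is sorted by retention time
    (masses without one keep input order, after the timed ones).
    """
    if not candidates:
        warnings.warn("empty candidate list: all observed masses left unassigned")

    theoretical = [(cand, cand.mass) for cand in candidates]
    assignments = []
    for obs in observed:
        hits = []
        for cand, tmass in theoretical:
            err = obs.mass - tmass
            strict = abs(err) <= tolerance.strict_window(tmass)
            loose = (
                not strict
                and tolerance.loose_da is not None
                and abs(err) <= tolerance.loose_da
            )
            if strict or loose:
                hits.append(
                    CandidateHit(
                        candidate=cand,
                        theoretical_mass=tmass,
                        error_da=err,
                        error_ppm=err / tmass * 1e6,
                        loose=loose,
                    )
                )
        hits.sort(
            key=lambda h: (
                abs(h.error_ppm),
                len(h.candidate.residue_mods),
                h.candidate.sequence,
                h.candidate.c_term,
                h.candidate.multimer,
            )
        )
        strict_hits = [h for h in hits if not h.loose]
        pool = strict_hits if strict_hits else hits
        if not pool:
            status: Status = "unassigned"
        elif len({h.candidate.key() for h in pool}) == 1:
            status = "unique"
        else:
            status = "ambiguous"
        assignments.append(
            Assignment(
                observed=obs,
                status=status,
                hits=tuple(hits),
                loose_only=bool(hits) and not strict_hits,
            )
        )
    assignments.sort(
        key=lambda a: (a.observed.rt is None, a.observed.rt if a.observed.rt is not None else 0.0)
    )
    return assignments


def fragment_ions(
    candidate: MaturePeptideCandidate,
    ion_types: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[tuple[str, float]]:
    """Theoretical b/y fragment m/z values of a monomeric candidate.

    b_i is the N-terminal fragment of i residues (neutral species = residue
    sum); y_i the C-terminal fragment (residue sum + water for a free acid,
    residue sum + NH3 for an amidated parent — the C-terminal state rides on
    y ions only).  An ion of charge z appears at (M + z·m_p)/z.  Residue
    modifications (e.g. Met S-oxide) shift the fragments that contain the
    modified position.
    """
    if candidate.multimer != "monomer":
        raise ValueError("fragment model is monomer-only; pass one chain")
    if max_charge < 1:
        raise ValueError("max_charge must be ≥ 1")
    bad = set(ion_types) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported ion types: {sorted(bad)}")

    seq = candidate.sequence
    n = len(seq)
    mod_mass_at = [0.0] * n
    for pos, mod in candidate.residue_mods:
        mod_mass_at[pos] += sum(
            cnt * chem.MONOISOTOPIC[el] for el, cnt in mod.delta.items()
        )
    residue = [chem.STANDARD_AA.mass(a) + mod_mass_at[i] for i, a in enumerate(seq)]

    c_term_mass = _WATER_MASS + (_AMIDE_SHIFT if candidate.c_term == "amide" else 0.0)
    ions = []
    for z in range(1, max_charge + 1):
        if "b" in ion_types:
            acc = 0.0
            for i in range(1, n):
                acc += residue[i - 1]
                ions.append((f"b{i}" + (f"+{z}" if z > 1 else ""), (acc + z * PROTON) / z))
        if "y" in ion_types:
            acc = c_term_mass
            for i in range(1, n):
                acc += residue[n - i]
                ions.append((f"y{i}" + (f"+{z}" if z > 1 else ""), (acc + z * PROTON) / z))
    return ions


def score_msms(
    peaklist: PeakList,
    candidate: MaturePeptideCandidate,
    fragment_tol_da: float = 0.02,
    precursor_tolerance: MatchTolerance = MatchTolerance(),
    max_charge: int = 1,
) -> Assignment:
    """Count theoretical b/y ions found in an MS/MS peak list.

    The peak list's deconvoluted precursor mass must fall within the
    precursor tolerance of the candidate.  Each theoretical ion counts as
    matched if any observed peak lies within ``fragment_tol_da``.  Returns an
    :class:`Assignment` carrying matched/total ion counts; an empty peak
    list yields zero matches and an ``unassigned`` status.
    """
    precursor_mass = peaklist.precursor_neutral_mass
    tmass = candidate.mass
    err = precursor_mass - tmass
    window = precursor_tolerance.strict_window(tmass)
    loose_ok = (
        precursor_tolerance.loose_da is not None and abs(err) <= precursor_tolerance.loose_da
    )
    if abs(err) > window and not loose_ok:
        raise ValueError(
            f"precursor mass {precursor_mass:.4f} outside tolerance of candidate "
            f"{candidate.label()} ({tmass:.4f} Da, |Δ|={abs(err):.4f} Da)"
        )

    theoretical = fragment_ions(candidate, max_charge=max_charge)
    obs = ObservedMass(mass=precursor_mass, rt=peaklist.rt, label=peaklist.id or "peaklist")
    if not peaklist.peaks:
        warnings.warn(f"{peaklist.id or 'peaklist'}: empty MS/MS peak list")
        return Assignment(
            observed=obs,
            status="unassigned",
            matched_ions=0,
            total_ions=len(theoretical),
        )

    mzs = sorted(mz for mz, _ in peaklist.peaks)
    matched = 0
    for _label, mz in theoretical:
        lo = bisect.bisect_left(mzs, mz - fragment_tol_da)
        if lo < len(mzs) and mzs[lo] <= mz + fragment_tol_da:
            matched += 1
    hit = CandidateHit(
        candidate=candidate,
        theoretical_mass=tmass,
        error_da=err,
        error_ppm=err / tmass * 1e6,
        loose=abs(err) > window,
    )
    return Assignment(
        observed=obs,
        status="unique",
        hits=(hit,),
        loose_only=abs(err) > window,
        matched_ions=matched,
        total_ions=len(theoretical),
    )


def bin_by_retention_time(
    peaklists: Sequence[PeakList], bin_width_min: float = 0.5
) -> dict[int, list[PeakList]]:
    """Virtual fractionation: group MS/MS spectra into retention-time bins."""
    if bin_width_min <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[int, list[PeakList]] = {}
    for pl in peaklists:
        if pl.rt is None:
            raise ValueError(f"{pl.id or 'peaklist'}: retention time required for binning")
        bins.setdefault(int(pl.rt // bin_width_min), []).append(pl)
    return bins
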