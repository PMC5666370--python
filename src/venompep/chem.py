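"""Exact elemental-formula and monoisotopic-mass arithmetic for peptides.

This module is the numerical core of the pipeline.  Peptide masses are
computed two independent ways — by summing elemental formulas and by summing
frozen residue-mass literals — and the two routes are required to agree to
sub-ppm precision (see the test suite).  All constants live in a packaged,
human-readable YAML table (``data/constants.yaml``) whose version string is
echoed into every report so numbers stay auditable.

Conventions
-----------
* Masses are monoisotopic daltons unless ``kind="average"`` is requested.
* A peptide *free acid* is the sum of residue formulas plus one water.
* C-terminal amidation replaces the terminal hydroxyl with an amine
  (net -O +N +H, a shift of -0.98402 Da).
* Methionine S-oxide adds one oxygen (+15.99491 Da).
* A disulfide homodimer is twice the monomer formula minus two hydrogens
  (-2.01565 Da relative to two free monomers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Iterable, Literal, Mapping

import yaml

__all__ = [
    "ElementalFormula",
    "AminoAcidTable",
    "ModificationSpec",
    "STANDARD_AA",
    "AMIDATION",
    "MET_OXIDE",
    "DISULFIDE_DIMER",
    "PROTON_MASS",
    "WATER",
    "CONSTANTS_VERSION",
    "formula_mass",
    "peptide_formula",
    "peptide_mass",
    "check_reported_formula",
]

MassKind = Literal["monoisotopic", "average"]
CTerm = Literal["free_acid", "amide"]
Multimer = Literal["monomer", "disulfide_homodimer"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_constants() -> dict:
    text = resources.files("venompep").joinpath("data/constants.yaml").read_text()
    return yaml.safe_load(text)


_CONST = _load_constants()
CONSTANTS_VERSION: str = str(_CONST["version"])
MONOISOTOPIC: Mapping[str, float] = MappingProxyType(dict(_CONST["atomic_masses"]["monoisotopic"]))
AVERAGE: Mapping[str, float] = MappingProxyType(dict(_CONST["atomic_masses"]["average"]))
PROTON_MASS: float = float(_CONST["proton_mass"])


class ElementalFormula:
    """Integer element counts with exact mass arithmetic.

    Immutable.  Addition and subtraction are element-wise; subtraction that
    would drive any count negative raises ``ValueError``.  ``counts`` only
    stores strictly positive entries, so two formulas built differently but
    describing the same composition compare (and hash) equal.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for el, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if n:
                clean[el] = n
        self._counts = MappingProxyType(clean)

    @property
    def counts(self) -> Mapping[str, int]:
        return self._counts

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-order text such as ``"C95H152N24O23S2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.replace(" ", "")):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text.replace(" ", "")):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def hill(self) -> str:
        """Hill-order serialization: C, then H, then other elements sorted."""
        order = [el for el in ("C", "H") if el in self._counts]
        order += sorted(el for el in self._counts if el not in ("C", "H"))
        return "".join(f"{el}{self._counts[el]}" for el in order)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for el, n in other._counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self._counts)
        for el, n in other._counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give negative {el} count ({counts.get(el, 0)} - {n})"
                )
            counts[el] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula can only be multiplied by a non-negative integer")
        return ElementalFormula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def shift(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Apply a signed element delta (e.g. a modification)."""
        counts = dict(self._counts)
        for el, n in delta.items():
            new = counts.get(el, 0) + int(n)
            if new < 0:
                raise ValueError(f"delta would give negative {el} count")
            counts[el] = new
        return ElementalFormula(counts)

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementalFormula) and dict(self._counts) == dict(other._counts)

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill() or 'empty'})"


WATER = ElementalFormula({"H": 2, "O": 1})


@dataclass(frozen=True)
class ModificationSpec:
    """A named formula delta with a placement constraint.

    ``constraint`` is one of ``"N-term"``, ``"C-term"``, ``"residue:X"``
    (applies only at residues with letter X) or ``"whole-molecule"``.
    Applying and then reverting a modification restores the original formula.
    """

    name: str
    delta: Mapping[str, int]
    constraint: str

    def apply(self, formula: ElementalFormula) -> ElementalFormula:
        return formula.shift(self.delta)

    def revert(self, formula: ElementalFormula) -> ElementalFormula:
        return formula.shift({el: -n for el, n in self.delta.items()})

    def residue_letter(self) -> str | None:
        if self.constraint.startswith("residue:"):
            return self.constraint.split(":", 1)[1]
        return None


def _load_modifications() -> dict[str, ModificationSpec]:
    mods = {}
    for name, spec in _CONST["modifications"].items():
        mods[name] = ModificationSpec(name=name, delta=MappingProxyType(dict(spec["delta"])), constraint=spec["constraint"])
    return mods


_MODS = _load_modifications()
AMIDATION: ModificationSpec = _MODS["amidation"]
MET_OXIDE: ModificationSpec = _MODS["met_oxide"]
DISULFIDE_DIMER: ModificationSpec = _MODS["disulfide_dimer"]


class AminoAcidTable:
    """Immutable residue-letter → (formula, monoisotopic mass) table.

    The numeric residue masses come from the constants file as independent
    literals and are validated against the residue formulas (1e-9 Da) when
    the table is built, so the two mass routes in this module stay honest.
    """

    def __init__(self, residues: Mapping[str, tuple[ElementalFormula, float]]):
        for letter, (formula, mass) in residues.items():
            derived = formula_mass(formula, "monoisotopic")
            if abs(derived - mass) > 1e-9:
                raise ValueError(
                    f"residue {letter}: stored mass {mass} disagrees with formula "
                    f"mass {derived} by more than 1e-9 Da"
                )
        self._residues = MappingProxyType(dict(residues))

    @classmethod
    def standard(cls) -> "AminoAcidTable":
        residues = {
            letter: (ElementalFormula.parse(spec["formula"]), float(spec["mass"]))
            for letter, spec in _CONST["residues"].items()
        }
        return cls(residues)

    @property
    def letters(self) -> frozenset[str]:
        return frozenset(self._residues)

    def formula(self, letter: str) -> ElementalFormula:
        try:
            return self._residues[letter][0]
        except KeyError:
            raise KeyError(f"unknown residue letter {letter!r}") from None

    def mass(self, letter: str) -> float:
        try:
            return self._residues[letter][1]
        except KeyError:
            raise KeyError(f"unknown residue letter {letter!r}") from None

    def validate(self, sequence: str) -> None:
        bad = sorted(set(sequence) - self.letters)
        if bad:
            raise ValueError(
                f"sequence contains unsupported residue letter(s) {''.join(bad)!r}; "
                f"only the 20 standard residues are accepted"
            )


def formula_mass(formula: ElementalFormula, kind: MassKind = "monoisotopic") -> float:
    """Mass of a formula in Da as Σ count × atomic mass.

    Raises ``KeyError`` naming the symbol if the formula contains an element
    absent from the atomic-mass table.
    """
    table = MONOISOTOPIC if kind == "monoisotopic" else AVERAGE
    total = 0.0
    for el, n in formula.counts.items():
        if el not in table:
            raise KeyError(f"no {kind} atomic mass for element {el!r}")
        total += n * table[el]
    return total


STANDARD_AA = AminoAcidTable.standard()


def _check_mods(sequence: str, residue_mods: Iterable[tuple[int, ModificationSpec]]) -> None:
    for pos, mod in residue_mods:
        if not 0 <= pos < len(sequence):
            raise ValueError(f"modification position {pos} outside sequence of length {len(sequence)}")
        want = mod.residue_letter()
        if want is not None and sequence[pos] != want:
            raise ValueError(
                f"modification {mod.name!r} requires residue {want} but position "
                f"{pos} is {sequence[pos]}"
            )


def peptide_formula(
    sequence: str,
    c_term: CTerm = "free_acid",
    residue_mods: Iterable[tuple[int, ModificationSpec]] | None = None,
    multimer: Multimer = "monomer",
    table: AminoAcidTable = STANDARD_AA,
) -> ElementalFormula:
    """Elemental formula of a peptide in a given terminal/modification state.

    ``residue_mods`` is a list of ``(position, ModificationSpec)`` with
    0-based positions.  For a disulfide homodimer the per-chain state
    (``c_term`` and ``residue_mods``) applies to each of the two identical
    chains and the dimer formula is twice the chain formula minus two
    hydrogens; the sequence must contain at least one cysteine.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    table.validate(sequence)
    residue_mods = list(residue_mods or [])
    _check_mods(sequence, residue_mods)

    formula = ElementalFormula()
    for letter in sequence:
        formula = formula + table.formula(letter)
    formula = formula + WATER
    if c_term == "amide":
        formula = AMIDATION.apply(formula)
    elif c_term != "free_acid":
        raise ValueError(f"unknown c_term {c_term!r}")
    for _pos, mod in residue_mods:
        formula = mod.apply(formula)

    if multimer == "disulfide_homodimer":
        if sequence.count("C") < 1:
            raise ValueError("disulfide homodimer requires at least one cysteine")
        formula = DISULFIDE_DIMER.apply(formula * 2)
    elif multimer != "monomer":
        raise ValueError(f"unknown multimer state {multimer!r}")
    return formula


def peptide_mass(
    sequence: str,
    c_term: CTerm = "free_acid",
    residue_mods: Iterable[tuple[int, ModificationSpec]] | None = None,
    multimer: Multimer = "monomer",
    kind: MassKind = "monoisotopic",
    table: AminoAcidTable = STANDARD_AA,
) -> float:
    """Peptide mass in Da.

    For the monoisotopic kind this sums the table's frozen residue-mass
    literals plus terminal/modification deltas — a code path independent of
    :func:`peptide_formula` — and is therefore cross-checked against the
    formula route by the test suite.  The average kind goes through the
    formula route directly.
    """
    if kind == "average":
        return formula_mass(
            peptide_formula(sequence, c_term, residue_mods, multimer, table), "average"
        )
    if not sequence:
        raise ValueError("empty peptide sequence")
    table.validate(sequence)
    residue_mods = list(residue_mods or [])
    _check_mods(sequence, residue_mods)

    mass = sum(table.mass(letter) for letter in sequence)
    mass += formula_mass(WATER)
    if c_term == "amide":
        mass += _delta_mass(AMIDATION)
    elif c_term != "free_acid":
        raise ValueError(f"unknown c_term {c_term!r}")
    mass += sum(_delta_mass(mod) for _pos, mod in residue_mods)
    if multimer == "disulfide_homodimer":
        if sequence.count("C") < 1:
            raise ValueError("disulfide homodimer requires at least one cysteine")
        mass = 2.0 * mass + _delta_mass(DISULFIDE_DIMER)
    elif multimer != "monomer":
        raise ValueError(f"unknown multimer state {multimer!r}")
    return mass


def _delta_mass(mod: ModificationSpec, kind: MassKind = "monoisotopic") -> float:
    table = MONOISOTOPIC if kind == "monoisotopic" else AVERAGE
    return sum(n * table[el] for el, n in mod.delta.items())


@dataclass(frozen=True)
class FormulaCheck:
    """Outcome of reconciling a reported formula with a sequence-derived one."""

    sequence_formula: ElementalFormula
    reported_formula: ElementalFormula
    sequence_mass: float
    reported_mass: float
    consistent: bool
    note: str = ""


def check_reported_formula(
    sequence: str,
    c_term: CTerm,
    reported: str | ElementalFormula,
    residue_mods: Iterable[tuple[int, ModificationSpec]] | None = None,
    multimer: Multimer = "monomer",
    tol_da: float = 0.01,
) -> FormulaCheck:
    """Reconcile a reported molecular formula against the sequence route.

    Published tables occasionally pair a sequence (e.g. an amidated peptide)
    with a formula that corresponds to a different terminal state.  This
    helper computes both the sequence-derived and the reported-formula masses
    and flags the pair as inconsistent when the formulas differ; reports can
    then show the discrepancy instead of silently picking one value.
    """
    rep = reported if isinstance(reported, ElementalFormula) else ElementalFormula.parse(reported)
    seq_formula = peptide_formula(sequence, c_term, residue_mods, multimer)
    seq_mass = formula_mass(seq_formula)
    rep_mass = formula_mass(rep)
    consistent = seq_formula == rep
    note = ""
    if not consistent:
        note = (
            f"sequence-derived formula {seq_formula.hill()} ({seq_mass:.3f} Da) "
            f"differs from reported {rep.hill()} ({rep_mass:.3f} Da) by "
            f"{seq_mass - rep_mass:+.3f} Da"
        )
    return FormulaCheck(seq_formula, rep, seq_mass, rep_mass, consistent, note)
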