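"""File formats and run configuration for the pipeline.

Readers and writers for the plain-text dialects the pipeline consumes and
emits: FASTA precursors (Biopython), named-column TSV/CSV tables (pandas),
MGF peak lists (pyteomics), and a YAML run configuration that round-trips
unchanged.  Every table this module writes starts with comment lines
recording the package version, the mass-constant table version and a
config hash, so reported numbers are auditable.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__, chem
from .precursor import MaturePeptideCandidate, PrecursorRecord
from .spectrum import Assignment, MatchTolerance, ObservedMass, PeakList

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_precursors",
    "write_annotations",
    "write_candidates",
    "read_candidates",
    "read_observed_masses",
    "write_observed_masses",
    "read_mgf",
    "write_mgf",
    "write_assignments",
    "read_count_table",
    "file_checksum",
]


@dataclass
class RunConfig:
    """All pipeline knobs, with defaults, serializable to/from YAML."""

    tolerance_ppm: float = 10.0
    tolerance_da: float = 0.02
    loose_da: Optional[float] = None
    fragment_tol_da: float = 0.02
    amidation: bool = True
    des_k: bool = True
    des_k_requires_e: bool = True
    dimers: bool = True
    ladder: bool = False
    min_length: int = 5
    seed: int = 0
    verbosity: int = 1

    def tolerance(self) -> MatchTolerance:
        return MatchTolerance(
            ppm=self.tolerance_ppm, da_floor=self.tolerance_da, loose_da=self.loose_da
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(config: Optional[RunConfig] = None) -> str:
    lines = [
        f"# venompep {__version__} (mass constants v{chem.CONSTANTS_VERSION})",
    ]
    if config is not None:
        lines.append(f"# config sha256:{config.digest()}")
    return "\n".join(lines) + "\n"


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA + annotations -> precursor records

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {id: sequence}.

    Wrapped lines are tolerated; trailing '*' stop codons are stripped with
    a warning; a file that does not start with '>' is rejected naming the
    file and line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path}:1: not a FASTA file (expected '>')")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            warnings.warn(f"{path}: stripped trailing stop codon '*' from {rec.id}")
            seq = seq.rstrip("*")
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


ANNOTATION_COLUMNS = ("id", "signal_end", "propeptide_end", "notes")


def read_precursors(fasta_path: str | Path, annotation_path: str | Path) -> list[PrecursorRecord]:
    """Join a precursor FASTA with its annotation table.

    The annotation TSV needs named columns ``id`` and ``signal_end``
    (0-based index one past the signal peptide); ``propeptide_end`` is
    optional per row (blank = derive the spacer by the dipeptidyl rule).
    """
    seqs = read_fasta(fasta_path)
    ann = pd.read_csv(annotation_path, sep="\t", comment="#")
    for col in ("id", "signal_end"):
        if col not in ann.columns:
            raise ValueError(f"{annotation_path}: missing required column {col!r}")
    records = []
    for _, row in ann.iterrows():
        sid = str(row["id"])
        if sid not in seqs:
            raise ValueError(f"{annotation_path}: id {sid!r} not present in {fasta_path}")
        pe = row.get("propeptide_end")
        propeptide_end = None if pd.isna(pe) else int(pe)
        records.append(
            PrecursorRecord(
                id=sid,
                sequence=seqs[sid],
                signal_end=int(row["signal_end"]),
                propeptide_end=propeptide_end,
                source=str(row["notes"]) if "notes" in ann.columns and not pd.isna(row.get("notes")) else None,
            )
        )
    missing = set(seqs) - {r.id for r in records}
    if missing:
        warnings.warn(f"{fasta_path}: {len(missing)} sequence(s) without annotation skipped")
    return records


def write_annotations(records: Sequence[PrecursorRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "signal_end": [r.signal_end for r in records],
            "propeptide_end": [r.propeptide_end for r in records],
            "notes": [r.source or "" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Candidate tables

CANDIDATE_COLUMNS = (
    "parent_id",
    "sequence",
    "c_term",
    "trimmed",
    "multimer",
    "provenance",
    "mods",
    "formula",
    "mass",
)


def write_candidates(
    candidates: Sequence[MaturePeptideCandidate],
    path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    rows = []
    for c in candidates:
        rows.append(
            {
                "parent_id": c.parent_id,
                "sequence": c.sequence,
                "c_term": c.c_term,
                "trimmed": c.trimmed or "none",
                "multimer": c.multimer,
                "provenance": c.provenance,
                "mods": ";".join(f"{mod.name}@{pos}" for pos, mod in c.residue_mods),
                "formula": c.formula.hill(),
                "mass": f"{c.mass:.3f}",
            }
        )
    with open(path, "w") as fh:
        fh.write(_header(config))
        pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(fh, sep="\t", index=False)


_MOD_BY_NAME = {
    "amidation": chem.AMIDATION,
    "met_oxide": chem.MET_OXIDE,
}


def read_candidates(path: str | Path) -> list[MaturePeptideCandidate]:
    """Rebuild candidates from a TSV; mass/formula are recomputed and verified."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("parent_id", "sequence", "c_term", "multimer"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        mods = []
        raw = row.get("mods")
        if isinstance(raw, str) and raw:
            for token in raw.split(";"):
                name, pos = token.rsplit("@", 1)
                if name not in _MOD_BY_NAME:
                    raise ValueError(f"{path}: unknown modification {name!r}")
                mods.append((int(pos), _MOD_BY_NAME[name]))
        trimmed = row.get("trimmed", "")
        cand = MaturePeptideCandidate(
            parent_id=str(row["parent_id"]),
            sequence=str(row["sequence"]),
            c_term=str(row["c_term"]),
            trimmed="" if trimmed in ("none", "", None) or pd.isna(trimmed) else str(trimmed),
            multimer=str(row["multimer"]),
            provenance=str(row.get("provenance", "full")),
            residue_mods=tuple(mods),
        )
        if "mass" in df.columns and not pd.isna(row["mass"]):
            if abs(cand.mass - float(row["mass"])) > 0.005:
                raise ValueError(
                    f"{path}: stored mass {row['mass']} disagrees with recomputed "
                    f"{cand.mass:.3f} for {cand.sequence}"
                )
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Observed masses + MGF

def read_observed_masses(path: str | Path) -> list[ObservedMass]:
    """CSV/TSV with named columns: mass (required), rt, area, label."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "mass" not in df.columns:
        raise ValueError(f"{path}: missing required column 'mass'")
    out = []
    for i, row in df.iterrows():
        out.append(
            ObservedMass(
                mass=float(row["mass"]),
                rt=None if "rt" not in df.columns or pd.isna(row.get("rt")) else float(row["rt"]),
                area=None if "area" not in df.columns or pd.isna(row.get("area")) else float(row["area"]),
                label=str(row["label"]) if "label" in df.columns and not pd.isna(row.get("label")) else f"obs{i}",
            )
        )
    return out


def write_observed_masses(observed: Sequence[ObservedMass], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mass": [f"{o.mass:.4f}" for o in observed],
            "rt": [o.rt for o in observed],
            "area": [o.area for o in observed],
            "label": [o.label for o in observed],
        }
    ).to_csv(path, index=False)


def write_mgf(peaklists: Sequence[PeakList], path: str | Path) -> None:
    from pyteomics import mgf

    spectra = []
    for pl in peaklists:
        spectra.append(
            {
                "m/z array": [mz for mz, _ in pl.peaks],
                "intensity array": [it for _, it in pl.peaks],
                "params": {
                    "title": pl.id,
                    "pepmass": pl.precursor_mz,
                    "charge": f"{pl.precursor_charge}+",
                    **({"rtinseconds": pl.rt * 60.0} if pl.rt is not None else {}),
                },
            }
        )
    mgf.write(spectra, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[PeakList]:
    from pyteomics import mgf

    out = []
    with mgf.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            charge = int(params["charge"][0]) if "charge" in params else 1
            rt = params.get("rtinseconds")
            out.append(
                PeakList(
                    peaks=tuple(
                        zip(
                            (float(x) for x in spec["m/z array"]),
                            (float(x) for x in spec["intensity array"]),
                        )
                    ),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    rt=float(rt) / 60.0 if rt is not None else None,
                    id=str(params.get("title", f"spectrum{i}")),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Assignment report

ASSIGNMENT_COLUMNS = (
    "label",
    "rt",
    "area",
    "observed_mass",
    "status",
    "loose_only",
    "parent_id",
    "sequence",
    "c_term",
    "multimer",
    "formula",
    "theoretical_mass",
    "error_da",
    "error_ppm",
    "n_candidates",
)


def write_assignments(
    assignments: Sequence[Assignment],
    path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    """Assignment TSV, one row per observed mass, best candidate first."""
    rows = []
    for a in assignments:
        best = a.best
        rows.append(
            {
                "label": a.observed.label,
                "rt": a.observed.rt,
                "area": a.observed.area,
                "observed_mass": f"{a.observed.mass:.3f}",
                "status": a.status,
                "loose_only": a.loose_only,
                "parent_id": best.candidate.parent_id if best else "",
                "sequence": best.candidate.label() if best else "",
                "c_term": best.candidate.c_term if best else "",
                "multimer": best.candidate.multimer if best else "",
                "formula": best.candidate.formula.hill() if best else "",
                "theoretical_mass": f"{best.theoretical_mass:.3f}" if best else "",
                "error_da": f"{best.error_da:.4f}" if best else "",
                "error_ppm": f"{best.error_ppm:.2f}" if best else "",
                "n_candidates": len(a.hits),
            }
        )
    with open(path, "w") as fh:
        fh.write(_header(config))
        pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("contig", "group", "category", "count") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
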