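"""Reconstructed example inputs: *Odontomachus monticola* pilosulin-like peptides.

Six precursor records for pilosulin-like peptides (PLP) 1–6 and the LC-ESI-MS
neutral-mass peak list of the whole venom, usable as a worked example and as
a regression fixture.  The mature regions and their C-terminal extensions
(Gly-Lys amidation donors on PLP1/5/6, Glu-Lys carboxypeptidase motifs on
PLP2/3, the single-cysteine PLP4 chain) follow the reported mature sequences;
the signal-peptide and acidic-spacer segments are SYNTHETIC stand-ins with
the canonical architecture (hydrophobic leader, X-Pro/X-Ala dipeptide
repeats), since only the mature region determines the candidate masses.
"""

from __future__ import annotations

from .precursor import PrecursorRecord
from .spectrum import ObservedMass

__all__ = [
    "MATURE_REGIONS",
    "example_precursors",
    "observed_venom_masses",
]

_SIGNAL = "MKPSVLVLAIVFVLAIV"  # synthetic leader
_SPACER = "EAEPEAEPDA"  # synthetic X-P/X-A dipeptide-repeat spacer

# Mature region plus C-terminal extension, as encoded in the precursor.
MATURE_REGIONS: dict[str, str] = {
    "PLP1": "GILDWGKKVMDWIKDKM" + "GK",
    "PLP2": "GWGSIFKTVGKMIAKAAVKAAPEAISAMASQNE" + "K",
    "PLP3": "KIKWGKIFKKGGKLIGKTALEAAANAAASEAISAMASQNE" + "K",
    "PLP4": "GVKELFGKAWGLVKKHLPKACGLLGYVKQ",
    "PLP5": "IWGALLGTLIPAITSAIQ" + "GK",
    "PLP6": "IKGKKIMKNMGKAMKIAGKVAKAMAPIVVPLIVSAA" + "GK",
}


def example_precursors() -> list[PrecursorRecord]:
    """The six pilosulin-like precursors with annotated boundaries."""
    records = []
    for pid, region in MATURE_REGIONS.items():
        records.append(
            PrecursorRecord(
                id=pid,
                sequence=_SIGNAL + _SPACER + region,
                signal_end=len(_SIGNAL),
                propeptide_end=len(_SIGNAL) + len(_SPACER),
                source="reconstructed; leader/spacer synthetic",
            )
        )
    return records


# Whole-venom LC-ESI-MS peak list (wide-pore C8 column): deconvoluted neutral
# monoisotopic mass, retention time (min), relative area (% of total ion
# current).  Areas reported as "<0.1" / "<1.0" are entered as 0.05 / 0.5.
_VENOM_PEAKS: list[tuple[str, float, float, float]] = [
    ("Om3264", 3263.957, 10.58, 0.41),
    ("Om4117", 4117.238, 11.04, 0.25),
    ("Om3489", 3488.881, 13.84, 0.46),
    ("Om4229", 4229.334, 14.45, 0.05),
    ("Om3101", 3100.615, 14.45, 0.05),
    ("Om4101", 4101.244, 15.04, 12.94),
    ("Om3704", 3704.235, 16.51, 4.29),
    ("Om4401", 4401.364, 17.51, 0.26),
    ("Om6368", 6367.557, 23.07, 20.85),
    ("Om6350", 6349.589, 23.99, 5.27),
    ("Om6332", 6331.631, 24.62, 5.42),
    ("Om3362", 3361.756, 25.37, 7.78),
    ("Om3325", 3324.856, 26.94, 6.97),
    ("Om2247", 2247.188, 27.66, 1.52),
    ("Om2119", 2119.094, 29.26, 0.50),
    ("Om2061", 2061.089, 29.76, 27.41),
    ("Om1782", 1782.019, 32.05, 1.08),
    ("Om1812", 1812.030, 33.62, 0.67),
    ("Om1837", 1836.995, 34.86, 3.65),
]


def observed_venom_masses() -> list[ObservedMass]:
    """The venom LC-MS neutral-mass list as ObservedMass records."""
    return [
        ObservedMass(mass=m, rt=rt, area=area, label=label)
        for label, m, rt, area in _VENOM_PEAKS
    ]
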