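"""Secondary-ion channel definitions.

A NanoSIMS acquisition records a small set of mass-resolved secondary ion
species in parallel.  Two detector configurations are used here: a
platinum run (``pt_run``) recording 194Pt-, 12C2-, 31P-, 34S- and 19F-,
and a nitrogen-isotope run (``n_run``) recording 12C14N-, 12C15N- and
12C2-.  The 12C2- dimer serves as the internal reference in both runs;
12C14N-/12C15N- carry the nitrogen isotopic composition; 31P-, 34S- and
19F- are biomarker/tracer channels used for compartment identification and
colocalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Channel roles within an acquisition.
ROLES = (
    "reference",       # internal intensity reference (12C2-)
    "nitrogen_major",  # 12C14N-
    "nitrogen_minor",  # 12C15N- (isotope label carrier)
    "biomarker",       # 31P-, 34S- morphology markers
    "tracer",          # 19F- (fluorine-containing dye)
    "analyte",         # 194Pt- (drug metal)
)


@dataclass(frozen=True)
class ChannelSpec:
    """One detected secondary-ion species.

    Parameters
    ----------
    species_label : str
        Controlled species symbol, e.g. ``"194Pt"`` or ``"12C14N"``.
    nominal_mass : int
        Nominal mass of the detected ion in amu; must be positive.
    role : str
        One of :data:`ROLES`.
    """

    species_label: str
    nominal_mass: int
    role: str

    def __post_init__(self):
        if self.species_label not in KNOWN_SPECIES:
            raise ValueError(
                f"unknown species_label {self.species_label!r}; "
                f"expected one of {sorted(KNOWN_SPECIES)}"
            )
        if self.nominal_mass <= 0:
            raise ValueError("nominal_mass must be positive")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")


#: Nominal masses and roles of the species the instrument configurations use.
_SPECIES_TABLE: dict[str, tuple[int, str]] = {
    "12C2": (24, "reference"),
    "12C14N": (26, "nitrogen_major"),
    "12C15N": (27, "nitrogen_minor"),
    "31P": (31, "biomarker"),
    "34S": (34, "biomarker"),
    "19F": (19, "tracer"),
    "194Pt": (194, "analyte"),
}

KNOWN_SPECIES = frozenset(_SPECIES_TABLE)


def channel(species_label: str) -> ChannelSpec:
    """Return the canonical :class:`ChannelSpec` for a species symbol."""
    try:
        mass, role = _SPECIES_TABLE[species_label]
    except KeyError:
        raise ValueError(
            f"unknown species_label {species_label!r}; "
            f"expected one of {sorted(KNOWN_SPECIES)}"
        ) from None
    return ChannelSpec(species_label, mass, role)


#: Channels that must be present for each run type.
REQUIRED_CHANNELS: dict[str, frozenset[str]] = {
    "pt_run": frozenset({"194Pt", "12C2"}),
    "n_run": frozenset({"12C14N", "12C15N", "12C2"}),
}

#: Full default channel complement of each run type.
DEFAULT_CHANNELS: dict[str, tuple[str, ...]] = {
    "pt_run": ("194Pt", "12C2", "31P", "34S", "19F"),
    "n_run": ("12C14N", "12C15N", "12C2"),
}
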