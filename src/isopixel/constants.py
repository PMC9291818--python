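"""Shared vocabularies and physical constants.

Species keys name the secondary ions counted in parallel by a NanoSIMS
detector array configured for CN work on biological sections: the two
monatomic carbon ions, the two diatomic carbon ions used for the carbon
isotope ratio, the two CN ions used for the nitrogen isotope ratio,
phosphorus, and the secondary-electron channel.
"""

from __future__ import annotations

#: Canonical species order; TIFF pages are written in this order.
SPECIES: tuple[str, ...] = (
    "12C",
    "13C",
    "12C12C",
    "13C12C",
    "12C14N",
    "12C15N",
    "31P",
    "SE",
)

#: Tissue classes of an ectomycorrhizal root-tip cross-section, outside-in:
#: external (emanating) hyphae, hyphal mantle, Hartig net, plant cortex,
#: endodermis, vascular tissue. "Resin" marks embedding-medium reference ROIs.
TISSUES: tuple[str, ...] = ("HE", "HM", "HN", "PC", "E", "VT")
TISSUES_EXTENDED: tuple[str, ...] = TISSUES + ("Resin",)

#: Sub-cellular compartments: cell wall and lumen.
COMPARTMENTS: tuple[str, ...] = ("CW", "L")
COMPARTMENTS_EXTENDED: tuple[str, ...] = COMPARTMENTS + ("none",)

#: Terrestrial natural isotope abundances, atom percent.
NATURAL_AT13C_PCT = 1.11
NATURAL_AT15N_PCT = 0.366

#: Unlabelled-control isotope fractions (at%) typical for resin-embedded
#: root sections measured with this instrument configuration; used as
#: generator defaults and as the default APE baseline.
CONTROL_AT13C_PCT = 1.07
CONTROL_AT15N_PCT = 0.37

#: Atomic masses (u), monoisotopic where an isotope is named.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "12C": 12.0,
    "13C": 13.003355,
    "N": 14.007,
    "14N": 14.003074,
    "15N": 15.000109,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
    "Cl": 35.45,
}

#: Mean molar mass of natural-abundance nitrogen (g/mol).
MOLAR_MASS_N = 14.007
#: Molar mass of the heavy nitrogen isotope (g/mol).
MOLAR_MASS_15N = 15.000109
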