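"""Reference tables: van der Waals radii, atomic masses, maximum residue SASA.

All radii and surface areas are in Angstrom / Angstrom^2, masses in Dalton.
Every table can be overridden from a two-column text file (see :mod:`surfdyn.io`).
"""

from __future__ import annotations

# Bondi-style van der Waals radii (Angstrom) for the elements that occur in
# protein heavy-atom / explicit-hydrogen structures.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

# Theoretical maximum accessible surface area of residue X in a Gly-X-Gly
# tripeptide (Angstrom^2), used to normalise residue SASA into "percent of
# maximum exposure". Tien et al. 2013 theoretical values.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_N_POINTS = 960  # Shrake-Rupley quadrature points per atom
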