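"""Residue classification sets and hydrophobicity scale.

The interface weight of the threading score counts receptor residues that are
hydrophobic or ionic. The sets below are the package defaults; every entry
point that uses them records the resolved sets in its run provenance so a user
override is always visible.
"""

from __future__ import annotations

# Hydrophobic side chains (aliphatic + aromatic + C, P).
HYDROPHOBIC: frozenset[str] = frozenset("AVLIMFWCP")

# Ionizable side chains; split by charge sign for the contact potential.
NEGATIVE: frozenset[str] = frozenset("DE")
POSITIVE: frozenset[str] = frozenset("KRH")
IONIC: frozenset[str] = NEGATIVE | POSITIVE

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy index (J. Mol. Biol. 157:105, 1982).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Heavy-atom distance (Angstrom) under which two residues are in contact.
CONTACT_THRESHOLD = 5.0
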