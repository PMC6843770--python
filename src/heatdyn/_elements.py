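"""Standard atomic weights and element inference from atom names.

Masses are assigned from the element, never read from coordinate files
(PDB/GRO carry none). Weights are IUPAC 2021 conventional values, amu.
"""

from __future__ import annotations

ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "D": 2.014, "HE": 4.0026,
    "LI": 6.94, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "AL": 26.982, "SI": 28.085,
    "P": 30.974, "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "MN": 54.938, "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546,
    "ZN": 65.38, "SE": 78.971, "BR": 79.904, "I": 126.904,
}

#: Residue names treated as standard amino acids (bead atom: CA).
AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common force-field / structure variants
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "CYM", "ASH", "GLH",
    "LYN", "MSE",
})

#: Residue names treated as nucleotides (bead atom: P).
NUCLEOTIDES = frozenset({
    "A", "C", "G", "U", "T", "I",
    "RA", "RC", "RG", "RU",
    "DA", "DC", "DG", "DT", "DU", "DI",
    "A3", "A5", "C3", "C5", "G3", "G5", "U3", "U5",
})

_TWO_LETTER = {"CL", "BR", "MG", "ZN", "MN", "FE", "NA", "CA", "NI", "CU",
               "SE", "CO", "HE", "LI", "AL", "SI"}


def element_from_name(atom_name: str, residue_name: str = "") -> str:
    """Infer the element symbol from a PDB-style atom name.

    Follows PDB conventions: digits stripped, hydrogens may be
    digit-prefixed (``1HB``), two-letter elements are only accepted for
    ions/hetero residues so that ``CA`` in an amino acid stays carbon.
    """
    name = atom_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():  # e.g. 1HB2
        name = name.lstrip("0123456789")
    if not name:
        raise ValueError(f"atom name {atom_name!r} has no letters")
    res = residue_name.strip().upper()
    if res in AMINO_ACIDS or res in NUCLEOTIDES:
        # within polymers one-letter elements only (CA = alpha carbon)
        sym = name[0]
        if sym == "H" or name.startswith("H"):
            return "H"
        if res == "MSE" and name.startswith("SE"):
            return "SE"
        return sym
    head = name[:2]
    if head in _TWO_LETTER and (len(name) == 2 or res == head or res in _TWO_LETTER):
        return head
    if head in _TWO_LETTER and head == res:
        return head
    return name[0]


def mass_of(element: str) -> float:
    """Standard atomic weight (amu) of *element*; raises for unknown symbols."""
    try:
        return ATOMIC_WEIGHTS[element.strip().upper()]
    except KeyError:
        raise KeyError(f"no standard atomic weight for element {element!r}") from None
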