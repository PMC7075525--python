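"""Static chemical tables shared across modules.

All values are standard reference data: heavy-atom compositions of the 20
proteinogenic amino acids, maximum solvent accessibilities (Tien et al.
theoretical maxima), hard-sphere radii used by the clash term, and the
amino-acid grouping used by the torsion potential.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "C",
}

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Heavy atoms of each residue type (PDB v3 names).  Together these define
#: the chemically-distinguishable heavy-atom alphabet used by the all-atom
#: interaction and packing potentials.
RESIDUE_HEAVY_ATOMS = {
    "A": ["N", "CA", "C", "O", "CB"],
    "R": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "N": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "D": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "C": ["N", "CA", "C", "O", "CB", "SG"],
    "Q": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "E": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "G": ["N", "CA", "C", "O"],
    "H": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "I": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "L": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "K": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "M": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "F": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "P": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "S": ["N", "CA", "C", "O", "CB", "OG"],
    "T": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "W": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
          "CE3", "CZ2", "CZ3", "CH2"],
    "Y": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
          "CZ", "OH"],
    "V": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}

#: Flat (aa, atom_name) -> integer alphabet over all residue heavy atoms.
ATOM_TYPES = {
    (aa, name): i
    for i, (aa, name) in enumerate(
        (aa, name) for aa in AMINO_ACIDS for name in RESIDUE_HEAVY_ATOMS[aa]
    )
}
N_ATOM_TYPES = len(ATOM_TYPES)

#: Theoretical maximum solvent accessibility in A^2 (Tien et al. 2013),
#: used to scale absolute accessibilities to relative ones.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Hard-sphere radii (A) by element, SCWRL3 convention.
CLASH_RADII = {"C": 1.6, "N": 1.3, "O": 1.3, "S": 1.7}
CLASH_LINEAR_ONSET = 0.8254  # penalty saturates at this fraction of R_ij
CLASH_MAX_PENALTY = 10.0

HYDROPHOBIC = set("AVLIMFWC")


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB heavy-atom name ('CA' -> 'C')."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper()


def torsion_group(sequence: str, index: int) -> int:
    """Amino-acid group used by the torsion potential's triplet key.

    Five groups: glycine, proline, pre-proline (any residue immediately
    preceding a proline), hydrophobic, polar.
    """
    aa = sequence[index]
    if aa == "G":
        return 0
    if aa == "P":
        return 1
    if index + 1 < len(sequence) and sequence[index + 1] == "P":
        return 2
    if aa in HYDROPHOBIC:
        return 3
    return 4


N_TORSION_GROUPS = 5
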