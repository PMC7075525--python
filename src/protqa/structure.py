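"""Structure model and PDB/FASTA input-output.

The in-memory representation is deliberately light: a :class:`Structure` is
an ordered list of :class:`Residue` objects for one polymer chain, indexed
contiguously from zero.  Author residue numbering is kept only as metadata;
every downstream computation indexes the extracted polymer sequence.

Parsing and writing go through biotite; alternate locations are resolved to
the highest-occupancy variant at read time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .constants import THREE_TO_ONE, ONE_TO_THREE, element_of
from .geometry import place_atom


class StructureError(ValueError):
    """Raised for unreadable or empty structure input."""


@dataclass
class Residue:
    index: int                      # 0-based position in the polymer
    number: int                     # author residue number
    icode: str                      # author insertion code ('' if none)
    aa: str                         # one-letter code, 'X' if non-standard
    atoms: dict = field(default_factory=dict)  # atom name -> np.ndarray (3,)

    @property
    def has_backbone(self) -> bool:
        return all(n in self.atoms for n in ("N", "CA", "C"))

    @property
    def ca(self):
        return self.atoms.get("CA")


@dataclass
class Structure:
    id: str
    residues: list

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i) -> Residue:
        return self.residues[i]

    # -- cached flat views -------------------------------------------------

    def atom_table(self):
        """Flat arrays (coords, residue indices, atom names) over all atoms."""
        coords, res_idx, names = [], [], []
        for r in self.residues:
            for name, xyz in r.atoms.items():
                coords.append(xyz)
                res_idx.append(r.index)
                names.append(name)
        if not coords:
            return np.zeros((0, 3)), np.zeros(0, dtype=int), []
        return np.asarray(coords, dtype=float), np.asarray(res_idx), names

    def ca_array(self):
        """(n, 3) array of Calpha coordinates with NaN for missing ones."""
        out = np.full((len(self.residues), 3), np.nan)
        for r in self.residues:
            if r.ca is not None:
                out[r.index] = r.ca
        return out

    def transformed(self, rotation=None, translation=None) -> "Structure":
        """Rigid-body copy (used by invariance tests and the generator)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation)
        trans = np.zeros(3) if translation is None else np.asarray(translation)
        residues = [
            Residue(r.index, r.number, r.icode, r.aa,
                    {n: rot @ xyz + trans for n, xyz in r.atoms.items()})
            for r in self.residues
        ]
        return Structure(self.id, residues)


def _structure_from_atom_array(array, struct_id: str) -> Structure:
    amino = bst.filter_amino_acids(array)
    array = array[amino & (array.element != "H") & (array.element != "D")]
    if array.array_length() == 0:
        raise StructureError(f"{struct_id}: no amino-acid residues found")
    residues = []
    for start in bst.get_residue_starts(array):
        res_mask = (
            (array.chain_id == array.chain_id[start])
            & (array.res_id == array.res_id[start])
            & (array.ins_code == array.ins_code[start])
        )
        sub = array[res_mask]
        aa = THREE_TO_ONE.get(sub.res_name[0], "X")
        atoms = {}
        for i in range(sub.array_length()):
            name = sub.atom_name[i]
            if name not in atoms:  # keep first occurrence per canonical name
                atoms[name] = np.asarray(sub.coord[i], dtype=float)
        residues.append(
            Residue(
                index=len(residues),
                number=int(sub.res_id[0]),
                icode=str(sub.ins_code[0]),
                aa=aa,
                atoms=atoms,
            )
        )
    return Structure(struct_id, residues)


def read_pdb(path, chain: str | None = None) -> Structure:
    """Read one polymer chain from a PDB file.

    HETATM records, waters and hydrogens are discarded; for alternate
    locations the highest-occupancy variant is kept.  If *chain* is None the
    first chain containing amino acids is used.
    """
    path = Path(path)
    try:
        pdb_file = bpdb.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    amino = bst.filter_amino_acids(array)
    if not amino.any():
        raise StructureError(f"{path}: no amino-acid residues found")
    if chain is None:
        chain = array.chain_id[amino][0]
    array = array[array.chain_id == chain]
    return _structure_from_atom_array(array, path.stem)


def structure_from_pdb_text(text: str, struct_id: str = "structure",
                            chain: str | None = None) -> Structure:
    """Parse PDB-format text (convenience for tests and fixtures)."""
    pdb_file = bpdb.PDBFile.read(io.StringIO(text))
    array = pdb_file.get_structure(model=1, altloc="occupancy")
    amino = bst.filter_amino_acids(array)
    if not amino.any():
        raise StructureError(f"{struct_id}: no amino-acid residues found")
    if chain is None:
        chain = array.chain_id[amino][0]
    return _structure_from_atom_array(array[array.chain_id == chain], struct_id)


def extract_sequence(s: Structure) -> str:
    if len(s) == 0:
        raise StructureError("empty structure has no sequence")
    return "".join(r.aa for r in s)


def ca_distance_map(s: Structure, cutoff: float) -> dict:
    """Unordered residue pairs (i, j), i < j, with Calpha distance < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = s.ca_array()
    valid = ~np.isnan(ca[:, 0])
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return {}
    d = np.linalg.norm(ca[idx, None, :] - ca[None, idx, :], axis=-1)
    out = {}
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            if d[a, b] < cutoff:
                out[(int(idx[a]), int(idx[b]))] = float(d[a, b])
    return out


# Ideal Cbeta internal coordinates relative to the backbone frame.
_CB_BOND = 1.53
_CB_ANGLE = 110.4      # N-CA-CB
_CB_DIHEDRAL = 122.55  # C-N-CA-CB improper (L-amino acids)


def infer_cb(residue: Residue):
    """Cbeta representative: the real CB if present, otherwise the ideal
    tetrahedral position constructed from N, CA, C.  Returns None when the
    backbone is incomplete (feature-invalid, not an error)."""
    if "CB" in residue.atoms:
        return residue.atoms["CB"]
    if not residue.has_backbone:
        return None
    return place_atom(
        residue.atoms["C"], residue.atoms["N"], residue.atoms["CA"],
        _CB_BOND, _CB_ANGLE, _CB_DIHEDRAL,
    )


def to_atom_array(s: Structure, b_factors=None):
    """Convert to a biotite AtomArray (for SASA and PDB writing)."""
    n_atoms = sum(len(r.atoms) for r in s.residues)
    array = bst.AtomArray(n_atoms)
    array.set_annotation("b_factor", np.zeros(n_atoms))
    i = 0
    for r in s.residues:
        b = 0.0 if b_factors is None else float(b_factors[r.index])
        for name, xyz in r.atoms.items():
            array.coord[i] = xyz
            array.chain_id[i] = "A"
            array.res_id[i] = r.number
            array.ins_code[i] = r.icode
            array.res_name[i] = ONE_TO_THREE.get(r.aa, "UNK")
            array.atom_name[i] = name
            array.element[i] = element_of(name)
            array.hetero[i] = False
            array.b_factor[i] = b
            i += 1
    return array


INVALID_BFACTOR = 99.99


def write_pdb(s: Structure, path) -> None:
    array = to_atom_array(s)
    f = bpdb.PDBFile()
    f.set_structure(array)
    f.write(str(path))


def write_scored_pdb(s: Structure, per_residue_scores, path) -> None:
    """Write the structure with per-residue scores x100 in the B-factor
    column; invalid scores (None/NaN) become the 99.99 sentinel."""
    if len(per_residue_scores) != len(s):
        raise ValueError("one score per residue required")
    b = []
    for v in per_residue_scores:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            b.append(INVALID_BFACTOR)
        else:
            b.append(round(float(v) * 100.0, 2))
    array = to_atom_array(s, b_factors=b)
    f = bpdb.PDBFile()
    f.set_structure(array)
    f.write(str(path))


def read_fasta(path) -> tuple[str, str]:
    """First record (id, sequence) of a FASTA file."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise StructureError(f"{path}: no FASTA records")
    return rec.id, str(rec.seq).upper()
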