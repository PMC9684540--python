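"""Backbone PDB reading and writing.

Only the backbone subset (N, CA, C, O) is handled; chains are written with
chain id 'A' and poly-glycine residue names until a sequence has been
designed.  Reading keeps the highest-occupancy altloc and rejects residues
with missing backbone atoms, naming the residue.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import BACKBONE_ATOMS, BackboneChain, chain_from_coords

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class PDBFormatError(ValueError):
    pass


def _prescan(path: Path) -> None:
    """Cheap structural validation so errors can name the offending line."""
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBFormatError(f"{path}: line {lineno}: truncated ATOM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise PDBFormatError(f"{path}: line {lineno}: {exc}") from exc


def read_pdb(path) -> tuple[BackboneChain, str]:
    """Read the first model's backbone; returns (chain, one-letter sequence).

    Residues missing any of N/CA/C/O are rejected with a residue-level
    message; the highest-occupancy altloc wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    _prescan(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[np.isin(atoms.atom_name, BACKBONE_ATOMS) & ~atoms.hetero]
    if atoms.array_length() == 0:
        raise PDBFormatError(f"{path}: no backbone atoms found")
    coords = []
    seq = []
    one_letter = {v: k for k, v in _THREE.items()}
    for res_atoms in struc.residue_iter(atoms):
        res_id = int(res_atoms.res_id[0])
        res_name = str(res_atoms.res_name[0])
        pos = {}
        for name in BACKBONE_ATOMS:
            sel = res_atoms[res_atoms.atom_name == name]
            if sel.array_length() == 0:
                raise PDBFormatError(
                    f"{path}: residue {res_name} {res_id} is missing atom {name}"
                )
            pos[name] = sel.coord[0]
        coords.append([pos[name] for name in BACKBONE_ATOMS])
        seq.append(one_letter.get(res_name, "X"))
    return chain_from_coords(np.array(coords)), "".join(seq)


def write_pdb(chain: BackboneChain, path, sequence: str | None = None) -> None:
    """Write the backbone as fixed-width PDB (chain 'A').

    Coordinates survive a write -> read round trip to 1e-3 A, the format's
    precision.  Without a designed sequence residues are written as GLY.
    """
    n = len(chain)
    if sequence is not None and len(sequence) != n:
        raise ValueError("sequence length mismatch")
    atoms = struc.AtomArray(n * 4)
    coords = chain.coords.reshape(n * 4, 3)
    atoms.coord = coords
    atoms.chain_id = np.full(n * 4, "A")
    atoms.res_id = np.repeat(np.arange(1, n + 1), 4)
    names = np.tile(np.array(BACKBONE_ATOMS), n)
    atoms.atom_name = names
    atoms.element = np.where(names == "N", "N", np.where(names == "O", "O", "C"))
    res_names = [
        _THREE.get(sequence[i], "GLY") if sequence else "GLY" for i in range(n)
    ]
    atoms.res_name = np.repeat(np.array(res_names), 4)
    atoms.hetero = np.zeros(n * 4, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
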