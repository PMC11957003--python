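"""Atomic structure parsing and atom-class assignment.

Heavy atoms are grouped into six classes used by the atom-type label volume:

====== =========================================================
class  meaning
====== =========================================================
0      everything else (side-chain carbons, S, P, metals, ligand atoms)
1      C-alpha of an amino-acid residue
2      C-beta of an amino-acid residue
3      backbone carbonyl carbon of an amino-acid residue
4      any oxygen atom
5      any nitrogen atom
====== =========================================================

Oxygen and nitrogen classes apply to all O/N atoms, backbone or side chain,
protein or not. The carbon classes require the element to actually be carbon
and the residue to be an amino acid, so e.g. a calcium ion whose atom name is
"CA" stays in class 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi

__all__ = [
    "AtomRecord",
    "Structure",
    "StructureFormatError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "classify_atom",
    "ATOM_CLASS_NAMES",
]

ATOM_CLASS_NAMES = {
    0: "other",
    1: "CA",
    2: "CB",
    3: "carbonyl C",
    4: "O",
    5: "N",
}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed structure contains no heavy atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with its residue context and Cartesian position (Angstrom)."""

    element: str
    atom_name: str
    residue_name: str
    chain_id: str
    coord: tuple[float, float, float]  # (x, y, z)
    occupancy: float = 1.0


@dataclass
class Structure:
    """An ordered collection of heavy atoms from one model."""

    atoms: list[AtomRecord] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self):
        """(N, 3) array of (x, y, z) coordinates in Angstrom."""
        import numpy as np

        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def classify_atom(atom: AtomRecord) -> int:
    """Map a heavy atom to its atom-type class in {0..5}.

    Total function: every atom receives a class, with 0 as the catch-all.
    """
    element = atom.element.strip().upper()
    if element == "O":
        return 4
    if element == "N":
        return 5
    if element == "C" and _is_amino_acid(atom.residue_name):
        name = atom.atom_name.strip().upper()
        if name == "CA":
            return 1
        if name == "CB":
            return 2
        if name == "C":
            return 3
    return 0


def read_structure(path: str | os.PathLike) -> Structure:
    """Parse a PDB or mmCIF file into the package's atom list.

    Returns all heavy atoms (element != H/D) of the first model, in file
    order. Waters are excluded; for alternate conformations only the first
    altloc is kept.

    Raises
    ------
    StructureFormatError
        If the file cannot be parsed.
    EmptyStructureError
        If no heavy atoms remain after filtering.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureFormatError(f"cannot parse structure {path!r}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()

    atoms: list[AtomRecord] = []
    if len(st) > 0:
        for chain in st[0]:
            for residue in chain:
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    atoms.append(
                        AtomRecord(
                            element=atom.element.name,
                            atom_name=atom.name,
                            residue_name=residue.name,
                            chain_id=chain.name,
                            coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                            occupancy=atom.occ,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"no heavy atoms found in {path!r}")
    return Structure(atoms=atoms, source_id=st.name or str(path))


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write the atom list as a single-model PDB (or mmCIF by extension).

    Atoms are grouped into residues whenever the (chain, residue_name) context
    repeats consecutively with a new backbone nitrogen; the writer exists so
    synthetic fixtures can be handed to external tools, not for archival
    round-tripping of deposited entries.
    """
    st = gemmi.Structure()
    st.name = structure.source_id or "cryolabel"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    seqid: dict[str, int] = {}
    for atom in structure.atoms:
        if atom.chain_id not in chains:
            chains[atom.chain_id] = gemmi.Chain(atom.chain_id)
            seqid[atom.chain_id] = 0
        chain = chains[atom.chain_id]
        start_new = (
            len(chain) == 0
            or chain[-1].name != atom.residue_name
            or atom.atom_name.strip().upper() == "N"
        )
        if start_new:
            seqid[atom.chain_id] += 1
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(seqid[atom.chain_id], " ")
            chain.add_residue(res)
        g_atom = gemmi.Atom()
        g_atom.name = atom.atom_name
        g_atom.element = gemmi.Element(atom.element)
        g_atom.pos = gemmi.Position(*atom.coord)
        g_atom.occ = atom.occupancy
        chain[-1].add_atom(g_atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
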