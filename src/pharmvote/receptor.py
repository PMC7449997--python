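"""Receptor conformations: a light atom-table view of one ligand-free protein frame.

A receptor conformation is one snapshot of the protein (e.g. an MD frame with
the ligand removed).  Only the information downstream stages need is kept:
element, atom/residue naming, chain, coordinates and a backbone flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: heavy backbone atom names; the C-terminal carboxyl OXT counts as backbone.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Atom:
    element: str
    atom_name: str
    residue_name: str
    residue_number: int
    chain: str
    coords: np.ndarray  # (3,) Å

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOMS


@dataclass
class ReceptorConformation:
    """One ligand-free receptor snapshot."""

    frame_index: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a receptor conformation needs at least one atom")
        for a in self.atoms:
            a.coords = np.asarray(a.coords, dtype=float)
            if not np.all(np.isfinite(a.coords)):
                raise ValueError(f"non-finite coordinates for atom {a.atom_name}")

    def coords_array(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain, residue_number), in file order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.residue_number), []).append(a)
        return out


def _element_from_pdb(name: str, element_field: str) -> str:
    el = element_field.strip()
    if el:
        return el[0].upper() + el[1:].lower()
    # fall back to the atom-name convention: first alphabetic character
    for ch in name.strip():
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(path: str | Path, frame_index: int = 0) -> ReceptorConformation:
    """Read ATOM/HETATM records of a single-model PDB file.

    Uses Biopython when the file parses cleanly; falls back to direct
    fixed-column parsing for minimal dialects (e.g. files without element
    columns).  Residue numbering is kept 1-based as in the file.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                if line.startswith("ENDMDL"):
                    break  # first model only
                continue
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or "A"
            resnum = int(line[22:26])
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            element = _element_from_pdb(name, line[76:78] if len(line) >= 78 else "")
            atoms.append(Atom(element, name, resname, resnum, chain, xyz))
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    return ReceptorConformation(frame_index=frame_index, atoms=atoms)


def write_pdb(conf: ReceptorConformation, path: str | Path) -> None:
    """Write a minimal single-model PDB file readable by read_pdb and standard tools."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, a in enumerate(conf.atoms, start=1):
            name = a.atom_name
            # PDB rule: 1-3 char names start in column 14
            pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            fh.write(
                f"ATOM  {i:5d} {pname}{'':1s}{a.residue_name:>3s} {a.chain:1s}"
                f"{a.residue_number:4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


def read_pdb_biopython(path: str | Path, frame_index: int = 0) -> ReceptorConformation:
    """Biopython-backed PDB reader (permissive mode); same output contract as read_pdb."""
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(PERMISSIVE=True, QUIET=True).get_structure("r", str(path))
    atoms: list[Atom] = []
    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        element=at.element.capitalize() if at.element else "X",
                        atom_name=at.get_name(),
                        residue_name=res.get_resname().strip(),
                        residue_number=res.get_id()[1],
                        chain=chain.get_id() or "A",
                        coords=np.asarray(at.get_coord(), dtype=float),
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return ReceptorConformation(frame_index=frame_index, atoms=atoms)
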