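"""Multi-conformer molecule libraries with typed feature points.

Two input routes:

* SDF with explicit 3D coordinates — chemistry is perceived with RDKit's
  published pharmacophore feature definitions (BaseFeatures.fdef: Donor,
  Acceptor, Aromatic, Hydrophobe, PosIonizable, NegIonizable).  Repeated
  records sharing a name are grouped as conformers of one member.
* a feature-cloud JSON dialect carrying pre-typed feature points and heavy
  atom coordinates directly — the synthetic generator's native format, so
  the geometric matcher is testable independently of chemistry perception.

Tautomers / protonation states are grouped under a single molecule id by
stripping a trailing ``_<integer>`` suffix from member names, so variants
of one compound share one vote.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MOLECULE_FEATURE_TYPES = (
    "donor",
    "acceptor",
    "hydrophobic",
    "aromatic",
    "positive_ion",
    "negative_ion",
)


class PerceptionError(ValueError):
    """Molecule lacks usable 3D coordinates for feature perception."""


@dataclass
class FeaturePoint:
    ftype: str
    coords: np.ndarray
    direction: np.ndarray | None = None

    def __post_init__(self):
        if self.ftype not in MOLECULE_FEATURE_TYPES:
            raise ValueError(f"unknown molecule feature type {self.ftype!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("feature point coordinates must be finite")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(self.direction)
            self.direction = self.direction / n if n > 0 else None


@dataclass
class Conformer:
    conformer_id: str
    heavy_atom_coords: np.ndarray  # (n, 3)
    feature_points: list[FeaturePoint] = field(default_factory=list)

    def __post_init__(self):
        self.heavy_atom_coords = np.atleast_2d(
            np.asarray(self.heavy_atom_coords, dtype=float)
        )
        if self.heavy_atom_coords.shape[0] < 1:
            raise ValueError("a conformer needs at least one heavy atom")


@dataclass
class MoleculeEntry:
    """One library molecule: tautomer members, each with 3D conformers."""

    molecule_id: str
    members: dict[str, list[Conformer]] = field(default_factory=dict)

    def __post_init__(self):
        if not any(self.members.values()):
            raise ValueError("a molecule entry needs at least one conformer")

    def all_conformers(self):
        for member_id, confs in self.members.items():
            for c in confs:
                yield member_id, c


_TAUTOMER_SUFFIX = re.compile(r"_\d+$")


def normalize_molecule_id(name: str, suffix_pattern: re.Pattern = _TAUTOMER_SUFFIX) -> str:
    """Group tautomer/protonation-state names: strip a trailing ``_<int>``."""
    return suffix_pattern.sub("", name.strip())


# ---------------------------------------------------------------------------
# RDKit perception
# ---------------------------------------------------------------------------

_FAMILY_TO_FTYPE = {
    "Donor": "donor",
    "Acceptor": "acceptor",
    "Aromatic": "aromatic",
    "Hydrophobe": "hydrophobic",
    "PosIonizable": "positive_ion",
    "NegIonizable": "negative_ion",
}

_factory = None


def _feature_factory():
    global _factory
    if _factory is None:
        import os

        from rdkit import RDConfig
        from rdkit.Chem import ChemicalFeatures

        _factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
    return _factory


def perceive_features(mol) -> list[FeaturePoint]:
    """Typed feature points of an RDKit molecule with one 3D conformer.

    Donor points carry a direction toward the mean attached-hydrogen
    position when explicit hydrogens are present.
    """
    from rdkit import Chem

    if mol is None:
        raise PerceptionError("molecule failed to parse")
    if mol.GetNumConformers() == 0:
        raise PerceptionError("molecule has no 3D coordinates")
    conf = mol.GetConformer()
    if not conf.Is3D():
        raise PerceptionError("molecule coordinates are not 3D")
    pos = conf.GetPositions()
    out: list[FeaturePoint] = []
    for feat in _feature_factory().GetFeaturesForMol(mol):
        ftype = _FAMILY_TO_FTYPE.get(feat.GetFamily())
        if ftype is None:
            continue
        center = np.array(list(feat.GetPos()), dtype=float)
        direction = None
        if ftype == "donor":
            # direction: heavy donor atom -> its hydrogens (mean)
            heavy = feat.GetAtomIds()[0]
            hs = [
                n.GetIdx()
                for n in mol.GetAtomWithIdx(heavy).GetNeighbors()
                if n.GetAtomicNum() == 1
            ]
            if hs:
                v = pos[hs].mean(axis=0) - pos[heavy]
                n = np.linalg.norm(v)
                if n > 0:
                    direction = v / n
        out.append(FeaturePoint(ftype=ftype, coords=center, direction=direction))
    return out


def _heavy_coords(mol) -> np.ndarray:
    pos = mol.GetConformer().GetPositions()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    return pos[heavy]


def read_sdf_library(path: str | Path) -> list[MoleculeEntry]:
    """Read a multi-conformer SDF: records sharing a title are conformers of
    one member; members sharing a tautomer-normalized id form one molecule."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    members: dict[str, list[Conformer]] = {}
    order: list[str] = []
    anon = 0
    for mol in supplier:
        if mol is None:
            continue
        name = (mol.GetProp("_Name") if mol.HasProp("_Name") else "").strip()
        if not name:
            anon += 1
            name = f"mol{anon}"
        feats = perceive_features(mol)
        conf = Conformer(
            conformer_id=f"{name}/c{len(members.get(name, []))}",
            heavy_atom_coords=_heavy_coords(mol),
            feature_points=feats,
        )
        if name not in members:
            order.append(name)
        members.setdefault(name, []).append(conf)
    entries: dict[str, MoleculeEntry] = {}
    entry_order: list[str] = []
    for name in order:
        mol_id = normalize_molecule_id(name)
        if mol_id not in entries:
            entries[mol_id] = MoleculeEntry(molecule_id=mol_id, members={name: members[name]})
            entry_order.append(mol_id)
        else:
            entries[mol_id].members.setdefault(name, []).extend(members[name])
    return [entries[i] for i in entry_order]


# ---------------------------------------------------------------------------
# feature-cloud JSON dialect
# ---------------------------------------------------------------------------

def write_feature_cloud(entries: list[MoleculeEntry], path: str | Path) -> None:
    doc = []
    for e in entries:
        members = []
        for member_id, confs in e.members.items():
            cl = []
            for c in confs:
                cl.append(
                    {
                        "atoms": [[float(v) for v in row] for row in c.heavy_atom_coords],
                        "features": [
                            {
                                "type": f.ftype,
                                "x": float(f.coords[0]),
                                "y": float(f.coords[1]),
                                "z": float(f.coords[2]),
                                **(
                                    {
                                        "dx": float(f.direction[0]),
                                        "dy": float(f.direction[1]),
                                        "dz": float(f.direction[2]),
                                    }
                                    if f.direction is not None
                                    else {}
                                ),
                            }
                            for f in c.feature_points
                        ],
                    }
                )
            members.append({"member_id": member_id, "conformers": cl})
        doc.append({"molecule_id": e.molecule_id, "members": members})
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_feature_cloud(path: str | Path) -> list[MoleculeEntry]:
    with open(path) as fh:
        doc = json.load(fh)
    entries = []
    for rec in doc:
        members: dict[str, list[Conformer]] = {}
        for mem in rec["members"]:
            confs = []
            for i, c in enumerate(mem["conformers"]):
                feats = [
                    FeaturePoint(
                        ftype=f["type"],
                        coords=[f["x"], f["y"], f["z"]],
                        direction=(
                            [f["dx"], f["dy"], f["dz"]] if "dx" in f else None
                        ),
                    )
                    for f in c["features"]
                ]
                confs.append(
                    Conformer(
                        conformer_id=f"{mem['member_id']}/c{i}",
                        heavy_atom_coords=np.asarray(c["atoms"], dtype=float),
                        feature_points=feats,
                    )
                )
            members[mem["member_id"]] = confs
        entries.append(MoleculeEntry(molecule_id=rec["molecule_id"], members=members))
    return entries


def read_labels(path: str | Path) -> dict[str, str]:
    """TSV of (molecule_id, ligand|decoy)."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mol_id, label = line.split("\t")[:2]
            if label not in ("ligand", "decoy"):
                raise ValueError(f"label must be ligand|decoy, got {label!r}")
            labels[mol_id] = label
    return labels


def read_library(path: str | Path) -> list[MoleculeEntry]:
    """Dispatch on extension: .sdf or feature-cloud .json."""
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        return read_sdf_library(path)
    if path.suffix.lower() == ".json":
        return read_feature_cloud(path)
    raise ValueError(f"unsupported library format: {path.suffix}")
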