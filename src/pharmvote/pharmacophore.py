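"""3-point pharmacophores with volume-exclusion spheres, plus Pharmer JSON export.

A pharmacophore is every combination of three features from one
(frame, active space) whose pairwise centers respect the coexistence rule
(features of *different* type may not sit closer than 1 Å).  Steric realism
comes from volume-exclusion spheres: radius 0.5 Å on each backbone heavy
atom and 1.5 Å on each residue side-chain center of mass — deliberately
small so slightly larger ligand groups still fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .features import ActiveSpace, PharmFeature
from .receptor import ReceptorConformation

logger = logging.getLogger(__name__)

BACKBONE_EXCLUSION_RADIUS = 0.5  # Å
SIDECHAIN_EXCLUSION_RADIUS = 1.5  # Å

DEFAULT_COEXISTENCE_MIN_DIST = 1.0  # Å


@dataclass
class ExclusionSphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("exclusion radius must be positive")


@dataclass
class Pharmacophore:
    """Exactly three features plus the frame's exclusion spheres."""

    features: list[PharmFeature]
    exclusions: list[ExclusionSphere] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    coexistence_min_dist: float = DEFAULT_COEXISTENCE_MIN_DIST

    def __post_init__(self):
        if len(self.features) != 3:
            raise ValueError("a pharmacophore has exactly 3 features")
        for f1, f2 in combinations(self.features, 2):
            if not coexistence_allowed(f1, f2, self.coexistence_min_dist):
                raise ValueError(
                    "features of different type closer than the coexistence limit"
                )


@dataclass
class PharmacophoreSet:
    """Union of the pharmacophores of one frame over its active spaces."""

    frame_index: int
    pharmacophores: list[Pharmacophore] = field(default_factory=list)

    def __len__(self):
        return len(self.pharmacophores)


def volume_exclusion(receptor: ReceptorConformation) -> list[ExclusionSphere]:
    """One 0.5 Å sphere per backbone heavy atom; one 1.5 Å sphere per residue
    side-chain center of mass (unweighted heavy-atom mean; glycine has none)."""
    spheres: list[ExclusionSphere] = []
    for atoms in receptor.residues().values():
        side = []
        for a in atoms:
            if a.element == "H":
                continue
            if a.is_backbone:
                spheres.append(ExclusionSphere(a.coords.copy(), BACKBONE_EXCLUSION_RADIUS))
            else:
                side.append(a.coords)
        if side:
            com = np.mean(side, axis=0)
            spheres.append(ExclusionSphere(com, SIDECHAIN_EXCLUSION_RADIUS))
    return spheres


def coexistence_allowed(
    f1: PharmFeature, f2: PharmFeature, min_dist: float = DEFAULT_COEXISTENCE_MIN_DIST
) -> bool:
    """Different-type features closer than min_dist may not coexist (strict <);
    same-type pairs are always allowed."""
    if f1.ftype == f2.ftype:
        return True
    return float(np.linalg.norm(f1.center - f2.center)) >= min_dist


def enumerate_pharmacophores(
    features: list[PharmFeature],
    exclusions: list[ExclusionSphere],
    space: ActiveSpace,
    frame: int,
    coexistence_min_dist: float = DEFAULT_COEXISTENCE_MIN_DIST,
) -> list[Pharmacophore]:
    """All C(n,3) feature triples whose three pairs are coexistence-allowed.

    Features are assumed already restricted to the active space.  Output
    order is the lexicographic order of feature indices, so enumeration is
    deterministic.
    """
    n = len(features)
    if n < 3:
        logger.warning(
            "frame %s space %s: only %d features, no pharmacophores", frame, space.id, n
        )
        return []
    out = []
    for i, j, k in combinations(range(n), 3):
        trio = (features[i], features[j], features[k])
        if (
            coexistence_allowed(trio[0], trio[1], coexistence_min_dist)
            and coexistence_allowed(trio[0], trio[2], coexistence_min_dist)
            and coexistence_allowed(trio[1], trio[2], coexistence_min_dist)
        ):
            out.append(
                Pharmacophore(
                    features=list(trio),
                    exclusions=exclusions,
                    provenance={"frame": frame, "active_space": space.id, "indices": (i, j, k)},
                    coexistence_min_dist=coexistence_min_dist,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pharmer JSON
# ---------------------------------------------------------------------------

_PHARMER_NAMES = {
    "aromatic": "Aromatic",
    "donor": "HydrogenDonor",
    "acceptor": "HydrogenAcceptor",
    "hydrophobic": "Hydrophobic",
}
_PHARMER_ION = {"positive": "PositiveIon", "negative": "NegativeIon"}
_FTYPE_FROM_PHARMER = {v: k for k, v in _PHARMER_NAMES.items()}


class PharmerExportError(ValueError):
    pass


def export_pharmer_json(
    p: Pharmacophore,
    path: str | Path,
    ion_sign: str | None = None,
    min_radius: float = 0.5,
) -> None:
    """Write a Pharmer-compatible pharmacophore query.

    Ionic features require an explicit ``ion_sign`` ("positive"/"negative")
    because the grid probe's charge sign is not modeled here.  Point radii
    are floored at ``min_radius`` so zero-rgyr single-cell features remain
    matchable by external tools.
    """
    points = []
    for f in p.features:
        if f.ftype in _PHARMER_NAMES:
            name = _PHARMER_NAMES[f.ftype]
        elif f.ftype in ("ion_dipole", "ion_ion"):
            if ion_sign not in _PHARMER_ION:
                raise PharmerExportError(
                    "exporting ionic features requires ion_sign='positive' or 'negative'"
                )
            name = _PHARMER_ION[ion_sign]
        else:
            raise PharmerExportError(f"no Pharmer name for feature type {f.ftype!r}")
        entry = {
            "name": name,
            "x": float(f.center[0]),
            "y": float(f.center[1]),
            "z": float(f.center[2]),
            "radius": float(max(f.rgyr, min_radius)),
            "enabled": True,
        }
        if f.direction is not None:
            entry["vector"] = [
                {
                    "x": float(f.direction[0]),
                    "y": float(f.direction[1]),
                    "z": float(f.direction[2]),
                }
            ]
            entry["vector_on"] = 1
        points.append(entry)
    for s in p.exclusions:
        points.append(
            {
                "name": "ExclusionSphere",
                "x": float(s.center[0]),
                "y": float(s.center[1]),
                "z": float(s.center[2]),
                "radius": float(s.radius),
                "enabled": True,
            }
        )
    with open(path, "w") as fh:
        json.dump({"points": points}, fh, indent=1)


def read_pharmer_json(path: str | Path) -> tuple[list[dict], list[ExclusionSphere]]:
    """Re-import a Pharmer query written by export_pharmer_json.

    Returns (feature point dicts, exclusion spheres); feature dicts carry
    name/center/radius/direction.  Used for round-trip validation and for
    loading externally edited queries.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats, excl = [], []
    for pt in doc.get("points", []):
        center = np.array([pt["x"], pt["y"], pt["z"]], dtype=float)
        if pt["name"] == "ExclusionSphere":
            excl.append(ExclusionSphere(center, float(pt["radius"])))
        else:
            vec = None
            if pt.get("vector"):
                v = pt["vector"][0]
                vec = np.array([v["x"], v["y"], v["z"]], dtype=float)
            feats.append(
                {
                    "name": pt["name"],
                    "ftype": _FTYPE_FROM_PHARMER.get(pt["name"]),
                    "center": center,
                    "radius": float(pt["radius"]),
                    "direction": vec,
                }
            )
    return feats, excl
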