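"""Pharmacophoric features from grid hotspots.

The best *x*% of negative-energy grid points form "hotspots": connected
clusters of favorable cells for one probe type.  Each cluster becomes one
feature with an energy-weighted center of mass and radius of gyration; the
radius doubles later as the matching tolerance.  H-bond features carry a
direction toward the nearest chemically complementary receptor atom.
Ion-ion interactions are treated separately: a fixed-radius (4.0 Å) feature
is placed on the charged-group atom of each Arg/Lys/Glu/Asp side chain
inside the active space.  Only features centered inside the active-space
sphere (default radius 5 Å around the grid center) are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridMap
from .receptor import ReceptorConformation

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("donor", "acceptor", "hydrophobic", "aromatic", "ion_dipole", "ion_ion")

ION_ION_RGYR = 4.0  # Å, fixed by convention for charged-residue features
ION_ION_ATOMS = {"ARG": "CZ", "LYS": "NZ", "GLU": "CD", "ASP": "CG"}

#: interaction class -> feature type (identity here, but kept explicit)
FTYPE_FOR_CLASS = {c: c for c in FEATURE_TYPES}


@dataclass
class ActiveSpace:
    """Sphere centered at the grid-map center restricting feature placement."""

    id: str
    center: np.ndarray
    radius: float = 5.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("active-space radius must be positive")

    def contains(self, point) -> bool:
        return float(np.linalg.norm(np.asarray(point) - self.center)) <= self.radius


@dataclass
class HotspotConfig:
    """Hotspot-selection knobs.

    x_percent is the grid-percentage threshold: the fraction (of the
    negative-energy points) selected as hotspot cells.  Published working
    values are 0.3, 0.5 and 0.7 (%); results are largely insensitive within
    that range.
    """

    x_percent: float = 0.7
    adjacency: str = "full_26"  # or "faces_6"
    coexistence_min_dist: float = 1.0  # Å

    def __post_init__(self):
        if not 0 < self.x_percent <= 100:
            raise ValueError("x_percent must be in (0, 100]")
        if self.adjacency not in ("full_26", "faces_6"):
            raise ValueError(f"unknown adjacency {self.adjacency!r}")


@dataclass
class Hotspot:
    """Connected cluster of selected grid cells from one map."""

    cells: list[tuple[int, int, int]]
    energies: np.ndarray  # kcal/mol, all < 0
    atom_type: str
    interaction_class: str

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.cells) == 0:
            raise ValueError("empty hotspot")
        if len(self.cells) != len(self.energies):
            raise ValueError("cells/energies length mismatch")
        if not np.all(self.energies < 0):
            raise ValueError("hotspot member energies must be negative")


@dataclass
class PharmFeature:
    """One typed pharmacophoric point."""

    ftype: str
    center: np.ndarray
    rgyr: float
    direction: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.rgyr < 0:
            raise ValueError("radius of gyration must be non-negative")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            nrm = np.linalg.norm(self.direction)
            if not np.isclose(nrm, 1.0, atol=1e-6):
                raise ValueError("direction must be a unit vector")
            if self.ftype not in ("donor", "acceptor"):
                raise ValueError("only H-bond features carry a direction")
        if self.ftype == "ion_ion" and not np.isclose(self.rgyr, ION_ION_RGYR):
            raise ValueError(f"ion_ion features have rgyr {ION_ION_RGYR} exactly")


def select_hotspot_cells(grid: GridMap, x_percent: float) -> list[tuple[int, int, int]]:
    """Indices of the k = floor(x/100 * N_neg) lowest-energy negative points.

    Ties at the cutoff energy break by lexicographic (ix, iy, iz) order, so
    selection is fully deterministic.
    """
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    e = grid.energies
    neg_idx = np.argwhere(e < 0)
    n_neg = len(neg_idx)
    k = int(np.floor(x_percent / 100.0 * n_neg + 1e-9))  # guard: 0.7% of 1000 is 7
    if k == 0:
        return []
    neg_e = e[neg_idx[:, 0], neg_idx[:, 1], neg_idx[:, 2]]
    # argwhere already yields lexicographic index order; stable sort on energy
    # therefore breaks energy ties lexicographically.
    order = np.argsort(neg_e, kind="stable")[:k]
    return [tuple(int(v) for v in neg_idx[i]) for i in order]


_STRUCTURES = {
    "full_26": np.ones((3, 3, 3), dtype=bool),
    "faces_6": ndimage.generate_binary_structure(3, 1),
}


def cluster_cells(
    cells: list[tuple[int, int, int]], adjacency: str = "full_26"
) -> list[list[tuple[int, int, int]]]:
    """Partition cells into connected components under the adjacency rule.

    Components are ordered by (size descending, then smallest member index),
    so output is deterministic.
    """
    if adjacency not in _STRUCTURES:
        raise ValueError(f"unknown adjacency {adjacency!r}")
    if not cells:
        return []
    arr = np.asarray(cells, dtype=int)
    lo = arr.min(axis=0)
    occ = np.zeros(arr.max(axis=0) - lo + 1, dtype=bool)
    occ[tuple((arr - lo).T)] = True
    labels, n = ndimage.label(occ, structure=_STRUCTURES[adjacency])
    comps: dict[int, list[tuple[int, int, int]]] = {}
    for cell, rel in zip(cells, arr - lo):
        comps.setdefault(int(labels[tuple(rel)]), []).append(cell)
    out = [sorted(v) for v in comps.values()]
    out.sort(key=lambda c: (-len(c), c[0]))
    return out


def hotspots_from_map(
    grid: GridMap,
    interaction_class: str,
    config: HotspotConfig | None = None,
) -> list[Hotspot]:
    """Select the top-x% cells of a retained map and cluster them into hotspots."""
    config = config or HotspotConfig()
    cells = select_hotspot_cells(grid, config.x_percent)
    clusters = cluster_cells(cells, config.adjacency)
    return [
        Hotspot(
            cells=c,
            energies=np.array([grid.energies[i] for i in c]),
            atom_type=grid.atom_type,
            interaction_class=interaction_class,
        )
        for c in clusters
    ]


def feature_from_hotspot(
    h: Hotspot, grid: GridMap, provenance: dict | None = None
) -> PharmFeature:
    """Energy-weighted center of mass and radius of gyration of one hotspot.

    Weights are |E| of the (strictly negative) member energies, so the most
    favorable cells dominate the feature position.
    """
    xyz = grid.index_coords(np.asarray(h.cells, dtype=float))
    w = np.abs(h.energies)
    center = (xyz * w[:, None]).sum(axis=0) / w.sum()
    if len(h.cells) == 1:
        rgyr = 0.0
    else:
        rgyr = float(np.sqrt((w * ((xyz - center) ** 2).sum(axis=1)).sum() / w.sum()))
    ftype = FTYPE_FOR_CLASS[h.interaction_class]
    return PharmFeature(
        ftype=ftype, center=center, rgyr=rgyr, provenance=dict(provenance or {})
    )


def _bonded_hydrogens(receptor: ReceptorConformation, max_bond: float = 1.25):
    """Hydrogens within bonding distance of an N/O heavy atom."""
    hs = [a for a in receptor.atoms if a.element == "H"]
    if not hs:
        return []
    no = [a for a in receptor.atoms if a.element in ("N", "O")]
    if not no:
        return []
    no_xyz = np.array([a.coords for a in no])
    out = []
    for h in hs:
        d = np.linalg.norm(no_xyz - h.coords, axis=1)
        if d.min() <= max_bond:
            out.append(h)
    return out


def _acceptor_counterparts(receptor: ReceptorConformation):
    """Receptor atoms a *donor* feature points at: O, plus N with no bound H."""
    hs = [a.coords for a in receptor.atoms if a.element == "H"]
    hs_xyz = np.array(hs) if hs else None
    out = []
    for a in receptor.atoms:
        if a.element == "O":
            out.append(a)
        elif a.element == "N":
            if hs_xyz is None:
                out.append(a)
            elif np.linalg.norm(hs_xyz - a.coords, axis=1).min() > 1.25:
                out.append(a)
    return out


_DONOR_HEAVY_FALLBACK_O = {"OG", "OG1", "OH"}  # Ser/Thr/Tyr hydroxyls


def _donor_counterparts(receptor: ReceptorConformation):
    """Receptor atoms an *acceptor* feature points at: donor hydrogens, or
    (hydrogen-free structures) donor heavy atoms."""
    hd = _bonded_hydrogens(receptor)
    if hd:
        return hd
    return [
        a
        for a in receptor.atoms
        if a.element == "N" or (a.element == "O" and a.atom_name in _DONOR_HEAVY_FALLBACK_O)
    ]


def assign_direction(
    f: PharmFeature, receptor: ReceptorConformation
) -> PharmFeature:
    """Attach a unit direction from the feature center toward the nearest
    chemically complementary receptor atom.  Only H-bond features qualify."""
    if f.ftype not in ("donor", "acceptor"):
        return f
    partners = (
        _acceptor_counterparts(receptor)
        if f.ftype == "donor"
        else _donor_counterparts(receptor)
    )
    if not partners:
        logger.warning("no counterpart atoms for %s feature; direction left unset", f.ftype)
        return f
    xyz = np.array([a.coords for a in partners])
    d = np.linalg.norm(xyz - f.center, axis=1)
    i = int(np.argmin(d))
    if d[i] < 1e-9:
        logger.warning("counterpart coincides with feature center; direction left unset")
        return f
    f.direction = (xyz[i] - f.center) / d[i]
    return f


def ion_ion_features(
    receptor: ReceptorConformation,
    space: ActiveSpace,
    ion_ion_retained: bool,
    frame: int | None = None,
) -> list[PharmFeature]:
    """Fixed-radius electrostatic features on charged side-chain group atoms.

    Emitted only when the charged map passed the ion-ion kurtosis test, in
    parallel with how grid-derived features require a retained map.
    """
    if not ion_ion_retained:
        return []
    out = []
    for a in receptor.atoms:
        if ION_ION_ATOMS.get(a.residue_name) == a.atom_name and space.contains(a.coords):
            out.append(
                PharmFeature(
                    ftype="ion_ion",
                    center=a.coords.copy(),
                    rgyr=ION_ION_RGYR,
                    provenance={
                        "frame": frame,
                        "active_space": space.id,
                        "residue": f"{a.chain}/{a.residue_name}{a.residue_number}",
                    },
                )
            )
    return out


def filter_by_active_space(
    features: list[PharmFeature], space: ActiveSpace
) -> list[PharmFeature]:
    """Keep features centered inside the sphere (boundary inclusive)."""
    return [f for f in features if space.contains(f.center)]


def features_for_frame(
    retained_maps: list[tuple[GridMap, str]],
    receptor: ReceptorConformation,
    space: ActiveSpace,
    config: HotspotConfig | None = None,
    frame: int | None = None,
    with_directions: bool = True,
) -> list[PharmFeature]:
    """All features of one (frame, active space): grid hotspots + ion residues."""
    config = config or HotspotConfig()
    feats: list[PharmFeature] = []
    ion_ion_on = False
    for grid, cls in retained_maps:
        if cls == "ion_ion":
            ion_ion_on = True
            continue  # ion-ion features come from residues, not grid clusters
        for i, h in enumerate(hotspots_from_map(grid, cls, config)):
            f = feature_from_hotspot(
                h, grid, provenance={"frame": frame, "active_space": space.id, "hotspot": i}
            )
            if with_directions:
                f = assign_direction(f, receptor)
            feats.append(f)
    feats = filter_by_active_space(feats, space)
    feats.extend(ion_ion_features(receptor, space, ion_ion_on, frame=frame))
    return feats
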