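"""Rigid 3-point pharmacophore matching with exclusion spheres.

A conformer matches a pharmacophore when some rigid placement (proper
rotation + translation; molecules cannot be mirrored) brings three of its
typed feature points inside the three pharmacophore features' effective
radii without pushing any heavy atom strictly into an exclusion sphere.

The effective radius of a feature is max(rgyr, min_tolerance): single-cell
hotspots have zero radius of gyration and would otherwise be unmatchable.

Search strategy per candidate type-compatible assignment:

1. pairwise-distance pre-filter: |d_conf(i,j) - d_pharm(i,j)| must not
   exceed r_eff_i + r_eff_j — a cheap necessary condition;
2. Kabsch superposition (unweighted, then tolerance-weighted) of the three
   matched points onto the feature centers, restricted to proper rotations;
3. if both seeds violate a per-point bound, a deterministic minimax
   refinement over SO(3) (L-BFGS on the rotation vector) hunts for any
   placement with all residuals inside tolerance — per-point feasibility is
   not identical to the least-squares optimum, and the contract here is
   placement *existence*;
4. collinear triples (either side) leave a free rotation about the line
   axis; these fall back to a deterministic sweep over that one-parameter
   family for both axis orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .library import Conformer, MoleculeEntry
from .pharmacophore import Pharmacophore, PharmacophoreSet

#: pharmacophore feature type -> compatible molecule feature types
COMPATIBLE_TYPES = {
    "donor": ("donor",),
    "acceptor": ("acceptor",),
    "hydrophobic": ("hydrophobic",),
    "aromatic": ("aromatic",),
    "ion_dipole": ("positive_ion", "negative_ion"),
    "ion_ion": ("positive_ion", "negative_ion"),
}

_COLLINEAR_TOL = 1e-8
_EPS = 1e-9


@dataclass
class MatchOptions:
    min_tolerance: float = 0.5  # Å floor on effective feature radius
    angle_tolerance: float = 45.0  # degrees, for directed features
    use_directions: bool = False

    def __post_init__(self):
        if self.min_tolerance <= 0:
            raise ValueError("min_tolerance must be positive")
        if not 0 < self.angle_tolerance <= 180:
            raise ValueError("angle_tolerance must be in (0, 180]")


def _kabsch(P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None):
    """Optimal proper rotation R and translation t with R@p + t ≈ q."""
    if weights is None:
        weights = np.ones(len(P))
    w = weights / weights.sum()
    pc = (P * w[:, None]).sum(axis=0)
    qc = (Q * w[:, None]).sum(axis=0)
    H = (w[:, None] * (P - pc)).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _is_collinear(pts: np.ndarray) -> bool:
    v1 = pts[1] - pts[0]
    v2 = pts[2] - pts[0]
    return float(np.linalg.norm(np.cross(v1, v2))) < _COLLINEAR_TOL * max(
        1.0, np.linalg.norm(v1) * np.linalg.norm(v2)
    )


def _residuals_ok(R, t, P, Q, r_eff) -> bool:
    res = np.linalg.norm((P @ R.T + t) - Q, axis=1)
    return bool(np.all(res <= r_eff + _EPS))


def _minimax_rotation(P, Q, r_eff):
    """Search SO(3) for a rotation whose per-point residuals (after optimal
    translation = centroid alignment) all fit inside tolerance.

    Deterministic: L-BFGS from a fixed small set of rotation-vector starts.
    Returns (R, t) or None.
    """
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - pc, Q - qc

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        res = np.linalg.norm(Pc @ R.T - Qc, axis=1) - r_eff
        # smooth max for optimizer stability
        return float(np.logaddexp.reduce(res * 50.0) / 50.0)

    R0, _ = _kabsch(P, Q)
    starts = [Rotation.from_matrix(R0).as_rotvec()]
    for ax in np.eye(3):
        starts.append(Rotation.from_matrix(R0).as_rotvec() + 0.35 * ax)
    for rv0 in starts:
        out = minimize(cost, rv0, method="L-BFGS-B")
        R = Rotation.from_rotvec(out.x).as_matrix()
        t = qc - R @ pc
        if _residuals_ok(R, t, P, Q, r_eff):
            return R, t
    return None


def _axis_family_transforms(P, Q, n_angles: int = 180):
    """Candidate transforms when either triple is collinear: align best-fit
    line directions (both senses) and sweep the free rotation about the axis."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)

    def line_dir(X):
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc)
        return Vt[0]

    u, v = line_dir(P), line_dir(Q)
    for sense in (1.0, -1.0):
        # rotation taking u -> sense*v
        target = sense * v
        cross = np.cross(u, target)
        dot = float(np.dot(u, target))
        if np.linalg.norm(cross) < 1e-12:
            R_align = np.eye(3) if dot > 0 else Rotation.from_rotvec(
                np.pi * _any_perpendicular(u)
            ).as_matrix()
        else:
            axis = cross / np.linalg.norm(cross)
            angle = np.arctan2(np.linalg.norm(cross), dot)
            R_align = Rotation.from_rotvec(axis * angle).as_matrix()
        for theta in np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False):
            R = Rotation.from_rotvec(target * theta).as_matrix() @ R_align
            yield R, qc - R @ pc


def _any_perpendicular(u):
    v = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, v)) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, v)
    return w / np.linalg.norm(w)


def _placement_ok(R, t, conformer, pharm, assigned_points, opt) -> bool:
    """Exclusion and direction checks under one rigid transform."""
    atoms = conformer.heavy_atom_coords @ R.T + t
    for s in pharm.exclusions:
        if np.any(np.linalg.norm(atoms - s.center, axis=1) < s.radius - _EPS):
            return False
    if opt.use_directions:
        cos_tol = np.cos(np.deg2rad(opt.angle_tolerance))
        for f, fp in zip(pharm.features, assigned_points):
            if f.direction is None or fp.direction is None:
                continue
            if float(np.dot(R @ fp.direction, f.direction)) < cos_tol - _EPS:
                return False
    return True


def match_conformer(
    conformer: Conformer, pharm: Pharmacophore, opt: MatchOptions | None = None
) -> bool:
    """True iff some rigid placement satisfies all three feature tolerances,
    the exclusion spheres and (optionally) the direction cones."""
    opt = opt or MatchOptions()
    Q = np.array([f.center for f in pharm.features])
    r_eff = np.array([max(f.rgyr, opt.min_tolerance) for f in pharm.features])
    d_pharm = np.linalg.norm(Q[:, None, :] - Q[None, :, :], axis=-1)

    candidates: list[list[int]] = []
    for f in pharm.features:
        ok_types = COMPATIBLE_TYPES[f.ftype]
        idxs = [i for i, fp in enumerate(conformer.feature_points) if fp.ftype in ok_types]
        if not idxs:
            return False
        candidates.append(idxs)

    pts = np.array([fp.coords for fp in conformer.feature_points]).reshape(-1, 3)
    seen = set()
    for a0 in candidates[0]:
        for a1 in candidates[1]:
            if a1 == a0:
                continue
            for a2 in candidates[2]:
                if a2 in (a0, a1):
                    continue
                key = (a0, a1, a2)
                if key in seen:
                    continue
                seen.add(key)
                P = pts[[a0, a1, a2]]
                # (i) pairwise-distance pre-filter
                ok = True
                for i, j in ((0, 1), (0, 2), (1, 2)):
                    dij = np.linalg.norm(P[i] - P[j])
                    if abs(dij - d_pharm[i, j]) > r_eff[i] + r_eff[j] + _EPS:
                        ok = False
                        break
                if not ok:
                    continue
                assigned = [conformer.feature_points[i] for i in (a0, a1, a2)]
                if _is_collinear(P) or _is_collinear(Q):
                    for R, t in _axis_family_transforms(P, Q):
                        if _residuals_ok(R, t, P, Q, r_eff) and _placement_ok(
                            R, t, conformer, pharm, assigned, opt
                        ):
                            return True
                    continue
                # (ii) superposition seeds, then minimax refinement
                placed = None
                for w in (None, 1.0 / r_eff**2):
                    R, t = _kabsch(P, Q, w)
                    if _residuals_ok(R, t, P, Q, r_eff):
                        placed = (R, t)
                        break
                if placed is None:
                    placed = _minimax_rotation(P, Q, r_eff)
                if placed is None:
                    continue
                if _placement_ok(*placed, conformer, pharm, assigned, opt):
                    return True
    return False


def match_molecule(
    m: MoleculeEntry, ps: PharmacophoreSet, opt: MatchOptions | None = None
) -> bool:
    """True iff any conformer of any tautomer member matches any pharmacophore
    of the frame's set; short-circuits on first success."""
    opt = opt or MatchOptions()
    for _, conf in m.all_conformers():
        for p in ps.pharmacophores:
            if match_conformer(conf, p, opt):
                return True
    return False
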