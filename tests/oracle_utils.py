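"""Independent brute-force oracles shared between unit and acceptance tests."""

import numpy as np
from scipy.spatial.transform import Rotation

from pharmvote.matcher import COMPATIBLE_TYPES


def random_rigid_transform(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t


def transform_search_match(conformer, pharm, opt, rng, n_rotations=3000):
    """Randomized placement-existence oracle for 3-point matching.

    For every type-compatible assignment, samples proper rotations and uses
    centroid-aligning translations; accepts when all three points land inside
    their effective radii, no heavy atom enters an exclusion sphere and
    (if enabled) directions agree.  A found placement is always genuine;
    the search may miss marginal placements, so it lower-bounds the matcher.
    """
    Q = np.array([f.center for f in pharm.features])
    r_eff = np.array([max(f.rgyr, opt.min_tolerance) for f in pharm.features])
    rots = Rotation.random(n_rotations, rng=rng).as_matrix()
    pts = np.array([fp.coords for fp in conformer.feature_points]).reshape(-1, 3)
    qc = Q.mean(axis=0)

    cand = []
    for f in pharm.features:
        ok = [i for i, fp in enumerate(conformer.feature_points)
              if fp.ftype in COMPATIBLE_TYPES[f.ftype]]
        if not ok:
            return False
        cand.append(ok)
    for a0 in cand[0]:
        for a1 in cand[1]:
            if a1 == a0:
                continue
            for a2 in cand[2]:
                if a2 in (a0, a1):
                    continue
                P = pts[[a0, a1, a2]]
                pc = P.mean(axis=0)
                # all rotations at once: (n, 3, 3) @ (3, 3pts)
                rp = np.einsum("nij,kj->nki", rots, P - pc)
                res = np.linalg.norm(rp + qc - Q, axis=2)  # (n, 3)
                hits = np.where(np.all(res <= r_eff, axis=1))[0]
                for h in hits:
                    R = rots[h]
                    t = qc - R @ pc
                    if _placement_ok(R, t, conformer, pharm, (a0, a1, a2), opt):
                        return True
    return False


def _placement_ok(R, t, conformer, pharm, assignment, opt):
    atoms = conformer.heavy_atom_coords @ R.T + t
    for s in pharm.exclusions:
        if np.any(np.linalg.norm(atoms - s.center, axis=1) < s.radius - 1e-9):
            return False
    if opt.use_directions:
        cos_tol = np.cos(np.deg2rad(opt.angle_tolerance))
        for f, idx in zip(pharm.features, assignment):
            fp = conformer.feature_points[idx]
            if f.direction is None or fp.direction is None:
                continue
            if float(np.dot(R @ fp.direction, f.direction)) < cos_tol:
                return False
    return True
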