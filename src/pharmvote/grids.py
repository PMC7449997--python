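"""Affinity grid maps: AutoGrid-format I/O, acceptor-map combination and a
simplified internal affinity calculator.

A grid map stores probe-atom interaction energies (kcal/mol) on a regular
cubic lattice around the binding site.  The on-disk format is the autogrid4
``.map`` layout: six header lines (GRID_PARAMETER_FILE, GRID_DATA_FILE,
MACROMOLECULE, SPACING, NELEMENTS, CENTER) followed by one energy per line
with the x index varying fastest.  A map declared ``NELEMENTS nx ny nz``
carries (nx+1)(ny+1)(nz+1) values (grid *points*, not cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .receptor import ReceptorConformation

ATOM_TYPES = (
    "donor",
    "acceptor_O",
    "acceptor_N",
    "acceptor_S",
    "acceptor_combined",
    "hydrophobic",
    "aromatic",
    "charged",
)

#: default box geometry: 12.5 Å per side at 0.25 Å spacing -> 50 intervals/axis
DEFAULT_BOX_SIDE = 12.5
DEFAULT_SPACING = 0.25


class GridFormatError(ValueError):
    """Raised for malformed AutoGrid map files."""


class IncompatibleGridError(ValueError):
    """Raised when maps to be combined do not share geometry."""


@dataclass
class GridMap:
    """One probe-atom affinity map on a regular grid.

    ``energies[ix, iy, iz]`` is the interaction energy (kcal/mol) at the grid
    point with coordinate ``center - (n/2)*spacing + i*spacing`` per axis.
    """

    atom_type: str
    center: np.ndarray  # (3,) Å
    spacing: float  # Å
    n_intervals: tuple[int, int, int]  # even; points per axis = n + 1
    energies: np.ndarray  # (nx+1, ny+1, nz+1)
    label: str = ""

    def __post_init__(self):
        if self.atom_type not in ATOM_TYPES:
            raise ValueError(f"unknown atom type {self.atom_type!r}")
        self.center = np.asarray(self.center, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        nx, ny, nz = self.n_intervals
        if self.energies.shape != (nx + 1, ny + 1, nz + 1):
            raise ValueError(
                f"energies shape {self.energies.shape} does not match "
                f"NELEMENTS {self.n_intervals}"
            )
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("grid energies must be finite")

    @property
    def n_points(self) -> int:
        return int(np.prod([n + 1 for n in self.n_intervals]))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.n_intervals[axis]
        return self.center[axis] - (n / 2) * self.spacing + np.arange(n + 1) * self.spacing

    def point_coords(self) -> np.ndarray:
        """Cartesian coordinates of every grid point, shape (nx+1, ny+1, nz+1, 3)."""
        ax = [self.axis_coords(i) for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def index_coords(self, idx) -> np.ndarray:
        """Coordinates of grid points given integer index triplets (k, 3)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        n = np.asarray(self.n_intervals, dtype=float)
        return self.center - (n / 2) * self.spacing + idx * self.spacing

    def same_geometry(self, other: "GridMap") -> bool:
        return (
            np.allclose(self.center, other.center)
            and np.isclose(self.spacing, other.spacing)
            and self.n_intervals == other.n_intervals
        )


def read_autogrid_map(path: str | Path) -> GridMap:
    """Read an autogrid4-format ``.map`` file."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise GridFormatError(f"{path}: fewer than 6 header lines")
    header = lines[:6]
    expect = (
        "GRID_PARAMETER_FILE",
        "GRID_DATA_FILE",
        "MACROMOLECULE",
        "SPACING",
        "NELEMENTS",
        "CENTER",
    )
    for line, key in zip(header, expect):
        tokens = line.split()
        if not tokens or tokens[0] != key:
            raise GridFormatError(f"{path}: expected header line {key!r}, got {line!r}")
    try:
        spacing = float(header[3].split()[1])
        nel = tuple(int(v) for v in header[4].split()[1:4])
        center = np.array([float(v) for v in header[5].split()[1:4]])
    except (IndexError, ValueError) as exc:
        raise GridFormatError(f"{path}: malformed header value: {exc}") from exc
    if len(nel) != 3:
        raise GridFormatError(f"{path}: NELEMENTS needs 3 integers: {header[4]!r}")
    n_values = int(np.prod([n + 1 for n in nel]))
    data = lines[6:]
    # trailing blank lines are tolerated
    while data and not data[-1].strip():
        data.pop()
    if len(data) != n_values:
        raise GridFormatError(
            f"{path}: expected {n_values} energy values for NELEMENTS "
            f"{nel}, found {len(data)} (truncated or padded file)"
        )
    values = np.array([float(v) for v in data])
    # file order: x fastest, then y, then z  ->  C-order array is (z, y, x)
    energies = values.reshape(nel[2] + 1, nel[1] + 1, nel[0] + 1).transpose(2, 1, 0)
    label = header[0].partition(" ")[2].strip()
    # atom type is not part of the format; caller may retag.  Use a neutral default.
    return GridMap(
        atom_type="hydrophobic" if "atomtype=" not in label else label.split("atomtype=")[1].split()[0],
        center=center,
        spacing=spacing,
        n_intervals=nel,
        energies=energies,
        label=label,
    )


def write_autogrid_map(grid: GridMap, path: str | Path) -> None:
    """Write an autogrid4-format ``.map`` file (energies at 3 decimals)."""
    if not np.all(np.isfinite(grid.energies)):
        raise ValueError("refusing to write non-finite grid energies")
    path = Path(path)
    nx, ny, nz = grid.n_intervals
    label = grid.label or f"atomtype={grid.atom_type}"
    if "atomtype=" not in label:
        label = f"{label} atomtype={grid.atom_type}".strip()
    with open(path, "w") as fh:
        fh.write(f"GRID_PARAMETER_FILE {label}\n")
        fh.write("GRID_DATA_FILE pharmvote.maps.fld\n")
        fh.write("MACROMOLECULE receptor.pdbqt\n")
        fh.write(f"SPACING {grid.spacing:g}\n")
        fh.write(f"NELEMENTS {nx} {ny} {nz}\n")
        fh.write(f"CENTER {grid.center[0]:.3f} {grid.center[1]:.3f} {grid.center[2]:.3f}\n")
        # x fastest
        flat = grid.energies.transpose(2, 1, 0).ravel()
        fh.write("\n".join(f"{v:.3f}" for v in flat))
        fh.write("\n")


def combine_acceptor_maps(maps: list[GridMap]) -> GridMap:
    """Combine O/N/S hydrogen-bond acceptor maps into one acceptor map.

    The combined energy at each grid point is the minimum (most favorable)
    over the input maps: a site is an acceptor hotspot if any acceptor
    flavor binds well there.
    """
    if not maps:
        raise ValueError("no maps to combine")
    allowed = {"acceptor_O", "acceptor_N", "acceptor_S", "acceptor_combined"}
    for m in maps:
        if m.atom_type not in allowed:
            raise ValueError(f"not an acceptor map: {m.atom_type}")
        if not m.same_geometry(maps[0]):
            raise IncompatibleGridError(
                "acceptor maps differ in center/spacing/dimensions"
            )
    energies = np.minimum.reduce([m.energies for m in maps])
    return GridMap(
        atom_type="acceptor_combined",
        center=maps[0].center.copy(),
        spacing=maps[0].spacing,
        n_intervals=maps[0].n_intervals,
        energies=energies,
        label="combined O/N/S acceptor",
    )


# ---------------------------------------------------------------------------
# simplified internal affinity calculator
# ---------------------------------------------------------------------------

@dataclass
class ProbeParams:
    """Pairwise-energy parameters for one probe type.

    lj_eps/lj_r0 define a 12-6 well against every receptor heavy atom;
    hbond_depth adds a Gaussian attraction at the ideal H-bond distance
    (1.9 Å) to complementary receptor atoms; coulomb_k adds a signed 1/r
    term to formally charged receptor groups.
    """

    lj_eps: float = 0.05  # kcal/mol
    lj_r0: float = 3.4  # Å
    hbond_depth: float = 0.0  # kcal/mol
    hbond_dist: float = 1.9  # Å
    hbond_width: float = 0.35  # Å
    coulomb_k: float = 0.0  # kcal·Å/mol (signed by receptor group charge)


DEFAULT_PROBE_PARAMS: dict[str, ProbeParams] = {
    "donor": ProbeParams(hbond_depth=2.5),
    "acceptor_O": ProbeParams(hbond_depth=2.5),
    "acceptor_N": ProbeParams(hbond_depth=2.0),
    "acceptor_S": ProbeParams(hbond_depth=1.0),
    "hydrophobic": ProbeParams(lj_eps=0.15, lj_r0=3.8),
    "aromatic": ProbeParams(lj_eps=0.12, lj_r0=3.7),
    "charged": ProbeParams(coulomb_k=12.0),
}

#: receptor atoms that complement an H-bonding probe
_COMPLEMENT = {
    "donor": lambda a: a.element == "O",  # probe donates to receptor O
    "acceptor_O": lambda a: a.element == "N",  # probe accepts from receptor N-H
    "acceptor_N": lambda a: a.element == "N",
    "acceptor_S": lambda a: a.element == "N",
}

#: formal charges of ionizable side-chain group atoms
_CHARGED_GROUP = {
    ("ARG", "CZ"): +1.0,
    ("LYS", "NZ"): +1.0,
    ("GLU", "CD"): -1.0,
    ("ASP", "CG"): -1.0,
}

ENERGY_CLAMP = 100.0  # kcal/mol upper bound on any grid point


def simplified_affinity_map(
    receptor: ReceptorConformation,
    probe: str,
    center,
    box_side: float = DEFAULT_BOX_SIDE,
    spacing: float = DEFAULT_SPACING,
    params: ProbeParams | None = None,
) -> GridMap:
    """Deterministic stand-in affinity calculator.

    Each grid-point energy is a sum over receptor heavy atoms of a
    probe-specific pairwise term (12-6 well, plus a Gaussian H-bond term for
    donor/acceptor probes, plus a signed Coulomb-like term for the charged
    probe), clamped to a finite maximum.  Not a force field — a testable
    surrogate with the right qualitative shape.
    """
    if probe not in ATOM_TYPES or probe == "acceptor_combined":
        raise ValueError(f"unsupported probe type {probe!r}")
    if box_side <= 0:
        raise ValueError("box_side must be positive")
    heavy = receptor.heavy_atoms()
    if not heavy:
        raise ValueError("receptor has no heavy atoms")
    if params is None:
        params = DEFAULT_PROBE_PARAMS[probe]
    center = np.asarray(center, dtype=float)

    n = int(round(box_side / spacing))
    if n % 2:
        n += 1  # keep an even interval count so the center is a grid point
    ax = [center[i] - (n / 2) * spacing + np.arange(n + 1) * spacing for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    coords = np.array([a.coords for a in heavy])
    # pairwise distances in chunks to bound memory
    energies = np.zeros(len(pts))
    comp = _COMPLEMENT.get(probe)
    comp_mask = (
        np.array([comp(a) for a in heavy]) if comp is not None else np.zeros(len(heavy), bool)
    )
    charges = np.array(
        [_CHARGED_GROUP.get((a.residue_name, a.atom_name), 0.0) for a in heavy]
    )
    chunk = 20000
    # complementary atoms interact through the H-bond term alone: the short
    # 1.9 Å contact would otherwise sit inside the generic 12-6 wall
    lj_mask = ~comp_mask if params.hbond_depth else np.ones(len(heavy), bool)
    for s in range(0, len(pts), chunk):
        d = np.linalg.norm(pts[s : s + chunk, None, :] - coords[None, :, :], axis=-1)
        d = np.maximum(d, 0.5)  # keep the r^-12 core finite; clamp handles the wall
        if lj_mask.any():
            sr6 = (params.lj_r0 / d[:, lj_mask]) ** 6
            energies[s : s + chunk] += (params.lj_eps * (sr6 * sr6 - 2.0 * sr6)).sum(
                axis=1
            )
        if params.hbond_depth and comp_mask.any():
            dh = d[:, comp_mask]
            e_h = -params.hbond_depth * np.exp(
                -((dh - params.hbond_dist) ** 2) / (2 * params.hbond_width**2)
            )
            energies[s : s + chunk] += e_h.sum(axis=1)
        if params.coulomb_k and charges.any():
            nz = charges != 0
            energies[s : s + chunk] += (params.coulomb_k * charges[nz] / d[:, nz]).sum(
                axis=1
            )
    energies = np.minimum(energies, ENERGY_CLAMP)
    return GridMap(
        atom_type=probe,
        center=center,
        spacing=spacing,
        n_intervals=(n, n, n),
        energies=energies.reshape(n + 1, n + 1, n + 1),
        label=f"simplified atomtype={probe}",
    )
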