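"""Receptor-specificity filter for affinity maps.

A flat affinity landscape (broad distribution of favorable energies spread
over the box) indicates that the site does not discriminate positions for
that probe type.  Flatness is scored by the Pearson kurtosis of the
histogram of negative grid energies; maps whose kurtosis exceeds a
class-specific threshold are discarded from feature generation.

Thresholds (kurtosis strictly above the value discards):

===========  =========
class        kurtosis
===========  =========
acceptor     3.0
aromatic     3.0
hydrophobic  3.0
donor        4.5
ion_dipole   23.0
ion_ion      50.0
===========  =========

A charged-probe map is evaluated under both ionic classes independently:
the same map may be retained as an ion-dipole map, an ion-ion map, both or
neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridMap

DEFAULT_BIN_WIDTH = 0.01  # kcal/mol

INTERACTION_CLASSES = (
    "donor",
    "acceptor",
    "hydrophobic",
    "aromatic",
    "ion_dipole",
    "ion_ion",
)

#: map atom type -> interaction classes it is screened under
CLASSES_FOR_ATOM_TYPE = {
    "donor": ("donor",),
    "acceptor_combined": ("acceptor",),
    "acceptor_O": ("acceptor",),
    "acceptor_N": ("acceptor",),
    "acceptor_S": ("acceptor",),
    "hydrophobic": ("hydrophobic",),
    "aromatic": ("aromatic",),
    "charged": ("ion_dipole", "ion_ion"),
}


class UndefinedKurtosisError(ValueError):
    """Histogram has fewer than two populated bins or zero variance."""


@dataclass
class AffinityHistogram:
    """Histogram of |E| over strictly negative grid energies."""

    bin_width: float
    bin_edges: np.ndarray  # ascending, length = len(counts) + 1
    counts: np.ndarray  # non-negative ints
    n_negative_cells: int
    atom_type: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges length mismatch")
        if self.counts.sum() != self.n_negative_cells:
            raise ValueError("histogram counts do not sum to n_negative_cells")

    @property
    def is_empty(self) -> bool:
        return self.n_negative_cells == 0

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FilterPolicy:
    """Per-class kurtosis ceilings; strictly larger kurtosis discards the map."""

    kurtosis_max: dict[str, float] = field(
        default_factory=lambda: {
            "acceptor": 3.0,
            "aromatic": 3.0,
            "hydrophobic": 3.0,
            "donor": 4.5,
            "ion_dipole": 23.0,
            "ion_ion": 50.0,
        }
    )

    def __post_init__(self):
        for cls, v in self.kurtosis_max.items():
            if cls not in INTERACTION_CLASSES:
                raise ValueError(f"unknown interaction class {cls!r}")
            if v <= 0:
                raise ValueError("kurtosis thresholds must be positive")


def negative_energy_histogram(
    grid: GridMap, bin_width: float = DEFAULT_BIN_WIDTH
) -> AffinityHistogram:
    """Histogram |E| of strictly negative grid energies with fixed-width bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    neg = np.abs(grid.energies[grid.energies < 0]).ravel()
    if neg.size == 0:
        return AffinityHistogram(
            bin_width=bin_width,
            bin_edges=np.array([0.0, bin_width]),
            counts=np.array([0]),
            n_negative_cells=0,
            atom_type=grid.atom_type,
        )
    n_bins = int(np.ceil(neg.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    # right edge inclusive for the max value
    counts, _ = np.histogram(neg, bins=edges)
    return AffinityHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts,
        n_negative_cells=int(neg.size),
        atom_type=grid.atom_type,
    )


def histogram_kurtosis(hist: AffinityHistogram) -> float:
    """Pearson (non-excess) kurtosis m4/m2^2 from bin centers weighted by counts.

    The normal distribution scores 3; the thresholds in FilterPolicy are
    calibrated against that reference.
    """
    if hist.is_empty or int(np.count_nonzero(hist.counts)) < 2:
        raise UndefinedKurtosisError("need at least two populated bins")
    x = hist.bin_centers()
    w = hist.counts.astype(float)
    mu = np.average(x, weights=w)
    d = x - mu
    m2 = np.average(d**2, weights=w)
    if m2 <= 0:
        raise UndefinedKurtosisError("zero variance histogram")
    m4 = np.average(d**4, weights=w)
    return float(m4 / m2**2)


def apply_specificity_filter(
    maps: list[GridMap],
    policy: FilterPolicy | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> list[tuple[GridMap, str]]:
    """Retain (map, interaction_class) pairs whose kurtosis passes the policy.

    Input should be the per-atom-type map set of one receptor conformation
    with acceptor flavors already combined.  A charged map may contribute up
    to two retained entries (ion_dipole and ion_ion).  Maps with empty or
    degenerate histograms carry no usable signal and are discarded.
    """
    if policy is None:
        policy = FilterPolicy()
    retained: list[tuple[GridMap, str]] = []
    for grid in maps:
        classes = CLASSES_FOR_ATOM_TYPE.get(grid.atom_type)
        if classes is None:
            raise ValueError(f"no interaction class for atom type {grid.atom_type!r}")
        hist = negative_energy_histogram(grid, bin_width=bin_width)
        try:
            kurt = histogram_kurtosis(hist)
        except UndefinedKurtosisError:
            continue  # no favorable signal -> nothing to extract anyway
        for cls in classes:
            if _passes(kurt, policy.kurtosis_max[cls]):
                retained.append((grid, cls))
    return retained


def _passes(kurt: float, threshold: float) -> bool:
    """Discard strictly above threshold, with a 1e-9 relative guard so a
    kurtosis that equals the threshold up to floating-point noise passes."""
    return kurt <= threshold * (1.0 + 1e-9)


def specificity_report(
    maps: list[GridMap],
    policy: FilterPolicy | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> list[dict]:
    """Per (map, class) record of kurtosis and the retain/discard decision."""
    if policy is None:
        policy = FilterPolicy()
    rows = []
    for grid in maps:
        hist = negative_energy_histogram(grid, bin_width=bin_width)
        try:
            kurt = histogram_kurtosis(hist)
        except UndefinedKurtosisError:
            kurt = float("nan")
        for cls in CLASSES_FOR_ATOM_TYPE.get(grid.atom_type, ()):
            retained = bool(np.isfinite(kurt) and _passes(kurt, policy.kurtosis_max[cls]))
            rows.append(
                {
                    "atom_type": grid.atom_type,
                    "interaction_class": cls,
                    "n_negative_cells": hist.n_negative_cells,
                    "kurtosis": kurt,
                    "retained": retained,
                }
            )
    return rows
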