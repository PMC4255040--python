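"""Spherical gold nanoparticles cut from an fcc lattice.

The particle is built by centering a sphere of radius r on a lattice atom
of the conventional fcc cell (lattice constant a, default 0.4078 nm for
gold) and keeping every lattice atom with distance <= r from the center.
The inclusive boundary and atom-centered sphere together fix the atom
count for each radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .model import MASS, Box, Frame, SiteRecord, Topology, Trajectory

__all__ = [
    "GOLD_LATTICE_CONSTANT",
    "FccSphereSpec",
    "NanoparticleCoords",
    "build_fcc_sphere",
    "pairwise_distance_distribution",
    "system_composition",
    "identify_surface_gold",
    "nanoparticle_trajectory",
]

#: conventional fcc lattice constant of bulk gold, nm
GOLD_LATTICE_CONSTANT = 0.4078

#: nearest-neighbour count in bulk fcc
FCC_COORDINATION = 12

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class FccSphereSpec:
    """Sphere-from-lattice construction parameters."""

    radius: float
    lattice_constant: float = GOLD_LATTICE_CONSTANT

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.lattice_constant <= 0:
            raise ValueError("lattice constant must be positive")


@dataclass
class NanoparticleCoords:
    """Atom positions (nm) of a cut fcc sphere, centered at the origin."""

    positions: np.ndarray
    center_index: int
    spec: FccSphereSpec

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def build_fcc_sphere(spec: FccSphereSpec) -> NanoparticleCoords:
    """All fcc lattice atoms within `spec.radius` of an atom at the origin.

    The lattice is generated as conventional cubic cells (corner plus three
    face centers) over a bounding cube of side 2r + 2a, so every candidate
    within the sphere is enumerated.
    """
    a = spec.lattice_constant
    r = spec.radius
    n = int(np.ceil(r / a)) + 1
    cells = np.arange(-n, n + 1)
    i, j, k = np.meshgrid(cells, cells, cells, indexing="ij")
    corners = np.stack([i, j, k], axis=-1).reshape(-1, 3).astype(float) * a
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    ) * a
    pts = (corners[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    keep = np.einsum("ij,ij->i", pts, pts) <= r * r + _BOUNDARY_TOL
    pts = pts[keep]
    # deterministic ordering: by distance, then lexicographic
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    pts = pts[order]
    center_index = int(np.argmin(np.einsum("ij,ij->i", pts, pts)))
    return NanoparticleCoords(pts, center_index, spec)


def pairwise_distance_distribution(
    coords: NanoparticleCoords | np.ndarray,
    bin_width: float = 0.02,
    max_distance: float | None = None,
):
    """Unit-area histogram of all unique interatomic distances.

    Returns a :class:`npbilayer.structure.Histogram`.
    """
    from .structure import Histogram  # local import to avoid a cycle

    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pos = coords.positions if isinstance(coords, NanoparticleCoords) else np.asarray(coords)
    if len(pos) < 2:
        raise ValueError("need at least 2 atoms for a distance distribution")
    d = pdist(pos)
    if max_distance is None:
        max_distance = float(d.max()) + bin_width
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    total = counts.sum()
    heights = counts / (total * bin_width) if total else counts.astype(float)
    return Histogram(edges=edges, heights=heights, normalization="unit_area")


def system_composition(
    n_gold: int,
    n_lipids: int,
    sites_per_lipid: int = 56,
    n_waters: int = 0,
    water_sites: int = 3,
) -> int:
    """Total site count of a gold + lipid + water system."""
    for v in (n_gold, n_lipids, sites_per_lipid, n_waters, water_sites):
        if v < 0:
            raise ValueError("all counts must be >= 0")
    return int(n_gold + n_lipids * sites_per_lipid + n_waters * water_sites)


def identify_surface_gold(
    coords: NanoparticleCoords | np.ndarray,
    neighbor_cutoff: float = 0.35,
) -> np.ndarray:
    """Indices of surface atoms: coordination number below the fcc bulk
    value of 12 within `neighbor_cutoff` (which must sit between the first
    and second fcc neighbour shells, a/sqrt(2) and a)."""
    pos = coords.positions if isinstance(coords, NanoparticleCoords) else np.asarray(coords)
    if len(pos) == 0:
        raise ValueError("need at least one atom")
    tree = cKDTree(pos)
    n_within = tree.query_ball_point(pos, neighbor_cutoff, return_length=True)
    coordination = n_within - 1  # drop self
    return np.flatnonzero(coordination < FCC_COORDINATION)


def nanoparticle_trajectory(coords: NanoparticleCoords, box_margin: float = 1.0) -> Trajectory:
    """Wrap a built particle as a one-frame Trajectory (for GRO export)."""
    pos = coords.positions
    span = pos.max(axis=0) - pos.min(axis=0) + 2 * box_margin
    box = Box(*np.maximum(span, box_margin))
    shifted = pos - pos.min(axis=0) + box_margin
    sites = [SiteRecord(0, "AU", "AU", MASS["AU"]) for _ in range(len(pos))]
    # site_name must be unique per molecule: number the atoms
    sites = [SiteRecord(0, "AU", f"AU{i+1}" if len(pos) > 1 else "AU", MASS["AU"])
             for i in range(len(pos))]
    topo = Topology(sites)
    return Trajectory(topo, [Frame(0.0, shifted, box)])
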