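"""Region-resolved structural observables of bilayer/nanoparticle systems.

Everything here is a time-and-ensemble average over a trajectory window:
partial density profiles along the bilayer normal, 2D water density maps,
head-group-to-gold distance distributions, radial distribution functions,
bond-angle and dihedral distributions, united-atom chain order parameters
(-S_CD), grid-based bilayer thickness, and the long-range area per lipid.

The bilayer normal is fixed to the box z axis.  Mass densities are reported
in kg/m^3 (1 u/nm^3 = 1.66054 kg/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    Box,
    Frame,
    Topology,
    Trajectory,
    assign_leaflets,
    minimum_image_vector,
)
from .regions import BUFFER, LR, SR, RegionBoundaries, RegionTags, tags_at

__all__ = [
    "U_PER_NM3_TO_KG_M3",
    "Histogram",
    "Profile1D",
    "DensityMap2D",
    "OrderProfile",
    "ThicknessField",
    "AreaPerLipidSeries",
    "partial_density_profile",
    "density_map_2d",
    "distance_distribution",
    "rdf",
    "angle_distribution",
    "dihedral_distribution",
    "order_parameter_scd",
    "grid_thickness",
    "area_per_lipid_lr",
]

#: mass-density conversion factor, u/nm^3 -> kg/m^3
U_PER_NM3_TO_KG_M3 = 1.66054

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class Histogram:
    """Binned distribution with a declared normalization."""

    edges: np.ndarray
    heights: np.ndarray
    normalization: str = "unit_area"  # or "per_contributing_atom"
    n_contributing: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def integral(self) -> float:
        return float(np.sum(self.heights * np.diff(self.edges)))


@dataclass
class Profile1D:
    """1D density profile along a box axis."""

    axis: str
    edges: np.ndarray
    values: np.ndarray  # kg/m^3 (mass mode) or nm^-3 (number mode)
    mode: str
    label: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class DensityMap2D:
    """Number density (nm^-3) on a 2D grid, averaged over the third axis."""

    axes: tuple[str, str]
    x_edges: np.ndarray
    z_edges: np.ndarray
    density: np.ndarray  # shape (nx, nz)
    window: tuple[float, float]


@dataclass
class OrderProfile:
    """-S_CD per carbon for one chain and one region subset."""

    chain: str
    carbons: list[str]
    minus_scd: np.ndarray
    region: str | None = None
    n_samples: int = 0


@dataclass
class ThicknessField:
    """Grid bilayer thickness and its distribution over masked cells."""

    grid: tuple[int, int]
    thickness: np.ndarray  # time-mean per cell, nm
    mask: np.ndarray  # True where the cell enters the distribution
    distribution: Histogram


@dataclass
class AreaPerLipidSeries:
    times: np.ndarray
    values: np.ndarray  # nm^2 per frame
    mean: float


def _window(traj: Trajectory, window: tuple[float, float] | None) -> Trajectory:
    if window is None:
        return traj
    return traj.window(*window)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def partial_density_profile(
    traj: Trajectory,
    selection: np.ndarray,
    n_bins: int = 100,
    window: tuple[float, float] | None = None,
    axis: str = "z",
    mode: str = "mass",
    label: str = "",
) -> Profile1D:
    """Mass (kg/m^3) or number (nm^-3) density profile along a box axis,
    frame-averaged over the window.  Coordinates are wrapped into the box
    along the profile axis; the box is taken from the first window frame."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    sub = _window(traj, window)
    ax = _AXIS[axis]
    box = sub.frames[0].box
    L = box.lengths[ax]
    edges = np.linspace(0.0, L, n_bins + 1)
    area = box.volume / L
    masses = sub.topology.masses[selection]
    acc = np.zeros(n_bins)
    for frame in sub.frames:
        c = frame.positions[selection, ax]
        c = c - L * np.floor(c / L)
        w = masses if mode == "mass" else None
        counts, _ = np.histogram(c, bins=edges, weights=w)
        acc += counts
    acc /= sub.n_frames
    bin_vol = area * (L / n_bins)
    values = acc / bin_vol
    if mode == "mass":
        values = values * U_PER_NM3_TO_KG_M3
    return Profile1D(axis=axis, edges=edges, values=values, mode=mode, label=label)


def density_map_2d(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[float, float] | None = None,
    bin_width: float = 0.1,
    axes: tuple[str, str] = ("x", "z"),
) -> DensityMap2D:
    """Number density (nm^-3) binned in two axes, averaged over the third
    axis and over the frames of the window (e.g. water around the AuNP)."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    sub = _window(traj, window)
    a0, a1 = _AXIS[axes[0]], _AXIS[axes[1]]
    a2 = 3 - a0 - a1
    box = sub.frames[0].box
    L0, L1, L2 = box.lengths[a0], box.lengths[a1], box.lengths[a2]
    e0 = np.arange(0.0, L0 + bin_width, bin_width)
    e1 = np.arange(0.0, L1 + bin_width, bin_width)
    acc = np.zeros((len(e0) - 1, len(e1) - 1))
    for frame in sub.frames:
        c = frame.positions[selection][:, [a0, a1]]
        c = c - np.array([L0, L1]) * np.floor(c / np.array([L0, L1]))
        hist, _, _ = np.histogram2d(c[:, 0], c[:, 1], bins=(e0, e1))
        acc += hist
    acc /= sub.n_frames
    d0 = np.diff(e0)[:, None]
    d1 = np.diff(e1)[None, :]
    density = acc / (d0 * d1 * L2)
    t = (sub.frames[0].time, sub.frames[-1].time)
    return DensityMap2D(axes=axes, x_edges=e0, z_edges=e1, density=density, window=t)


# ---------------------------------------------------------------------------
# distance distributions and RDF
# ---------------------------------------------------------------------------


def distance_distribution(
    traj: Trajectory,
    site_names: str | Sequence[str],
    surface_gold_indices: np.ndarray,
    contact_cutoff: float = 1.0,
    vicinity_cutoff: float = 0.6,
    bin_width: float = 0.02,
    headgroup_sites: Sequence[str] | None = None,
    lipid_type: str = "AOPC",
    window: tuple[float, float] | None = None,
    mode: str = "minimum",
) -> Histogram:
    """Distance distribution between named head-group sites and the
    nanoparticle's surface gold atoms.

    Per frame the surface set is restricted to gold atoms within
    `vicinity_cutoff` of any lipid head-group site; each named site within
    `contact_cutoff` of that set contributes its minimum distance
    (``mode="minimum"``, the contact-layer measure) or all its distances
    within the cutoff (``mode="all_pairs"``).  Heights are divided by
    (number of contributing sites x bin width), so the histogram has unit
    area over contributing sites.
    """
    surface_gold_indices = np.asarray(surface_gold_indices)
    if surface_gold_indices.size == 0:
        raise ValueError("no surface gold atoms given")
    sub = _window(traj, window)
    topo = sub.topology
    if headgroup_sites is None:
        from .model import AOPC_HEADGROUP_SITES

        headgroup_sites = AOPC_HEADGROUP_SITES
    head_idx = topo.select(molecule_type=lipid_type, site_name=list(headgroup_sites))
    named_idx = topo.select(molecule_type=lipid_type, site_name=site_names)
    edges = np.arange(0.0, contact_cutoff + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_contrib = 0
    for frame in sub.frames:
        gold = frame.positions[surface_gold_indices]
        # restrict to gold in the vicinity of head groups
        dv = minimum_image_vector(
            gold[:, None, :], frame.positions[head_idx][None, :, :], frame.box
        )
        near = (np.linalg.norm(dv, axis=-1).min(axis=1)) <= vicinity_cutoff
        if not near.any():
            continue
        gnear = gold[near]
        dv = minimum_image_vector(
            frame.positions[named_idx][:, None, :], gnear[None, :, :], frame.box
        )
        d = np.linalg.norm(dv, axis=-1)
        if mode == "minimum":
            dmin = d.min(axis=1)
            contrib = dmin[dmin <= contact_cutoff]
        else:
            contrib = d[d <= contact_cutoff]
        n_contrib += len(contrib)
        c, _ = np.histogram(contrib, bins=edges)
        counts += c
    heights = counts / (n_contrib * bin_width) if n_contrib else counts
    return Histogram(edges=edges, heights=heights,
                     normalization="per_contributing_atom", n_contributing=n_contrib)


def rdf(
    traj: Trajectory,
    ref_selection: np.ndarray,
    target_selection: np.ndarray,
    bin_width: float = 0.02,
    r_max: float | None = None,
    window: tuple[float, float] | None = None,
) -> Histogram:
    """Pair correlation g(r) between two selections, normalized by the
    ideal-gas shell count at the target's mean number density."""
    ref_selection = np.asarray(ref_selection)
    target_selection = np.asarray(target_selection)
    if ref_selection.size == 0 or target_selection.size == 0:
        raise ValueError("rdf selections must be non-empty")
    sub = _window(traj, window)
    box = sub.frames[0].box
    half_min = float(box.lengths.min() / 2.0)
    if r_max is None:
        r_max = half_min
    elif r_max > half_min:
        import warnings

        warnings.warn(f"r_max {r_max} exceeds half the box; clipped to {half_min}")
        r_max = half_min
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    overlap = np.intersect1d(ref_selection, target_selection).size > 0
    for frame in sub.frames:
        dv = minimum_image_vector(
            frame.positions[ref_selection][:, None, :],
            frame.positions[target_selection][None, :, :],
            frame.box,
        )
        d = np.linalg.norm(dv, axis=-1)
        if overlap:
            d = d[d > 1e-9]  # drop self pairs
        c, _ = np.histogram(d, bins=edges)
        counts += c
    counts /= sub.n_frames
    rho = target_selection.size / box.volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = rho * shell * ref_selection.size
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    return Histogram(edges=edges, heights=g, normalization="rdf")


# ---------------------------------------------------------------------------
# angles and dihedrals
# ---------------------------------------------------------------------------


def _region_lipids(
    topo: Topology,
    tags: RegionTags | list[RegionTags] | None,
    region: str | None,
    time: float,
    lipid_type: str,
) -> np.ndarray:
    lipids = topo.lipid_ids(lipid_type)
    if tags is None or region is None:
        return lipids
    t = tags_at(tags, time) if isinstance(tags, list) else tags
    keep = [m for m in lipids if t.labels.get(int(m)) == region]
    return np.array(keep, dtype=int)


def angle_distribution(
    traj: Trajectory,
    site_triplet: Sequence[str],
    tags: RegionTags | list[RegionTags] | None = None,
    region: str | None = None,
    bin_width_deg: float = 2.0,
    window: tuple[float, float] | None = None,
    lipid_type: str = "AOPC",
) -> Histogram:
    """Unit-area distribution of the interior angle at the middle site of
    a bonded triplet (e.g. N-C25-C24), minimum-image displacements."""
    if len(site_triplet) != 3:
        raise ValueError("need exactly three site names")
    sub = _window(traj, window)
    topo = sub.topology
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    counts = np.zeros(len(edges) - 1)
    for frame in sub.frames:
        lipids = _region_lipids(topo, tags, region, frame.time, lipid_type)
        if lipids.size == 0:
            continue
        ia = topo.site_matrix(lipids, site_triplet[0])
        ib = topo.site_matrix(lipids, site_triplet[1])
        ic = topo.site_matrix(lipids, site_triplet[2])
        v1 = minimum_image_vector(frame.positions[ib], frame.positions[ia], frame.box)
        v2 = minimum_image_vector(frame.positions[ib], frame.positions[ic], frame.box)
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        c, _ = np.histogram(ang, bins=edges)
        counts += c
    total = counts.sum()
    heights = counts / (total * bin_width_deg) if total else counts
    return Histogram(edges=edges, heights=heights, normalization="unit_area",
                     n_contributing=int(total))


def dihedral_angles(
    frame: Frame,
    ia: np.ndarray,
    ib: np.ndarray,
    ic: np.ndarray,
    id_: np.ndarray,
) -> np.ndarray:
    """Signed dihedrals a-b-c-d in degrees, IUPAC convention (cis = 0)."""
    p = frame.positions
    b1 = minimum_image_vector(p[ia], p[ib], frame.box)
    b2 = minimum_image_vector(p[ib], p[ic], frame.box)
    b3 = minimum_image_vector(p[ic], p[id_], frame.box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.degrees(np.arctan2(y, x))


def dihedral_distribution(
    traj: Trajectory,
    site_quadruplet: Sequence[str],
    tags: RegionTags | list[RegionTags] | None = None,
    region: str | None = None,
    bin_width_deg: float = 5.0,
    window: tuple[float, float] | None = None,
    lipid_type: str = "AOPC",
) -> Histogram:
    """Unit-area distribution of the signed dihedral of a bonded
    quadruplet (e.g. N-C25-C24-O6) in (-180, 180]."""
    if len(site_quadruplet) != 4:
        raise ValueError("need exactly four site names")
    sub = _window(traj, window)
    topo = sub.topology
    edges = np.arange(-180.0, 180.0 + bin_width_deg, bin_width_deg)
    counts = np.zeros(len(edges) - 1)
    n_skipped = 0
    for frame in sub.frames:
        lipids = _region_lipids(topo, tags, region, frame.time, lipid_type)
        if lipids.size == 0:
            continue
        idx = [topo.site_matrix(lipids, s) for s in site_quadruplet]
        p = frame.positions
        b2 = minimum_image_vector(p[idx[1]], p[idx[2]], frame.box)
        b1 = minimum_image_vector(p[idx[0]], p[idx[1]], frame.box)
        b3 = minimum_image_vector(p[idx[2]], p[idx[3]], frame.box)
        degen = (np.linalg.norm(np.cross(b1, b2), axis=1) < 1e-10) | (
            np.linalg.norm(np.cross(b2, b3), axis=1) < 1e-10
        )
        n_skipped += int(degen.sum())
        if degen.all():
            continue
        phi = dihedral_angles(frame, idx[0][~degen], idx[1][~degen],
                              idx[2][~degen], idx[3][~degen])
        # map exactly -180 to +180 so the domain is (-180, 180]
        phi = np.where(phi <= -180.0 + 1e-9, 180.0, phi)
        c, _ = np.histogram(phi, bins=edges)
        counts += c
    total = counts.sum()
    heights = counts / (total * bin_width_deg) if total else counts
    h = Histogram(edges=edges, heights=heights, normalization="unit_area",
                  n_contributing=int(total))
    h.n_skipped = n_skipped
    return h


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------


def order_parameter_scd(
    traj: Trajectory,
    chain: str = "sn1",
    carbons: Sequence[str] | None = None,
    tags: RegionTags | list[RegionTags] | None = None,
    region: str | None = None,
    window: tuple[float, float] | None = None,
    lipid_type: str = "AOPC",
) -> OrderProfile:
    """United-atom chain order parameter -S_CD per carbon.

    For carbon i the molecular frame is built from its chain neighbours:
    z_mol along C(i-1) -> C(i+1), x_mol normal to the C(i-1),C(i),C(i+1)
    plane, y_mol completing the right-handed frame.  With
    S_aa = <(3 cos^2 theta_a - 1)/2> against the lab bilayer normal,
    S_CD = (2/3) S_xx + (1/3) S_yy and -S_CD is reported, averaged over the
    requested lipids and frames.
    """
    sub = _window(traj, window)
    topo = sub.topology
    if chain not in topo.chains:
        raise ValueError(f"topology has no chain {chain!r}")
    chain_sites = topo.chains[chain]
    if len(chain_sites) < 3:
        raise ValueError("need at least 3 chain carbons")
    if carbons is None:
        carbons = chain_sites[1:-1]  # all with both neighbours
    pos_in_chain = {s: i for i, s in enumerate(chain_sites)}
    for c in carbons:
        i = pos_in_chain.get(c)
        if i is None or i == 0 or i == len(chain_sites) - 1:
            raise ValueError(f"carbon {c!r} lacks a chain neighbour on each side")
    normal = np.array([0.0, 0.0, 1.0])
    sums_xx = np.zeros(len(carbons))
    sums_yy = np.zeros(len(carbons))
    n_samples = np.zeros(len(carbons), dtype=int)
    index_cache: dict[bytes, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for frame in sub.frames:
        lipids = _region_lipids(topo, tags, region, frame.time, lipid_type)
        if lipids.size == 0:
            continue
        key = lipids.tobytes()
        if key not in index_cache:
            index_cache[key] = [
                (
                    topo.site_matrix(lipids, chain_sites[pos_in_chain[c] - 1]),
                    topo.site_matrix(lipids, c),
                    topo.site_matrix(lipids, chain_sites[pos_in_chain[c] + 1]),
                )
                for c in carbons
            ]
        for k, c in enumerate(carbons):
            im, i0, ip = index_cache[key][k]
            p = frame.positions
            v_prev = minimum_image_vector(p[im], p[i0], frame.box)
            v_next = minimum_image_vector(p[i0], p[ip], frame.box)
            zmol = v_prev + v_next  # = C(i-1) -> C(i+1)
            zmol /= np.linalg.norm(zmol, axis=1, keepdims=True)
            xmol = np.cross(v_prev, v_next)
            xmol /= np.linalg.norm(xmol, axis=1, keepdims=True)
            ymol = np.cross(zmol, xmol)
            cx = xmol @ normal
            cy = ymol @ normal
            sums_xx[k] += np.sum(1.5 * cx**2 - 0.5)
            sums_yy[k] += np.sum(1.5 * cy**2 - 0.5)
            n_samples[k] += lipids.size
    if np.any(n_samples == 0):
        raise ValueError("no samples for at least one carbon (empty region subset?)")
    s_xx = sums_xx / n_samples
    s_yy = sums_yy / n_samples
    minus_scd = -(2.0 / 3.0 * s_xx + 1.0 / 3.0 * s_yy)
    return OrderProfile(chain=chain, carbons=list(carbons), minus_scd=minus_scd,
                        region=region, n_samples=int(n_samples[0]))


# ---------------------------------------------------------------------------
# thickness and area per lipid
# ---------------------------------------------------------------------------


def _fill_from_nearest(values: np.ndarray, occupied: np.ndarray,
                       lx: float, ly: float) -> np.ndarray:
    """Fill unoccupied grid cells from the nearest occupied cell, with
    minimum-image distances between cell centers."""
    nx, ny = values.shape
    if occupied.all():
        return values
    if not occupied.any():
        raise ValueError("no occupied cells to fill from")
    cx = (np.arange(nx) + 0.5) * lx / nx
    cy = (np.arange(ny) + 0.5) * ly / ny
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    occ = np.argwhere(occupied)
    occ_x = gx[occupied]
    occ_y = gy[occupied]
    out = values.copy()
    empty = np.argwhere(~occupied)
    for ex, ey in empty:
        dx = gx[ex, ey] - occ_x
        dy = gy[ex, ey] - occ_y
        dx -= lx * np.floor(dx / lx + 0.5)
        dy -= ly * np.floor(dy / ly + 0.5)
        j = np.argmin(dx**2 + dy**2)
        out[ex, ey] = values[occ[j][0], occ[j][1]]
    return out


def grid_thickness(
    traj: Trajectory,
    grid: tuple[int, int] = (50, 50),
    window: tuple[float, float] | None = None,
    bin_width: float = 0.05,
    np_com: np.ndarray | None = None,
    d_buf: float | None = None,
    region_mask: str = "LR",
    lipid_type: str = "AOPC",
    nitrogen_site: str = "N",
) -> ThicknessField:
    """Grid-based bilayer thickness from leaflet nitrogen z coordinates.

    Per frame, N sites are binned into an (nx, ny) grid per leaflet; cell
    thickness is mean(upper N z) - mean(lower N z), empty cells are filled
    from the nearest occupied cell.  With a nanoparticle CoM and buffer
    cutoff, the LR mask keeps cells whose center lies at xy distance
    >= d_buf from the CoM (SR mask: < d_buf).  The distribution collects
    masked cell values over all frames, normalized to unit area.
    """
    sub = _window(traj, window)
    topo = sub.topology
    lipids = topo.lipid_ids(lipid_type)
    leaflets = assign_leaflets(sub.frames[0], topo, None, lipid_type)
    n_idx = {
        lab: topo.site_matrix(leaflets.lipids_in(lab), nitrogen_site)
        for lab in ("upper", "lower")
    }
    for lab, idx in n_idx.items():
        if idx.size == 0:
            raise ValueError(f"{lab} leaflet has no {nitrogen_site} sites")
    nx, ny = grid
    box = sub.frames[0].box
    lx, ly = box.lx, box.ly
    # cell mask from nanoparticle geometry
    mask = np.ones((nx, ny), dtype=bool)
    if np_com is not None and d_buf is not None:
        cx = (np.arange(nx) + 0.5) * lx / nx
        cy = (np.arange(ny) + 0.5) * ly / ny
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        dx = gx - np_com[0]
        dy = gy - np_com[1]
        dx -= lx * np.floor(dx / lx + 0.5)
        dy -= ly * np.floor(dy / ly + 0.5)
        far = np.hypot(dx, dy) >= d_buf
        mask = far if region_mask == "LR" else ~far
    samples: list[np.ndarray] = []
    acc = np.zeros((nx, ny))
    for frame in sub.frames:
        fields = {}
        for lab in ("upper", "lower"):
            p = frame.positions[n_idx[lab]]
            ix = np.clip((np.mod(p[:, 0], lx) / lx * nx).astype(int), 0, nx - 1)
            iy = np.clip((np.mod(p[:, 1], ly) / ly * ny).astype(int), 0, ny - 1)
            zsum = np.zeros((nx, ny))
            cnt = np.zeros((nx, ny))
            np.add.at(zsum, (ix, iy), p[:, 2])
            np.add.at(cnt, (ix, iy), 1.0)
            occupied = cnt > 0
            mean_z = np.divide(zsum, cnt, out=np.zeros_like(zsum), where=occupied)
            fields[lab] = _fill_from_nearest(mean_z, occupied, lx, ly)
        thick = fields["upper"] - fields["lower"]
        acc += thick
        samples.append(thick[mask])
    acc /= sub.n_frames
    all_samples = np.concatenate(samples)
    if all_samples.size == 0:
        raise ValueError("region mask excludes every grid cell")
    lo = np.floor(all_samples.min() / bin_width) * bin_width
    hi = np.ceil(all_samples.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(all_samples, bins=edges)
    heights = counts / (counts.sum() * bin_width)
    dist = Histogram(edges=edges, heights=heights, normalization="unit_area",
                     n_contributing=int(all_samples.size))
    return ThicknessField(grid=grid, thickness=acc, mask=mask, distribution=dist)


def area_per_lipid_lr(
    traj: Trajectory,
    tags: list[RegionTags] | None,
    boundaries: RegionBoundaries | None,
    window: tuple[float, float] | None = None,
    exclusion: str = "disc",
    lipid_type: str = "AOPC",
) -> AreaPerLipidSeries:
    """Long-range area per lipid.

    With a nanoparticle, the SR + buffer footprint is removed from the box
    area as the projected disc pi * d_buf^2 and the remainder divided by
    the number of LR lipids of the interacting leaflet (per frame, using
    that frame's epoch tags).  Without a nanoparticle the whole box area is
    divided by the leaflet lipid count.
    """
    if exclusion != "disc":
        raise NotImplementedError("only the disc exclusion strategy is implemented")
    sub = _window(traj, window)
    topo = sub.topology
    times = []
    values = []
    for frame in sub.frames:
        a_box = frame.box.lx * frame.box.ly
        if boundaries is None or tags is None:
            leaflets = assign_leaflets(frame, topo, None, lipid_type)
            n_upper = len(leaflets.lipids_in("upper"))
            n_lower = len(leaflets.lipids_in("lower"))
            a = a_box / max(n_upper, n_lower)
        else:
            t = tags_at(tags, frame.time)
            n_lr = len(t.lipids_in(LR))
            if n_lr == 0:
                raise ValueError(f"no LR lipids at t={frame.time}")
            a = (a_box - np.pi * boundaries.d_buf**2) / n_lr
        times.append(frame.time)
        values.append(a)
    values = np.array(values)
    return AreaPerLipidSeries(times=np.array(times), values=values,
                              mean=float(values.mean()))
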