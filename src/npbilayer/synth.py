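"""Synthetic bilayer + nanoparticle + water trajectories with ground truth.

This is a *kinematic* generator, not a physics engine: chain order, leaflet
separation, area per lipid and lateral diffusion constants are imposed by
construction and recorded as ground truth, so every analysis stage can be
validated by parameter recovery.

Geometry conventions
--------------------
* The bilayer midplane sits at z = lz/2; head-group N sites of the two
  leaflets at midplane +/- h/2 (h = leaflet separation, N-to-N).
* Lipids occupy a jittered rectangular grid at the configured area per
  lipid; each lipid keeps a fixed internal conformation and moves as a
  rigid body: a 2D Gaussian walk in xy (per-axis step variance 2 D dt,
  D chosen by the lipid's region) and an Ornstein-Uhlenbeck process in z.
* Acyl chains are grown with bond length 0.153 nm and tetrahedral-like
  angle 111 deg; dihedrals are trans with probability 1 - gauche_probability
  (else gauche +/-60 deg); the sn2 C37-C38 bond is a cis double bond.
  The whole lipid is tilted by a fixed polar angle theta with
  cos^2(theta) = tilt_mean_cos2 of its region and uniform azimuth, which
  makes the expected chain order parameter the closed form
  -S_CD = (3 <cos^2 theta> - 1) / 4.
* The nanoparticle is a rigid fcc sphere following a linear z path at the
  box center in xy.  Water is single-site (OW) and resampled uniformly
  outside the bilayer slab each frame (valid for density observables, not
  for water dynamics); an optional fixed cluster of waters rides within
  0.5 nm of the particle surface inside the slab.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .model import (
    AOPC_CHAINS,
    AOPC_SITES,
    MASS,
    Box,
    Frame,
    SiteRecord,
    Topology,
    Trajectory,
)
from .nanoparticle import FccSphereSpec, build_fcc_sphere
from .regions import BUFFER, LR, OTHER_LEAFLET, SR, RegionBoundaries

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "expected_scd",
    "generate_lipid_conformation",
    "generate_trajectory",
    "generate_brownian_tracers",
]

_BOND_CC = 0.153  # nm
_ANGLE_CC = 111.0  # deg
_REGIONS = (SR, BUFFER, LR)


def expected_scd(mean_cos2_tilt: float) -> float:
    """Closed-form -S_CD of a rigid all-trans chain tilted with uniform
    azimuth so that <cos^2 theta> = `mean_cos2_tilt`.

    0.5 for a chain along the normal, 0 at the isotropic value 1/3.
    """
    if not (1.0 / 3.0 - 1e-12 <= mean_cos2_tilt <= 1.0 + 1e-12):
        raise ValueError(
            f"<cos^2 theta> must lie in [1/3, 1], got {mean_cos2_tilt}"
        )
    return (3.0 * mean_cos2_tilt - 1.0) / 4.0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic system.

    Defaults mirror a fluid-phase PC bilayer perturbed by a 2-nm gold
    particle: 64 lipids per leaflet, area per lipid 0.62 nm^2, N-to-N
    leaflet separation 4.0 nm, long-range lateral diffusion
    0.015 nm^2/ns (= 1.5e-7 cm^2/s) with slower short-range lipids, and
    chain tilt order decreasing from LR to SR.
    """

    n_lipids_per_leaflet: int = 64
    lx: float | None = None  # nm; default sqrt(n * area_per_lipid)
    ly: float | None = None
    lz: float | None = None  # nm; default h + 4
    leaflet_separation: float = 4.0  # nm, N-to-N
    area_per_lipid: float = 0.62  # nm^2
    tilt_mean_cos2: dict = field(
        default_factory=lambda: {SR: 0.45, BUFFER: 0.55, LR: 0.65}
    )
    gauche_probability: dict = field(
        default_factory=lambda: {SR: 0.0, BUFFER: 0.0, LR: 0.0}
    )
    d_lateral: dict = field(
        default_factory=lambda: {SR: 0.0098, BUFFER: 0.012, LR: 0.015}
    )  # nm^2/ns
    z_fluctuation_sigma: float = 0.05  # nm
    z_relaxation_ns: float = 1.0
    np_radius: float | None = 1.0  # nm; None = reference system, no particle
    np_z_start: float | None = None  # nm above midplane; default h/2 + r
    np_z_end: float | None = None  # default: same as start (static particle)
    sn2_cis_kink: bool = True
    water_number_density: float = 8.0  # nm^-3 (thinned bulk; see docs)
    cluster_waters_near_np: int = 20
    xy_jitter_fraction: float = 0.1  # of grid pitch
    dt: float = 0.1  # ns between frames
    n_frames: int = 51
    seed: int = 0

    def resolved_box(self) -> Box:
        n = self.n_lipids_per_leaflet
        lx = self.lx if self.lx is not None else float(np.sqrt(n * self.area_per_lipid))
        ly = self.ly if self.ly is not None else float(np.sqrt(n * self.area_per_lipid))
        lz = self.lz if self.lz is not None else self.leaflet_separation + 4.0
        if self.area_per_lipid * n > lx * ly + 1e-9:
            raise ValueError(
                f"area per lipid {self.area_per_lipid} x {n} lipids exceeds "
                f"box area {lx * ly:.3f} nm^2"
            )
        return Box(lx, ly, lz)

    def validate(self) -> None:
        for reg in _REGIONS:
            c = self.tilt_mean_cos2[reg]
            if not (1.0 / 3.0 - 1e-12 <= c <= 1.0 + 1e-12):
                raise ValueError(f"tilt_mean_cos2[{reg}]={c} outside [1/3, 1]")
            if self.d_lateral[reg] < 0 or not (0 <= self.gauche_probability[reg] <= 1):
                raise ValueError("rates must be >= 0, probabilities in [0, 1]")
        if self.n_lipids_per_leaflet < 1 or self.n_frames < 1 or self.dt <= 0:
            raise ValueError("need >= 1 lipid, >= 1 frame, dt > 0")
        self.resolved_box()


@dataclass
class GroundTruth:
    """What the generator imposed, for parameter-recovery tests."""

    scd: dict  # region -> expected -S_CD (closed form, interior carbons)
    d_lateral: dict  # region -> nm^2/ns
    thickness: float  # nm
    area_per_lipid: float  # nm^2 (actual lx*ly/n per leaflet)
    leaflet: dict  # lipid id -> upper/lower
    region: dict  # lipid id -> region at t=0 (interacting leaflet) / LR
    np_center_start: list | None
    np_center_end: list | None

    def to_json(self, path) -> None:
        d = asdict(self)
        d["leaflet"] = {str(k): v for k, v in self.leaflet.items()}
        d["region"] = {str(k): v for k, v in self.region.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# internal-coordinate chain building
# ---------------------------------------------------------------------------


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and dihedral a-b-c-d."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # collinear seed: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _zigzag(n: int, bond: float, angle_deg: float, origin: np.ndarray) -> np.ndarray:
    """n-site all-trans zigzag running along -z, first site at `origin`."""
    half = np.radians(angle_deg) / 2.0
    c = bond * np.cos(half)
    s = bond * np.sin(half)
    pts = np.zeros((n, 3))
    for k in range(n):
        pts[k] = origin + np.array([(c / 2.0) * ((-1) ** k) - c / 2.0, 0.0, -k * s])
    return pts


def _chain_dihedrals(n_bonds: int, gauche_p: float, rng: np.random.Generator) -> np.ndarray:
    dih = np.full(n_bonds, 180.0)
    if gauche_p > 0:
        u = rng.random(n_bonds)
        g = u < gauche_p
        signs = np.where(rng.random(n_bonds) < 0.5, 60.0, -60.0)
        dih[g] = signs[g]
    return dih


_SITE_ORDER = [n for n, _ in AOPC_SITES]
_SITE_POS = {n: i for i, n in enumerate(_SITE_ORDER)}


def generate_lipid_conformation(
    config: GeneratorConfig,
    rng: np.random.Generator,
    region: str,
) -> np.ndarray:
    """Coordinates (56, 3) of one AOPC lipid in its local frame.

    The head group has a fixed internal geometry on an all-trans backbone
    N-C25-C24-O6-P-O3-C23-C22-C1 running along -z; both acyl chains grow
    further down.  The whole molecule is then tilted by the fixed polar
    angle of the region (uniform azimuth, uniform pre-twist) about the N
    site, which sits at the local origin.
    """
    gauche_p = config.gauche_probability[region]
    pos = np.zeros((56, 3))

    def put(name: str, p: np.ndarray) -> None:
        pos[_SITE_POS[name]] = p

    def get(name: str) -> np.ndarray:
        return pos[_SITE_POS[name]]

    backbone = ["N", "C25", "C24", "O6", "P", "O3", "C23", "C22", "C1"]
    bb = _zigzag(len(backbone), _BOND_CC, _ANGLE_CC, np.zeros(3))
    for name, p in zip(backbone, bb):
        put(name, p)
    # N-methyls: three staggered positions off the N-C25 bond
    for name, dih in (("C26", 60.0), ("C27", 180.0), ("C28", -60.0)):
        put(name, _nerf(get("C24"), get("C25"), get("N"), 0.147, 109.5, dih))
    # non-ester phosphate oxygens
    put("O4", _nerf(get("C24"), get("O6"), get("P"), 0.148, 109.5, 60.0))
    put("O5", _nerf(get("C24"), get("O6"), get("P"), 0.148, 109.5, -60.0))
    # sn1 ester + chain C21..C2
    put("O1", _nerf(get("C23"), get("C22"), get("C1"), 0.143, _ANGLE_CC, 180.0))
    put("C21", _nerf(get("C22"), get("C1"), get("O1"), 0.136, 117.0, 180.0))
    put("O7", _nerf(get("C1"), get("O1"), get("C21"), 0.123, 121.0, 0.0))
    sn1 = AOPC_CHAINS["sn1"]
    dihs = _chain_dihedrals(len(sn1), gauche_p, rng)
    prev3 = [get("O1"), get("C21")]
    put("C20", _nerf(get("C1"), get("O1"), get("C21"), _BOND_CC, 114.0, 180.0))
    prev3 = [get("O1"), get("C21"), get("C20")]
    for i, name in enumerate(sn1[2:]):
        p = _nerf(prev3[-3], prev3[-2], prev3[-1], _BOND_CC, _ANGLE_CC, dihs[i])
        put(name, p)
        prev3.append(p)
    # sn2 ester + chain C31..C48 with cis kink at C37-C38
    put("O2", _nerf(get("O3"), get("C23"), get("C22"), 0.143, 109.5, 60.0))
    put("C31", _nerf(get("C23"), get("C22"), get("O2"), 0.136, 117.0, 180.0))
    put("O8", _nerf(get("C22"), get("O2"), get("C31"), 0.123, 121.0, 0.0))
    sn2 = AOPC_CHAINS["sn2"]
    dihs2 = _chain_dihedrals(len(sn2), gauche_p, rng)
    put("C32", _nerf(get("C22"), get("O2"), get("C31"), _BOND_CC, 114.0, 180.0))
    prev3 = [get("O2"), get("C31"), get("C32")]
    for i, name in enumerate(sn2[2:]):
        angle = _ANGLE_CC
        dih = dihs2[i]
        if config.sn2_cis_kink:
            # name is placed after prev two chain carbons; the C37=C38 bond
            # forces angle 120 at both ends and a cis dihedral across it
            if name in ("C38", "C39"):
                angle = 120.0
            if name == "C39":
                dih = 0.0
        p = _nerf(prev3[-3], prev3[-2], prev3[-1], _BOND_CC, angle, dih)
        put(name, p)
        prev3.append(p)

    # align the sn1 chain axis exactly with -z before tilting, so the
    # imposed tilt is exact for the saturated chain (the ester geometry
    # otherwise leaves the zigzag axis a degree or two off the normal)
    axis = get("C2") - get("C20")
    pos = pos @ _rotation_onto(axis / np.linalg.norm(axis), np.array([0.0, 0.0, -1.0])).T

    # region-dependent tilt: fixed polar angle, uniform azimuth and pre-twist
    cos2 = config.tilt_mean_cos2[region]
    theta = float(np.arccos(np.sqrt(cos2)))
    psi, phi = rng.uniform(0, 2 * np.pi, size=2)
    rz_psi = _rot_z(psi)
    ry = _rot_y(theta)
    rz_phi = _rot_z(phi)
    return pos @ (rz_phi @ ry @ rz_psi).T


def _rotation_onto(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u to unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis perpendicular to u
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2 * K @ K
    w = np.cross(u, v)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------


def _lipid_grid(n: int, lx: float, ly: float, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    nx = int(np.ceil(np.sqrt(n * lx / ly)))
    ny = int(np.ceil(n / nx))
    px, py = lx / nx, ly / ny
    pts = []
    for iy in range(ny):
        for ix in range(nx):
            if len(pts) == n:
                break
            pts.append([(ix + 0.5) * px, (iy + 0.5) * py])
    pts = np.array(pts)
    pts += rng.uniform(-jitter, jitter, size=pts.shape) * np.array([px, py])
    return pts


def generate_trajectory(config: GeneratorConfig) -> tuple[Trajectory, GroundTruth]:
    """Build the synthetic trajectory and its ground truth.

    Deterministic for a fixed config (all randomness through one seeded
    generator).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    box = config.resolved_box()
    n = config.n_lipids_per_leaflet
    h = config.leaflet_separation
    zmid = box.lz / 2.0
    apl_actual = box.lx * box.ly / n

    # nanoparticle path (xy at box center)
    np_coords = None
    np_start = np_end = None
    if config.np_radius is not None and config.np_radius > 0:
        np_coords = build_fcc_sphere(FccSphereSpec(config.np_radius))
        z0 = config.np_z_start if config.np_z_start is not None else h / 2 + config.np_radius
        z1 = config.np_z_end if config.np_z_end is not None else z0
        np_start = np.array([box.lx / 2, box.ly / 2, zmid + z0])
        np_end = np.array([box.lx / 2, box.ly / 2, zmid + z1])

    # lipid anchors (N sites) per leaflet
    anchors = {
        "upper": np.column_stack(
            [_lipid_grid(n, box.lx, box.ly, config.xy_jitter_fraction, rng),
             np.full(n, zmid + h / 2)]
        ),
        "lower": np.column_stack(
            [_lipid_grid(n, box.lx, box.ly, config.xy_jitter_fraction, rng),
             np.full(n, zmid - h / 2)]
        ),
    }

    # ground-truth regions at t=0 (upper leaflet interacts; 3D N distance)
    regions: dict[int, str] = {}
    leaflet_of: dict[int, str] = {}
    boundaries = (
        RegionBoundaries(config.np_radius) if np_coords is not None else None
    )
    lipid_id = 0
    conformations = []
    lipid_leaflet_order = []
    for leaflet in ("upper", "lower"):
        for i in range(n):
            if leaflet == "upper" and boundaries is not None:
                d = float(np.linalg.norm(anchors["upper"][i] - np_start))
                if d <= boundaries.d_sr:
                    reg = SR
                elif d < boundaries.d_buf:
                    reg = BUFFER
                else:
                    reg = LR
            else:
                reg = LR if leaflet == "upper" or boundaries is None else OTHER_LEAFLET
            true_reg = reg if reg != OTHER_LEAFLET else LR
            local = generate_lipid_conformation(config, rng, true_reg)
            if leaflet == "lower":
                local = local * np.array([1.0, 1.0, -1.0])
            conformations.append(local)
            regions[lipid_id] = reg if leaflet == "upper" else OTHER_LEAFLET
            leaflet_of[lipid_id] = leaflet
            lipid_leaflet_order.append((lipid_id, leaflet, i, true_reg))
            lipid_id += 1
    n_lipids = lipid_id

    # waters: uniform outside the slab [zmid - h/2, zmid + h/2]
    slab_lo, slab_hi = zmid - h / 2, zmid + h / 2
    vol_below = box.lx * box.ly * slab_lo
    vol_above = box.lx * box.ly * (box.lz - slab_hi)
    n_below = int(round(config.water_number_density * vol_below))
    n_above = int(round(config.water_number_density * vol_above))
    n_cluster = config.cluster_waters_near_np if np_coords is not None else 0

    # fixed cluster offsets: within 0.5 nm of the particle surface, below
    # the particle center (inside the slab side)
    cluster_offsets = np.zeros((n_cluster, 3))
    if n_cluster:
        r = config.np_radius
        u = rng.normal(size=(n_cluster, 3))
        u[:, 2] = -np.abs(u[:, 2])  # point into the bilayer
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        shell = r + rng.uniform(0.05, 0.5, size=n_cluster)
        cluster_offsets = u * shell[:, None]

    # topology
    sites: list[SiteRecord] = []
    for (lid, leaflet, i, reg) in lipid_leaflet_order:
        sites.extend(SiteRecord(lid, "AOPC", name, m) for name, m in AOPC_SITES)
    mol = n_lipids
    if np_coords is not None:
        sites.extend(
            SiteRecord(mol, "AU", f"AU{i+1}", MASS["AU"])
            for i in range(np_coords.n_atoms)
        )
        mol += 1
    n_waters = n_below + n_above + n_cluster
    for w in range(n_waters):
        sites.append(SiteRecord(mol + w, "SOL", "OW", MASS["OW"]))
    topology = Topology(sites, AOPC_CHAINS)

    # per-lipid walks
    dt = config.dt
    nf = config.n_frames
    steps_xy = np.zeros((nf, n_lipids, 2))
    for (lid, leaflet, i, reg) in lipid_leaflet_order:
        D = config.d_lateral[reg]
        if D > 0 and nf > 1:
            steps_xy[1:, lid] = rng.normal(
                scale=np.sqrt(2 * D * dt), size=(nf - 1, 2)
            )
    xy_disp = np.cumsum(steps_xy, axis=0)

    sigma = config.z_fluctuation_sigma
    z_off = np.zeros((nf, n_lipids))
    if sigma > 0:
        rho = float(np.exp(-dt / config.z_relaxation_ns))
        z_off[0] = rng.normal(scale=sigma, size=n_lipids)
        innov = rng.normal(scale=sigma * np.sqrt(1 - rho**2), size=(nf - 1, n_lipids))
        for t in range(1, nf):
            z_off[t] = rho * z_off[t - 1] + innov[t - 1]

    # water randomness drawn per frame below (order fixed for determinism)
    frames: list[Frame] = []
    L = box.lengths
    for t in range(nf):
        pos = np.empty((topology.n_sites, 3))
        frac = t / (nf - 1) if nf > 1 else 0.0
        np_center = None
        if np_coords is not None:
            np_center = np_start + frac * (np_end - np_start)
        k = 0
        for (lid, leaflet, i, reg) in lipid_leaflet_order:
            anchor = anchors[leaflet][i].copy()
            anchor[:2] += xy_disp[t, lid]
            anchor[2] += z_off[t, lid]
            # wrap the whole molecule rigidly by its anchor
            shift = np.floor(anchor[:2] / L[:2]) * L[:2]
            anchor[:2] -= shift
            pos[k : k + 56] = anchors_plus = anchor + conformations[lid]
            k += 56
        if np_coords is not None:
            pos[k : k + np_coords.n_atoms] = np_center + np_coords.positions
            k += np_coords.n_atoms
        if n_below:
            w = rng.random((n_below, 3))
            pos[k : k + n_below] = w * np.array([box.lx, box.ly, slab_lo])
            k += n_below
        if n_above:
            w = rng.random((n_above, 3))
            pos[k : k + n_above] = w * np.array(
                [box.lx, box.ly, box.lz - slab_hi]
            ) + np.array([0.0, 0.0, slab_hi])
            k += n_above
        if n_cluster:
            jitter = rng.normal(scale=0.01, size=(n_cluster, 3))
            pos[k : k + n_cluster] = np_center + cluster_offsets + jitter
            k += n_cluster
        frames.append(Frame(t * dt, pos, box))

    truth = GroundTruth(
        scd={reg: expected_scd(config.tilt_mean_cos2[reg]) for reg in _REGIONS},
        d_lateral=dict(config.d_lateral),
        thickness=h,
        area_per_lipid=apl_actual,
        leaflet=leaflet_of,
        region=regions,
        np_center_start=None if np_start is None else np_start.tolist(),
        np_center_end=None if np_end is None else np_end.tolist(),
    )
    return Trajectory(topology, frames), truth


# ---------------------------------------------------------------------------
# Brownian tracers (diffusion/MSD validation fixture)
# ---------------------------------------------------------------------------


def generate_brownian_tracers(
    D: float,
    n_tracers: int,
    dt: float,
    n_frames: int,
    seed: int,
    ndim: int = 2,
    box_edge: float = 1000.0,
) -> Trajectory:
    """Independent Gaussian random walks with per-axis step variance 2*D*dt.

    2D walks (default) move in xy with z fixed at the box center; use
    ndim=3 for full 3D diffusion.  Coordinates are left unwrapped (the box
    is made large enough to contain the walks).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_frames, n_tracers, 3))
    if D > 0 and n_frames > 1:
        steps[1:, :, :ndim] = rng.normal(
            scale=np.sqrt(2 * D * dt), size=(n_frames - 1, n_tracers, ndim)
        )
    pos = np.cumsum(steps, axis=0) + box_edge / 2.0
    box = Box(box_edge, box_edge, box_edge)
    sites = [SiteRecord(i, "TRC", "X", 1.0) for i in range(n_tracers)]
    topo = Topology(sites)
    frames = [Frame(t * dt, pos[t], box) for t in range(n_frames)]
    return Trajectory(topo, frames)
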