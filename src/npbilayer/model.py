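"""Core coordinate/topology data model for bilayer + nanoparticle systems.

Units are fixed package-wide: lengths in nm, times in ns, masses in atomic
mass units (u).  Boxes are orthorhombic; analyses that need whole molecules
re-wrap each molecule about its first site rather than assuming pre-wrapped
input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Box",
    "SiteRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "AOPC_SITES",
    "AOPC_CHAINS",
    "aopc_site_records",
    "minimum_image_vector",
    "center_of_mass",
    "assign_leaflets",
    "LeafletAssignment",
]

# united-atom masses (u) used throughout
MASS = {
    "N": 14.007,
    "P": 30.974,
    "O": 15.999,
    "CH": 13.019,
    "CH2": 14.027,
    "CH3": 15.035,
    "C": 12.011,  # carbonyl carbon, no hydrogens
    "OW": 18.015,  # single-site water oxygen carries the whole molecule mass
    "AU": 196.967,
}


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation box with edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box edges must be strictly positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz


@dataclass(frozen=True)
class SiteRecord:
    """One interaction site: which molecule it belongs to and what it is."""

    molecule_id: int
    molecule_type: str  # AOPC, AU, SOL, ...
    site_name: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"site mass must be positive: {self}")


# ---------------------------------------------------------------------------
# AOPC united-atom site layout (56 sites).
#
# The head-group naming follows the connectivity used for the analyses:
# choline N with three N-methyl carbons (C26-C28), the N-C25-C24-O6-P
# backbone, phosphate oxygens O4/O5 (non-ester) and O3/O6 (bridging),
# glycerol C23-C22-C1, an sn1 ester (O1, carbonyl O7) carrying the
# 20-carbon saturated arachidoyl chain C21..C2, and an sn2 ester
# (O2, carbonyl O8) carrying the 18-carbon oleoyl chain C31..C48 with a
# cis double bond at C37-C38.  The numbering is self-consistent within
# this package; only the names quoted above are load-bearing.
# ---------------------------------------------------------------------------

_SN1_CARBONS = [f"C{i}" for i in range(21, 1, -1)]  # C21 (ester) .. C2 (terminal)
_SN2_CARBONS = [f"C{i}" for i in range(31, 49)]  # C31 (ester) .. C48 (terminal)

AOPC_SITES: list[tuple[str, float]] = (
    [
        ("N", MASS["N"]),
        ("C26", MASS["CH3"]),
        ("C27", MASS["CH3"]),
        ("C28", MASS["CH3"]),
        ("C25", MASS["CH2"]),
        ("C24", MASS["CH2"]),
        ("O6", MASS["O"]),
        ("P", MASS["P"]),
        ("O4", MASS["O"]),
        ("O5", MASS["O"]),
        ("O3", MASS["O"]),
        ("C23", MASS["CH2"]),
        ("C22", MASS["CH"]),
        ("C1", MASS["CH2"]),
        ("O1", MASS["O"]),
    ]
    + [("C21", MASS["C"])]
    + [(c, MASS["CH2"]) for c in _SN1_CARBONS[1:-1]]
    + [("C2", MASS["CH3"])]
    + [("O7", MASS["O"])]
    + [("O2", MASS["O"])]
    + [("C31", MASS["C"])]
    + [
        (c, MASS["CH"] if c in ("C37", "C38") else MASS["CH2"])
        for c in _SN2_CARBONS[1:-1]
    ]
    + [("C48", MASS["CH3"])]
    + [("O8", MASS["O"])]
)

assert len(AOPC_SITES) == 56

AOPC_CHAINS: dict[str, list[str]] = {"sn1": _SN1_CARBONS, "sn2": _SN2_CARBONS}

#: sn2 carbon pair joined by the cis double bond
AOPC_UNSATURATED_PAIR = ("C37", "C38")

#: head-group sites used for nanoparticle-contact analyses
AOPC_HEADGROUP_SITES = [
    "N", "C26", "C27", "C28", "C25", "C24", "O6", "P", "O4", "O5", "O3",
]


def aopc_site_records(molecule_id: int) -> list[SiteRecord]:
    """Site records for one AOPC lipid, in canonical order."""
    return [SiteRecord(molecule_id, "AOPC", n, m) for n, m in AOPC_SITES]


class Topology:
    """Ordered site table with per-molecule structure and chain definitions.

    Every molecule of a given type must have an identical site layout; this
    is validated lazily when per-molecule lookups are first used.
    """

    def __init__(
        self,
        sites: Sequence[SiteRecord],
        chains: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        if not sites:
            raise ValueError("topology needs at least one site")
        self.sites = list(sites)
        self.chains = {k: list(v) for k, v in (chains or {}).items()}
        for name, carbons in self.chains.items():
            if len(carbons) < 3:
                raise ValueError(
                    f"chain {name!r} has {len(carbons)} carbons; need >= 3"
                )
        self.molecule_ids = np.array([s.molecule_id for s in self.sites])
        self.molecule_types = np.array([s.molecule_type for s in self.sites])
        self.site_names = np.array([s.site_name for s in self.sites])
        self.masses = np.array([s.mass for s in self.sites], dtype=float)
        # uniqueness of site_name within each molecule
        seen: set[tuple[int, str]] = set()
        for s in self.sites:
            key = (s.molecule_id, s.site_name)
            if key in seen:
                raise ValueError(f"duplicate site {s.site_name!r} in molecule {s.molecule_id}")
            seen.add(key)
        self._site_index = {
            (s.molecule_id, s.site_name): i for i, s in enumerate(self.sites)
        }

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def select(
        self,
        molecule_type: str | None = None,
        site_name: str | Sequence[str] | None = None,
    ) -> np.ndarray:
        """Indices of sites matching molecule type and/or site name(s)."""
        mask = np.ones(self.n_sites, dtype=bool)
        if molecule_type is not None:
            mask &= self.molecule_types == molecule_type
        if site_name is not None:
            names = [site_name] if isinstance(site_name, str) else list(site_name)
            mask &= np.isin(self.site_names, names)
        return np.flatnonzero(mask)

    def molecules_of_type(self, molecule_type: str) -> np.ndarray:
        """Sorted unique molecule ids of a given type."""
        return np.unique(self.molecule_ids[self.molecule_types == molecule_type])

    def lipid_ids(self, lipid_type: str = "AOPC") -> np.ndarray:
        return self.molecules_of_type(lipid_type)

    def sites_of(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_ids == molecule_id)

    def index_of(self, molecule_id: int, site_name: str) -> int:
        try:
            return self._site_index[(molecule_id, site_name)]
        except KeyError:
            raise KeyError(
                f"molecule {molecule_id} has no site named {site_name!r}"
            ) from None

    def site_matrix(self, molecule_ids: Iterable[int], site_name: str) -> np.ndarray:
        """Index array (n_molecules,) of one named site across molecules."""
        return np.array([self.index_of(m, site_name) for m in molecule_ids])

    # -- manifest I/O -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "sites": [
                [s.molecule_id, s.molecule_type, s.site_name, s.mass]
                for s in self.sites
            ],
            "chains": self.chains,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Topology":
        with open(path) as fh:
            payload = json.load(fh)
        sites = [SiteRecord(int(a), b, c, float(d)) for a, b, c, d in payload["sites"]]
        return cls(sites, payload.get("chains"))


@dataclass
class Frame:
    """One coordinate snapshot: time (ns), positions (n_sites, 3) nm, box."""

    time: float
    positions: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_sites, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")


class Trajectory:
    """A topology plus an ordered list of frames with constant site count."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]) -> None:
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        for f in frames:
            if f.positions.shape[0] != topology.n_sites:
                raise ValueError(
                    f"frame at t={f.time} has {f.positions.shape[0]} sites, "
                    f"topology has {topology.n_sites}"
                )
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = list(frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def window(self, t0: float | None = None, t1: float | None = None) -> "Trajectory":
        """Sub-trajectory with t0 <= time <= t1 (None = open end)."""
        sel = [
            f
            for f in self.frames
            if (t0 is None or f.time >= t0 - 1e-9) and (t1 is None or f.time <= t1 + 1e-9)
        ]
        if not sel:
            raise ValueError(f"empty time window [{t0}, {t1}]")
        return Trajectory(self.topology, sel)

    def last(self, span_ns: float) -> "Trajectory":
        """The final `span_ns` nanoseconds of the trajectory."""
        return self.window(self.frames[-1].time - span_ns, None)


# ---------------------------------------------------------------------------
# periodic-boundary utilities
# ---------------------------------------------------------------------------


def minimum_image_vector(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Displacement b - a with each component wrapped into [-L/2, +L/2).

    Broadcasts over leading dimensions of `a`/`b`.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = box.lengths
    return d - L * np.floor(d / L + 0.5)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    return np.linalg.norm(minimum_image_vector(a, b, box), axis=-1)


def rewrap_about_first(positions: np.ndarray, box: Box) -> np.ndarray:
    """Make a selection whole: each site moved to its minimum image
    relative to the first site."""
    ref = positions[0]
    return ref + minimum_image_vector(ref, positions, box)


def center_of_mass(
    frame: Frame,
    selection: np.ndarray,
    masses: np.ndarray,
) -> np.ndarray:
    """Mass-weighted mean position of a selection, after re-wrapping the
    selection about its first site so split molecules are made whole."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection in center_of_mass")
    pos = rewrap_about_first(frame.positions[selection], frame.box)
    m = np.asarray(masses, dtype=float)[selection]
    return (pos * m[:, None]).sum(axis=0) / m.sum()


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels and the nanoparticle-interacting leaflet."""

    labels: dict[int, str]  # lipid molecule_id -> "upper" | "lower"
    interacting: str | None  # "upper" | "lower" | None when no NP given

    def lipids_in(self, leaflet: str) -> list[int]:
        return [m for m, lab in self.labels.items() if lab == leaflet]

    @property
    def interacting_lipids(self) -> list[int]:
        if self.interacting is None:
            raise ValueError("no interacting leaflet: nanoparticle CoM not given")
        return self.lipids_in(self.interacting)


def assign_leaflets(
    frame: Frame,
    topology: Topology,
    np_com: np.ndarray | None = None,
    lipid_type: str = "AOPC",
    phosphorus_site: str = "P",
) -> LeafletAssignment:
    """Split lipids into upper/lower leaflets by the sign of z_P - z_mid.

    z_mid is the median of all phosphorus z coordinates.  When a
    nanoparticle CoM is given, the interacting leaflet is the one whose mean
    P z is nearer the CoM z (minimum-image along z); an exact tie goes to
    the upper leaflet.
    """
    lipids = topology.lipid_ids(lipid_type)
    if lipids.size == 0:
        raise ValueError(f"no lipids of type {lipid_type!r} in topology")
    p_idx = topology.site_matrix(lipids, phosphorus_site)
    z = frame.positions[p_idx, 2]
    z_mid = float(np.median(z))
    upper = z > z_mid
    lower = z < z_mid
    # median sites (even count straddles): assign by >= to upper
    upper |= ~lower
    if upper.all() or lower.all():
        raise ValueError("monolayer detected: all P sites on one side of the midplane")
    labels = {int(m): ("upper" if u else "lower") for m, u in zip(lipids, upper)}
    interacting = None
    if np_com is not None:
        zu = z[upper].mean()
        zl = z[~upper].mean()
        lz = frame.box.lz
        znp = float(np_com[2])

        def zdist(za: float) -> float:
            d = znp - za
            return abs(d - lz * np.floor(d / lz + 0.5))

        interacting = "upper" if zdist(zu) <= zdist(zl) else "lower"
    return LeafletAssignment(labels, interacting)
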