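"""GRO-format trajectory I/O (fixed columns, nm), plus XYZ/PDB export.

A multi-frame GRO file is simply concatenated single-frame blocks; this is
the package's zero-dependency trajectory format.  Velocities are ignored on
read and never written.  Frame times are taken from a ``t=`` token in the
title line when present, otherwise frames are numbered 0, 1, 2, ... ns.
"""

from __future__ import annotations

import re
from typing import Sequence

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

__all__ = ["read_gro", "write_gro", "write_xyz", "write_pdb", "infer_mass"]


class GroParseError(ValueError):
    pass


_AOPC_MASS = dict(AOPC_SITES)


def infer_mass(molecule_type: str, site_name: str) -> float:
    """Best-effort united-atom mass from residue/site naming."""
    if molecule_type == "AOPC" and site_name in _AOPC_MASS:
        return _AOPC_MASS[site_name]
    if site_name.upper().startswith("AU"):
        return MASS["AU"]
    if site_name.upper().startswith("OW"):
        return MASS["OW"]
    first = site_name[0].upper()
    if first == "N":
        return MASS["N"]
    if first == "P":
        return MASS["P"]
    if first == "O":
        return MASS["O"]
    if first == "C":
        return MASS["CH2"]
    if first == "H":
        return 1.008
    raise GroParseError(f"cannot infer a mass for site {site_name!r}")


_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_frame_block(lines: list[str], lineno0: int):
    """Parse one frame block; returns (title, records, positions, box)."""
    title = lines[0].rstrip("\n")
    try:
        n_atoms = int(lines[1].strip())
    except (ValueError, IndexError):
        raise GroParseError(
            f"line {lineno0 + 2}: expected an integer atom count, got {lines[1]!r}"
        )
    if len(lines) < n_atoms + 3:
        raise GroParseError(
            f"line {lineno0 + 2}: header declares {n_atoms} atoms but only "
            f"{max(0, len(lines) - 3)} atom lines present before end of file"
        )
    records: list[tuple[int, str, str]] = []
    pos = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        ln = lines[2 + i]
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            atomname = ln[10:15].strip()
            pos[i, 0] = float(ln[20:28])
            pos[i, 1] = float(ln[28:36])
            pos[i, 2] = float(ln[36:44])
        except (ValueError, IndexError):
            raise GroParseError(f"line {lineno0 + 3 + i}: malformed atom line {ln!r}")
        records.append((resid, resname, atomname))
    box_line = lines[2 + n_atoms].split()
    if len(box_line) < 3:
        raise GroParseError(
            f"line {lineno0 + 3 + n_atoms}: missing or short box line"
        )
    v = [float(x) for x in box_line]
    if len(v) > 3 and any(abs(x) > 1e-12 for x in v[3:]):
        raise ValueError("triclinic boxes are not supported (off-diagonal box vector)")
    return title, records, pos, Box(v[0], v[1], v[2])


def read_gro(path, topology: Topology | None = None) -> Trajectory:
    """Read a single- or multi-frame GRO file.

    When no topology is supplied, one is inferred from residue/atom names:
    masses from a united-atom table and, if the lipid layout matches the
    canonical AOPC site set, sn1/sn2 chain definitions are attached.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[Frame] = []
    records0: list[tuple[int, str, str]] | None = None
    i = 0
    iframe = 0
    while i < len(lines):
        if not lines[i].strip() and i + 1 >= len(lines):
            break  # trailing blank line
        title, records, pos, box = _parse_frame_block(lines[i:], i)
        n = len(records)
        if records0 is None:
            records0 = records
        elif records != records0:
            raise GroParseError(f"frame {iframe}: site ordering differs from frame 0")
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else float(iframe)
        frames.append(Frame(time, pos, box))
        i += n + 3
        iframe += 1
    if records0 is None:
        raise GroParseError(f"{path}: empty GRO file")
    if topology is None:
        # residues in GRO may share ids across molecules types; re-key by
        # (running molecule counter) when resid resets or changes
        sites: list[SiteRecord] = []
        mol = -1
        prev = None
        for resid, resname, atomname in records0:
            if (resid, resname) != prev:
                mol += 1
                prev = (resid, resname)
            sites.append(SiteRecord(mol, resname, atomname, infer_mass(resname, atomname)))
        chains = None
        aopc_names = [n for n, _ in AOPC_SITES]
        if any(s.molecule_type == "AOPC" for s in sites):
            lip0 = [s.site_name for s in sites if s.molecule_type == "AOPC"][
                : len(aopc_names)
            ]
            if lip0 == aopc_names:
                chains = AOPC_CHAINS
        topology = Topology(sites, chains)
    return Trajectory(topology, frames)


def _format_frame(fh, frame: Frame, topology: Topology, title: str) -> None:
    fh.write(f"{title} t= {frame.time:.6f}\n")
    fh.write(f"{topology.n_sites}\n")
    for i, s in enumerate(topology.sites):
        x, y, z = frame.positions[i]
        fh.write(
            "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
            % ((s.molecule_id + 1) % 100000, s.molecule_type[:5], s.site_name[:5],
               (i + 1) % 100000, x, y, z)
        )
    b = frame.box
    fh.write(f"{b.lx:10.5f}{b.ly:10.5f}{b.lz:10.5f}\n")


def write_gro(traj: Trajectory, path, title: str = "npbilayer") -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            _format_frame(fh, frame, traj.topology, title)


def write_xyz(positions: Sequence[Sequence[float]], path, element: str = "Au") -> None:
    """XYZ export (Angstrom, as the format convention expects)."""
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\nnpbilayer\n")
        for x, y, z in positions * 10.0:
            fh.write(f"{element:<2s} {x:12.5f} {y:12.5f} {z:12.5f}\n")


def write_pdb(positions: Sequence[Sequence[float]], path, element: str = "AU",
              resname: str = "AU") -> None:
    """Minimal single-model PDB export (HETATM records, Angstrom)."""
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(positions * 10.0, start=1):
            fh.write(
                "HETATM%5d %-4s %-4s%5d    %8.3f%8.3f%8.3f  1.00  0.00          %2s\n"
                % (i % 100000, element[:4], resname[:4], 1, x, y, z, element[:2])
            )
        fh.write("END\n")
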