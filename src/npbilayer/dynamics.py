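"""Mean-square displacement and lateral/normal diffusion coefficients.

The MSD of a tagged lipid subset is computed the interval-averaged way:
the analysis window (default the last 20 ns) is cut into consecutive
intervals (default 2 ns); inside each interval displacements are measured
from the interval's first frame and averaged over intervals and over
molecules whose region tag is constant across the interval.  Diffusion
coefficients come from the least-squares slope of MSD(tau) over a central
fit fraction via the Einstein relation MSD = 2 d D tau, reported in cm^2/s
(1 nm^2/ns = 1e-5 cm^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Topology, Trajectory, rewrap_about_first
from .regions import RegionTags, tags_at

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "unwrap_positions",
    "com_trajectory",
    "msd",
    "diffusion_coefficient",
    "NM2_PER_NS_TO_CM2_PER_S",
]

NM2_PER_NS_TO_CM2_PER_S = 1.0e-5

_MODE_AXES = {"lateral": (0, 1), "normal": (2,), "full": (0, 1, 2)}
_MODE_DIM = {"lateral": 2, "normal": 1, "full": 3}


@dataclass
class MSDCurve:
    lags: np.ndarray  # ns, starting at 0
    values: np.ndarray  # nm^2
    mode: str
    subset: str
    n_molecules: int
    n_origins: int


@dataclass
class DiffusionEstimate:
    d_cm2_s: float
    uncertainty_cm2_s: float
    fit_range_ns: tuple[float, float]
    dimensionality: int
    clamped: bool = False

    @property
    def d_e7(self) -> float:
        """D in the conventional table units of 1e-7 cm^2/s."""
        return self.d_cm2_s * 1e7

    @property
    def uncertainty_e7(self) -> float:
        return self.uncertainty_cm2_s * 1e7


def unwrap_positions(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """Continuous coordinates (n_frames, n_sel, 3) for a selection.

    Inter-frame jumps larger than half the box are undone by adding or
    subtracting box vectors.  A jump of exactly half a box edge is
    ambiguous and raises.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    out = np.empty((traj.n_frames, selection.size, 3))
    out[0] = traj.frames[0].positions[selection]
    for t in range(1, traj.n_frames):
        frame = traj.frames[t]
        L = frame.box.lengths
        d = frame.positions[selection] - traj.frames[t - 1].positions[selection]
        if np.any(np.isclose(np.abs(np.abs(d) - L / 2.0), 0.0, atol=1e-9)):
            raise ValueError(
                f"ambiguous half-box jump between frames {t - 1} and {t}"
            )
        shift = -L * np.round(d / L)
        out[t] = out[t - 1] + d + shift
    return out


def com_trajectory(
    traj: Trajectory,
    molecule_ids: np.ndarray,
    site_name: str | None = None,
) -> np.ndarray:
    """Unwrapped per-molecule position series (n_frames, n_mol, 3).

    Position = mass-weighted CoM of all molecule sites (default) or a
    single named site.  Each molecule is first made whole in frame 0 by
    re-wrapping about its first site; sites are then unwrapped over time,
    which keeps molecules whole throughout.
    """
    topo = traj.topology
    molecule_ids = np.asarray(molecule_ids)
    if molecule_ids.size == 0:
        raise ValueError("no molecules selected")
    if site_name is not None:
        idx = topo.site_matrix(molecule_ids, site_name)
        return unwrap_positions(traj, idx)
    groups = [topo.sites_of(int(m)) for m in molecule_ids]
    all_idx = np.concatenate(groups)
    unwrapped = unwrap_positions(traj, all_idx)
    # frame-0 re-wrap per molecule, applied as a constant offset
    offset = np.zeros((len(all_idx), 3))
    p0 = traj.frames[0].positions
    start = 0
    for g in groups:
        whole = rewrap_about_first(p0[g], traj.frames[0].box)
        offset[start : start + len(g)] = whole - p0[g]
        start += len(g)
    unwrapped = unwrapped + offset
    out = np.empty((traj.n_frames, molecule_ids.size, 3))
    start = 0
    for k, g in enumerate(groups):
        m = topo.masses[g]
        seg = unwrapped[:, start : start + len(g), :]
        out[:, k, :] = (seg * m[None, :, None]).sum(axis=1) / m.sum()
        start += len(g)
    return out


def msd(
    traj: Trajectory,
    tags: list[RegionTags] | None = None,
    subset: str = "all",
    mode: str = "lateral",
    window: tuple[float, float] | None = None,
    interval_ns: float = 2.0,
    molecule_type: str | None = None,
    site_name: str | None = None,
) -> MSDCurve:
    """Interval-averaged MSD of a lipid (or tracer) subset.

    `subset` is a region label (SR/BUFFER/LR) or "all"; molecules whose tag
    changes within an interval are excluded from that interval.  `mode`
    selects the displacement components: lateral (xy), normal (z) or full.
    """
    if mode not in _MODE_AXES:
        raise ValueError(f"unknown mode {mode!r}")
    if molecule_type is None:
        molecule_type = "AOPC" if "AOPC" in traj.topology.molecule_types else \
            str(traj.topology.molecule_types[0])
    sub = traj if window is None else traj.window(*window)
    times = sub.times
    dt = np.diff(times)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("msd requires uniformly spaced frames")
    step = dt[0] if len(dt) else 0.0
    if step <= 0:
        raise ValueError("need at least two frames")
    frames_per_interval = int(round(interval_ns / step))
    if frames_per_interval < 2:
        raise ValueError("interval too short for the frame spacing")
    n_intervals = (sub.n_frames - 1) // frames_per_interval
    if n_intervals < 1:
        raise ValueError("window shorter than one interval")
    mols = sub.topology.molecules_of_type(molecule_type)
    pos = com_trajectory(sub, mols, site_name=site_name)
    axes = list(_MODE_AXES[mode])
    n_lags = frames_per_interval + 1
    acc = np.zeros(n_lags)
    counts = np.zeros(n_lags)
    n_used_mols = 0
    for b in range(n_intervals):
        i0 = b * frames_per_interval
        i1 = i0 + frames_per_interval
        if subset == "all" or tags is None:
            keep = np.ones(len(mols), dtype=bool)
        else:
            t_start = tags_at(tags, times[i0])
            t_end = tags_at(tags, times[i1] - 1e-9)
            keep = np.array(
                [
                    t_start.labels.get(int(m)) == subset
                    and t_end.labels.get(int(m)) == subset
                    for m in mols
                ]
            )
        if not keep.any():
            continue
        n_used_mols = max(n_used_mols, int(keep.sum()))
        d = pos[i0 : i1 + 1, keep][:, :, axes] - pos[i0, keep][None, :, axes]
        sq = np.sum(d**2, axis=-1).mean(axis=1)
        acc[: len(sq)] += sq
        counts[: len(sq)] += 1
    if counts[0] == 0:
        n_dropped = len(mols)
        raise ValueError(
            f"subset {subset!r} empty after tag-constancy filter "
            f"({n_dropped} molecules dropped)"
        )
    values = acc / counts
    lags = np.arange(n_lags) * step
    return MSDCurve(lags=lags, values=values, mode=mode, subset=subset,
                    n_molecules=n_used_mols, n_origins=int(counts[0]))


def _fit_slope(lags: np.ndarray, values: np.ndarray) -> float:
    m, _ = np.polyfit(lags, values, 1)
    return float(m)


def diffusion_coefficient(
    curve: MSDCurve,
    fit_fraction: tuple[float, float] = (0.1, 0.9),
) -> DiffusionEstimate:
    """Einstein-relation diffusion coefficient from an MSD curve.

    D = slope / (2 d) over the central fit fraction of the lag range; the
    uncertainty is |D_first_half - D_second_half| / 2 over the two halves
    of the fit range.  A negative fitted slope is clamped to D = 0 with
    the `clamped` flag set.
    """
    d = _MODE_DIM[curve.mode]
    tau_max = curve.lags[-1]
    lo, hi = fit_fraction[0] * tau_max, fit_fraction[1] * tau_max
    sel = (curve.lags >= lo - 1e-12) & (curve.lags <= hi + 1e-12)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 lag points in the fit range")
    lags = curve.lags[sel]
    vals = curve.values[sel]
    slope = _fit_slope(lags, vals)
    mid = lags[0] + (lags[-1] - lags[0]) / 2.0
    first = lags <= mid
    second = lags >= mid
    d1 = _fit_slope(lags[first], vals[first]) / (2 * d)
    d2 = _fit_slope(lags[second], vals[second]) / (2 * d)
    D = slope / (2 * d)
    clamped = False
    if D < 0:
        import warnings

        warnings.warn("negative fitted MSD slope; clamping D to 0")
        D = 0.0
        clamped = True
    return DiffusionEstimate(
        d_cm2_s=D * NM2_PER_NS_TO_CM2_PER_S,
        uncertainty_cm2_s=abs(d1 - d2) / 2.0 * NM2_PER_NS_TO_CM2_PER_S,
        fit_range_ns=(float(lags[0]), float(lags[-1])),
        dimensionality=d,
        clamped=clamped,
    )
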