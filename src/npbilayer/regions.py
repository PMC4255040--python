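"""Short-range / buffer / long-range lipid classification around the AuNP.

Lipids of the nanoparticle-interacting leaflet are classified every epoch
(default 10 ns) by the 3D minimum-image distance of their head-group
nitrogen from the nanoparticle center of mass:

* SR      : d <= r + 1.5 nm
* BUFFER  : r + 1.5 nm < d < r + 2.0 nm   (excluded from most analyses)
* LR      : d >= r + 2.0 nm

Boundary ties therefore go to the non-buffer region.  Lipids of the other
leaflet are tagged OTHER_LEAFLET.  Without a nanoparticle every lipid is LR
(reference-system convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    Frame,
    LeafletAssignment,
    Topology,
    Trajectory,
    assign_leaflets,
    center_of_mass,
    minimum_image_distance,
)

__all__ = [
    "SR",
    "BUFFER",
    "LR",
    "OTHER_LEAFLET",
    "RegionBoundaries",
    "RegionTags",
    "classify_lipids",
    "tag_trajectory",
    "region_counts",
]

SR = "SR"
BUFFER = "BUFFER"
LR = "LR"
OTHER_LEAFLET = "OTHER_LEAFLET"

#: short-range margin beyond the particle radius, nm
SR_MARGIN = 1.5
#: buffer shell width beyond the SR cutoff, nm
BUFFER_WIDTH = 0.5


@dataclass(frozen=True)
class RegionBoundaries:
    """SR/buffer/LR distance cutoffs for a nanoparticle of radius r (nm)."""

    r: float
    sr_margin: float = SR_MARGIN
    buffer_width: float = BUFFER_WIDTH

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("nanoparticle radius must be >= 0")
        if self.sr_margin <= 0 or self.buffer_width <= 0:
            raise ValueError("margins must be positive")

    @property
    def d_sr(self) -> float:
        return self.r + self.sr_margin

    @property
    def d_buf(self) -> float:
        return self.r + self.sr_margin + self.buffer_width


@dataclass
class RegionTags:
    """Per-lipid region labels for one epoch."""

    epoch_index: int
    t_start: float
    t_end: float
    labels: dict[int, str]

    def lipids_in(self, region: str) -> list[int]:
        return [m for m, lab in self.labels.items() if lab == region]

    def counts(self) -> dict[str, int]:
        return {
            reg: sum(1 for lab in self.labels.values() if lab == reg)
            for reg in (SR, BUFFER, LR, OTHER_LEAFLET)
        }

    def to_dict(self) -> dict:
        return {
            "epoch_index": self.epoch_index,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "labels": {str(k): v for k, v in self.labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionTags":
        return cls(
            int(d["epoch_index"]),
            float(d["t_start"]),
            float(d["t_end"]),
            {int(k): v for k, v in d["labels"].items()},
        )


def classify_lipids(
    frame: Frame,
    topology: Topology,
    np_com: np.ndarray | None,
    boundaries: RegionBoundaries | None,
    leaflets: LeafletAssignment | None = None,
    lipid_type: str = "AOPC",
    nitrogen_site: str = "N",
    epoch_index: int = 0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> RegionTags:
    """Classify the interacting-leaflet lipids of one frame.

    With no nanoparticle (``np_com is None``) all lipids are LR.
    """
    lipids = topology.lipid_ids(lipid_type)
    if t_start is None:
        t_start = frame.time
    if t_end is None:
        t_end = frame.time
    if np_com is None or boundaries is None:
        labels = {int(m): LR for m in lipids}
        return RegionTags(epoch_index, t_start, t_end, labels)
    if leaflets is None:
        leaflets = assign_leaflets(frame, topology, np_com, lipid_type)
    interacting = set(leaflets.interacting_lipids)
    labels: dict[int, str] = {}
    for m in lipids:
        m = int(m)
        if m not in interacting:
            labels[m] = OTHER_LEAFLET
            continue
        try:
            n_idx = topology.index_of(m, nitrogen_site)
        except KeyError:
            raise ValueError(f"lipid {m} is missing its {nitrogen_site!r} site")
        d = float(
            minimum_image_distance(frame.positions[n_idx], np_com, frame.box)
        )
        if d <= boundaries.d_sr:
            labels[m] = SR
        elif d < boundaries.d_buf:
            labels[m] = BUFFER
        else:
            labels[m] = LR
    return RegionTags(epoch_index, t_start, t_end, labels)


def tag_trajectory(
    traj: Trajectory,
    boundaries: RegionBoundaries | None,
    epoch_length_ns: float = 10.0,
    lipid_type: str = "AOPC",
    gold_type: str = "AU",
) -> list[RegionTags]:
    """Re-tag lipids every epoch.

    Boundaries are evaluated on the first frame at/after each epoch start;
    the nanoparticle CoM is recomputed there.  Leaflet identity is fixed
    from the first frame of the trajectory.  Tags are held constant within
    the epoch.
    """
    if epoch_length_ns <= 0:
        raise ValueError("epoch length must be positive")
    times = traj.times
    t0, t_last = times[0], times[-1]
    gold_idx = traj.topology.select(molecule_type=gold_type)
    has_np = gold_idx.size > 0 and boundaries is not None

    def np_com_at(frame: Frame) -> np.ndarray | None:
        if not has_np:
            return None
        return center_of_mass(frame, gold_idx, traj.topology.masses)

    leaflets = None
    if has_np:
        leaflets = assign_leaflets(
            traj.frames[0], traj.topology, np_com_at(traj.frames[0]), lipid_type
        )
    n_epochs = max(1, int(np.ceil((t_last - t0) / epoch_length_ns - 1e-9)))
    tags: list[RegionTags] = []
    for e in range(n_epochs):
        start = t0 + e * epoch_length_ns
        end = start + epoch_length_ns
        i = int(np.searchsorted(times, start - 1e-9))
        frame = traj.frames[min(i, traj.n_frames - 1)]
        tags.append(
            classify_lipids(
                frame,
                traj.topology,
                np_com_at(frame),
                boundaries if has_np else None,
                leaflets=leaflets,
                lipid_type=lipid_type,
                epoch_index=e,
                t_start=start,
                t_end=end,
            )
        )
    return tags


def tags_at(tags: list[RegionTags], time: float) -> RegionTags:
    """The epoch tags governing a given time (last epoch is closed above)."""
    for t in tags:
        if t.t_start - 1e-9 <= time < t.t_end - 1e-9:
            return t
    return tags[-1]


def region_counts(tags: list[RegionTags]) -> pd.DataFrame:
    """Per-epoch lipid counts in each region."""
    rows = []
    for t in tags:
        c = t.counts()
        rows.append(
            {
                "epoch": t.epoch_index,
                "t_start": t.t_start,
                "t_end": t.t_end,
                "n_SR": c[SR],
                "n_BUFFER": c[BUFFER],
                "n_LR": c[LR],
                "n_other_leaflet": c[OTHER_LEAFLET],
            }
        )
    return pd.DataFrame(rows)
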