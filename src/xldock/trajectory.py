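"""Distance time-series over conformational trajectories.

Trajectories are consumed as multi-model PDB (the format-neutral common
denominator for snapshot series).  The analyses mirror how restrained and
unrestrained simulation runs are judged: per-restraint distance traces
against their d0 threshold, minimum-distance traces from a probe residue's
Cβ to any heavy atom of a target chain, and centroid/RMSD displacement of
a region after superposition on an anchor region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .restraints import RestraintSet
from .structures import ResidueRef, Structure, Trajectory, distance, get_anchor_atom

__all__ = [
    "DistanceSeries",
    "RunProtocol",
    "restraint_series",
    "min_distance_series",
    "displacement_summary",
]


@dataclass
class DistanceSeries:
    """Per-frame distances for one restraint or probe, with threshold."""

    series_id: str
    distances: np.ndarray
    frame_labels: np.ndarray
    d0: float | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        self.frame_labels = np.asarray(self.frame_labels, float)
        if self.distances.shape != self.frame_labels.shape:
            raise ValueError("distances and frame labels must align")

    @property
    def n_frames(self) -> int:
        return self.distances.size

    @property
    def fraction_within(self) -> float:
        """Fraction of frames with d ≤ d0 (nan when no threshold is set)."""
        if self.d0 is None:
            return float("nan")
        return float(np.mean(self.distances <= self.d0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "series": self.series_id,
                "frame": self.frame_labels,
                "distance": self.distances,
                "d0": self.d0,
            }
        )


@dataclass(frozen=True)
class RunProtocol:
    """Bookkeeping for a restrained-then-free run.

    ``restrained_until`` is the frame label at which restraints were
    switched off (0 for an unrestrained run); ``weight`` is the harmonic
    weight applied during the restrained phase.
    """

    restrained_until: float = 0.0
    weight: float = 10.0

    def restrained_mask(self, labels: np.ndarray) -> np.ndarray:
        return np.asarray(labels, float) <= self.restrained_until


def restraint_series(t: Trajectory, rs: RestraintSet) -> list[DistanceSeries]:
    """One distance trace per restraint across all frames."""
    labels = np.array(t.labels())
    out = []
    for r in rs:
        (ca, sa, ia, aa), (cb, sb, ib, ab) = r.anchors()
        d = np.empty(len(t.frames))
        for i, frame in enumerate(t.frames):
            atom_a = get_anchor_atom(frame, (ca, sa, ia), aa)
            atom_b = get_anchor_atom(frame, (cb, sb, ib), ab)
            d[i] = distance(atom_a, atom_b)
        out.append(
            DistanceSeries(
                series_id=r.label or f"{ca}{sa}:{aa}-{cb}{sb}:{ab}",
                distances=d,
                frame_labels=labels,
                d0=r.d0,
            )
        )
    return out


def min_distance_series(
    t: Trajectory,
    probe: ResidueRef | tuple,
    target_chain: str,
    threshold: float | None = 9.0,
) -> DistanceSeries:
    """Per-frame minimum distance from the probe Cβ to target heavy atoms."""
    if isinstance(probe, ResidueRef):
        key = (probe.chain, probe.seq, probe.icode)
    else:
        key = (probe + ("",))[:3]
    labels = np.array(t.labels())
    d = np.empty(len(t.frames))
    for i, frame in enumerate(t.frames):
        cb = get_anchor_atom(frame, key, "CB")
        target = frame.coords(chain=target_chain, heavy_only=True)
        if target.shape[0] == 0:
            raise ValueError(f"target chain {target_chain!r} has no heavy atoms")
        d[i] = float(np.min(np.linalg.norm(target - cb.xyz, axis=1)))
    return DistanceSeries(
        series_id=f"min:{key[0]}{key[1]}-chain{target_chain}",
        distances=d,
        frame_labels=labels,
        d0=threshold,
    )


def _region_coords(frame: Structure, region: set[tuple[str, int]], atom_names=("N", "CA", "C")) -> np.ndarray:
    pts = []
    for chain, seq in sorted(region):
        res = frame.get_residue(chain, seq)
        for name in atom_names:
            if res.has_atom(name):
                pts.append(res.atom(name).xyz)
    if not pts:
        raise ValueError("region resolves to no backbone atoms")
    return np.array(pts)


def _superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation taking mobile onto reference."""
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    return R, t


@dataclass
class DisplacementSummary:
    """Per-frame centroid displacement and backbone RMSD of a region."""

    centroid_displacement: np.ndarray
    rmsd: np.ndarray
    frame_labels: np.ndarray
    reference_frame: int

    @property
    def max_displacement(self) -> float:
        return float(self.centroid_displacement.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_labels,
                "centroid_displacement": self.centroid_displacement,
                "rmsd": self.rmsd,
            }
        )


def displacement_summary(
    t: Trajectory,
    region: set[tuple[str, int]],
    reference_frame: int = 0,
    anchor_region: set[tuple[str, int]] | None = None,
) -> DisplacementSummary:
    """Region motion relative to a reference frame.

    Each frame is first superposed onto the reference on ``anchor_region``
    (backbone least-squares fit); the region's centroid displacement and
    backbone RMSD are then measured in that common frame.  With no anchor
    region the fit is skipped and raw coordinates are compared.
    """
    if not region:
        raise ValueError("empty region")
    ref = t.frames[reference_frame]
    ref_region = _region_coords(ref, region)
    ref_centroid = ref_region.mean(axis=0)
    anchor_ref = _region_coords(ref, anchor_region) if anchor_region else None
    n = len(t.frames)
    disp = np.empty(n)
    rmsd = np.empty(n)
    for i, frame in enumerate(t.frames):
        coords = _region_coords(frame, region)
        if anchor_ref is not None:
            R, trans = _superpose(_region_coords(frame, anchor_region), anchor_ref)
            coords = coords @ R.T + trans
        disp[i] = float(np.linalg.norm(coords.mean(axis=0) - ref_centroid))
        rmsd[i] = float(np.sqrt(np.mean(np.sum((coords - ref_region) ** 2, axis=1))))
    return DisplacementSummary(
        centroid_displacement=disp,
        rmsd=rmsd,
        frame_labels=np.array(t.labels()),
        reference_frame=reference_frame,
    )
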