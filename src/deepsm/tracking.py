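"""Frame-to-frame particle linking and 3D trajectory assembly.

Detections are linked greedily by nearest neighbour under a maximum-jump
gate, with short gaps bridged; each linked detection is refined to sub-pixel
XY by Gaussian fitting of the matched-filter response and to Z through the
evanescent-decay law.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal

from .analysis import _matched_kernel, compute_snr_db, detect_particles
from .optics import OpticalModel
from .reconstruct import (
    BindingEvent,
    infer_z,
    localize_xy,
    measure_amplitude,
    theoretical_dmax,
)
from .simulate import ImageSequence

__all__ = ["Trajectory", "DisplacementSummary", "track", "displacement_summary"]


@dataclasses.dataclass
class Trajectory:
    particle_id: int
    table: pd.DataFrame  # columns: frame, t_ms, x_px, y_px, x_nm, y_nm, z_nm, intensity, snr_db
    events: list[BindingEvent] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def positions_nm(self) -> np.ndarray:
        return self.table[["x_nm", "y_nm", "z_nm"]].to_numpy()


@dataclasses.dataclass
class DisplacementSummary:
    dx_max_nm: float
    dy_max_nm: float
    dz_max_nm: float
    dx_max_theory_nm: float
    dz_max_theory_nm: float
    precision_nm: tuple[float, float, float]


class _Track:
    __slots__ = ("rows", "last_frame", "last_xy")

    def __init__(self, row, frame, xy):
        self.rows = [row]
        self.last_frame = frame
        self.last_xy = xy


def track(
    seq: ImageSequence,
    optical: OpticalModel | None = None,
    background: np.ndarray | None = None,
    link_gate_px: float = 5.0,
    max_gap_frames: int = 2,
    min_length: int = 2,
    decay_nm: float | None = None,
    threshold_db: float | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Detect, link and localize particles across a sequence.

    Returns the trajectories (length >= ``min_length``) and a table of
    detections that could not be linked.  Z is inferred per frame from the
    5x5 mean of the absolute matched-filter response, taking I0 as the
    trajectory's maximum (particle closest to the surface).
    """
    optical = optical or OpticalModel()
    if background is None:
        background = np.full(seq.frames.shape[1:], optical.background_level)
    decay = decay_nm if decay_nm is not None else optical.evanescent_decay_nm
    kernel = _matched_kernel(optical)
    px_nm = seq.pixel_size_um * 1e3

    kwargs = {} if threshold_db is None else {"threshold_db": threshold_db}
    tracks: list[_Track] = []
    done: list[_Track] = []
    orphans = []
    for frame_idx in range(len(seq)):
        diff = seq.frames[frame_idx] - background
        response = np.abs(signal.fftconvolve(diff, kernel[::-1, ::-1], mode="same"))
        detections = detect_particles(diff, optical, **kwargs)

        # expire stale tracks
        still_open = []
        for tr in tracks:
            if frame_idx - tr.last_frame > max_gap_frames + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        tracks = still_open

        used = set()
        assignments: list[tuple[float, _Track, int]] = []
        for tr in tracks:
            for j, (dx, dy) in enumerate(detections):
                dist = np.hypot(dx - tr.last_xy[0], dy - tr.last_xy[1])
                gap = frame_idx - tr.last_frame
                if dist <= link_gate_px * gap:
                    assignments.append((dist, tr, j))
        assignments.sort(key=lambda a: a[0])
        matched_tracks = set()
        for dist, tr, j in assignments:
            if j in used or id(tr) in matched_tracks:
                continue
            used.add(j)
            matched_tracks.add(id(tr))
            row = _measure(diff, response, detections[j], frame_idx, seq, optical)
            if row is not None:
                tr.rows.append(row)
                tr.last_frame = frame_idx
                tr.last_xy = (row["x_px"], row["y_px"])
        for j, det in enumerate(detections):
            if j in used:
                continue
            row = _measure(diff, response, det, frame_idx, seq, optical)
            if row is None:
                orphans.append({"frame": frame_idx, "x_px": det[0], "y_px": det[1]})
                continue
            tracks.append(_Track(row, frame_idx, (row["x_px"], row["y_px"])))
    done.extend(tracks)

    trajectories = []
    pid = 0
    for tr in done:
        if len(tr.rows) < min_length:
            orphans.extend(
                {"frame": r["frame"], "x_px": r["x_px"], "y_px": r["y_px"]}
                for r in tr.rows
            )
            continue
        table = pd.DataFrame(tr.rows)
        i0 = float(table["intensity"].max())
        table["z_nm"] = [
            infer_z(v, i0, decay) if 0 < v <= i0 else 0.0
            for v in table["intensity"]
        ]
        table["x_nm"] = table["x_px"] * px_nm
        table["y_nm"] = table["y_px"] * px_nm
        trajectories.append(Trajectory(pid, table.reset_index(drop=True)))
        pid += 1
    orphan_table = pd.DataFrame(orphans, columns=["frame", "x_px", "y_px"])
    return trajectories, orphan_table


def _measure(diff, response, det, frame_idx, seq, optical):
    try:
        x, y = localize_xy(response, det)
        intensity = measure_amplitude(response, (x, y))
        snr = compute_snr_db(diff, (x, y)).snr_db
    except ValueError:
        return None
    return {
        "frame": frame_idx,
        "t_ms": frame_idx * seq.frame_interval_ms,
        "x_px": x,
        "y_px": y,
        "intensity": intensity,
        "snr_db": snr,
    }


def displacement_summary(
    trajectory: Trajectory,
    diameter_nm: float,
    contour_length_nm: float,
    z_cutoff_nm: float = 20.0,
) -> DisplacementSummary:
    """Empirical max displacements vs. the tether-geometry bounds.

    Lateral statistics are restricted to frames with Z <= ``z_cutoff_nm``,
    where localization is reliable; the precision triple is the per-axis SD.
    """
    table = trajectory.table
    near = table[table["z_nm"] <= z_cutoff_nm]
    if len(near) == 0:
        near = table
    dx = float(near["x_nm"].max() - near["x_nm"].min())
    dy = float(near["y_nm"].max() - near["y_nm"].min())
    dz = float(table["z_nm"].max() - table["z_nm"].min())
    dxy_theory, dz_theory = theoretical_dmax(diameter_nm, contour_length_nm)
    precision = (
        float(near["x_nm"].std(ddof=1)) if len(near) > 1 else 0.0,
        float(near["y_nm"].std(ddof=1)) if len(near) > 1 else 0.0,
        float(table["z_nm"].std(ddof=1)) if len(table) > 1 else 0.0,
    )
    return DisplacementSummary(dx, dy, dz, dxy_theory, dz_theory, precision)
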