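"""Projection of tracked cells onto a reference curve and event kymographs.

The notochord (or any reference polyline, ordered posterior -> anterior) is
used as a moving spatial reference frame: each cell is projected to its
nearest point on the curve (Euclidean distance), giving an arc-length
coordinate measured from the posterior tail tip, and a lateral offset.
Event kymographs are (time-row x arc-length-bin) matrices coloured by an
event value (last-peak or onset time); intra-somite phase profiles relate
normalised rostro-caudal position to event time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceCurve",
    "project_to_curve",
    "project_table",
    "align_segments",
    "Kymograph",
    "build_event_kymograph",
    "somite_phase_profile",
]


def project_to_curve(point: Sequence[float],
                     vertices: np.ndarray) -> tuple[float, float]:
    """Nearest-point projection of a 2-D point onto a polyline.

    Returns (arc_length, lateral_offset): arc length from the posterior end
    (vertex 0) to the foot of the projection, and the unsigned Euclidean
    distance.  Ties are broken toward the smaller arc length.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValueError("curve frame needs >= 2 (x, y) vertices")
    p = np.asarray(point, dtype=float)
    a = v[:-1]
    b = v[1:]
    ab = b - a
    seg_len = np.linalg.norm(ab, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("degenerate zero-length curve segment")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = np.einsum("ij,ij->i", p - a, ab) / seg_len**2
    t = np.clip(t, 0.0, 1.0)
    foot = a + t[:, None] * ab
    dist = np.linalg.norm(p - foot, axis=1)
    arcs = cum[:-1] + t * seg_len
    # smallest distance; ties (within float tolerance) toward smaller arc
    dmin = dist.min()
    candidates = np.flatnonzero(dist <= dmin + 1e-9)
    i = candidates[np.argmin(arcs[candidates])]
    return float(arcs[i]), float(dist[i])


@dataclass
class ReferenceCurve:
    """Per-frame reference polyline, ordered posterior -> anterior."""

    frames: dict[int, np.ndarray]

    def __post_init__(self):
        for f, v in self.frames.items():
            v = np.asarray(v, dtype=float)
            if v.shape[0] < 2:
                raise ValueError(f"frame {f}: need >= 2 vertices")
            d = np.linalg.norm(np.diff(v, axis=0), axis=1)
            if np.any(d <= 0):
                raise ValueError(f"frame {f}: arc length must strictly increase")
            self.frames[f] = v

    def vertices(self, frame: int) -> np.ndarray:
        return self.frames[frame]

    def total_length(self, frame: int) -> float:
        v = self.frames[frame]
        return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())

    def point_at_arc(self, frame: int, s: float) -> np.ndarray:
        """Inverse mapping: the curve point at arc length s (clamped)."""
        v = self.frames[frame]
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (s - cum[i]) / seg[i]
        return v[i] + t * (v[i + 1] - v[i])

    @classmethod
    def static_line(cls, length: float, frames: Iterable[int],
                    n_vertices: int = 50, curvature: float = 0.0) -> "ReferenceCurve":
        """A straight (or gently bowed) posterior->anterior test curve."""
        x = np.linspace(0.0, length, n_vertices)
        y = curvature * np.sin(np.pi * x / length) if curvature else np.zeros_like(x)
        v = np.column_stack([x, y])
        return cls(frames={f: v.copy() for f in frames})


def project_table(tracks: pd.DataFrame, curve: ReferenceCurve) -> pd.DataFrame:
    """Project every (cell, frame) row of a track table onto the curve.

    Expects columns cell_id, frame, x, y; an optional z column is ignored
    after the planar flattening.  Adds arc_length and lateral_offset."""
    out = tracks.copy()
    arcs = np.empty(len(tracks))
    offs = np.empty(len(tracks))
    pts = tracks[["x", "y"]].to_numpy(dtype=float)
    for i, (frame, p) in enumerate(zip(tracks["frame"].to_numpy(), pts)):
        arcs[i], offs[i] = project_to_curve(p, curve.vertices(int(frame)))
    out["arc_length"] = arcs
    out["lateral_offset"] = offs
    return out


def align_segments(projected: pd.DataFrame,
                   anchors: Optional[dict[int, float]] = None) -> pd.DataFrame:
    """Map each frame's projections to a common arc-length origin.

    ``anchors`` gives the per-frame arc length of the alignment landmark
    (for example the anterior-most formed somite boundary); by default the
    posterior tail tip (arc length 0) is used, i.e. positions are already
    in the common frame.  Adds an ``aligned_arc`` column."""
    out = projected.copy()
    if anchors is None:
        out["aligned_arc"] = out["arc_length"]
        return out
    anchor = out["frame"].map(lambda f: anchors.get(int(f), 0.0))
    out["aligned_arc"] = out["arc_length"] - anchor
    return out


@dataclass
class Kymograph:
    """(time-row x arc-bin) matrix of event values with occupancy counts."""

    values: np.ndarray  # NaN where empty
    counts: np.ndarray
    row_times: np.ndarray
    bin_edges: np.ndarray
    color_semantics: str = "last_peak"

    @property
    def total_cells(self) -> int:
        return int(self.counts.sum())


def build_event_kymograph(events: pd.DataFrame, bin_width: float = 10.0,
                          row_interval: Optional[float] = None,
                          color_semantics: str = "last_peak",
                          arc_range: Optional[tuple[float, float]] = None) -> Kymograph:
    """Bin per-cell events into a kymograph.

    ``events`` needs one row per cell with columns event_time and
    aligned_arc (the position where the event occurred).  Rows are time
    bins of width ``row_interval`` (defaults to spanning 40 rows); columns
    are arc-length bins of ``bin_width``.  Multiple cells in a bin are
    averaged; empty bins are NaN."""
    if events.empty:
        raise ValueError("no events to bin")
    t = events["event_time"].to_numpy(dtype=float)
    s = events["aligned_arc"].to_numpy(dtype=float)
    if arc_range is None:
        arc_range = (float(np.floor(s.min() / bin_width) * bin_width),
                     float(np.ceil(s.max() / bin_width) * bin_width))
    lo, hi = arc_range
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    if row_interval is None:
        row_interval = max((t.max() - t.min()) / 40.0, 1e-9)
    t0 = t.min()
    n_rows = int(np.floor((t.max() - t0) / row_interval)) + 1
    values = np.zeros((n_rows, len(edges) - 1))
    counts = np.zeros_like(values, dtype=int)
    for ti, si in zip(t, s):
        r = min(int((ti - t0) / row_interval), n_rows - 1)
        c = min(int((si - lo) / bin_width), len(edges) - 2)
        c = max(c, 0)
        values[r, c] += ti
        counts[r, c] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, values / np.maximum(counts, 1), np.nan)
    row_times = t0 + row_interval * np.arange(n_rows)
    return Kymograph(values=values, counts=counts, row_times=row_times,
                     bin_edges=edges, color_semantics=color_semantics)


def somite_phase_profile(cells: pd.DataFrame,
                         event_col: str = "event_time") -> tuple[pd.DataFrame, float, int]:
    """Intra-somite phase profile: normalised rostro-caudal position versus
    event time.

    ``cells`` needs columns somite (label), arc_length (position at the
    event) and the event column.  Within each somite, positions are
    normalised so 0 = rostral (anterior) and 1 = caudal (posterior).
    Returns (profile table, intra-somite rank correlation of position vs
    time -- the cell-count-weighted mean of per-somite Spearman
    coefficients -- and the number of excluded unlabelled cells)."""
    labelled = cells.dropna(subset=["somite"])
    n_excluded = len(cells) - len(labelled)
    rows = []
    rhos: list[tuple[float, int]] = []
    for somite, grp in labelled.groupby("somite"):
        s = grp["arc_length"].to_numpy(dtype=float)
        ev = grp[event_col].to_numpy(dtype=float)
        span = s.max() - s.min()
        # anterior = larger arc length = rostral = coordinate 0
        rc = (s.max() - s) / span if span > 0 else np.full(len(s), 0.5)
        for cid, pos, e in zip(grp["cell_id"], rc, ev):
            rows.append({"cell_id": cid, "somite": somite,
                         "rostrocaudal_pos": float(pos), event_col: float(e)})
        if len(grp) >= 3 and len(np.unique(rc)) > 1 and len(np.unique(ev)) > 1:
            rhos.append((float(stats.spearmanr(rc, ev).statistic), len(grp)))
    profile = pd.DataFrame(rows)
    if rhos:
        weights = np.array([n for _, n in rhos], dtype=float)
        rho = float(np.average([r for r, _ in rhos], weights=weights))
    else:
        rho = 0.0
    return profile, rho, n_excluded
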