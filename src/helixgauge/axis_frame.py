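"""Helical-axis trace and the discrete Frenet frame along it.

The helical axis is the discrete curve of midpoints r_i between paired
backbone points of the two strands.  At each interior axis point a discrete
frame is built from neighbouring points only:

    t_i = (r_{i+1} - r_i) / |r_{i+1} - r_i|          (tangent)
    b_i = (t_{i-1} × t_i) / |t_{i-1} × t_i|          (binormal)
    n_i = b_i × t_i                                   (normal)

so that (t, b, n) is a right-handed orthonormal triple wherever consecutive
tangents are not collinear.  Internal length unit is nm (coordinates arrive
in Å and are converted once here): the model's curvature/torsion magnitudes
and the elastic-constant prefactors are dimensionally sensible only with
nm-scale steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContentError, DegenerateGeometryError
from .structure_io import DuplexPairing

ANGSTROM_PER_NM = 10.0

#: Consecutive axis points closer than this (nm) are rejected as degenerate.
MIN_STEP_NM = 0.01

#: Tangent cross products smaller than this mark a frame site invalid.
CROSS_TOLERANCE = 1e-8


@dataclass
class AxisTrace:
    """Axis points r_i (nm), arc steps Δs_{i,i-1} and cumulative arc length."""

    points: np.ndarray          # (N, 3) nm
    steps: np.ndarray           # (N,) nm; steps[i] = |r_i - r_{i-1}|, steps[0] = nan
    cumulative_arc: np.ndarray  # (N,) nm; arc[0] = 0

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class FrameSet:
    """Discrete frames along the axis, with per-site validity flags.

    ``tangents[i]`` is defined for i in [0, N-2]; ``binormals``/``normals``
    for i in [1, N-2] where consecutive tangents are not collinear.
    Undefined entries are NaN.
    """

    tangents: np.ndarray    # (N, 3)
    binormals: np.ndarray   # (N, 3)
    normals: np.ndarray     # (N, 3)
    valid: np.ndarray       # (N,) bool: full (t, b, n) triple available
    site_range: tuple[int, int]   # inclusive index interval of potentially valid sites

    def __len__(self) -> int:
        return len(self.valid)

    def matrix(self, i: int) -> np.ndarray:
        """Frame at site i as a 3×3 matrix with rows (n_i, b_i, t_i)."""
        if not self.valid[i]:
            raise ValueError(f"no valid frame at site {i}")
        return np.stack([self.normals[i], self.binormals[i], self.tangents[i]])


def axis_trace(pairing: DuplexPairing) -> AxisTrace:
    """Midpoint axis r_i = (l_i + l'_i)/2 of a paired duplex, in nm."""
    if len(pairing) < 2:
        raise ContentError("need at least 2 base pairs to define an axis")
    a_pts = pairing.trace_a.points
    b_pts = pairing.trace_b.points
    mids = np.stack(
        [(a_pts[ia] + b_pts[ib]) / 2.0 for ia, ib in pairing.pairs]
    ) / ANGSTROM_PER_NM
    return axis_from_points(mids)


def axis_from_points(points_nm: np.ndarray, min_step: float = MIN_STEP_NM) -> AxisTrace:
    """Build an :class:`AxisTrace` from raw axis points already in nm.

    ``min_step`` guards against (near-)coincident points; the default is the
    base-pair-scale threshold, which callers sampling much finer curves may
    lower.
    """
    points = np.asarray(points_nm, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ContentError("axis needs an (N>=2, 3) array of points")
    deltas = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(deltas < min_step):
        bad = int(np.argmax(deltas < min_step)) + 1
        raise DegenerateGeometryError(
            f"axis points {bad - 1} and {bad} are {deltas[bad - 1]:.4g} nm apart "
            f"(< {min_step} nm)"
        )
    steps = np.concatenate([[np.nan], deltas])
    arc = np.concatenate([[0.0], np.cumsum(deltas)])
    return AxisTrace(points=points, steps=steps, cumulative_arc=arc)


def build_frames(points: np.ndarray, tolerance: float = CROSS_TOLERANCE) -> FrameSet:
    """Construct the discrete frame (t, b, n) along ordered axis points.

    Sites where |t_{i-1} × t_i| < ``tolerance`` (locally collinear axis) are
    marked invalid and excluded from all downstream statistics.
    """
    points = np.asarray(points, dtype=float)
    n_pts = len(points)
    if n_pts < 3:
        raise ContentError(f"need at least 3 axis points to build frames, got {n_pts}")
    tangents = np.full((n_pts, 3), np.nan)
    binormals = np.full((n_pts, 3), np.nan)
    normals = np.full((n_pts, 3), np.nan)
    valid = np.zeros(n_pts, dtype=bool)

    diffs = points[1:] - points[:-1]
    norms = np.linalg.norm(diffs, axis=1)
    if np.any(norms == 0):
        raise DegenerateGeometryError("coincident consecutive axis points")
    tangents[:-1] = diffs / norms[:, None]

    for i in range(1, n_pts - 1):
        cross = np.cross(tangents[i - 1], tangents[i])
        cross_norm = np.linalg.norm(cross)
        if cross_norm < tolerance:
            continue
        binormals[i] = cross / cross_norm
        normal = np.cross(binormals[i], tangents[i])
        normals[i] = normal / np.linalg.norm(normal)
        valid[i] = True
    return FrameSet(
        tangents=tangents,
        binormals=binormals,
        normals=normals,
        valid=valid,
        site_range=(1, n_pts - 2),
    )


def frames_tsv(axis: AxisTrace, frames: FrameSet) -> str:
    """TSV dump: site, r (nm), t, b, n components, valid flag."""
    header = (
        "site\tr_x_nm\tr_y_nm\tr_z_nm\tt_x\tt_y\tt_z\tb_x\tb_y\tb_z\tn_x\tn_y\tn_z\tvalid"
    )
    rows = [header]
    for i in range(len(axis)):
        vals = list(axis.points[i]) + list(frames.tangents[i]) + \
            list(frames.binormals[i]) + list(frames.normals[i])
        rows.append(
            f"{i}\t" + "\t".join(f"{v:.10g}" for v in vals) + f"\t{int(frames.valid[i])}"
        )
    return "\n".join(rows) + "\n"
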