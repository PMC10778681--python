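"""Frame-transfer rotations, zyz Euler angles and the gauge potential.

The frame at site i+1 is reached from the frame at site i by the transfer
rotation R_{i+1,i} = F_{i+1} F_i^T (frames as row-stacked (n, b, t) matrices),
and from the anchor frame by the ordered cumulative product
R_{i+1,1} = R_{i+1,i} ... R_{2,1}.

Euler angles use the zyz convention R = Rz(alpha) Ry(beta) Rz(gamma), all
three angles stored in [0, 2pi).  The angles of a site are the zyz angles of
the site's absolute orientation expressed in *helix-aligned* coordinates (the
structure's mean advance direction rotated onto +z): alpha is then the
precession of the base-pair frame about the helical axis, beta the tilt of
the tangent away from it, and gamma the spin of the frame about its own
tangent.  The helical phase

    chi = alpha + gamma   (mod 2pi)

accumulates the full rotation of the frame about the helical axis and is
continuous through the gimbal singularity (beta -> 0), where alpha and gamma
separately are not.  Its period-corrected step is the gauge potential

    d_rho = d_chi  in (-pi, pi],

the signed rotation angle between consecutive base pairs: positive for a
right-handed (B-type) helix, negative for a left-handed (Z-type) one.  On an
ideal duplex it recovers the generator twist exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContentError, DegenerateGeometryError
from .axis_frame import FrameSet

TWO_PI = 2.0 * np.pi

#: sin(beta) below this is treated as gimbal lock (gamma := 0).
GIMBAL_TOLERANCE = 1e-8

#: Maximum deviation from orthogonality accepted by extract_zyz.
ORTHOGONALITY_TOLERANCE = 1e-6

#: Number of terminal axis sites without a complete evaluation (head + tail).
BLIND_SITES = 4


def zyz_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix Rz(alpha) @ Ry(beta) @ Rz(gamma) (standard zyz)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    return np.array(
        [
            [ca * cb * cg - sa * sg, -ca * cb * sg - sa * cg, ca * sb],
            [sa * cb * cg + ca * sg, -sa * cb * sg + ca * cg, sa * sb],
            [-sb * cg, sb * sg, cb],
        ]
    )


def extract_zyz(R: np.ndarray, gimbal_tolerance: float = GIMBAL_TOLERANCE) -> tuple[float, float, float]:
    """zyz Euler angles (alpha, beta, gamma) of a rotation, each in [0, 2pi).

    beta = atan2(sqrt(r13^2 + r23^2), r33) lies in [0, pi]; alpha and gamma
    come from atan2 and are shifted by +2pi when negative so every stored
    angle lands in [0, 2pi).  At gimbal lock (sin beta < tolerance) the
    convention gamma = 0, alpha = total z-rotation applies.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {R.shape}")
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > ORTHOGONALITY_TOLERANCE or np.linalg.det(R) < 0:
        raise ValueError(f"matrix is not a proper rotation (orthogonality error {err:.2e})")
    sin_beta = np.hypot(R[0, 2], R[1, 2])
    beta = np.arctan2(sin_beta, R[2, 2])
    if sin_beta < gimbal_tolerance:
        # rotation (almost) purely about z: put the whole angle into alpha
        if R[2, 2] > 0:
            alpha = np.arctan2(R[1, 0], R[0, 0])
        else:
            alpha = np.arctan2(-R[1, 0], -R[0, 0])
        gamma = 0.0
    else:
        alpha = np.arctan2(R[1, 2], R[0, 2])
        gamma = np.arctan2(R[2, 1], -R[2, 0])
    return (float(alpha % TWO_PI), float(beta), float(gamma % TWO_PI))


def periodic_difference(theta: np.ndarray) -> np.ndarray:
    """Minimal signed consecutive differences of a periodic angle series.

    Each difference theta_{i+1} - theta_i is wrapped into (-pi, pi]: the +2pi
    correction at the period edge for right-handed rotation, and its mirror
    for left-handed rotation.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or len(theta) < 2:
        raise ValueError("need a 1-d angle series of length >= 2")
    return wrap_signed(np.diff(theta))


def wrap_signed(delta: np.ndarray) -> np.ndarray:
    """Wrap angle difference(s) into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(delta, dtype=float), TWO_PI)


@dataclass
class RotationSeries:
    """Relative and cumulative frame-transfer rotations along the axis.

    ``relative[i]`` is R_{i+1,i} (frame i -> frame i+1); ``cumulative[i]`` is
    the ordered product from the segment anchor up to site i (identity at the
    anchor).  Runs of invalid frames split the series into ``segments``
    (inclusive site intervals).  Undefined entries are NaN.
    """

    relative: np.ndarray     # (N, 3, 3)
    cumulative: np.ndarray   # (N, 3, 3)
    segments: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.relative)


def rotation_series(frames: FrameSet) -> RotationSeries:
    """Build transfer rotations R_{i+1,i} = F_{i+1} F_i^T and their cumulative products."""
    n = len(frames)
    relative = np.full((n, 3, 3), np.nan)
    cumulative = np.full((n, 3, 3), np.nan)
    segments: list[tuple[int, int]] = []

    i = 0
    while i < n:
        if not frames.valid[i]:
            i += 1
            continue
        start = i
        while i + 1 < n and frames.valid[i + 1]:
            i += 1
        end = i
        i += 1
        if end == start:
            continue  # an isolated valid frame supports no transfer
        segments.append((start, end))
        cumulative[start] = np.eye(3)
        acc = np.eye(3)
        for k in range(start, end):
            rel = frames.matrix(k + 1) @ frames.matrix(k).T
            relative[k] = rel
            acc = rel @ acc
            cumulative[k + 1] = acc
    if not segments:
        raise ContentError("no two consecutive valid frames: cannot chain rotations")
    return RotationSeries(relative=relative, cumulative=cumulative, segments=segments)


def helical_axis_direction(frames: FrameSet) -> np.ndarray:
    """Unit mean tangent: the structure's overall advance direction."""
    tangents = frames.tangents[~np.isnan(frames.tangents).any(axis=1)]
    mean = tangents.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-6:
        raise DegenerateGeometryError(
            "tangents average to zero: no well-defined helical advance direction"
        )
    return mean / norm


def alignment_rotation(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``direction`` onto +z (pi about x for -z)."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    c = u[2]
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # pi about x
    axis = np.cross(u, [0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass
class EulerSeries:
    """Per-site zyz Euler angles, helical phase, and period-corrected steps.

    ``alpha``, ``beta``, ``gamma`` are in [0, 2pi); ``chi`` = alpha + gamma
    (mod 2pi) is the helical phase whose step ``d_chi`` is the gauge
    potential ``d_rho`` (identically equal).  All differences lie in
    (-pi, pi].  ``evaluable`` marks the sites with a complete free-energy
    evaluation; for a clean N-site axis exactly four terminal sites (two at
    each end) are blind.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    chi: np.ndarray
    d_alpha: np.ndarray
    d_beta: np.ndarray
    d_chi: np.ndarray
    evaluable: np.ndarray     # (N,) bool
    axis_direction: np.ndarray

    @property
    def d_rho(self) -> np.ndarray:
        """Gauge potential per step; identified with d_chi."""
        return self.d_chi

    def __len__(self) -> int:
        return len(self.alpha)

    def mean_gauge(self) -> float:
        """Mean gauge potential over evaluable sites (rad)."""
        vals = self.d_chi[self.evaluable]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ContentError("no evaluable gauge-potential values")
        return float(vals.mean())


def cumulative_euler(
    rotations: RotationSeries,
    frames: FrameSet,
    axis_direction: np.ndarray | None = None,
) -> EulerSeries:
    """Euler angles of each site's orientation in helix-aligned coordinates.

    The cumulative transfer rotation composed with the anchor frame gives the
    site's absolute orientation (R_{i,anchor} F_anchor = F_i); expressed in
    coordinates where the helical advance direction is +z, its zyz angles
    separate precession (alpha), tilt (beta) and spin (gamma).  Differences
    are taken per segment with the minimal signed wrap.
    """
    n = len(frames)
    if axis_direction is None:
        axis_direction = helical_axis_direction(frames)
    align = alignment_rotation(axis_direction)

    alpha = np.full(n, np.nan)
    beta = np.full(n, np.nan)
    gamma = np.full(n, np.nan)
    chi = np.full(n, np.nan)
    for start, end in rotations.segments:
        anchor = frames.matrix(start)
        for i in range(start, end + 1):
            orientation = rotations.cumulative[i] @ anchor   # rows (n, b, t) at site i
            a, b, g = extract_zyz(align @ orientation.T)
            alpha[i], beta[i], gamma[i] = a, b, g
            chi[i] = (a + g) % TWO_PI

    d_alpha = np.full(n, np.nan)
    d_beta = np.full(n, np.nan)
    d_chi = np.full(n, np.nan)
    for start, end in rotations.segments:
        for i in range(start, end):
            d_alpha[i] = wrap_signed(alpha[i + 1] - alpha[i])
            d_beta[i] = wrap_signed(beta[i + 1] - beta[i])
            d_chi[i] = wrap_signed(chi[i + 1] - chi[i])

    # Site accounting: two blind sites at each end of the axis.  The frame
    # needs both neighbours, and the angle chain consumes one further site at
    # the head, so the evaluable window is [2, N-3] (0-based).
    evaluable = np.zeros(n, dtype=bool)
    lo, hi = 2, n - 3
    for i in range(max(lo, 0), min(hi, n - 1) + 1):
        evaluable[i] = not np.isnan(d_chi[i])
    return EulerSeries(
        alpha=alpha, beta=beta, gamma=gamma, chi=chi,
        d_alpha=d_alpha, d_beta=d_beta, d_chi=d_chi,
        evaluable=evaluable, axis_direction=np.asarray(axis_direction, dtype=float),
    )


def euler_tsv(euler: EulerSeries) -> str:
    """TSV dump: site, alpha, beta, gamma, chi, d_alpha, d_beta, d_chi, d_rho (rad)."""
    header = "site\talpha_rad\tbeta_rad\tgamma_rad\tchi_rad\td_alpha_rad\td_beta_rad\td_chi_rad\td_rho_rad"
    rows = [header]
    for i in range(len(euler)):
        vals = [euler.alpha[i], euler.beta[i], euler.gamma[i], euler.chi[i],
                euler.d_alpha[i], euler.d_beta[i], euler.d_chi[i], euler.d_chi[i]]
        rows.append(f"{i}\t" + "\t".join(f"{v:.10g}" for v in vals))
    return "\n".join(rows) + "\n"
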