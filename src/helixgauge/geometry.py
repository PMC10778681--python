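"""Geodesic curvature, normal curvature and geodesic torsion per site.

Discretized curve-on-surface geometry of the helical axis:

    k_n,i   =  d_beta_i  / ds
    k_g,i   = -(d_alpha_i / ds) * sin(beta_i)
    tau_g,i =  (d_alpha_i / ds) * cos(beta_i)

with beta_i the cumulative tilt angle at site i.  The overall curvature is
k = sqrt(k_g^2 + k_n^2) and the overall torsion keeps the model's literal
mixed combination tau = tau_g + d_chi/ds - d_rho (rad/nm plus rad once
discretized; reported in "model units").

The step ds pairs the angle difference d(angle)_{i+1,i} with the *trailing*
arc step ds_{i,i-1} ("paper" pairing, the model's printed convention); the
"forward" mode uses ds_{i+1,i} instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SeriesAlignmentError
from .axis_frame import AxisTrace
from .euler_series import EulerSeries


@dataclass
class GeometrySeries:
    """Per-site curvature/torsion components (nm^-1) with validity flags."""

    k_g: np.ndarray
    k_n: np.ndarray
    tau_g: np.ndarray
    k_total: np.ndarray
    tau_total: np.ndarray
    valid: np.ndarray       # aligned with the Euler evaluable range
    step_used: np.ndarray   # the ds actually divided by, per site (nm)

    def __len__(self) -> int:
        return len(self.k_g)


def geometry_series(
    euler: EulerSeries, axis: AxisTrace, step_pairing: str = "paper"
) -> GeometrySeries:
    """Convert Euler-angle steps and arc steps into curvature/torsion series."""
    n = len(euler)
    if len(axis) != n:
        raise SeriesAlignmentError(
            f"euler series has {n} sites but axis trace has {len(axis)}"
        )
    if step_pairing not in ("paper", "forward"):
        raise ValueError(f"step_pairing must be 'paper' or 'forward', got {step_pairing!r}")

    step = np.full(n, np.nan)
    for i in range(n):
        j = i if step_pairing == "paper" else i + 1
        if 0 < j < n:
            step[i] = axis.steps[j]

    with np.errstate(invalid="ignore"):
        rate_alpha = euler.d_alpha / step
        k_n = euler.d_beta / step
        k_g = -rate_alpha * np.sin(euler.beta)
        tau_g = rate_alpha * np.cos(euler.beta)
        k_total = np.sqrt(k_g ** 2 + k_n ** 2)
        tau_total = tau_g + euler.d_chi / step - euler.d_rho

    valid = euler.evaluable & ~np.isnan(k_total) & ~np.isnan(step)
    return GeometrySeries(
        k_g=k_g, k_n=k_n, tau_g=tau_g, k_total=k_total, tau_total=tau_total,
        valid=valid, step_used=step,
    )


def geometry_tsv(geom: GeometrySeries) -> str:
    """TSV dump: site, k_g, k_n, tau_g, k, tau (nm^-1 / model units)."""
    header = "site\tk_g_per_nm\tk_n_per_nm\ttau_g_per_nm\tk_per_nm\ttau_model_units"
    rows = [header]
    for i in range(len(geom)):
        vals = [geom.k_g[i], geom.k_n[i], geom.tau_g[i], geom.k_total[i], geom.tau_total[i]]
        rows.append(f"{i}\t" + "\t".join(f"{v:.10g}" for v in vals))
    return "\n".join(rows) + "\n"
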