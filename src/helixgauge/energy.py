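"""Critical-state free-energy density per site and chirality classification.

Per site the model evaluates

    F_i = (B_i/2) (k_n^2 + k_g^2)
        + (C_i/2) (tau_g + d_chi/ds - d_rho)^2
        + (d1/2) (d_rho/ds)^2
        + tau_c * d_rho

where B_i = (b/ds) * 1e-1 * 4.1e-21 J and C_i = (c/ds) * 1e-1 * 4.1e-21 J are
per-site bending/twisting elastic constants from the persistence lengths b
and c (nm), d1 = D1/omega0^2 penalizes gauge-potential gradients, and the
critical torque tau_c < 0 linearly rewards right-handed twist (d_rho > 0) —
the term that makes the free energy chirally asymmetric.  F splits into the
geometric part Fs (first two terms) and the effective potential (last two).

Absolute F values depend on b and c, which are configuration, not
observables; the chirality-discriminating structure (sign of mean d_rho, the
tau_c term) does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContentError, SeriesAlignmentError
from .axis_frame import AxisTrace
from .euler_series import EulerSeries, BLIND_SITES
from .geometry import GeometrySeries

KT_R = 4.1e-21  # J; thermal prefactor of the elastic constants


@dataclass
class EnergyParams:
    """Physical parameters of the free-energy evaluation.

    b, c : bending / twisting persistence length (nm).  Literature-typical
        B-DNA values are the defaults; absolute free energies scale with
        them, so they are deliberately visible configuration.
    D1, omega0 : effective-potential scale (J) and reference twist
        (rad per bp); d1 = D1 / omega0**2.
    tau_c : critical torque (J), negative — biases toward right-handed twist.
    """

    b: float = 50.0
    c: float = 100.0
    D1: float = 4.1e-21
    omega0: float = 0.6
    tau_c: float = -7.9e-21
    kT_R: float = KT_R

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0 or self.omega0 <= 0:
            raise ValueError("b, c and omega0 must be positive")

    @property
    def d1(self) -> float:
        return self.D1 / self.omega0 ** 2

    def as_dict(self) -> dict[str, float]:
        return {
            "b_nm": self.b, "c_nm": self.c, "D1_J": self.D1,
            "omega0_rad_per_bp": self.omega0, "d1_J": self.d1,
            "tau_c_J": self.tau_c, "kT_R_J": self.kT_R,
        }


def elastic_constants(step: float, params: EnergyParams) -> tuple[float, float]:
    """Per-site bending and twisting elastic constants (B_i, C_i) in J."""
    if not step > 0:
        raise ValueError(f"arc step must be positive, got {step}")
    B = (params.b / step) * 1e-1 * params.kT_R
    C = (params.c / step) * 1e-1 * params.kT_R
    return (B, C)


@dataclass
class EnergySeries:
    """Per-site free-energy density F_i = Fs_i + potential_i (J)."""

    F: np.ndarray
    Fs: np.ndarray          # geometric part: bending + torsion terms
    potential: np.ndarray   # effective potential: d1 and tau_c terms
    B: np.ndarray           # per-site bending constant (J)
    C: np.ndarray           # per-site twisting constant (J)
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.F)


def free_energy_series(
    geom: GeometrySeries,
    euler: EulerSeries,
    axis: AxisTrace,
    params: EnergyParams | None = None,
) -> EnergySeries:
    """Evaluate the discretized critical-state free energy per site."""
    params = params or EnergyParams()
    n = len(geom)
    if len(euler) != n or len(axis) != n:
        raise SeriesAlignmentError("geometry, euler and axis series must share site indexing")

    step = geom.step_used
    with np.errstate(invalid="ignore"):
        B = (params.b / step) * 1e-1 * params.kT_R
        C = (params.c / step) * 1e-1 * params.kT_R
        bend = 0.5 * B * (geom.k_n ** 2 + geom.k_g ** 2)
        twist = 0.5 * C * (geom.tau_g + euler.d_chi / step - euler.d_rho) ** 2
        Fs = bend + twist
        potential = 0.5 * params.d1 * (euler.d_rho / step) ** 2 + params.tau_c * euler.d_rho
        F = Fs + potential
    valid = geom.valid & ~np.isnan(F)
    return EnergySeries(F=F, Fs=Fs, potential=potential, B=B, C=C, valid=valid)


def classify_chirality(euler: EulerSeries, threshold: float = 0.05) -> str:
    """Handedness call from the mean gauge potential.

    Returns "right" (B-type) if mean d_rho > threshold, "left" (Z-type) if
    below -threshold, "ambiguous" otherwise.  Default threshold 0.05 rad.
    """
    mean = euler.mean_gauge()
    if mean > threshold:
        return "right"
    if mean < -threshold:
        return "left"
    return "ambiguous"


def _quartiles(values: np.ndarray) -> dict[str, float]:
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return {"mean": float("nan"), "q1": float("nan"),
                "median": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"mean": float(values.mean()), "q1": float(q1),
            "median": float(med), "q3": float(q3)}


@dataclass
class SummaryStats:
    """Per-structure means and quartiles over valid sites, plus site accounting."""

    n_sites: int
    n_valid: int
    n_invalid: int
    n_blind: int
    handedness: str
    mean_gauge: float
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_valid": self.n_valid,
            "n_invalid": self.n_invalid,
            "n_blind": self.n_blind,
            "handedness": self.handedness,
            "mean_gauge_rad": self.mean_gauge,
            **{k: v for k, v in self.stats.items()},
        }


def summarize(
    axis: AxisTrace,
    euler: EulerSeries,
    geom: GeometrySeries,
    energy: EnergySeries,
    threshold: float = 0.05,
) -> SummaryStats:
    """Aggregate per-site series into per-structure statistics.

    Means and quartiles are computed only over valid sites; the four terminal
    blind sites and any interior invalid sites are counted separately so that
    valid + invalid + blind = N.
    """
    n = len(axis)
    valid = energy.valid
    n_valid = int(valid.sum())
    n_blind = min(BLIND_SITES, n)
    n_invalid = n - n_valid - n_blind
    if n_invalid < 0:
        raise ContentError("site accounting failed: more valid sites than non-blind sites")
    sel = lambda arr: np.where(valid, arr, np.nan)
    stats = {
        "F_J": _quartiles(sel(energy.F)),
        "Fs_J": _quartiles(sel(energy.Fs)),
        "d_rho_rad": _quartiles(sel(euler.d_rho)),
        "k_per_nm": _quartiles(sel(geom.k_total)),
        "tau_model_units": _quartiles(sel(geom.tau_total)),
        "abs_k_g_per_nm": _quartiles(np.abs(sel(geom.k_g))),
        "abs_k_n_per_nm": _quartiles(np.abs(sel(geom.k_n))),
    }
    return SummaryStats(
        n_sites=n,
        n_valid=n_valid,
        n_invalid=n_invalid,
        n_blind=n_blind,
        handedness=classify_chirality(euler, threshold),
        mean_gauge=euler.mean_gauge(),
        stats=stats,
    )
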