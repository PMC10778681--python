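"""Model/Results interface tying the pipeline together.

`ChiralStateModel` holds a paired duplex plus configuration; `fit()` runs
backbone extraction → axis trace → discrete frames → transfer rotations →
helix-aligned Euler angles → curvature/torsion → free energy, and returns a
`ChiralStateResults` carrying every intermediate series, per-structure
statistics, and a text `summary()`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import axis_frame, energy, euler_series, geometry, structure_io
from .energy import EnergyParams, EnergySeries, SummaryStats
from .errors import ContentError
from .structure_io import DuplexPairing, NucleotideUnit

#: Fewer usable base pairs than this cannot yield any evaluable site.
MIN_PAIRS = 5


class ChiralStateModel:
    """Discrete critical-state model of a DNA duplex.

    Parameters
    ----------
    pairing : DuplexPairing
        Paired backbone traces of the two strands.
    params : EnergyParams, optional
        Elastic and effective-potential parameters (defaults: b=50 nm,
        c=100 nm, D1=4.1e-21 J, omega0=0.6 rad/bp, tau_c=-7.9e-21 J).
    step_pairing : {"paper", "forward"}
        How angle steps pair with arc steps in the geometry stage.
    frame_tolerance : float
        Cross-product threshold below which a frame site is invalid.
    chirality_threshold : float
        |mean gauge| below this is classified "ambiguous" (rad).
    """

    def __init__(
        self,
        pairing: DuplexPairing,
        params: EnergyParams | None = None,
        step_pairing: str = "paper",
        frame_tolerance: float = axis_frame.CROSS_TOLERANCE,
        chirality_threshold: float = 0.05,
    ):
        if len(pairing) < MIN_PAIRS:
            raise ContentError(
                f"duplex too short: {len(pairing)} usable pairs, need >= {MIN_PAIRS}"
            )
        self.pairing = pairing
        self.params = params or EnergyParams()
        self.step_pairing = step_pairing
        self.frame_tolerance = frame_tolerance
        self.chirality_threshold = chirality_threshold

    @classmethod
    def from_structure(
        cls,
        chains: list[tuple[str, list[NucleotideUnit]]],
        chain_pair: tuple[str, str] | None = None,
        **kwargs,
    ) -> "ChiralStateModel":
        """Build a model from in-memory chains (e.g. the synthetic generator)."""
        by_id = dict(chains)
        if chain_pair is None:
            if len(chains) < 2:
                raise ContentError(f"need two nucleic-acid chains, found {len(chains)}")
            chain_pair = (chains[0][0], chains[1][0])
        for cid in chain_pair:
            if cid not in by_id:
                raise ContentError(
                    f"chain {cid!r} not found (available: {', '.join(by_id)})"
                )
        trace_a = structure_io.trace_from_units(by_id[chain_pair[0]])
        trace_b = structure_io.trace_from_units(by_id[chain_pair[1]])
        return cls(structure_io.pair_strands(trace_a, trace_b), **kwargs)

    @classmethod
    def from_pdb(
        cls,
        path: str,
        chain_pair: tuple[str, str] | None = None,
        model_index: int = 0,
        **kwargs,
    ) -> "ChiralStateModel":
        """Read a duplex from a PDB file and build a model."""
        chains = structure_io.read_structure(path, model_index=model_index)
        return cls.from_structure(chains, chain_pair=chain_pair, **kwargs)

    def fit(self) -> "ChiralStateResults":
        """Run the full pipeline and return results."""
        axis = axis_frame.axis_trace(self.pairing)
        frames = axis_frame.build_frames(axis.points, tolerance=self.frame_tolerance)
        rotations = euler_series.rotation_series(frames)
        euler = euler_series.cumulative_euler(rotations, frames)
        geom = geometry.geometry_series(euler, axis, step_pairing=self.step_pairing)
        en = energy.free_energy_series(geom, euler, axis, self.params)
        stats = energy.summarize(axis, euler, geom, en, threshold=self.chirality_threshold)
        return ChiralStateResults(
            model=self, axis=axis, frames=frames, rotations=rotations,
            euler=euler, geometry=geom, energy=en, stats=stats,
        )


@dataclass
class ChiralStateResults:
    """Fitted per-site series, statistics and reporting helpers."""

    model: ChiralStateModel
    axis: axis_frame.AxisTrace
    frames: axis_frame.FrameSet
    rotations: euler_series.RotationSeries
    euler: euler_series.EulerSeries
    geometry: geometry.GeometrySeries
    energy: EnergySeries
    stats: SummaryStats

    @property
    def mean_gauge(self) -> float:
        """Mean gauge potential over evaluable sites (rad)."""
        return self.euler.mean_gauge()

    @property
    def handedness(self) -> str:
        return self.stats.handedness

    def per_site(self) -> pd.DataFrame:
        """Per-site table: arc step, angles, curvature/torsion, energies."""
        n = len(self.axis)
        return pd.DataFrame({
            "site": np.arange(n),
            "ds_nm": self.axis.steps,
            "alpha_rad": self.euler.alpha,
            "beta_rad": self.euler.beta,
            "gamma_rad": self.euler.gamma,
            "chi_rad": self.euler.chi,
            "d_rho_rad": self.euler.d_rho,
            "k_g_per_nm": self.geometry.k_g,
            "k_n_per_nm": self.geometry.k_n,
            "tau_g_per_nm": self.geometry.tau_g,
            "k_per_nm": self.geometry.k_total,
            "tau_model_units": self.geometry.tau_total,
            "B_J": self.energy.B,
            "C_J": self.energy.C,
            "Fs_J": self.energy.Fs,
            "F_J": self.energy.F,
            "valid": self.energy.valid,
        })

    def summary_dict(self, provenance: bool = True) -> dict:
        out = dict(self.stats.as_dict())
        if provenance:
            out["config"] = {
                **self.model.params.as_dict(),
                "step_pairing": self.model.step_pairing,
                "frame_tolerance": self.model.frame_tolerance,
                "chirality_threshold_rad": self.model.chirality_threshold,
                "length_unit": "nm",
            }
        return out

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.stats
        lines = [
            "Discrete critical-state model fit",
            "=" * 42,
            f"sites (base pairs)        {s.n_sites}",
            f"  evaluable / invalid / blind   {s.n_valid} / {s.n_invalid} / {s.n_blind}",
            f"handedness                {s.handedness}",
            f"mean gauge potential      {s.mean_gauge:+.4f} rad/bp",
            "-" * 42,
            f"{'quantity':<22}{'mean':>12}{'median':>12}",
        ]
        show = [
            ("F (1e-21 J)", "F_J", 1e21),
            ("Fs (1e-21 J)", "Fs_J", 1e21),
            ("d_rho (rad)", "d_rho_rad", 1.0),
            ("k (1/nm)", "k_per_nm", 1.0),
            ("tau (model units)", "tau_model_units", 1.0),
            ("|k_g| (1/nm)", "abs_k_g_per_nm", 1.0),
            ("|k_n| (1/nm)", "abs_k_n_per_nm", 1.0),
        ]
        for label, key, scale in show:
            q = s.stats[key]
            lines.append(f"{label:<22}{q['mean'] * scale:>12.4f}{q['median'] * scale:>12.4f}")
        return "\n".join(lines)

    def to_csv(self, path: str) -> None:
        self.per_site().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path: str, provenance: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(provenance=provenance), fh, indent=2, sort_keys=True)
            fh.write("\n")
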