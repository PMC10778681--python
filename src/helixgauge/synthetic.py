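"""Ideal duplex generator and continuous-helix closed forms.

The generator places backbone representative points of both strands on a
common cylinder: strand A at azimuth i*twist and height i*rise, strand B at
azimuth i*twist + phase gap.  Because the gap is not 180 degrees (real DNA's
grooves are asymmetric), the midpoint axis is itself a genuine small-radius
helix — radius backbone_radius * |cos(gap/2)| — rather than a straight line,
which gives the axis nonzero curvature as in real structures.  Four
pseudo-atoms named C3', C4', O3', C1' are placed around each backbone point
at tetrahedral offsets scaled by ``atom_jitter``; their offsets sum to zero,
so their mean reproduces the backbone point exactly at any jitter.

The classical circular-helix closed forms (curvature R/(R^2+c^2), torsion
c/(R^2+c^2) for radius R and pitch-per-radian c) are the analytic oracle the
discrete estimators converge to as the angular step shrinks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from .structure_io import BACKBONE_ATOMS, NucleotideUnit, write_pdb

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RESNAME = {"A": "DA", "T": "DT", "C": "DC", "G": "DG"}

# unit tetrahedral directions; they sum to zero, so the four-atom mean is
# exactly the backbone point at any jitter
_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)


@dataclass(frozen=True)
class HelixSpec:
    """Geometric specification of an ideal duplex.

    twist is signed rad per bp (> 0 right-handed); rise, backbone_radius and
    atom_jitter are nm; strand_phase_gap is the angular offset (rad) between
    the two strands' backbone points within a base pair.
    """

    n_bp: int = 12
    twist: float = 2.0 * math.pi / 10.5
    rise: float = 0.34
    backbone_radius: float = 0.94
    strand_phase_gap: float = math.radians(154.0)
    atom_jitter: float = 0.0
    seed: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.n_bp < 5:
            raise ValueError("n_bp must be >= 5")
        if self.rise <= 0 or self.backbone_radius <= 0:
            raise ValueError("rise and backbone_radius must be positive")
        if not abs(self.twist) < math.pi:
            raise ValueError("|twist| must be < pi rad per bp")
        if self.atom_jitter < 0:
            raise ValueError("atom_jitter must be >= 0")

    @property
    def axis_radius(self) -> float:
        """Radius (nm) of the midpoint helical axis."""
        return self.backbone_radius * abs(math.cos(self.strand_phase_gap / 2.0))


#: Canonical B-form: 10.5 bp/turn right-handed, fiber-diffraction rise/radius.
B_FORM = HelixSpec()

#: Idealized Z-form: 12 bp/turn left-handed, alternating d(CG); the 167 deg
#: phase gap narrows the axis helix so its curvature matches the scale seen
#: for left-handed duplexes (~0.21 nm^-1).
Z_FORM = HelixSpec(
    twist=-2.0 * math.pi / 12.0,
    rise=0.37,
    strand_phase_gap=math.radians(167.0),
    sequence="CG",
)


def spec_for_form(form: str, **overrides) -> HelixSpec:
    """B_FORM or Z_FORM with field overrides applied."""
    base = {"B": B_FORM, "Z": Z_FORM}.get(form.upper())
    if base is None:
        raise ValueError(f"unknown form {form!r}: expected 'B' or 'Z'")
    return replace(base, **overrides)


def _sequence(spec: HelixSpec) -> str:
    pattern = spec.sequence or "ACGT"
    pattern = pattern.upper()
    if any(ch not in _COMPLEMENT for ch in pattern):
        raise ValueError(f"sequence may only contain ACGT, got {spec.sequence!r}")
    return "".join(itertools.islice(itertools.cycle(pattern), spec.n_bp))


def _pseudo_atoms(center_nm: np.ndarray, jitter: float, rng: np.random.Generator) -> dict:
    if jitter > 0:
        # random proper rotation of the tetrahedron per site; offsets still sum to zero
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        offsets = (_TETRA @ rot.T) * jitter
    else:
        offsets = np.zeros((4, 3))
    return {
        name: (center_nm + offsets[k]) * 10.0  # nm -> Angstrom
        for k, name in enumerate(BACKBONE_ATOMS)
    }


def ideal_duplex(spec: HelixSpec) -> list[tuple[str, list[NucleotideUnit]]]:
    """Generate an ideal duplex as two antiparallel chains of nucleotide units.

    Chain A runs 5'->3' in generator order; chain B is the complementary
    strand listed in its own 5'->3' order (reversed), so base pair i joins
    A's residue i+1 with B's residue n_bp-i.  Coordinates are in Angstrom.
    """
    seq = _sequence(spec)
    rng = np.random.default_rng(spec.seed)
    units_a, units_b = [], []
    for i in range(spec.n_bp):
        angle = i * spec.twist
        height = i * spec.rise
        center_a = np.array([
            spec.backbone_radius * math.cos(angle),
            spec.backbone_radius * math.sin(angle),
            height,
        ])
        center_b = np.array([
            spec.backbone_radius * math.cos(angle + spec.strand_phase_gap),
            spec.backbone_radius * math.sin(angle + spec.strand_phase_gap),
            height,
        ])
        units_a.append(NucleotideUnit(
            chain_id="A", residue_index=i + 1, residue_name=_RESNAME[seq[i]],
            atom_coords=_pseudo_atoms(center_a, spec.atom_jitter, rng),
        ))
        units_b.append(NucleotideUnit(
            chain_id="B", residue_index=spec.n_bp - i, residue_name=_RESNAME[_COMPLEMENT[seq[i]]],
            atom_coords=_pseudo_atoms(center_b, spec.atom_jitter, rng),
        ))
    units_b.reverse()  # antiparallel: chain B written 5'->3'
    return [("A", units_a), ("B", units_b)]


def mirror(structure: list[tuple[str, list[NucleotideUnit]]]) -> list[tuple[str, list[NucleotideUnit]]]:
    """Reflect every atom through the xy-plane: (x, y, z) -> (x, y, -z).

    An exact involution that flips the handedness of any helix while leaving
    residue content and all pairwise distances unchanged.
    """
    out = []
    for chain_id, units in structure:
        new_units = [
            NucleotideUnit(
                chain_id=u.chain_id,
                residue_index=u.residue_index,
                residue_name=u.residue_name,
                atom_coords={k: v * np.array([1.0, 1.0, -1.0]) for k, v in u.atom_coords.items()},
            )
            for u in units
        ]
        out.append((chain_id, new_units))
    return out


def continuous_helix_forms(radius: float, pitch_per_radian: float) -> tuple[float, float]:
    """Closed-form curvature and torsion of a circular helix (nm^-1).

    For r(theta) = (R cos theta, R sin theta, c theta): curvature
    R/(R^2+c^2), torsion c/(R^2+c^2) — the limits of the discrete estimators
    as the sampling step shrinks.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    denom = radius ** 2 + pitch_per_radian ** 2
    return (radius / denom, pitch_per_radian / denom)


def helix_points(
    radius: float, pitch_per_radian: float, step_angle: float, n_points: int,
    phase: float = 0.0,
) -> np.ndarray:
    """Sample points of a continuous circular helix (nm) at a fixed angular step."""
    theta = phase + step_angle * np.arange(n_points)
    return np.stack([
        radius * np.cos(theta), radius * np.sin(theta), pitch_per_radian * theta
    ], axis=1)


def write_duplex_pdb(spec: HelixSpec, path: str) -> None:
    """Generate an ideal duplex and write it as a PDB file."""
    write_pdb(ideal_duplex(spec), path)
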