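"""Read and write duplex DNA structures and reduce nucleotides to backbone points.

Each deoxynucleotide is represented by a single point: the arithmetic mean of
its C3', C4', O3' and C1' sugar atoms.  The deoxyribose links base and
phosphate backbone, so this mean is a robust per-residue proxy for the
backbone position.  The two strands of a duplex are paired positionally
(antiparallel index reversal), with Watson-Crick complementarity recorded as a
per-pair validation flag rather than used to drive the pairing.

PDB input/output is delegated to :mod:`gemmi`; both the prime (``C3'``) and
legacy asterisk (``C3*``) atom-name dialects are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import ContentError, MissingAtomError

#: Canonical names of the four backbone atoms that define a residue's point.
BACKBONE_ATOMS = ("C3'", "C4'", "O3'", "C1'")

#: Standard deoxynucleotide residue names and common aliases.
STANDARD_RESIDUES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}

_WATSON_CRICK = {"A": "T", "T": "A", "C": "G", "G": "C"}

_SOLVENT = {"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "CA", "ZN", "MN", "SO4", "PO4"}


def normalize_atom_name(name: str) -> str:
    """Map PDB atom-name dialects (``C3*``, unicode primes) to ``C3'``."""
    return name.strip().replace("*", "'").replace("′", "'")


def base_letter(residue_name: str) -> str | None:
    """One-letter base code for a residue name, or None if not standard."""
    return STANDARD_RESIDUES.get(residue_name.strip().upper())


@dataclass
class NucleotideUnit:
    """A single nucleotide: identity plus the coordinates of its named atoms (Å)."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_coords: dict[str, np.ndarray]

    @property
    def missing_atoms(self) -> tuple[str, ...]:
        return tuple(a for a in BACKBONE_ATOMS if a not in self.atom_coords)

    @property
    def usable(self) -> bool:
        """True when all four backbone atoms are present."""
        return not self.missing_atoms


@dataclass
class BackboneTrace:
    """Ordered backbone representative points of one strand, 5'→3' (Å)."""

    chain_id: str
    points: np.ndarray                      # (N, 3) Å
    residue_indices: list[int]
    residue_names: list[str]
    numbering_gaps: list[int] = field(default_factory=list)   # positions after which numbering jumps
    skipped_units: list[NucleotideUnit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DuplexPairing:
    """Positional antiparallel pairing of two backbone traces."""

    trace_a: BackboneTrace
    trace_b: BackboneTrace
    pairs: list[tuple[int, int]]
    complementarity_ok: list[bool]

    def __len__(self) -> int:
        return len(self.pairs)


def backbone_point(unit: NucleotideUnit) -> np.ndarray:
    """Arithmetic mean of the four backbone atoms (Å).

    Raises :class:`MissingAtomError` naming any absent atom.
    """
    missing = unit.missing_atoms
    if missing:
        raise MissingAtomError(
            f"{unit.chain_id}/{unit.residue_name}{unit.residue_index}: "
            f"missing backbone atom(s) {', '.join(missing)}"
        )
    coords = np.stack([np.asarray(unit.atom_coords[a], dtype=float) for a in BACKBONE_ATOMS])
    return coords.mean(axis=0)


def _residue_units(chain: gemmi.Chain) -> list[NucleotideUnit]:
    units = []
    for residue in chain:
        rname = residue.name.strip().upper()
        if rname in _SOLVENT:
            continue
        # pick the highest-occupancy location per canonical atom name
        best: dict[str, tuple[float, np.ndarray]] = {}
        for atom in residue:
            name = normalize_atom_name(atom.name)
            occ = atom.occ if atom.occ > 0 else 1.0
            if name not in best or occ > best[name][0]:
                best[name] = (occ, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
        coords = {n: xyz for n, (occ, xyz) in best.items()}
        is_standard = rname in STANDARD_RESIDUES
        has_backbone = all(a in coords for a in BACKBONE_ATOMS)
        # modified nucleotides qualify via their sugar atoms alone
        if is_standard or has_backbone:
            units.append(
                NucleotideUnit(
                    chain_id=chain.name,
                    residue_index=residue.seqid.num,
                    residue_name=rname,
                    atom_coords=coords,
                )
            )
    return units


def read_structure(path: str, model_index: int = 0) -> list[tuple[str, list[NucleotideUnit]]]:
    """Read a PDB file and return nucleotide units grouped by chain.

    Only nucleic-acid residues are returned (standard deoxynucleotide names,
    their aliases, and modified residues carrying all four backbone atoms);
    waters, ions and protein chains are excluded.  Alternate locations are
    resolved to the highest-occupancy coordinate.  Only the model selected by
    ``model_index`` (default: first) is read.
    """
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise OSError(f"cannot read PDB file {path!r}: {exc}") from exc
    if len(structure) == 0:
        raise ContentError(f"{path!r}: no models in file")
    if model_index >= len(structure):
        raise ContentError(
            f"{path!r}: model index {model_index} out of range ({len(structure)} models)"
        )
    model = structure[model_index]
    chains: list[tuple[str, list[NucleotideUnit]]] = []
    seen = []
    for chain in model:
        seen.append(chain.name)
        units = _residue_units(chain)
        if units:
            chains.append((chain.name, units))
    if not chains:
        raise ContentError(
            f"{path!r}: no nucleic-acid chain found (chains seen: {', '.join(seen) or 'none'})"
        )
    return chains


def trace_from_units(units: list[NucleotideUnit]) -> BackboneTrace:
    """Reduce a chain of nucleotide units to a :class:`BackboneTrace`.

    Unusable units (missing backbone atoms) are recorded in
    ``skipped_units`` — flagged, never silently dropped.  Jumps in author
    residue numbering are recorded in ``numbering_gaps``.
    """
    if not units:
        raise ContentError("empty chain: no nucleotide units")
    points, indices, names, skipped, gaps = [], [], [], [], []
    for unit in units:
        if not unit.usable:
            skipped.append(unit)
            continue
        points.append(backbone_point(unit))
        indices.append(unit.residue_index)
        names.append(unit.residue_name)
    if not points:
        raise ContentError(f"chain {units[0].chain_id}: no usable nucleotides")
    for k in range(1, len(indices)):
        if indices[k] - indices[k - 1] != 1:
            gaps.append(k - 1)
    return BackboneTrace(
        chain_id=units[0].chain_id,
        points=np.stack(points),
        residue_indices=indices,
        residue_names=names,
        numbering_gaps=gaps,
        skipped_units=skipped,
    )


def pair_strands(
    trace_a: BackboneTrace, trace_b: BackboneTrace, rule: str = "antiparallel"
) -> DuplexPairing:
    """Pair two strands positionally: position i of A with position N_b-1-i of B.

    The pairing is truncated to the shorter strand; a non-Watson-Crick pair is
    flagged in ``complementarity_ok`` but kept.
    """
    if len(trace_a) == 0 or len(trace_b) == 0:
        raise ContentError("cannot pair an empty trace")
    if rule != "antiparallel":
        raise ValueError(f"unknown pairing rule {rule!r}")
    n = min(len(trace_a), len(trace_b))
    nb = len(trace_b)
    pairs = [(i, nb - 1 - i) for i in range(n)]
    ok = []
    for ia, ib in pairs:
        la = base_letter(trace_a.residue_names[ia])
        lb = base_letter(trace_b.residue_names[ib])
        ok.append(la is not None and lb is not None and _WATSON_CRICK[la] == lb)
    return DuplexPairing(trace_a=trace_a, trace_b=trace_b, pairs=pairs, complementarity_ok=ok)


def write_pdb(chains: list[tuple[str, list[NucleotideUnit]]], path: str) -> None:
    """Write chains of nucleotide units as a standard PDB file (ATOM records)."""
    structure = gemmi.Structure()
    structure.name = "helixgauge"
    model = gemmi.Model("1")
    serial = 1
    for chain_id, units in chains:
        chain = gemmi.Chain(chain_id)
        for unit in units:
            residue = gemmi.Residue()
            residue.name = unit.residue_name
            residue.seqid = gemmi.SeqId(unit.residue_index, " ")
            residue.het_flag = "A"
            for name, xyz in unit.atom_coords.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.serial = serial
                serial += 1
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def backbone_tsv(trace: BackboneTrace) -> str:
    """TSV dump of backbone points: chain, residue index, x, y, z (Å)."""
    lines = ["chain\tresidue_index\tx_A\ty_A\tz_A"]
    for idx, point in zip(trace.residue_indices, trace.points):
        lines.append(
            f"{trace.chain_id}\t{idx}\t" + "\t".join(f"{v:.10g}" for v in point)
        )
    return "\n".join(lines) + "\n"
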