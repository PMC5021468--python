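"""Ground-truth structural fixtures.

Every other module is tested against structures generated here: an
idealized helical poly-alanine backbone with charged residues substituted
at chosen positions, their charged side-chain atoms placed so that the
minimum charged-atom distance between a planted pair equals a requested
target exactly.  A second subunit can be generated by a stated rigid
transform -- either as explicit coordinates (a dimer in the asymmetric
unit) or as biological-assembly records on a monomer (emulating a
crystallographic 2-fold).  SEQRES can be made a superset of the modeled
residues (disordered N-terminus), and waters / glycerol / sulfate are
appended on request.

The emitted truth is *re-derived* from the final coordinates by an
exhaustive double-loop distance scan (`brute_force_ion_pairs`), so it
stays correct even if planted and incidental contacts interact; the same
scan doubles as the independent oracle for the production detector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ion_pairs import CHARGED_ATOMS
from .structure_io import (
    AssemblyTransform,
    Atom,
    Residue,
    Structure,
    write_pdb,
)


class FixtureError(ValueError):
    """Raised when a fixture specification is geometrically infeasible."""


@dataclass(frozen=True)
class PlantedPair:
    """A positive/negative residue pair with a target minimum distance (A)."""

    pos_index: int
    neg_index: int
    distance: float
    pos_name: str = "LYS"
    neg_name: str = "GLU"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise FixtureError("planted distance must be positive")
        if self.pos_name not in ("ARG", "LYS", "HIS"):
            raise FixtureError(f"{self.pos_name} is not a positive residue type")
        if self.neg_name not in ("ASP", "GLU"):
            raise FixtureError(f"{self.neg_name} is not a negative residue type")


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int = 60
    planted_pairs: tuple[PlantedPair, ...] = ()
    dimer_transform: tuple[np.ndarray, np.ndarray] | None = None
    monomer_with_transforms: bool = False
    n_missing_nterm: int = 0
    n_waters: int = 0
    hetero: tuple[str, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class FixtureTruth:
    expected_ion_pairs: list[dict] = field(default_factory=list)
    expected_assembly_chain_count: int = 1
    expected_sequence: dict[str, str] = field(default_factory=dict)
    applied_transform: tuple[list, list] | None = None
    cutoff: float = 4.0


def rotation_about_z(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def default_dimer_transform() -> tuple[np.ndarray, np.ndarray]:
    """180 degrees about z plus a 30-A offset: a well-separated 2-fold mate."""
    return rotation_about_z(180.0), np.array([30.0, 0.0, 0.0])


# helix parameters: ~3.6 residues/turn, 1.5 A rise, 2.3 A radius
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)


def _helix_ca(k: int) -> np.ndarray:
    return np.array([
        _HELIX_RADIUS * math.cos(_HELIX_TURN * k),
        _HELIX_RADIUS * math.sin(_HELIX_TURN * k),
        _HELIX_RISE * k,
    ])


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise FixtureError("degenerate direction while placing side chains")
    return v / norm


def _perpendicular(u: np.ndarray) -> np.ndarray:
    probe = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(u, probe))


def _charged_atom_positions(
    name: str, anchor: np.ndarray, u: np.ndarray, primary_offset: float
) -> dict[str, np.ndarray]:
    """Charged atoms for a residue: primary atom on the contact line at
    ``anchor + primary_offset * u``; any siblings strictly farther."""
    primary = anchor + primary_offset * u
    w = _perpendicular(u)
    if name == "ARG":
        return {"NE": primary, "NH1": primary + 0.4 * w, "NH2": primary - 0.4 * w}
    if name == "LYS":
        return {"NZ": primary}
    if name == "HIS":
        return {"ND1": primary, "NE2": primary + 0.4 * w}
    if name == "ASP":
        return {"OD1": primary, "OD2": primary + 0.4 * w}
    if name == "GLU":
        return {"OE1": primary, "OE2": primary + 0.4 * w}
    raise FixtureError(f"no charged-atom template for {name}")


def _validate_spec(spec: FixtureSpec, first_id: int, last_id: int) -> None:
    used: set[int] = set()
    for pair in spec.planted_pairs:
        for idx in (pair.pos_index, pair.neg_index):
            if not first_id <= idx <= last_id:
                raise FixtureError(f"planted residue {idx} outside modeled range "
                                   f"{first_id}-{last_id}")
            if idx in used:
                raise FixtureError(
                    f"residue {idx} appears in more than one planted pair; "
                    "contradictory side-chain placements"
                )
            used.add(idx)
        if abs(pair.pos_index - pair.neg_index) < 5:
            raise FixtureError(
                f"planted residues {pair.pos_index} and {pair.neg_index} are "
                "closer than 5 positions; backbone geometry cannot guarantee "
                "the target distance"
            )


def make_dimer_fixture(spec: FixtureSpec) -> tuple[Structure, FixtureTruth]:
    """Build a fixture structure and its ground truth.

    The minimum charged-atom distance of each planted pair equals its
    target exactly in memory (the PDB format's 3-decimal coordinates add
    up to ~3e-3 A on re-reading).  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    first_id = spec.n_missing_nterm + 1
    last_id = spec.n_missing_nterm + spec.n_residues
    _validate_spec(spec, first_id, last_id)

    names = {pair.pos_index: pair.pos_name for pair in spec.planted_pairs}
    names.update({pair.neg_index: pair.neg_name for pair in spec.planted_pairs})

    ca = {k: _helix_ca(k) for k in range(first_id, last_id + 1)}
    if spec.noise_sd > 0:
        for k in ca:
            ca[k] = ca[k] + rng.normal(0.0, spec.noise_sd, size=3)

    side_chains: dict[int, dict[str, np.ndarray]] = {}
    for pair in spec.planted_pairs:
        u = _unit(ca[pair.neg_index] - ca[pair.pos_index])
        pos_atoms = _charged_atom_positions(pair.pos_name, ca[pair.pos_index], u, 1.2)
        primary_name = next(iter(pos_atoms))
        neg_atoms = _charged_atom_positions(
            pair.neg_name, pos_atoms[primary_name], u, pair.distance
        )
        side_chains[pair.pos_index] = pos_atoms
        side_chains[pair.neg_index] = neg_atoms

    residues: list[Residue] = []
    for k in range(first_id, last_id + 1):
        name = names.get(k, "ALA")
        pos = ca[k]
        atoms = [
            Atom("N", "N", pos + np.array([-0.6, -1.1, -0.4]), record_kind="polymer"),
            Atom("CA", "C", pos, record_kind="polymer"),
            Atom("C", "C", pos + np.array([0.9, 0.9, 0.6]), record_kind="polymer"),
            Atom("O", "O", pos + np.array([1.9, 0.7, 0.8]), record_kind="polymer"),
            Atom("CB", "C", pos + _unit(np.array([pos[0], pos[1], 0.0]) + 1e-9) * 1.5,
                 record_kind="polymer"),
        ]
        for atom_name, atom_pos in side_chains.get(k, {}).items():
            atoms.append(Atom(atom_name, atom_name[0], atom_pos, record_kind="polymer"))
        residues.append(Residue(name=name, seq_id=k, chain_id="A", atoms=atoms))

    from .structure_io import STANDARD_AA3  # one-letter lookup
    modeled_letters = "".join(STANDARD_AA3[r.name] for r in residues)
    missing_prefix = ("M" + "S" * max(spec.n_missing_nterm - 1, 0))[: spec.n_missing_nterm]
    seqres = missing_prefix + modeled_letters

    structure = Structure(source_id=f"fixture-seed{spec.seed}")
    structure.chains["A"] = residues
    structure.seqres["A"] = seqres

    transform = spec.dimer_transform
    truth = FixtureTruth(cutoff=4.0)
    if transform is not None:
        R = np.asarray(transform[0], dtype=float)
        t = np.asarray(transform[1], dtype=float)
        truth.applied_transform = (R.tolist(), t.tolist())
        truth.expected_assembly_chain_count = 2
        identity = AssemblyTransform(np.eye(3), np.zeros(3), ("A",))
        mate = AssemblyTransform(R, t, ("A",))
        if spec.monomer_with_transforms:
            structure.assembly_transforms = [identity, mate]
        else:
            chain_b = []
            for res in residues:
                atoms = [Atom(a.name, a.element, R @ a.position + t,
                              record_kind=a.record_kind) for a in res.atoms]
                chain_b.append(Residue(name=res.name, seq_id=res.seq_id,
                                       chain_id="B", atoms=atoms))
            structure.chains["B"] = chain_b
            structure.seqres["B"] = seqres
            structure.assembly_transforms = [
                AssemblyTransform(np.eye(3), np.zeros(3), ("A", "B"))
            ]

    _append_solvent(structure, spec)
    structure.validate()

    truth.expected_sequence = dict(structure.seqres)
    truth.expected_ion_pairs = brute_force_ion_pairs(
        _expanded_for_truth(structure, spec), cutoff=truth.cutoff
    )
    _check_planted(spec, truth)
    return structure, truth


def _append_solvent(structure: Structure, spec: FixtureSpec) -> None:
    chain = structure.chains["A"]
    for i in range(spec.n_waters):
        pos = np.array([6.0 * i, -25.0, -20.0])
        chain.append(Residue(
            name="HOH", seq_id=501 + i, chain_id="A",
            atoms=[Atom("O", "O", pos, record_kind="water")],
        ))
    hetero_templates = {
        "GOL": [("C1", "C", (0, 0, 0)), ("O1", "O", (1.4, 0, 0)),
                ("C2", "C", (0, 1.5, 0)), ("O2", "O", (1.4, 1.5, 0)),
                ("C3", "C", (0, 3.0, 0)), ("O3", "O", (1.4, 3.0, 0))],
        "SO4": [("S", "S", (0, 0, 0)), ("O1", "O", (1.5, 0, 0)),
                ("O2", "O", (-1.5, 0, 0)), ("O3", "O", (0, 1.5, 0)),
                ("O4", "O", (0, -1.5, 0))],
    }
    for i, code in enumerate(spec.hetero):
        if code not in hetero_templates:
            raise FixtureError(f"no template for hetero group {code!r}")
        origin = np.array([8.0 * i, 25.0, -20.0])
        atoms = [Atom(n, el, origin + np.array(off), record_kind="hetero")
                 for n, el, off in hetero_templates[code]]
        chain.append(Residue(name=code, seq_id=601 + i, chain_id="A", atoms=atoms))


def _expanded_for_truth(structure: Structure, spec: FixtureSpec) -> Structure:
    """Monomer-with-transform fixtures are expanded by plain matrix algebra
    (independent of build_assembly) so the truth covers the full dimer."""
    if not spec.monomer_with_transforms or spec.dimer_transform is None:
        return structure
    R = np.asarray(spec.dimer_transform[0], dtype=float)
    t = np.asarray(spec.dimer_transform[1], dtype=float)
    expanded = structure.copy()
    chain_b = []
    for res in structure.chains["A"]:
        atoms = [Atom(a.name, a.element, R @ a.position + t,
                      record_kind=a.record_kind) for a in res.atoms]
        chain_b.append(Residue(name=res.name, seq_id=res.seq_id,
                               chain_id="A-2", atoms=atoms))
    expanded.chains["A-2"] = chain_b
    return expanded


def _check_planted(spec: FixtureSpec, truth: FixtureTruth) -> None:
    found = {
        (p["pos"][1], p["neg"][1]): p["distance"]
        for p in truth.expected_ion_pairs
        if p["pos"][0] == "A" and p["neg"][0] == "A"
    }
    for pair in spec.planted_pairs:
        if pair.pos_name == "HIS":
            continue  # truth scan excludes His by default
        if pair.distance <= truth.cutoff:
            got = found.get((pair.pos_index, pair.neg_index))
            if got is None or abs(got - pair.distance) > 1e-3:
                raise FixtureError(
                    f"planted pair {pair.pos_index}-{pair.neg_index} realized at "
                    f"{got} A instead of {pair.distance} A (interference between "
                    "planted placements)"
                )
        elif (pair.pos_index, pair.neg_index) in found:
            raise FixtureError(
                f"planted pair {pair.pos_index}-{pair.neg_index} was meant to "
                f"sit beyond the cutoff but was detected"
            )


# --------------------------------------------------------------------------
# the independent oracle

def brute_force_ion_pairs(
    s: Structure,
    cutoff: float = 4.0,
    include_histidine: bool = False,
) -> list[dict]:
    """Exhaustive double-loop opposite-charge scan; the detection oracle.

    Deliberately naive: every charged atom of every positive residue is
    compared against every charged atom of every negative residue.
    """
    positive = {"ARG", "LYS"} | ({"HIS"} if include_histidine else set())
    negative = {"ASP", "GLU"}
    charged: list[tuple[str, int, str, str, np.ndarray]] = []
    for chain_id in s.chains:
        for res in s.polymer_residues(chain_id):
            if res.name not in positive | negative:
                continue
            for atom_name in CHARGED_ATOMS.get(res.name, ()):
                atom = res.get_atom(atom_name)
                if atom is not None:
                    charged.append((chain_id, res.seq_id, res.name, atom_name,
                                    atom.position))
    pairs: dict[tuple, float] = {}
    for ca_, sa, na, _, pa in charged:
        if na not in positive:
            continue
        for cb, sb, nb, _, pb in charged:
            if nb not in negative:
                continue
            d = float(np.linalg.norm(pa - pb))
            key = ((ca_, sa, na), (cb, sb, nb))
            if d <= cutoff and (key not in pairs or d < pairs[key]):
                pairs[key] = d
    out = [
        {"pos": list(key[0]), "neg": list(key[1]), "distance": d}
        for key, d in pairs.items()
    ]
    out.sort(key=lambda p: (p["pos"][0], p["pos"][1], p["neg"][0], p["neg"][1]))
    return out


# --------------------------------------------------------------------------
# perturbation (drives the hinge-motion superposition tests)

def perturb_structure(
    s: Structure,
    domain_interval: tuple[int, int],
    rotation_angle: float,
    noise_sd: float,
    seed: int,
    chain_id: str | None = None,
) -> Structure:
    """Rigidly rotate one residue interval; jitter everything else.

    The rotation axis is the global z direction through the Calpha of the
    interval's first modeled residue, so the motion is a pure hinge: the
    moved interval superposes back onto itself exactly, while whole-chain
    RMSD grows with the angle.  Gaussian jitter (sd in A) is added to atoms
    outside the interval.  Deterministic under ``seed``.
    """
    lo, hi = domain_interval
    if lo > hi:
        raise ValueError("empty domain interval")
    out = s.copy()
    rng = np.random.default_rng(seed)
    chain = chain_id or next(iter(out.chains))
    pivot = None
    for res in out.polymer_residues(chain):
        if lo <= res.seq_id <= hi:
            ca = res.get_atom("CA")
            if ca is not None:
                pivot = ca.position.copy()
                break
    if pivot is None:
        raise ValueError(f"no Calpha found in interval {domain_interval}")
    R = rotation_about_z(rotation_angle)
    rotate = rotation_angle % 360.0 != 0.0
    for res in out.chains[chain]:
        inside = res.record_kind == "polymer" and lo <= res.seq_id <= hi
        for atom in res.atoms:
            if inside:
                if rotate:
                    atom.position = R @ (atom.position - pivot) + pivot
            elif noise_sd > 0:
                atom.position = atom.position + rng.normal(0.0, noise_sd, size=3)
    return out


# --------------------------------------------------------------------------
# emission

def write_manifest(truth: FixtureTruth, path: str | Path) -> None:
    payload = {
        "cutoff": truth.cutoff,
        "expected_ion_pairs": truth.expected_ion_pairs,
        "expected_assembly_chain_count": truth.expected_assembly_chain_count,
        "expected_sequence": truth.expected_sequence,
        "applied_transform": truth.applied_transform,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def emit_fixture(spec: FixtureSpec, directory: str | Path,
                 stem: str = "fixture") -> tuple[Path, Path]:
    """Write ``<stem>.pdb`` and ``<stem>.manifest.json``; returns both paths.

    Same spec + seed gives byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    structure, truth = make_dimer_fixture(spec)
    pdb_path = directory / f"{stem}.pdb"
    manifest_path = directory / f"{stem}.manifest.json"
    write_pdb(structure, pdb_path)
    write_manifest(truth, manifest_path)
    return pdb_path, manifest_path
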