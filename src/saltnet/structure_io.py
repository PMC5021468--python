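"""Reading, writing and assembling protein structures.

The in-memory model is deliberately small: a :class:`Structure` is an
ordered mapping of chain ids to residue lists, plus the metadata needed by
the downstream analyses (SEQRES sequences, unit cell, biological-assembly
transforms).  Parsing is delegated to :mod:`gemmi`; this module converts the
gemmi hierarchy into plain dataclasses and enforces the contracts the rest
of the package relies on (altloc policy, heavy atoms only, author residue
numbering).
"""

from __future__ import annotations

import copy
import logging
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

import gemmi
import numpy as np

logger = logging.getLogger("saltnet")

STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in STANDARD_AA3.items()}
AA1_TO_AA3["X"] = "UNK"

RecordKind = Literal["polymer", "water", "hetero"]


class PDBFormatError(ValueError):
    """Raised when a coordinate file violates the fixed-column PDB format."""


class AssemblyError(ValueError):
    """Raised when a biological assembly cannot be built."""


@dataclass
class Atom:
    """A single heavy atom.

    ``record_kind`` mirrors the residue it belongs to so that atom-level
    consumers need not walk back up the hierarchy.
    """

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    record_kind: RecordKind = "polymer"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def record_kind(self) -> RecordKind:
        return self.atoms[0].record_kind if self.atoms else "polymer"

    def get_atom(self, name: str) -> Atom | None:
        """First atom with the given name (after altloc policy, the only one)."""
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def validate(self) -> None:
        seen = set()
        for atom in self.atoms:
            key = (atom.name, atom.altloc)
            if key in seen:
                raise ValueError(
                    f"residue {self.name}{self.seq_id}/{self.chain_id}: "
                    f"duplicate atom {key}"
                )
            seen.add(key)


@dataclass
class AssemblyTransform:
    """One operator from the deposited biological-assembly records."""

    rotation: np.ndarray
    translation: np.ndarray
    chain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=1e-9) and np.allclose(
            self.translation, 0.0, atol=1e-9
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Structure:
    """Hierarchical coordinate model: chains -> residues -> atoms."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    seqres: dict[str, str] = field(default_factory=dict)
    cell: tuple[float, float, float, float, float, float] | None = None
    assembly_transforms: list[AssemblyTransform] = field(default_factory=list)
    source_id: str = ""

    def validate(self) -> None:
        for chain_id, residues in self.chains.items():
            for res in residues:
                if res.chain_id != chain_id:
                    raise ValueError(
                        f"residue {res.name}{res.seq_id} carries chain id "
                        f"{res.chain_id!r} but lives in chain {chain_id!r}"
                    )
                res.validate()
        for t in self.assembly_transforms:
            if not np.allclose(t.rotation @ t.rotation.T, np.eye(3), atol=1e-4):
                raise ValueError("assembly transform rotation is not orthonormal")

    def residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain_id, ()):
            if res.seq_id == seq_id and res.icode == icode:
                return res
        return None

    def iter_residues(self, kind: RecordKind | None = None) -> Iterator[Residue]:
        for residues in self.chains.values():
            for res in residues:
                if kind is None or res.record_kind == kind:
                    yield res

    def polymer_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.chains.get(chain_id, ()) if r.record_kind == "polymer"]

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass
class ModelStats:
    n_protein_atoms: int
    n_waters: int
    n_hetero_groups: int
    n_modeled_residues_per_chain: dict[str, int]

    def __post_init__(self) -> None:
        counts = [self.n_protein_atoms, self.n_waters, self.n_hetero_groups,
                  *self.n_modeled_residues_per_chain.values()]
        if any(c < 0 for c in counts):
            raise ValueError("model statistics must be non-negative")


# --------------------------------------------------------------------------
# reading

def _classify_residue(res: gemmi.Residue) -> RecordKind:
    if res.is_water():
        return "water"
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return "polymer"
    return "hetero"


def _validate_coordinate_records(text: str, path: Path) -> int:
    """Check fixed-column sanity of ATOM/HETATM records; return their count.

    gemmi is forgiving about malformed numeric fields, so the strictness the
    file contract demands is applied here before handing off.
    """
    n_coord = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_coord += 1
        if len(line) < 54:
            raise PDBFormatError(f"{path}: line {lineno}: coordinate record shorter than 54 columns")
        fields = [line[30:38], line[38:46], line[46:54]]
        if len(line) >= 60:
            fields.append(line[54:60])
        for text_field in fields:
            try:
                float(text_field)
            except ValueError:
                raise PDBFormatError(
                    f"{path}: line {lineno}: malformed numeric field {text_field.strip()!r}"
                ) from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBFormatError(
                f"{path}: line {lineno}: malformed residue number {line[22:26].strip()!r}"
            ) from None
    return n_coord


def _seqres_one_letter(names: Iterable[str]) -> str:
    out = []
    for name in names:
        out.append(STANDARD_AA3.get(name.upper(), "X"))
    return "".join(out)


def read_pdb(path: str | Path) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Hydrogens are dropped; all alternate locations are retained (see
    :func:`dedupe_altlocs` for the single-conformer policy used by the
    geometric analyses).  Author residue numbering is kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if _validate_coordinate_records(text, path) == 0:
        raise PDBFormatError(f"{path}: no ATOM or HETATM records")

    st = gemmi.read_structure(str(path), merge_chain_parts=True)
    st.setup_entities()

    structure = Structure(source_id=st.name or path.stem)
    cell = st.cell
    if cell and cell.a > 1.0:  # gemmi uses a dummy 1 A cell when CRYST1 absent
        structure.cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            kind = _classify_residue(res)
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    altloc=at.altloc if at.altloc != "\0" else "",
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    record_kind=kind,
                ))
            residues.append(Residue(
                name=res.name, seq_id=res.seqid.num, chain_id=chain.name,
                atoms=atoms, icode=res.seqid.icode.strip(),
            ))
        if chain.name in structure.chains:
            structure.chains[chain.name].extend(residues)
        else:
            structure.chains[chain.name] = residues

    for chain in model:
        polymer = chain.get_polymer()
        entity = st.get_entity_of(polymer)
        if entity is not None and entity.full_sequence:
            structure.seqres[chain.name] = _seqres_one_letter(
                gemmi.Entity.first_mon(item) for item in entity.full_sequence
            )

    if st.assemblies:
        assembly = st.assemblies[0]
        for gen in assembly.generators:
            chain_ids = tuple(gen.chains)
            for op in gen.operators:
                tr = op.transform
                structure.assembly_transforms.append(AssemblyTransform(
                    rotation=np.array(tr.mat.tolist()),
                    translation=np.array(tr.vec.tolist()),
                    chain_ids=chain_ids,
                ))

    structure.validate()
    return structure


# --------------------------------------------------------------------------
# altloc policy

def dedupe_altlocs(s: Structure) -> Structure:
    """Return a copy keeping one conformer per atom name.

    Highest occupancy wins; ties go to the conformer that appears first in
    the file.  Downstream geometry (ion pairs, RMSD) always runs on the
    deduplicated model.
    """
    out = s.copy()
    for residues in out.chains.values():
        for res in residues:
            best: dict[str, Atom] = {}
            for atom in res.atoms:
                prev = best.get(atom.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    best[atom.name] = atom
            kept = []
            seen = set()
            for atom in res.atoms:  # preserve file order
                if atom.name not in seen and best[atom.name] is atom:
                    atom.altloc = ""
                    kept.append(atom)
                    seen.add(atom.name)
            res.atoms = kept
    return out


# --------------------------------------------------------------------------
# assembly

def build_assembly(
    s: Structure,
    mode: Literal["asymmetric_unit", "biological_assembly"] = "biological_assembly",
) -> Structure:
    """Expand the asymmetric unit into the deposited biological assembly.

    Each stored transform is applied to its target chains.  The identity
    operator reuses the original chain; generated copies get ``-2``, ``-3``
    ... suffixes so every chain traces back to its source.  Requesting the
    biological assembly of a file without assembly records is an error --
    silently returning the monomer would corrupt every dimer-level count.
    """
    if mode == "asymmetric_unit":
        return s
    if mode != "biological_assembly":
        raise ValueError(f"unknown assembly mode {mode!r}")
    if not s.assembly_transforms:
        raise AssemblyError(
            f"{s.source_id or 'structure'}: no assembly records; cannot build "
            "the biological assembly"
        )

    out = Structure(cell=s.cell, source_id=s.source_id,
                    assembly_transforms=list(s.assembly_transforms))
    copy_counter: dict[str, int] = {}
    for transform in s.assembly_transforms:
        for chain_id in transform.chain_ids:
            if chain_id not in s.chains:
                raise AssemblyError(
                    f"assembly transform targets unknown chain {chain_id!r}"
                )
            if transform.is_identity and chain_id not in out.chains:
                new_id = chain_id
            else:
                copy_counter[chain_id] = copy_counter.get(chain_id, 1) + 1
                new_id = f"{chain_id}-{copy_counter[chain_id]}"
            new_residues = []
            for res in s.chains[chain_id]:
                new_atoms = [replace(
                    atom, position=transform.apply(atom.position[None, :])[0]
                ) for atom in res.atoms]
                new_residues.append(Residue(
                    name=res.name, seq_id=res.seq_id, chain_id=new_id,
                    atoms=new_atoms, icode=res.icode,
                ))
            out.chains[new_id] = new_residues
            if chain_id in s.seqres:
                out.seqres[new_id] = s.seqres[chain_id]
    out.validate()
    return out


# --------------------------------------------------------------------------
# audit

def model_stats(s: Structure) -> ModelStats:
    """Count protein atoms, waters and hetero groups (asymmetric unit).

    Protein atoms are counted after altloc deduplication: one position per
    atom name, highest occupancy wins.
    """
    deduped = dedupe_altlocs(s)
    n_protein = 0
    n_waters = 0
    n_hetero = 0
    per_chain: dict[str, int] = {}
    for chain_id, residues in deduped.chains.items():
        for res in residues:
            kind = res.record_kind
            if kind == "polymer":
                n_protein += len(res.atoms)
                per_chain[chain_id] = per_chain.get(chain_id, 0) + 1
            elif kind == "water":
                n_waters += 1
            else:
                n_hetero += 1
    return ModelStats(
        n_protein_atoms=n_protein,
        n_waters=n_waters,
        n_hetero_groups=n_hetero,
        n_modeled_residues_per_chain=per_chain,
    )


# --------------------------------------------------------------------------
# writing

def _chain_id_map(chain_ids: Iterable[str]) -> dict[str, str]:
    """Map possibly multi-character chain ids onto single PDB columns."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    pool = list(string.ascii_uppercase + string.ascii_lowercase + string.digits)
    ids = list(chain_ids)
    for cid in ids:
        if len(cid) == 1 and cid not in used:
            mapping[cid] = cid
            used.add(cid)
    for cid in ids:
        if cid in mapping:
            continue
        base = cid[0] if cid and cid[0] not in used else next(c for c in pool if c not in used)
        mapping[cid] = base
        used.add(base)
        if base != cid:
            logger.warning("write_pdb: chain id %r written as %r", cid, base)
    return mapping


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def write_pdb(s: Structure, path: str | Path) -> dict[str, str]:
    """Write a Structure as fixed-column PDB; returns the chain-id mapping.

    Output is deterministic for a given structure (coordinates to 3 decimal
    places, the format's precision), which the synthetic fixtures rely on.
    """
    path = Path(path)
    id_map = _chain_id_map(s.chains.keys())
    lines: list[str] = []
    if s.cell is not None:
        a, b, c, al, be, ga = s.cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1"
        )
    if s.assembly_transforms:
        lines.append("REMARK 350 BIOMOLECULE: 1")
        current_chains: tuple[str, ...] | None = None
        for i, t in enumerate(s.assembly_transforms, start=1):
            if t.chain_ids != current_chains:
                shown = ", ".join(id_map.get(c, c) for c in t.chain_ids)
                lines.append(f"REMARK 350 APPLY THE FOLLOWING TO CHAINS: {shown}")
                current_chains = t.chain_ids
            for row in range(3):
                vals = "".join(f"{t.rotation[row, col]:10.6f}" for col in range(3))
                lines.append(
                    f"REMARK 350   BIOMT{row + 1} {i:3d}{vals}{t.translation[row]:15.5f}"
                )
    for chain_id, seq in s.seqres.items():
        codes = [AA1_TO_AA3.get(c, "UNK") for c in seq]
        for ser, start in enumerate(range(0, len(codes), 13), start=1):
            chunk = " ".join(codes[start:start + 13])
            lines.append(
                f"SEQRES {ser:3d} {id_map.get(chain_id, chain_id)} {len(codes):4d}  {chunk}"
            )
    serial = 0
    for chain_id, residues in s.chains.items():
        cid = id_map[chain_id]
        last_polymer = None
        for res in residues:
            record = "ATOM  " if res.record_kind == "polymer" else "HETATM"
            for atom in res.atoms:
                serial += 1
                name = _format_atom_name(atom.name, atom.element)
                alt = atom.altloc or " "
                x, y, z = atom.position
                lines.append(
                    f"{record}{serial:5d} {name}{alt}{res.name:>3s} {cid}"
                    f"{res.seq_id:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
            if res.record_kind == "polymer":
                last_polymer = res
        if last_polymer is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_polymer.name:>3s} {cid}"
                f"{last_polymer.seq_id:4d}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return id_map
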