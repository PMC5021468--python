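from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from saltnet import (
    Atom,
    FixtureSpec,
    PlantedPair,
    Residue,
    Structure,
    default_dimer_transform,
    locate_structure,
    make_dimer_fixture,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


def entry_path(pdb_id: str) -> Path | None:
    """Local copy of a deposited PDB entry, if the user has placed one."""
    return locate_structure(pdb_id, DATA_DIR)


def make_residue(chain_id: str, seq_id: int, name: str,
                 atoms: dict[str, tuple[float, float, float]],
                 kind: str = "polymer") -> Residue:
    """Hand-build a residue with explicit atom coordinates."""
    return Residue(
        name=name, seq_id=seq_id, chain_id=chain_id,
        atoms=[Atom(n, n[0], np.array(p, dtype=float), record_kind=kind)
               for n, p in atoms.items()],
    )


@pytest.fixture
def planted_dimer():
    """Dimer with intra-chain planted contacts straddling the 4.0-A cutoff."""
    spec = FixtureSpec(
        n_residues=60,
        planted_pairs=(
            PlantedPair(10, 20, 3.0, "ARG", "GLU"),
            PlantedPair(30, 40, 3.9, "LYS", "ASP"),
            PlantedPair(45, 55, 4.5, "LYS", "GLU"),
        ),
        dimer_transform=default_dimer_transform(),
        n_missing_nterm=2,
        n_waters=4,
        hetero=("GOL", "SO4"),
        seed=101,
    )
    structure, truth = make_dimer_fixture(spec)
    return spec, structure, truth


@pytest.fixture
def monomer_biomt():
    """Monomer carrying assembly transforms (crystallographic-2-fold style)."""
    spec = FixtureSpec(
        n_residues=40,
        planted_pairs=(PlantedPair(5, 15, 3.5, "ARG", "GLU"),),
        dimer_transform=default_dimer_transform(),
        monomer_with_transforms=True,
        seed=202,
    )
    structure, truth = make_dimer_fixture(spec)
    return spec, structure, truth


@pytest.fixture
def interface_dimer():
    """Hand-built two-chain structure with one intersubunit salt bridge
    between the C-terminal region of chain A and the N-terminal region of
    chain B, plus one intrasubunit bridge inside chain A."""
    s = Structure(source_id="interface-toy")
    backbone = {"N": (0, -1, 0), "CA": (0, 0, 0), "C": (1, 0, 0), "O": (2, 0, 0)}

    def shifted(base: dict, dx: float, dy: float = 0.0) -> dict:
        return {k: (x + dx, y + dy, z) for k, (x, y, z) in base.items()}

    chain_a = []
    for i in range(1, 61):
        chain_a.append(make_residue("A", i, "ALA", shifted(backbone, 6.0 * i)))
    # intrasubunit pair: LYS5 NZ at (30, 5, 0) vs GLU12 OE1 at (30, 8, 0) -> 3.0
    chain_a[4] = make_residue("A", 5, "LYS",
                              {**shifted(backbone, 30.0), "NZ": (30, 5, 0)})
    chain_a[11] = make_residue("A", 12, "GLU",
                               {**shifted(backbone, 72.0), "OE1": (30, 8, 0),
                                "OE2": (30, 9.2, 0)})
    # C-terminal arginine reaching across the interface
    chain_a[57] = make_residue("A", 58, "ARG",
                               {**shifted(backbone, 348.0),
                                "NE": (400, 50, 0), "NH1": (400, 50.8, 0),
                                "NH2": (400, 49.2, 0)})
    chain_b = []
    for i in range(1, 61):
        chain_b.append(make_residue("B", i, "ALA", shifted(backbone, 6.0 * i, 100.0)))
    # N-terminal glutamate: OE1 at 3.5 A from A/ARG58 NE
    chain_b[7] = make_residue("B", 8, "GLU",
                              {**shifted(backbone, 48.0, 100.0),
                               "OE1": (400, 53.5, 0), "OE2": (400, 54.7, 0)})
    s.chains["A"] = chain_a
    s.chains["B"] = chain_b
    s.validate()
    return s
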