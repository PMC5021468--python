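"""Ion-pair (salt-bridge) detection, classification and networking.

An ion pair is a pair of oppositely charged residues whose charged
side-chain atoms approach within a distance criterion (default 4.0 A,
inclusive).  Counting is at residue granularity: however many atom-atom
contacts two residues make, they contribute one pair.  Pairs are labelled
by span (intra- vs intersubunit) and by the structural region of each
partner, which is what lets the interterminal contacts -- the C-terminal
arm of one subunit clamping the N-terminal region of the other -- be
reported separately.  Connected components of the pair graph form ion-pair
networks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Structure, dedupe_altlocs

logger = logging.getLogger("saltnet")

#: Side-chain atoms treated as charge carriers, per residue type.
CHARGED_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

Span = Literal["intrasubunit", "intersubunit"]
Region = Literal["large_domain", "small_domain", "n_terminal", "c_terminal", "unassigned"]
TERMINAL_REGIONS = frozenset({"n_terminal", "c_terminal"})


@dataclass(frozen=True)
class ResidueId:
    chain_id: str
    seq_id: int
    name: str

    def __str__(self) -> str:
        return f"{self.name}{self.seq_id}/{self.chain_id}"


@dataclass(frozen=True)
class IonPairParams:
    """Detection criteria.  Defaults follow the 4.0-A opposite-charge rule.

    Histidine is excluded from the positive set by default (its protonation
    is ambiguous at crystallographic pH); flip ``include_histidine`` for a
    sensitivity analysis.
    """

    cutoff: float = 4.0
    positive_residues: frozenset[str] = frozenset({"ARG", "LYS"})
    negative_residues: frozenset[str] = frozenset({"ASP", "GLU"})
    include_histidine: bool = False
    charged_atoms: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CHARGED_ATOMS)
    )

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.positive_residues & self.negative_residues:
            raise ValueError("positive and negative residue sets must be disjoint")

    @property
    def effective_positive(self) -> frozenset[str]:
        if self.include_histidine:
            return self.positive_residues | {"HIS"}
        return self.positive_residues


@dataclass
class IonPair:
    """One opposite-charge residue contact; ``res_a`` is the positive partner."""

    res_a: ResidueId
    res_b: ResidueId
    min_distance: float
    closest_atom_pair: tuple[str, str]
    span: Span | None = None
    regions: tuple[Region, Region] | None = None

    @property
    def is_interterminal(self) -> bool:
        return (
            self.span == "intersubunit"
            and self.regions is not None
            and set(self.regions) <= TERMINAL_REGIONS
        )

    def involves(self, name: str, seq_id: int) -> bool:
        return any(r.name == name and r.seq_id == seq_id for r in (self.res_a, self.res_b))


Interval = tuple[int, int]


def _in_intervals(seq_id: int, intervals: Iterable[Interval]) -> bool:
    return any(lo <= seq_id <= hi for lo, hi in intervals)


@dataclass(frozen=True)
class DomainDefinition:
    """Residue-number intervals delimiting the structural regions of a chain.

    Terminal intervals take precedence over domain intervals when labelling
    (the N-terminal stretch is part of the large domain, but for ion-pair
    bookkeeping its terminal identity is the informative one).
    """

    large_domain: tuple[Interval, ...] = ()
    small_domain: tuple[Interval, ...] = ()
    n_terminal: Interval | None = None
    c_terminal: Interval | None = None

    def __post_init__(self) -> None:
        for intervals in (self.large_domain, self.small_domain):
            spans = sorted(intervals)
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError("overlapping intervals within a domain field")

    def region_of(self, seq_id: int) -> Region:
        if self.c_terminal and _in_intervals(seq_id, [self.c_terminal]):
            return "c_terminal"
        if self.n_terminal and _in_intervals(seq_id, [self.n_terminal]):
            return "n_terminal"
        if _in_intervals(seq_id, self.small_domain):
            return "small_domain"
        if _in_intervals(seq_id, self.large_domain):
            return "large_domain"
        return "unassigned"


# Domain boundaries of the two citrate-synthase isozymes (author numbering).
ST1805_DOMAINS = DomainDefinition(
    large_domain=((3, 216), (325, 378)),
    small_domain=((217, 324),),
    n_terminal=(1, 60),
    c_terminal=(354, 378),
)
ST0587_DOMAINS = DomainDefinition(
    large_domain=((1, 212), (321, 373)),
    small_domain=((213, 320),),
    n_terminal=(1, 60),
    c_terminal=(349, 373),
)

#: Putative substrate-binding residues (the primed entry sits on the partner
#: chain of the dimer).
ACTIVE_SITE_ST1805 = (
    ("HIS", 184), ("HIS", 259), ("ARG", 268), ("ARG", 339), ("ARG", 359),
)
ACTIVE_SITE_ST0587 = (
    ("HIS", 180), ("HIS", 215), ("HIS", 254), ("ARG", 263), ("ARG", 335), ("ARG", 354),
)


def default_domains(
    s: Structure,
    n_terminal_length: int = 60,
    c_terminal_length: int = 25,
) -> dict[str, DomainDefinition]:
    """Heuristic per-chain region intervals when none are supplied.

    The N-terminal region is taken as the first ``n_terminal_length``
    residue numbers and the C-terminal region as the last
    ``c_terminal_length``; in these enzymes that covers the interterminal
    contacts (partners out to the E helix, around residue 60, and the
    C-terminal arm).  Domains are left empty -- they are protein-specific
    knowledge the caller can supply.
    """
    out = {}
    for chain_id in s.chains:
        polymer = s.polymer_residues(chain_id)
        if not polymer:
            continue
        lo = min(r.seq_id for r in polymer)
        hi = max(r.seq_id for r in polymer)
        out[chain_id] = DomainDefinition(
            n_terminal=(lo, lo + n_terminal_length - 1),
            c_terminal=(hi - c_terminal_length + 1, hi),
        )
    return out


# --------------------------------------------------------------------------
# detection

def _charged_atom_table(
    s: Structure, params: IonPairParams
) -> tuple[list[tuple[ResidueId, str]], np.ndarray, list[str]]:
    """Flatten charged atoms into (owner, atom-name) rows plus coordinates."""
    charged_sets = params.effective_positive | params.negative_residues
    owners: list[tuple[ResidueId, str]] = []
    coords: list[np.ndarray] = []
    charges: list[str] = []
    for chain_id in s.chains:
        for res in s.polymer_residues(chain_id):
            if res.name not in charged_sets:
                continue
            wanted = params.charged_atoms.get(res.name, ())
            atoms = [a for name in wanted if (a := res.get_atom(name)) is not None]
            if not atoms:
                logger.warning(
                    "find_ion_pairs: %s%d/%s has no charged side-chain atoms "
                    "(disorder?); skipped", res.name, res.seq_id, chain_id,
                )
                continue
            rid = ResidueId(chain_id, res.seq_id, res.name)
            charge = "+" if res.name in params.effective_positive else "-"
            for atom in atoms:
                owners.append((rid, atom.name))
                coords.append(atom.position)
                charges.append(charge)
    if not coords:
        return [], np.empty((0, 3)), []
    return owners, np.vstack(coords), charges


def find_ion_pairs(s: Structure, params: IonPairParams | None = None) -> list[IonPair]:
    """Detect opposite-charge residue pairs within the distance cutoff.

    The comparison is inclusive (min charged-atom distance <= cutoff).
    Residues whose charged side-chain atoms are all missing are skipped
    with a warning.  Output is sorted by (chain_a, seq_a, chain_b, seq_b).
    """
    params = params or IonPairParams()
    s = dedupe_altlocs(s)
    owners, coords, charges = _charged_atom_table(s, params)
    pos_idx = [i for i, c in enumerate(charges) if c == "+"]
    neg_idx = [i for i, c in enumerate(charges) if c == "-"]
    best: dict[tuple[ResidueId, ResidueId], tuple[float, tuple[str, str]]] = {}
    if pos_idx and neg_idx:
        pos_coords = coords[pos_idx]
        neg_coords = coords[neg_idx]
        tree = cKDTree(neg_coords)
        # small slack so exact-boundary contacts survive kd-tree fp pruning
        neighbor_lists = tree.query_ball_point(pos_coords, r=params.cutoff * (1 + 1e-9))
        for pi, neighbors in zip(pos_idx, neighbor_lists):
            rid_a, atom_a = owners[pi]
            for nj in neighbors:
                ni = neg_idx[nj]
                rid_b, atom_b = owners[ni]
                d = float(np.linalg.norm(coords[pi] - coords[ni]))
                if d > params.cutoff:
                    continue
                key = (rid_a, rid_b)
                if key not in best or d < best[key][0]:
                    best[key] = (d, (atom_a, atom_b))
    pairs = [
        IonPair(
            res_a=a, res_b=b, min_distance=d, closest_atom_pair=atoms,
            span="intersubunit" if a.chain_id != b.chain_id else "intrasubunit",
        )
        for (a, b), (d, atoms) in best.items()
    ]
    pairs.sort(key=lambda p: (p.res_a.chain_id, p.res_a.seq_id, p.res_b.chain_id, p.res_b.seq_id))
    return pairs


# --------------------------------------------------------------------------
# classification

def classify_pairs(
    pairs: Sequence[IonPair],
    domains_by_chain: Mapping[str, DomainDefinition],
) -> list[IonPair]:
    """Fill span and region labels on each pair.

    A pair is *interterminal* when it spans two subunits and both partners
    carry terminal-region labels (one chain's C-terminal arm against the
    other's N-terminal region).  Residues falling outside every interval
    are labelled ``unassigned`` and logged.
    """
    out = []
    for pair in pairs:
        regions = []
        for rid in (pair.res_a, pair.res_b):
            definition = domains_by_chain.get(rid.chain_id)
            region: Region = "unassigned" if definition is None else definition.region_of(rid.seq_id)
            if region == "unassigned":
                logger.warning("classify_pairs: %s outside all region intervals", rid)
            regions.append(region)
        span: Span = (
            "intersubunit" if pair.res_a.chain_id != pair.res_b.chain_id else "intrasubunit"
        )
        out.append(replace(pair, span=span, regions=(regions[0], regions[1])))
    return out


def pair_counts(pairs: Sequence[IonPair]) -> dict[str, int]:
    """Summary tallies used in reports (total / span / interterminal / regions)."""
    counts = {
        "total": len(pairs),
        "intrasubunit": sum(p.span == "intrasubunit" for p in pairs),
        "intersubunit": sum(p.span == "intersubunit" for p in pairs),
        "interterminal": sum(p.is_interterminal for p in pairs),
    }
    by_region: dict[str, int] = {}
    for p in pairs:
        if p.regions:
            label = "-".join(sorted(p.regions))
            by_region[label] = by_region.get(label, 0) + 1
    counts["by_region"] = by_region  # type: ignore[assignment]
    return counts


# --------------------------------------------------------------------------
# networks

@dataclass
class IonPairNetwork:
    members: frozenset[ResidueId]
    edges: tuple[IonPair, ...]
    size: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("a network needs at least two members")

    def member_set(self) -> set[tuple[str, int, str]]:
        return {(r.chain_id, r.seq_id, r.name) for r in self.members}


def build_networks(pairs: Sequence[IonPair]) -> list[IonPairNetwork]:
    """Connected components of the residue/ion-pair graph, largest first.

    Two-member components (simple pairs) are included; the field's notion
    of a *network* is usually >= 3 residues, which callers can filter on
    ``size``.
    """
    graph = nx.Graph()
    for pair in pairs:
        graph.add_edge(pair.res_a, pair.res_b)
    networks = []
    for component in nx.connected_components(graph):
        edges = tuple(
            p for p in pairs if p.res_a in component and p.res_b in component
        )
        networks.append(IonPairNetwork(
            members=frozenset(component), edges=edges, size=len(component),
        ))
    networks.sort(
        key=lambda n: (-n.size, min((r.chain_id, r.seq_id) for r in n.members))
    )
    return networks


# --------------------------------------------------------------------------
# active site

def active_site_check(
    s: Structure,
    expected: Sequence[ResidueId],
) -> list[tuple[ResidueId, bool]]:
    """Verify that each expected residue is present with the expected name."""
    report = []
    for rid in expected:
        res = s.residue(rid.chain_id, rid.seq_id)
        report.append((rid, res is not None and res.name == rid.name))
    return report


# --------------------------------------------------------------------------
# report output

def pairs_to_dataframe(pairs: Sequence[IonPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "chain_a": p.res_a.chain_id, "res_a": p.res_a.name, "num_a": p.res_a.seq_id,
            "chain_b": p.res_b.chain_id, "res_b": p.res_b.name, "num_b": p.res_b.seq_id,
            "min_distance": round(p.min_distance, 3),
            "span": p.span or "",
            "region_a": p.regions[0] if p.regions else "",
            "region_b": p.regions[1] if p.regions else "",
        })
    return pd.DataFrame(rows, columns=[
        "chain_a", "res_a", "num_a", "chain_b", "res_b", "num_b",
        "min_distance", "span", "region_a", "region_b",
    ])


def write_pairs_tsv(pairs: Sequence[IonPair], path: str | Path) -> None:
    pairs_to_dataframe(pairs).to_csv(path, sep="\t", index=False)


def pairs_to_json(pairs: Sequence[IonPair], networks: Sequence[IonPairNetwork] | None = None) -> str:
    records = pairs_to_dataframe(pairs).to_dict(orient="records")
    payload: dict = {"pairs": records}
    if networks is not None:
        payload["networks"] = [
            {
                "size": n.size,
                "members": sorted(
                    f"{r.name}{r.seq_id}/{r.chain_id}" for r in n.members
                ),
            }
            for n in networks
        ]
    return json.dumps(payload, indent=2, sort_keys=True)
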