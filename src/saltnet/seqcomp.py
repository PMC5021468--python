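"""Sequence extraction, global alignment and amino-acid composition.

Composition is the classic thermostability screen: thermophilic enzymes
tend to be enriched in the charged residues Glu and Lys (ion-pair
formation) and depleted in the oxidation/deamidation-prone Cys, Met, Asn
and Gln.  The module reports per-residue counts and percentages plus those
derived indicators, and a Needleman-Wunsch/Gotoh global aligner provides
percent identity and the residue correspondence used for cross-protein
RMSD.

Alignment conventions
---------------------
Affine gaps: a gap of length L costs ``gap_open + (L - 1) * gap_extend``.
End gaps are penalized (true global alignment).  Traceback ties are broken
deterministically: diagonal, then up (gap in *b*), then left (gap in *a*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure_io import STANDARD_AA3, Structure

logger = logging.getLogger("saltnet")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Row order of the composition table (Gly ... Pro, then Total).
COMPOSITION_ROW_ORDER = list("GAVLIFYWCMSTNQDEHKRP")

DenominatorRule = Literal["shorter_sequence", "aligned_columns", "alignment_length"]


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    source: Literal["seqres", "atom_records"]
    numbering: tuple[int, ...] | None = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - set(AA_ALPHABET + "X")
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
        if self.numbering is not None and len(self.numbering) != len(self.residues):
            raise ValueError("numbering length must match sequence length")

    def __len__(self) -> int:
        return len(self.residues)


def extract_sequence(
    s: Structure,
    chain: str,
    source: Literal["seqres", "atom_records"] = "seqres",
) -> ProteinSequence:
    """One-letter sequence of a chain.

    ``seqres`` gives the full deposited sequence; ``atom_records`` gives
    only the modeled residues, in author-number order, with the numbering
    retained (needed to map alignments back onto coordinates).
    Non-standard residues become ``X``.
    """
    if chain not in s.chains:
        raise KeyError(f"unknown chain {chain!r}")
    if source == "seqres":
        if chain not in s.seqres:
            raise ValueError(f"chain {chain!r} has no SEQRES record")
        return ProteinSequence(
            id=f"{s.source_id}_{chain}", residues=s.seqres[chain],
            source="seqres", chain_id=chain,
        )
    residues = sorted(s.polymer_residues(chain), key=lambda r: (r.seq_id, r.icode))
    if not residues:
        raise ValueError(f"chain {chain!r} has no polymer residues")
    letters = "".join(STANDARD_AA3.get(r.name, "X") for r in residues)
    return ProteinSequence(
        id=f"{s.source_id}_{chain}", residues=letters, source="atom_records",
        numbering=tuple(r.seq_id for r in residues), chain_id=chain,
    )


# --------------------------------------------------------------------------
# alignment

@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float
    n_identical: int
    denominator_rule: DenominatorRule

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")
        if not 0.0 <= self.identity_percent <= 100.0:
            raise ValueError("identity_percent outside [0, 100]")


def _resolve_matrix(matrix) -> Mapping:
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


def _pair_score(matrix: Mapping, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        try:
            return float(matrix[b, a])
        except (KeyError, IndexError):
            # unknown residue (X) against anything: neutral
            return 0.0


NEG_INF = float("-inf")


def global_align(
    a: ProteinSequence | str,
    b: ProteinSequence | str,
    matrix="BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator_rule: DenominatorRule = "shorter_sequence",
) -> AlignmentResult:
    """Needleman-Wunsch global alignment with affine gaps (Gotoh).

    ``gap_open`` is the cost of a gap's first position and ``gap_extend``
    of each further position.  Identity is reported under
    ``denominator_rule`` (default: percent of the shorter sequence).
    """
    sa = a.residues if isinstance(a, ProteinSequence) else a
    sb = b.residues if isinstance(b, ProteinSequence) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    sub = _resolve_matrix(matrix)
    n, m = len(sa), len(sb)

    # Three-state Gotoh: M diagonal, X gap in b (consumes a, "up"),
    # Y gap in a (consumes b, "left").
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    # pointer codes: 0 from M, 1 from X, 2 from Y
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        ptr_x[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        ptr_y[0, j] = 2 if j > 1 else 0

    def argbest(vm: float, vx: float, vy: float) -> tuple[float, int]:
        # deterministic preference: M (diagonal), then X (up), then Y (left)
        if vm >= vx and vm >= vy:
            return vm, 0
        if vx >= vy:
            return vx, 1
        return vy, 2

    for i in range(1, n + 1):
        ai = sa[i - 1]
        row_scores = [_pair_score(sub, ai, bj) for bj in sb]
        for j in range(1, m + 1):
            v, p = argbest(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = v + row_scores[j - 1]
            ptr_m[i, j] = p
            vo, ve = M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend
            if vo >= ve:
                X[i, j], ptr_x[i, j] = vo, 0
            else:
                X[i, j], ptr_x[i, j] = ve, 1
            vo, ve = M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend
            if vo >= ve:
                Y[i, j], ptr_y[i, j] = vo, 0
            else:
                Y[i, j], ptr_y[i, j] = ve, 2

    score, state = argbest(M[n, m], X[n, m], Y[n, m])
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            state = ptr_m[i, j]
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            state = ptr_x[i, j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            state = ptr_y[i, j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    n_identical = sum(
        ca == cb and ca != "-" for ca, cb in zip(aligned_a, aligned_b)
    )
    denom = {
        "shorter_sequence": min(n, m),
        "aligned_columns": sum(
            ca != "-" and cb != "-" for ca, cb in zip(aligned_a, aligned_b)
        ),
        "alignment_length": len(aligned_a),
    }[denominator_rule]
    identity = 100.0 * n_identical / denom if denom else 0.0
    return AlignmentResult(
        aligned_a=aligned_a, aligned_b=aligned_b, score=float(score),
        identity_percent=identity, n_identical=n_identical,
        denominator_rule=denominator_rule,
    )


# --------------------------------------------------------------------------
# composition

@dataclass
class CompositionTable:
    id: str
    counts: dict[str, int]
    percents: dict[str, float]
    total: int
    indicators: dict[str, float]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) > self.total:
            raise ValueError("counts exceed total")
        spread = abs(sum(self.percents.values()) - 100.0)
        if self.total and sum(self.counts.values()) == self.total and spread > 0.5:
            raise ValueError("percentages do not sum to 100 within rounding")


def composition(seq: ProteinSequence | str, id: str = "") -> CompositionTable:
    """Per-amino-acid counts and one-decimal percentages, plus indicators.

    ``X`` residues count toward the total but fall in no bin (logged).
    Indicators: E+K content (charge/ion-pair potential), N+Q (thermolabile
    deamidation), C+M (oxidation-sensitive sulfur) and all charged
    D+E+K+R+H, all in percent of the total.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    label = id or (seq.id if isinstance(seq, ProteinSequence) else "")
    counts = {aa: residues.count(aa) for aa in AA_ALPHABET}
    total = len(residues)
    n_unknown = total - sum(counts.values())
    if n_unknown:
        logger.warning("composition %s: %d unknown (X) residues counted only in total",
                       label, n_unknown)
    percents = {aa: round(100.0 * c / total, 1) if total else 0.0
                for aa, c in counts.items()}
    indicators = {
        "charged_EK": round(percents["E"] + percents["K"], 1),
        "thermolabile_NQ": round(percents["N"] + percents["Q"], 1),
        "sulfur_CM": round(percents["C"] + percents["M"], 1),
        "all_charged_DEKR_H": round(
            percents["D"] + percents["E"] + percents["K"] + percents["R"] + percents["H"], 1
        ),
    }
    return CompositionTable(id=label, counts=counts, percents=percents,
                            total=total, indicators=indicators)


def compare_compositions(tables: Sequence[CompositionTable]) -> dict:
    """Tabulate indicators side by side and flag their ordering.

    No statistical test is attached -- with a handful of sequences the
    ordering itself is the observation.
    """
    if len(tables) < 2:
        raise ValueError("need at least two composition tables to compare")
    report: dict = {"ids": [t.id for t in tables], "indicators": {}}
    for name in tables[0].indicators:
        values = [t.indicators[name] for t in tables]
        if len(set(values)) == 1:
            ordering = "equal"
        else:
            ranked = sorted(zip(values, [t.id for t in tables]), reverse=True)
            ordering = " > ".join(tid for _, tid in ranked)
        report["indicators"][name] = {"values": dict(zip(report["ids"], values)),
                                      "ordering": ordering}
    return report


def composition_to_tsv(tables: Sequence[CompositionTable], path: str | Path) -> None:
    """Write composition tables in the conventional row order (Gly...Pro, Total)."""
    aa3 = {v: k.capitalize() for k, v in STANDARD_AA3.items()}
    lines = ["\t".join(["residue"] + [t.id for t in tables])]
    for aa in COMPOSITION_ROW_ORDER:
        cells = [f"{t.counts[aa]}\t({t.percents[aa]:.1f})" for t in tables]
        lines.append("\t".join([aa3[aa]] + cells))
    lines.append("\t".join(["Total"] + [f"{t.total}\t" for t in tables]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# FASTA plumbing

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = "".join(
            c if c in AA_ALPHABET else "X" for c in str(record.seq).upper()
        )
        out.append(ProteinSequence(id=record.id, residues=seq, source="seqres"))
    return out


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
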