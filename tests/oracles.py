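"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the alignment oracle
enumerates alignments recursively, the rotation oracle minimizes RMSD
numerically over rotation space, and the detection oracle is the exhaustive
double-loop scan from the synthetic module.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def enumerate_alignment_score(a: str, b: str, pair_score, gap_open: float,
                              gap_extend: float) -> float:
    """Max global-alignment score by exhaustive recursion over alignments.

    A gap of length L costs gap_open + (L-1) * gap_extend; end gaps are
    penalized.  Feasible for short strings only.
    """
    best = -math.inf

    def rec(i: int, j: int, acc: float, last: str | None) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + pair_score(a[i], b[j]), "m")
        if i < len(a):
            cost = gap_extend if last == "ga" else gap_open
            rec(i + 1, j, acc - cost, "ga")
        if j < len(b):
            cost = gap_extend if last == "gb" else gap_open
            rec(i, j + 1, acc - cost, "gb")

    rec(0, 0, 0.0, None)
    return best


def toy_pair_score(a: str, b: str) -> float:
    """Simple 4-letter test scoring: +3 match, -1 mismatch."""
    return 3.0 if a == b else -1.0


def _rmsd_for_rotation(R: np.ndarray, P: np.ndarray, Q: np.ndarray) -> float:
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def min_rmsd_by_search(P: np.ndarray, Q: np.ndarray,
                       grid_step_deg: float = 20.0) -> float:
    """Minimum superposition RMSD found by rotation-space search.

    Coarse Euler-angle grid followed by Nelder-Mead refinement of the
    rotation vector; independent of any closed-form solution.
    """
    best_rmsd = math.inf
    best_rotvec = np.zeros(3)
    step = math.radians(grid_step_deg)
    n1 = int(2 * math.pi / step)
    n2 = int(math.pi / step) + 1
    for i in range(n1):
        for j in range(n2):
            for k in range(n1):
                R = Rotation.from_euler(
                    "zyz", [i * step, j * step, k * step]
                ).as_matrix()
                r = _rmsd_for_rotation(R, P, Q)
                if r < best_rmsd:
                    best_rmsd = r
                    best_rotvec = Rotation.from_matrix(R).as_rotvec()

    def objective(rotvec: np.ndarray) -> float:
        return _rmsd_for_rotation(Rotation.from_rotvec(rotvec).as_matrix(), P, Q)

    result = minimize(objective, best_rotvec, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(min(best_rmsd, result.fun))
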