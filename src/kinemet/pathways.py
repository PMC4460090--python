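"""Structural pathway analysis: elementary flux modes and flux-balance checks.

Elementary flux modes (EFMs) are the minimal-support flux vectors v with
N·v = 0 that respect irreversibility (v_r >= 0 on irreversible reactions).
They are computed by the classical tableau (double-description) iteration
over exact rational arithmetic: reversible reactions are split into forward
and backward columns, the irreversible problem is solved, and the spurious
forward/backward 2-cycles are removed on recombination.  Exactness at desk
scale (<= 32 reactions) beats floating-point tableaux.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Sequence

import numpy as np

from .core import StoichiometricMatrix

__all__ = ["FluxMode", "elementary_flux_modes", "verify_flux_distribution"]

MAX_REACTIONS = 32


class FluxMode:
    """An elementary flux mode: per-reaction rational weights.

    Weights are normalized so the smallest nonzero |weight| is 1; negative
    weights occur only on reversible reactions.
    """

    def __init__(self, reaction_ids: Sequence[str], weights: Sequence[Fraction]):
        self.reaction_ids = list(reaction_ids)
        self.weights = _normalize(list(weights))

    @property
    def support(self) -> frozenset[str]:
        return frozenset(
            rid for rid, w in zip(self.reaction_ids, self.weights) if w != 0
        )

    def as_dict(self) -> dict[str, Fraction]:
        return dict(zip(self.reaction_ids, self.weights))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FluxMode)
            and self.reaction_ids == other.reaction_ids
            and self.weights == other.weights
        )

    def __hash__(self) -> int:
        return hash((tuple(self.reaction_ids), tuple(self.weights)))

    def __repr__(self) -> str:
        terms = ", ".join(
            f"{rid}={w}" for rid, w in zip(self.reaction_ids, self.weights) if w != 0
        )
        return f"FluxMode({terms})"


def _normalize(weights: list[Fraction]) -> list[Fraction]:
    nz = [abs(w) for w in weights if w != 0]
    if not nz:
        return weights
    scale = min(nz)
    return [w / scale for w in weights]


def elementary_flux_modes(
    matrix: StoichiometricMatrix, reversible: Sequence[bool] | None = None
) -> list[FluxMode]:
    """Complete, duplicate-free set of elementary modes of N.

    ``reversible`` gives a per-reaction flag (defaults to all irreversible).
    Ordering is deterministic: lexicographic by support (reaction indices).
    Refuses (ValueError) beyond 32 reactions — no silent truncation.
    """
    n_rxn = len(matrix.reaction_ids)
    if n_rxn > MAX_REACTIONS:
        raise ValueError(
            f"elementary-mode enumeration limited to {MAX_REACTIONS} reactions "
            f"(got {n_rxn})"
        )
    if reversible is None:
        reversible = [False] * n_rxn
    if len(reversible) != n_rxn:
        raise ValueError("reversibility flags must match the number of reactions")

    # split reversible columns: column list holds (orig_index, sign)
    cols: list[tuple[int, int]] = []
    for j in range(n_rxn):
        cols.append((j, +1))
        if reversible[j]:
            cols.append((j, -1))
    m = len(matrix.species_ids)
    N = [
        [Fraction(int(matrix.matrix[i, j]) * sign) for (j, sign) in cols]
        for i in range(m)
    ]

    # Schuster tableau: rows are candidate modes over split flux space
    n_split = len(cols)
    modes: list[list[Fraction]] = [
        [Fraction(int(k == j)) for k in range(n_split)] for j in range(n_split)
    ]
    residuals: list[list[Fraction]] = [
        [N[i][j] for i in range(m)] for j in range(n_split)
    ]

    for i in range(m):  # impose each metabolite balance in turn
        zero, pos, neg = [], [], []
        for mode, res in zip(modes, residuals):
            (zero if res[i] == 0 else pos if res[i] > 0 else neg).append((mode, res))
        new_modes = [mv for mv, _ in zero]
        new_res = [rv for _, rv in zero]
        for mp, rp in pos:
            for mn, rn in neg:
                a, b = -rn[i], rp[i]  # both positive ⇒ combination is conic
                new_modes.append([a * x + b * y for x, y in zip(mp, mn)])
                new_res.append([a * x + b * y for x, y in zip(rp, rn)])
        # elementarity: keep only minimal supports, deduplicated
        supports = [frozenset(_support(mv)) for mv in new_modes]
        modes, residuals = [], []
        seen: set[frozenset[int]] = set()
        for idx, s in enumerate(supports):
            if s in seen:
                continue
            if any(k != idx and supports[k] < s for k in range(len(supports))):
                continue
            seen.add(s)
            modes.append(new_modes[idx])
            residuals.append(new_res[idx])

    # recombine split columns back to the original reaction space
    out: list[FluxMode] = []
    seen_w: set[tuple[Fraction, ...]] = set()
    for mv in modes:
        w = [Fraction(0)] * n_rxn
        for k, (j, sign) in enumerate(cols):
            w[j] += sign * mv[k]
        if all(x == 0 for x in w):
            continue  # futile forward/backward 2-cycle of a split reaction
        fm = FluxMode(matrix.reaction_ids, w)
        key = tuple(fm.weights)
        if key not in seen_w:
            seen_w.add(key)
            out.append(fm)
    out.sort(key=lambda fm: sorted(matrix.reaction_ids.index(r) for r in fm.support))
    return out


def _support(vec: list[Fraction]) -> set[int]:
    return {k for k, w in enumerate(vec) if w != 0}


def verify_flux_distribution(
    matrix: StoichiometricMatrix, fluxes: Sequence[float], tol: float = 1e-6
) -> tuple[bool, float]:
    """Check the steady-state balance ‖N·v‖∞ <= tol.

    Returns (balanced?, residual); the residual is always computed.
    """
    v = np.asarray(fluxes, dtype=float)
    if v.shape != (len(matrix.reaction_ids),):
        raise ValueError(
            f"flux vector length {v.shape} does not match "
            f"{len(matrix.reaction_ids)} reactions"
        )
    r = matrix.matrix @ v
    residual = float(np.max(np.abs(r))) if r.size else 0.0
    return residual <= tol, residual


# ---------------------------------------------------------------------------
# Brute-force oracle (used by the test suite and the acceptance property
# check): enumerate candidate supports, keep those whose restricted null
# space is one-dimensional, sign-feasible and support-minimal.
# ---------------------------------------------------------------------------

def _nullspace_frac(A: list[list[Fraction]], n: int) -> list[list[Fraction]]:
    """Null-space basis of an m×n Fraction matrix by Gauss–Jordan."""
    A = [row[:] for row in A]
    m = len(A)
    piv_col: list[int] = []
    r = 0
    for c in range(n):
        pr = next((i for i in range(r, m) if A[i][c] != 0), None)
        if pr is None:
            continue
        A[r], A[pr] = A[pr], A[r]
        pivot = A[r][c]
        A[r] = [x / pivot for x in A[r]]
        for i in range(m):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [x - f * y for x, y in zip(A[i], A[r])]
        piv_col.append(c)
        r += 1
        if r == m:
            break
    free = [c for c in range(n) if c not in piv_col]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * n
        vec[fc] = Fraction(1)
        for ri, pc in enumerate(piv_col):
            vec[pc] = -A[ri][fc]
        basis.append(vec)
    return basis


def _efm_bruteforce(
    matrix: StoichiometricMatrix, reversible: Sequence[bool] | None = None
) -> list[FluxMode]:
    """Exponential-time reference enumeration (supports <= 2^n_reactions)."""
    n = len(matrix.reaction_ids)
    if reversible is None:
        reversible = [False] * n
    m = len(matrix.species_ids)
    Nf = [[Fraction(int(matrix.matrix[i, j])) for j in range(n)] for i in range(m)]
    found: list[tuple[frozenset[int], list[Fraction]]] = []
    for size in range(1, n + 1):
        for supp in combinations(range(n), size):
            ss = frozenset(supp)
            if any(prev < ss for prev, _ in found):
                continue
            sub = [[Nf[i][j] for j in supp] for i in range(m)]
            basis = _nullspace_frac(sub, len(supp))
            if len(basis) != 1:
                continue
            vec = basis[0]
            if any(w == 0 for w in vec):
                continue  # support not fully used ⇒ handled at smaller size
            # a fully reversible support admits both orientations as modes
            for cand in (vec, [-w for w in vec]):
                if all(cand[k] > 0 or reversible[supp[k]] for k in range(len(supp))):
                    full = [Fraction(0)] * n
                    for k, j in enumerate(supp):
                        full[j] = cand[k]
                    found.append((ss, full))
    out = [FluxMode(matrix.reaction_ids, w) for _, w in found]
    out.sort(key=lambda fm: sorted(matrix.reaction_ids.index(r) for r in fm.support))
    return out
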