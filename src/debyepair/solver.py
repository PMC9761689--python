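"""Solution of the assembled transmission systems.

Direct factorization is the default.  For large truncation degrees the
system becomes ill-conditioned (the condition number grows rapidly with
n_max); a Tikhonov-regularized solve with the noise-level-free
quasi-optimality parameter choice is provided: the perturbed normal system
(A'A + alpha E) x = A'b is solved over a geometric grid
alpha_i = alpha0 q^i, i = 1..M, and the solution with the smallest
2-norm discrepancy ||A x_alpha - b|| is returned.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import numpy as np
import scipy.linalg

from .assembly import BlockSystem

__all__ = ["SolveReport", "solve_direct", "solve_regularized", "solve_auto",
           "condition_number"]

AUTO_CONDITION_THRESHOLD = 1e10


@dataclasses.dataclass
class SolveReport:
    """Solution vector with diagnostics.

    ``coefficients`` holds per-particle dicts of triangular (n_max+1)^2
    arrays L, M, G, H (kBT/e potential units, the radial conventions of the
    field expansions).
    """

    x: np.ndarray
    coefficients: List[Dict[str, np.ndarray]]
    condition_number: float
    residual_norm: float
    alpha: Optional[float] = None
    discrepancy: Optional[float] = None
    mode: str = "direct"

    def __post_init__(self):
        if self.condition_number < 1.0 - 1e-9:
            raise ValueError("condition number is the ratio of extreme singular values (>= 1)")


def condition_number(matrix: np.ndarray) -> float:
    """2-norm condition number: ratio of largest to smallest singular value."""
    s = scipy.linalg.svdvals(matrix)
    smin = s[-1]
    return float(s[0] / smin) if smin > 0 else np.inf


def _report(system: BlockSystem, x: np.ndarray, cond: float, **kw) -> SolveReport:
    resid = float(np.linalg.norm(system.matrix @ x - system.rhs))
    x_phys = system.unscale(x)
    return SolveReport(
        x=x_phys,
        coefficients=system.packing.unpack(x_phys),
        condition_number=cond,
        residual_norm=resid,
        **kw,
    )


def solve_direct(system: BlockSystem) -> SolveReport:
    """Direct LU solve of the global system; reports the condition number
    and residual.  Raises on numerically singular matrices, recommending
    the regularized solver."""
    A, b = system.matrix, system.rhs
    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(b)):
        raise FloatingPointError("system contains non-finite entries")
    cond = condition_number(A)
    if cond > 1.0 / np.finfo(float).eps:
        raise np.linalg.LinAlgError(
            f"system numerically singular (condition number {cond:.3e}); "
            "use solve_regularized"
        )
    x = scipy.linalg.solve(A, b)
    return _report(system, x, cond, mode="direct")


def solve_regularized(
    system: BlockSystem,
    regularizer: Optional[np.ndarray] = None,
    alpha0: float = 0.8**5,
    q: float = 0.8,
    M: int = 100,
    use_penalized_criterion: bool = False,
) -> SolveReport:
    """Tikhonov solve with quasi-optimality selection of alpha.

    Solves (A'A + alpha E) x = A'b for alpha on the geometric grid
    alpha_i = alpha0 * q^i, i = 1..M (defaults 0.8^5, 0.8, 100, i.e. the
    grid 0.8^6 .. 0.8^105) and keeps the x with the smallest discrepancy
    ||A x - b||.  E defaults to the identity (symmetric positive-definite
    required).  Ties within 1e-12 relative discrepancy resolve to the
    largest alpha (stability first).  ``use_penalized_criterion`` selects
    alpha by the penalized least-squares value ||Ax-b||^2 + alpha x'Ex
    instead.
    """
    if alpha0 <= 0 or not 0 < q < 1 or M < 1:
        raise ValueError("need alpha0 > 0, 0 < q < 1, M >= 1")
    A, b = system.matrix, system.rhs
    cond = condition_number(A)
    alphas = alpha0 * q ** np.arange(1, M + 1)
    solutions = []
    if regularizer is None:
        # identity regularizer: solve through the SVD once
        U, s, Vt = scipy.linalg.svd(A, full_matrices=False)
        ub = U.T @ b
        for alpha in alphas:
            filt = s / (s * s + alpha)
            solutions.append(Vt.T @ (filt * ub))
        Emat = None
    else:
        Emat = np.asarray(regularizer, dtype=float)
        if Emat.shape != A.shape or not np.allclose(Emat, Emat.T, atol=1e-12):
            raise ValueError("regularizer must be symmetric with the system's shape")
        try:
            scipy.linalg.cholesky(Emat)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError("regularizer must be positive-definite") from exc
        AtA, Atb = A.T @ A, A.T @ b
        for alpha in alphas:
            c, low = scipy.linalg.cho_factor(AtA + alpha * Emat)
            solutions.append(scipy.linalg.cho_solve((c, low), Atb))
    # noise-level-free selection: smallest 2-norm discrepancy ||A x - b||
    # over the grid (the geometric grid's smallest alpha bounds the filter
    # strength from below); ties within 1e-12 relative resolve to the
    # largest alpha (stability first).
    best = None
    for i, alpha in enumerate(alphas):
        x = solutions[i]
        crit = disc = float(np.linalg.norm(A @ x - b))
        if use_penalized_criterion:
            pen = float(x @ (Emat @ x)) if Emat is not None else float(x @ x)
            crit = disc**2 + alpha * pen
        if best is None or crit < best[0] * (1 - 1e-12):
            best = (crit, i, disc)
    _, i, disc = best
    alpha, x = alphas[i], solutions[i]
    return _report(system, x, cond, alpha=float(alpha), discrepancy=disc,
                   mode="regularized")


def solve_auto(system: BlockSystem, **reg_kwargs) -> SolveReport:
    """Direct solve unless the condition number exceeds 1e10, then
    regularized (small systems: the two coincide in practice)."""
    cond = condition_number(system.matrix)
    if cond <= AUTO_CONDITION_THRESHOLD:
        return solve_direct(system)
    return solve_regularized(system, **reg_kwargs)
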