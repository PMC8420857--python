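"""Self-consistent SVD deconvolution of a CD spectrum into six fractions.

The scheme follows the SELCON3 family of methods.  The query spectrum is
prepended to the reference spectra matrix and a guess of its fractions to the
reference fractions matrix.  An SVD of the combined spectra matrix yields, for
each truncation order k, a candidate solution

    f_k = F · V_k · S_k⁻¹ · U_kᵀ · q

where F is the (classes × proteins) fraction matrix including the current
guess, and q the query spectrum.  The guess is replaced by the highest-order
solution and the procedure iterated to self-consistency.  At convergence the
solutions across truncation orders are screened by four selection rules:

* sum rule        — fractions sum to 1 within ``tol_sum``
* fraction rule   — every class ≥ −0.025
* spectral fit    — rank-k reconstruction of the query within ``fit_max`` RMSD
* helix stability — helix total within ``helix_tol`` of the highest-order
                    converged solution

Surviving solutions are averaged, negatives clipped to zero and the result
renormalized to sum 1.  The cleanup is applied only to the final average so
the small-negative floor stays observable to the fraction rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConsistencyError,
    InvalidParameterError,
    NoSolutionError,
    NonConvergenceError,
)
from .refset import CLASS_NAMES, FractionVector, ReferenceSet, build_matrices
from .spectra import CDSpectrum, resample_to_grid

__all__ = [
    "SelconConfig",
    "SelconDiagnostics",
    "initial_guess",
    "selcon_deconvolve",
    "total_contents",
]

#: singular values below this relative threshold are treated as rank-deficient
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class SelconConfig:
    """Thresholds of the self-consistent deconvolution.

    Defaults are the literature-standard values; every one is surfaced here
    so sensitivity can be probed.
    """

    tol_sum: float = 0.05          # sum rule half-width around 1
    fraction_floor: float = -0.025  # fraction rule lower bound
    fit_max: float = 0.25          # spectral-fit rule, Δε RMSD
    helix_tol: float = 0.03        # helix-stability rule half-width
    tol_sc: float = 1e-3           # self-consistency stopping threshold
    max_iter: int = 100
    k_max: int = 8                 # SVD truncation orders 1..min(k_max, n, rank)
    range_nm: tuple[float, float] = (175.0, 240.0)


@dataclass(frozen=True)
class SelconDiagnostics:
    iterations: int
    converged: bool
    n_candidates: int
    n_survivors: int
    rejections: dict = field(default_factory=dict)
    surviving_orders: tuple[int, ...] = ()
    fit_rmsd: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "n_candidates": self.n_candidates,
            "n_survivors": self.n_survivors,
            "rejections": dict(self.rejections),
            "surviving_orders": list(self.surviving_orders),
            "fit_rmsd": {str(k): v for k, v in self.fit_rmsd.items()},
        }


def initial_guess(query: CDSpectrum, rs: ReferenceSet) -> FractionVector:
    """Fractions of the reference protein whose spectrum is nearest the query.

    Nearest is minimal RMSD over the shared grid; ties go to the
    lower-index member.  The query must already be on the reference grid.
    """
    if len(rs) == 0:
        raise InvalidParameterError("empty reference set")
    if len(query) != rs.grid.size or not np.allclose(query.wavelengths, rs.grid):
        raise ConsistencyError("query must be resampled to the reference grid first")
    best_i, best_rmsd = 0, np.inf
    for i, p in enumerate(rs.proteins):
        rmsd = float(np.sqrt(np.mean((p.spectrum.values - query.values) ** 2)))
        if rmsd < best_rmsd - 1e-15:
            best_i, best_rmsd = i, rmsd
    return rs.proteins[best_i].fractions


def _analysis_grid(query: CDSpectrum, rs: ReferenceSet, config: SelconConfig) -> np.ndarray:
    lo = max(config.range_nm[0], query.span[0], rs.grid[0])
    hi = min(config.range_nm[1], query.span[1], rs.grid[-1])
    if hi - lo < 40.0 - 1e-9:
        raise InvalidParameterError(
            f"query and reference set overlap only [{lo:g}, {hi:g}] nm; >= 40 nm required"
        )
    mask = (rs.grid >= lo - 1e-9) & (rs.grid <= hi + 1e-9)
    return rs.grid[mask]


def _solve_orders(C: np.ndarray, F: np.ndarray, q: np.ndarray, k_max: int):
    """Candidate fraction solutions and fit RMSDs for truncation orders 1..k_max."""
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    rank = int(np.sum(s > _RANK_RTOL * s[0]))
    orders = range(1, min(k_max, rank) + 1)
    sols, fits = {}, {}
    for k in orders:
        Uk, sk, Vtk = U[:, :k], s[:k], Vt[:k]
        X = F @ Vtk.T @ np.diag(1.0 / sk) @ Uk.T     # classes × wavelengths
        sols[k] = X @ q
        recon = Uk @ (sk * Vtk[:, 0])                # rank-k reconstruction of query column
        fits[k] = float(np.sqrt(np.mean((recon - q) ** 2)))
    return sols, fits


def selcon_deconvolve(
    query: CDSpectrum, rs: ReferenceSet, config: SelconConfig | None = None
) -> tuple[FractionVector, SelconDiagnostics]:
    """Estimate six secondary-structure fractions from a query CD spectrum.

    Raises :class:`NoSolutionError` when the selection rules retain no
    candidate and :class:`NonConvergenceError` when the self-consistency
    loop does not settle within ``max_iter``.
    """
    config = config or SelconConfig()
    grid = _analysis_grid(query, rs, config)
    rs_grid = ReferenceSet(rs.proteins, grid)
    q_spec = resample_to_grid(query, grid)
    spectra, fractions = build_matrices(rs_grid)
    C_ref = spectra.to_numpy()
    F_ref = fractions.to_numpy()
    q = q_spec.values

    guess = initial_guess(q_spec, rs_grid).as_array()

    def select(sols, fits):
        """Apply the four selection rules; survivors and per-rule rejection counts."""
        k_top = max(sols)
        helix_ref = sols[k_top][0] + sols[k_top][1]
        rejections = {"sum": 0, "fraction": 0, "fit": 0, "helix": 0}
        survivors, orders = [], []
        for k, f in sols.items():
            total = float(f.sum())
            if not (1.0 - config.tol_sum <= total <= 1.0 + config.tol_sum):
                rejections["sum"] += 1
                continue
            if np.any(f < config.fraction_floor):
                rejections["fraction"] += 1
                continue
            if fits[k] > config.fit_max:
                rejections["fit"] += 1
                continue
            if abs((f[0] + f[1]) - helix_ref) > config.helix_tol:
                rejections["helix"] += 1
                continue
            survivors.append(f)
            orders.append(k)
        return survivors, orders, rejections

    # Self-consistency: the guess is replaced by the mean of the solutions
    # that pass the selection rules (falling back to the highest-order
    # solution when none passes), which anchors the feedback near sum 1.
    # A candidate order sitting exactly on a rule boundary can make the
    # survivor set alternate, giving a period-2 limit cycle instead of a
    # fixed point; the update is damped and a detected two-cycle is resolved
    # to its midpoint.
    def solve_at(g):
        C = np.column_stack([q, C_ref])
        F = np.column_stack([g, F_ref])
        return _solve_orders(C, F, q, config.k_max)

    converged = False
    iterations = 0
    history: list[np.ndarray] = []
    for iterations in range(1, config.max_iter + 1):
        sols, fits = solve_at(guess)
        survivors, _, _ = select(sols, fits)
        new_guess = np.mean(survivors, axis=0) if survivors else sols[max(sols)]
        if np.max(np.abs(new_guess - guess)) < config.tol_sc:
            guess = new_guess
            converged = True
            break
        if len(history) >= 2 and np.max(np.abs(new_guess - history[-2])) < config.tol_sc:
            guess = 0.5 * (new_guess + history[-1])
            converged = True
            break
        history.append(new_guess)
        guess = 0.5 * (guess + new_guess)
    if not converged:
        raise NonConvergenceError(
            f"self-consistency did not converge in {config.max_iter} iterations"
        )

    sols, fits = solve_at(guess)
    survivors, surviving_orders, rejections = select(sols, fits)

    diag = SelconDiagnostics(
        iterations=iterations,
        converged=converged,
        n_candidates=len(sols),
        n_survivors=len(survivors),
        rejections=rejections,
        surviving_orders=tuple(surviving_orders),
        fit_rmsd={k: round(v, 6) for k, v in fits.items()},
    )
    if not survivors:
        raise NoSolutionError(
            "no solution passed the selection rules "
            f"(rejections: {rejections})",
            diagnostics=diag,
        )
    mean_sol = np.mean(survivors, axis=0)
    final = FractionVector.from_raw(mean_sol)
    return final, diag


def total_contents(f: FractionVector) -> tuple[float, float, float]:
    """Collapse six classes to (helix, strand, other) totals.

    Helix = ordered + distorted helix; strand likewise; turns and unordered
    structures together form the "other" class.  The triple sums to 1.
    """
    helix = f.h_r + f.h_d
    strand = f.s_r + f.s_d
    other = f.turn + f.unordered
    return helix, strand, other
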