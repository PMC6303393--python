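"""Homogeneous fixed points and Turing (diffusion-driven) instability tests.

A homogeneous steady state (N*, L*) solves f = g = 0. With diffusion ratio
d = D_L / D_N, the steady state is Turing unstable -- stable to homogeneous
perturbations but unstable to a band of finite wavenumbers -- iff the four
classic inequalities hold at (N*, L*):

    (1) f_N + g_L < 0
    (2) f_N g_L - f_L g_N > 0
    (3) d f_N + g_L > 0
    (4) (d f_N + g_L)^2 - 4 d (f_N g_L - f_L g_N) > 0

Conditions (1)-(2) are stability without diffusion; (3)-(4) open the unstable
wavenumber band. With d = 1, (1) and (3) are contradictory, so equal
diffusivities can never satisfy the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelKind, ModelParameters
from .reactions import jacobian, reaction_terms

__all__ = [
    "FixedPoint",
    "TuringResult",
    "find_fixed_points",
    "turing_condition",
    "select_fixed_point",
    "turing_phase_diagram",
]

#: residual bound for an accepted root, in nM min^-1
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A root of f = g = 0 with its diffusion-free stability."""

    N_star: float
    L_star: float
    residual: float
    locally_stable_without_diffusion: bool


@dataclass(frozen=True)
class TuringResult:
    """The four instability inequalities evaluated at one fixed point."""

    cond1: bool  # f_N + g_L < 0
    cond2: bool  # f_N g_L - f_L g_N > 0
    cond3: bool  # d f_N + g_L > 0
    cond4: bool  # (d f_N + g_L)^2 - 4 d (f_N g_L - f_L g_N) > 0
    satisfied: bool
    d: float


def _stable_without_diffusion(N: float, L: float, p: ModelParameters, m: ModelKind) -> bool:
    f_N, f_L, g_N, g_L = jacobian(N, L, p, m)
    trace = f_N + g_L
    det = f_N * g_L - f_L * g_N
    return trace < 0.0 and det > 0.0


def _newton(N0: float, L0: float, p: ModelParameters, m: ModelKind,
            max_iter: int = 200, tol_sq: float = 1e-24) -> tuple[float, float] | None:
    """Damped 2D Newton iteration on (f, g); None on divergence."""
    N, L = N0, L0
    for _ in range(max_iter):
        try:
            f, g = reaction_terms(N, L, p, m)
        except ValueError:
            return None
        if f * f + g * g < tol_sq:
            return N, L
        f_N, f_L, g_N, g_L = jacobian(N, L, p, m)
        det = f_N * g_L - f_L * g_N
        if det == 0.0 or not np.isfinite(det):
            return None
        dN = (f * g_L - g * f_L) / det
        dL = (g * f_N - f * g_N) / det
        # keep iterates in the physical quadrant
        step = 1.0
        while step > 1e-6 and (N - step * dN < 0.0 or L - step * dL < 0.0):
            step *= 0.5
        N -= step * dN
        L -= step * dL
        if not (np.isfinite(N) and np.isfinite(L)):
            return None
    f, g = reaction_terms(N, L, p, m)
    if f * f + g * g < tol_sq:
        return N, L
    return None


def find_fixed_points(
    p: ModelParameters,
    m: ModelKind,
    n_seeds: int = 60,
    seed_range: tuple[float, float] = (1e-3, 1e3),
) -> list[FixedPoint]:
    """All distinct non-negative roots of f = g = 0, origin included.

    Roots are located by Newton iteration from log-spaced Nodal seeds
    (the Lefty seed follows the competitive steady-state ray
    L = alpha_L * gamma_N / (alpha_N * gamma_L) * N, which is a good guess
    for both models), deduplicated at relative tolerance 1e-6 and verified
    against the residual bound. Seeds whose iteration diverges are skipped.
    """
    points: list[FixedPoint] = [
        FixedPoint(0.0, 0.0, 0.0, _stable_without_diffusion(0.0, 0.0, p, m))
    ]
    if p.alpha_N == 0.0:
        return points
    ray = p.alpha_L * p.gamma_N / (p.alpha_N * p.gamma_L)
    roots: list[tuple[float, float]] = []
    for N0 in np.geomspace(seed_range[0], seed_range[1], n_seeds):
        res = _newton(N0, ray * N0, p, m)
        if res is None:
            continue
        N, L = res
        if N < 0 or L < 0:
            continue
        if max(N, L) < 1e-8:
            continue  # converged back to the origin, already included
        if any(
            abs(N - Nr) <= 1e-6 * max(abs(N), abs(Nr), 1e-300)
            and abs(L - Lr) <= 1e-6 * max(abs(L), abs(Lr), 1e-300)
            for Nr, Lr in roots
        ):
            continue
        roots.append((N, L))
    for N, L in sorted(roots):
        f, g = reaction_terms(N, L, p, m)
        residual = max(abs(f), abs(g))
        if residual >= RESIDUAL_TOL:
            continue
        points.append(FixedPoint(N, L, residual, _stable_without_diffusion(N, L, p, m)))
    return points


def turing_condition(fp: FixedPoint, p: ModelParameters, m: ModelKind) -> TuringResult:
    """Evaluate the four instability inequalities at a fixed point."""
    if fp.residual >= RESIDUAL_TOL:
        raise ValueError(f"not a converged fixed point (residual {fp.residual:g})")
    if p.D_N == 0.0:
        raise ValueError("D_N must be positive to form the diffusion ratio")
    f_N, f_L, g_N, g_L = jacobian(fp.N_star, fp.L_star, p, m)
    d = p.D_L / p.D_N
    trace = f_N + g_L
    det = f_N * g_L - f_L * g_N
    h = d * f_N + g_L
    cond1 = trace < 0.0
    cond2 = det > 0.0
    cond3 = h > 0.0
    cond4 = h * h - 4.0 * d * det > 0.0
    return TuringResult(cond1, cond2, cond3, cond4,
                        cond1 and cond2 and cond3 and cond4, d)


def select_fixed_point(points: list[FixedPoint]) -> FixedPoint | None:
    """The largest-N nontrivial fixed point that is stable without diffusion.

    The origin always exists but carries no pattern; the instability test is
    evaluated on the patterned (high-activity) branch.
    """
    candidates = [fp for fp in points
                  if fp.N_star > 0 and fp.locally_stable_without_diffusion]
    if not candidates:
        return None
    return max(candidates, key=lambda fp: fp.N_star)


def turing_phase_diagram(
    alpha_N_values,
    alpha_L_values,
    p: ModelParameters,
    m: ModelKind,
    any_fixed_point: bool = False,
) -> np.ndarray:
    """Boolean grid over (alpha_N, alpha_L): does the cell pass the test?

    A cell is True iff a nontrivial, diffusion-free-stable fixed point of the
    cell's parameter set satisfies all four inequalities. By default only the
    largest-N stable branch is tested; ``any_fixed_point=True`` accepts any
    nontrivial stable root instead.
    """
    alpha_N_values = np.asarray(alpha_N_values, dtype=float)
    alpha_L_values = np.asarray(alpha_L_values, dtype=float)
    grid = np.zeros((alpha_N_values.size, alpha_L_values.size), dtype=bool)
    for i, aN in enumerate(alpha_N_values):
        for j, aL in enumerate(alpha_L_values):
            pij = p.replace(alpha_N=float(aN), alpha_L=float(aL))
            pts = [fp for fp in find_fixed_points(pij, m)
                   if fp.N_star > 0 and fp.locally_stable_without_diffusion]
            if not any_fixed_point:
                sel = select_fixed_point(pts)
                pts = [sel] if sel is not None else []
            grid[i, j] = any(turing_condition(fp, pij, m).satisfied for fp in pts)
    return grid
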