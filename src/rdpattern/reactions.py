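"""Reaction terms and Jacobians of the two Nodal-Lefty models.

Both models share a single Hill-type activation term: Nodal activates
production of both species, and Lefty raises the effective dissociation
constant by competing for receptors,

    H(N, L) = N^n_N / ( N^n_N + [ K_N (1 + (L/K_L)^n_L) ]^n_N ).

Competitive inhibition model:

    f(N, L) = alpha_N * H - gamma_N * N
    g(N, L) = alpha_L * H - gamma_L * L

Competitive + direct inhibition model additionally removes both species by
Nodal-Lefty complex formation:

    f -= k_plus * N * L,   g -= k_plus * N * L.

The Hill exponents are non-integer (2.63, 1.09), so powers are computed via
exp/log on strictly positive arguments with the N = 0 and L = 0 boundary
handled as explicit branches; this keeps the origin (a fixed point of both
models) free of NaNs.
"""

from __future__ import annotations

import numpy as np

from .params import ModelKind, ModelParameters

__all__ = ["hill_activation", "reaction_terms", "jacobian"]


def _validate(N: np.ndarray, L: np.ndarray) -> None:
    if np.any(N < 0) or np.any(L < 0):
        raise ValueError("concentrations must be non-negative")
    if not (np.all(np.isfinite(N)) and np.all(np.isfinite(L))):
        raise ValueError("concentrations must be finite")


def _bracket(L: np.ndarray, p: ModelParameters) -> np.ndarray:
    """K_N * (1 + (L/K_L)^n_L), the Lefty-raised dissociation constant."""
    ratio = np.zeros_like(L)
    pos = L > 0
    ratio[pos] = np.exp(p.n_L * (np.log(L[pos]) - np.log(p.K_L)))
    return p.K_N * (1.0 + ratio)


def _as_flat_pair(N, L):
    """Broadcast, validate and flatten; returns (N, L, shape, scalar_flag)."""
    N = np.asarray(N, dtype=float)
    L = np.asarray(L, dtype=float)
    _validate(N, L)
    N, L = np.broadcast_arrays(N, L)
    shape = N.shape
    scalar = N.ndim == 0
    return N.ravel().copy(), L.ravel().copy(), shape, scalar


def _restore(arrs, shape, scalar):
    out = tuple(a.reshape(shape) for a in arrs)
    if scalar:
        out = tuple(float(a) for a in out)
    return out if len(out) > 1 else out[0]


def hill_activation(N, L, p: ModelParameters):
    """Fractional pathway activation H(N, L) in [0, 1].

    Strictly increasing in N (for N > 0) and strictly decreasing in L.
    Accepts scalars or arrays (broadcast); returns the same shape.
    """
    N, L, shape, scalar = _as_flat_pair(N, L)
    B = _bracket(L, p)
    H = np.zeros(N.shape)
    pos = N > 0
    # H = 1 / (1 + (B/N)^n_N), numerically robust for large N
    u = np.exp(p.n_N * (np.log(B[pos]) - np.log(N[pos])))
    H[pos] = 1.0 / (1.0 + u)
    return _restore((H,), shape, scalar)


def _hill_and_partials(N, L, p: ModelParameters):
    """H and its partial derivatives (dH/dN, dH/dL), vectorized."""
    B = _bracket(L, p)
    H = np.zeros(N.shape)
    dHdN = np.zeros(N.shape)
    dHdL = np.zeros(N.shape)

    pos = N > 0
    u = np.exp(p.n_N * (np.log(B[pos]) - np.log(N[pos])))  # (B/N)^n_N
    s = 1.0 / (1.0 + u)
    H[pos] = s
    dHdN[pos] = p.n_N * u * s * s / N[pos]

    # d(log B)/dL = n_L * (L/K_L)^n_L / (L * (1 + (L/K_L)^n_L))
    r = np.zeros(N.shape)
    lpos = L > 0
    r[lpos] = np.exp(p.n_L * (np.log(L[lpos]) - np.log(p.K_L)))
    dlogB = np.zeros(N.shape)
    dlogB[lpos] = p.n_L * r[lpos] / (L[lpos] * (1.0 + r[lpos]))
    if np.any(~lpos):
        if p.n_L > 1.0:
            pass  # derivative of (L/K_L)^n_L vanishes at L = 0
        elif p.n_L == 1.0:
            dlogB[~lpos] = 1.0 / p.K_L
        else:
            raise FloatingPointError("Hill derivative singular at L = 0 for n_L < 1")
    dHdL[pos] = -p.n_N * u * s * s * dlogB[pos]

    if np.any(~pos):
        if p.n_N > 1.0:
            pass  # dH/dN -> 0 as N -> 0+
        elif p.n_N == 1.0:
            dHdN[~pos] = 1.0 / B[~pos]
        else:
            raise FloatingPointError("Hill derivative singular at N = 0 for n_N < 1")
    return H, dHdN, dHdL


def reaction_terms(N, L, p: ModelParameters, m: ModelKind):
    """Net production rates (f, g) of Nodal and Lefty in nM min^-1."""
    N, L, shape, scalar = _as_flat_pair(N, L)
    H = np.asarray(hill_activation(N, L, p))
    f = p.alpha_N * H - p.gamma_N * N
    g = p.alpha_L * H - p.gamma_L * L
    if m is ModelKind.COMPETITIVE_PLUS_DIRECT:
        complexation = p.k_plus * N * L
        f = f - complexation
        g = g - complexation
    return _restore((f, g), shape, scalar)


def jacobian(N, L, p: ModelParameters, m: ModelKind):
    """Partial derivatives (f_N, f_L, g_N, g_L) at (N, L), in min^-1.

    Closed-form differentiation of the reaction terms; the boundary N = 0
    (or L = 0) is handled analytically and raises if the Hill exponent makes
    the derivative singular there (n < 1).
    """
    N, L, shape, scalar = _as_flat_pair(N, L)
    H, dHdN, dHdL = _hill_and_partials(N, L, p)
    f_N = p.alpha_N * dHdN - p.gamma_N
    f_L = p.alpha_N * dHdL
    g_N = p.alpha_L * dHdN
    g_L = p.alpha_L * dHdL - p.gamma_L
    if m is ModelKind.COMPETITIVE_PLUS_DIRECT:
        f_N = f_N - p.k_plus * L
        f_L = f_L - p.k_plus * N
        g_N = g_N - p.k_plus * L
        g_L = g_L - p.k_plus * N
    return _restore((f_N, f_L, g_N, g_L), shape, scalar)
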