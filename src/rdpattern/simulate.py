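"""Explicit-Euler integration of the Nodal-Lefty reaction-diffusion models.

The PDEs are solved on a regular grid (1D or 2D) with second-order central
finite differences for the Laplacian and forward-Euler time stepping,

    N <- N + dt * ( f(N, L) + D_N lap N ),
    L <- L + dt * ( g(N, L) + D_L lap L ).

The explicit scheme requires dt < dx^2 / (2 * ndim * max(D_N, D_L)); the
configuration refuses to integrate outside that bound. Concentrations are
clamped to zero after every step (the clamped magnitude is tracked and is
expected to stay at rounding level).

Outcome classification: a final Nodal field is a
"pattern" when max(N) > 2 * min(N) (and the maximum clears a 0.01 nM floor),
otherwise "high" or "low" depending on whether max(N) exceeds 0.01 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .params import ModelKind, ModelParameters

__all__ = [
    "SimulationConfig",
    "StateField",
    "SimulationResult",
    "PhaseDiagram",
    "laplacian",
    "make_initial_condition",
    "integrate",
    "classify_outcome",
    "phase_diagram",
    "default_alpha_grid",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Discretization of space and time for one run.

    ``domain_length`` is the side length per axis (um); the grid then has
    ``domain_length / dx`` points per axis. ``record_every`` (min) controls
    snapshot spacing; by default only the initial and final states are kept.
    """

    dimensionality: int = 1
    domain_length: float = 2000.0
    dx: float = 10.0
    dt: float = 0.4
    duration: float = 42000.0
    boundary: str = "no_flux"
    record_every: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        if self.dx <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("dx, dt and duration must be positive")
        if self.boundary not in ("no_flux", "periodic"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        n = self.domain_length / self.dx
        if abs(n - round(n)) > 1e-9 or round(n) < 8:
            raise ValueError("domain_length / dx must be an integer >= 8")

    @property
    def n_points(self) -> int:
        return int(round(self.domain_length / self.dx))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def stability_bound(self, p: ModelParameters) -> float:
        """Largest stable explicit-Euler dt for these parameters."""
        return self.dx**2 / (2.0 * self.dimensionality * max(p.D_N, p.D_L))

    def check_stability(self, p: ModelParameters) -> None:
        bound = self.stability_bound(p)
        if self.dt >= bound:
            raise ValueError(
                f"dt = {self.dt} violates the explicit-Euler stability bound "
                f"dx^2 / (2 * ndim * D_max) = {bound:.6g}"
            )


@dataclass
class StateField:
    """Gridded Nodal and Lefty concentration fields (nM) with spacing dx (um)."""

    N_field: np.ndarray
    L_field: np.ndarray
    dx: float

    def __post_init__(self) -> None:
        self.N_field = np.asarray(self.N_field, dtype=float)
        self.L_field = np.asarray(self.L_field, dtype=float)
        if self.N_field.shape != self.L_field.shape:
            raise ValueError("N and L fields must share a shape")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if not (np.all(np.isfinite(self.N_field)) and np.all(np.isfinite(self.L_field))):
            raise ValueError("fields must be finite")
        if np.any(self.N_field < 0) or np.any(self.L_field < 0):
            raise ValueError("fields must be non-negative")

    def copy(self) -> "StateField":
        return StateField(self.N_field.copy(), self.L_field.copy(), self.dx)


@dataclass
class SimulationResult:
    """Time-ordered snapshots plus the post-hoc outcome label."""

    snapshots: list[tuple[float, StateField]]
    outcome: str
    max_clamped: float = 0.0  # largest negative excursion zeroed per step (nM)

    @property
    def final(self) -> StateField:
        return self.snapshots[-1][1]

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.snapshots])


@dataclass
class PhaseDiagram:
    """Outcome labels over a (alpha_N, alpha_L) production-rate grid."""

    alpha_N_values: np.ndarray
    alpha_L_values: np.ndarray
    outcomes: np.ndarray  # dtype=object/str, shape (len(alpha_N), len(alpha_L))

    def pattern_mask(self) -> np.ndarray:
        return self.outcomes == "pattern"


def laplacian(field: np.ndarray, dx: float, boundary: str = "no_flux") -> np.ndarray:
    """Second-order central-difference Laplacian (per um^2), 1D or 2D.

    ``no_flux`` mirrors the edge value into the ghost cell (zero-gradient
    closure); ``periodic`` wraps around.
    """
    field = np.asarray(field, dtype=float)
    if dx <= 0:
        raise ValueError("dx must be positive")
    if field.ndim not in (1, 2) or min(field.shape) < 2:
        raise ValueError("field must be 1D or 2D with >= 2 points per axis")
    if boundary == "periodic":
        pad = lambda a, ax: np.concatenate(
            [a.take([-1], axis=ax), a, a.take([0], axis=ax)], axis=ax
        )
    elif boundary == "no_flux":
        pad = lambda a, ax: np.concatenate(
            [a.take([0], axis=ax), a, a.take([-1], axis=ax)], axis=ax
        )
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    out = np.zeros_like(field)
    for ax in range(field.ndim):
        g = pad(field, ax)
        sl = [slice(None)] * field.ndim
        lo, mid, hi = slice(0, -2), slice(1, -1), slice(2, None)
        sl_lo, sl_mid, sl_hi = list(sl), list(sl), list(sl)
        sl_lo[ax], sl_mid[ax], sl_hi[ax] = lo, mid, hi
        out += g[tuple(sl_lo)] - 2.0 * g[tuple(sl_mid)] + g[tuple(sl_hi)]
    return out / dx**2


def make_initial_condition(
    kind: str,
    config: SimulationConfig,
    amplitude: float = 20.0,
    pulse_width: float = 50.0,
    fraction: float = 0.1,
    seed: int | None = None,
    centers: tuple[float, ...] = (0.25, 0.75),
) -> StateField:
    """Construct the starting Nodal/Lefty fields.

    kinds
    -----
    ``two_pulses``
        Rectangular pulses of height ``amplitude`` in both species, centered
        at the given domain fractions (default 1/4 and 3/4; in 2D the pulses
        sit on the diagonal).
    ``uniform``
        Constant fields at ``amplitude``.
    ``random_noise``
        i.i.d. uniform values on [0, amplitude].
    ``mixed_fraction``
        A proportion ``fraction`` of grid sites (chosen at random) set to
        ``amplitude``, the rest zero -- emulating seeding a given ratio of
        reporter-positive cells.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = config.n_points
    shape = (n,) if config.dimensionality == 1 else (n, n)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if kind == "uniform":
        N = np.full(shape, float(amplitude))
        return StateField(N, N.copy(), config.dx)
    if kind == "random_noise":
        N = rng.uniform(0.0, amplitude, size=shape) if amplitude > 0 else np.zeros(shape)
        L = rng.uniform(0.0, amplitude, size=shape) if amplitude > 0 else np.zeros(shape)
        return StateField(N, L, config.dx)
    if kind == "mixed_fraction":
        n_sites = int(round(fraction * np.prod(shape)))
        flat = np.zeros(int(np.prod(shape)))
        idx = rng.choice(flat.size, size=n_sites, replace=False)
        flat[idx] = amplitude
        N = flat.reshape(shape)
        return StateField(N, N.copy(), config.dx)
    if kind == "two_pulses":
        if pulse_width < config.dx:
            raise ValueError("pulse_width must be at least one grid spacing")
        w = int(round(pulse_width / config.dx))
        N = np.zeros(shape)
        for c in centers:
            ci = int(round(c * n))
            start = max(0, min(n - w, ci - w // 2))
            if config.dimensionality == 1:
                N[start : start + w] = amplitude
            else:
                N[start : start + w, start : start + w] = amplitude
        return StateField(N, N.copy(), config.dx)
    raise ValueError(f"unknown initial-condition kind {kind!r}")


@njit(cache=True)
def _euler_1d(N, L, aN, aL, nN, nL, KN, KL, gamN, gamL, DN, DL, kp,
              dt, inv_dx2, n_steps, periodic):  # pragma: no cover - jitted
    nx = N.shape[0]
    Nn = np.empty(nx)
    Ln = np.empty(nx)
    max_clamp = 0.0
    for _ in range(n_steps):
        for i in range(nx):
            if periodic:
                im = nx - 1 if i == 0 else i - 1
                ip = 0 if i == nx - 1 else i + 1
            else:
                im = 0 if i == 0 else i - 1
                ip = nx - 1 if i == nx - 1 else i + 1
            Ni = N[i]
            Li = L[i]
            lapN = (N[im] - 2.0 * Ni + N[ip]) * inv_dx2
            lapL = (L[im] - 2.0 * Li + L[ip]) * inv_dx2
            if Ni > 0.0:
                B = KN * (1.0 + (Li / KL) ** nL)
                H = 1.0 / (1.0 + (B / Ni) ** nN)
            else:
                H = 0.0
            complexation = kp * Ni * Li
            nv = Ni + dt * (aN * H - gamN * Ni - complexation + DN * lapN)
            lv = Li + dt * (aL * H - gamL * Li - complexation + DL * lapL)
            if nv < 0.0:
                if -nv > max_clamp:
                    max_clamp = -nv
                nv = 0.0
            if lv < 0.0:
                if -lv > max_clamp:
                    max_clamp = -lv
                lv = 0.0
            Nn[i] = nv
            Ln[i] = lv
        N, Nn = Nn, N
        L, Ln = Ln, L
    return N, L, max_clamp


@njit(cache=True)
def _euler_2d(N, L, aN, aL, nN, nL, KN, KL, gamN, gamL, DN, DL, kp,
              dt, inv_dx2, n_steps, periodic):  # pragma: no cover - jitted
    ny, nx = N.shape
    Nn = np.empty((ny, nx))
    Ln = np.empty((ny, nx))
    max_clamp = 0.0
    for _ in range(n_steps):
        for j in range(ny):
            if periodic:
                jm = ny - 1 if j == 0 else j - 1
                jp = 0 if j == ny - 1 else j + 1
            else:
                jm = 0 if j == 0 else j - 1
                jp = ny - 1 if j == ny - 1 else j + 1
            for i in range(nx):
                if periodic:
                    im = nx - 1 if i == 0 else i - 1
                    ip = 0 if i == nx - 1 else i + 1
                else:
                    im = 0 if i == 0 else i - 1
                    ip = nx - 1 if i == nx - 1 else i + 1
                Ni = N[j, i]
                Li = L[j, i]
                lapN = (N[j, im] + N[j, ip] + N[jm, i] + N[jp, i] - 4.0 * Ni) * inv_dx2
                lapL = (L[j, im] + L[j, ip] + L[jm, i] + L[jp, i] - 4.0 * Li) * inv_dx2
                if Ni > 0.0:
                    B = KN * (1.0 + (Li / KL) ** nL)
                    H = 1.0 / (1.0 + (B / Ni) ** nN)
                else:
                    H = 0.0
                complexation = kp * Ni * Li
                nv = Ni + dt * (aN * H - gamN * Ni - complexation + DN * lapN)
                lv = Li + dt * (aL * H - gamL * Li - complexation + DL * lapL)
                if nv < 0.0:
                    if -nv > max_clamp:
                        max_clamp = -nv
                    nv = 0.0
                if lv < 0.0:
                    if -lv > max_clamp:
                        max_clamp = -lv
                    lv = 0.0
                Nn[j, i] = nv
                Ln[j, i] = lv
        N, Nn = Nn, N
        L, Ln = Ln, L
    return N, L, max_clamp


def integrate(
    initial: StateField,
    p: ModelParameters,
    m: ModelKind,
    config: SimulationConfig,
) -> SimulationResult:
    """Forward-Euler integration from ``initial`` for ``config.duration`` min."""
    config.check_stability(p)
    expected = (config.n_points,) if config.dimensionality == 1 else (config.n_points,) * 2
    if initial.N_field.shape != expected:
        raise ValueError(
            f"initial field shape {initial.N_field.shape} does not match config grid {expected}"
        )
    kp = p.k_plus if m is ModelKind.COMPETITIVE_PLUS_DIRECT else 0.0
    kernel = _euler_1d if config.dimensionality == 1 else _euler_2d
    periodic = config.boundary == "periodic"
    inv_dx2 = 1.0 / config.dx**2

    record_every = config.record_every or config.duration
    steps_per_chunk = max(1, int(round(record_every / config.dt)))
    n_steps = config.n_steps

    # private working copies: the kernel's buffer swap writes into its input
    # arrays, and the caller's initial state must never be mutated
    N = np.array(initial.N_field, dtype=float, order="C", copy=True)
    L = np.array(initial.L_field, dtype=float, order="C", copy=True)
    snapshots: list[tuple[float, StateField]] = [(0.0, initial.copy())]
    max_clamp = 0.0
    done = 0
    while done < n_steps:
        chunk = min(steps_per_chunk, n_steps - done)
        N, L, clamp = kernel(
            N, L, p.alpha_N, p.alpha_L, p.n_N, p.n_L, p.K_N, p.K_L,
            p.gamma_N, p.gamma_L, p.D_N, p.D_L, kp,
            config.dt, inv_dx2, chunk, periodic,
        )
        done += chunk
        max_clamp = max(max_clamp, clamp)
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(L))):
            bad = np.argwhere(~(np.isfinite(N) & np.isfinite(L)))
            raise FloatingPointError(
                f"non-finite concentration at step {done} (first bad site {bad[0]})"
            )
        snapshots.append((done * config.dt, StateField(N.copy(), L.copy(), config.dx)))
    outcome = classify_outcome(snapshots[-1][1])
    return SimulationResult(snapshots, outcome, max_clamp)


def classify_outcome(
    final: StateField, p_threshold: float = 0.01, ratio: float = 2.0
) -> str:
    """Label a final Nodal field as ``pattern``, ``high`` or ``low``.

    ``pattern`` iff max(N) > ratio * min(N) and max(N) > p_threshold;
    otherwise ``high`` iff max(N) > p_threshold, else ``low``.
    """
    nmax = float(final.N_field.max())
    nmin = float(final.N_field.min())
    if nmax > ratio * nmin and nmax > p_threshold:
        return "pattern"
    return "high" if nmax > p_threshold else "low"


def default_alpha_grid(n: int = 17, lo: float = 0.25, hi: float = 8.0) -> np.ndarray:
    """Log-spaced production-rate scan values (nM min^-1)."""
    return np.geomspace(lo, hi, n)


def phase_diagram(
    alpha_N_values,
    alpha_L_values,
    p: ModelParameters,
    m: ModelKind,
    config: SimulationConfig,
    initial: StateField | None = None,
) -> PhaseDiagram:
    """Scan (alpha_N, alpha_L), integrating from the two-pulse initial state.

    Each cell runs a fresh simulation and classifies the final snapshot.
    """
    alpha_N_values = np.asarray(alpha_N_values, dtype=float)
    alpha_L_values = np.asarray(alpha_L_values, dtype=float)
    if alpha_N_values.size == 0 or alpha_L_values.size == 0:
        raise ValueError("alpha value lists must be non-empty")
    if initial is None:
        initial = make_initial_condition("two_pulses", config)
    cfg = replace(config, record_every=None)
    outcomes = np.empty((alpha_N_values.size, alpha_L_values.size), dtype=object)
    for i, aN in enumerate(alpha_N_values):
        for j, aL in enumerate(alpha_L_values):
            pij = p.replace(alpha_N=float(aN), alpha_L=float(aL))
            try:
                res = integrate(initial.copy(), pij, m, cfg)
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"cell (alpha_N={aN:g}, alpha_L={aL:g}): {err}"
                ) from err
            outcomes[i, j] = res.outcome
    return PhaseDiagram(alpha_N_values, alpha_L_values, outcomes)
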