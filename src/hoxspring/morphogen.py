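"""Macroscale morphogen gradient along the anterior–posterior embryonic axis.

A morphogen (FGF-like) is secreted from a posterior source and spreads by
passive diffusion combined with first-order degradation,

    dC/dt = D d2C/dx2 - k_deg * C,

which at steady state yields the exponential gradient

    C(x) = C0 * exp(-|x - x_src| / lambda),     lambda = sqrt(D / k_deg).

The axis runs from x = 0 (anterior) to x = L (posterior); by default the
source sits at the posterior pole, so posterior cells see high concentration.
An ordered ladder of concentration thresholds T1 < T2 < ... < Tm carves the
axis into nested expression domains S1 ⊇ S2 ⊇ ... ⊇ Sm, and the number of
thresholds a cell's concentration exceeds defines its quantized positional
factor P — the macroscale input to the pulling force F = P × N.

Units: axis lengths in mm, time in arbitrary developmental units (the decay
rate k_deg sets the clock), concentrations in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .errors import ConfigurationError, InputError, ParameterError

__all__ = [
    "MorphogenParams",
    "MorphogenField",
    "ThresholdSet",
    "ExpressionWindow",
    "Domain",
    "DomainSet",
    "GridSpec",
    "default_morphogen_params",
    "steady_state_concentration",
    "steady_state_profile",
    "transient_profile",
    "transient_snapshots",
    "implant_bead",
    "expression_domains",
    "window_domain",
    "p_factor",
    "p_factor_profile",
]

# Defaults shared across the package: a 1 mm axis with decay length L/6 so the
# gradient spans the whole axis while staying numerically resolvable.
DEFAULT_AXIS_LENGTH = 1.0          # mm
DEFAULT_DECAY_RATE = 0.1           # 1 / time unit
DEFAULT_LENGTH_SCALE = DEFAULT_AXIS_LENGTH / 6.0
DEFAULT_DIFFUSION = DEFAULT_DECAY_RATE * DEFAULT_LENGTH_SCALE**2
DEFAULT_AMPLITUDE = 1.0
DEFAULT_N_NODES = 401


@dataclass(frozen=True)
class MorphogenParams:
    """Physical parameters of the 1D diffusion–decay gradient.

    ``extra_sources`` holds (position, amplitude) pairs for implanted beads;
    the resulting profile is the superposition of all source kernels.
    """

    diffusion_coeff: float = DEFAULT_DIFFUSION      # mm^2 / time
    decay_rate: float = DEFAULT_DECAY_RATE          # 1 / time
    source_amplitude: float = DEFAULT_AMPLITUDE     # conc. units
    axis_length: float = DEFAULT_AXIS_LENGTH        # mm
    source_position: float = DEFAULT_AXIS_LENGTH    # mm (posterior pole)
    extra_sources: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.diffusion_coeff <= 0:
            raise ParameterError(
                f"diffusion_coeff must be > 0 (got {self.diffusion_coeff})")
        if self.decay_rate <= 0:
            raise ParameterError(
                f"decay_rate must be > 0 (got {self.decay_rate})")
        if self.source_amplitude < 0:
            raise ParameterError(
                f"source_amplitude must be >= 0 (got {self.source_amplitude})")
        if self.axis_length <= 0:
            raise ParameterError(
                f"axis_length must be > 0 (got {self.axis_length})")
        if not 0 <= self.source_position <= self.axis_length:
            raise ParameterError(
                f"source_position must lie in [0, {self.axis_length}] "
                f"(got {self.source_position})")
        for pos, amp in self.extra_sources:
            if not 0 <= pos <= self.axis_length:
                raise ParameterError(
                    f"extra source position {pos} outside [0, {self.axis_length}]")
            if amp < 0:
                raise ParameterError(
                    f"extra source amplitude must be >= 0 (got {amp})")

    @property
    def length_scale(self) -> float:
        """Gradient decay length lambda = sqrt(D / k_deg) in mm."""
        return math.sqrt(self.diffusion_coeff / self.decay_rate)

    def sources(self) -> tuple[tuple[float, float], ...]:
        """All (position, amplitude) sources, primary first."""
        return ((self.source_position, self.source_amplitude),
                *self.extra_sources)


def default_morphogen_params() -> MorphogenParams:
    return MorphogenParams()


@dataclass(frozen=True)
class MorphogenField:
    """Concentration profile C(x) sampled on an ordered axis grid at time t."""

    grid: np.ndarray            # mm, ascending, 0 = anterior
    concentrations: np.ndarray  # conc. units, >= 0
    time: float                 # time units; math.inf marks steady state

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "concentrations", conc)
        if grid.ndim != 1 or conc.shape != grid.shape:
            raise InputError("grid and concentrations must be matching 1D arrays")
        if grid.size == 0:
            raise InputError("empty grid")
        if np.any(np.diff(grid) <= 0):
            raise InputError("grid must be strictly increasing")
        if np.any(conc < 0):
            raise InputError("concentrations must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.grid, "t": self.time, "concentration": self.concentrations})


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing concentration thresholds, one per gene rank."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(v <= 0 for v in vals):
            raise ParameterError("thresholds must be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ParameterError(
                f"thresholds must be strictly increasing (got {vals})")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def default_for(cls, params: MorphogenParams, n_genes: int = 9) -> "ThresholdSet":
        """Thresholds placing steady-state anterior boundaries evenly on the axis.

        Threshold j is the steady-state concentration at distance
        d_j = (n+1-j)/(n+1) * L from the source, so gene rank j's domain ends
        at axis fraction j/(n+1) from the posterior pole outward.
        """
        if n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        lam = params.length_scale
        L = params.axis_length
        c0 = params.source_amplitude
        if c0 <= 0:
            raise ParameterError("cannot derive thresholds from a zero source")
        dists = [(n_genes + 1 - j) / (n_genes + 1) * L for j in range(1, n_genes + 1)]
        return cls(tuple(c0 * math.exp(-d / lam) for d in dists))


@dataclass(frozen=True)
class ExpressionWindow:
    """Band-pass expression rule: allowed for lower <= C <= upper."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ParameterError(
                f"window requires 0 < lower < upper (got {self.lower}, {self.upper})")


@dataclass(frozen=True)
class Domain:
    """A set of axis positions, stored as a boolean mask over the grid."""

    grid: np.ndarray
    mask: np.ndarray

    def positions(self) -> np.ndarray:
        return self.grid[self.mask]

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    def anterior_boundary(self) -> float:
        """Smallest (most anterior) member position; nan if empty."""
        pos = self.positions()
        return float(pos[0]) if pos.size else math.nan


@dataclass(frozen=True)
class DomainSet:
    """Nested expression domains S1 ⊇ S2 ⊇ ... ⊇ Sm, one per threshold."""

    grid: np.ndarray
    masks: np.ndarray  # (m, n_nodes) boolean

    def __len__(self) -> int:
        return int(self.masks.shape[0])

    def domain(self, j: int) -> Domain:
        """1-based domain S_j."""
        if not 1 <= j <= len(self):
            raise InputError(f"domain index {j} outside 1..{len(self)}")
        return Domain(self.grid, self.masks[j - 1])

    def is_nested(self) -> bool:
        return all(
            bool(np.all(self.masks[j + 1] <= self.masks[j]))
            for j in range(len(self) - 1))


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def steady_state_concentration(params: MorphogenParams, x) -> np.ndarray:
    """Closed-form steady-state concentration at position(s) ``x``.

    Superposition of exponential kernels C_s * exp(-|x - x_s| / lambda) over
    all sources, evaluated on the axis.
    """
    x = np.asarray(x, dtype=float)
    lam = params.length_scale
    out = np.zeros_like(x)
    for pos, amp in params.sources():
        out = out + amp * np.exp(-np.abs(x - pos) / lam)
    return out


def steady_state_profile(
    params: MorphogenParams, n_nodes: int = DEFAULT_N_NODES
) -> MorphogenField:
    """Steady-state gradient on a uniform axis grid (time = inf)."""
    if n_nodes < 2:
        raise ConfigurationError(f"n_nodes must be >= 2 (got {n_nodes})")
    grid = np.linspace(0.0, params.axis_length, n_nodes)
    return MorphogenField(grid, steady_state_concentration(params, grid), math.inf)


# ---------------------------------------------------------------------------
# Transient dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Space-time discretization for the transient solver.

    ``dt`` defaults to 0.25 * dx^2 / D. The backward-Euler scheme is
    unconditionally stable; the dt guard below rejects steps so coarse that
    the discrete transient would be meaningless.
    """

    n_nodes: int = DEFAULT_N_NODES
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ConfigurationError(
                f"n_nodes must be >= 3 for the transient solver (got {self.n_nodes})")
        if self.dt is not None and self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0 (got {self.dt})")

    def resolve_dt(self, params: MorphogenParams) -> float:
        dx = params.axis_length / (self.n_nodes - 1)
        dt = self.dt if self.dt is not None else 0.25 * dx**2 / params.diffusion_coeff
        if dt * params.decay_rate > 2.0:
            raise ConfigurationError(
                f"timestep dt={dt:g} too coarse for decay rate "
                f"{params.decay_rate:g}: require dt * k_deg <= 2 "
                f"(got {dt * params.decay_rate:g}); refine dt or the grid")
        return dt


def _single_source_snapshots(
    params: MorphogenParams,
    src_pos: float,
    amplitude: float,
    times: np.ndarray,
    grid: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Backward-Euler integration of one clamped source from C(x,0) = 0.

    The source node is held at its amplitude (Dirichlet); non-source boundary
    nodes carry a second-order Robin open-boundary condition dC/dx = ±C/lambda
    matching the decaying exponential, so the discrete steady state equals the
    closed-form profile.
    """
    n = grid.size
    dx = grid[1] - grid[0]
    D = params.diffusion_coeff
    k = params.decay_rate
    lam = params.length_scale
    alpha = D / dx**2
    src = int(np.argmin(np.abs(grid - src_pos)))

    main = np.full(n, 1.0 / dt + k + 2.0 * alpha)
    lower = np.full(n - 1, -alpha)   # A[i, i-1]
    upper = np.full(n - 1, -alpha)   # A[i, i+1]
    # Robin rows via ghost-node elimination (skipped if the end is the source)
    robin_diag = 1.0 / dt + k + 2.0 * alpha * (1.0 + dx / lam)
    if src != 0:
        main[0] = robin_diag
        upper[0] = -2.0 * alpha
    if src != n - 1:
        main[n - 1] = robin_diag
        lower[n - 2] = -2.0 * alpha
    # Dirichlet clamp at the source node
    main[src] = 1.0
    if src > 0:
        lower[src - 1] = 0.0
    if src < n - 1:
        upper[src] = 0.0

    rows = np.concatenate([np.arange(n), np.arange(1, n), np.arange(n - 1)])
    cols = np.concatenate([np.arange(n), np.arange(n - 1), np.arange(1, n)])
    vals = np.concatenate([main, lower, upper])
    lu = splu(csc_matrix((vals, (rows, cols)), shape=(n, n)))

    steps = np.rint(times / dt).astype(int)
    out = np.zeros((times.size, n))
    c = np.zeros(n)
    inv_dt = 1.0 / dt
    next_snap = 0
    # emit any t ≈ 0 snapshots (zero field)
    while next_snap < steps.size and steps[next_snap] == 0:
        next_snap += 1
    for step in range(1, int(steps.max(initial=0)) + 1):
        rhs = c * inv_dt
        rhs[src] = amplitude
        c = lu.solve(rhs)
        while next_snap < steps.size and steps[next_snap] == step:
            out[next_snap] = c
            next_snap += 1
    return out


def transient_snapshots(
    params: MorphogenParams,
    times,
    grid_spec: GridSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the diffusion–decay PDE and sample it at the given times.

    Returns ``(grid, C)`` with ``C`` of shape (len(times), n_nodes). Times are
    rounded to the nearest integration step. Multiple sources are superposed
    (each clamped in its own linear solve), so the t → ∞ limit matches the
    closed-form superposed steady state.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ParameterError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise InputError("times must be sorted ascending")
    spec = grid_spec or GridSpec()
    dt = spec.resolve_dt(params)
    grid = np.linspace(0.0, params.axis_length, spec.n_nodes)
    total = np.zeros((times.size, spec.n_nodes))
    for pos, amp in params.sources():
        if amp == 0:
            continue
        total += _single_source_snapshots(params, pos, amp, times, grid, dt)
    return grid, total


def transient_profile(
    params: MorphogenParams, t: float, grid_spec: GridSpec | None = None
) -> MorphogenField:
    """Numerical C(x, t) starting from C(x, 0) = 0 with clamped source(s)."""
    grid, snaps = transient_snapshots(params, [t], grid_spec)
    return MorphogenField(grid, np.clip(snaps[0], 0.0, None), float(t))


# ---------------------------------------------------------------------------
# Bead implantation
# ---------------------------------------------------------------------------

def implant_bead(
    params: MorphogenParams, position: float, amplitude: float
) -> MorphogenParams:
    """Add a morphogen-soaked bead (an extra clamped source) at ``position``."""
    if not 0 <= position <= params.axis_length:
        raise ParameterError(
            f"bead position {position} outside [0, {params.axis_length}]")
    if amplitude < 0:
        raise ParameterError(f"bead amplitude must be >= 0 (got {amplitude})")
    return replace(params, extra_sources=params.extra_sources + ((position, amplitude),))


# ---------------------------------------------------------------------------
# Threshold readout
# ---------------------------------------------------------------------------

def expression_domains(field: MorphogenField, thresholds: ThresholdSet) -> DomainSet:
    """Domains S_j = {x : C(x) >= T_j}; nesting follows from T monotonicity."""
    if field.grid.size == 0:
        raise InputError("empty grid")
    conc = field.concentrations
    masks = conc[None, :] >= thresholds.as_array()[:, None]
    return DomainSet(field.grid, masks)


def window_domain(field: MorphogenField, window: ExpressionWindow) -> Domain:
    """Band-pass domain {x : lower <= C(x) <= upper}.

    With a bead implanted at the tip of an intact axis the tip concentration
    can exceed ``upper``, excluding the tip neighborhood from the domain.
    """
    conc = field.concentrations
    return Domain(field.grid, (conc >= window.lower) & (conc <= window.upper))


def p_factor_profile(field: MorphogenField, thresholds: ThresholdSet) -> np.ndarray:
    """Integer P at every grid node: the count of thresholds satisfied."""
    return np.searchsorted(
        thresholds.as_array(), field.concentrations, side="right"
    ).astype(int)


def p_factor(field: MorphogenField, thresholds: ThresholdSet, x: float) -> int:
    """Quantized positional factor P = #{j : C(x) >= T_j} at the node nearest x."""
    idx = int(np.argmin(np.abs(field.grid - x)))
    return int(p_factor_profile(field, thresholds)[idx])
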