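"""Space-time in-silico experiments on wild-type and edited HoxD clusters.

For every cell position x and time t the pipeline composes the two scales:

    C(x, t)  →  P(x, t)  →  F = P × N  →  spring response  →  extrusion,

identifying "expression" of a gene with its extrusion into the transcription
factory regime. From the resulting expression map it derives per-gene onset
times, anterior expression boundaries, and geometry traces, and classifies
mutant phenotypes against the wild type:

- posterior deletions → retarded posteriorization (later onset, boundary
  shifted posteriorly);
- anterior deletions → premature anteriorization (earlier onset, boundary
  shifted anteriorly); the analogue rule holds for duplications.

The module also packages the Kondo–Duboule deletion suite: Del I (Hoxd11–13
deleted), Del II (Del I plus the centromeric Evx2 flank), and Del III (flank
only), whose predicted phenotypes are Del II premature, Del I retarded, and
Del III premature with strictly reduced elongation at every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import (
    DEFAULT_PROBES,
    EditSpec,
    HoxCluster,
    apply_edit,
    n_factor,
    wild_type_cluster,
)
from .errors import ConfigurationError, InputError, ParameterError
from .mechanics import SpringParams, force, spring_response
from .morphogen import (
    GridSpec,
    MorphogenParams,
    ThresholdSet,
    default_morphogen_params,
    transient_snapshots,
)

__all__ = [
    "Scenario",
    "ExperimentResult",
    "PhenotypeComparison",
    "KondoDubouleSuite",
    "default_time_grid",
    "default_scenario",
    "required_p_factor",
    "run_scenario",
    "compare_to_wildtype",
    "kondo_duboule_suite",
    "kondo_duboule_edits",
    "scale_gap_orders",
    "RETARDED",
    "PREMATURE",
    "UNCHANGED",
]

RETARDED = "retarded_posteriorization"
PREMATURE = "premature_anteriorization"
UNCHANGED = "unchanged"

# Fraction of the axis by which the comparison cell sits posterior to the
# anterior-most boundary among the compared scenarios (keeps the readout off
# the exact domain edge, where crossing times diverge).
BOUNDARY_MARGIN_FRACTION = 0.05


def default_time_grid(decay_rate: float = 0.1, n: int = 64) -> tuple[float, ...]:
    """t = 0 plus log-spaced times up to the equilibration horizon 10/k_deg.

    Log spacing resolves the geometric ladder of threshold-crossing times near
    the source; the horizon is where the transient has converged to the
    steady-state gradient.
    """
    t_max = 10.0 / decay_rate
    ts = np.geomspace(t_max / 2000.0, t_max, n)
    return (0.0, *map(float, ts))


@dataclass(frozen=True)
class Scenario:
    """Declarative description of one in-silico experiment."""

    morphogen: MorphogenParams = field(default_factory=default_morphogen_params)
    thresholds: ThresholdSet | None = None
    spring: SpringParams = field(default_factory=SpringParams)
    edit: EditSpec | None = None
    times: tuple[float, ...] | None = None
    n_nodes: int = 201
    dt: float | None = None
    probes: tuple[str, ...] = DEFAULT_PROBES
    p_mode: str = "integer"          # "integer" (default) or "continuous"
    geometry_position: float | None = None   # default 0.95 * axis length
    charge: float = 1.0
    rescale_rest_length: bool = True
    noise_sd: float = 0.0            # nm, geometry readout only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_mode not in ("integer", "continuous"):
            raise ConfigurationError(
                f"p_mode must be integer|continuous (got {self.p_mode!r})")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0 (got {self.noise_sd})")
        if self.times is not None:
            ts = tuple(float(t) for t in self.times)
            object.__setattr__(self, "times", ts)
            if any(t < 0 for t in ts) or any(
                    b <= a for a, b in zip(ts, ts[1:])):
                raise ConfigurationError(
                    "times must be non-negative and strictly increasing")

    def resolved_thresholds(self) -> ThresholdSet:
        if self.thresholds is not None:
            return self.thresholds
        return ThresholdSet.default_for(self.morphogen, n_genes=9)

    def resolved_times(self) -> np.ndarray:
        ts = self.times
        if ts is None:
            ts = default_time_grid(self.morphogen.decay_rate)
        return np.asarray(ts, dtype=float)

    def resolved_geometry_position(self) -> float:
        if self.geometry_position is not None:
            return self.geometry_position
        return 0.95 * self.morphogen.axis_length

    def build_cluster(self) -> HoxCluster:
        cl = wild_type_cluster(charge=self.charge)
        if self.edit is not None:
            cl = apply_edit(cl, self.edit,
                            rescale_rest_length=self.rescale_rest_length)
        return cl


def default_scenario(**overrides) -> Scenario:
    return replace(Scenario(), **overrides) if overrides else Scenario()


def required_p_factor(
    cluster: HoxCluster,
    spring: SpringParams,
    gene: str,
    quantized: bool = True,
) -> float:
    """Smallest P at which ``gene`` is extruded, from the extrusion inequality.

    Rank i needs F + sigma*d >= tau*i with F = P*N; for an unanchored cluster
    the slide amplifies the drive by g = 1 + sigma*phi/k_slide, so
    P* = tau*i / (g*N). Quantized mode returns the integer ceiling (the first
    quantized P level that satisfies it).
    """
    rank = cluster.rank(gene)
    gain = 1.0 if cluster.anchored else spring.drive_gain
    p_star = spring.extrusion_slope * rank / (gain * n_factor(cluster))
    if quantized:
        return float(math.ceil(p_star - 1e-9))
    return p_star


@dataclass(frozen=True)
class ExperimentResult:
    """Full space-time record of one scenario run."""

    scenario: Scenario
    cluster: HoxCluster
    grid: np.ndarray                 # axis positions, mm
    times: np.ndarray                # time grid
    p_map: np.ndarray                # (T, X) positional factor
    expressed: np.ndarray            # (genes, T, X) boolean extrusion map
    onset: np.ndarray                # (genes, X) first expression time, inf if never
    boundaries: np.ndarray           # (genes, T) anterior boundary, inf if absent
    required_p: dict[str, float]
    geometry: pd.DataFrame           # per-time trace at the geometry cell

    @property
    def genes(self) -> tuple[str, ...]:
        return self.cluster.names

    def _gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise InputError(
                f"gene {gene!r} absent from result (has {self.genes})") from None

    def _node_index(self, x: float) -> int:
        return int(np.argmin(np.abs(self.grid - x)))

    def onset_at(self, gene: str, x: float) -> float:
        """First time ``gene`` is expressed at the node nearest x (inf if never)."""
        return float(self.onset[self._gene_index(gene), self._node_index(x)])

    def expressed_by(self, gene: str, t_ref: float, x: float) -> bool:
        """Staging predicate: is ``gene`` expressed at ``x`` by time ``t_ref``?

        Maps embryo stages (e.g. E8) onto the simulation clock through a
        user-chosen reference time; no absolute developmental clock is
        imposed by the model.
        """
        return self.onset_at(gene, x) <= t_ref

    def final_boundary(self, gene: str) -> float:
        """Anterior expression boundary at the last recorded time (inf if absent)."""
        return float(self.boundaries[self._gene_index(gene), -1])

    def expression_table(self) -> pd.DataFrame:
        """Tidy expression map (gene, x, t, expressed)."""
        g, t, x = np.meshgrid(
            np.arange(len(self.genes)), self.times, self.grid, indexing="ij")
        return pd.DataFrame(
            {
                "gene": np.asarray(self.genes)[g.ravel()],
                "x": x.ravel(),
                "t": t.ravel(),
                "expressed": self.expressed.ravel().astype(int),
            }
        )

    def onset_table(self) -> pd.DataFrame:
        g, x = np.meshgrid(np.arange(len(self.genes)), self.grid, indexing="ij")
        onset = self.onset.ravel()
        return pd.DataFrame(
            {
                "gene": np.asarray(self.genes)[g.ravel()],
                "x": x.ravel(),
                "onset": np.where(np.isfinite(onset), onset, np.nan),
            }
        )

    def boundary_table(self) -> pd.DataFrame:
        g, t = np.meshgrid(np.arange(len(self.genes)), self.times, indexing="ij")
        b = self.boundaries.ravel()
        return pd.DataFrame(
            {
                "gene": np.asarray(self.genes)[g.ravel()],
                "t": t.ravel(),
                "anterior_boundary": np.where(np.isfinite(b), b, np.nan),
            }
        )


def _p_map(scenario: Scenario, conc: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    thr = thresholds.as_array()
    if scenario.p_mode == "integer":
        return np.searchsorted(thr, conc, side="right").astype(float)
    m = len(thr)
    return np.clip(m * conc / thr[-1], 0.0, float(m))


def run_scenario(
    scenario: Scenario,
    _snapshots: tuple[np.ndarray, np.ndarray] | None = None,
) -> ExperimentResult:
    """Execute the C → P → N → F → spring → extrusion pipeline on the grids.

    ``_snapshots`` lets suite drivers share one morphogen solve between
    scenarios that differ only in their cluster edit.
    """
    cluster = scenario.build_cluster()
    for probe in scenario.probes:
        if probe not in cluster.names:
            raise ConfigurationError(
                f"probe {probe!r} absent from the edited cluster {cluster.names}")

    times = scenario.resolved_times()
    thresholds = scenario.resolved_thresholds()
    if _snapshots is not None:
        grid, conc = _snapshots
        if conc.shape != (times.size, grid.size):
            raise ConfigurationError("precomputed snapshots do not match the grids")
    else:
        grid, conc = transient_snapshots(
            scenario.morphogen, times,
            GridSpec(n_nodes=scenario.n_nodes, dt=scenario.dt))

    p_map = _p_map(scenario, conc, thresholds)

    quantized = scenario.p_mode == "integer"
    required = {
        name: required_p_factor(cluster, scenario.spring, name, quantized=quantized)
        for name in cluster.names
    }
    req = np.array([required[n] for n in cluster.names])
    expressed = p_map[None, :, :] >= req[:, None, None]

    # onset: first time index with expression, per gene and position
    any_t = expressed.any(axis=1)
    first_t = expressed.argmax(axis=1)
    onset = np.where(any_t, times[first_t], np.inf)

    # anterior boundary: first expressed node, per gene and time
    any_x = expressed.any(axis=2)
    first_x = expressed.argmax(axis=2)
    boundaries = np.where(any_x, grid[first_x], np.inf)

    # geometry trace at the reference cell
    x_geo = scenario.resolved_geometry_position()
    p_ref = p_map[:, int(np.argmin(np.abs(grid - x_geo)))]
    n_val = n_factor(cluster)
    rows = []
    for t, p in zip(times, p_ref):
        resp = spring_response(force(p, n_val), scenario.spring, cluster)
        rows.append(
            (t, p, p * n_val, resp.elongation, resp.slide, resp.total_length))
    geometry = pd.DataFrame(
        rows, columns=["t", "P", "F", "elongation", "slide", "total_length"])

    return ExperimentResult(
        scenario=scenario,
        cluster=cluster,
        grid=grid,
        times=times,
        p_map=p_map,
        expressed=expressed,
        onset=onset,
        boundaries=boundaries,
        required_p=required,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# Phenotype comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeComparison:
    """Per-probe mutant-vs-wild-type phenotype classification."""

    table: pd.DataFrame      # probe, onset/boundary deltas, ratio, label
    labels: dict[str, str]   # probe -> classification

    def label(self, probe: str) -> str:
        try:
            return self.labels[probe]
        except KeyError:
            raise InputError(f"no comparison recorded for probe {probe!r}") from None


def _comparison_cell(
    results: tuple[ExperimentResult, ...], probe: str
) -> float | None:
    """Common readout cell: just posterior of every scenario's final boundary.

    Returns None when the probe is expressed nowhere in any result.
    """
    bounds = [r.final_boundary(probe) for r in results]
    finite = [b for b in bounds if math.isfinite(b)]
    if not finite:
        return None
    L = results[0].scenario.morphogen.axis_length
    margin = BOUNDARY_MARGIN_FRACTION * L
    return min(max(finite) + margin, float(results[0].grid[-1]))


def compare_to_wildtype(
    mutant: ExperimentResult,
    wild_type: ExperimentResult,
    probes: tuple[str, ...] | None = None,
) -> PhenotypeComparison:
    """Classify each probe as retarded / premature / unchanged vs wild type.

    Onsets are compared at a common cell just posterior of both anterior
    boundaries, so every compared scenario eventually expresses the probe
    there when it expresses it anywhere at all.
    """
    if mutant.grid.shape != wild_type.grid.shape or not np.array_equal(
            mutant.grid, wild_type.grid):
        raise InputError("mutant and wild-type results use different axis grids")
    if not np.array_equal(mutant.times, wild_type.times):
        raise InputError("mutant and wild-type results use different time grids")
    probes = probes if probes is not None else wild_type.scenario.probes
    rows = []
    labels: dict[str, str] = {}
    for probe in probes:
        if probe not in wild_type.genes:
            raise InputError(f"probe {probe!r} absent from the wild-type result")
        if probe not in mutant.genes:
            raise InputError(f"probe {probe!r} absent from the mutant result")
        cell = _comparison_cell((mutant, wild_type), probe)
        b_wt = wild_type.final_boundary(probe)
        b_mut = mutant.final_boundary(probe)
        if cell is None:
            onset_wt = onset_mut = math.inf
        else:
            onset_wt = wild_type.onset_at(probe, cell)
            onset_mut = mutant.onset_at(probe, cell)
        d_onset = onset_mut - onset_wt
        if math.isnan(d_onset):  # inf - inf: never expressed in either
            d_onset = 0.0
        d_boundary = b_mut - b_wt
        if math.isnan(d_boundary):
            d_boundary = 0.0
        if d_onset > 0:
            label = RETARDED
        elif d_onset < 0:
            label = PREMATURE
        else:
            label = UNCHANGED
        # label consistency: the boundary must not shift against the onset
        if (label == RETARDED and d_boundary < 0) or (
                label == PREMATURE and d_boundary > 0):
            raise InputError(
                f"inconsistent phenotype for {probe}: onset shift {d_onset:g} "
                f"vs boundary shift {d_boundary:g}")
        ratio = (
            mutant.geometry["total_length"].iloc[-1]
            / wild_type.geometry["total_length"].iloc[-1]
        )
        labels[probe] = label
        rows.append(
            {
                "probe": probe,
                "onset_wild_type": onset_wt,
                "onset_mutant": onset_mut,
                "d_onset": d_onset,
                "boundary_wild_type": b_wt,
                "boundary_mutant": b_mut,
                "d_boundary": d_boundary,
                "elongation_ratio": ratio,
                "label": label,
            }
        )
    return PhenotypeComparison(table=pd.DataFrame(rows), labels=labels)


# ---------------------------------------------------------------------------
# Kondo–Duboule suite
# ---------------------------------------------------------------------------

def kondo_duboule_edits() -> dict[str, EditSpec | None]:
    """The four scenarios: wild type, Del I, Del II, Del III."""
    posterior = ("Hoxd11", "Hoxd12", "Hoxd13")
    return {
        "wild_type": None,
        "del_i": EditSpec(operation="delete", targets=posterior),
        "del_ii": EditSpec(operation="delete", targets=posterior,
                           remove_centromeric_anchor=True),
        "del_iii": EditSpec(operation="none", remove_centromeric_anchor=True),
    }


@dataclass(frozen=True)
class KondoDubouleSuite:
    """Results and phenotype comparisons of the four deletion scenarios."""

    results: dict[str, ExperimentResult]
    comparisons: dict[str, PhenotypeComparison]

    def probe_onsets(self, probe: str) -> dict[str, float]:
        """Onset of ``probe`` in every scenario, read at one common cell."""
        members = tuple(
            r for r in self.results.values() if probe in r.genes)
        cell = _comparison_cell(members, probe)
        out = {}
        for name, res in self.results.items():
            if probe not in res.genes:
                out[name] = math.inf
            else:
                out[name] = math.inf if cell is None else res.onset_at(probe, cell)
        return out


def kondo_duboule_suite(base: Scenario | None = None) -> KondoDubouleSuite:
    """Run wild type, Del I, Del II and Del III from one base configuration.

    All four share the morphogen field, so the transient PDE is solved once.
    """
    base = base if base is not None else Scenario()
    times = base.resolved_times()
    snapshots = transient_snapshots(
        base.morphogen, times, GridSpec(n_nodes=base.n_nodes, dt=base.dt))
    results = {
        name: run_scenario(replace(base, edit=edit), _snapshots=snapshots)
        for name, edit in kondo_duboule_edits().items()
    }
    wt = results["wild_type"]
    comparisons = {
        name: compare_to_wildtype(results[name], wt)
        for name in ("del_i", "del_ii", "del_iii")
    }
    return KondoDubouleSuite(results=results, comparisons=comparisons)


# ---------------------------------------------------------------------------
# Scale-gap check
# ---------------------------------------------------------------------------

def scale_gap_orders(
    axis_length_mm: float = 1.0,
    cluster_length_nm: float = 100.0,
) -> float:
    """Orders of magnitude between the embryo axis and the compact cluster.

    log10(axis length / cluster length): 1 mm vs 100 nm gives 4 — the
    macro/micro scale gap the force model is built to bridge.
    """
    if axis_length_mm <= 0 or cluster_length_nm <= 0:
        raise ParameterError("lengths must be > 0")
    return math.log10(axis_length_mm * 1.0e6 / cluster_length_nm)
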