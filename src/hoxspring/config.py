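"""Scenario configuration files, presets, and result serialization.

Configurations are declarative TOML (or JSON) documents; every key has a
default, so an empty file is a valid wild-type run. Unknown keys are rejected
with their dotted paths, invariant violations with the offending field name.
Result tables are written as TSV/CSV with fixed 6-significant-digit floats so
re-running the same configuration and seed reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .cluster import EditSpec
from .errors import ConfigurationError
from .experiments import (
    KondoDubouleSuite,
    ExperimentResult,
    Scenario,
    kondo_duboule_suite,
    run_scenario,
)
from .mechanics import SpringParams, extrusion_state, force, geometry_table, spring_response
from .morphogen import MorphogenParams, ThresholdSet
from . import cluster as _cluster
from . import __version__ as _pkg_version

__all__ = [
    "RunConfig",
    "load_config",
    "write_config",
    "resolved_config_dict",
    "config_hash",
    "write_results",
    "cluster_to_bed",
    "PRESETS",
]

PRESETS = ("wild-type", "kondo-duboule")
FLOAT_FORMAT = "%.6g"

_SCHEMA: dict[str, tuple[str, ...]] = {
    "run": ("preset", "seed"),
    "morphogen": ("diffusion_coeff", "decay_rate", "source_amplitude",
                  "axis_length", "source_position", "extra_sources"),
    "thresholds": ("values", "n_genes"),
    "cluster": ("charge", "rescale_rest_length"),
    "edit": ("operation", "targets", "remove_centromeric_anchor"),
    "spring": ("spring_constant", "friction_fraction", "slide_stiffness",
               "slide_coupling", "extrusion_slope"),
    "experiment": ("times", "n_nodes", "dt", "probes", "p_mode",
                   "geometry_position", "noise_sd"),
}


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run: one scenario, or the Kondo–Duboule suite."""

    scenario: Scenario
    suite: str | None = None       # None or "kondo-duboule"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.suite not in (None, "kondo-duboule"):
            raise ConfigurationError(
                f"run.preset: unknown suite {self.suite!r}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError(
                f"run.seed must be a non-negative integer (got {self.seed!r})")


def _check_unknown_keys(doc: dict) -> None:
    bad: list[str] = []
    for section, body in doc.items():
        if section not in _SCHEMA:
            bad.append(section)
            continue
        if not isinstance(body, dict):
            raise ConfigurationError(
                f"section [{section}] must be a table of keys")
        for key in body:
            if key not in _SCHEMA[section]:
                bad.append(f"{section}.{key}")
    if bad:
        raise ConfigurationError(f"unknown configuration keys: {', '.join(bad)}")


def _build_run(doc: dict) -> RunConfig:
    _check_unknown_keys(doc)
    run = doc.get("run", {})
    preset = run.get("preset")
    suite = None
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigurationError(
                f"run.preset: unknown preset {preset!r}; available: {PRESETS}")
        if preset == "kondo-duboule":
            suite = "kondo-duboule"
    seed = run.get("seed", 0)

    mp = doc.get("morphogen", {})
    extra = tuple(tuple(map(float, s)) for s in mp.get("extra_sources", ()))
    defaults = MorphogenParams()
    morphogen = MorphogenParams(
        diffusion_coeff=mp.get("diffusion_coeff", defaults.diffusion_coeff),
        decay_rate=mp.get("decay_rate", defaults.decay_rate),
        source_amplitude=mp.get("source_amplitude", defaults.source_amplitude),
        axis_length=mp.get("axis_length", defaults.axis_length),
        source_position=mp.get(
            "source_position", mp.get("axis_length", defaults.source_position)),
        extra_sources=extra,
    )

    th = doc.get("thresholds", {})
    if "values" in th:
        thresholds = ThresholdSet(tuple(float(v) for v in th["values"]))
    elif "n_genes" in th:
        thresholds = ThresholdSet.default_for(morphogen, n_genes=int(th["n_genes"]))
    else:
        thresholds = None

    ed = doc.get("edit", {})
    edit = None
    if ed:
        edit = EditSpec(
            operation=ed.get("operation", "none"),
            targets=tuple(ed.get("targets", ())),
            remove_centromeric_anchor=ed.get("remove_centromeric_anchor", False),
        )

    sp = doc.get("spring", {})
    spring_defaults = SpringParams()
    spring = SpringParams(
        spring_constant=sp.get("spring_constant", spring_defaults.spring_constant),
        friction_fraction=sp.get(
            "friction_fraction", spring_defaults.friction_fraction),
        slide_stiffness=sp.get("slide_stiffness", spring_defaults.slide_stiffness),
        slide_coupling=sp.get("slide_coupling", spring_defaults.slide_coupling),
        extrusion_slope=sp.get("extrusion_slope", spring_defaults.extrusion_slope),
    )

    ex = doc.get("experiment", {})
    cl = doc.get("cluster", {})
    scenario = Scenario(
        morphogen=morphogen,
        thresholds=thresholds,
        spring=spring,
        edit=edit,
        times=tuple(ex["times"]) if "times" in ex else None,
        n_nodes=int(ex.get("n_nodes", 201)),
        dt=ex.get("dt"),
        probes=tuple(ex.get("probes", _cluster.DEFAULT_PROBES)),
        p_mode=ex.get("p_mode", "integer"),
        geometry_position=ex.get("geometry_position"),
        charge=float(cl.get("charge", 1.0)),
        rescale_rest_length=bool(cl.get("rescale_rest_length", True)),
        noise_sd=float(ex.get("noise_sd", 0.0)),
        seed=seed,
    )
    return RunConfig(scenario=scenario, suite=suite, seed=seed)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration.

    An empty document resolves to the all-defaults wild-type run.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text) if text.strip() else {}
    else:
        try:
            doc = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"invalid TOML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a table/object")
    return _build_run(doc)


def resolved_config_dict(run: RunConfig) -> dict:
    """Canonical fully-resolved dictionary form of a run configuration."""
    sc = run.scenario
    mp = sc.morphogen
    thresholds = sc.resolved_thresholds()
    doc = {
        "run": {"seed": run.seed,
                **({"preset": run.suite} if run.suite else {})},
        "morphogen": {
            "diffusion_coeff": mp.diffusion_coeff,
            "decay_rate": mp.decay_rate,
            "source_amplitude": mp.source_amplitude,
            "axis_length": mp.axis_length,
            "source_position": mp.source_position,
            "extra_sources": [list(s) for s in mp.extra_sources],
        },
        "thresholds": {"values": list(thresholds.values)},
        "cluster": {"charge": sc.charge,
                    "rescale_rest_length": sc.rescale_rest_length},
        "spring": {
            "spring_constant": sc.spring.spring_constant,
            "friction_fraction": sc.spring.friction_fraction,
            "slide_stiffness": sc.spring.slide_stiffness,
            "slide_coupling": sc.spring.slide_coupling,
            "extrusion_slope": sc.spring.extrusion_slope,
        },
        "experiment": {
            "times": [float(t) for t in sc.resolved_times()],
            "n_nodes": sc.n_nodes,
            "probes": list(sc.probes),
            "p_mode": sc.p_mode,
            "geometry_position": sc.resolved_geometry_position(),
            "noise_sd": sc.noise_sd,
            **({"dt": sc.dt} if sc.dt is not None else {}),
        },
    }
    if sc.edit is not None:
        doc["edit"] = {
            "operation": sc.edit.operation,
            "targets": list(sc.edit.targets),
            "remove_centromeric_anchor": sc.edit.remove_centromeric_anchor,
        }
    return doc


def write_config(run: RunConfig, path: str | Path) -> Path:
    """Serialize the resolved configuration as JSON (re-loadable)."""
    path = Path(path)
    path.write_text(json.dumps(resolved_config_dict(run), indent=2, sort_keys=True))
    return path


def config_hash(run: RunConfig) -> str:
    payload = json.dumps(resolved_config_dict(run), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def cluster_to_bed(cluster, path: str | Path) -> Path:
    """BED-like export of the cluster: 0-based half-open nm intervals.

    Each locus spans from its rest offset to the next locus (the last one to
    the rest length), on the abstract contig "HoxD".
    """
    path = Path(path)
    offs = [int(round(l.rest_offset)) for l in cluster.loci]
    ends = offs[1:] + [max(int(round(cluster.rest_length)), offs[-1] + 1)]
    lines = [
        f"HoxD\t{start}\t{end}\t{locus.name}\t{int(locus.charge * 100)}\t+"
        for locus, start, end in zip(cluster.loci, offs, ends)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def _final_geometry(result: ExperimentResult):
    """Per-locus geometry at the last recorded time, with readout noise."""
    sc = result.scenario
    p_final = result.geometry["P"].iloc[-1]
    state = force(p_final, sum(l.charge for l in result.cluster.loci))
    resp = spring_response(state, sc.spring, result.cluster)
    extr = extrusion_state(result.cluster, state, resp, sc.spring)
    return geometry_table(result.cluster, resp, extr,
                          noise_sd=sc.noise_sd, seed=sc.seed)


def _write_result_files(result: ExperimentResult, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    df = result.expression_table()
    files["expression_map.tsv"] = outdir / "expression_map.tsv"
    df.to_csv(files["expression_map.tsv"], sep="\t", index=False,
              float_format=FLOAT_FORMAT)
    files["onset_table.tsv"] = outdir / "onset_table.tsv"
    result.onset_table().to_csv(files["onset_table.tsv"], sep="\t", index=False,
                                float_format=FLOAT_FORMAT)
    files["boundaries.tsv"] = outdir / "boundaries.tsv"
    result.boundary_table().to_csv(files["boundaries.tsv"], sep="\t", index=False,
                                   float_format=FLOAT_FORMAT)
    files["geometry_trace.tsv"] = outdir / "geometry_trace.tsv"
    result.geometry.to_csv(files["geometry_trace.tsv"], sep="\t", index=False,
                           float_format=FLOAT_FORMAT)
    files["geometry.csv"] = outdir / "geometry.csv"
    _final_geometry(result).to_csv(files["geometry.csv"], index=False,
                                   float_format=FLOAT_FORMAT)
    files["cluster.bed"] = cluster_to_bed(result.cluster, outdir / "cluster.bed")
    return files


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(
    run: RunConfig,
    outcome: ExperimentResult | KondoDubouleSuite,
    outdir: str | Path,
) -> dict:
    """Write the deterministic result file set plus a hashed manifest.

    Returns the manifest (also written as manifest.json). Identical
    configuration and seed reproduce identical content hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    if isinstance(outcome, KondoDubouleSuite):
        for name, res in outcome.results.items():
            sub = _write_result_files(res, outdir / name)
            files.update({f"{name}/{k}": v for k, v in sub.items()})
        comp = np.sort(list(outcome.comparisons))  # stable order
        import pandas as pd

        table = pd.concat(
            [outcome.comparisons[n].table.assign(scenario=n) for n in comp],
            ignore_index=True,
        )
        path = outdir / "phenotype_comparison.tsv"
        table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        files["phenotype_comparison.tsv"] = path
    else:
        files.update(_write_result_files(outcome, outdir))

    resolved = resolved_config_dict(run)
    log = outdir / "run.log"
    log.write_text(
        "hoxspring run\n"
        f"version: {_pkg_version}\n"
        f"seed: {run.seed}\n"
        f"config_sha256: {config_hash(run)}\n"
        "resolved config:\n"
        + json.dumps(resolved, indent=2, sort_keys=True)
        + "\n"
    )
    files["run.log"] = log
    manifest = {
        "package_version": _pkg_version,
        "seed": run.seed,
        "config_sha256": config_hash(run),
        "config": resolved,
        "files": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def execute(run: RunConfig) -> ExperimentResult | KondoDubouleSuite:
    """Run the scenario or suite a configuration describes."""
    if run.suite == "kondo-duboule":
        return kondo_duboule_suite(run.scenario)
    return run_scenario(run.scenario)
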