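"""End-to-end orchestration of one network run.

A :class:`SimulationConfig` bundles the geometry, the input-rate
specification, the branching and granular-layer parameters and the stellate
contact law.  :func:`simulate` executes input synthesis -> calibration ->
granular recoding -> stellate/Purkinje sampling -> nuclear convergence in
memory; :func:`run_network` additionally writes tidy CSVs and a manifest
from which a run is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .geometry import NetworkGeometry
from .granular import (
    CalibrationResult,
    FieldActivity,
    FileCode,
    FiringRule,
    GolgiParams,
    assemble_file_codes,
    calibrate_inhibition_scale,
    run_granular_layer,
)
from .molecular import (
    PCNetwork,
    PurkinjeLayerResult,
    StellateLayerResult,
    StellateSampleLaw,
    build_pc_afferent_networks,
    integrate_pc,
    simulate_stellate_layer,
)
from .mossy import (
    BranchingParams,
    InputLayer,
    RankInputSpec,
    SineDriveSpec,
    build_input_layer,
    export_field_rates,
)
from .nuclear import NuclearOutputs, project_to_nucleus

__version__ = "0.1.0"

__all__ = [
    "SimulationConfig",
    "NetworkRun",
    "RunManifest",
    "simulate",
    "run_from_layer",
    "run_network",
]


@dataclass(frozen=True)
class CalibrationSettings:
    target: float | None = None  # default: geometry.active_fraction_target
    tol: float = 0.02
    mode: str = "offset"
    subsample_fraction: float = 0.25
    calibration_granule: int = 2000


@dataclass(frozen=True)
class SimulationConfig:
    geometry: NetworkGeometry = dfield(default_factory=NetworkGeometry)
    input: RankInputSpec = dfield(default_factory=RankInputSpec.uniform)
    branching: BranchingParams = dfield(default_factory=BranchingParams)
    golgi: GolgiParams = dfield(default_factory=GolgiParams)
    rule: FiringRule = dfield(default_factory=FiringRule)
    law: StellateSampleLaw = dfield(default_factory=StellateSampleLaw)
    calibration: CalibrationSettings = dfield(default_factory=CalibrationSettings)

    @property
    def target_fraction(self) -> float:
        return (
            self.calibration.target
            if self.calibration.target is not None
            else self.geometry.active_fraction_target
        )

    def rank_specs(self) -> list[RankInputSpec]:
        return [self.input] * self.geometry.n_ranks

    def scaled(self, factor: float) -> "SimulationConfig":
        return dataclasses.replace(self, geometry=self.geometry.scaled(factor))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "SimulationConfig":
        kwargs: dict[str, Any] = {}
        if "geometry" in data:
            kwargs["geometry"] = NetworkGeometry.from_mapping(data["geometry"])
        if "input" in data:
            spec = dict(data["input"])
            if "sine" in spec and spec["sine"] is not None:
                spec["sine"] = SineDriveSpec(**spec["sine"])
            if "bands" in spec and spec["bands"] is not None:
                spec["bands"] = tuple(tuple(b) for b in spec["bands"])
            kwargs["input"] = RankInputSpec(**spec)
        for key, klass in (
            ("branching", BranchingParams),
            ("golgi", GolgiParams),
            ("rule", FiringRule),
            ("law", StellateSampleLaw),
            ("calibration", CalibrationSettings),
        ):
            if key in data:
                kwargs[key] = klass(**data[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls.from_mapping(data or {})


@dataclass
class NetworkRun:
    """All stage outputs of one end-to-end run."""

    config: SimulationConfig
    geom: NetworkGeometry
    seed: int
    layer: InputLayer
    calibration: CalibrationResult
    activities: list[list[FieldActivity]]
    files: list[FileCode]
    stellate: StellateLayerResult
    networks: list[PCNetwork]
    pcs: PurkinjeLayerResult
    nuclear: NuclearOutputs


def run_from_layer(
    config: SimulationConfig,
    layer: InputLayer,
    calibration: CalibrationResult,
    seed: int,
    geom: NetworkGeometry | None = None,
    networks: list[PCNetwork] | None = None,
) -> NetworkRun:
    """Run granular -> molecular -> nuclear on an existing input layer with a
    frozen calibration (used for input shifts and phase sweeps)."""
    geom = geom or layer.geom
    activities = run_granular_layer(
        layer,
        calibration.scale,
        calibration.offset,
        seed=seed,
        golgi=config.golgi,
        rule=config.rule,
    )
    files = assemble_file_codes(activities, geom)
    stellate = simulate_stellate_layer(
        files, config.law, geom, substream(seed, "stellate"), store_inputs=False
    )
    if networks is None:
        networks = build_pc_afferent_networks(geom, substream(seed, "networks"))
    pcs = integrate_pc(stellate, networks, geom, substream(seed, "purkinje"))
    nuclear = project_to_nucleus(pcs, geom, substream(seed, "nuclear"))
    return NetworkRun(
        config=config,
        geom=geom,
        seed=seed,
        layer=layer,
        calibration=calibration,
        activities=activities,
        files=files,
        stellate=stellate,
        networks=networks,
        pcs=pcs,
        nuclear=nuclear,
    )


def simulate(
    config: SimulationConfig | None = None,
    seed: int = 0,
    scale: float = 1.0,
    calibration: CalibrationResult | None = None,
) -> NetworkRun:
    """Execute the full pipeline in memory and return every stage's outputs."""
    config = config or SimulationConfig()
    geom = config.geometry if scale == 1.0 else config.geometry.scaled(scale)
    geom.validate()
    layer = build_input_layer(config.rank_specs(), geom, config.branching, seed=seed)
    if calibration is None:
        cal = config.calibration
        calibration = calibrate_inhibition_scale(
            layer,
            target=config.target_fraction,
            tol=cal.tol,
            seed=seed,
            golgi=config.golgi,
            rule=config.rule,
            mode=cal.mode,
            subsample_fraction=cal.subsample_fraction,
            calibration_granule=cal.calibration_granule,
        )
    return run_from_layer(config, layer, calibration, seed, geom=geom)


@dataclass
class RunManifest:
    master_seed: int
    config_digest: str
    version: str
    stages: list[str]
    outputs: dict[str, str]  # path -> sha256
    calibration: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_layer_csvs(run: NetworkRun, outdir: Path) -> dict[str, Path]:
    paths: dict[str, Path] = {}
    paths["mossy"] = export_field_rates(run.layer, outdir / "mossy.csv")

    pf = pd.concat(
        [
            pd.DataFrame({"file": fc.file_index, "rate_hz": fc.pf_rates})
            for fc in run.files
        ],
        ignore_index=True,
    )
    paths["pf"] = outdir / "pf.csv"
    pf.to_csv(paths["pf"], index=False)

    st = pd.DataFrame(
        {
            "sector": run.stellate.sector,
            "depth_layer": run.stellate.depth_layer,
            "cell": run.stellate.cell_index,
            "n_inputs": run.stellate.n_inputs,
            "output": run.stellate.outputs,
        }
    )
    paths["stellate"] = outdir / "stellate.csv"
    st.to_csv(paths["stellate"], index=False)

    n_pc, n_comp = run.pcs.compartments.shape
    comp = pd.DataFrame(
        {
            "sector": np.repeat(run.pcs.sector, n_comp),
            "pc": np.repeat(run.pcs.pc_index, n_comp),
            "compartment": np.tile(np.arange(n_comp), n_pc),
            "flank_a": run.pcs.compartments_by_flank[:, 0, :].ravel(),
            "flank_b": run.pcs.compartments_by_flank[:, 1, :].ravel(),
            "value": run.pcs.compartments.ravel(),
        }
    )
    paths["compartment"] = outdir / "compartment.csv"
    comp.to_csv(paths["compartment"], index=False)

    soma = pd.DataFrame(
        {"sector": run.pcs.sector, "pc": run.pcs.pc_index, "value": run.pcs.soma}
    )
    paths["soma"] = outdir / "soma.csv"
    soma.to_csv(paths["soma"], index=False)

    nuc = pd.DataFrame(
        {
            "cell": run.nuclear.cell_index,
            "sample_size": run.nuclear.sample_size,
            "output": run.nuclear.outputs,
        }
    )
    paths["nuclear"] = outdir / "nuclear.csv"
    nuc.to_csv(paths["nuclear"], index=False)

    dens = pd.DataFrame(
        {
            "rank": [a.rank_index for row in run.activities for a in row],
            "field": [a.field_index for row in run.activities for a in row],
            "fraction_active": [a.fraction_active for row in run.activities for a in row],
        }
    )
    dens["file_density"] = dens["field"].map(
        {fc.file_index: fc.density for fc in run.files}
    )
    paths["densities"] = outdir / "densities.csv"
    dens.to_csv(paths["densities"], index=False)
    return paths


def run_network(
    config: SimulationConfig | str | Path | None,
    seed: int,
    outdir: str | Path,
    scale: float = 1.0,
) -> RunManifest:
    """Execute the pipeline and export per-layer CSVs plus a manifest."""
    if config is None:
        config = SimulationConfig()
    elif isinstance(config, (str, Path)):
        config = SimulationConfig.from_file(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = simulate(config, seed=seed, scale=scale)

    from .metrics import layer_summaries  # local import to avoid cycle

    paths = _write_layer_csvs(run, outdir)
    summary_path = outdir / "summary.csv"
    layer_summaries(run).to_csv(summary_path, index=False)
    paths["summary"] = summary_path

    cal_path = outdir / "calibration.json"
    cal = dataclasses.asdict(run.calibration)
    cal["seed"] = seed
    cal_path.write_text(json.dumps(cal, indent=2))
    paths["calibration"] = cal_path

    manifest = RunManifest(
        master_seed=seed,
        config_digest=config.digest(),
        version=__version__,
        stages=["mossy", "calibrate", "granular", "stellate", "purkinje", "nuclear"],
        outputs={str(p): _sha256(p) for p in paths.values()},
        calibration=cal,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
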