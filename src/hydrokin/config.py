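"""Pipeline configuration: YAML schema, validation, and execution.

A pipeline run is: obtain one trajectory per temperature (either
simulated here or read from disk), compute MSD and a diffusion estimate
per temperature, assemble D(T), fit the Arrhenius and deformed-Arrhenius
laws, and write a JSON report plus CSV tables.  Every downstream
precondition that can be checked from the config alone is validated
before any computation starts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from . import io as hio
from .kinetics import (
    classify_arrhenius,
    compare_models,
    fit_arrhenius,
    fit_super_arrhenius,
)
from .msd import compute_msd, fit_msd, unwrap_pbc
from .synthetic import (
    BulkSimParams,
    ChannelSimParams,
    simulate_bulk_brownian,
    simulate_channel_hopping,
)

log = logging.getLogger("hydrokin")

_SIM_KINDS = ("bulk_brownian", "channel_hopping")


@dataclass
class MsdSettings:
    model: str = "dim_2nDt"
    n_dim: int = 3
    max_lag: float | None = None
    window: tuple[float, float] | None = None
    single_origin: bool = False
    constrain_v: bool = True

    def validate(self) -> None:
        if self.model not in ("paper_4Dt", "dim_2nDt"):
            raise ConfigurationError(f"msd.model must be paper_4Dt|dim_2nDt, got {self.model!r}")
        if self.n_dim < 1:
            raise ConfigurationError("msd.n_dim must be >= 1")
        if self.max_lag is not None and self.max_lag <= 0:
            raise ConfigurationError("msd.max_lag must be positive")
        if self.window is not None:
            lo, hi = self.window
            if not (0 <= lo < hi):
                raise ConfigurationError("msd.window must satisfy 0 <= lo < hi")


@dataclass
class FitSettings:
    ea_temperatures: tuple[float, ...] = (290.0, 300.0, 310.0)

    def validate(self) -> None:
        if any(T <= 0 for T in self.ea_temperatures):
            raise ConfigurationError("fit.ea_temperatures must be positive")


@dataclass
class ChannelSettings:
    path: str | None = None
    cutoff: float = 3.0
    stride: int | None = None

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("channel.cutoff must be positive")
        if self.stride is not None and self.stride < 1:
            raise ConfigurationError("channel.stride must be >= 1")
        if self.path is not None and not Path(self.path).exists():
            raise ConfigurationError(f"channel.path does not exist: {self.path}")


@dataclass
class PipelineConfig:
    """Validated settings for one `hydrokin pipeline` run."""

    output_dir: str = "hydrokin_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict | None = None
    trajectories: list[dict] = field(default_factory=list)
    msd: MsdSettings = field(default_factory=MsdSettings)
    fit: FitSettings = field(default_factory=FitSettings)
    channel: ChannelSettings | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            output_dir=doc.get("output_dir", "hydrokin_out"),
            seed=int(doc.get("seed", 0)),
            log_level=str(doc.get("log_level", "INFO")),
            simulate=doc.get("simulate"),
            trajectories=list(doc.get("trajectories", [])),
            msd=MsdSettings(**{**doc.get("msd", {}), **(
                {"window": tuple(doc["msd"]["window"])}
                if doc.get("msd", {}).get("window") else {})}),
            fit=FitSettings(**{
                "ea_temperatures": tuple(doc.get("fit", {}).get(
                    "ea_temperatures", (290.0, 300.0, 310.0)))}),
            channel=ChannelSettings(**doc["channel"]) if "channel" in doc else None,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if bool(self.simulate) == bool(self.trajectories):
            raise ConfigurationError(
                "exactly one of 'simulate' or 'trajectories' must be given"
            )
        if self.simulate:
            kind = self.simulate.get("kind")
            if kind not in _SIM_KINDS:
                raise ConfigurationError(f"simulate.kind must be one of {_SIM_KINDS}")
            temps = self.simulate.get("temperatures", [])
            if len(temps) < 2:
                raise ConfigurationError("simulate.temperatures needs >= 2 entries")
            if len(set(temps)) != len(temps):
                raise ConfigurationError("simulate.temperatures must be distinct")
            for key in ("n_particles", "n_frames"):
                if self.simulate.get(key, 1) < 1:
                    raise ConfigurationError(f"simulate.{key} must be >= 1")
            if self.simulate.get("dt", 1.0) <= 0:
                raise ConfigurationError("simulate.dt must be positive")
        for i, spec in enumerate(self.trajectories):
            if "path" not in spec or "temperature_K" not in spec:
                raise ConfigurationError(
                    f"trajectories[{i}] needs 'path' and 'temperature_K'"
                )
            if not Path(spec["path"]).exists():
                raise ConfigurationError(
                    f"trajectories[{i}].path does not exist: {spec['path']}"
                )
            if float(spec["temperature_K"]) <= 0:
                raise ConfigurationError(f"trajectories[{i}].temperature_K must be > 0")
        temps = [float(s["temperature_K"]) for s in self.trajectories]
        if len(set(temps)) != len(temps):
            raise ConfigurationError("trajectory temperatures must be distinct")
        self.msd.validate()
        self.fit.validate()
        if self.channel is not None:
            self.channel.validate()


def _simulated_runs(cfg: PipelineConfig):
    sim = dict(cfg.simulate or {})
    kind = sim.pop("kind")
    temps = sim.pop("temperatures")
    for i, T in enumerate(sorted(float(t) for t in temps)):
        seed = cfg.seed * 10007 + i
        if kind == "bulk_brownian":
            params = BulkSimParams(**sim, temperature=T, seed=seed)
            traj = simulate_bulk_brownian(params)
        else:
            params = ChannelSimParams(**sim, temperature=T, seed=seed)
            traj = simulate_channel_hopping(params)
        yield T, traj


def _loaded_runs(cfg: PipelineConfig):
    for spec in sorted(cfg.trajectories, key=lambda s: float(s["temperature_K"])):
        traj = hio.read_trajectory(
            spec["path"], spec.get("format"), dt=float(spec.get("dt", 1.0))
        )
        yield float(spec["temperature_K"]), traj


def run_pipeline(cfg: PipelineConfig, config_source: str = "<dict>") -> dict:
    """Execute trajectory -> MSD -> D(T) -> deformed-Arrhenius fit -> report.

    Returns the report dict; artifacts (JSON report, D(T) CSV, per-T MSD
    CSVs) land in cfg.output_dir.
    """
    from .kinetics import RateSeries

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs = _simulated_runs(cfg) if cfg.simulate else _loaded_runs(cfg)

    temps, Ds, per_T = [], [], {}
    for T, traj in runs:
        if traj.wrapped:
            traj = unwrap_pbc(traj)
        curve = compute_msd(
            traj, max_lag=cfg.msd.max_lag, single_origin=cfg.msd.single_origin
        )
        est = fit_msd(
            curve, cfg.msd.model, cfg.msd.window,
            n_dim=cfg.msd.n_dim, constrain_v=cfg.msd.constrain_v,
        )
        hio.write_msd_csv(curve, out / f"msd_{T:g}K.csv")
        log.info("T=%g K: D = %.3e m^2/s", T, est.D)
        temps.append(T)
        Ds.append(est.D)
        per_T[f"{T:g}"] = hio.diffusion_report(est)

    series = RateSeries(np.asarray(temps), np.asarray(Ds), value_kind="diffusion")
    hio.write_rate_csv(series, out / "diffusion_vs_temperature.csv")

    lin = fit_arrhenius(series)
    quad = fit_super_arrhenius(series)
    comparison = compare_models(series) if len(series) >= 4 else None
    report = {
        "diffusion_by_temperature": per_T,
        "arrhenius": hio.fit_report(lin, cfg.fit.ea_temperatures),
        "super_arrhenius": hio.fit_report(quad, cfg.fit.ea_temperatures),
        "classification": classify_arrhenius(quad),
    }
    if comparison is not None:
        report["preferred_model"] = comparison.preferred
    hio.write_report(
        report,
        out / "report.json",
        inputs={"config": str(config_source)},
        settings={"msd": dataclasses.asdict(cfg.msd),
                  "fit": dataclasses.asdict(cfg.fit)},
        seed=cfg.seed,
    )
    log.info("classification: %s", report["classification"])
    return report
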