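"""Run configuration and reproducible pipeline orchestration.

A :class:`RunConfig` collects per-stage parameter blocks (unknown keys are
rejected), a single global seed that feeds every stochastic stage, and an
output directory.  :func:`run_pipeline` generates synthetic inputs for all
three pipelines, analyzes them, and records a :class:`RunManifest` with
input digests, the config snapshot and per-stage outputs and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dsc import fit_two_state, reversibility, subtract_baseline
from .errors import ConfigError
from .kinetics import fit_boltzmann
from .pipeline import analyze_heightmap
from .synthetic import (
    AfmBackground,
    AfmSimSpec,
    KineticSimSpec,
    ThermogramSimSpec,
    gen_afm_image,
    gen_kinetic_trace,
    gen_thermogram,
    write_ground_truth_json,
    write_heightmap_ascii,
    write_thermogram_csv,
    write_trace_csv,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]


def _from_mapping(cls, data: dict, context: str):
    """Strict dataclass construction: unknown keys are configuration errors."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class KineticsConfig:
    y1: float = 0.0
    y2: float = 100.0
    t_lag: float = 64.8
    t_half: float = 80.3
    t_max: float = 200.0
    dt: float = 1.0
    noise_sd: float = 1.0
    normalize: str | None = None


@dataclass(frozen=True)
class DscConfig:
    T_d: float = 66.57
    dH_cal: float = 432.2
    dH_vH: float = 448.5
    T_min: float = 25.0
    T_max: float = 110.0
    dT: float = 0.05
    noise_sd: float = 0.0
    baseline: str = "progress"
    rescan_scale: float = 0.98


@dataclass(frozen=True)
class AfmConfig:
    image_size: int = 512
    pixel_size: float = 4.0
    populations: tuple = ((2.6, 0.4, 30), (3.7, 0.8, 30), (6.1, 1.1, 30))
    fibril_width: tuple = (10.0, 1.0)
    tilt: tuple = (0.004, -0.003)
    bow_amplitude: float = 0.4
    roughness_sd: float = 0.15
    min_separation: float = 28.0
    bin_width: float = 0.25
    n_peaks: int | None = 3
    rule: str = "sqrt_n"


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "fibrilmorph_run"
    verbosity: int = 1
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    dsc: DscConfig = field(default_factory=DscConfig)
    afm: AfmConfig = field(default_factory=AfmConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {}
        for name, sub_cls in (("kinetics", KineticsConfig), ("dsc", DscConfig), ("afm", AfmConfig)):
            if name in data:
                block = data.pop(name)
                if not isinstance(block, dict):
                    raise ConfigError(f"{name} block must be a mapping")
                if name == "afm":
                    for key in ("populations", "fibril_width", "tilt"):
                        if key in block:
                            block[key] = _to_tuple(block[key])
                sub[name] = _from_mapping(sub_cls, block, name)
        return _from_mapping(cls, {**data, **sub}, "run config")


def _to_tuple(obj):
    if isinstance(obj, (list, tuple)):
        return tuple(_to_tuple(v) for v in obj)
    return obj


def load_config(path: str | Path) -> RunConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return RunConfig.from_dict(data)


@dataclass
class RunManifest:
    """Record of one pipeline run: digests, config, outputs, warnings."""

    config: dict
    version: str
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Generate synthetic inputs for all three pipelines and analyze them."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- kinetics
        kc = config.kinetics
        t_grid = np.arange(0.0, kc.t_max + kc.dt / 2, kc.dt)
        trace = gen_kinetic_trace(KineticSimSpec(
            y1=kc.y1, y2=kc.y2, t_lag=kc.t_lag, t_half=kc.t_half,
            t_grid=t_grid, noise_sd=kc.noise_sd, seed=config.seed,
        ))
        trace_path = out / "kinetic_trace.csv"
        write_trace_csv(trace, trace_path)
        kfit = fit_boltzmann(trace)
        (out / "kinetic_fit.json").write_text(json.dumps(kfit.as_dict(), indent=2))
        manifest.results["kinetics"] = kfit.as_dict()

        # --- DSC
        dc = config.dsc
        T_grid = np.arange(dc.T_min, dc.T_max + dc.dT / 2, dc.dT)
        spec = ThermogramSimSpec(
            T_d=dc.T_d, dH_cal=dc.dH_cal, dH_vH=dc.dH_vH,
            T_grid=T_grid, noise_sd=dc.noise_sd, seed=config.seed,
        )
        tg1 = gen_thermogram(spec, scan_index=1)
        tg2 = gen_thermogram(spec, scan_index=2, scale=dc.rescan_scale)
        write_thermogram_csv(tg1, out / "thermogram_scan1.csv")
        write_thermogram_csv(tg2, out / "thermogram_scan2.csv")
        s1 = subtract_baseline(tg1, method=dc.baseline)
        s2 = subtract_baseline(tg2, method=dc.baseline)
        dfit = fit_two_state(s1, rescan=s2)
        (out / "dsc_fit.json").write_text(json.dumps(dfit.as_dict(), indent=2))
        manifest.results["dsc"] = dfit.as_dict()
        manifest.results["dsc"]["reversibility_check"] = reversibility(s1, s2)

        # --- AFM
        ac = config.afm
        afm_spec = AfmSimSpec(
            image_shape=(ac.image_size, ac.image_size),
            pixel_size=ac.pixel_size,
            populations=ac.populations,
            fibril_width=ac.fibril_width,
            background=AfmBackground(
                tilt=ac.tilt, bow_amplitude=ac.bow_amplitude, roughness_sd=ac.roughness_sd,
            ),
            min_separation=ac.min_separation,
            seed=config.seed,
        )
        hmap, truth = gen_afm_image(afm_spec)
        map_path = out / "heightmap.txt"
        write_heightmap_ascii(hmap, map_path)
        write_ground_truth_json(truth, out / "heightmap_truth.json")
        analysis = analyze_heightmap(
            hmap, bin_width=ac.bin_width, n_peaks=ac.n_peaks, rule=ac.rule,
        )
        (out / "afm_summary.json").write_text(json.dumps(analysis.summary(), indent=2))
        manifest.results["afm"] = analysis.summary()

        manifest.warnings = [str(w.message) for w in caught]

    for p in sorted(out.iterdir()):
        if p.suffix in (".csv", ".txt", ".json") and p.name != "manifest.json":
            manifest.outputs[p.name] = str(p)
            manifest.input_digests[p.name] = _digest(p)
    manifest.write(out / "manifest.json")
    return manifest
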