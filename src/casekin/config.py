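"""Run configuration: YAML/JSON schema, validation, and the run manifest.

Schema (all keys optional unless a requested stage needs them)::

    rates:            # either per-(mg/L) coefficients ...
      k1: 0.0264
      k2: 0.0015
      k3: 0.0008
      ka: 0.0
    # ... or effective products at a reference enzyme concentration:
    #   k1E0: 0.0066
    #   k3E0: 0.0002   (then enzyme.E0 is the reference concentration)
    enzyme:
      E0: 0.25         # mg/L; a list runs multi-concentration stages
    grid:
      t_end_s: 20000
      n_points: 2001
    stages: [gen_tmax, simulate, fit_k2]
    seed: 0
    ss_mode: S_plus_halfX_plus_Y

Validation failures raise :class:`~casekin.errors.ConfigError` naming the
offending key.  Every pipeline run emits a JSON manifest recording the
config hash, seed, package version and per-stage inputs/outputs, which is
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .kinetics import EnzymeSetting, RateConstants

__all__ = [
    "load_config",
    "rates_from_config",
    "enzyme_levels_from_config",
    "time_grid_from_config",
    "RunManifest",
    "run_pipeline",
    "KNOWN_STAGES",
]

_SCHEMA_VERSION = 1

KNOWN_KEYS = {
    "rates",
    "enzyme",
    "grid",
    "stages",
    "seed",
    "ss_mode",
    "lag_threshold",
    "ftir",
    "afm",
    "tmax_noise_sigma",
    "schema_version",
    "tmax_table",
}

KNOWN_STAGES = (
    "gen_tmax",
    "gen_ftir",
    "gen_afm",
    "simulate",
    "tmax",
    "fit_k2",
    "predict_ss",
    "ftir",
    "afm",
)


def load_config(path) -> dict:
    """Load and validate a YAML/JSON config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}", key=str(p))
    text = p.read_text()
    try:
        cfg = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse config: {exc}", key=str(p)) from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping", key=str(p))
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ConfigError("unknown config key", key=sorted(unknown)[0])
    for stage in cfg.get("stages", []):
        if stage not in KNOWN_STAGES:
            raise ConfigError(
                f"unknown stage (known: {', '.join(KNOWN_STAGES)})", key=stage
            )
    return cfg


def _require(cfg: dict, key: str) -> dict:
    if key not in cfg:
        raise ConfigError("required section missing", key=key)
    if not isinstance(cfg[key], dict):
        raise ConfigError("must be a mapping", key=key)
    return cfg[key]


def rates_from_config(cfg: dict) -> RateConstants:
    """Build rate constants from either per-(mg/L) coefficients (k1, k3)
    or effective products (k1E0, k3E0) plus the reference enzyme.E0."""
    r = _require(cfg, "rates")
    if "k2" not in r:
        raise ConfigError("k2 is required", key="rates.k2")
    ka = float(r.get("ka", 0.0))
    ka_prop = bool(r.get("ka_enzyme_proportional", True))
    has_coeff = "k1" in r and "k3" in r
    has_eff = "k1E0" in r and "k3E0" in r
    if has_coeff and has_eff:
        raise ConfigError("give either k1/k3 or k1E0/k3E0, not both", key="rates")
    try:
        if has_coeff:
            return RateConstants(
                k1=float(r["k1"]), k2=float(r["k2"]), k3=float(r["k3"]),
                ka=ka, ka_enzyme_proportional=ka_prop,
            )
        if has_eff:
            e = _require(cfg, "enzyme")
            e0 = e.get("E0")
            if e0 is None:
                raise ConfigError(
                    "enzyme.E0 (reference concentration) is required with k1E0/k3E0",
                    key="enzyme.E0",
                )
            e0_ref = float(e0[0]) if isinstance(e0, (list, tuple)) else float(e0)
            return RateConstants.from_effective(
                k1E0=float(r["k1E0"]), k2=float(r["k2"]), k3E0=float(r["k3E0"]),
                E0=e0_ref, ka=ka, ka_enzyme_proportional=ka_prop,
            )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(str(exc), key="rates") from exc
    raise ConfigError("need k1/k3 or k1E0/k3E0", key="rates")


def enzyme_levels_from_config(cfg: dict) -> list[float]:
    e = _require(cfg, "enzyme")
    e0 = e.get("E0")
    if e0 is None:
        raise ConfigError("enzyme.E0 is required", key="enzyme.E0")
    levels = list(e0) if isinstance(e0, (list, tuple)) else [e0]
    try:
        levels = [float(v) for v in levels]
    except (TypeError, ValueError) as exc:
        raise ConfigError("E0 must be numeric", key="enzyme.E0") from exc
    if any(v <= 0 for v in levels):
        raise ConfigError("E0 values must be > 0", key="enzyme.E0")
    return levels


def time_grid_from_config(cfg: dict) -> np.ndarray:
    g = cfg.get("grid", {})
    if not isinstance(g, dict):
        raise ConfigError("must be a mapping", key="grid")
    t_end = float(g.get("t_end_s", 2e4))
    n = int(g.get("n_points", 2001))
    if t_end <= 0:
        raise ConfigError("t_end_s must be > 0", key="grid.t_end_s")
    if n < 2:
        raise ConfigError("n_points must be >= 2", key="grid.n_points")
    return np.linspace(0.0, t_end, n)


# ---------------------------------------------------------------------------
# manifest + pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    started_utc: str
    finished_utc: str = ""
    stages: dict = field(default_factory=dict)  # stage -> {inputs, outputs}
    schema_version: int = _SCHEMA_VERSION

    def record(self, stage: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[stage] = {"inputs": inputs, "outputs": outputs}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _utcnow() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the stages requested in the config, in dependency order
    (generators first, then kinetics, then FTIR/AFM analysis), writing all
    artifacts plus a manifest.json into ``out_dir``."""
    from . import __version__, afm, ftir, io as ckio, synthetic
    from .kinetics import (
        fit_k2,
        predict_secondary_structure,
        species_closed_form,
        tmax_from_constants,
    )

    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    manifest = RunManifest(
        config_hash=hashlib.sha256(Path(config_path).read_bytes()).hexdigest(),
        seed=seed,
        package_version=__version__,
        started_utc=_utcnow(),
    )
    requested = cfg.get("stages", ["simulate"])
    ordered = [s for s in KNOWN_STAGES if s in requested]

    rates = rates_from_config(cfg)
    levels = enzyme_levels_from_config(cfg)
    times = time_grid_from_config(cfg)
    ss_mode = cfg.get("ss_mode", "S_plus_halfX_plus_Y")
    rng = np.random.default_rng(seed)

    gen_cfg = synthetic.GeneratorConfig(
        seed=seed,
        kinetics=synthetic.KineticsConfig(
            rates=rates,
            e0_grid=tuple(levels),
            tmax_noise_sigma=float(cfg.get("tmax_noise_sigma", 0.1)),
        ),
    )

    ftir_series_path = out / "ftir_series.csv"
    enzyme_ref_path = out / "ftir_enzyme_reference.csv"
    tmax_table_path = out / "tmax_observations.csv"
    particles_path = out / "afm_particles.csv"

    for stage in ordered:
        if stage == "gen_tmax":
            obs, truth = synthetic.gen_tmax_dataset(gen_cfg, rng=rng)
            ckio.write_tmax_table(obs, tmax_table_path)
            truth_path = out / "tmax_truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        **{k: truth[k] for k in ("k1", "k2", "k3", "noise_sigma")},
                        "tmax_noiseless_s": {
                            str(k): v for k, v in truth["tmax_noiseless_s"].items()
                        },
                    },
                    indent=2,
                )
            )
            manifest.record(stage, [str(config_path)],
                            [str(tmax_table_path), str(truth_path)])
        elif stage == "gen_ftir":
            traj = species_closed_form(
                rates, EnzymeSetting(E0=levels[0]), times
            )
            series, enz, truth = synthetic.gen_ftir_series(gen_cfg, traj, rng=rng)
            ckio.write_spectrum_series(series, ftir_series_path)
            ckio.write_spectrum(enz, enzyme_ref_path)
            truth_path = out / "ftir_truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "structure_mode": truth["structure_mode"],
                        "noise_sigma": truth["noise_sigma"],
                        "t_min": truth["t_min"].tolist(),
                        "schedules": {
                            str(k): v.tolist() for k, v in truth["schedules"].items()
                        },
                    },
                    indent=2,
                )
            )
            manifest.record(stage, [str(config_path)],
                            [str(ftir_series_path), str(enzyme_ref_path),
                             str(truth_path)])
        elif stage == "gen_afm":
            ens, _truth = synthetic.gen_particle_ensemble(gen_cfg, rng=rng)
            ckio.write_particles(ens, particles_path)
            manifest.record(stage, [str(config_path)], [str(particles_path)])
        elif stage == "simulate":
            outputs = []
            for e0 in levels:
                traj = species_closed_form(rates, EnzymeSetting(E0=e0), times)
                p = out / f"trajectory_E0_{e0:g}.csv"
                ckio.write_trajectory(traj, p)
                outputs.append(str(p))
            manifest.record(stage, [str(config_path)], outputs)
        elif stage == "tmax":
            vals = {
                f"{e0:g}": tmax_from_constants(rates, EnzymeSetting(E0=e0))
                for e0 in levels
            }
            p = out / "tmax_model.json"
            p.write_text(json.dumps({"tmax_s_by_E0": vals}, indent=2))
            manifest.record(stage, [str(config_path)], [str(p)])
        elif stage == "fit_k2":
            table = Path(cfg.get("tmax_table", tmax_table_path))
            obs = ckio.read_tmax_table(table)
            fit = fit_k2(obs, k1=rates.k1, k3=rates.k3)
            p = out / "k2_fit.json"
            p.write_text(
                json.dumps(
                    {
                        "k2_s^-1": fit.k2,
                        "sse_s^2": fit.sse,
                        "residuals_s": fit.residuals.tolist(),
                    },
                    indent=2,
                )
            )
            fit.to_frame().to_csv(out / "k2_fit_residuals.csv", index=False)
            manifest.record(stage, [str(table)],
                            [str(p), str(out / "k2_fit_residuals.csv")])
        elif stage == "predict_ss":
            outputs = []
            for e0 in levels:
                traj = species_closed_form(rates, EnzymeSetting(E0=e0), times)
                ss = predict_secondary_structure(traj, mode=ss_mode)
                p = out / f"secondary_structure_{ss_mode}_E0_{e0:g}.csv"
                import pandas as pd

                pd.DataFrame({"t_s": traj.times, "ss_fraction": ss}).to_csv(
                    p, index=False
                )
                outputs.append(str(p))
            manifest.record(stage, [str(config_path)], outputs)
        elif stage == "ftir":
            series = ckio.read_spectrum_series(ftir_series_path)
            enz = ckio.read_spectrum(enzyme_ref_path)
            traces = ftir.process_reaction_series(series, enz)
            outputs = []
            for band, trace in traces.items():
                p = out / f"band_trace_{band:g}.csv"
                trace.to_frame().to_csv(p, index=False)
                outputs.append(str(p))
            manifest.record(stage, [str(ftir_series_path), str(enzyme_ref_path)],
                            outputs)
        elif stage == "afm":
            ens = ckio.read_particles(particles_path)
            stats = afm.summary_stats(ens)
            hist = afm.height_histogram(ens)
            p = out / "afm_summary.json"
            p.write_text(
                json.dumps({**stats, "height_modes_nm": hist.modes_nm}, indent=2)
            )
            hist.to_frame().to_csv(out / "afm_height_histogram.csv", index=False)
            manifest.record(stage, [str(particles_path)],
                            [str(p), str(out / "afm_height_histogram.csv")])

    manifest.finished_utc = _utcnow()
    manifest.write(out / "manifest.json")
    return manifest
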