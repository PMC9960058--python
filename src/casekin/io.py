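"""Delimited-text I/O for trajectories, t_max tables, spectra and particles.

All on-disk formats are plain CSV/TSV:

- trajectories: columns ``t_s, S, X, Y, N, Z``;
- t_max observation tables: columns ``E0_mg_per_L, tmax_s``;
- spectral series: wide table, first column ``wavenumber_cm1``, one
  ``t_<minutes>`` column per acquisition time;
- particle tables: columns ``height_nm, diameter_nm``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import ParticleEnsemble
from .errors import ConfigError, EmptyInputError
from .ftir import Spectrum, SpectrumSeries
from .kinetics import KineticTrajectory, TmaxObservation

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_tmax_table",
    "read_tmax_table",
    "write_spectrum_series",
    "read_spectrum_series",
    "write_particles",
    "read_particles",
]


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def write_trajectory(traj: KineticTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> KineticTrajectory:
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    required = {"t_s", "S", "X", "Y", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory table missing columns {sorted(missing)}")
    z = df["Z"].to_numpy() if "Z" in df.columns else None
    if z is not None and np.allclose(z, 0.0):
        z = None
    return KineticTrajectory(
        times=df["t_s"].to_numpy(),
        S=df["S"].to_numpy(),
        X=df["X"].to_numpy(),
        Y=df["Y"].to_numpy(),
        N=df["N"].to_numpy(),
        Z=z,
    )


def write_tmax_table(observations: list[TmaxObservation], path) -> None:
    pd.DataFrame(
        {
            "E0_mg_per_L": [o.E0 for o in observations],
            "tmax_s": [o.tmax for o in observations],
        }
    ).to_csv(path, index=False)


def read_tmax_table(path) -> list[TmaxObservation]:
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    missing = {"E0_mg_per_L", "tmax_s"} - set(df.columns)
    if missing:
        raise ConfigError(f"tmax table missing columns {sorted(missing)}")
    if df.empty:
        raise EmptyInputError(f"tmax table {path} is empty")
    return [
        TmaxObservation(E0=row.E0_mg_per_L, tmax=row.tmax_s)
        for row in df.itertuples()
    ]


_TIME_COL = re.compile(r"^t_([0-9]+(?:\.[0-9]+)?)$")


def write_spectrum_series(series: SpectrumSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_spectrum_series(path) -> SpectrumSeries:
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    if "wavenumber_cm1" not in df.columns:
        raise ConfigError("wide spectral table needs a 'wavenumber_cm1' first column")
    times, cols = [], []
    for col in df.columns:
        m = _TIME_COL.match(col)
        if m:
            times.append(float(m.group(1)))
            cols.append(col)
    if not cols:
        raise EmptyInputError(f"no t_<minutes> columns found in {path}")
    order = np.argsort(times)
    wn = df["wavenumber_cm1"].to_numpy(dtype=float)
    spectra = [
        Spectrum(
            wavenumbers=wn.copy(),
            absorbance=df[cols[i]].to_numpy(dtype=float),
            meta={"t_min": times[i]},
        )
        for i in order
    ]
    return SpectrumSeries(spectra=spectra, t_min=np.asarray(sorted(times)))


def write_spectrum(s: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": s.wavenumbers, "absorbance": s.absorbance}
    ).to_csv(path, index=False)


def read_spectrum(path) -> Spectrum:
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    missing = {"wavenumber_cm1", "absorbance"} - set(df.columns)
    if missing:
        raise ConfigError(f"spectrum table missing columns {sorted(missing)}")
    return Spectrum(
        wavenumbers=df["wavenumber_cm1"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
    )


def write_particles(ens: ParticleEnsemble, path) -> None:
    ens.to_frame().to_csv(path, index=False)


def read_particles(path, label: str = "") -> ParticleEnsemble:
    df = pd.read_csv(path, sep=_sep_for(Path(path)))
    missing = {"height_nm", "diameter_nm"} - set(df.columns)
    if missing:
        raise ConfigError(f"particle table missing columns {sorted(missing)}")
    return ParticleEnsemble.from_arrays(
        df["height_nm"].to_numpy(dtype=float),
        df["diameter_nm"].to_numpy(dtype=float),
        label=label or str(path),
    )
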