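"""Synthetic data with known ground truth for every pipeline stage.

Generates the three observable classes the analysis consumes:

- (E0, t_max) tables emulating nanoparticle-peak times read off light
  scattering at several enzyme concentrations, with multiplicative
  lognormal timing noise;
- FTIR absorbance time series in the 1800-1300 cm^-1 window whose band
  amplitudes follow the kinetic model (structure bands track the
  secondary-structure prediction, carboxylate bands track the product
  fraction), on top of an enzyme profile, a linear baseline drift and
  Gaussian noise;
- AFM particle ensembles with a Gaussian-mixture height distribution and
  a truncated-normal diameter distribution.

Every generator returns a ground-truth record alongside the data, so
downstream recovery can be scored without re-deriving the truth.  All
randomness flows through one seeded numpy Generator: identical seed and
config give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .afm import ParticleEnsemble
from .errors import ConfigError, OutOfRangeError
from .ftir import Spectrum, SpectrumSeries
from .kinetics import (
    EnzymeSetting,
    KineticTrajectory,
    RateConstants,
    TmaxObservation,
    predict_secondary_structure,
    tmax_from_constants,
)

__all__ = [
    "KineticsConfig",
    "FtirBand",
    "FtirConfig",
    "AfmConfig",
    "GeneratorConfig",
    "gen_tmax_dataset",
    "gen_ftir_series",
    "gen_particle_ensemble",
    "default_config",
]

#: Reference constants of the model at E0 = 0.25 mg/L:
#: k1*E0 = 0.0066 s^-1, k2 = 0.0015 s^-1, k3*E0 = 0.0002 s^-1.
REFERENCE_RATES = RateConstants.from_effective(
    k1E0=0.0066, k2=0.0015, k3E0=0.0002, E0=0.25
)


@dataclass(frozen=True)
class KineticsConfig:
    """Kinetic ground truth: rate constants and the enzyme-concentration
    grid at which observations are simulated (mg/L)."""

    rates: RateConstants = REFERENCE_RATES
    e0_grid: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0)
    tmax_noise_sigma: float = 0.1  # lognormal sigma on t_max, multiplicative

    def __post_init__(self) -> None:
        if self.tmax_noise_sigma < 0:
            raise ConfigError("noise sigma must be >= 0", key="tmax_noise_sigma")
        if any(e <= 0 for e in self.e0_grid):
            raise ConfigError("enzyme concentrations must be > 0", key="e0_grid")


@dataclass(frozen=True)
class FtirBand:
    """One synthetic absorption band: Gaussian in wavenumber, amplitude
    coupled to a kinetic observable.

    couples: "structure" -> amplitude follows the secondary-structure
    prediction; "product" -> amplitude follows the product fraction N(t).
    """

    center_cm1: float
    sigma_cm1: float
    amplitude: float  # AU at coupling value 1
    couples: str  # "structure" | "product"
    offset: float = 0.0  # residual amplitude that never reacts, AU

    def __post_init__(self) -> None:
        if self.couples not in ("structure", "product"):
            raise ConfigError(
                f"band coupling must be 'structure' or 'product', got {self.couples!r}",
                key="couples",
            )
        if self.sigma_cm1 <= 0 or self.amplitude < 0 or self.offset < 0:
            raise ConfigError("band sigma must be > 0, amplitudes >= 0", key="bands")


def _default_bands() -> tuple[FtirBand, ...]:
    # beta-sheet and alpha-helix track secondary structure; the two
    # carboxylate stretches track product release.  Residual offsets keep
    # the amide window strictly positive so area normalization is valid.
    return (
        FtirBand(1633.0, 12.0, 0.50, "structure", offset=0.20),
        FtirBand(1650.0, 12.0, 0.40, "structure", offset=0.20),
        FtirBand(1593.0, 12.0, 0.30, "product", offset=0.02),
        FtirBand(1405.0, 12.0, 0.20, "product", offset=0.02),
    )


@dataclass(frozen=True)
class FtirConfig:
    """Forward model of the reaction FTIR series.

    The grid is 1800-1300 cm^-1 at 4 cm^-1 (instrument resolution);
    acquisition starts at 1 min and runs to 90 min.  The structure bands'
    default coupling is the S + X/2 + Y retention hypothesis.
    """

    bands: tuple[FtirBand, ...] = field(default_factory=_default_bands)
    grid_max_cm1: float = 1800.0
    grid_min_cm1: float = 1300.0
    grid_step_cm1: float = 4.0
    t_min: tuple[float, ...] = (1.0, 2.0, 4.0, 7.0, 10.0, 15.0, 20.0, 30.0,
                                45.0, 60.0, 75.0, 90.0)
    structure_mode: str = "S_plus_halfX_plus_Y"
    noise_sigma: float = 0.002  # AU, additive white noise
    baseline_slope: float = 1e-4  # AU per cm^-1, linear drift
    baseline_offset: float = 0.05  # AU
    enzyme_amplitude: float = 0.05  # AU, broad enzyme profile
    enzyme_center_cm1: float = 1550.0
    enzyme_sigma_cm1: float = 120.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be >= 0", key="noise_sigma")
        if not self.t_min or any(np.diff(self.t_min) <= 0):
            raise ConfigError("t_min must be strictly increasing", key="t_min")

    def wavenumber_grid(self) -> np.ndarray:
        # descending grid, high to low wavenumber (FTIR convention)
        return np.arange(self.grid_max_cm1, self.grid_min_cm1 - 1e-9,
                         -self.grid_step_cm1)


@dataclass(frozen=True)
class AfmConfig:
    """Sampling model for particle ensembles: Gaussian mixture for heights,
    single normal for diameters, both truncated at 0 by resampling."""

    n_particles: int = 1000
    height_means_nm: tuple[float, ...] = (0.8, 3.8)
    height_sds_nm: tuple[float, ...] = (0.2, 0.6)
    height_weights: tuple[float, ...] = (0.4, 0.6)
    diameter_mean_nm: float = 58.0
    diameter_sd_nm: float = 12.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        k = len(self.height_means_nm)
        if len(self.height_sds_nm) != k or len(self.height_weights) != k:
            raise ConfigError(
                "height mixture means/sds/weights must have equal length",
                key="height_weights",
            )
        if abs(sum(self.height_weights) - 1.0) > 1e-9:
            raise ConfigError("mixture weights must sum to 1", key="height_weights")
        if any(w < 0 for w in self.height_weights):
            raise ConfigError("mixture weights must be >= 0", key="height_weights")
        if self.n_particles < 0:
            raise ConfigError("n_particles must be >= 0", key="n_particles")


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed plus per-stage sub-configs."""

    seed: int = 0
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    ftir: FtirConfig = field(default_factory=FtirConfig)
    afm: AfmConfig = field(default_factory=AfmConfig)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_config(seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(seed=seed)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_tmax_dataset(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[TmaxObservation], dict]:
    """Simulate nanoparticle-peak times at each enzyme concentration.

    The noiseless t_max comes from the model's transcendental peak
    condition; multiplicative lognormal noise (median 1) emulates the
    1-2 min read-off resolution of scattering kinetics.  Returns the
    observations and a ground-truth record (true constants, noiseless
    t_max values).
    """
    rng = cfg.rng() if rng is None else rng
    kc = cfg.kinetics
    obs = []
    truth_tmax = {}
    for e0 in kc.e0_grid:
        t_true = tmax_from_constants(kc.rates, EnzymeSetting(E0=e0))
        truth_tmax[e0] = t_true
        factor = (
            rng.lognormal(mean=0.0, sigma=kc.tmax_noise_sigma)
            if kc.tmax_noise_sigma > 0
            else 1.0
        )
        obs.append(TmaxObservation(E0=e0, tmax=t_true * factor))
    truth = {
        "k1": kc.rates.k1,
        "k2": kc.rates.k2,
        "k3": kc.rates.k3,
        "noise_sigma": kc.tmax_noise_sigma,
        "tmax_noiseless_s": truth_tmax,
    }
    return obs, truth


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _normalized_band_truth(
    fc: FtirConfig,
    wn: np.ndarray,
    schedules: dict[float, np.ndarray],
    anchors: tuple[float, float] = (1725.0, 1375.0),
    target_area: float = 1.0,
) -> dict[float, np.ndarray]:
    """Exact noiseless read-off the processing chain should recover.

    Replays the two-anchor baseline, window clip, equal-area normalization
    and linear band read-off on the clean band-sum spectrum (baseline drift
    and enzyme profile cancel exactly in the chain, so they are omitted
    here).  This is the scoreable ground truth: band overlap and the
    time-varying window area make the raw amplitude schedules A_b(t)
    unobservable directly.
    """
    hi, lo = max(anchors), min(anchors)
    x = wn[::-1] if wn[1] < wn[0] else wn  # ascending
    n_t = len(next(iter(schedules.values())))
    out = {c: np.empty(n_t) for c in schedules}
    for j in range(n_t):
        y = np.zeros_like(x)
        for b in fc.bands:
            y = y + schedules[b.center_cm1][j] * _gauss(x, b.center_cm1, b.sigma_cm1)
        y_lo, y_hi = np.interp(lo, x, y), np.interp(hi, x, y)
        inside = (x >= lo) & (x <= hi)
        xs = np.concatenate([[lo], x[inside], [hi]])
        ys = np.concatenate([[y_lo], y[inside], [y_hi]])
        line = y_lo + (y_hi - y_lo) * (xs - lo) / (hi - lo)
        corr = ys - line
        area = np.trapezoid(corr, xs)
        norm = corr * (target_area / area)
        for c in schedules:
            out[c][j] = np.interp(c, xs, norm)
    return out


def gen_ftir_series(
    cfg: GeneratorConfig,
    trajectory: KineticTrajectory,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumSeries, Spectrum, dict]:
    """Forward-model an FTIR reaction series from a kinetic trajectory.

    absorbance(nu, t) = sum_b A_b(t) Gauss(nu; c_b, sigma_b)
                        + baseline(nu) + enzyme(nu) + noise

    Structure-band amplitudes follow the configured secondary-structure
    prediction evaluated on the trajectory; product-band amplitudes follow
    N(t).  Returns (series, enzyme reference spectrum, truth record).

    The truth record carries both the raw amplitude schedules A_b(t) and
    ``normalized_traces``: the exact difference-spectrum values the
    processing chain recovers at each band in the noiseless limit (the
    equal-area normalization and band overlap make raw amplitudes
    unobservable as-is).
    """
    rng = cfg.rng() if rng is None else rng
    fc = cfg.ftir
    t_s = np.asarray(fc.t_min, dtype=float) * 60.0
    if t_s[0] < trajectory.times[0] or t_s[-1] > trajectory.times[-1]:
        raise OutOfRangeError(
            f"requested times [{t_s[0]}, {t_s[-1]}] s outside trajectory span "
            f"[{trajectory.times[0]}, {trajectory.times[-1]}] s"
        )
    structure = np.interp(
        t_s,
        trajectory.times,
        predict_secondary_structure(trajectory, mode=fc.structure_mode),
    )
    product = np.interp(t_s, trajectory.times, trajectory.N)

    wn = fc.wavenumber_grid()
    baseline = fc.baseline_offset + fc.baseline_slope * (wn - fc.grid_min_cm1)
    enzyme_prof = fc.enzyme_amplitude * _gauss(wn, fc.enzyme_center_cm1,
                                               fc.enzyme_sigma_cm1)
    enzyme_ref = Spectrum(
        wavenumbers=wn.copy(),
        absorbance=enzyme_prof.copy(),
        meta={"label": "enzyme_reference"},
    )

    schedules: dict[float, np.ndarray] = {}
    for b in cfg.ftir.bands:
        coupling = structure if b.couples == "structure" else product
        schedules[b.center_cm1] = b.offset + b.amplitude * coupling

    spectra = []
    for j, tm in enumerate(fc.t_min):
        ab = baseline + enzyme_prof
        for b in fc.bands:
            ab = ab + schedules[b.center_cm1][j] * _gauss(wn, b.center_cm1, b.sigma_cm1)
        if fc.noise_sigma > 0:
            ab = ab + rng.normal(0.0, fc.noise_sigma, size=wn.shape)
        spectra.append(
            Spectrum(wavenumbers=wn.copy(), absorbance=ab, meta={"t_min": tm})
        )
    series = SpectrumSeries(spectra=spectra, t_min=np.asarray(fc.t_min, dtype=float))
    norm = _normalized_band_truth(fc, wn, schedules)
    truth = {
        "schedules": schedules,
        "normalized_schedules": norm,
        "normalized_traces": {c: v - v[0] for c, v in norm.items()},
        "structure_mode": fc.structure_mode,
        "noise_sigma": fc.noise_sigma,
        "t_min": np.asarray(fc.t_min, dtype=float),
    }
    return series, enzyme_ref, truth


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Positive normal samples; negatives are resampled, not clipped, so
    the distribution stays smooth near zero."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def gen_particle_ensemble(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[ParticleEnsemble, dict]:
    """Sample a particle ensemble from the configured mixture model.

    Heights come from a Gaussian mixture (component per mode of the
    stopped-reaction height distribution), diameters from one truncated
    normal.  Returns the ensemble and the generating parameters as truth.
    """
    rng = cfg.rng() if rng is None else rng
    ac = cfg.afm
    n = ac.n_particles
    if n == 0:
        return ParticleEnsemble(particles=[], label=ac.label), {"config": ac}
    comp = rng.choice(len(ac.height_weights), size=n, p=np.asarray(ac.height_weights))
    heights = np.empty(n)
    for k in range(len(ac.height_weights)):
        mask = comp == k
        if mask.any():
            heights[mask] = _truncated_normal(
                rng, ac.height_means_nm[k], ac.height_sds_nm[k], int(mask.sum())
            )
    diameters = _truncated_normal(rng, ac.diameter_mean_nm, ac.diameter_sd_nm, n)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # tall-thin samples (H > D) are possible draws; the warning is for
        # real data entry, not for the generator's own output
        _warnings.simplefilter("ignore")
        ens = ParticleEnsemble.from_arrays(heights, diameters, label=ac.label)
    truth = {"config": ac, "component": comp}
    return ens, truth
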