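"""FTIR difference-spectrum processing for proteolysis monitoring.

Implements the standard amide-region processing chain for reaction series
recorded in a thermostatted transmission cell:

1. subtract the enzyme-solution spectrum from each reaction spectrum;
2. subtract a straight baseline through the anchor points at
   1725 and 1375 cm^-1 and keep only that window;
3. normalize every spectrum to equal area over the window;
4. subtract the first spectrum of the series (t = 1 min) to obtain
   difference spectra;
5. read band intensities off the difference spectra.

Band conventions (amide I and carboxylate region): beta-sheet ~1633 cm^-1,
alpha-helix ~1650 cm^-1, antisymmetric/symmetric free-carboxylate
stretches ~1593 / ~1405 cm^-1 (the product signal).  "Delta absorbance" is
(spectrum at t) - (spectrum at 1 min), so structure loss is negative and
product growth positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyInputError,
    GridMismatchError,
    InvalidGridError,
    NormalizationError,
    OutOfRangeError,
    StageError,
)

__all__ = [
    "Spectrum",
    "SpectrumSeries",
    "BandTrace",
    "DEFAULT_ANCHORS",
    "DEFAULT_BANDS",
    "subtract_reference",
    "baseline_correct",
    "normalize_area",
    "difference_series",
    "band_timecourse",
    "process_reaction_series",
    "regrid",
]

#: Baseline anchor wavenumbers, cm^-1 (high, low).
DEFAULT_ANCHORS: tuple[float, float] = (1725.0, 1375.0)

#: Default band read-off positions, cm^-1.
DEFAULT_BANDS: tuple[float, ...] = (1633.0, 1650.0, 1593.0)


@dataclass
class Spectrum:
    """A single absorbance spectrum on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray  # cm^-1
    absorbance: np.ndarray  # AU
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        wn, ab = self.wavenumbers, self.absorbance
        if wn.ndim != 1 or wn.size < 2:
            raise InvalidGridError("wavenumber grid must be 1-D with >= 2 points")
        if ab.shape != wn.shape:
            raise InvalidGridError(
                f"absorbance shape {ab.shape} != grid shape {wn.shape}"
            )
        if np.any(~np.isfinite(wn)) or np.any(~np.isfinite(ab)):
            raise InvalidGridError("spectrum contains NaN or infinite values")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidGridError("wavenumber grid must be strictly monotone")

    @property
    def ascending(self) -> bool:
        return bool(self.wavenumbers[1] > self.wavenumbers[0])

    def _asc(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid and absorbance in ascending wavenumber order."""
        if self.ascending:
            return self.wavenumbers, self.absorbance
        return self.wavenumbers[::-1], self.absorbance[::-1]

    def value_at(self, wn: float) -> float:
        """Absorbance at a wavenumber, linearly interpolated between the two
        nearest grid points (grid-resolution independent read-off)."""
        x, y = self._asc()
        if wn < x[0] or wn > x[-1]:
            raise OutOfRangeError(
                f"{wn} cm^-1 outside grid span [{x[0]}, {x[-1]}] cm^-1"
            )
        return float(np.interp(wn, x, y))

    def window_area(self, window: tuple[float, float] = DEFAULT_ANCHORS) -> float:
        """Signed trapezoidal integral of absorbance over the window, AU*cm^-1."""
        hi, lo = max(window), min(window)
        x, y = self._asc()
        if lo < x[0] or hi > x[-1]:
            raise OutOfRangeError(
                f"window [{lo}, {hi}] exceeds grid span [{x[0]}, {x[-1]}]"
            )
        inside = (x >= lo) & (x <= hi)
        xs = x[inside]
        ys = y[inside]
        # include exact window edges by interpolation
        if xs.size == 0 or xs[0] > lo:
            xs = np.concatenate([[lo], xs])
            ys = np.concatenate([[np.interp(lo, x, y)], ys])
        if xs[-1] < hi:
            xs = np.concatenate([xs, [hi]])
            ys = np.concatenate([ys, [np.interp(hi, x, y)]])
        return float(np.trapezoid(ys, xs))


@dataclass
class SpectrumSeries:
    """Time-ordered spectra sharing one wavenumber grid."""

    spectra: list[Spectrum]
    t_min: np.ndarray  # acquisition times, minutes

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        if len(self.spectra) == 0:
            raise EmptyInputError("spectrum series is empty")
        if self.t_min.shape != (len(self.spectra),):
            raise InvalidGridError("t_min length must equal number of spectra")
        if self.t_min.size > 1 and np.any(np.diff(self.t_min) <= 0):
            raise InvalidGridError("acquisition times must be strictly increasing")
        grid = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise GridMismatchError(
                    "all spectra in a series must share an identical grid; "
                    "use regrid() explicitly"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def __len__(self) -> int:
        return len(self.spectra)

    def map(self, fn, stage: str | None = None) -> "SpectrumSeries":
        """Apply a Spectrum -> Spectrum operation to every member."""
        out = []
        for s in self.spectra:
            try:
                out.append(fn(s))
            except Exception as exc:  # attach stage name for diagnosability
                if stage is not None:
                    raise StageError(stage, exc) from exc
                raise
        return SpectrumSeries(spectra=out, t_min=self.t_min.copy())

    def to_frame(self):
        """Wide DataFrame: wavenumber_cm1 column + one t_<minutes> column per time."""
        import pandas as pd

        data = {"wavenumber_cm1": self.wavenumbers}
        for s, t in zip(self.spectra, self.t_min):
            data[f"t_{t:g}"] = s.absorbance
        return pd.DataFrame(data)


@dataclass
class BandTrace:
    """Difference-spectrum intensity vs time at one band position."""

    t_min: np.ndarray
    delta_abs: np.ndarray  # AU
    band_cm1: float

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.delta_abs = np.asarray(self.delta_abs, dtype=float)
        if self.t_min.shape != self.delta_abs.shape:
            raise InvalidGridError("t_min and delta_abs must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_min": self.t_min, "delta_abs": self.delta_abs})


# ---------------------------------------------------------------------------
# processing operations
# ---------------------------------------------------------------------------


def subtract_reference(mixture: Spectrum, reference: Spectrum) -> Spectrum:
    """Subtract the enzyme-solution reference spectrum pointwise.

    Grids must be identical; no silent interpolation is performed (call
    :func:`regrid` first if they differ).
    """
    if not np.array_equal(mixture.wavenumbers, reference.wavenumbers):
        raise GridMismatchError(
            "mixture and reference grids differ; regrid() explicitly first"
        )
    meta = dict(mixture.meta)
    meta["reference"] = reference.meta.get("label", "enzyme_reference")
    return Spectrum(
        wavenumbers=mixture.wavenumbers.copy(),
        absorbance=mixture.absorbance - reference.absorbance,
        meta=meta,
    )


def baseline_correct(
    s: Spectrum, anchors: tuple[float, float] = DEFAULT_ANCHORS
) -> Spectrum:
    """Two-anchor linear baseline correction.

    A straight line through the spectrum's values at the two anchor
    wavenumbers is subtracted, and only the window between the anchors is
    returned.  The output is exactly zero at both anchors.
    """
    hi, lo = max(anchors), min(anchors)
    x, y = s._asc()
    if lo < x[0] or hi > x[-1]:
        raise OutOfRangeError(
            f"anchors ({lo}, {hi}) cm^-1 outside grid span [{x[0]}, {x[-1]}]"
        )
    y_lo = np.interp(lo, x, y)
    y_hi = np.interp(hi, x, y)
    inside = (x >= lo) & (x <= hi)
    xs = x[inside]
    ys = y[inside]
    if xs.size == 0 or xs[0] > lo:
        xs = np.concatenate([[lo], xs])
        ys = np.concatenate([[y_lo], ys])
    if xs[-1] < hi:
        xs = np.concatenate([xs, [hi]])
        ys = np.concatenate([ys, [y_hi]])
    line = y_lo + (y_hi - y_lo) * (xs - lo) / (hi - lo)
    corrected = ys - line
    if not s.ascending:
        xs, corrected = xs[::-1], corrected[::-1]
    meta = dict(s.meta)
    meta["baseline_anchors_cm1"] = (hi, lo)
    return Spectrum(wavenumbers=xs, absorbance=corrected, meta=meta)


def normalize_area(
    s: Spectrum,
    window: tuple[float, float] = DEFAULT_ANCHORS,
    target_area: float = 1.0,
) -> Spectrum:
    """Scale the spectrum so its signed trapezoidal area over the window
    equals ``target_area`` (default 1 AU*cm^-1).

    The area is signed, not absolute: a baseline-corrected amide window is
    non-negative in practice, and a non-positive area signals an upstream
    problem rather than something to silently rectify.
    """
    if target_area <= 0:
        raise NormalizationError(f"target_area must be > 0, got {target_area}")
    area = s.window_area(window)
    if area <= 0:
        raise NormalizationError(
            f"window area {area:.4g} AU*cm^-1 is not positive; "
            "normalization impossible"
        )
    meta = dict(s.meta)
    meta["area_normalized_to"] = target_area
    return Spectrum(
        wavenumbers=s.wavenumbers.copy(),
        absorbance=s.absorbance * (target_area / area),
        meta=meta,
    )


def difference_series(series: SpectrumSeries) -> SpectrumSeries:
    """Subtract the first spectrum (t = 1 min convention) from every member.

    The first difference spectrum is identically zero by construction.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot difference an empty series")
    ref = series.spectra[0]
    out = []
    for s in series.spectra:
        meta = dict(s.meta)
        meta["difference_vs_t_min"] = float(series.t_min[0])
        out.append(
            Spectrum(
                wavenumbers=s.wavenumbers.copy(),
                absorbance=s.absorbance - ref.absorbance,
                meta=meta,
            )
        )
    return SpectrumSeries(spectra=out, t_min=series.t_min.copy())


def band_timecourse(diff_series: SpectrumSeries, band_cm1: float) -> BandTrace:
    """Difference-spectrum intensity vs time at one band position,
    linearly interpolated between the two nearest grid points."""
    vals = np.array([s.value_at(band_cm1) for s in diff_series.spectra])
    return BandTrace(t_min=diff_series.t_min.copy(), delta_abs=vals, band_cm1=band_cm1)


def process_reaction_series(
    raw_series: SpectrumSeries,
    enzyme_reference: Spectrum,
    bands: tuple[float, ...] = DEFAULT_BANDS,
    anchors: tuple[float, float] = DEFAULT_ANCHORS,
) -> dict[float, BandTrace]:
    """Full processing chain: reference subtraction, two-anchor baseline,
    equal-area normalization, first-spectrum differencing, band read-off.

    The stage order is fixed (it is not commutative: normalizing before
    baseline correction redistributes the baseline into the scale factor).
    Errors are re-raised with the failing stage name attached.
    """
    series = raw_series.map(
        lambda s: subtract_reference(s, enzyme_reference), stage="subtract_reference"
    )
    series = series.map(lambda s: baseline_correct(s, anchors), stage="baseline_correct")
    series = series.map(
        lambda s: normalize_area(s, window=anchors), stage="normalize_area"
    )
    try:
        diffs = difference_series(series)
    except Exception as exc:
        raise StageError("difference_series", exc) from exc
    traces: dict[float, BandTrace] = {}
    for band in bands:
        try:
            traces[band] = band_timecourse(diffs, band)
        except Exception as exc:
            raise StageError("band_timecourse", exc) from exc
    return traces


def regrid(s: Spectrum, new_wavenumbers: np.ndarray) -> Spectrum:
    """Linear interpolation onto a new grid (the only sanctioned resampling
    path; series operations never resample implicitly)."""
    new = np.asarray(new_wavenumbers, dtype=float)
    x, y = s._asc()
    if new.min() < x[0] or new.max() > x[-1]:
        raise OutOfRangeError("new grid extends beyond the original span")
    d = np.diff(new)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise InvalidGridError("new grid must be strictly monotone")
    asc_new = new if d[0] > 0 else new[::-1]
    vals = np.interp(asc_new, x, y)
    if d[0] < 0:
        vals = vals[::-1]
    meta = dict(s.meta)
    meta["regridded"] = True
    return Spectrum(wavenumbers=new, absorbance=vals, meta=meta)
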