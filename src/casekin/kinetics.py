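"""Three-stage kinetic model of tryptic proteolysis of beta-casein micelles.

The reaction scheme is a linear compartment chain

    S --k1*E0--> X --k2--> Y --k3*E0--> N
                           |
                           +--ka*E0--> Z   (aggregation branch, default off)

where S are intact micelles, X micelles with hydrolyzed peptide bonds,
Y new nanoparticles reassembled from micelle fragments, N soluble peptide
products and Z large aggregates.  The first and third stage rates scale
with the enzyme concentration E0 (trypsin, mg/L); the second stage —
rearrangement of the hydrolyzed micelle into new nanoparticles — is a
property of the substrate and does not depend on E0.  All species are
fractions of the initial micellar substrate (S0 = 1).

The chain admits closed-form (Bateman-type) solutions for distinct
effective rates; a high-order Runge-Kutta integrator covers the general
case including coincident rates and the aggregation branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .errors import (
    DegenerateRatesError,
    IntegrationError,
    InvalidGridError,
    InvalidParameterError,
    RootNotFoundError,
)

__all__ = [
    "RateConstants",
    "EnzymeSetting",
    "KineticTrajectory",
    "TmaxObservation",
    "species_closed_form",
    "y_concentration",
    "dy_dt_expression",
    "tmax_from_constants",
    "fit_k2",
    "FitResult",
    "predict_secondary_structure",
    "ode_oracle",
    "product_lag_time",
    "interior_local_max_time",
    "RATE_COINCIDENCE_RTOL",
]

#: Relative tolerance below which two effective rates are treated as
#: coincident and the closed form (whose denominators vanish) is abandoned
#: in favour of numerical integration.
RATE_COINCIDENCE_RTOL = 1e-10


@dataclass(frozen=True)
class RateConstants:
    """Rate coefficients of the three-stage proteolysis chain.

    Parameters
    ----------
    k1 : float
        First-stage coefficient, s^-1 per (mg/L of enzyme).  The effective
        rate of micelle hydrolysis is ``k1 * E0``.
    k2 : float
        Second-stage rate, s^-1.  Enzyme-independent: the rearrangement of
        hydrolyzed micelles into new nanoparticles is substrate-driven.
    k3 : float
        Third-stage coefficient, s^-1 per (mg/L).  Effective degradation
        rate of nanoparticles into peptide products is ``k3 * E0``.
    ka : float, optional
        Aggregation coefficient for the Y -> Z branch, default 0 (branch
        off).  Whether aggregation scales with enzyme concentration is not
        settled; ``ka_enzyme_proportional`` controls the convention
        (default True, so the effective rate is ``ka * E0``).
    """

    k1: float
    k2: float
    k3: float
    ka: float = 0.0
    ka_enzyme_proportional: bool = True

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "ka"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")

    @classmethod
    def from_effective(
        cls,
        k1E0: float,
        k2: float,
        k3E0: float,
        E0: float,
        ka: float = 0.0,
        ka_enzyme_proportional: bool = True,
    ) -> "RateConstants":
        """Build from the effective first/third-stage rates measured at a
        reference enzyme concentration ``E0`` (the form in which the model
        constants are usually reported)."""
        if E0 <= 0 or not np.isfinite(E0):
            raise InvalidParameterError(f"E0 must be > 0, got {E0!r}")
        return cls(
            k1=k1E0 / E0,
            k2=k2,
            k3=k3E0 / E0,
            ka=ka,
            ka_enzyme_proportional=ka_enzyme_proportional,
        )

    def effective(self, E0: float) -> tuple[float, float, float, float]:
        """Effective rates ``(k1*E0, k2, k3*E0, ka_eff)`` at enzyme
        concentration ``E0``."""
        ka_eff = self.ka * E0 if self.ka_enzyme_proportional else self.ka
        return self.k1 * E0, self.k2, self.k3 * E0, ka_eff

    def with_k2(self, k2: float) -> "RateConstants":
        return replace(self, k2=k2)


@dataclass(frozen=True)
class EnzymeSetting:
    """Enzyme concentration and (normalized) substrate bookkeeping.

    All model species are fractions of the initial substrate, so S0 is 1
    by construction; ``s0_over_e0`` is retained only as w/w bookkeeping.
    """

    E0: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.E0) or self.E0 <= 0:
            raise InvalidParameterError(f"E0 must be > 0, got {self.E0!r}")
        if self.S0 != 1.0:
            raise InvalidParameterError(
                "closed-form computations assume S0 = 1 (species are fractions)"
            )

    @property
    def s0_over_e0(self) -> float:
        return self.S0 / self.E0


@dataclass
class KineticTrajectory:
    """Time grid plus species fractions of the proteolysis chain."""

    times: np.ndarray
    S: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    N: np.ndarray
    Z: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("S", "X", "Y", "N"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)

    @property
    def z_or_zero(self) -> np.ndarray:
        return self.Z if self.Z is not None else np.zeros_like(self.times)

    def total(self) -> np.ndarray:
        """Mass balance S+X+Y+N(+Z); equals 1 at every grid point."""
        return self.S + self.X + self.Y + self.N + self.z_or_zero

    def to_frame(self):
        """Trajectory as a pandas DataFrame (columns t_s, S, X, Y, N, Z)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.times,
                "S": self.S,
                "X": self.X,
                "Y": self.Y,
                "N": self.N,
                "Z": self.z_or_zero,
            }
        )


@dataclass(frozen=True)
class TmaxObservation:
    """One observed (enzyme concentration, nanoparticle-peak time) pair."""

    E0: float
    tmax: float

    def __post_init__(self) -> None:
        if self.E0 <= 0 or not np.isfinite(self.E0):
            raise InvalidParameterError(f"E0 must be > 0, got {self.E0!r}")
        if self.tmax <= 0 or not np.isfinite(self.tmax):
            raise InvalidParameterError(f"tmax must be > 0, got {self.tmax!r}")


# ---------------------------------------------------------------------------
# grid and degeneracy helpers
# ---------------------------------------------------------------------------


def _validate_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1 or t.size == 0:
        raise InvalidGridError("time grid must be a non-empty 1-D array")
    if np.any(~np.isfinite(t)):
        raise InvalidGridError("time grid contains NaN or infinite values")
    if np.any(t < 0):
        raise InvalidGridError("time grid contains negative times")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise InvalidGridError("time grid must be strictly increasing")
    return t


def _rates_degenerate(a: float, b: float, c: float) -> bool:
    """True if any pair of effective rates coincides within
    RATE_COINCIDENCE_RTOL (relative)."""
    for u, v in ((a, b), (a, c), (b, c)):
        scale = max(abs(u), abs(v))
        if scale == 0.0 or abs(u - v) < RATE_COINCIDENCE_RTOL * scale:
            return True
    return False


# ---------------------------------------------------------------------------
# closed-form solutions
# ---------------------------------------------------------------------------


def y_concentration(rc: RateConstants, env: EnzymeSetting, t) -> np.ndarray | float:
    """Nanoparticle fraction Y(t) from the three-exponential closed form.

    With a = k1*E0, b = k2, c = k3*E0 (all distinct, S0 = 1):

        Y(t) = a*b * [ exp(-a t) / ((b-a)(c-a))
                     + exp(-b t) / ((b-c)(b-a))
                     + exp(-c t) / ((c-a)(c-b)) ]

    Y rises from 0, peaks at ``tmax`` and decays back to 0: the
    nanoparticle population is transient, created by stage 2 and consumed
    by stage 3.

    Raises
    ------
    DegenerateRatesError
        If any two effective rates coincide within tolerance; use
        :func:`ode_oracle` for that regime.
    """
    a, b, c, _ = rc.effective(env.E0)
    if _rates_degenerate(a, b, c):
        raise DegenerateRatesError(
            f"effective rates coincide (k1E0={a}, k2={b}, k3E0={c}); "
            "use ode_oracle for degenerate rates"
        )
    t_arr = np.asarray(t, dtype=float)
    y = (
        a
        * b
        * (
            np.exp(-a * t_arr) / ((b - a) * (c - a))
            + np.exp(-b * t_arr) / ((b - c) * (b - a))
            + np.exp(-c * t_arr) / ((c - a) * (c - b))
        )
    )
    return y if np.ndim(t) else float(y)


def dy_dt_expression(rc: RateConstants, env: EnzymeSetting, t) -> np.ndarray | float:
    """The transcendental expression whose positive root is t_max.

    Proportional to dY/dt of the closed form:

        k1E0 (k3E0 - k2) e^{-k1E0 t}
        - k2 (k3E0 - k1E0) e^{-k2 t}
        - k3E0 (k1E0 - k2) e^{-k3E0 t}

    Vanishes identically at t = 0 (both X and Y start at zero), so the
    physically meaningful root is the interior one.
    """
    a, b, c, _ = rc.effective(env.E0)
    t_arr = np.asarray(t, dtype=float)
    val = (
        a * (c - b) * np.exp(-a * t_arr)
        - b * (c - a) * np.exp(-b * t_arr)
        - c * (a - b) * np.exp(-c * t_arr)
    )
    return val if np.ndim(t) else float(val)


def species_closed_form(
    rc: RateConstants, env: EnzymeSetting, times
) -> KineticTrajectory:
    """Closed-form trajectory of all species for the ka = 0 chain.

    S(t) = exp(-a t);  X(t) = a/(b-a) (exp(-a t) - exp(-b t));
    Y(t) per :func:`y_concentration`;  N(t) = 1 - S - X - Y, which makes
    conservation exact by construction.

    Falls back to the numerical integrator when effective rates coincide
    within ``RATE_COINCIDENCE_RTOL`` (the closed-form denominators vanish).
    """
    if rc.ka != 0.0:
        raise InvalidParameterError(
            "closed form covers the ka = 0 chain; use ode_oracle for ka > 0"
        )
    t = _validate_times(times)
    a, b, c, _ = rc.effective(env.E0)
    if _rates_degenerate(a, b, c):
        return ode_oracle(rc, env, t)
    S = np.exp(-a * t)
    X = a / (b - a) * (np.exp(-a * t) - np.exp(-b * t))
    Y = np.asarray(y_concentration(rc, env, t))
    N = 1.0 - S - X - Y
    return KineticTrajectory(
        times=t, S=S, X=X, Y=Y, N=N, Z=None, meta={"method": "closed_form", "E0": env.E0}
    )


# ---------------------------------------------------------------------------
# numerical oracle
# ---------------------------------------------------------------------------


def ode_oracle(rc: RateConstants, env: EnzymeSetting, times) -> KineticTrajectory:
    """Numerically integrate the full chain, including the aggregation
    branch (ka > 0) and coincident rates.

        dS/dt = -k1E0 S
        dX/dt =  k1E0 S - k2 X
        dY/dt =  k2 X - (k3E0 + ka_eff) Y
        dN/dt =  k3E0 Y
        dZ/dt =  ka_eff Y

    Uses an 8th-order Runge-Kutta scheme at tight tolerances; serves as
    the independent oracle for the closed form and as the fallback for
    degenerate rates.
    """
    t = _validate_times(times)
    a, b, c, ka_eff = rc.effective(env.E0)

    def rhs(_t, y):
        S, X, Y, _N, _Z = y
        return [
            -a * S,
            a * S - b * X,
            b * X - (c + ka_eff) * Y,
            c * Y,
            ka_eff * Y,
        ]

    t0, t1 = 0.0, float(t[-1]) if t[-1] > 0 else 1.0
    sol = solve_ivp(
        rhs,
        (t0, t1),
        [1.0, 0.0, 0.0, 0.0, 0.0],
        t_eval=t,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    S, X, Y, N, Z = sol.y
    return KineticTrajectory(
        times=t,
        S=S,
        X=X,
        Y=Y,
        N=N,
        Z=Z if ka_eff > 0 else None,
        meta={"method": "ode_dop853", "E0": env.E0},
    )


# ---------------------------------------------------------------------------
# t_max
# ---------------------------------------------------------------------------


def tmax_from_constants(rc: RateConstants, env: EnzymeSetting) -> float:
    """Time at which the nanoparticle fraction Y(t) peaks.

    Solves the transcendental dY/dt = 0 condition by bracketing the
    interior sign change of :func:`dy_dt_expression` on a log-spaced scan
    of (0, 10/min(rates)], then polishing with Brent's method.

    Raises
    ------
    RootNotFoundError
        If no sign change is found on the scanned bracket (reported).
    DegenerateRatesError
        If effective rates coincide (closed-form condition invalid); the
        peak can still be located via ode_oracle + grid argmax.
    """
    a, b, c, _ = rc.effective(env.E0)
    if a <= 0 or b <= 0 or c <= 0:
        raise InvalidParameterError(
            f"t_max requires strictly positive rates, got ({a}, {b}, {c})"
        )
    if _rates_degenerate(a, b, c):
        raise DegenerateRatesError(
            "t_max condition assumes distinct effective rates; "
            "locate the peak numerically for coincident rates"
        )
    rates = (a, b, c)
    t_lo = 1e-3 / max(rates)
    t_hi = 10.0 / min(rates)
    grid = np.geomspace(t_lo, t_hi, 400)
    vals = np.asarray(dy_dt_expression(rc, env, grid))
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise RootNotFoundError(
            f"no sign change of the t_max condition on [{t_lo:.3g}, {t_hi:.3g}] s",
            bracket=(t_lo, t_hi),
        )
    i = idx[0]
    root = brentq(
        lambda tt: dy_dt_expression(rc, env, tt),
        grid[i],
        grid[i + 1],
        xtol=1e-12,
        rtol=1e-14,
    )
    return float(root)


# ---------------------------------------------------------------------------
# k2 fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Result of the k2 least-squares fit with per-point diagnostics."""

    k2: float
    sse: float
    residuals: np.ndarray  # observed - predicted tmax, s
    predicted: np.ndarray  # model tmax at each E0, s
    observations: list[TmaxObservation]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "E0_mg_per_L": [o.E0 for o in self.observations],
                "tmax_obs_s": [o.tmax for o in self.observations],
                "tmax_fit_s": self.predicted,
                "residual_s": self.residuals,
            }
        )


def fit_k2(
    observations: list[TmaxObservation],
    k1: float,
    k3: float,
    bounds: tuple[float, float] = (1e-6, 1.0),
) -> FitResult:
    """Fit the enzyme-independent rearrangement rate k2 from observed
    (E0, t_max) pairs with k1 and k3 held fixed.

    Minimizes the sum of squared residuals between observed peak times and
    the model's t_max at each enzyme concentration (bounded 1-D scalar
    minimization).  With a single noiseless observation the inversion is
    exact (zero residual).
    """
    if not observations:
        raise InvalidParameterError("at least one t_max observation is required")
    if k1 <= 0 or k3 <= 0:
        raise InvalidParameterError("k1 and k3 must be fixed and positive")
    e0s = [o.E0 for o in observations]
    if len(set(e0s)) == 1 and len(observations) > 1:
        tmaxs = {o.tmax for o in observations}
        if len(tmaxs) > 1:
            warnings.warn(
                "all observations share one E0 with inconsistent tmax; "
                "returning the least-squares optimum anyway",
                stacklevel=2,
            )

    def predict(k2: float) -> np.ndarray:
        rc = RateConstants(k1=k1, k2=k2, k3=k3)
        return np.array(
            [tmax_from_constants(rc, EnzymeSetting(E0=o.E0)) for o in observations]
        )

    obs = np.array([o.tmax for o in observations])

    def sse(k2: float) -> float:
        try:
            return float(np.sum((obs - predict(k2)) ** 2))
        except (RootNotFoundError, DegenerateRatesError):
            return np.inf  # penalize pathological k2 during the search

    res = minimize_scalar(
        sse, bounds=bounds, method="bounded", options={"xatol": 1e-12}
    )
    k2_hat = float(res.x)
    pred = predict(k2_hat)
    return FitResult(
        k2=k2_hat,
        sse=float(res.fun),
        residuals=obs - pred,
        predicted=pred,
        observations=list(observations),
    )


# ---------------------------------------------------------------------------
# derived predictions
# ---------------------------------------------------------------------------

SS_MODES = ("S_plus_Y", "S_plus_halfX_plus_Y")


def predict_secondary_structure(
    traj: KineticTrajectory, mode: str = "S_plus_halfX_plus_Y"
) -> np.ndarray:
    """Predicted overall secondary-structure content, as a fraction of the
    initial structure.

    Two retention hypotheses:

    - ``"S_plus_Y"``: regular structure survives only in intact micelles
      and in the reassembled nanoparticles -> S + Y.
    - ``"S_plus_halfX_plus_Y"``: hydrolyzed micelles additionally retain
      half of their structure -> S + X/2 + Y.  This variant tracks the
      measured beta-sheet/alpha-helix time courses more closely and is
      the default.

    Both start at 1 and decay to 0 once all mass reaches the products
    (ka = 0); at low enzyme the curve shows an interior local maximum as
    nanoparticles transiently accumulate.
    """
    if mode == "S_plus_Y":
        return traj.S + traj.Y
    if mode == "S_plus_halfX_plus_Y":
        return traj.S + traj.X / 2.0 + traj.Y
    raise InvalidParameterError(f"unknown mode {mode!r}; expected one of {SS_MODES}")


def product_lag_time(
    traj: KineticTrajectory, threshold: float = 0.05
) -> float:
    """Lag time of product release: first time N(t) reaches ``threshold``,
    linearly interpolated between grid points.

    Returns ``inf`` (with a warning) if N never reaches the threshold on
    the grid.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    if threshold == 0:
        return 0.0
    N, t = traj.N, traj.times
    above = np.nonzero(N >= threshold)[0]
    if above.size == 0:
        warnings.warn(
            f"N never reaches threshold {threshold} on the grid "
            f"(max N = {N.max():.4g}); lag is beyond the grid",
            stacklevel=2,
        )
        return float("inf")
    i = above[0]
    if i == 0:
        return float(t[0])
    # linear interpolation on the bracketing segment
    t0, t1 = t[i - 1], t[i]
    n0, n1 = N[i - 1], N[i]
    if n1 == n0:
        return float(t1)
    return float(t0 + (threshold - n0) * (t1 - t0) / (n1 - n0))


def interior_local_max_time(times: np.ndarray, values: np.ndarray) -> float | None:
    """Time of the first interior local maximum that follows an initial
    decline (the transient structure-recovery bump of S + X/2 + Y).

    Returns None when the curve decays monotonically (no interior
    maximum, e.g. at very high enzyme concentration).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size < 3:
        return None
    dv = np.diff(v)
    # first strict rise after the initial decline
    falling = np.nonzero(dv < 0)[0]
    if falling.size == 0:
        return None
    start = falling[0]
    rising = np.nonzero(dv[start:] > 0)[0]
    if rising.size == 0:
        return None
    rise_at = start + rising[0]
    # peak: first downturn after the rise
    down = np.nonzero(dv[rise_at:] <= 0)[0]
    if down.size == 0:
        return None
    peak_idx = rise_at + down[0]
    return float(t[peak_idx])
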