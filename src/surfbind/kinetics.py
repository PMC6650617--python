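"""Hydrogen-bond existence autocorrelation, rate analysis, and free energies.

The bond-existence function h(t) (1 when the bond satisfies the geometric
criteria, 0 otherwise) is converted into an autocorrelation function,
fitted with a sum of exponentials, and integrated to give the relaxation
time tau_R. Breaking/reforming rate constants (k, k') follow the
Luzar-Chandler picture via least squares on -dC/dt = k*C - k'*N, where
N(t) is the crossing correlation <h(0)(1-h(t))>/<h> (the bond is broken at
t but the pair is still available to re-form; this estimator treats every
originally bonded pair as available, the appropriate contract for bound
protein-ligand pairs).

The free energy of breaking a bond uses the Eyring (transition-state)
form applied to the relaxation time:

    dG = R*T*ln(k_B*T*tau_R / h)

with CODATA k_B and h and R = 8.314 J mol^-1 K^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .contacts import HBondSeries

__all__ = [
    "BOLTZMANN_J_PER_K",
    "PLANCK_J_S",
    "GAS_CONSTANT_J_PER_MOL_K",
    "Autocorrelation",
    "RelaxationFit",
    "HBondKinetics",
    "autocorrelation",
    "crossing_correlation",
    "fit_relaxation",
    "mean_lifetime",
    "luzar_chandler_rates",
    "eyring_free_energy",
    "analyze_kinetics",
]

BOLTZMANN_J_PER_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
GAS_CONSTANT_J_PER_MOL_K = 8.314

_ESTIMATORS = ("fluctuation", "intermittent", "continuous")


@dataclass
class Autocorrelation:
    """Normalized bond-existence correlation on a lag grid (ps)."""

    lags: np.ndarray
    values: np.ndarray
    estimator: str

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if np.any(self.lags < 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be nonnegative and increasing")


@dataclass
class RelaxationFit:
    """Multi-exponential fit of an autocorrelation.

    ``tau_r`` is the integral of the fitted decay, sum(a_i * tau_i), with
    the amplitudes constrained to the simplex (a_i >= 0, sum a_i = 1).
    """

    tau_r: float
    taus: np.ndarray
    amplitudes: np.ndarray
    residual_rms: float
    window: tuple[float, float]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        )


@dataclass
class HBondKinetics:
    """Per-complex hydrogen-bond kinetics and thermodynamics summary."""

    lifetime: float          # ps, mean continuous on-segment duration
    relaxation_time: float   # ps, integral of the ACF fit
    k_forward: float         # ps^-1, breaking
    k_backward: float        # ps^-1, reforming
    free_energy: float       # kJ/mol, Eyring dG of breaking
    temperature: float       # K


def _pooled_raw_correlation(
    matrix: np.ndarray, max_lag: int
) -> tuple[np.ndarray, float]:
    """<h(0)h(t)> pooled over bonds and time origins, lags 0..max_lag."""
    n = matrix.shape[1]
    num = np.zeros(max_lag + 1)
    for row in matrix.astype(float):
        acf_full = fftconvolve(row, row[::-1])
        num += acf_full[n - 1 : n + max_lag]
    origins = matrix.shape[0] * (n - np.arange(max_lag + 1))
    hbar = float(matrix.mean())
    # fftconvolve is O(n log n) but accumulates ~1e-10 absolute noise;
    # round to the nearest count since h is 0/1
    return np.round(num) / origins, hbar


def autocorrelation(
    series: HBondSeries,
    estimator: str = "fluctuation",
    max_lag: int | None = None,
) -> Autocorrelation:
    """Bond-existence autocorrelation averaged over bonds and time origins.

    Estimators:

    - ``fluctuation``: ``(<h0 ht> - <h>^2) / (<h>(1 - <h>))`` — decays from
      1 to 0, the default for exponential fitting.
    - ``intermittent``: ``<h0 ht> / <h>`` — the raw survival measure, which
      plateaus at <h> for a stationary series.
    - ``continuous``: h is zeroed after the first break, so only unbroken
      stretches contribute.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}")
    matrix = series.matrix
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("need at least 2 frames")
    if n < 100:
        import warnings

        warnings.warn(
            "fewer than 100 frames; the autocorrelation will be noisy",
            stacklevel=2,
        )
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    lags = np.arange(max_lag + 1) * series.dt

    if estimator == "continuous":
        run_lengths = []
        for row in matrix:
            padded = np.concatenate(([0], row.astype(int), [0]))
            edges = np.diff(padded)
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            run_lengths.extend((ends - starts).tolist())
        L = np.sort(np.array(run_lengths))
        if L.size == 0:
            raise ValueError("series is never on; continuous ACF undefined")
        csum = np.concatenate(([0], np.cumsum(L)))
        total = csum[-1]
        m = np.arange(max_lag + 1)
        idx = np.searchsorted(L, m, side="right")
        s = (total - csum[idx]) - m * (L.size - idx)
        return Autocorrelation(lags, s / s[0], "continuous")

    raw, hbar = _pooled_raw_correlation(matrix, max_lag)
    if estimator == "intermittent":
        if hbar == 0:
            raise ValueError("series is never on; <h> = 0")
        return Autocorrelation(lags, raw / hbar, "intermittent")
    # fluctuation
    var = hbar * (1.0 - hbar)
    if var == 0:
        constant_rows = [
            series.bonds[i]
            for i in range(matrix.shape[0])
            if matrix[i].all() or not matrix[i].any()
        ]
        raise ValueError(
            "fluctuation normalization undefined for constant series; "
            f"constant bond(s): {constant_rows[:5]}"
        )
    return Autocorrelation(lags, (raw - hbar**2) / var, "fluctuation")


def crossing_correlation(
    series: HBondSeries, max_lag: int | None = None
) -> Autocorrelation:
    """N(t) = <h(0)(1 - h(t))> / <h>: bound at 0, broken at t.

    For the bound protein-ligand bonds treated here every originally
    bonded pair remains available to re-form, so no additional distance
    gate is applied; N complements the intermittent correlation,
    N(t) = 1 - C_int(t).
    """
    matrix = series.matrix
    n = matrix.shape[1]
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    raw, hbar = _pooled_raw_correlation(matrix, max_lag)
    if hbar == 0:
        raise ValueError("series is never on; <h> = 0")
    lags = np.arange(max_lag + 1) * series.dt
    return Autocorrelation(lags, 1.0 - raw / hbar, "crossing")


def _auto_window(acf: Autocorrelation) -> np.ndarray:
    """Default fit window: lags up to the first C(t) < 0.03 or 1/3 of the
    grid, whichever is smaller (tail noise otherwise dominates)."""
    below = np.flatnonzero(acf.values < 0.03)
    stop = below[0] + 1 if below.size else len(acf.lags)
    stop = min(stop, max(len(acf.lags) // 3, 6))
    return np.arange(min(stop, len(acf.lags)))


def fit_relaxation(
    acf: Autocorrelation,
    n_exponentials: int = 1,
    window: str | tuple[float, float] | None = "auto",
) -> RelaxationFit:
    """Nonlinear least-squares fit of sum(a_i exp(-t/tau_i)), sum(a_i) = 1.

    The relaxation time is the analytic integral of the fit,
    ``tau_R = sum(a_i * tau_i)``. ``window`` restricts the lags used:
    ``"auto"`` (default rule), ``None`` (all), or an explicit (lo, hi) ps.
    """
    if window == "auto":
        idx = _auto_window(acf)
    elif window is None:
        idx = np.arange(len(acf.lags))
    else:
        lo, hi = window
        idx = np.flatnonzero((acf.lags >= lo) & (acf.lags <= hi))
    t = acf.lags[idx]
    c = acf.values[idx]
    if np.count_nonzero(t > 0) < 5:
        raise ValueError("need at least 5 lag points beyond t = 0")

    # crude initial tau: first crossing of 1/e (linear interp), else span/3
    below = np.flatnonzero(c <= np.exp(-1.0))
    tau0 = float(t[below[0]]) if below.size and t[below[0]] > 0 else t[-1] / 3.0
    tau0 = max(tau0, acf.lags[1] if len(acf.lags) > 1 else 1.0)

    k = n_exponentials
    if k < 1:
        raise ValueError("n_exponentials must be >= 1")
    tau_init = np.geomspace(tau0 / (2.0**(k - 1)), tau0 * (2.0**(k - 1)), k)

    def unpack(params):
        taus = np.exp(params[:k])
        if k == 1:
            amps = np.ones(1)
        else:
            z = np.concatenate((params[k:], [0.0]))
            z = z - z.max()
            amps = np.exp(z) / np.exp(z).sum()
        return taus, amps

    def resid(params):
        taus, amps = unpack(params)
        model = np.sum(
            amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0
        )
        return model - c

    x0 = np.concatenate((np.log(tau_init), np.zeros(max(k - 1, 0))))
    result = least_squares(resid, x0, method="lm", max_nfev=20_000)
    if not result.success:
        raise RuntimeError(
            "relaxation fit did not converge; try fewer exponentials"
        )
    taus, amps = unpack(result.x)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    tau_r = float(np.sum(amps * taus))
    if not np.isfinite(tau_r) or tau_r <= 0:
        raise RuntimeError(
            "relaxation fit produced a non-positive time scale; try fewer "
            "exponentials"
        )
    return RelaxationFit(
        tau_r=tau_r,
        taus=taus,
        amplitudes=amps,
        residual_rms=float(np.sqrt(np.mean(result.fun**2))),
        window=(float(t[0]), float(t[-1])),
    )


def mean_lifetime(series: HBondSeries, estimator: str = "segments") -> float:
    """Mean hydrogen-bond lifetime tau_HB in ps.

    ``segments`` (default): mean duration of *completed* continuous
    on-segments, pooled over bonds; runs touching either end of the series
    are discarded as censored. ``acf_integral``: trapezoidal integral of
    the continuous autocorrelation (flagged alternative; depends on the
    available lag range).
    """
    if estimator == "acf_integral":
        acf = autocorrelation(series, "continuous")
        return float(np.trapezoid(acf.values, acf.lags))
    if estimator != "segments":
        raise ValueError("estimator must be 'segments' or 'acf_integral'")
    durations = []
    n = series.matrix.shape[1]
    for row in series.matrix:
        padded = np.concatenate(([0], row.astype(int), [0]))
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if s == 0 or e == n:  # censored at a series boundary
                continue
            durations.append(e - s)
    if not durations:
        raise ValueError("no completed on-segment in the series")
    return float(np.mean(durations) * series.dt)


def luzar_chandler_rates(
    C: Autocorrelation,
    N: Autocorrelation,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Breaking/reforming rate constants from -dC/dt = k*C - k'*N.

    C should be the intermittent correlation and N the crossing
    correlation on the same lag grid; the derivative is taken by central
    differences and (k, k') solved by linear least squares over the fitted
    window.
    """
    if C.lags.shape != N.lags.shape or not np.allclose(C.lags, N.lags):
        raise ValueError("C and N must share one lag grid")
    idx = np.arange(len(C.lags))
    if window is not None:
        lo, hi = window
        idx = np.flatnonzero((C.lags >= lo) & (C.lags <= hi))
    t = C.lags[idx]
    c = C.values[idx]
    nvals = N.values[idx]
    if len(t) < 3:
        raise ValueError("need at least 3 lag points")
    dcdt = np.gradient(c, t)
    design = np.column_stack((c, -nvals))
    rank = np.linalg.matrix_rank(design)
    if rank < 2:
        raise ValueError("singular normal equations: C and N are collinear")
    coef, *_ = np.linalg.lstsq(design, -dcdt, rcond=None)
    return float(coef[0]), float(coef[1])


def eyring_free_energy(tau_r: float, temperature: float) -> float:
    """Activation free energy (kJ/mol) of bond breaking from tau_R (ps).

    dG = R*T*ln(k_B*T*tau_R/h); tau_R equal to h/(k_B*T) (~0.16 ps at
    298 K) gives exactly zero.
    """
    if tau_r <= 0:
        raise ValueError("relaxation time must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    ratio = BOLTZMANN_J_PER_K * temperature * (tau_r * 1e-12) / PLANCK_J_S
    return GAS_CONSTANT_J_PER_MOL_K * temperature * np.log(ratio) / 1000.0


def analyze_kinetics(
    series: HBondSeries,
    temperature: float = 298.0,
    n_exponentials: int = 1,
    max_lag: int | None = None,
) -> HBondKinetics:
    """Full kinetics summary for one pooled bond ensemble.

    Bonds of a complex are pooled (bond- and time-origin averaged) before
    fitting, so one lifetime/relaxation/free-energy triple is reported per
    complex.
    """
    fluct = autocorrelation(series, "fluctuation", max_lag=max_lag)
    fit = fit_relaxation(fluct, n_exponentials=n_exponentials)
    inter = autocorrelation(series, "intermittent", max_lag=max_lag)
    crossing = crossing_correlation(series, max_lag=max_lag)
    # restrict the rate fit to the decaying part of C; the equilibrium
    # plateau (dC/dt ~ 0) otherwise dominates the least squares
    k_fwd, k_back = luzar_chandler_rates(
        inter, crossing, window=(0.0, 5.0 * fit.tau_r)
    )
    return HBondKinetics(
        lifetime=mean_lifetime(series),
        relaxation_time=fit.tau_r,
        k_forward=k_fwd,
        k_backward=k_back,
        free_energy=eyring_free_energy(fit.tau_r, temperature),
        temperature=temperature,
    )
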