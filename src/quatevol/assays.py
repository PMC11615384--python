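"""Enzyme function and stability quantification.

Covers the four assay readouts used to compare enzyme variants:

* DTNB-coupled kinetic traces (absorbance of the TNB anion at 412 nm):
  initial velocity from the longest linear window from the trace start.
* Michaelis-Menten fits v = Vmax * S / (Km + S) to substrate-velocity
  tables; kcat = Vmax / [E].
* Thermal melts (ellipticity vs temperature): Tm is the 50%-unfolded
  midpoint of the min-max-scaled curve, read off by linear interpolation;
  a two-transition variant splits the curve at a fixed temperature and
  scales each segment independently.
* Growth curves (OD600 vs time): maximum specific growth rate from a
  logistic fit, falling back to the peak of the smoothed log-OD derivative
  when the culture never approaches saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

#: molar extinction coefficient of 2-nitro-5-thiobenzoate at 412 nm
DEFAULT_EPSILON_M_CM = 14150.0
DEFAULT_PATH_CM = 1.0
#: default temperature at which two-transition melts are partitioned, deg C
DEFAULT_SPLIT_C = 65.0


class AssayError(ValueError):
    pass


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticTrace:
    """A412 time course of one reaction well."""

    time_s: np.ndarray
    a412: np.ndarray
    epsilon_M_cm: float = DEFAULT_EPSILON_M_CM
    path_cm: float = DEFAULT_PATH_CM
    enzyme_nM: float | None = None
    substrate_uM: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.a412 = np.asarray(self.a412, float)
        if len(self.time_s) != len(self.a412):
            raise AssayError("time and absorbance lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise AssayError("time points must be strictly increasing")
        if self.epsilon_M_cm <= 0 or self.path_cm <= 0:
            raise AssayError("extinction coefficient and path length must be > 0")


@dataclass
class InitialRate:
    v_uM_per_min: float
    v_per_site_s: float | None
    slope_AU_per_min: float
    window_points: int
    r_squared: float


def _linfit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def initial_rate(trace: KineticTrace, min_points: int = 5,
                 r2_threshold: float = 0.99) -> InitialRate:
    """Initial velocity from the longest linear window anchored at t = 0.

    The window grows from the first ``min_points`` points and keeps every
    extension whose linear fit retains R^2 >= ``r2_threshold``; the largest
    admissible window wins (reproducible, no manual window picking).  The
    slope converts to product concentration via Beer-Lambert:
    v [M/min] = slope [AU/min] / (epsilon * path).
    """
    t, a = trace.time_s, trace.a412
    if len(t) < min_points:
        raise AssayError(f"need >= {min_points} points, got {len(t)}")
    best = None
    for end in range(min_points, len(t) + 1):
        slope, _, r2 = _linfit_r2(t[:end], a[:end])
        if r2 >= r2_threshold:
            best = (end, slope, r2)
    if best is None:
        raise AssayError(
            f"no initial window of >= {min_points} points reaches "
            f"R^2 >= {r2_threshold}; trace looks noise-dominated")
    end, slope_per_s, r2 = best
    slope_per_min = slope_per_s * 60.0
    v_M_per_min = slope_per_min / (trace.epsilon_M_cm * trace.path_cm)
    v_uM_per_min = v_M_per_min * 1e6
    v_site = None
    if trace.enzyme_nM is not None and trace.enzyme_nM > 0:
        v_site = (v_uM_per_min / 60.0) / (trace.enzyme_nM * 1e-3)  # s^-1
    return InitialRate(v_uM_per_min=v_uM_per_min, v_per_site_s=v_site,
                       slope_AU_per_min=slope_per_min, window_points=end,
                       r_squared=r2)


@dataclass
class RateTable:
    """Substrate-velocity pairs, optionally replicated."""

    substrate_uM: np.ndarray
    velocity: np.ndarray
    replicate: np.ndarray | None = None
    velocity_units: str = "uM_per_s"  # or "per_site_s"

    def __post_init__(self) -> None:
        self.substrate_uM = np.asarray(self.substrate_uM, float)
        self.velocity = np.asarray(self.velocity, float)
        if len(self.substrate_uM) != len(self.velocity):
            raise AssayError("substrate and velocity lengths differ")
        if np.any(self.substrate_uM < 0):
            raise AssayError("substrate concentrations must be >= 0")
        if len(np.unique(self.substrate_uM)) < 4:
            raise AssayError("need >= 4 distinct substrate levels to fit")


@dataclass
class MMFit:
    kcat_s: float
    km_uM: float
    vmax: float
    kcat_se: float
    km_se: float
    r_squared: float
    warnings: list[str] = field(default_factory=list)


def fit_michaelis_menten(rates: RateTable, enzyme_uM: float | None = None) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Initialization: Vmax0 = max observed v, Km0 = substrate at half-max.
    If velocities are in uM/s, ``enzyme_uM`` converts Vmax to kcat; if they
    are already per active site (1/s), kcat = Vmax.
    """
    S, v = rates.substrate_uM, rates.velocity
    warns = []
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise AssayError("all velocities are <= 0; nothing to fit")
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2))])
    km0 = max(km0, 1e-6)

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    try:
        popt, pcov = curve_fit(mm, S, v, p0=[vmax0, km0], maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise AssayError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise AssayError(
            f"fit returned non-positive parameters (Vmax={vmax:.3g}, Km={km:.3g})")
    if km > S.max():
        warns.append("Km exceeds the largest substrate level; poorly constrained")
    if km < S.min():
        warns.append("Km below the smallest substrate level; poorly constrained")
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    pred = mm(S, *popt)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
    if rates.velocity_units == "per_site_s":
        kcat, kcat_se = float(vmax), float(perr[0])
    else:
        if enzyme_uM is None or enzyme_uM <= 0:
            raise AssayError("velocities in uM/s need a positive enzyme_uM for kcat")
        kcat, kcat_se = float(vmax / enzyme_uM), float(perr[0] / enzyme_uM)
    return MMFit(kcat_s=kcat, km_uM=float(km), vmax=float(vmax),
                 kcat_se=kcat_se, km_se=float(perr[1]), r_squared=r2,
                 warnings=warns)


# ---------------------------------------------------------------------------
# thermal stability
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    """Single-wavelength melt: signal (e.g. 223 nm ellipticity) vs temperature."""

    temperature_C: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, float)
        self.signal = np.asarray(self.signal, float)
        if len(self.temperature_C) != len(self.signal):
            raise AssayError("temperature and signal lengths differ")
        if np.any(np.diff(self.temperature_C) <= 0):
            raise AssayError("temperatures must be strictly increasing")


@dataclass
class MeltResult:
    tm_C: float | None
    tm2_C: float | None = None
    split_C: float | None = None
    multimodal: bool = False


def _scale_unit(signal: np.ndarray, noise_floor: float) -> np.ndarray:
    rng = signal.max() - signal.min()
    if rng <= noise_floor:
        raise AssayError("signal spans no transition (range below noise floor)")
    scaled = (signal - signal.min()) / rng
    # orient so the scaled curve rises with temperature (fraction unfolded)
    if scaled[-1] < scaled[0]:
        scaled = 1.0 - scaled
    return scaled


def estimate_tm(curve: MeltCurve, noise_floor: float = 1e-12) -> MeltResult:
    """Melt midpoint: temperature of the 50%-unfolded crossing.

    The signal is min-max scaled to [0, 1] (fraction unfolded) and the first
    0.5 crossing is located by linear interpolation.  Multiple crossings set
    ``multimodal`` and the first is reported.
    """
    T = curve.temperature_C
    y = _scale_unit(curve.signal, noise_floor) - 0.5
    crossings = []
    for i in range(len(y) - 1):
        if y[i] == 0.0:
            crossings.append(T[i])
        elif y[i] * y[i + 1] < 0:
            frac = -y[i] / (y[i + 1] - y[i])
            crossings.append(T[i] + frac * (T[i + 1] - T[i]))
    if y[-1] == 0.0:
        crossings.append(T[-1])
    if not crossings:
        raise AssayError("melt curve never crosses 50% unfolded")
    if len(crossings) > 1:
        warnings.warn("melt curve crosses 50% more than once; reporting the "
                      "first crossing", stacklevel=2)
    return MeltResult(tm_C=float(crossings[0]), multimodal=len(crossings) > 1)


def two_step_tm(curve: MeltCurve, split_C: float = DEFAULT_SPLIT_C,
                flat_fraction: float = 0.05) -> MeltResult:
    """Two-transition melt analysis.

    The curve is partitioned at ``split_C``; each segment is min-max scaled
    independently and its own 50% midpoint extracted — appropriate when a
    destabilized first transition precedes the main unfolding event.

    A segment whose signal range is below ``flat_fraction`` of the whole
    curve's range contains no transition: its midpoint is reported as None
    and the analysis reduces to the other segment (e.g. a split placed below
    the onset of a single transition puts the whole event in the second
    segment).  If neither segment contains a transition, an error names the
    offending segments.
    """
    T = curve.temperature_C
    if not (T.min() < split_C < T.max()):
        raise AssayError(
            f"split {split_C} degC lies outside the scanned range "
            f"[{T.min()}, {T.max()}]")
    total_range = float(curve.signal.max() - curve.signal.min())
    lo = T < split_C
    hi = ~lo
    tms: list[float | None] = []
    multimodal = False
    for name, mask in (("first", lo), ("second", hi)):
        seg_signal = curve.signal[mask]
        if len(seg_signal) < 2 or (seg_signal.max() - seg_signal.min()
                                   < flat_fraction * total_range):
            tms.append(None)
            continue
        seg = MeltCurve(temperature_C=T[mask], signal=seg_signal)
        try:
            res = estimate_tm(seg)
        except AssayError as exc:
            raise AssayError(
                f"{name} segment (split at {split_C} degC): {exc}") from exc
        tms.append(res.tm_C)
        multimodal = multimodal or res.multimodal
    if tms[0] is None and tms[1] is None:
        raise AssayError(
            f"neither segment (split at {split_C} degC) spans a transition")
    return MeltResult(tm_C=tms[0], tm2_C=tms[1], split_C=split_C,
                      multimodal=multimodal)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    time_h: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, float)
        self.od600 = np.asarray(self.od600, float)
        if len(self.time_h) != len(self.od600):
            raise AssayError("time and OD lengths differ")
        if np.any(self.od600 < 0):
            raise AssayError("OD values must be >= 0")


@dataclass
class GrowthFit:
    mu_max_h: float
    model: str
    carrying_capacity: float | None = None
    n0: float | None = None
    r_squared: float | None = None
    no_growth: bool = False


def _logistic(t, n0, r, k):
    return k / (1.0 + (k / n0 - 1.0) * np.exp(-r * t))


def max_growth_rate(curve: GrowthCurve, min_points: int = 10,
                    noise_od: float = 0.01) -> GrowthFit:
    """Maximum specific growth rate mu_max from an OD600 time course.

    Fits a logistic model N(t) = K / (1 + (K/N0 - 1) e^{-rt}); mu_max = r.
    When the culture never approaches its fitted carrying capacity (the
    logistic plateau is unidentified, e.g. purely exponential growth) or the
    fit fails, mu_max falls back to the maximum of the smoothed derivative
    of ln OD.  Cultures whose final OD stays within ``noise_od`` of the
    start are flagged as no-growth with mu_max = 0.
    """
    t, od = curve.time_h, curve.od600
    if len(t) < min_points:
        raise AssayError(f"need >= {min_points} time points, got {len(t)}")
    if od[-1] <= od[0] + noise_od:
        return GrowthFit(mu_max_h=0.0, model="none", no_growth=True)

    def derivative_mu() -> float:
        pos = np.maximum(od, 1e-6)
        ln = np.log(pos)
        if len(ln) >= 7:
            ln = savgol_filter(ln, 7, 2)
        dln = np.gradient(ln, t)
        return float(dln.max())

    n0 = max(float(od[0]), 1e-4)
    k0 = max(float(od.max()), n0 * 2)
    r0 = max(derivative_mu(), 1e-3)
    try:
        popt, _ = curve_fit(_logistic, t, od, p0=[n0, r0, k0],
                            bounds=([1e-8, 1e-6, 1e-6], [np.inf] * 3),
                            maxfev=20000)
        n0_f, r_f, k_f = popt
        pred = _logistic(t, *popt)
        ss_res = float(np.sum((od - pred) ** 2))
        ss_tot = float(np.sum((od - od.mean()) ** 2))
        r2 = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
        if od.max() >= 0.5 * k_f:
            return GrowthFit(mu_max_h=float(r_f), model="logistic",
                             carrying_capacity=float(k_f), n0=float(n0_f),
                             r_squared=r2)
    except RuntimeError:
        pass
    return GrowthFit(mu_max_h=derivative_mu(), model="log_derivative")
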