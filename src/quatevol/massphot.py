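"""Mass-photometry oligomer deconvolution.

Mass photometry records one mass (or raw ratiometric contrast) per landing
particle.  For a homo-oligomer of known monomer mass m0, the mass histogram
is a mixture of peaks near integer multiples n*m0.  This module calibrates
contrast to mass against protein standards, fits a stoichiometry-constrained
Gaussian mixture to the event stream, converts particle fractions to subunit
("active-site") fractions, and classifies assemblies as monodisperse, mixed,
or polydisperse.

Particle fractions answer "what share of complexes are hexamers"; subunit
fractions weight each complex by its n subunits and answer "what share of
active sites sit in hexamers" — the quantity that matters for catalysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


class MassPhotError(ValueError):
    pass


#: practical lower detection bound of the instrument, kDa
DEFAULT_MASS_FLOOR = 40.0
#: maximum relative deviation of a fitted peak from n * monomer_mass
DEFAULT_MASS_TOL = 0.10


@dataclass
class EventTable:
    """Per-particle events: ``mass_kda`` and/or raw ``contrast`` columns."""

    data: pd.DataFrame
    duration_s: float | None = None
    buffer: str | None = None
    effector: str | None = None
    effector_uM: float | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise MassPhotError("event table needs at least one event")
        if "mass_kda" not in self.data and "contrast" not in self.data:
            raise MassPhotError("need a 'mass_kda' or 'contrast' column")
        if "mass_kda" in self.data and (self.data["mass_kda"] <= 0).any():
            raise MassPhotError("masses must be positive")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path, **meta) -> "EventTable":
        return cls(data=pd.read_csv(path), **meta)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class CalibrationModel:
    """Linear contrast-to-mass map fitted against known standards."""

    slope: float      # kDa per contrast unit
    intercept: float  # kDa
    r_squared: float
    standards: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise MassPhotError(f"calibration slope must be > 0, got {self.slope}")
        if len(self.standards) < 2:
            raise MassPhotError("calibration needs at least two standards")

    def to_mass(self, contrast: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(contrast, float) + self.intercept


def _contrast_mode(values: np.ndarray) -> float:
    """Peak of a kernel-density estimate (robust against stray events)."""
    values = np.asarray(values, float)
    if np.ptp(values) < 1e-12:
        return float(values[0])
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def fit_calibration(standards: dict[str, tuple[np.ndarray, float]],
                    min_events: int = 50) -> CalibrationModel:
    """Fit mass = slope * contrast + intercept against standard species.

    ``standards`` maps species label -> (contrast events, known mass in kDa).
    Each species' representative contrast is the mode of its event
    distribution; the line is ordinary least squares through the
    (mode, known mass) points.
    """
    if len(standards) < 2:
        raise MassPhotError(
            f"need >= 2 calibration standards, got {len(standards)}")
    labels, modes, masses = [], [], []
    for label, (events, known) in standards.items():
        events = np.asarray(events, float)
        if len(events) < min_events:
            raise MassPhotError(
                f"standard {label!r} has {len(events)} events; need >= {min_events}")
        labels.append(label)
        modes.append(_contrast_mode(events))
        masses.append(float(known))
    modes = np.array(modes)
    masses = np.array(masses)
    if np.ptp(modes) < 1e-12:
        raise MassPhotError("calibration standards have identical contrasts")
    slope, intercept = np.polyfit(modes, masses, 1)
    pred = slope * modes + intercept
    ss_res = float(np.sum((masses - pred) ** 2))
    ss_tot = float(np.sum((masses - masses.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            r_squared=r2,
                            standards=list(zip(labels, masses.tolist())))


@dataclass
class OligomerComponent:
    n: int
    mean_kda: float
    width_kda: float
    particle_fraction: float


@dataclass
class OligomerProfile:
    """Stoichiometry-resolved decomposition of an MP event stream."""

    monomer_mass: float
    components: list[OligomerComponent]
    unassigned_fraction: float = 0.0
    n_events: int = 0
    n_below_floor: int = 0

    def __post_init__(self) -> None:
        ns = [c.n for c in self.components]
        if any(n < 1 or int(n) != n for n in ns):
            raise MassPhotError("stoichiometries must be positive integers")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise MassPhotError("stoichiometries must be strictly increasing")
        total = sum(c.particle_fraction for c in self.components) + self.unassigned_fraction
        if abs(total - 1.0) > 1e-6:
            raise MassPhotError(f"fractions must sum to 1, got {total:.8f}")

    def particle_fractions(self) -> dict[int, float]:
        return {c.n: c.particle_fraction for c in self.components}

    def to_dict(self) -> dict:
        return {
            "monomer_mass_kda": self.monomer_mass,
            "components": [{"n": c.n, "mean_kda": c.mean_kda,
                            "width_kda": c.width_kda,
                            "particle_fraction": c.particle_fraction}
                           for c in self.components],
            "unassigned_fraction": self.unassigned_fraction,
            "n_events": self.n_events,
            "n_below_floor": self.n_below_floor,
            "subunit_fractions": subunit_fractions(self) if self.components else {},
        }

    @classmethod
    def from_fractions(cls, monomer_mass: float, fractions: dict[int, float],
                       width_rel: float = 0.04) -> "OligomerProfile":
        """Build an idealized profile directly from particle fractions."""
        comps = [OligomerComponent(n=n, mean_kda=n * monomer_mass,
                                   width_kda=width_rel * n * monomer_mass,
                                   particle_fraction=f)
                 for n, f in sorted(fractions.items())]
        return cls(monomer_mass=monomer_mass, components=comps)


def _constrained_em(masses: np.ndarray, monomer_mass: float, ns: np.ndarray,
                    mass_tol: float, max_iter: int = 300,
                    tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM for a Gaussian mixture whose means are tied to n * m0 (+/- tol)."""
    N = len(masses)
    mu = ns * monomer_mass * 1.0
    lo, hi = ns * monomer_mass * (1 - mass_tol), ns * monomer_mass * (1 + mass_tol)
    sigma_floor = max(0.002 * monomer_mass, 1e-3)
    sigma = np.maximum(0.04 * mu, sigma_floor)
    # initialize weights from nearest-stoichiometry assignment
    nearest = np.argmin(np.abs(masses[:, None] - mu[None, :]), axis=1)
    w = np.bincount(nearest, minlength=len(ns)).astype(float)
    w = np.maximum(w, 0.5)
    w /= w.sum()
    ll_old = -np.inf
    for _ in range(max_iter):
        logpdf = (-0.5 * ((masses[:, None] - mu[None, :]) / sigma[None, :]) ** 2
                  - np.log(sigma[None, :]) - 0.5 * np.log(2 * np.pi)
                  + np.log(np.maximum(w[None, :], 1e-300)))
        m = logpdf.max(axis=1, keepdims=True)
        p = np.exp(logpdf - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float((np.log(norm).ravel() + m.ravel()).sum())
        nk = resp.sum(axis=0)
        w = nk / N
        active = nk > 1e-12
        mu_new = mu.copy()
        mu_new[active] = (resp[:, active] * masses[:, None]).sum(axis=0) / nk[active]
        mu = np.clip(mu_new, lo, hi)
        var = np.full_like(mu, sigma_floor**2)
        var[active] = (resp[:, active] * (masses[:, None] - mu[None, active]) ** 2
                       ).sum(axis=0) / nk[active]
        sigma = np.sqrt(np.maximum(var, sigma_floor**2))
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return w, mu, sigma, ll


def detect_oligomers(events: EventTable, monomer_mass: float, n_max: int = 12,
                     calibration: CalibrationModel | None = None,
                     mass_floor: float = DEFAULT_MASS_FLOOR,
                     mass_tol: float = DEFAULT_MASS_TOL) -> OligomerProfile:
    """Fit a stoichiometry-constrained Gaussian mixture to MP events.

    Component means are tied to n * monomer_mass within ``mass_tol`` relative
    deviation (instrument mass error plus purification-tag mass).  The set of
    stoichiometries retained is chosen by BIC among nested candidate subsets
    ranked by initial histogram support.  Events below ``mass_floor`` are
    excluded from fitting and reported in the unassigned fraction.
    """
    if monomer_mass <= 0:
        raise MassPhotError(f"monomer mass must be > 0, got {monomer_mass}")
    if n_max < 1:
        raise MassPhotError(f"n_max must be >= 1, got {n_max}")
    df = events.data
    if "mass_kda" in df:
        masses = df["mass_kda"].to_numpy(float)
    else:
        if calibration is None:
            raise MassPhotError("raw contrast events need a calibration model")
        masses = calibration.to_mass(df["contrast"].to_numpy(float))
    total = len(masses)
    keep = masses >= mass_floor
    n_below = int(total - keep.sum())
    masses = masses[keep]
    if len(masses) == 0:
        raise MassPhotError(
            f"all {total} events fall below the {mass_floor} kDa instrument floor")

    candidates = np.array([n for n in range(1, n_max + 1)
                           if n * monomer_mass * (1 + mass_tol) >= mass_floor])
    if len(candidates) == 0:
        raise MassPhotError("no candidate stoichiometry lies above the mass floor")

    # rank candidates by nearest-multiple histogram support
    nearest = np.argmin(np.abs(masses[:, None] - candidates[None, :] * monomer_mass),
                        axis=1)
    support = np.bincount(nearest, minlength=len(candidates))
    order = np.argsort(-support, kind="stable")

    best = None
    N = len(masses)
    max_components = int((support > 0).sum())
    for j in range(1, max_components + 1):
        ns = np.sort(candidates[order[:j]])
        w, mu, sigma, ll = _constrained_em(masses, monomer_mass, ns, mass_tol)
        n_params = 3 * len(ns) - 1
        bic = -2 * ll + n_params * np.log(N)
        if not np.isfinite(bic):
            continue
        if best is None or bic < best[0] - 1e-9:
            best = (bic, ns, w, mu, sigma)
    if best is None:
        raise MassPhotError("mixture fit failed to converge for any candidate set")
    _, ns, w, mu, sigma = best

    retained = 1.0 - n_below / total
    comps = []
    for i in np.argsort(ns):
        if w[i] < 1e-9:
            continue
        comps.append(OligomerComponent(n=int(ns[i]), mean_kda=float(mu[i]),
                                       width_kda=float(sigma[i]),
                                       particle_fraction=float(w[i] * retained)))
    unassigned = 1.0 - sum(c.particle_fraction for c in comps)
    return OligomerProfile(monomer_mass=monomer_mass, components=comps,
                           unassigned_fraction=float(unassigned),
                           n_events=total, n_below_floor=n_below)


def subunit_fractions(profile: OligomerProfile) -> dict[int, float]:
    """Fraction of subunits (== active sites) in each stoichiometry.

    f_n = n * w_n / sum_m m * w_m over assigned components, where w are
    particle fractions.
    """
    if not profile.components:
        raise MassPhotError("profile has no assigned components")
    weights = {c.n: c.n * c.particle_fraction for c in profile.components}
    total = sum(weights.values())
    if total <= 0:
        raise MassPhotError("profile has zero total subunit weight")
    return {n: v / total for n, v in weights.items()}


@dataclass
class DispersityReport:
    label: str
    dominant_n: int | None
    even_series: bool
    oddmers_present: bool
    theta_mono: float
    theta_min: float


def classify_dispersity(profile: OligomerProfile, theta_mono: float = 0.80,
                        theta_min: float = 0.05) -> DispersityReport:
    """Monodisperse / polydisperse / mixed classification.

    monodisperse(n): one stoichiometry holds >= theta_mono of particles.
    polydisperse: at least three stoichiometries each hold >= theta_min —
    the ladder-of-oligomers phenotype (multimers of dimers plus minor
    oddmers).  Everything else is "mixed".
    """
    fr = profile.particle_fractions()
    dominant_n, dominant_f = None, 0.0
    for n, f in fr.items():
        if f > dominant_f:
            dominant_n, dominant_f = n, f
    above_min = [n for n, f in fr.items() if f >= theta_min]
    even_series = len([n for n in fr if n % 2 == 0]) >= 3
    oddmers = any(n % 2 == 1 and n >= 3 and fr[n] >= theta_min for n in fr)
    if dominant_f >= theta_mono:
        label = f"monodisperse({dominant_n})"
    elif len(above_min) >= 3:
        label = "polydisperse"
    else:
        label = "mixed"
    return DispersityReport(label=label, dominant_n=dominant_n,
                            even_series=even_series, oddmers_present=oddmers,
                            theta_mono=theta_mono, theta_min=theta_min)


@dataclass
class ConditionShift:
    """Per-stoichiometry fraction changes between two conditions."""

    deltas: pd.DataFrame
    headline_n: int
    headline_subunit_delta: float


def compare_conditions(profile_a: OligomerProfile,
                       profile_b: OligomerProfile) -> ConditionShift:
    """Fraction shifts (b - a), e.g. with vs without an effector ligand."""
    if abs(profile_a.monomer_mass - profile_b.monomer_mass) > 1e-9:
        raise MassPhotError("profiles have different monomer masses")
    pa, pb = profile_a.particle_fractions(), profile_b.particle_fractions()
    sa, sb = subunit_fractions(profile_a), subunit_fractions(profile_b)
    ns = sorted(set(pa) | set(pb))
    rows = [{"n": n,
             "particle_delta": pb.get(n, 0.0) - pa.get(n, 0.0),
             "subunit_delta": sb.get(n, 0.0) - sa.get(n, 0.0)} for n in ns]
    df = pd.DataFrame(rows)
    i = int(df["subunit_delta"].abs().idxmax())
    return ConditionShift(deltas=df, headline_n=int(df.loc[i, "n"]),
                          headline_subunit_delta=float(df.loc[i, "subunit_delta"]))
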