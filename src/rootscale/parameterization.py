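"""Derive simulation parameters from platform measurements.

Turns seedling time series (tap length, total lateral length, lateral
count every other day), flowering counts and mature-platform summaries into
the per-order axis parameters of the simulator, and assembles the three
parameterization scenarios:

1. seedling elongation rates (linear growth) + flowering-constrained
   elongation + even seedling spacing;
2. exponential rise to the measured final lengths, branch caps from the
   measured totals, no phenological constraint;
3. as scenario 1 but with the tap's uneven mature spacing via a
   branch-scaling function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .fixtures import GenotypeRecord
from .simulator import (
    AxisParameters,
    BranchScaling,
    RootSystem,
    SEGMENT_BOUNDS,
    SefSchedule,
)

__all__ = [
    "SeedlingTimeSeries",
    "FloweringSeries",
    "FloweringModel",
    "ScenarioConfig",
    "fit_linear_rate",
    "mean_single_lateral_length",
    "fit_exponential",
    "fit_flowering_gaussian",
    "interbranch_distance",
    "compute_sbf",
    "nob_from_final",
    "build_scenario",
]

# Constant spatial/tropism parameters shared by all genotypes: insertion
# angles (rad) for first-/second-order laterals, tropism trials per order,
# tip-flexibility and radii (cm) per order.
THETA_FIRST = 1.05
THETA_SECOND = 1.57
TROPISM_N = {0: 1.5, 1: 1.0, 2: 1.0}
SIGMA_FLEX = 0.3
RADIUS = {0: 0.07, 1: 0.04, 2: 0.02}
APICAL_ZONE = 2.5
BASAL_ZONE = 0.5
UNCONSTRAINED_NOB = 1000
HARVEST_DAY = 82.0


@dataclass
class SeedlingTimeSeries:
    """Observations of one seedling replicate.

    ``observations`` rows: (day after germination, tap length cm, total
    lateral length cm, lateral count, mean branching angle rad).
    """

    genotype: str
    replicate: str | int
    observations: list[tuple[float, float, float, int, float]]

    def __post_init__(self) -> None:
        days = [o[0] for o in self.observations]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("observation days must be strictly increasing")
        if any(o[1] < 0 or o[2] < 0 or o[3] < 0 for o in self.observations):
            raise ValueError("lengths and counts must be non-negative")

    @property
    def days(self) -> list[float]:
        return [o[0] for o in self.observations]


@dataclass
class FloweringSeries:
    genotype: str
    observations: list[tuple[float, float]]  # (day, flower count)

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.observations):
            raise ValueError("flower counts must be non-negative")


@dataclass
class FloweringModel:
    amplitude: float
    peak_day: float
    width: float
    onset_day: float
    fit_r2: float

    def schedule(self) -> SefSchedule:
        return SefSchedule(self.onset_day, self.peak_day)


@dataclass
class ScenarioConfig:
    """A fully resolved simulation input for one genotype."""

    scenario: int
    genotype: str
    params_by_order: dict[int, AxisParameters]
    sef: SefSchedule | None = None
    sbf: BranchScaling | None = None
    duration: float = HARVEST_DAY
    dt: float = 0.1
    seed: int = 0

    def build_system(self, seed: int | None = None) -> RootSystem:
        return RootSystem(
            self.params_by_order,
            sef=self.sef,
            sbf=self.sbf,
            seed=self.seed if seed is None else seed,
        )

    def simulate(self, seed: int | None = None) -> RootSystem:
        system = self.build_system(seed)
        system.grow(self.duration, self.dt)
        return system


# --------------------------------------------------------------------------
# trait fitting
# --------------------------------------------------------------------------

def fit_linear_rate(series: SeedlingTimeSeries, trait: str = "tap") -> float:
    """Elongation rate (cm/day) as the slope through the last two
    observations; ``trait`` is ``"tap"`` or ``"lateral"`` (the latter on the
    mean single-lateral length)."""
    if trait == "tap":
        pts = [(o[0], o[1]) for o in series.observations]
    elif trait == "lateral":
        pts = mean_single_lateral_length(series)
    else:
        raise ValueError("trait must be 'tap' or 'lateral'")
    if len(pts) < 2:
        raise ValueError("need at least two observations")
    (d1, l1), (d2, l2) = pts[-2], pts[-1]
    if d2 == d1:
        raise ValueError("zero time spacing between the last observations")
    return (l2 - l1) / (d2 - d1)


def mean_single_lateral_length(
    series: SeedlingTimeSeries,
) -> list[tuple[float, float]]:
    """Per-day average single-lateral length: total length / count.

    Days with zero laterals are excluded with a warning.
    """
    out = []
    skipped = []
    for day, _tap, lat_total, lat_n, _angle in series.observations:
        if lat_n > 0:
            out.append((day, lat_total / lat_n))
        else:
            skipped.append(day)
    if skipped:
        warnings.warn(
            f"{series.genotype}/{series.replicate}: excluded days without "
            f"laterals: {skipped}",
            stacklevel=2,
        )
    return out


def fit_exponential(
    days: np.ndarray, lengths: np.ndarray, final_length: float
) -> tuple[float, float]:
    """Fit the negative-exponential growth curve with a fixed maximum.

    The maximum ``k`` is pinned to the measured final length; the initial
    rate ``r`` is the least-squares fit of ``k (1 - exp(-r t / k))`` to the
    early (seedling-window) observations.  Returns ``(r, k)``.
    """
    if final_length <= 0:
        raise ValueError("final_length must be positive")
    days = np.asarray(days, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if days.size < 1:
        raise ValueError("need at least one early observation")
    k = float(final_length)

    def model(t, r):
        return k * (1.0 - np.exp(-r * t / k))

    slope0 = max(lengths[-1] / max(days[-1], 1e-9), 1e-6)
    popt, _ = curve_fit(model, days, lengths, p0=[slope0], maxfev=10000)
    return float(popt[0]), k


def fit_flowering_gaussian(series: FloweringSeries) -> FloweringModel:
    """Three-parameter Gaussian fit of the flower-count time course.

    Returns the fitted peak day (the Gaussian mean), with the onset taken
    as the first day a flower was observed.  The fit is multi-started from
    perturbations of the count-weighted moments to dodge the local minima a
    sparse three-parameter fit invites.
    """
    obs = series.observations
    if len(obs) < 4:
        raise ValueError("need at least four observations")
    t = np.array([o[0] for o in obs], dtype=float)
    c = np.array([o[1] for o in obs], dtype=float)
    if not np.any(c > 0):
        raise ValueError("all flower counts are zero; nothing to fit")

    def model(x, a, mu, w):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * w**2))

    w_mean = float(np.sum(t * c) / np.sum(c))
    w_sd = float(np.sqrt(np.sum(c * (t - w_mean) ** 2) / np.sum(c)))
    w_sd = max(w_sd, 0.5)
    best = None
    best_sse = math.inf
    for mu0, w0 in ((w_mean, w_sd), (w_mean - w_sd, w_sd), (w_mean + w_sd, 2 * w_sd)):
        try:
            popt, _ = curve_fit(
                model,
                t,
                c,
                p0=[float(c.max()), mu0, w0],
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(t, *popt) - c) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError("flowering Gaussian fit failed to converge")
    a, mu, w = float(best[0]), float(best[1]), abs(float(best[2]))
    sst = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else float("nan")
    onset = float(t[np.argmax(c > 0)])
    return FloweringModel(a, mu, w, onset, r2)


def interbranch_distance(tap_length: float, n_first_order: float) -> float:
    """Mean spacing between first-order laterals: tap length / count."""
    if n_first_order < 1:
        raise ValueError("need at least one lateral")
    return tap_length / n_first_order


def compute_sbf(
    counts_per_segment: np.ndarray,
    segment_lengths: np.ndarray,
    mean_ln: float,
    bounds: tuple[float, ...] = SEGMENT_BOUNDS,
) -> BranchScaling:
    """Branch-scaling probabilities from per-segment lateral counts.

    Each segment's probability is the observed count over the count even
    spacing at ``mean_ln`` would produce there; values above 1 are clipped
    with a warning (choose a denser base spacing to avoid clipping).
    """
    counts = np.asarray(counts_per_segment, dtype=float)
    lengths = np.asarray(segment_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and segment lengths must align")
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    if mean_ln <= 0:
        raise ValueError("mean_ln must be positive")
    probs = counts / (lengths / mean_ln)
    if np.any(probs > 1.0 + 1e-9):
        warnings.warn(
            "observed lateral density exceeds the base spacing; "
            "probabilities clipped to 1",
            stacklevel=2,
        )
    probs = np.clip(probs, 0.0, 1.0)
    n = len(probs)
    return BranchScaling(bounds[: n + 1], tuple(float(p) for p in probs))


def nob_from_final(
    final_length: float,
    ln: float,
    la: float = APICAL_ZONE,
    lb: float = BASAL_ZONE,
) -> int:
    """Branch-number cap that pins the maximum length to ``final_length``
    (inverse of ``k = la + lb + (nob - 1) ln``)."""
    if final_length <= la + lb:
        raise ValueError("final length does not exceed the unbranched zones")
    return int(round((final_length - la - lb) / ln)) + 1


# --------------------------------------------------------------------------
# scenario assembly
# --------------------------------------------------------------------------

def _axis(order: int, r: float, gf: str, ln: float, nob: int) -> AxisParameters:
    if order == 2:
        # no apical zone and no branching: the maximum length collapses to
        # the 0.5 cm basal zone
        return AxisParameters(
            order=2,
            r=r,
            gf=gf,
            apical_zone=0.0,
            basal_zone=BASAL_ZONE,
            interbranch=0.0,
            nob=1,
            theta=THETA_SECOND,
            tropism_N=TROPISM_N[2],
            sigma_flex=SIGMA_FLEX,
            radius=RADIUS[2],
        )
    return AxisParameters(
        order=order,
        r=r,
        gf=gf,
        apical_zone=APICAL_ZONE,
        basal_zone=BASAL_ZONE,
        interbranch=ln,
        nob=nob,
        theta=0.0 if order == 0 else THETA_FIRST,
        tropism_N=TROPISM_N[order],
        sigma_flex=SIGMA_FLEX,
        radius=RADIUS[order],
    )


def build_scenario(
    record: GenotypeRecord,
    scenario: int,
    duration: float = HARVEST_DAY,
    dt: float = 0.1,
    seed: int = 0,
) -> ScenarioConfig:
    """Resolve one genotype's record into a runnable scenario configuration.

    Scenario 1 uses seedling linear rates, the flowering schedule and even
    seedling spacing with an unconstrained branch cap; scenario 2 uses the
    exponential rates with the measurement-derived branch caps and no
    schedule; scenario 3 modifies scenario 1's tap to the uneven mature
    spacing (densest-segment base spacing, per-segment emergence
    probabilities), leaving everything else untouched.
    """
    if scenario == 1 or scenario == 3:
        sef = SefSchedule(record.flowering_onset, record.flowering_peak)
        tap_ln = record.ln_seedling
        sbf = None
        if scenario == 3:
            if not record.segment_interbranch:
                raise ValueError(
                    f"{record.genotype}: no per-segment spacing data for scenario 3"
                )
            bs = np.asarray(record.segment_bounds)
            seg_ln = np.asarray(record.segment_interbranch)
            tap_ln = float(seg_ln.min())
            counts = np.diff(bs) / seg_ln
            sbf = compute_sbf(counts, np.diff(bs), tap_ln, SEGMENT_BOUNDS)
        params = {
            0: _axis(0, record.r_tap_linear, "linear", tap_ln, UNCONSTRAINED_NOB),
            1: _axis(
                1, record.r_lateral_linear, "linear", record.ln_seedling,
                UNCONSTRAINED_NOB,
            ),
            2: _axis(2, record.r_lateral_linear, "linear", 0.0, 1),
        }
        return ScenarioConfig(
            scenario, record.genotype, params, sef=sef, sbf=sbf,
            duration=duration, dt=dt, seed=seed,
        )
    if scenario == 2:
        for name in ("tap_mature", "nob_tap", "nob_lateral"):
            if not math.isfinite(getattr(record, name)):
                raise ValueError(f"{record.genotype}: missing {name} for scenario 2")
        params = {
            0: _axis(
                0, record.r_tap_exp, "exponential", record.ln_seedling,
                int(round(record.nob_tap)),
            ),
            1: _axis(
                1, record.r_lateral_exp, "exponential", record.ln_seedling,
                int(round(record.nob_lateral)),
            ),
            2: _axis(2, record.r_lateral_exp, "exponential", 0.0, 1),
        }
        return ScenarioConfig(
            2, record.genotype, params, sef=None, sbf=None,
            duration=duration, dt=dt, seed=seed,
        )
    raise ValueError("scenario must be 1, 2 or 3")
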