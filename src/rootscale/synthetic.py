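"""Synthetic two-platform phenotyping datasets with known ground truth.

Emulates the study design the packaged tables come from: an agar-plate
seedling platform imaged every other day up to day 7 (12 replicates) and a
sand-column mature platform harvested at day 82 (8 replicates), plus
flower counts every other day.  Seedling axes elongate linearly (with an
optional early-rate decay mimicking the observed slow-down), lateral
counts arise from the interbranch-spacing process, mature systems are
produced by the simulator itself, and flower counts follow a Gaussian
pulse between onset and past peak.

Noise is multiplicative lognormal on lengths (nonnegative, scale-free) and
binomial thinning on counts.  Because the synthetic mature platform is
generated by the same simulator family the pipeline fits, passing
recovery tests demonstrates self-consistency of the pipeline, not external
validity on real columns.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .fixtures import GenotypeRecord
from .parameterization import (
    APICAL_ZONE,
    BASAL_ZONE,
    FloweringSeries,
    SeedlingTimeSeries,
    THETA_FIRST,
    UNCONSTRAINED_NOB,
    fit_flowering_gaussian,
    fit_linear_rate,
    fit_exponential,
    interbranch_distance,
    _axis,
)
from .simulator import (
    BranchScaling,
    RootSystem,
    SEGMENT_BOUNDS,
    SefSchedule,
    lateral_count_by_segment,
    total_root_length,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "make_truth",
    "generate_seedling_platform",
    "generate_mature_platform",
    "generate_dataset",
    "recover_records",
]

SEEDLING_DAYS = (1.0, 3.0, 5.0, 7.0)
# observed early-rate decay on the seedling platform: day 3-5 rate is 6.4%
# below day 1-3, day 5-7 is 11.6% below day 3-5
DECAY_35 = 0.064
DECAY_57 = 0.116


@dataclass
class SyntheticConfig:
    """Study-design knobs; defaults mirror the real experiment.

    True-parameter ranges span the fitted values of the 16 real genotypes
    (tap rate 0.51-1.46 cm/d, lateral rate 0.42-1.05 cm/d, seedling
    interbranch distance 0.34-0.72 cm, flowering onset day 31-48 with a
    2.5-19.1 day ramp to peak).
    """

    n_genotypes: int = 16
    seedling_replicates: int = 12
    mature_replicates: int = 8
    r_tap_range: tuple[float, float] = (0.51, 1.46)
    r_lateral_range: tuple[float, float] = (0.42, 1.05)
    ln_range: tuple[float, float] = (0.34, 0.72)
    onset_range: tuple[float, float] = (31.0, 48.0)
    flowering_span_range: tuple[float, float] = (2.5, 19.1)
    sbf_family: str = "even"          # "even" or "linear" uneven spacing
    seedling_cv: float = 0.3          # lognormal length CV, seedling platform
    mature_cv: float = 0.5            # lognormal length CV, mature platform
    count_thinning: float = 0.0       # probability a lateral goes uncounted
    early_rate_decay: bool = True
    harvest_day: float = 82.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.r_tap_range,
            self.r_lateral_range,
            self.ln_range,
            self.onset_range,
            self.flowering_span_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive with lo <= hi")
        if min(self.seedling_cv, self.mature_cv, self.count_thinning) < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class SyntheticTruth:
    """Generating parameters of one synthetic genotype."""

    genotype: str
    r_tap: float
    r_lateral: float
    ln: float
    onset_day: float
    peak_day: float
    flower_amplitude: float
    sbf: BranchScaling | None = None


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: list[SyntheticTruth]
    seedling: list[SeedlingTimeSeries]
    flowering: list[FloweringSeries]
    mature: list[GenotypeRecord] = field(default_factory=list)


def _uniform(rng: random.Random, bounds: tuple[float, float]) -> float:
    return rng.uniform(*bounds)


def make_truth(config: SyntheticConfig) -> list[SyntheticTruth]:
    """Seeded draws of per-genotype true parameters within the ranges."""
    rng = random.Random(config.seed)
    out = []
    for i in range(config.n_genotypes):
        onset = _uniform(rng, config.onset_range)
        span = _uniform(rng, config.flowering_span_range)
        ln = _uniform(rng, config.ln_range)
        sbf = None
        if config.sbf_family == "linear":
            # acropetally thinning emergence, mirroring the mature platform
            probs = tuple(np.linspace(1.0, 0.2, len(SEGMENT_BOUNDS) - 1))
            sbf = BranchScaling(SEGMENT_BOUNDS, probs)
        elif config.sbf_family != "even":
            raise ValueError("sbf_family must be 'even' or 'linear'")
        out.append(
            SyntheticTruth(
                genotype=f"G{i + 1:02d}",
                r_tap=_uniform(rng, config.r_tap_range),
                r_lateral=_uniform(rng, config.r_lateral_range),
                ln=ln,
                onset_day=onset,
                peak_day=onset + span,
                flower_amplitude=rng.uniform(5.0, 15.0),
                sbf=sbf,
            )
        )
    return out


def _lognormal_factor(rng: random.Random, cv: float) -> float:
    if cv <= 0:
        return 1.0
    s2 = math.log(1.0 + cv * cv)
    return math.exp(rng.gauss(-0.5 * s2, math.sqrt(s2)))


def _seedling_tap_length(day: float, r: float, decay: bool) -> float:
    """Piecewise-linear tap growth whose day 5-7 slope equals r exactly."""
    if not decay:
        return r * day
    r35 = r / (1.0 - DECAY_57)
    r13 = r35 / (1.0 - DECAY_35)
    if day <= 3:
        return r13 * day
    if day <= 5:
        return 3 * r13 + (day - 3) * r35
    return 3 * r13 + 2 * r35 + (day - 5) * r


def _first_emergence_day(truth: SyntheticTruth, decay: bool) -> float:
    """Day the first lateral appears: the tap has developed its basal and
    apical zones."""
    target = APICAL_ZONE + BASAL_ZONE
    lo, hi = 0.0, 20.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _seedling_tap_length(mid, truth.r_tap, decay) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _seedling_laterals(
    day: float, truth: SyntheticTruth, decay: bool
) -> tuple[float, int]:
    """Total lateral length and count at a seedling observation day.

    Counts follow the platform's measurement convention (tap length over
    mean spacing, an integer) and the average single lateral elongates
    linearly at the true lateral rate from first emergence, so noiseless
    observations return the generating rates exactly and the spacing up to
    count rounding.
    """
    tap = _seedling_tap_length(day, truth.r_tap, decay)
    t1 = _first_emergence_day(truth, decay)
    if day <= t1:
        return 0.0, 0
    n = max(int(round(tap / truth.ln)), 1)
    mean_single = truth.r_lateral * (day - t1)
    return mean_single * n, n


def generate_seedling_platform(
    truth: list[SyntheticTruth], config: SyntheticConfig
) -> list[SeedlingTimeSeries]:
    """Seedling time series (days 1, 3, 5, 7) for every genotype/replicate."""
    rng = random.Random(config.seed * 4 + 1)
    out = []
    for tr in truth:
        for rep in range(config.seedling_replicates):
            obs = []
            for day in SEEDLING_DAYS:
                tap = _seedling_tap_length(day, tr.r_tap, config.early_rate_decay)
                lat_total, lat_n = _seedling_laterals(
                    day, tr, config.early_rate_decay
                )
                tap *= _lognormal_factor(rng, config.seedling_cv)
                lat_total *= _lognormal_factor(rng, config.seedling_cv)
                if config.count_thinning > 0 and lat_n > 0:
                    lat_n = sum(
                        rng.random() >= config.count_thinning
                        for _ in range(lat_n)
                    )
                angle = rng.gauss(THETA_FIRST, 0.05 if config.seedling_cv else 0.0)
                obs.append((day, tap, lat_total, lat_n, angle))
            out.append(SeedlingTimeSeries(tr.genotype, rep, obs))
    return out


def _flowering_series(
    tr: SyntheticTruth, rng: random.Random, cv: float
) -> FloweringSeries:
    width = max((tr.peak_day - tr.onset_day) / 2.0, 1.0)
    days = np.arange(tr.onset_day, tr.peak_day + 2.5 * width, 2.0)
    obs = []
    for d in days:
        c = tr.flower_amplitude * math.exp(
            -((d - tr.peak_day) ** 2) / (2.0 * width**2)
        )
        obs.append((float(d), c * _lognormal_factor(rng, cv)))
    return FloweringSeries(tr.genotype, obs)


def generate_mature_platform(
    truth: list[SyntheticTruth], config: SyntheticConfig
) -> tuple[list[GenotypeRecord], list[FloweringSeries]]:
    """Mature-platform records: the simulator run to harvest with the truth
    parameters, plus Gaussian flowering counts.

    Observation noise multiplies the harvested lengths per replicate; the
    returned record carries replicate means.
    """
    rng = random.Random(config.seed * 4 + 2)
    records, flowering = [], []
    for i, tr in enumerate(truth):
        sef = SefSchedule(tr.onset_day, tr.peak_day)
        params = {
            0: _axis(0, tr.r_tap, "linear", tr.ln, UNCONSTRAINED_NOB),
            1: _axis(1, tr.r_lateral, "linear", tr.ln, UNCONSTRAINED_NOB),
            2: _axis(2, tr.r_lateral, "linear", 0.0, 1),
        }
        system = RootSystem(
            params, sef=sef, sbf=tr.sbf, seed=(config.seed * 7919 + i) % 2**31
        )
        system.grow(config.harvest_day, config.dt)
        tap_len = system.tap.length
        lat_len = total_root_length(system, orders=(1, 2))
        counts = np.asarray(lateral_count_by_segment(system), dtype=float)
        n_first = counts.sum()
        reps = max(config.mature_replicates, 1)
        tap_obs = float(
            np.mean([tap_len * _lognormal_factor(rng, config.mature_cv) for _ in range(reps)])
        )
        lat_obs = float(
            np.mean([lat_len * _lognormal_factor(rng, config.mature_cv) for _ in range(reps)])
        )
        ln_mature = (
            interbranch_distance(tap_obs, n_first) if n_first >= 1 else float("nan")
        )
        first_len = min(2.5, tap_obs)
        ln_first = (
            first_len / counts[0] if counts[0] > 0 else ln_mature
        )
        records.append(
            GenotypeRecord(
                genotype=tr.genotype,
                tap_seedling=float("nan"),
                lateral_seedling=float("nan"),
                ln_seedling=float("nan"),
                ln_seedling_first=float("nan"),
                tap_mature=tap_obs,
                lateral_mature=lat_obs,
                ln_mature=ln_mature,
                ln_mature_first=float(ln_first),
                flowering_onset=tr.onset_day,
                flowering_peak=tr.peak_day,
                r_tap_linear=float("nan"),
                r_lateral_linear=float("nan"),
                r_tap_exp=float("nan"),
                r_lateral_exp=float("nan"),
                nob_tap=float("nan"),
                nob_lateral=float("nan"),
            )
        )
        flowering.append(_flowering_series(tr, rng, config.mature_cv))
    return records, flowering


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full two-platform dataset: truth, seedling series, flowering counts
    and mature records."""
    truth = make_truth(config)
    seedling = generate_seedling_platform(truth, config)
    mature, flowering = generate_mature_platform(truth, config)
    return SyntheticDataset(
        config=config,
        truth=truth,
        seedling=seedling,
        flowering=flowering,
        mature=mature,
    )


def recover_records(dataset: SyntheticDataset) -> list[GenotypeRecord]:
    """Parameterize the synthetic observations exactly as real data would
    be: per-replicate linear rates averaged per genotype, day-7 interbranch
    distance, Gaussian flowering fit, plus the exponential-scenario inputs
    derived from the mature totals."""
    by_genotype: dict[str, list[SeedlingTimeSeries]] = {}
    for s in dataset.seedling:
        by_genotype.setdefault(s.genotype, []).append(s)
    flowering = {f.genotype: f for f in dataset.flowering}
    mature = {m.genotype: m for m in dataset.mature}
    out = []
    for tr in dataset.truth:
        series = by_genotype[tr.genotype]
        r_tap = float(np.mean([fit_linear_rate(s, "tap") for s in series]))
        r_lat = float(np.mean([fit_linear_rate(s, "lateral") for s in series]))
        day7 = [(s.observations[-1][1], s.observations[-1][3]) for s in series]
        ln_est = float(
            np.mean(
                [
                    interbranch_distance(tap, n)
                    for tap, n in day7
                    if n >= 1
                ]
            )
        )
        tap_seedling = float(np.mean([t for t, _ in day7]))
        lat_seedling = float(np.mean([s.observations[-1][2] for s in series]))
        fl = fit_flowering_gaussian(flowering[tr.genotype])
        m = mature[tr.genotype]
        days = np.asarray(SEEDLING_DAYS)
        taps = np.array(
            [
                np.mean([s.observations[i][1] for s in series])
                for i in range(len(SEEDLING_DAYS))
            ]
        )
        r_exp, _k = fit_exponential(days, taps, m.tap_mature)
        out.append(
            GenotypeRecord(
                genotype=tr.genotype,
                tap_seedling=tap_seedling,
                lateral_seedling=lat_seedling,
                ln_seedling=ln_est,
                ln_seedling_first=ln_est,
                tap_mature=m.tap_mature,
                lateral_mature=m.lateral_mature,
                ln_mature=m.ln_mature,
                ln_mature_first=m.ln_mature_first,
                flowering_onset=fl.onset_day,
                flowering_peak=fl.peak_day,
                r_tap_linear=r_tap,
                r_lateral_linear=r_lat,
                r_tap_exp=r_exp,
                r_lateral_exp=r_exp * tr.r_lateral / max(tr.r_tap, 1e-9),
                nob_tap=m.tap_mature / ln_est,
                nob_lateral=float("nan"),
                segment_bounds=(),
                segment_interbranch=(),
            )
        )
    return out
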