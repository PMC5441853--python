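"""Packaged genotype tables for the 16 European pea cultivars.

The CSVs under ``rootscale/data`` carry, per genotype: flowering onset and
Gaussian-fitted peak day, tap/lateral lengths and interbranch distances on
both phenotyping platforms (agar-plate seedlings at 7 days after
germination, sand-column mature plants at ~82 days), and the elongation
rates / branch-number caps driving the three simulation scenarios.

Per-segment mature interbranch distances (the uneven-spacing input of
Scenario 3) are not available as a printed table; a synthetic stand-in is
reconstructed from the published summary values — see
:func:`synthetic_segment_interbranch`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .simulator import SEGMENT_BOUNDS

__all__ = [
    "GenotypeRecord",
    "load_table",
    "load_fixtures",
    "synthetic_segment_interbranch",
]

_TABLES = ("genotypes", "flowering", "platform_traits", "growth_parameters")


def load_table(name: str) -> pd.DataFrame:
    """Load one packaged CSV (genotypes, flowering, platform_traits,
    growth_parameters) as a DataFrame."""
    if name not in _TABLES:
        raise KeyError(f"unknown fixture table {name!r}; have {_TABLES}")
    ref = resources.files("rootscale").joinpath(f"data/{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@dataclass
class GenotypeRecord:
    """One genotype's measured traits on both platforms plus phenology."""

    genotype: str
    # seedling platform (7 days after germination)
    tap_seedling: float
    lateral_seedling: float
    ln_seedling: float
    ln_seedling_first: float
    # mature platform (~82 days after germination)
    tap_mature: float
    lateral_mature: float
    ln_mature: float
    ln_mature_first: float
    # flowering phenology, days after germination
    flowering_onset: float
    flowering_peak: float
    # elongation parameters (linear scenarios use r_*_linear, the
    # exponential scenario r_*_exp with the printed branch caps)
    r_tap_linear: float
    r_lateral_linear: float
    r_tap_exp: float
    r_lateral_exp: float
    nob_tap: float
    nob_lateral: float
    # synthetic per-segment interbranch distances along the mature tap
    segment_bounds: tuple[float, ...] = ()
    segment_interbranch: tuple[float, ...] = ()

    @property
    def total_mature(self) -> float:
        return self.tap_mature + self.lateral_mature

    @property
    def total_seedling(self) -> float:
        return self.tap_seedling + self.lateral_seedling

    @property
    def n_first_order_mature(self) -> float:
        """Measured first-order lateral count (tap length / mean spacing)."""
        return self.tap_mature / self.ln_mature


def synthetic_segment_interbranch(
    tap_length: float,
    ln_mean: float,
    ln_first: float,
    bounds: tuple[float, ...] = SEGMENT_BOUNDS,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """SYNTHETIC per-segment interbranch distances along the mature tap.

    The per-segment table this reconstructs is not published; the stand-in
    satisfies every printed constraint instead:

    * the first segment (0-2.5 cm) keeps its printed interbranch distance,
    * the distance increases linearly with depth (evaluated at segment
      midpoints), matching the reported acropetal increase,
    * the total lateral count equals ``tap_length / ln_mean``, anchoring
      the profile to the printed whole-tap average.

    Returns ``(bounds, per-segment ln)`` clipped to the actual tap length.
    The slope of the linear profile is solved numerically; it is 0 when the
    mean equals the first-segment value and grows as the profile steepens.
    """
    if tap_length <= bounds[1]:
        raise ValueError("tap shorter than the first segment")
    if not 0 < ln_first <= ln_mean:
        raise ValueError("need 0 < first-segment ln <= mean ln")
    bs = [b for b in bounds if b < tap_length] + [tap_length]
    lens = np.diff(bs)
    mids = (np.asarray(bs[:-1]) + np.asarray(bs[1:])) / 2.0
    n_total = tap_length / ln_mean

    def count_gap(slope: float) -> float:
        ln_seg = ln_first + slope * (mids - mids[0])
        return float(np.sum(lens / ln_seg)) - n_total

    if abs(ln_mean - ln_first) < 1e-12:
        slope = 0.0
    else:
        slope = brentq(count_gap, 0.0, 1e3)
    ln_seg = ln_first + slope * (mids - mids[0])
    return tuple(float(b) for b in bs), tuple(float(x) for x in ln_seg)


def load_fixtures() -> list[GenotypeRecord]:
    """All 16 genotype records, merged from the packaged tables."""
    traits = load_table("platform_traits").set_index("genotype")
    flowering = load_table("flowering").set_index("genotype")
    growth = load_table("growth_parameters").set_index("genotype")
    records = []
    for g in traits.index:
        t, f, gr = traits.loc[g], flowering.loc[g], growth.loc[g]
        seg_bounds, seg_ln = synthetic_segment_interbranch(
            float(t.tap_mature_cm),
            float(t.ln_mature_cm),
            float(t.ln_mature_first_segment_cm),
        )
        records.append(
            GenotypeRecord(
                genotype=g,
                tap_seedling=float(t.tap_seedling_cm),
                lateral_seedling=float(t.lateral_seedling_cm),
                ln_seedling=float(t.ln_seedling_cm),
                ln_seedling_first=float(t.ln_seedling_first_segment_cm),
                tap_mature=float(t.tap_mature_cm),
                lateral_mature=float(t.lateral_mature_cm),
                ln_mature=float(t.ln_mature_cm),
                ln_mature_first=float(t.ln_mature_first_segment_cm),
                flowering_onset=float(f.onset_dag),
                flowering_peak=float(f.peak_dag),
                r_tap_linear=float(gr.r_tap_linear),
                r_lateral_linear=float(gr.r_lateral_linear),
                r_tap_exp=float(gr.r_tap_exp),
                r_lateral_exp=float(gr.r_lateral_exp),
                nob_tap=float(gr.nob_tap),
                nob_lateral=float(gr.nob_lateral),
                segment_bounds=seg_bounds,
                segment_interbranch=seg_ln,
            )
        )
    if len(records) != 16 or any(
        not math.isfinite(r.total_mature) for r in records
    ):
        raise RuntimeError("packaged fixture tables are corrupt")
    return records
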