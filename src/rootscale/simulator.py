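"""Root system architecture simulator.

Grows a three-dimensional pea-style root system from per-order axis
parameters: a tap root (order 0) bearing first-order laterals, which in
turn bear second-order laterals.  Each axis elongates according to either

* a linear growth function whose rate can be scaled down by a phenological
  elongation-reduction schedule (``SefSchedule``), or
* a negative-exponential rise to a maximum length
  ``l(t) = k (1 - exp(-r t / k))``,

where the maximum length is ``k = la + lb + (nob - 1) ln`` (apical zone +
basal zone + branching zone).  Lateral roots emerge at fixed spacing ``ln``
within the developing branching zone, each at a fixed insertion angle, and
tap-borne emergence can be thinned per tap segment by a branch-scaling
function (``BranchScaling``).  Growth direction follows a random-optimisation
tropism: from N random tip-deflection candidates the one best satisfying an
objective (downward for gravitropism) is chosen.

Coordinates are in cm with z positive downward; time is in days after
germination.
"""

from __future__ import annotations

import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

__all__ = [
    "AxisParameters",
    "SefSchedule",
    "BranchScaling",
    "RootNode",
    "RootAxis",
    "RootSystem",
    "max_length",
    "axis_length_exponential",
    "axis_length_linear_sef",
    "sef_factor",
    "tropism_direction",
    "grow",
    "total_root_length",
    "length_distribution_along_tap",
    "lateral_count_by_segment",
    "TROPISM_OBJECTIVES",
]

# Tap-segment breakpoints (cm of arc length along the tap) used for the
# branch-scaling function and for depth-profile measurements.
SEGMENT_BOUNDS = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 100.0)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class AxisParameters:
    """Growth, branching and tropism parameters of one root order.

    ``apical_zone`` (la) and ``basal_zone`` (lb) are the unbranched tip and
    base of the axis; ``interbranch`` (ln) spaces branch points within the
    branching zone and ``nob`` caps their number.  Orders that never branch
    (``nob <= 1``) may leave ``interbranch`` at 0; their maximum length then
    collapses to ``apical_zone + basal_zone``.
    """

    order: int
    r: float                      # initial elongation rate, cm / day
    gf: str = "linear"            # "linear" or "exponential"
    apical_zone: float = 2.5      # la, cm
    basal_zone: float = 0.5       # lb, cm
    interbranch: float = 0.0      # ln, cm
    nob: int = 1                  # maximum number of branches
    theta: float = 0.0            # insertion angle on the parent, rad
    tropism_type: str = "gravitropism"
    tropism_N: float = 1.0        # expected number of trials per step
    sigma_flex: float = 0.3       # directional-change strength, 1 / cm
    radius: float = 0.05          # cm
    life_span: float = math.inf   # days

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("elongation rate r must be non-negative")
        if self.gf not in ("linear", "exponential"):
            raise ValueError(f"unknown growth function {self.gf!r}")
        if self.apical_zone < 0 or self.basal_zone < 0:
            raise ValueError("zone lengths must be non-negative")
        if self.nob < 1:
            raise ValueError("nob must be at least 1")
        if self.nob > 1 and self.interbranch <= 0:
            raise ValueError("branching axes need a positive interbranch distance")
        if not 0.0 <= self.theta <= math.pi:
            raise ValueError("theta must lie in [0, pi]")
        if self.tropism_N < 1:
            raise ValueError("tropism_N must be at least 1")
        if self.sigma_flex < 0:
            raise ValueError("sigma_flex must be non-negative")


def max_length(params: AxisParameters) -> float:
    """Maximum axis length ``k = la + lb + (nob - 1) ln`` in cm."""
    return params.apical_zone + params.basal_zone + (params.nob - 1) * params.interbranch


@dataclass(frozen=True)
class SefSchedule:
    """Phenological elongation-reduction schedule.

    The scale factor is 1 up to ``onset_day`` (first flower), declines
    linearly, and reaches 0 at ``peak_day`` (peak flowering), after which
    elongation has ceased.
    """

    onset_day: float
    peak_day: float

    def __post_init__(self) -> None:
        if self.onset_day < 0:
            raise ValueError("onset_day must be non-negative")
        if self.peak_day <= self.onset_day:
            raise ValueError("peak_day must exceed onset_day")

    def factor(self, t: float) -> float:
        if t <= self.onset_day:
            return 1.0
        if t >= self.peak_day:
            return 0.0
        return (self.peak_day - t) / (self.peak_day - self.onset_day)

    def integral(self, t: float) -> float:
        """``∫_0^t factor(u) du`` — the effective growing time up to day t."""
        if t <= self.onset_day:
            return max(t, 0.0)
        span = self.peak_day - self.onset_day
        if t >= self.peak_day:
            return self.onset_day + span / 2.0
        u = t - self.onset_day
        return self.onset_day + u - u * u / (2.0 * span)


def sef_factor(t: float, schedule: SefSchedule) -> float:
    """Elongation scale factor in [0, 1] at day ``t``."""
    return schedule.factor(t)


@dataclass(frozen=True)
class BranchScaling:
    """Per-tap-segment probability that a potential branch point emits a lateral.

    A probability of 1 in every segment reproduces even spacing at the tap's
    interbranch distance; 0.5 halves the emergent lateral density in that
    segment.
    """

    segment_bounds: Sequence[float] = SEGMENT_BOUNDS
    probabilities: Sequence[float] = (1.0,) * (len(SEGMENT_BOUNDS) - 1)

    def __post_init__(self) -> None:
        bounds = tuple(self.segment_bounds)
        probs = tuple(self.probabilities)
        if len(probs) != len(bounds) - 1:
            raise ValueError("need one probability per segment")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("segment bounds must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "segment_bounds", bounds)
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def even(cls) -> "BranchScaling":
        return cls()

    def probability_at(self, arc: float) -> float:
        """Emergence probability for a branch point at tap arc length ``arc``.

        Arcs beyond the last breakpoint inherit the last segment's value.
        """
        i = bisect_right(self.segment_bounds, arc) - 1
        i = min(max(i, 0), len(self.probabilities) - 1)
        return self.probabilities[i]


# --------------------------------------------------------------------------
# growth functions (closed forms; the stepper uses their increments)
# --------------------------------------------------------------------------

def axis_length_exponential(t: float, params: AxisParameters) -> float:
    """Negative-exponential axis length ``k (1 - exp(-r t / k))`` at age t."""
    if t < 0:
        raise ValueError("age must be non-negative")
    k = max_length(params)
    if k <= 0:
        raise ValueError("non-positive maximum length: invalid parameterization")
    return k * (1.0 - math.exp(-params.r * t / k))


def axis_length_linear_sef(
    t: float,
    params: AxisParameters,
    schedule: SefSchedule | None = None,
    emergence_time: float = 0.0,
) -> float:
    """Linear axis length under a reduction schedule: ``r ∫ sef(u) du``.

    The integral runs from the axis's emergence day to ``t`` (both in days
    after germination); without a schedule this is plain linear growth
    ``r (t - emergence_time)``.  Uncapped — the simulation clips at the
    maximum length where one applies.
    """
    if t < emergence_time:
        raise ValueError("t precedes the axis's emergence")
    if schedule is None:
        return params.r * (t - emergence_time)
    return params.r * (schedule.integral(t) - schedule.integral(emergence_time))


# --------------------------------------------------------------------------
# tropism
# --------------------------------------------------------------------------

def _normalize(v: tuple[float, float, float]) -> tuple[float, float, float]:
    n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if n == 0.0:
        raise ValueError("zero-length heading: corrupt axis state")
    return (v[0] / n, v[1] / n, v[2] / n)


def _perturb(
    heading: tuple[float, float, float],
    sigma: float,
    step: float,
    rng: random.Random,
) -> tuple[float, float, float]:
    """One candidate heading: rotate by a zero-mean random angle of scale
    sigma*step about a uniformly random azimuth."""
    alpha = abs(rng.gauss(0.0, sigma * step))
    if alpha == 0.0:
        return heading
    hx, hy, hz = heading
    # build an orthonormal frame (u, v) perpendicular to the heading
    if abs(hx) < 0.9:
        ux, uy, uz = 0.0, -hz, hy
    else:
        ux, uy, uz = -hz, 0.0, hx
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = hy * uz - hz * uy
    vy = hz * ux - hx * uz
    vz = hx * uy - hy * ux
    phi = rng.uniform(0.0, 2.0 * math.pi)
    ca, sa = math.cos(alpha), math.sin(alpha)
    cp, sp = math.cos(phi), math.sin(phi)
    return _normalize(
        (
            ca * hx + sa * (cp * ux + sp * vx),
            ca * hy + sa * (cp * uy + sp * vy),
            ca * hz + sa * (cp * uz + sp * vz),
        )
    )


def _gravitropism(candidate: tuple[float, float, float]) -> float:
    # minimise upward-ness: z is positive downward
    return -candidate[2]


def _no_tropism(candidate: tuple[float, float, float]) -> float:
    return 0.0


def _unavailable(name: str) -> Callable[[tuple[float, float, float]], float]:
    def stub(candidate: tuple[float, float, float]) -> float:
        raise NotImplementedError(
            f"{name} needs an environment field; pass a custom objective callable"
        )

    return stub


TROPISM_OBJECTIVES: dict[str, Callable[[tuple[float, float, float]], float]] = {
    "none": _no_tropism,
    "gravitropism": _gravitropism,
    "hydrotropism": _unavailable("hydrotropism"),
    "chemotropism": _unavailable("chemotropism"),
}


def tropism_direction(
    heading: tuple[float, float, float],
    params: AxisParameters,
    rng: random.Random,
    step: float = 0.1,
    objective: Callable[[tuple[float, float, float]], float] | None = None,
) -> tuple[float, float, float]:
    """Next tip heading by random optimisation.

    Draws N candidate perturbations of the current heading (angular scale
    ``sigma_flex * step``) and returns the one minimising the objective.
    A fractional ``tropism_N`` is realised stochastically (e.g. 1.5 means 1
    or 2 trials with equal probability).  With ``sigma_flex == 0`` the
    heading is returned unchanged.
    """
    heading = _normalize(heading)
    if params.sigma_flex == 0.0:
        return heading
    if objective is None:
        objective = TROPISM_OBJECTIVES[params.tropism_type]
    n_base = int(params.tropism_N)
    frac = params.tropism_N - n_base
    n = n_base + (1 if frac > 0 and rng.random() < frac else 0)
    best = None
    best_val = math.inf
    for _ in range(max(n, 1)):
        cand = _perturb(heading, params.sigma_flex, step, rng)
        val = objective(cand)
        if val < best_val:
            best, best_val = cand, val
    return best if best is not None else heading


# --------------------------------------------------------------------------
# root system containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RootNode:
    """One polyline vertex of a root axis."""

    position: tuple[float, float, float]  # cm, z positive downward
    arc_length: float                     # cm from the axis base
    creation_time: float                  # day


@dataclass
class RootAxis:
    """One root axis: a polyline with creation times plus branch bookkeeping."""

    params: AxisParameters
    emergence_time: float
    parent: "RootAxis | None" = None
    branch_arc: float = 0.0               # arc position on the parent, cm
    nodes: list[RootNode] = field(default_factory=list)
    children: list["RootAxis"] = field(default_factory=list)
    heading: tuple[float, float, float] = (0.0, 0.0, 1.0)
    length: float = 0.0
    _next_branch: int = 0                 # index of the next potential branch
    _done: bool = False

    @property
    def order(self) -> int:
        return self.params.order

    def target_length(self, t: float, sef: SefSchedule | None) -> float:
        """Closed-form length at day ``t``.

        Exponential growth is bounded by the maximum length by
        construction.  Linear growth is limited by the reduction schedule
        rather than the branch cap, except for axes without a branching
        zone (no interbranch distance), whose full extent is just the
        basal plus apical zone.
        """
        age = t - self.emergence_time
        if age <= 0:
            return 0.0
        if self.params.gf == "exponential":
            return axis_length_exponential(age, self.params)
        length = axis_length_linear_sef(t, self.params, sef, self.emergence_time)
        if self.params.interbranch <= 0:
            return min(length, self.params.apical_zone + self.params.basal_zone)
        return length

    def position_at(self, arc: float) -> tuple[float, float, float]:
        """Interpolated position at arc length ``arc`` along the polyline."""
        nodes = self.nodes
        if not nodes:
            raise ValueError("axis has no geometry")
        arcs = [n.arc_length for n in nodes]
        i = bisect_right(arcs, arc)
        if i <= 0:
            return nodes[0].position
        if i >= len(nodes):
            return nodes[-1].position
        a, b = nodes[i - 1], nodes[i]
        span = b.arc_length - a.arc_length
        w = 0.0 if span <= 0 else (arc - a.arc_length) / span
        return (
            a.position[0] + w * (b.position[0] - a.position[0]),
            a.position[1] + w * (b.position[1] - a.position[1]),
            a.position[2] + w * (b.position[2] - a.position[2]),
        )

    def subtree_length(self) -> float:
        total = self.length
        for child in self.children:
            total += child.subtree_length()
        return total


class RootSystem:
    """A growing root system: one tap root and its lateral hierarchy.

    Parameters
    ----------
    params_by_order:
        ``{0: tap, 1: first-order, 2: second-order}`` axis parameters;
        orders may be omitted to suppress deeper branching.
    sef:
        Optional global elongation-reduction schedule (applies to every
        linear-growth axis).
    sbf:
        Branch-scaling function thinning tap-borne lateral emergence;
        ``None`` means even spacing (probability 1 everywhere).
    seed:
        Seed of the single RNG driving tropism and probabilistic emergence.
    """

    def __init__(
        self,
        params_by_order: dict[int, AxisParameters],
        sef: SefSchedule | None = None,
        sbf: BranchScaling | None = None,
        seed: int = 0,
        max_order: int | None = None,
    ) -> None:
        if 0 not in params_by_order:
            raise ValueError("need tap-root (order 0) parameters")
        self.params_by_order = dict(params_by_order)
        self.sef = sef
        self.sbf = sbf
        self.seed = seed
        self.rng = random.Random(seed)
        self.clock = 0.0
        self.max_order = (
            max(self.params_by_order) if max_order is None else max_order
        )
        tap = RootAxis(
            params=self.params_by_order[0],
            emergence_time=0.0,
            heading=(0.0, 0.0, 1.0),
        )
        tap.nodes.append(RootNode((0.0, 0.0, 0.0), 0.0, 0.0))
        self.axes: list[RootAxis] = [tap]
        self._active: list[RootAxis] = [tap]

    @property
    def tap(self) -> RootAxis:
        return self.axes[0]

    # -- growth -------------------------------------------------------------

    def _spawn_child(self, parent: RootAxis, arc: float, t: float) -> None:
        order = parent.order + 1
        params = self.params_by_order.get(order)
        if params is None or order > self.max_order:
            return
        pos = parent.position_at(arc)
        # insertion: parent heading rotated by theta about a random azimuth
        rng = self.rng
        hx, hy, hz = parent.heading
        if abs(hx) < 0.9:
            u = _normalize((0.0, -hz, hy))
        else:
            u = _normalize((-hz, 0.0, hx))
        v = (
            hy * u[2] - hz * u[1],
            hz * u[0] - hx * u[2],
            hx * u[1] - hy * u[0],
        )
        phi = rng.uniform(0.0, 2.0 * math.pi)
        ct, st = math.cos(params.theta), math.sin(params.theta)
        cp, sp = math.cos(phi), math.sin(phi)
        heading = _normalize(
            (
                ct * hx + st * (cp * u[0] + sp * v[0]),
                ct * hy + st * (cp * u[1] + sp * v[1]),
                ct * hz + st * (cp * u[2] + sp * v[2]),
            )
        )
        child = RootAxis(
            params=params,
            emergence_time=t,
            parent=parent,
            branch_arc=arc,
            heading=heading,
        )
        child.nodes.append(RootNode(pos, 0.0, t))
        parent.children.append(child)
        self.axes.append(child)
        self._active.append(child)

    def _emit_branches(self, axis: RootAxis, t: float) -> None:
        """Create branch points the growing zone has passed; Bernoulli-thin
        tap-borne ones by the branch-scaling function."""
        p = axis.params
        if p.interbranch <= 0:
            return
        while axis._next_branch < p.nob:
            arc = p.basal_zone + axis._next_branch * p.interbranch
            if axis.length < arc + p.apical_zone:
                break
            axis._next_branch += 1
            if axis.order == 0 and self.sbf is not None:
                if self.rng.random() >= self.sbf.probability_at(arc):
                    continue
            self._spawn_child(axis, arc, t)

    def grow(self, until: float, dt: float = 0.1) -> "RootSystem":
        """Advance the system from its current clock to day ``until``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if until < self.clock - 1e-12:
            raise ValueError("cannot grow into the past")
        t = self.clock
        while t < until - 1e-12:
            t_next = min(t + dt, until)
            still_active: list[RootAxis] = []
            for axis in self._active:
                if axis._done:
                    continue
                target = axis.target_length(t_next, self.sef)
                dl = target - axis.length
                if dl > 1e-12:
                    axis.heading = tropism_direction(
                        axis.heading, axis.params, self.rng, step=dl
                    )
                    last = axis.nodes[-1]
                    hx, hy, hz = axis.heading
                    pos = (
                        last.position[0] + dl * hx,
                        last.position[1] + dl * hy,
                        last.position[2] + dl * hz,
                    )
                    axis.length = target
                    axis.nodes.append(RootNode(pos, target, t_next))
                    self._emit_branches(axis, t_next)
                if self._finished(axis, t_next):
                    axis._done = True
                else:
                    still_active.append(axis)
            self._active = still_active
            t = t_next
        self.clock = until
        return self

    def _finished(self, axis: RootAxis, t: float) -> bool:
        p = axis.params
        if p.gf == "exponential":
            return axis.length >= max_length(p) - 1e-4
        if p.interbranch <= 0 and axis.length >= p.apical_zone + p.basal_zone - 1e-9:
            return True
        return self.sef is not None and t >= self.sef.peak_day


def grow(system: RootSystem, until: float, dt: float = 0.1) -> RootSystem:
    """Functional wrapper around :meth:`RootSystem.grow`."""
    return system.grow(until, dt)


# --------------------------------------------------------------------------
# measurements
# --------------------------------------------------------------------------

def total_root_length(
    system: RootSystem, orders: Iterable[int] | None = None
) -> float:
    """Summed axis length (cm) over the selected root orders (all by default)."""
    if orders is None:
        return sum(a.length for a in system.axes)
    wanted = set(orders)
    return sum(a.length for a in system.axes if a.order in wanted)


def lateral_count_by_segment(
    system: RootSystem, bounds: Sequence[float] = SEGMENT_BOUNDS
) -> list[int]:
    """Number of first-order branch points per tap segment.

    Branch points beyond the last breakpoint are counted in the last
    segment; the total equals the number of first-order axes.
    """
    counts = [0] * (len(bounds) - 1)
    for axis in system.tap.children:
        i = bisect_right(bounds, axis.branch_arc) - 1
        i = min(max(i, 0), len(counts) - 1)
        counts[i] += 1
    return counts


def length_distribution_along_tap(
    system: RootSystem,
    bounds: Sequence[float] = SEGMENT_BOUNDS,
    include_tap: bool = True,
) -> list[float]:
    """Fractional root length per tap segment.

    Each segment receives the tap's own length inside it (optional, included
    by default) plus the full subtree length of every lateral whose branch
    point lies in the segment.  Fractions sum to 1.
    """
    n_seg = len(bounds) - 1
    if n_seg < 1:
        raise ValueError("need at least one segment")
    length = [0.0] * n_seg
    tap = system.tap
    if tap.length <= 0 and not tap.children:
        raise ValueError("empty root system")
    if include_tap:
        for i in range(n_seg):
            lo, hi = bounds[i], bounds[i + 1]
            if i == n_seg - 1:
                hi = max(hi, tap.length)
            length[i] += max(0.0, min(tap.length, hi) - lo)
    for axis in tap.children:
        i = bisect_right(bounds, axis.branch_arc) - 1
        i = min(max(i, 0), n_seg - 1)
        length[i] += axis.subtree_length()
    total = sum(length)
    if total <= 0:
        raise ValueError("root system has no length to distribute")
    return [x / total for x in length]
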