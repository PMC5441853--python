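"""Growth functions, branching, tropism and system-level invariants."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootscale.simulator import (
    AxisParameters,
    BranchScaling,
    RootSystem,
    SefSchedule,
    axis_length_exponential,
    axis_length_linear_sef,
    grow,
    lateral_count_by_segment,
    length_distribution_along_tap,
    max_length,
    sef_factor,
    total_root_length,
    tropism_direction,
)

from conftest import lateral_params, stub_params, tap_params
from _oracle import CascadeOracle


# --------------------------------------------------------------------------
# closed-form pieces
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "la,lb,nob,ln,expected",
    [
        (2.5, 0.5, 1, 0.7, 3.0),
        (2.5, 0.5, 131, 0.34, 47.2),
        (2.5, 0.5, 1000, 0.5, 502.5),
    ],
)
def test_max_length_closed_form(la, lb, nob, ln, expected):
    p = AxisParameters(order=0, r=1.0, apical_zone=la, basal_zone=lb,
                       interbranch=ln, nob=nob)
    assert max_length(p) == pytest.approx(expected)


def test_exponential_growth_curve():
    # k = 20 via la+lb+(nob-1)ln
    p = AxisParameters(order=0, r=2.0, gf="exponential", interbranch=17.0, nob=2)
    assert max_length(p) == pytest.approx(20.0)
    assert axis_length_exponential(0.0, p) == 0.0
    assert axis_length_exponential(5.0, p) == pytest.approx(
        20.0 * (1 - math.exp(-0.5))
    )
    # asymptote: within 1e-6 of k at large t
    p10 = AxisParameters(order=0, r=1.0, gf="exponential", interbranch=7.0, nob=2)
    assert axis_length_exponential(200.0, p10) == pytest.approx(10.0, abs=1e-6)
    # initial slope equals r
    eps = 1e-7
    assert axis_length_exponential(eps, p) / eps == pytest.approx(2.0, rel=1e-5)


def test_exponential_rejects_degenerate_maximum():
    p = AxisParameters(order=2, r=1.0, gf="exponential", apical_zone=0.0,
                       basal_zone=0.0, nob=1)
    with pytest.raises(ValueError):
        axis_length_exponential(1.0, p)


def test_sef_factor_ramp():
    s = SefSchedule(31.0, 33.5)  # Portugal4 flowering window
    assert sef_factor(31.0, s) == 1.0
    assert sef_factor(33.5, s) == 0.0
    assert sef_factor(32.25, s) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        SefSchedule(33.5, 31.0)


def test_linear_sef_closed_form():
    # plateau value r * (onset + (peak - onset)/2), Portugal4 rates
    p = AxisParameters(order=0, r=0.77)
    s = SefSchedule(31.0, 33.5)
    plateau = 0.77 * (31.0 + 1.25)
    assert axis_length_linear_sef(33.5, p, s) == pytest.approx(plateau)
    assert axis_length_linear_sef(90.0, p, s) == pytest.approx(plateau)
    assert axis_length_linear_sef(0.0, p, s) == 0.0
    # Estonia2: r * onset at the ramp start
    p2 = AxisParameters(order=0, r=1.30)
    assert axis_length_linear_sef(34.0, p2, SefSchedule(34.0, 49.1)) == pytest.approx(44.2)


@given(
    t1=st.floats(0.0, 80.0),
    dt=st.floats(0.01, 20.0),
    onset=st.floats(1.0, 50.0),
    span=st.floats(0.5, 30.0),
    r=st.floats(0.1, 3.0),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_elongation_monotone_and_bounded(t1, dt, onset, span, r):
    """Length is nondecreasing in time for both growth functions and the
    exponential law never exceeds its maximum."""
    s = SefSchedule(onset, onset + span)
    lin = AxisParameters(order=0, r=r)
    assert axis_length_linear_sef(t1 + dt, lin, s) >= axis_length_linear_sef(t1, lin, s) - 1e-12
    exp = AxisParameters(order=0, r=r, gf="exponential", interbranch=5.0, nob=3)
    k = max_length(exp)
    l1, l2 = axis_length_exponential(t1, exp), axis_length_exponential(t1 + dt, exp)
    assert l2 >= l1 - 1e-12
    assert l2 <= k
    # relative gap to the asymptote closes by t = 20 k / r
    assert (k - axis_length_exponential(20.0 * k / r, exp)) / k < 1e-4


# --------------------------------------------------------------------------
# tropism
# --------------------------------------------------------------------------

def test_tropism_zero_flexibility_keeps_heading():
    p = tap_params(sigma=0.0)
    rng = random.Random(0)
    assert tropism_direction((0.0, 0.0, 1.0), p, rng) == (0.0, 0.0, 1.0)


def test_tropism_rejects_zero_heading():
    with pytest.raises(ValueError):
        tropism_direction((0.0, 0.0, 0.0), tap_params(), random.Random(0))


def test_gravitropism_steers_downward_monotone_in_trials():
    """With more trials the chosen heading is on average more downward."""
    rng = random.Random(42)
    heading = (1.0, 0.0, 0.0)  # horizontal start
    means = []
    for n in (1, 10, 100):
        p = tap_params(sigma=0.3)
        p.tropism_N = float(n)
        zs = [
            tropism_direction(heading, p, rng, step=1.0)[2] for _ in range(2000)
        ]
        means.append(np.mean(zs))
    assert means[0] <= means[1] <= means[2]
    assert means[2] > 0  # definitely tilted downward


def test_no_tropism_is_a_random_walk():
    """A 'none' objective accepts the single perturbation unchanged in law:
    the mean heading change is zero but individual draws deviate."""
    p = tap_params(sigma=0.3)
    p.tropism_type = "none"
    p.tropism_N = 1.0
    rng = random.Random(7)
    out = [tropism_direction((0.0, 0.0, 1.0), p, rng, step=1.0) for _ in range(500)]
    assert any(abs(h[0]) > 1e-6 for h in out)
    assert np.mean([h[0] for h in out]) == pytest.approx(0.0, abs=0.05)


# --------------------------------------------------------------------------
# grow()
# --------------------------------------------------------------------------

def test_tap_only_straight_down():
    system = RootSystem({0: tap_params(r=1.0, ln=100.0, nob=1)})
    grow(system, 10.0)
    assert system.tap.length == pytest.approx(10.0)
    assert system.tap.nodes[-1].position[2] == pytest.approx(10.0)
    assert len(system.axes) == 1  # branching zone never reached


def test_grow_argument_validation():
    system = RootSystem({0: tap_params()})
    with pytest.raises(ValueError):
        system.grow(5.0, dt=0.0)
    system.grow(5.0)
    with pytest.raises(ValueError):
        system.grow(1.0)


def test_lateral_count_matches_analytic_count():
    ln = 0.5
    system = RootSystem({0: tap_params(r=1.0, ln=ln), 1: lateral_params(r=0.0, ln=ln)})
    grow(system, 20.0)
    expected = math.floor((system.tap.length - 3.0) / ln) + 1
    assert abs(len(system.tap.children) - expected) <= 1


def test_branch_positions_and_emergence_order():
    system = RootSystem({0: tap_params(r=1.0, ln=0.5), 1: lateral_params(r=0.1)})
    grow(system, 15.0)
    arcs = [c.branch_arc for c in system.tap.children]
    times = [c.emergence_time for c in system.tap.children]
    assert arcs == sorted(arcs)
    assert times == sorted(times)
    assert arcs[0] == pytest.approx(0.5)  # first branch at the basal zone
    # emergence only after the apical zone develops past the branch point
    for c in system.tap.children:
        assert system.tap.target_length(c.emergence_time, None) >= c.branch_arc + 2.5 - 0.15


def test_sbf_half_density_on_fine_spacing():
    """Emergence probability 0.5 at 0.1 cm spacing yields about 5 laterals
    per cm of branching zone."""
    sbf = BranchScaling(probabilities=(0.5,) * 6)
    counts = []
    for seed in range(30):
        system = RootSystem(
            {0: tap_params(r=1.0, ln=0.1), 1: lateral_params(r=0.0)},
            sbf=sbf,
            seed=seed,
        )
        grow(system, 23.0)  # branching zone ~20 cm
        zone = system.tap.length - 3.0
        counts.append(len(system.tap.children) / zone)
    assert np.mean(counts) == pytest.approx(5.0, rel=0.1)


def test_sbf_zero_blocks_segments():
    sbf = BranchScaling(probabilities=(1.0, 1.0, 0.0, 0.0, 0.0, 0.0))
    system = RootSystem(
        {0: tap_params(r=1.0, ln=0.5), 1: lateral_params(r=0.0)}, sbf=sbf
    )
    grow(system, 30.0)
    counts = lateral_count_by_segment(system)
    assert sum(counts[2:]) == 0
    assert counts[0] > 0 and counts[1] > 0


def test_nob_caps_branch_number():
    system = RootSystem({0: tap_params(r=1.0, ln=0.5, nob=5), 1: lateral_params(r=0.0)})
    grow(system, 30.0)
    assert len(system.tap.children) == 5


# --------------------------------------------------------------------------
# measurements
# --------------------------------------------------------------------------

def test_total_root_length_sums_orders():
    system = RootSystem(
        {0: tap_params(r=1.0, ln=2.0), 1: lateral_params(r=0.4, ln=2.0)}
    )
    grow(system, 10.0)
    assert total_root_length(system) == pytest.approx(
        total_root_length(system, orders=(0,)) + total_root_length(system, orders=(1,))
    )
    assert total_root_length(system, orders=(0,)) == pytest.approx(10.0)


def test_distribution_tap_only_split_in_half():
    system = RootSystem({0: tap_params(r=1.0, ln=100.0, nob=1)})
    grow(system, 10.0)
    fractions = length_distribution_along_tap(system, bounds=(0.0, 5.0, 10.0))
    assert fractions == pytest.approx([0.5, 0.5])


def test_distribution_normalises_and_declines_basally(records):
    """Even spacing: earlier (shallower) laterals are older and longer, so
    fractions decrease from basal to apical segments."""
    from rootscale.pipeline import simulate_genotype

    s = simulate_genotype(records[1], 1, seed=0)  # Estonia2, even spacing
    f = s.depth_fractions
    assert f.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(f >= 0)
    # root length per cm of tap declines with depth (segments widen, so the
    # raw per-segment fractions alone are not comparable)
    # (the first segment hosts the unbranched 0.5 cm basal zone, so the
    # decline starts from the second segment)
    widths = np.diff(np.array([0.0, 2.5, 5.0, 10.0, 20.0, 40.0]))
    density = f[:5] / widths
    assert np.all(np.diff(density[1:]) < 0)


def test_distribution_empty_system_raises():
    system = RootSystem({0: tap_params()})
    with pytest.raises(ValueError):
        length_distribution_along_tap(system)


# --------------------------------------------------------------------------
# system-level invariants
# --------------------------------------------------------------------------

def params_for(record, scenario=1):
    from rootscale.parameterization import build_scenario

    return build_scenario(record, scenario)


def test_lengths_decoupled_from_geometry_and_seed(records):
    """With all emergence probabilities 0 or 1, totals, counts and the tap
    distribution are identical across seeds and tropism settings."""
    from rootscale.pipeline import simulate_genotype

    rec = records[3]  # Estonia4
    a = simulate_genotype(rec, 1, seed=1)
    b = simulate_genotype(rec, 1, seed=999)
    assert a.total_length == pytest.approx(b.total_length, rel=1e-12)
    assert a.n_first_order == b.n_first_order
    assert a.depth_fractions == pytest.approx(b.depth_fractions)


def test_dt_halving_stability(records):
    """Halving the step changes Scenario-1 total length by < 1%."""
    from rootscale.pipeline import simulate_genotype

    for rec in (records[0], records[7]):  # Estonia1, Latvia4
        coarse = simulate_genotype(rec, 1, seed=0, dt=0.2)
        fine = simulate_genotype(rec, 1, seed=0, dt=0.1)
        assert fine.total_length == pytest.approx(coarse.total_length, rel=0.01)


@pytest.mark.parametrize("index", [1, 7, 13])  # Estonia2, Latvia4, Portugal4
def test_oracle_equivalence_even_spacing(records, index):
    """Simulated first-order count and total length match the closed-form
    cascade oracle to within one lateral and 2% length."""
    from rootscale.pipeline import simulate_genotype

    rec = records[index]
    oracle = CascadeOracle(
        r_tap=rec.r_tap_linear,
        r_lateral=rec.r_lateral_linear,
        ln=rec.ln_seedling,
        onset=rec.flowering_onset,
        peak=rec.flowering_peak,
    ).totals(82.0)
    sim = simulate_genotype(rec, 1, seed=0)
    assert abs(sim.n_first_order - oracle["n_first_order"]) <= 1
    assert sim.total_length == pytest.approx(oracle["total_length"], rel=0.02)
    assert 100 * sim.top5_share == pytest.approx(100 * oracle["top5_share"], abs=1.0)


def test_sbf_linearity_of_expected_counts():
    """Expected lateral count scales linearly with the emergence
    probability (Monte-Carlo over 200 seeds per level, slope within 5%)."""
    probs = (0.25, 0.5, 0.75, 1.0)
    means = []
    for p in probs:
        sbf = BranchScaling(probabilities=(p,) * 6)
        counts = []
        for seed in range(200):
            system = RootSystem(
                {0: tap_params(r=1.0, ln=0.2), 1: lateral_params(r=0.0)},
                sbf=sbf,
                seed=seed,
            )
            grow(system, 13.0, dt=0.25)
            counts.append(len(system.tap.children))
        means.append(np.mean(counts))
    slope = np.polyfit(probs, means, 1)[0]
    assert slope == pytest.approx(means[-1], rel=0.05)  # count at p=1 per unit p
    assert means[0] == pytest.approx(means[-1] * 0.25, rel=0.1)
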