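# Methods

## The problem

High-throughput root phenotyping works on seedlings (agar plates, a week of
growth); breeders need mature root systems (sand columns, ~82 days).  The
two platforms rank genotypes differently, so direct regression from
seedling traits to mature traits fails.  `rootscale` bridges the gap
mechanistically: a root system architecture (RSA) model is parameterized
from the seedling traits of each genotype, run forward to harvest, and the
simulated mature traits are compared with measured ones.  The packaged
study system is 16 European pea (*Pisum sativum* L.) cultivars phenotyped
on both platforms.

## The growth model

Each root axis (tap = order 0, first-order lateral, second-order lateral)
carries its own parameter set.  An axis consists of an unbranched basal
zone (`lb` = 0.5 cm), a branching zone with potential branch points every
`ln` cm (at most `nob` of them), and an unbranched apical zone
(`la` = 2.5 cm).  Its maximum length is

    k = la + lb + (nob - 1) ln.

Elongation follows one of two laws:

* **negative exponential**: `l(t) = k (1 - exp(-r t / k))`, initial rate
  `r`, asymptote `k`;
* **linear with a phenological brake**: rate `r` scaled by the *sef*
  (scale elongation function), which is 1 until flowering onset, falls
  linearly, and is 0 at peak flowering.  Integrated, the axis length
  plateaus at `r (onset + (peak - onset)/2)` for an axis present from
  germination.  The schedule is calendar-based (days after germination)
  and applies to every linear axis regardless of its own age; exponential
  axes ignore it (the two are never combined in the scenarios).

A lateral at branch arc `a` emerges once the parent is longer than
`a + la` — the apical zone must develop past the branch point.  Tap-borne
emergence can be thinned per tap segment (bounds 0, 2.5, 5, 10, 20, 40,
100 cm) by the *sbf* (scale branching function): one Bernoulli draw per
branch point at creation time, so counts are seed-reproducible and a
probability of 1 everywhere reproduces even spacing.

Second-order laterals have no apical zone and no interbranch distance of
their own, so their maximum length collapses to the 0.5 cm basal zone:
they are short capped stubs growing at the first-order rate, spaced along
first-order axes at the tap's interbranch distance.  This reading is
what the parameter table implies (second-order entries carry no apical
zone and no spacing), and it is quantitatively decisive: letting
second-order roots elongate freely over-predicts total root length about
nine-fold, while omitting them under-predicts by half.  Third and higher
orders are out of scope.

Growth direction uses random-optimisation tropism: per step, `N`
candidate headings are drawn (rotation by a zero-mean angle of scale
`sigma * step` about a uniform azimuth) and the candidate that best
satisfies the objective — the most downward heading, for gravitropism —
is kept.  A fractional `N` (the tap uses 1.5) is realised as 1 or 2
trials with equal probability.  Geometry never feeds back on growth, so
total length, counts and the along-tap distribution are independent of
the tropism settings and the RNG seed whenever all emergence
probabilities are 0 or 1 (this decoupling is tested).

The stepper advances all active axes with closed-form length increments
(default `dt` = 0.1 day), so discretisation only affects emergence timing:
halving `dt` moves totals by well under 1% (tested).  Axis state is
polylines with per-node creation times, exportable as RSML.

## Parameterization scenarios

Constants for all genotypes: insertion angles 1.05 rad (first order on
tap) and 1.57 rad (second order), tropism strength N = 1.5 / 1 / 1,
flexibility sigma = 0.3 /cm, radii 0.07 / 0.04 / 0.02 cm, life spans
unbounded.  Harvest at day 82 after germination (the clock origin is
configurable; with the flowering brake the choice is immaterial because
growth stops at peak flowering).

* **Scenario 1** (seedling data + phenology): linear rates from the slope
  through the last two seedling observations (days 5 and 7) — tap
  directly, laterals on the *average single lateral* (total lateral
  length / count); tap spacing = seedling interbranch distance (tap
  length / lateral count at day 7); `nob` = 1000, i.e. unconstrained;
  *sef* from the genotype's flowering onset and Gaussian-fitted peak.
* **Scenario 2** (seedling + final lengths): exponential growth with the
  measured mature lengths as asymptotes, rates fitted from the seedling
  window, branch caps `nob` from the measurement-derived table, no *sef*.
* **Scenario 3** (seedling elongation + mature branching): as scenario 1,
  but the tap's branching uses the mature per-segment spacing: the base
  spacing is the densest (first) segment's interbranch distance and each
  deeper segment is thinned by `sbf_s = ln_first / ln_s`, so realised
  densities match the mature segment data.  Basing the spacing on the
  whole-tap mean instead would require probabilities above 1 in the top
  segments (they are clipped, with a warning, in `compute_sbf`) and could
  not reproduce the observed top-heavy architecture.  Laterals keep the
  seedling spacing, as in scenario 1.

The per-segment mature spacing table is not available; a **synthetic
stand-in** is reconstructed per genotype from three published summary
constraints: the printed first-segment value, a linear increase of
interbranch distance with depth (evaluated at segment midpoints), and a
total count equal to tap length over the printed whole-tap mean.  The
slope is solved numerically (it is the only free quantity).  Everything
downstream of scenario 3 inherits the uncertainty of this reconstruction;
see Limitations.

The branch-cap inversion `nob_from_final` inverts the maximum-length
formula for user data.  The packaged cap values are carried as printed
even though they do not satisfy that inversion exactly (they equal mature
tap length / seedling spacing for the tap; the lateral caps' derivation
is not recoverable) — discrepancies are surfaced, not reconciled.

## Evaluation battery

For each trait (total root length, first-order lateral number, depth
distribution) predictions are compared against the mature measurements
with: RMSE; percentage mean error `100 |mean(P - O)| / mean(O)` (the
magnitude convention, with the signed bias reported alongside);
Willmott's index of agreement
`d = 1 - sum((P-O)^2) / sum((|P-Obar| + |O-Obar|)^2)` (note `d` is
invariant to a joint constant shift of both vectors — every term is a
deviation from the observed mean); Spearman rank correlation (the
breeder's ranking accuracy); a through-origin regression of predicted on
observed with the slope tested against 1 (uncentred R²,
`1 - SSE/sum(y²)`, not comparable to a centred R²) and a free-intercept
regression with the intercept tested against 0; and quartile shifts
(fractions of genotypes changing rank quartile, and by more than one).
The regression direction (predicted on observed) is a convention switch.
The direct-comparison baseline uses the raw seedling trait as the
prediction of the mature trait — the magnitude mismatch is the point of
that baseline.

The measured per-segment root-length distribution did not survive in the
source tables, so the depth-distribution block compares simulations
against a proxy built from the reconstructed segment counts with a
linearly declining length weight; it is reported for qualitative context
and never asserted numerically.

## Synthetic data

The generator emulates both platforms with known truth: per-genotype
parameters drawn from the ranges spanned by the real fits (tap rate
0.51–1.46 cm/d, lateral rate 0.42–1.05 cm/d, spacing 0.34–0.72 cm,
flowering onset day 31–48 with a 2.5–19.1 day ramp), 12 seedling
replicates observed on days 1/3/5/7, 8 mature replicates harvested at day
82, flower counts every other day.  Seedling tap growth includes the
platform's observed early-rate decay (day 5–7 rate 11.6% below day 3–5,
itself 6.4% below day 1–3) constructed so the day 5–7 slope equals the
true rate; lateral counts follow the measurement convention (tap length /
spacing, rounded) and the mean single lateral elongates exactly linearly,
so noiseless fits return the generating rates to machine precision and
the spacing up to count rounding (a few percent at day-7 tap lengths —
integer counts make exact spacing recovery impossible in principle).
Noise is multiplicative lognormal on lengths (platform-scale CVs of 0.3
seedling / 0.5 mature by default) and binomial thinning on counts.  The
synthetic mature platform is produced by the same simulator family the
pipeline fits, so recovery tests demonstrate self-consistency of the
estimation chain, not external validity on real sand columns.

## Numerical choices

* `dt` = 0.1 day; exponential axes retire once within 1e-4 cm of their
  asymptote; linear axes retire at the *sef* peak.
* Branch points are laid down from arc `lb`, spaced `ln`, capped at
  `nob`; emergence probabilities beyond the last segment bound inherit
  the last segment's value (the deepest measured class extends to the
  tap apex).
* The flowering Gaussian is fitted by multi-start least squares seeded
  from count-weighted moments (three starts) to dodge the local minima a
  three-parameter fit on sparse counts invites; degenerate (all-zero)
  series raise.
* Quartile ties are broken deterministically by label order, with a
  warning.
* One seeded RNG per simulation drives tropism and emergence; scenario
  runs derive one child seed per genotype from the pipeline seed.

## Problem sizes

The full reproduction (3 scenarios x 16 genotypes at `dt` = 0.1, with
systems up to ~7,000 axes) runs in about half a minute on one core; the
acceptance script (scenario 1 only) in a few seconds; the complete test
suite, including a shared full reproduction and Monte-Carlo property
tests, in a few minutes.

## Known limitations

* The scenario-3 inputs rest on the reconstructed segment table.  Under
  it, scenario 3 lands at a top-5 cm share near 51% (published value
  53.8%) and an index of agreement for total root length essentially tied
  with scenario 1 (≈0.93–0.94 for both; the published comparison is 0.95
  vs 0.94, also a 0.01 margin).  The published strict ordering of the two
  is therefore not stably reproduced, and the corresponding check is
  expected to fail by ~0.01 — the honest resolution given the missing
  table.
* Tropism parameters are held constant; root angles were never validated
  against the mature platform, so the 3-D geometry is illustrative.
* The lateral-rate parameter is fitted on the average single lateral and
  then applied to every lateral; real lateral-length hierarchies are
  wider.
* Measured lateral caps (`nob`) for scenario 2 are taken as printed;
  their derivation could not be reproduced, and scenario 2's absolute
  magnitudes are the least reliable of the three (as in the source
  comparison, where it is the weakest scenario).
* No soil coupling, water/nutrient function, root decay or biomass.
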