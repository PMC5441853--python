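"""Goodness-of-fit battery for simulated vs measured root traits.

The battery follows the standard crop-model evaluation toolkit: RMSE,
percentage mean error, Willmott's index of agreement

    d = 1 - sum((P_i - O_i)^2) / sum((|P_i - Obar| + |O_i - Obar|)^2),

Spearman rank correlation (the breeder's ranking accuracy), regression
diagnostics against the 1:1 line (through-origin slope tested against 1,
free intercept tested against 0) and a quartile-shift summary of how many
genotypes a breeder would mis-allocate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedObservations",
    "GoodnessOfFit",
    "rmse",
    "mean_error_pct",
    "signed_mean_error_pct",
    "index_of_agreement",
    "spearman",
    "regression_tests",
    "quartile_shift",
    "distribution_fit",
    "evaluate_pairs",
]


@dataclass
class PairedObservations:
    """Observed and predicted values of one trait across genotypes."""

    labels: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    trait: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if len(self.labels) != self.observed.size or (
            self.observed.size != self.predicted.size
        ):
            raise ValueError("labels, observed and predicted must align")
        if self.observed.size < 1:
            raise ValueError("need at least one pair")
        if not (
            np.all(np.isfinite(self.observed))
            and np.all(np.isfinite(self.predicted))
        ):
            raise ValueError("values must be finite")


@dataclass
class GoodnessOfFit:
    rmse: float
    mean_error_pct: float
    bias_pct: float                      # signed companion of mean_error_pct
    index_of_agreement: float
    spearman_rho: float
    spearman_p: float
    pearson_r2: float
    slope: float                         # through-origin slope
    slope_p_vs_1: float
    slope_r2: float                      # uncentred R^2 of the origin fit
    intercept: float                     # free-regression intercept
    intercept_p_vs_0: float
    quartile_changed: float | None = None
    quartile_shift_gt1: float | None = None
    extra: dict = field(default_factory=dict)


def rmse(pairs: PairedObservations) -> float:
    """Root mean square error, in the trait's units."""
    return float(np.sqrt(np.mean((pairs.predicted - pairs.observed) ** 2)))


def signed_mean_error_pct(pairs: PairedObservations) -> float:
    """Signed mean error as a percentage of the observed mean."""
    mo = pairs.observed.mean()
    if mo == 0:
        raise ValueError("observed mean is zero")
    return float(100.0 * (pairs.predicted - pairs.observed).mean() / mo)


def mean_error_pct(pairs: PairedObservations) -> float:
    """Magnitude of the mean error as a percentage of the observed mean."""
    return abs(signed_mean_error_pct(pairs))


def index_of_agreement(pairs: PairedObservations) -> float:
    """Willmott's index of agreement d in [0, 1] (1 = perfect)."""
    o, p = pairs.observed, pairs.predicted
    if np.allclose(o, o[0]):
        raise ValueError("observed values are constant")
    ob = o.mean()
    denom = np.sum((np.abs(p - ob) + np.abs(o - ob)) ** 2)
    return float(1.0 - np.sum((p - o) ** 2) / denom)


def spearman(pairs: PairedObservations) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) and its p-value."""
    if pairs.observed.size < 3:
        raise ValueError("need at least three pairs for a rank correlation")
    if np.allclose(pairs.observed, pairs.observed[0]) or np.allclose(
        pairs.predicted, pairs.predicted[0]
    ):
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(pairs.predicted, pairs.observed)
    return float(rho), float(p)


def regression_tests(pairs: PairedObservations) -> dict:
    """Departure of predictions from the 1:1 line.

    Regresses predicted on observed: (a) through the origin, slope tested
    against 1 with the uncentred R^2 convention (1 - SSE / sum(y^2), not
    comparable to a centred R^2); (b) with a free intercept, the intercept
    tested against 0.
    """
    import statsmodels.api as sm

    x, y = pairs.observed, pairs.predicted
    if x.size < 3:
        raise ValueError("need at least three pairs for regression diagnostics")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regressor")
    origin = sm.OLS(y, x[:, None]).fit()
    slope = float(origin.params[0])
    slope_se = float(origin.bse[0])
    df = int(origin.df_resid)
    if slope_se == 0.0:
        p_slope = 1.0 if abs(slope - 1.0) < 1e-12 else 0.0
    else:
        p_slope = 2.0 * stats.t.sf(abs((slope - 1.0) / slope_se), df)
    r2_origin = float(1.0 - np.sum(origin.resid**2) / np.sum(y**2))
    free = sm.OLS(y, sm.add_constant(x)).fit()
    intercept = float(free.params[0])
    p_intercept = float(free.pvalues[0])
    return {
        "slope": slope,
        "slope_se": slope_se,
        "slope_p_vs_1": float(p_slope),
        "slope_r2": r2_origin,
        "intercept": intercept,
        "intercept_p_vs_0": p_intercept,
        "free_slope": float(free.params[1]),
    }


def quartile_shift(pairs: PairedObservations) -> tuple[float, float]:
    """Fractions of genotypes changing rank quartile between the two
    rankings, and shifting by more than one quartile.

    Both vectors are ranked best-to-worst (descending) and split into four
    equal blocks; ties across a block boundary are broken by label order
    (with a warning).
    """
    n = pairs.observed.size
    if n % 4 != 0:
        raise ValueError("need a population divisible into quartiles")

    def blocks(v: np.ndarray) -> np.ndarray:
        order = np.lexsort((np.array(pairs.labels), -v))
        q = np.empty(n, dtype=int)
        q[order] = np.arange(n) // (n // 4)
        return q

    for v in (pairs.observed, pairs.predicted):
        if np.unique(v).size < n:
            warnings.warn("ties broken by label order", stacklevel=2)
            break
    qo, qp = blocks(pairs.observed), blocks(pairs.predicted)
    changed = float(np.mean(qo != qp))
    gt1 = float(np.mean(np.abs(qo - qp) > 1))
    return changed, gt1


def distribution_fit(
    sim_fractions: dict[str, np.ndarray],
    obs_fractions: dict[str, np.ndarray],
) -> dict:
    """Agreement of per-genotype depth distributions (fractions per tap
    segment).

    Returns per-genotype Pearson R^2 across the segment bins plus pooled
    statistics (RMSE, index of agreement, Spearman) over all
    genotype x segment pairs.
    """
    if set(sim_fractions) != set(obs_fractions):
        raise ValueError("genotype sets differ")
    per_genotype = {}
    pooled_sim, pooled_obs, labels = [], [], []
    for g in sorted(sim_fractions):
        s = np.asarray(sim_fractions[g], dtype=float)
        o = np.asarray(obs_fractions[g], dtype=float)
        if s.shape != o.shape:
            raise ValueError(f"{g}: segment bins differ")
        for v, name in ((s, "simulated"), (o, "observed")):
            if abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{g}: {name} fractions do not sum to 1")
        r = stats.pearsonr(s, o)
        per_genotype[g] = {"r2": float(r[0] ** 2), "p": float(r[1])}
        pooled_sim.extend(s)
        pooled_obs.extend(o)
        labels.extend(f"{g}:{i}" for i in range(s.size))
    pooled = PairedObservations(
        labels, np.array(pooled_obs), np.array(pooled_sim), trait="depth fraction"
    )
    pooled_stats = evaluate_pairs(pooled, quartiles=False)
    return {
        "per_genotype": per_genotype,
        "mean_r2": float(
            np.mean([v["r2"] for v in per_genotype.values()])
        ),
        "pooled": pooled_stats,
    }


def evaluate_pairs(
    pairs: PairedObservations, quartiles: bool = True
) -> GoodnessOfFit:
    """Run the whole battery on one paired trait."""
    rho, p = spearman(pairs)
    reg = regression_tests(pairs)
    pr = stats.pearsonr(pairs.predicted, pairs.observed)
    qc = qs = None
    if quartiles and pairs.observed.size % 4 == 0:
        qc, qs = quartile_shift(pairs)
    return GoodnessOfFit(
        rmse=rmse(pairs),
        mean_error_pct=mean_error_pct(pairs),
        bias_pct=signed_mean_error_pct(pairs),
        index_of_agreement=index_of_agreement(pairs),
        spearman_rho=rho,
        spearman_p=p,
        pearson_r2=float(pr[0] ** 2),
        slope=reg["slope"],
        slope_p_vs_1=reg["slope_p_vs_1"],
        slope_r2=reg["slope_r2"],
        intercept=reg["intercept"],
        intercept_p_vs_0=reg["intercept_p_vs_0"],
        quartile_changed=qc,
        quartile_shift_gt1=qs,
    )
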