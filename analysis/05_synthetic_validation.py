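"""Validate the estimation chain on synthetic data with known truth.

Runs the generator-fit-simulate loop at zero noise (parameter recovery and
ranking self-consistency) and sweeps the seedling platform noise to show
how ranking recovery degrades.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from rootscale.parameterization import fit_linear_rate
from rootscale.pipeline import simulate_genotype
from rootscale.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_seedling_platform,
    make_truth,
    recover_records,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def zero_noise_roundtrip() -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = generate_dataset(
            SyntheticConfig(n_genotypes=8, seedling_replicates=3,
                            seedling_cv=0.0, mature_cv=0.0, seed=21)
        )
        recs = recover_records(ds)
        rows = []
        for t, r in zip(ds.truth, recs):
            sim = simulate_genotype(r, 1, seed=0)
            rows.append(
                {
                    "genotype": t.genotype,
                    "r_tap_true": t.r_tap,
                    "r_tap_est": r.r_tap_linear,
                    "ln_true": t.ln,
                    "ln_est": r.ln_seedling,
                    "peak_true": t.peak_day,
                    "peak_est": r.flowering_peak,
                    "total_sim": sim.total_length,
                    "total_truth_platform": t.r_tap and (r.tap_mature + r.lateral_mature),
                }
            )
    return pd.DataFrame(rows)


def noise_sweep() -> pd.DataFrame:
    rows = []
    for cv in (0.0, 0.1, 0.25, 0.5):
        rhos = []
        for rep in range(10):
            cfg = SyntheticConfig(
                n_genotypes=8, seedling_replicates=12, seedling_cv=cv,
                mature_cv=0.0, seed=300 + rep,
            )
            truth = make_truth(cfg)
            series = generate_seedling_platform(truth, cfg)
            est = {}
            for s in series:
                est.setdefault(s.genotype, []).append(fit_linear_rate(s, "tap"))
            rho, _ = stats.spearmanr(
                [np.mean(est[t.genotype]) for t in truth],
                [t.r_tap for t in truth],
            )
            rhos.append(rho)
        rows.append({"seedling_cv": cv, "mean_rank_recovery": np.mean(rhos)})
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    roundtrip = zero_noise_roundtrip()
    roundtrip.to_csv(OUT / "synthetic_recovery.csv", index=False)
    err = np.max(np.abs(roundtrip.r_tap_est - roundtrip.r_tap_true))
    print(f"zero-noise tap-rate recovery: max |error| = {err:.2e} cm/day")
    rho, _ = stats.spearmanr(roundtrip.total_sim, roundtrip.total_truth_platform)
    print(f"self-consistency ranking (simulated vs synthetic mature): rho = {rho:.3f}")

    sweep = noise_sweep()
    sweep.to_csv(OUT / "synthetic_noise_sweep.csv", index=False)
    print("rank recovery vs platform noise (12 replicates):")
    print(sweep.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
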