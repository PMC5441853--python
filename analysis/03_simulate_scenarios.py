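"""Simulate all genotypes under the three scenarios to harvest (day 82).

Writes per-genotype outcome summaries (total length, lateral number,
top-5 cm share) to results/scenario_summaries.csv plus RSML exports of two
contrasting genotypes (dense Latvia4 vs sparse Estonia3) under scenario 1.
"""

import warnings
from pathlib import Path

from rootscale.fixtures import load_fixtures
from rootscale.io import write_rsml
from rootscale.parameterization import build_scenario
from rootscale.pipeline import reproduce_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = reproduce_experiment(seed=SEED)
    frame = report.summary_frame()
    frame.to_csv(OUT / "scenario_summaries.csv", index=False)
    means = frame.groupby("scenario")[["total_length_cm", "top5_share_pct"]].mean()
    print("Scenario means across the 16 genotypes:")
    print(means.round(1))
    print(
        "Even spacing (scenarios 1-2) spreads root length down the tap; the "
        "uneven mature spacing of scenario 3 concentrates "
        f"{means.loc[3, 'top5_share_pct']:.0f}% of it in the top 5 cm."
    )

    records = {r.genotype: r for r in load_fixtures()}
    for genotype in ("Latvia4", "Estonia3"):
        system = build_scenario(records[genotype], 1, seed=SEED).simulate()
        write_rsml(system, OUT / f"{genotype.lower()}_scenario1.rsml", label=genotype)
    print(f"wrote example architectures -> {OUT}/*_scenario1.rsml")


if __name__ == "__main__":
    main()
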