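"""Classify nutritional balance at the 50 Mg/ha yield cutoff.

Uses the balanced-management scenario (every plot at the recommended split-N
dose, complete tissue records) so that class membership is governed by
cultivar and tissue composition.  Compares raw concentrations against clr
values as features and writes the per-specimen confusion quadrants; the true
negatives feed the standards derivation (see 05).
"""

import argparse
from pathlib import Path

import pandas as pd

from onioncnd import GeneratorConfig, ModelConfig, assemble, classify_balance, generate_trials
from onioncnd.feature_table import TISSUE_COLUMNS, tissue_to_clr


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--repeats", type=int, default=100)
    parser.add_argument("--plots-per-trial", type=int, default=50)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    trial_set = generate_trials(
        GeneratorConfig.balanced_management(seed=args.seed, plots_per_trial=args.plots_per_trial)
    )
    trial_set.frame.to_csv(args.out / "balanced_observations.csv", index=False)
    matrix = assemble(trial_set.observations, groups=("management", "tissue"))
    matrix = matrix.select(["cultivar", *TISSUE_COLUMNS])

    rows = []
    for features, m in [("raw concentrations", matrix), ("clr values", tissue_to_clr(matrix))]:
        for learner in ("random_forest", "gradient_boosting"):
            config = ModelConfig(learner=learner, repeats=args.repeats, seed=args.seed)
            report = classify_balance(m, config)
            rows.append({"learner": learner, "features": features,
                         "auc": round(report.auc, 3), "ca": round(report.ca, 3)})
            print(f"{learner:18s} {features:20s} AUC={report.auc:.3f}  CA={report.ca:.3f}")
            if learner == "random_forest" and features == "raw concentrations":
                pd.DataFrame(
                    {"row": range(len(report.quadrants)), "quadrant": report.quadrants}
                ).to_csv(args.out / "quadrants.csv", index=False)
                print(f"  quadrants: {report.quadrant_counts()}")

    pd.DataFrame(rows).to_csv(args.out / "classification_summary.csv", index=False)
    print(f"\nwrote {args.out / 'classification_summary.csv'} and quadrants.csv")


if __name__ == "__main__":
    main()
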