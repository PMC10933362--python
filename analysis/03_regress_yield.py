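"""Evaluate tree-ensemble regression of marketable bulb yield.

Random forest (10 trees per bag) and extreme gradient boosting (100 trees)
under repeated stratified 70:30 partitions, with and without the P/K doses
(the minimum-data-set comparison).  Reports averaged RMSE, MAE and R².
"""

import argparse
from pathlib import Path

import pandas as pd

from onioncnd import ModelConfig, assemble, evaluate_regression, impute
from onioncnd.feature_table import frame_to_observations


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--repeats", type=int, default=100)
    parser.add_argument("--observations", type=Path, default=Path("results/observations.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    observations = frame_to_observations(pd.read_csv(args.observations))
    rows = []
    for exclude, label in [((), "including PK doses"), (("p_dose", "k_dose"), "excluding PK doses")]:
        matrix = impute(assemble(observations, exclude=exclude), seed=args.seed)
        for learner in ("gradient_boosting", "random_forest"):
            config = ModelConfig(learner=learner, repeats=args.repeats, seed=args.seed)
            report = evaluate_regression(matrix, config)
            rows.append(
                {
                    "learner": learner,
                    "features": label,
                    "rmse_kg_ha": round(report.rmse, 0),
                    "mae_kg_ha": round(report.mae, 0),
                    "median_ae_kg_ha": round(report.median_ae, 0),
                    "r2": round(report.r2, 3),
                }
            )
            print(f"{learner:18s} {label:20s} RMSE={report.rmse:6.0f}  "
                  f"MAE={report.mae:6.0f}  R2={report.r2:.3f}")
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "regression_summary.csv", index=False)
    print(f"\nwrote {args.out / 'regression_summary.csv'}")


if __name__ == "__main__":
    main()
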