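"""Rank candidate features for bulb yield.

RReliefF scores every feature against the continuous yield target; the gain
ratio scores cultivar and tissue features against the binary high/low-yield
class at the 50 Mg/ha cutoff.  Expected on the synthetic conditions: the
split-N dose and tissue S dominate (the generator's planted signals).
"""

import argparse
from pathlib import Path

import pandas as pd

from onioncnd import assemble, gain_ratio, impute, rrelieff
from onioncnd.feature_table import FERTILIZATION_COLUMNS, TISSUE_COLUMNS, frame_to_observations


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--observations", type=Path, default=Path("results/observations.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    observations = frame_to_observations(pd.read_csv(args.observations))
    matrix = impute(assemble(observations), seed=args.seed)

    relieff = rrelieff(matrix, seed=args.seed)
    relieff.write(args.out / "relevance_rrelieff.csv")
    relieff.plot(args.out / "relevance_rrelieff.png", title="RReliefF relevance for bulb yield")
    print("top 8 features by RReliefF:")
    print(relieff.to_frame().head(8).to_string(index=False))
    print(f"top controllable feature: {relieff.top(among=FERTILIZATION_COLUMNS)}")

    labels = matrix.target.to_numpy() > 50_000.0
    tissue_matrix = matrix.select(["cultivar", *TISSUE_COLUMNS])
    ratio = gain_ratio(tissue_matrix, class_labels=labels)
    ratio.write(args.out / "relevance_gain_ratio.csv")
    ratio.plot(args.out / "relevance_gain_ratio.png",
               title="Gain ratio at the 50 Mg/ha cutoff")
    print("\ntop 5 cultivar/tissue features by gain ratio:")
    print(ratio.to_frame().head(5).to_string(index=False))


if __name__ == "__main__":
    main()
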