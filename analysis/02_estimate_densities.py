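"""Estimate stage-specific densities from the 3-pass removal catches with
the Zippin/Seber constant-effort maximum-likelihood estimator.

Reads results/data/catches.csv, writes results/densities.csv.
"""

from pathlib import Path

import pandas as pd

from troutcap import pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catches = pd.read_csv(ROOT / "data" / "catches.csv")
    densities = pipeline.estimate_densities(catches)
    densities.to_csv(ROOT / "densities.csv", index=False)
    print(f"estimated {len(densities)} site x year x stage densities "
          f"({densities.attrs['n_no_estimate']} catch patterns admitted no "
          "estimate and were dropped)")
    print("capture probability p_hat: "
          f"median {densities['p_hat'].median():.2f}")
    print(densities.groupby("stage")["density"].describe()[
        ["mean", "50%", "max"]].round(0))


if __name__ == "__main__":
    main()
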