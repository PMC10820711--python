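"""Roast-degree chemometrics on the GC-MS volatile table.

Per origin: exploratory PCA, PLS-DA with Venetian-blinds cross-validation
(LV count by parsimonious RMSECV/misclassification), VID marker selection
(signed 0.8 rule for the per-roast key markers, |0.9| magnitude rule for
the heatmap), and the scaled-intensity heatmap matrix.  Prints the chosen
model complexity, classification metrics, and marker counts.
"""

import argparse
from pathlib import Path

from roastchem.containers import SpectraSet, VolatileTable
from roastchem.pipeline import PipelineConfig, run_classification


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/classification"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = PipelineConfig(out_dir=str(args.out), seed=args.seed)
    spectra = SpectraSet.read(args.data)
    volatiles = VolatileTable.read(args.data)
    bundle = run_classification(config, spectra, volatiles)

    for origin in bundle["origins"]:
        res = bundle["gcms"][origin]
        cv = res["cv"]
        m = res["metrics"]
        print(f"\n{origin} (GC-MS): {cv.n_lv} LVs, CV misclassification "
              f"{cv.criterion[cv.n_lv - 1]:.3f}, calibration accuracy {m.accuracy:.3f}")
        print(f"  explained Y variance at {cv.n_lv} LVs: "
              f"{cv.explained_y[cv.n_lv - 1]:.2f}")
        print("  VID > 0.8 markers:",
              {cls: len(comps) for cls, comps in res["markers"].items()})
        print(f"  heatmap compounds (|VID| > 0.9): {len(res['heatmap'])}")


if __name__ == "__main__":
    main()
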