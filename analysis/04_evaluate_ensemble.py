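"""Cross-validate the 17 ensemble algorithms and screen by performance.

Each algorithm is fit on the modal-subset modeling sample with 10
subsampling runs reserving 15% per class, and scored by test AUC and
max-TSS.  Algorithms with mean AUC under 0.7, mean TSS under 0.5, or
many raw predictions outside [0, 1] are dropped.  Writes the metric
table and the retained tags to results/evaluation/.
"""

import json
from pathlib import Path

import pandas as pd

from ensemblesdm import algorithms
from ensemblesdm.evaluation import (CVPlan, evaluate_algorithms,
                                    screen_algorithms)
from ensemblesdm.occurrences import PixelDataset

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "evaluation"
SEED = 21


def main() -> None:
    with open(ROOT / "selection" / "tally.json") as fh:
        modal = json.load(fh)["modal_subset"]
    modeling = PixelDataset.from_frame(
        pd.read_csv(ROOT / "selection" / "pixels_modeling.csv"))
    modeling = modeling.subset_variables(modal)

    tags = [s.name for s in algorithms.registry()]
    plan = CVPlan(n_runs=10, test_fraction=0.15, seed=SEED)
    metrics = evaluate_algorithms(tags, modeling, plan, seed=SEED)
    retained = screen_algorithms(metrics)

    table = pd.DataFrame([{
        "algorithm": m.algorithm, "mean_auc": round(m.mean_auc, 4),
        "mean_tss": round(m.mean_tss, 4),
        "range_violation_fraction": m.range_violation_fraction,
        "retained": m.algorithm in retained} for m in metrics])
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "algorithm_metrics.csv", index=False)
    with open(OUT / "retained.json", "w") as fh:
        json.dump({"retained": retained, "modal_subset": modal}, fh, indent=2)

    print(table.sort_values("mean_auc", ascending=False).to_string(index=False))
    print(f"\nretained {len(retained)}/{len(tags)} algorithms")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
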