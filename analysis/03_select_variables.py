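"""Stability variable selection over 1,000 absence resamples.

Reads the thinned pixel dataset, repeats the 1:10 absence subsampling
1,000 times, runs the four-stage selection pipeline on each resample,
and writes the subset tally plus per-variable selection counts (the
selection-frequency table) to results/selection/.
"""

import json
from pathlib import Path

import pandas as pd

from ensemblesdm.occurrences import PixelDataset, sample_absences
from ensemblesdm.selection import select_variables, stability_selection

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "selection"
SEED = 11
REPEATS = 1000


def main() -> None:
    thinned = PixelDataset.from_frame(
        pd.read_csv(ROOT / "prepared" / "pixels_thinned.csv"))
    tally = stability_selection(thinned, n_repeats=REPEATS, ratio=10,
                                master_seed=SEED)

    per_var: dict[str, int] = {v: 0 for v in thinned.variable_names}
    for subset, count in tally.subset_frequencies.items():
        for v in subset:
            per_var[v] += count
    counts = pd.DataFrame(sorted(per_var.items(), key=lambda kv: -kv[1]),
                          columns=["variable", "times_selected"])

    modeling = sample_absences(thinned, ratio=10,
                               seed=tally.representative_seed)
    sel = select_variables(modeling)

    OUT.mkdir(parents=True, exist_ok=True)
    counts.to_csv(OUT / "variable_selection_counts.csv", index=False)
    with open(OUT / "tally.json", "w") as fh:
        json.dump({"n_repeats": tally.n_repeats,
                   "modal_subset": list(tally.modal_subset),
                   "modal_count": tally.subset_frequencies[tally.modal_subset],
                   "n_unique_subsets": len(tally.subset_frequencies),
                   "representative_seed": tally.representative_seed,
                   "selection_glm_aic": sel.aic,
                   "selection_glm_d_squared": sel.d_squared}, fh, indent=2)
    modeling.to_frame().to_csv(OUT / "pixels_modeling.csv", index=False)

    print(f"{len(tally.subset_frequencies)} unique subsets over "
          f"{REPEATS} resamples")
    print(f"modal subset ({tally.subset_frequencies[tally.modal_subset]}x): "
          f"{list(tally.modal_subset)}")
    print(f"selection GLM D^2 = {sel.d_squared:.3f}, AIC = {sel.aic:.1f}")
    print(counts.head(8).to_string(index=False))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
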