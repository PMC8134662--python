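"""RReliefF region selection against the 48-hour NIHSS.

Weights every coverage-retained imaging feature column with the Relief
regression estimator (exhaustive pass, k=5 neighbours), writes the weights
to results/, and compares the selected regions with the generative truth.
This is a descriptive whole-cohort map; the model comparison in
05_compare_models.py re-derives the selection from training rows only.
"""

import json
from pathlib import Path

import pandas as pd

from strokenest.features import build_feature_matrix, coverage_filter
from strokenest.relieff import regions_from_selected, rrelieff, select_features
from strokenest.simulate import SimulatedCohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = SimulatedCohort.load(RESULTS / "cohort")
    retained = coverage_filter(
        cohort.lesions, unit="region", threshold=0.10, atlas=cohort.atlas
    )
    fm = build_feature_matrix(
        cohort.lesions, cohort.patient_ids, cohort.atlas, retained
    )
    y48 = cohort.clinical.set_index("patient_id")["nihss_48h"].astype(float)
    weights = rrelieff(fm.values, y48, m=None, k=5, seed=0)
    weights.to_frame().to_csv(RESULTS / "relieff_weights.csv", index=False)

    selected = select_features(weights)
    regions = regions_from_selected(selected, fm.manifest)
    truth = set(json.loads(
        (RESULTS / "cohort" / "ground_truth.json").read_text()
    )["eloquent_regions"])
    print(f"coverage filter kept {len(retained)}/{len(cohort.atlas.region_ids)} regions")
    print(f"Relief selected {len(selected)} columns -> {len(regions)} regions: {regions}")
    print(f"true eloquent set: {sorted(truth)}; recovered "
          f"{len(truth & set(regions))}/{len(truth)}")
    top = weights.weights.sort_values(ascending=False).head(5)
    print("top feature weights:")
    print(top.round(4).to_string())


if __name__ == "__main__":
    main()
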