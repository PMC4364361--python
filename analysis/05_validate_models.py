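"""Validation battery for the top GFA models: R², LOO R²cv, RMSE, F on the
training set; R²pred, test RMSE and Roy's rm² metrics on the test set; and
the 500-round Y-randomization robustness check.

Writes results/model_ranking.csv (one row per model, best-per-criterion
flagged) and results/model1_validation.json.
"""

import json
from pathlib import Path

import pandas as pd

from micelle_qspr.data_io import read_descriptor_table
from micelle_qspr.duplex import SplitResult
from micelle_qspr.validation import validate_model

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026

if __name__ == "__main__":
    table = read_descriptor_table(RESULTS / "reduced_table.csv", "LC",
                                  response_scale="ln")
    split = SplitResult.load(RESULTS / "duplex_split.json")
    train = table.select_samples(split.training_ids)
    test = table.select_samples(split.test_ids)
    models = json.loads((RESULTS / "gfa_models.json").read_text())

    rows, reports = [], []
    for m in models:
        rep = validate_model(train, test, m["descriptors"],
                             y_rand_iterations=500, seed=SEED)
        reports.append(rep)
        rows.append({"model": m["rank"], **rep.to_row()})
    ranking = pd.DataFrame(rows).set_index("model")
    ranking.to_csv(RESULTS / "model_ranking.csv")
    print(ranking.round(4).to_string())
    for crit, better in [("R2", "max"), ("R2cv", "max"), ("F", "max"),
                         ("RMSE(a)", "min"), ("R2pred", "max"),
                         ("RMSE(b)", "min")]:
        idx = ranking[crit].idxmax() if better == "max" else ranking[crit].idxmin()
        print(f"best on {crit}: model {idx}")
    best = reports[0]
    (RESULTS / "model1_validation.json").write_text(best.to_json())
    print(f"Y-randomization means (model 1): R2 {best.y_rand_mean_r2:.3f}, "
          f"R2cv {best.y_rand_mean_r2cv:.3f} -> "
          f"{'reliable' if best.verdicts['y_randomization_reliable'] else 'suspect'}")
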