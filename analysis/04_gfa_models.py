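"""Evolve 5-descriptor regression models with the GFA search on the
training set and report the ten best distinct models by lack-of-fit, with
coefficient inference for the top model.

Writes results/gfa_models.json and results/model1_coefficients.csv.
"""

import json
from pathlib import Path

from micelle_qspr.data_io import read_descriptor_table
from micelle_qspr.duplex import SplitResult
from micelle_qspr.gfa import GfaConfig, evolve
from micelle_qspr.mlr import coefficient_stats

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026

if __name__ == "__main__":
    table = read_descriptor_table(RESULTS / "reduced_table.csv", "LC",
                                  response_scale="ln")
    split = SplitResult.load(RESULTS / "duplex_split.json")
    train = table.select_samples(split.training_ids)
    cfg = GfaConfig(population_size=60, generations=40, subset_size=5,
                    top_n=10, seed=SEED)
    result = evolve(train, cfg)
    payload = [
        {"rank": i + 1, "descriptors": list(m.descriptor_subset),
         "coefficients": m.coefficients.tolist(), "intercept": m.intercept,
         "lof": result.lof_values[i], "r2": result.r2_values[i],
         "r2cv": result.r2cv_values[i]}
        for i, m in enumerate(result.models)
    ]
    (RESULTS / "gfa_models.json").write_text(json.dumps(payload, indent=2))
    best = result.best
    print(f"evaluated {result.evaluation_count} distinct subsets")
    print(f"best model: {', '.join(best.descriptor_subset)} "
          f"(LOF {result.lof_values[0]:.6f}, R2 {result.r2_values[0]:.3f})")
    stats = coefficient_stats(best, train)
    df = stats.to_dataframe().round(4)
    df.to_csv(RESULTS / "model1_coefficients.csv")
    print(df.to_string())
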