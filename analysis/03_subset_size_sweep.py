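"""Determine the optimal descriptor count: run the GFA search at subset
sizes 1-7 on the training set and compare best R² and LOO R²cv per size.
The recommended size is the smallest beyond which R²cv stops improving.

Writes results/subset_size_sweep.csv.
"""

from pathlib import Path

from micelle_qspr.data_io import read_descriptor_table
from micelle_qspr.duplex import SplitResult
from micelle_qspr.gfa import GfaConfig, sweep_subset_size

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026

if __name__ == "__main__":
    table = read_descriptor_table(RESULTS / "reduced_table.csv", "LC",
                                  response_scale="ln")
    split = SplitResult.load(RESULTS / "duplex_split.json")
    train = table.select_samples(split.training_ids)
    cfg = GfaConfig(population_size=60, generations=40, top_n=1, seed=SEED)
    df, recommended = sweep_subset_size(train, range(1, 8), cfg)
    df.to_csv(RESULTS / "subset_size_sweep.csv", index=False)
    print(df.to_string(index=False))
    print(f"recommended subset size: {recommended} "
          "(R2cv stops improving beyond it)")
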