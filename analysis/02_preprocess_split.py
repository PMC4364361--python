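"""Pre-reduce the descriptor table (constant / near-constant / r > 0.99
pairs), ln-transform LC, Mean/SD-standardize, and split 22 training / 8 test
formulations with the Duplex algorithm.

Writes results/reduced_table.csv, results/prereduction_log.json and
results/duplex_split.json.
"""

from pathlib import Path

from micelle_qspr.data_io import (
    ln_transform_response,
    prereduce,
    read_descriptor_table,
    standardize,
    write_descriptor_table,
)
from micelle_qspr.duplex import duplex_split

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    table = read_descriptor_table(RESULTS / "simulated_study.csv", "LC")
    reduced, log = prereduce(table)
    removed = (len(log.removed_constant) + len(log.removed_near_constant)
               + len(log.removed_correlated))
    print(f"pre-reduction removed {removed} descriptors "
          f"({len(log.removed_correlated)} correlated pairs)")
    reduced = standardize(ln_transform_response(reduced))[0]
    split = duplex_split(reduced, n_test=8, standardize_first=False)
    print(f"Duplex split: {len(split.training_ids)} training / "
          f"{len(split.test_ids)} test")
    print(f"test formulations: {', '.join(split.test_ids)}")
    write_descriptor_table(reduced, RESULTS / "reduced_table.csv")
    (RESULTS / "prereduction_log.json").write_text(log.to_json())
    (RESULTS / "duplex_split.json").write_text(split.to_json())
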