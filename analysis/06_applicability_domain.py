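"""Leverage applicability domain of the best model: per-sample hat values
against the training design, standardized cross-validated residuals, the
warning leverage h* = 3(p+1)/n and the ±3 residual band (Williams plot
table).

Writes results/williams.csv.
"""

import json
from pathlib import Path

from micelle_qspr.data_io import read_descriptor_table
from micelle_qspr.domain import williams_report
from micelle_qspr.duplex import SplitResult
from micelle_qspr.mlr import fit_mlr

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    table = read_descriptor_table(RESULTS / "reduced_table.csv", "LC",
                                  response_scale="ln")
    split = SplitResult.load(RESULTS / "duplex_split.json")
    train = table.select_samples(split.training_ids)
    test = table.select_samples(split.test_ids)
    subset = json.loads((RESULTS / "gfa_models.json").read_text())[0]["descriptors"]
    model = fit_mlr(train, subset)
    report = williams_report(train, test, subset, model)
    report.to_dataframe().round(4).to_csv(RESULTS / "williams.csv", index=False)
    n_out = int((~report.in_domain).sum())
    print(f"h* = {report.h_star:.4f}; residual band ±{report.residual_limit:.0f}")
    print(f"{len(report.sample_ids) - n_out}/{len(report.sample_ids)} samples "
          "inside the applicability domain")
    if n_out:
        df = report.to_dataframe()
        print(df[~df['in_domain']].to_string(index=False))
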