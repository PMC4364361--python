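"""Synthetic descriptor tables with the structure the pipeline assumes.

The generator emulates a drug-loaded micelle formulation study: ~30 samples
(15 star polymers at two drug/polymer feed ratios), ~36 molecular
descriptors containing correlated blocks (energy and surface descriptors of
a polymer co-vary in practice), and a positive drug-loading-capacity (LC)
response whose natural log follows a planted 5-descriptor linear model plus
Gaussian noise.  Optional near-duplicate columns (pairwise r > 0.99)
exercise the pre-reduction filter.  Ground truth (true subset, coefficients,
noise level, the ln-scale response) travels in the table metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import DescriptorTable, TableError, read_descriptor_table

__all__ = ["SyntheticSpec", "generate", "FixtureMissing", "fixture_from_supplementary"]

#: planted model mirroring the published optimization equation:
#: ln(LC) = −1.953·SSOV + 1.101·SSA + 0.339·EV + 0.320·TPE + 0.525·IE + 2.548
DEFAULT_SIGNAL = {
    "SSOV": -1.953,
    "SSA": 1.101,
    "EV": 0.339,
    "TPE": 0.320,
    "IE": 0.525,
}
DEFAULT_INTERCEPT = 2.548


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated formulation study."""

    n_samples: int = 30
    n_descriptors: int = 36
    signal: dict = field(default_factory=lambda: dict(DEFAULT_SIGNAL))
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = 0.07  # ln-scale noise, matching the observed training RMSE
    #: (block size, within-block correlation) for consecutive filler columns
    correlation_blocks: tuple = ((4, 0.7), (3, 0.5))
    n_redundant: int = 0  # extra near-duplicate columns (r > 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.signal) > self.n_descriptors:
            raise ValueError("more signal descriptors than columns")
        for size, r in self.correlation_blocks:
            if not 0 <= r < 1:
                raise ValueError(f"within-block correlation {r} outside [0, 1)")
            if size < 2:
                raise ValueError("correlation blocks need at least 2 columns")


def _descriptor_names(spec: SyntheticSpec) -> list[str]:
    names = list(spec.signal)
    fillers = spec.n_descriptors - len(names)
    names += [f"D{i:02d}" for i in range(1, fillers + 1)]
    return names


def generate(spec: SyntheticSpec) -> DescriptorTable:
    """Draw one synthetic descriptor table with planted response."""
    rng = np.random.default_rng(spec.seed)
    names = _descriptor_names(spec)
    n, p = spec.n_samples, spec.n_descriptors
    n_signal = len(spec.signal)

    # covariance: identity for signal columns (identifiability of the planted
    # subset), equicorrelated blocks over consecutive filler columns
    cov = np.eye(p)
    cursor = n_signal
    for size, r in spec.correlation_blocks:
        if cursor + size > p:
            break
        block = slice(cursor, cursor + size)
        cov[block, block] = r
        cov[block, block][np.diag_indices(size)] = 1.0
        cursor += size
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("requested correlation structure is not positive definite") from err
    X = rng.standard_normal((n, p)) @ chol.T
    # Mean/SD-standardized marginals by construction
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    # near-duplicate columns to exercise pre-reduction
    redundant_of = []
    if spec.n_redundant:
        source_cols = rng.choice(p, size=spec.n_redundant, replace=False)
        dups = []
        for j, src in enumerate(source_cols):
            noisy = X[:, src] + 0.02 * rng.standard_normal(n)
            noisy = (noisy - noisy.mean()) / noisy.std(ddof=1)
            dups.append(noisy)
            redundant_of.append((f"{names[src]}_dup{j + 1}", names[src]))
            names.append(f"{names[src]}_dup{j + 1}")
        X = np.column_stack([X] + dups)

    betas = np.array([spec.signal[s] for s in spec.signal])
    signal_X = X[:, :n_signal]
    ln_lc = spec.intercept + signal_X @ betas + spec.noise_sd * rng.standard_normal(n)

    if n == 30:  # 15 polymers at the two drug/polymer feed ratios
        ids = [f"P{i:02d}_r{ratio}" for i in range(1, 16) for ratio in (10, 20)]
    else:
        ids = [f"S{i:02d}" for i in range(1, n + 1)]

    return DescriptorTable(
        sample_ids=tuple(ids),
        descriptor_names=tuple(names),
        values=X,
        response=np.exp(ln_lc),
        response_name="LC",
        response_scale="raw",
        metadata={
            "ground_truth": {
                "signal": dict(spec.signal),
                "intercept": spec.intercept,
                "noise_sd": spec.noise_sd,
                "ln_response": ln_lc.tolist(),
                "redundant_of": redundant_of,
                "seed": spec.seed,
            }
        },
    )


class FixtureMissing(Exception):
    """A hand-transcribed supplementary-table fixture is not present."""


def fixture_from_supplementary(
    path: str | Path, expected_samples: int = 30
) -> DescriptorTable:
    """Load a hand-transcribed study data table (descriptors + LC per sample).

    Raises :class:`FixtureMissing` when the transcription is absent so tests
    depending on it can skip rather than fail.
    """
    path = Path(path)
    if not path.exists():
        raise FixtureMissing(f"no transcription at {path}")
    table = read_descriptor_table(path, response_column="LC")
    if table.n_samples != expected_samples:
        raise TableError(
            f"expected {expected_samples} samples, transcription has {table.n_samples}"
        )
    table.metadata["source"] = "study data transcription"
    return table
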