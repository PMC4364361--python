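"""Duplex partitioning of a dataset into representative training and test sets.

The Duplex algorithm works on pairwise Euclidean distances in descriptor
space: the globally furthest pair seeds the training set, the furthest pair
among the remaining samples seeds the test set, and the remaining samples are
then assigned alternately (training first) to whichever set is due, each time
picking the sample furthest — by summed distance — from the members already in
the receiving set.  Once the test set reaches the requested size every
leftover goes to training.  All ties break toward the lowest sample index, so
the split is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import DescriptorTable, standardize

__all__ = ["SplitResult", "duplex_split"]


@dataclass(frozen=True)
class SplitResult:
    """Training/test partition plus the distance decisions that produced it."""

    training_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    #: (sample id, "train"|"test", selection distance) in assignment order
    selection_trace: tuple[tuple[str, str, float], ...] = field(default=())

    def to_json(self) -> str:
        return json.dumps(
            {
                "training_ids": list(self.training_ids),
                "test_ids": list(self.test_ids),
                "selection_trace": [
                    {"sample": s, "set": d, "distance": x}
                    for s, d, x in self.selection_trace
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        obj = json.loads(text)
        return cls(
            training_ids=tuple(obj["training_ids"]),
            test_ids=tuple(obj["test_ids"]),
            selection_trace=tuple(
                (r["sample"], r["set"], r["distance"])
                for r in obj.get("selection_trace", [])
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SplitResult":
        return cls.from_json(Path(path).read_text())


def _furthest_pair(dist: np.ndarray, candidates: list[int]) -> tuple[int, int, float]:
    """Pair of candidates at maximum distance; lowest-index pair wins ties."""
    best = (-1, -1, -np.inf)
    for a_pos, a in enumerate(candidates):
        for b in candidates[a_pos + 1 :]:
            if dist[a, b] > best[2]:
                best = (a, b, dist[a, b])
    return best


def duplex_split(
    table: DescriptorTable, n_test: int, standardize_first: bool = True
) -> SplitResult:
    """Partition ``table`` into training and test sets by the Duplex rule.

    Parameters
    ----------
    table
        Descriptor table; distances use all descriptor columns.
    n_test
        Number of samples assigned to the test set.
    standardize_first
        Compute distances on Mean/SD-standardized descriptors (default) so no
        single descriptor dominates the metric.
    """
    n = table.n_samples
    if n_test < 1:
        raise ValueError("n_test must be at least 1")
    if n < 4 or n < n_test + 2:
        raise ValueError(
            f"need at least max(4, n_test + 2) samples, got {n} with n_test={n_test}"
        )
    work = standardize(table)[0] if standardize_first else table
    dist = squareform(pdist(work.values, metric="euclidean"))

    remaining = list(range(n))
    train: list[int] = []
    test: list[int] = []
    trace: list[tuple[str, str, float]] = []

    def assign(idx: int, dest: str, d: float) -> None:
        (train if dest == "train" else test).append(idx)
        remaining.remove(idx)
        trace.append((table.sample_ids[idx], dest, float(d)))

    a, b, d0 = _furthest_pair(dist, remaining)
    assign(a, "train", d0)
    assign(b, "train", d0)
    if n_test >= 2 or len(remaining) > 0:
        a, b, d1 = _furthest_pair(dist, remaining)
        if n_test >= 2:
            assign(a, "test", d1)
            assign(b, "test", d1)
        else:  # test set of one: seed with the lower-index member of the pair
            assign(a, "test", d1)

    n_train_target = n - n_test
    turn = "train"
    while remaining:
        if len(test) >= n_test:
            dest = "train"
        elif len(train) >= n_train_target:
            dest = "test"
        else:
            dest = turn
            turn = "test" if turn == "train" else "train"
        members = train if dest == "train" else test
        sums = np.array([dist[i, members].sum() for i in remaining])
        pick = remaining[int(np.argmax(sums))]  # argmax: first (lowest index) wins
        assign(pick, dest, float(np.max(sums)))

    return SplitResult(
        training_ids=tuple(table.sample_ids[i] for i in sorted(train)),
        test_ids=tuple(table.sample_ids[i] for i in sorted(test)),
        selection_trace=tuple(trace),
    )
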