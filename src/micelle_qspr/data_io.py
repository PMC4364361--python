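"""Descriptor tables: loading, response transform, standardization, pre-reduction.

The universal currency of the pipeline is the :class:`DescriptorTable` — a
samples × descriptors matrix with an optional response vector (drug-loading
capacity, LC % w/w, modeled on the natural-log scale).  Before any model
building the descriptor block is pre-reduced: constant and near-constant
columns are dropped, and of any pair with |Pearson r| above a threshold
(default 0.99) one member is removed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "StandardizationParams",
    "PrereductionLog",
    "TableError",
    "read_descriptor_table",
    "write_descriptor_table",
    "ln_transform_response",
    "standardize",
    "apply_standardization",
    "invert_standardization",
    "prereduce",
]


class TableError(ValueError):
    """Raised when a descriptor table violates its invariants."""


@dataclass(frozen=True)
class DescriptorTable:
    """Samples × descriptors matrix with an optional aligned response.

    Parameters
    ----------
    sample_ids
        Ordered unique sample labels (rows).
    descriptor_names
        Ordered unique descriptor labels (columns).
    values
        Real matrix, shape ``(n_samples, n_descriptors)``.
    response
        Optional response vector aligned to ``sample_ids``.
    response_name
        Label of the response column (e.g. ``"LC"``).
    response_scale
        ``"raw"`` or ``"ln"`` — whether the response has been log-transformed.
    metadata
        Free-form provenance (e.g. planted ground truth of a simulation).
    """

    sample_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray
    response: np.ndarray | None = None
    response_name: str = "LC"
    response_scale: str = "raw"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(
            self, "descriptor_names", tuple(str(d) for d in self.descriptor_names)
        )
        if values.ndim != 2:
            raise TableError("descriptor values must be a 2-D matrix")
        n, p = values.shape
        if n != len(self.sample_ids):
            raise TableError(
                f"{n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.descriptor_names):
            raise TableError(
                f"{p} columns but {len(self.descriptor_names)} descriptor names"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.descriptor_names, "descriptor name")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise TableError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )
        if self.response is not None:
            resp = np.asarray(self.response, dtype=float)
            object.__setattr__(self, "response", resp)
            if resp.shape != (n,):
                raise TableError(
                    f"response length {resp.shape} does not match {n} samples"
                )
            if not np.isfinite(resp).all():
                i = int(np.argwhere(~np.isfinite(resp))[0])
                raise TableError(
                    f"non-finite response for sample {self.sample_ids[i]!r}"
                )
        if self.response_scale not in ("raw", "ln"):
            raise TableError(f"unknown response scale {self.response_scale!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]

    def columns(self, names) -> np.ndarray:
        idx = [self.descriptor_names.index(n) for n in names]
        return self.values[:, idx]

    def select_descriptors(self, names) -> "DescriptorTable":
        names = tuple(names)
        return dataclasses.replace(
            self, descriptor_names=names, values=self.columns(names)
        )

    def select_samples(self, ids) -> "DescriptorTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return dataclasses.replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            values=self.values[idx],
            response=None if self.response is None else self.response[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.descriptor_names)
        )
        df.index.name = "sample_id"
        if self.response is not None:
            df[self.response_name] = self.response
        return df


def _check_unique(items, what: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise TableError(f"duplicate {what}: {item!r}")
        seen.add(item)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-descriptor mean and sample standard deviation (ddof=1)."""

    descriptor_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if np.any(self.sds <= 0):
            bad = self.descriptor_names[int(np.argmax(self.sds <= 0))]
            raise TableError(f"non-positive standard deviation for {bad!r}")


@dataclass
class PrereductionLog:
    """Record of every column removed during pre-reduction and why."""

    removed_constant: list[str] = field(default_factory=list)
    removed_near_constant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 0.99
    near_constant_rule: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_constant": self.removed_constant,
                "removed_near_constant": self.removed_near_constant,
                "removed_correlated": [
                    {"kept": k, "removed": r, "correlation": c}
                    for k, r, c in self.removed_correlated
                ],
                "threshold": self.threshold,
                "near_constant_rule": self.near_constant_rule,
            },
            indent=2,
        )


def read_descriptor_table(
    path: str | Path,
    response_column: str | None = "LC",
    response_scale: str = "raw",
) -> DescriptorTable:
    """Read a descriptor table from CSV (first column = sample id).

    ``response_column``, when present in the header, is split off into the
    response vector; pass ``None`` for a pure descriptor table.
    ``response_scale`` declares whether the stored response is raw LC or
    already ln-transformed.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise TableError(f"duplicate sample id: {dup!r} in {path}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            sample = df.index[converted.isna()][0]
            raise TableError(
                f"non-numeric cell at sample {sample!r}, column {col!r} in {path}"
            )
        numeric[col] = converted
    response = None
    scale = response_scale
    if response_column is not None:
        if response_column not in numeric.columns:
            raise TableError(f"response column {response_column!r} not found in {path}")
        response = numeric.pop(response_column).to_numpy()
    return DescriptorTable(
        sample_ids=tuple(df.index.astype(str)),
        descriptor_names=tuple(numeric.columns.astype(str)),
        values=numeric.to_numpy(),
        response=response,
        response_name=response_column or "LC",
        response_scale=scale,
    )


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path)


def ln_transform_response(table: DescriptorTable) -> DescriptorTable:
    """Replace the response by its natural log (LC -> ln LC)."""
    if table.response is None:
        raise TableError("table carries no response to transform")
    if table.response_scale != "raw":
        raise TableError(f"response already on scale {table.response_scale!r}")
    if np.any(table.response <= 0):
        i = int(np.argmax(table.response <= 0))
        raise TableError(
            f"non-positive response for sample {table.sample_ids[i]!r}: "
            f"{table.response[i]}"
        )
    return dataclasses.replace(
        table, response=np.log(table.response), response_scale="ln"
    )


def standardize(table: DescriptorTable) -> tuple[DescriptorTable, StandardizationParams]:
    """Mean/SD standardization (sample sd, ddof=1) of every descriptor column."""
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = table.descriptor_names[int(np.argmax(sds <= 0))]
        raise TableError(f"zero-variance column {bad!r}; pre-reduce first")
    params = StandardizationParams(table.descriptor_names, means, sds)
    return apply_standardization(table, params), params


def apply_standardization(
    table: DescriptorTable, params: StandardizationParams
) -> DescriptorTable:
    if table.descriptor_names != params.descriptor_names:
        raise TableError("standardization params do not match table columns")
    return dataclasses.replace(table, values=(table.values - params.means) / params.sds)


def invert_standardization(
    table: DescriptorTable, params: StandardizationParams
) -> DescriptorTable:
    if table.descriptor_names != params.descriptor_names:
        raise TableError("standardization params do not match table columns")
    return dataclasses.replace(table, values=table.values * params.sds + params.means)


def _near_constant_mask(values: np.ndarray, identical_fraction: float = 0.95):
    """Columns that are constant or nearly so.

    A column is near-constant when sd < 1e-8·(1+|mean|) or when more than
    ``identical_fraction`` of its values are identical.
    """
    n = values.shape[0]
    sds = values.std(axis=0, ddof=1) if n > 1 else np.zeros(values.shape[1])
    means = values.mean(axis=0)
    constant = np.array([np.all(col == col[0]) for col in values.T])
    tiny_sd = sds < 1e-8 * (1.0 + np.abs(means))
    mostly_same = np.array(
        [np.max(np.unique(col, return_counts=True)[1]) / n > identical_fraction
         for col in values.T]
    )
    return constant, (~constant) & (tiny_sd | mostly_same)


def prereduce(
    table: DescriptorTable,
    corr_threshold: float = 0.99,
    identical_fraction: float = 0.95,
) -> tuple[DescriptorTable, PrereductionLog]:
    """Drop constant, near-constant and highly inter-correlated descriptors.

    Correlated pairs (|Pearson r| > ``corr_threshold``) are visited in order
    of descending |r|; the member with the larger mean absolute correlation to
    the remaining columns is removed (tie broken toward the later column).
    """
    if table.n_descriptors < 2:
        raise TableError("pre-reduction needs at least two descriptors")
    log = PrereductionLog(
        threshold=corr_threshold,
        near_constant_rule=(
            f"sd < 1e-8*(1+|mean|) or > {identical_fraction:.0%} identical values"
        ),
    )
    constant, near_constant = _near_constant_mask(table.values, identical_fraction)
    keep = [
        name
        for i, name in enumerate(table.descriptor_names)
        if not (constant[i] or near_constant[i])
    ]
    log.removed_constant = [n for i, n in enumerate(table.descriptor_names) if constant[i]]
    log.removed_near_constant = [
        n for i, n in enumerate(table.descriptor_names) if near_constant[i]
    ]
    if not keep:
        raise TableError("pre-reduction removed every descriptor")

    # iteratively peel off the worst member of the currently-highest |r| pair
    while True:
        sub = table.select_descriptors(keep)
        corr = np.corrcoef(sub.values, rowvar=False)
        if corr.ndim == 0:  # single column left
            break
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(abs_corr), abs_corr.shape)
        if abs_corr[i, j] <= corr_threshold:
            break
        # remove whichever of i, j is on average more redundant with the rest
        mean_i = abs_corr[i].sum() / (len(keep) - 1)
        mean_j = abs_corr[j].sum() / (len(keep) - 1)
        drop, kept = (i, j) if mean_i > mean_j else (j, i) if mean_j > mean_i else (
            (max(i, j), min(i, j))
        )
        log.removed_correlated.append(
            (keep[kept], keep[drop], float(corr[i, j]))
        )
        del keep[drop]
        if len(keep) < 2:
            break
    if not keep:
        raise TableError("pre-reduction removed every descriptor")
    return table.select_descriptors(keep), log
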