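"""Structure–property interpretation of a fitted micelle model.

Two views connect the selected descriptors back to polymer chemistry:
Pearson correlations between monomer-segment content (caprolactone PCL,
pH-sensitive PDEA, hydrophilic PPEGMA, and composites such as PCL+PDEA) and
each descriptor, and per-monomer descriptor contributions expressed as a
ratio of ratios against a reference monomer — the reference row is 1 for
every descriptor by construction, so the table is invariant to any global
rescaling of the underlying values or bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DescriptorTable

__all__ = [
    "SegmentComposition",
    "segment_descriptor_correlation",
    "monomer_contribution",
    "contribution_table",
]


@dataclass(frozen=True)
class SegmentComposition:
    """Per-sample monomer-segment counts (or weights), plus derived sums."""

    sample_ids: tuple[str, ...]
    segments: dict  # name -> vector of counts aligned to sample_ids
    composites: dict = field(default_factory=dict)  # name -> list of components

    def __post_init__(self) -> None:
        segs = {k: np.asarray(v, float) for k, v in self.segments.items()}
        object.__setattr__(self, "segments", segs)
        n = len(self.sample_ids)
        for name, vec in segs.items():
            if vec.shape != (n,):
                raise ValueError(f"segment {name!r} length mismatch")
            if np.any(vec < 0):
                raise ValueError(f"segment {name!r} has negative counts")

    def vector(self, name: str) -> np.ndarray:
        if name in self.segments:
            return self.segments[name]
        if name in self.composites:
            return np.sum([self.vector(c) for c in self.composites[name]], axis=0)
        raise KeyError(name)

    def all_names(self) -> tuple[str, ...]:
        return tuple(self.segments) + tuple(self.composites)


def segment_descriptor_correlation(
    composition: SegmentComposition,
    table: DescriptorTable,
    descriptors,
) -> pd.DataFrame:
    """Pearson r of each segment (rows) with each descriptor (columns)."""
    if composition.sample_ids != table.sample_ids:
        raise ValueError("composition and table sample ids differ")
    descriptors = tuple(descriptors)
    out = {}
    for seg in composition.all_names():
        svec = composition.vector(seg)
        if np.std(svec) == 0:
            raise ValueError(f"segment {seg!r} has zero variance")
        row = []
        for d in descriptors:
            dvec = table.column(d)
            if np.std(dvec) == 0:
                raise ValueError(f"descriptor {d!r} has zero variance")
            row.append(float(np.corrcoef(svec, dvec)[0, 1]))
        out[seg] = row
    return pd.DataFrame.from_dict(out, orient="index", columns=descriptors)


def monomer_contribution(
    value_per_monomer: float,
    basis_per_monomer: float,
    value_ref: float,
    basis_ref: float,
) -> float:
    """Contribution ratio of one monomer relative to the reference monomer.

    ``C = (value/basis) / (value_ref/basis_ref)``; feeding the reference's
    own value and basis yields 1 by construction.
    """
    for name, v in (
        ("value_per_monomer", value_per_monomer),
        ("basis_per_monomer", basis_per_monomer),
        ("value_ref", value_ref),
        ("basis_ref", basis_ref),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (value_per_monomer / basis_per_monomer) / (value_ref / basis_ref)


def contribution_table(
    values: pd.DataFrame, bases: pd.Series | dict, reference: str
) -> pd.DataFrame:
    """Per-(monomer, descriptor) contribution ratios against ``reference``.

    ``values``: rows = monomers, columns = descriptors (descriptor value
    attributable to each monomer); ``bases``: per-monomer normalizing basis
    (e.g. a per-unit total).  The reference monomer's row is identically 1.
    """
    bases = pd.Series(bases)
    if reference not in values.index:
        raise KeyError(f"reference monomer {reference!r} not in table")
    missing = set(values.index) - set(bases.index)
    if missing:
        raise KeyError(f"missing basis for monomers: {sorted(missing)}")
    if values.isna().any().any():
        raise ValueError("missing cell in contribution values")
    out = values.copy().astype(float)
    for mono in values.index:
        for desc in values.columns:
            out.loc[mono, desc] = monomer_contribution(
                float(values.loc[mono, desc]),
                float(bases[mono]),
                float(values.loc[reference, desc]),
                float(bases[reference]),
            )
    return out
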