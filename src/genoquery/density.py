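"""Variant density and cumulated numeric-field series over a sequence interval.

Densities are binned counts of (optionally query-filtered) variants on a
1-based inclusive interval.  Re-binning at a different resolution is simply
a recomputation with a new ``n_bins`` — zooming in recomputes at full
resolution rather than subdividing coarse bins.  The position exactly at
``range_max`` falls in the last bin (clamping), matching the inclusive
interval convention used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import DatasetDescriptor, ValidationError
from .store import VariantStore


@dataclass
class DensityBins:
    sequence: str
    range_min: int
    range_max: int
    n_bins: int
    counts: list[int]
    field_sums: Optional[list[float]] = None

    @property
    def bin_width(self) -> float:
        return (self.range_max - self.range_min + 1) / self.n_bins

    def bin_edges(self) -> list[tuple[int, int]]:
        """Inclusive (start, end) positions of each bin, for reporting."""
        w = self.bin_width
        edges = []
        for b in range(self.n_bins):
            start = self.range_min + int(np.floor(b * w))
            end = self.range_min + int(np.ceil((b + 1) * w)) - 1
            edges.append((start, min(end, self.range_max)))
        return edges


def _check(dataset: DatasetDescriptor, sequence: str, range_min: int, range_max: int, n_bins: int):
    if sequence not in dataset.sequences:
        raise ValidationError(f"unknown sequence {sequence!r}")
    if range_min > range_max:
        raise ValidationError("range_min > range_max")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")


def _bin_of(positions: np.ndarray, range_min: int, width: float, n_bins: int) -> np.ndarray:
    b = np.floor((positions - range_min) / width).astype(int)
    return np.clip(b, 0, n_bins - 1)


def compute_density(
    store: VariantStore,
    dataset: DatasetDescriptor,
    sequence: str,
    range_min: int,
    range_max: int,
    n_bins: int,
    variant_ids: Optional[set] = None,
) -> DensityBins:
    """Binned variant counts on an interval, via the variant-level index."""
    _check(dataset, sequence, range_min, range_max, n_bins)
    positions = np.asarray(
        store.variant_positions(dataset, sequence, range_min, range_max, variant_ids),
        dtype=float,
    )
    counts = np.zeros(n_bins, dtype=int)
    if positions.size:
        width = (range_max - range_min + 1) / n_bins
        np.add.at(counts, _bin_of(positions, range_min, width, n_bins), 1)
    return DensityBins(sequence, range_min, range_max, n_bins, counts.tolist())


def compute_field_series(
    store: VariantStore,
    dataset: DatasetDescriptor,
    field: str,
    individuals: Sequence[str],
    sequence: str,
    range_min: int,
    range_max: int,
    n_bins: int,
    variant_ids: Optional[set] = None,
) -> DensityBins:
    """Density bins plus the field's per-bin sum over selected individuals.

    ``field_sums[b]`` accumulates, over variants falling in bin ``b``, the
    stored values of ``field`` for the selected individuals; absent values
    contribute nothing.
    """
    _check(dataset, sequence, range_min, range_max, n_bins)
    if field not in dataset.numeric_fields:
        raise ValidationError(
            f"unknown field {field!r}; detected fields: {sorted(dataset.numeric_fields)}"
        )
    bad = set(individuals) - set(dataset.individuals)
    if bad:
        raise ValidationError(f"unknown individual(s): {sorted(bad)[:5]}")
    width = (range_max - range_min + 1) / n_bins
    counts = np.zeros(n_bins, dtype=int)
    sums = np.zeros(n_bins, dtype=float)
    inds = list(individuals)
    for rec, run in store.iter_records(dataset, variant_ids):
        if rec.sequence != sequence or not range_min <= rec.position <= range_max:
            continue
        b = int(_bin_of(np.asarray([float(rec.position)]), range_min, width, n_bins)[0])
        counts[b] += 1
        for ind in inds:
            v = run.numeric_values.get(ind, {}).get(field)
            if v is not None:
                sums[b] += v
    return DensityBins(sequence, range_min, range_max, n_bins, counts.tolist(), sums.tolist())
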