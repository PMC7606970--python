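"""Cell density in halite from DAPI-stained filter counts.

Ground halite (0.5 g) is dissolved, the suspension filtered onto a
25-mm-diameter filter, and cells counted in several microscope fields of
view per filter.  Each field count converts to a per-image density:

    density = count × (filter_area / eFOV) × (V_total / V_filtered) / mass

with eFOV the effective field of view of the camera (0.203 mm² at 400×),
filter_area = 226.98 mm², and the volume ratio correcting for the fraction
of the suspension that was filtered.  Per-image estimates outside k = 2
sample standard deviations of their mean are discarded in a single pass and
the density reported as the mean of the retained estimates.

The total suspension volume is not a fixed instrument constant; the default
of 10 ml is a documented convention and absolute densities scale linearly
with it — set ``volume_total`` to the value actually used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CountingConstants",
    "FieldCountSet",
    "DensityEstimate",
    "reject_outliers",
    "per_image_density",
    "cells_per_gram",
]


@dataclass(frozen=True)
class CountingConstants:
    """Microscopy and sample-prep constants for the density calculation."""

    efov_mm2: float = 0.203
    filter_area_mm2: float = 226.98
    volume_filtered_ml: float = 2.0
    volume_total_ml: float = 10.0
    mass_g: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.volume_filtered_ml > self.volume_total_ml:
            raise ValueError("volume_filtered_ml cannot exceed volume_total_ml")

    @property
    def cells_per_count(self) -> float:
        """Density (cells/g) contributed by one counted cell in one image."""
        return (
            (self.filter_area_mm2 / self.efov_mm2)
            * (self.volume_total_ml / self.volume_filtered_ml)
            / self.mass_g
        )


@dataclass
class FieldCountSet:
    """Per-image cell counts for one biological sample.

    The study design pools 3 filters × 5 images = 15 counts per sample;
    any number is accepted.  ``filters`` optionally records which technical
    replicate (filter) each image came from.
    """

    counts: np.ndarray
    filters: np.ndarray | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValueError("counts must be a non-empty 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.filters is not None:
            self.filters = np.asarray(self.filters)
            if self.filters.shape != self.counts.shape:
                raise ValueError("filters must align with counts")


@dataclass(frozen=True)
class DensityEstimate:
    cells_per_gram: float
    n_used: int
    n_discarded: int

    def __post_init__(self) -> None:
        if self.cells_per_gram < 0:
            raise ValueError("density cannot be negative")


def reject_outliers(values, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier rejection: drop values more than ``k`` sample
    standard deviations from the mean of all values.

    Not iterated; with zero spread everything is retained.  Returns the
    retained values and the indices of discarded ones.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector of at least two values")
    if not k > 0:
        raise ValueError("k must be positive")
    sd = values.std(ddof=1)
    if sd == 0:
        return values, np.array([], dtype=int)
    out = np.abs(values - values.mean()) > k * sd
    return values[~out], np.flatnonzero(out)


def per_image_density(counts, constants: CountingConstants) -> np.ndarray:
    """Convert per-image counts to per-image density estimates (cells/g)."""
    return np.asarray(counts, dtype=float) * constants.cells_per_count


def cells_per_gram(
    fields: FieldCountSet,
    constants: CountingConstants = CountingConstants(),
    k: float = 2.0,
) -> DensityEstimate:
    """Estimate cells per gram of halite from a set of field counts.

    Per-image densities are pooled across filters within the sample,
    outliers rejected once (``k`` SDs), and the mean of the retained
    estimates returned.
    """
    dens = per_image_density(fields.counts, constants)
    if len(dens) >= 2:
        retained, discarded = reject_outliers(dens, k=k)
    else:
        retained, discarded = dens, np.array([], dtype=int)
    if len(retained) == 0:
        raise ValueError("all field counts were discarded as outliers")
    return DensityEstimate(
        cells_per_gram=float(retained.mean()),
        n_used=len(retained),
        n_discarded=len(discarded),
    )
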