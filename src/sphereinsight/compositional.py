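"""Closure to the simplex and the square-root map onto the unit hypersphere.

Zero handling is the whole point of this module: microbiome count tables are
overwhelmingly zero, and the square-root transform is chosen precisely because
it sends exact zeros to exact zeros — no pseudocount, no zero replacement,
anywhere. Log-ratio transforms (alr/clr/ilr) are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .tabular_io import CountTable

_ATOL = 1e-12


@dataclass
class CompositionTable:
    """Samples x taxa relative abundances; each row sums to 1.

    Boundary zeros are allowed: zero-inflated data live on the closed simplex,
    and entries that were exactly zero as counts remain exactly zero here.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("composition shape does not match identifier lists")
        if np.any(self.values < 0):
            raise ValidationError("composition has negative entries")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"row {self.sample_ids[bad]!r} sums to {sums[bad]!r}, expected 1"
            )


@dataclass
class SpherePoints:
    """Samples as unit vectors on the nonnegative orthant of the hypersphere."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("sphere points must be nonnegative")
        norms = np.linalg.norm(self.values, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValidationError(
                f"row {self.sample_ids[bad]!r} has norm {norms[bad]!r}, expected 1"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class ZeroMask:
    """Boolean samples x taxa matrix, True exactly where the raw count is 0."""

    mask: np.ndarray = field()

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


def closure(table: CountTable) -> CompositionTable:
    """Divide each sample's counts by its total, mapping onto the simplex.

    Zeros are preserved exactly. An all-zero sample has no composition and is
    an error (the reader already rejects these, but defend here too).
    """
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    zero_rows = np.nonzero(totals == 0)[0]
    if zero_rows.size:
        raise ValidationError(
            f"sample {table.sample_ids[zero_rows[0]]!r} has zero total count; "
            "closure undefined"
        )
    return CompositionTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
        values=counts / totals[:, None],
    )


def sqrt_transform(comp: CompositionTable) -> SpherePoints:
    """Elementwise square root: the simplex maps onto the unit hypersphere.

    Because composition rows sum to 1, the transformed rows have unit l2 norm;
    exact zeros map to exact zeros, so the zero pattern of the counts survives
    intact on the sphere.
    """
    if np.any(comp.values < 0):
        raise ValidationError("negative composition entry")
    return SpherePoints(
        sample_ids=list(comp.sample_ids),
        taxon_ids=list(comp.taxon_ids),
        values=np.sqrt(comp.values),
    )


def zero_mask(table: CountTable) -> ZeroMask:
    """True iff the raw count is exactly zero (structural or sampling zero)."""
    return ZeroMask(mask=np.asarray(table.counts) == 0)
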