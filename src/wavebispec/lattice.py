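"""Dense bifrequency-lattice view of per-pair fields.

Peak detection, contour statistics, band averaging and local-maxima counts
all act on a rectangular (f1, f2) lattice with a validity mask; per-pair
WBS/WBC fields are scattered onto the canonical triangle (f1 <= f2) of the
scale-grid lattice, and synthetic test fields can be built directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wbs import WBCField, WBSField

__all__ = ["PairLattice", "as_lattice"]


@dataclass
class PairLattice:
    """Real-valued field on a (f1, f2) lattice.

    ``values[i, j]`` corresponds to (f1_axis[i], f2_axis[j]); ``mask`` is
    True where the field is defined.
    """

    values: np.ndarray
    f1_axis: np.ndarray
    f2_axis: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.f1_axis = np.asarray(self.f1_axis, dtype=np.float64)
        self.f2_axis = np.asarray(self.f2_axis, dtype=np.float64)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.f1_axis.size, self.f2_axis.size):
            raise ValueError("lattice shape does not match frequency axes")

    @classmethod
    def full(cls, values, f1_axis, f2_axis) -> "PairLattice":
        return cls(values=values, f1_axis=f1_axis, f2_axis=f2_axis,
                   mask=np.ones(np.shape(values), dtype=bool))

    def masked(self, fill: float = np.nan) -> np.ndarray:
        out = np.where(self.mask, self.values, fill)
        return out


def as_lattice(field: "WBSField | WBCField | PairLattice", kind: str = "amp") -> PairLattice:
    """Scatter a per-pair field onto the canonical (f1 <= f2) lattice.

    ``kind`` selects 'amp' (modulus, or the real WBC value) or 'phase'.
    """
    if isinstance(field, PairLattice):
        return field
    grid = field.grid
    freqs = grid.scale_grid.freqs
    n = freqs.size
    vals = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    if isinstance(field, WBSField):
        data = field.amplitude if kind == "amp" else field.biphase
    else:
        data = field.values
    vals[grid.i1, grid.i2] = data
    mask[grid.i1, grid.i2] = True
    return PairLattice(values=vals, f1_axis=freqs, f2_axis=freqs, mask=mask)
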