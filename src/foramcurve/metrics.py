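"""Segmentation accuracy and volumetric trait measurements.

The multi-label Dice score between two segmentations ``X`` and ``X'`` over a
set of labels is

    Dice = 2 * sum_i |X_i ∩ X'_i| / (|X| + |X'|)

where ``X_i`` is the voxel subset of ``X`` carrying label ``i`` and ``|X|``
counts the voxels of ``X`` whose label is in scope.  By default only the two
foreground classes (external, internal) are in scope: including the dominant
background class would inflate the score toward 1 and mask segmentation
differences.  Pass ``include_background=True`` for the strict all-label
reading.

Volumetric traits are total volume (external + internal) and "percentage
calcite", computed literally as external volume / internal volume * 100.  A
``fraction_of_total`` convention (external / (external + internal) * 100) is
available behind ``calcite_convention``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, SpecificationError
from .stackio import EXTERNAL, INTERNAL, LABEL_CODES

FOREGROUND_LABELS = frozenset({EXTERNAL, INTERNAL})


def dice(
    X: np.ndarray,
    X_prime: np.ndarray,
    labels_in_scope: frozenset[int] | set[int] = FOREGROUND_LABELS,
    *,
    include_background: bool = False,
) -> float:
    """Multi-label Dice score between two categorical grids.

    Returns a value in [0, 1]; 1 when both segmentations have zero in-scope
    voxels (perfect vacuous agreement, by convention).
    """
    X = np.asarray(X)
    X_prime = np.asarray(X_prime)
    if X.shape != X_prime.shape:
        raise DimensionError(
            f"segmentation shapes differ: {tuple(X.shape)} vs {tuple(X_prime.shape)}"
        )
    scope = set(labels_in_scope) | (set(LABEL_CODES) if include_background else set())
    if not scope:
        raise SpecificationError("labels_in_scope must be non-empty")
    matched = 0
    size_x = 0
    size_xp = 0
    for code in sorted(scope):
        in_x = X == code
        in_xp = X_prime == code
        matched += int(np.count_nonzero(in_x & in_xp))
        size_x += int(np.count_nonzero(in_x))
        size_xp += int(np.count_nonzero(in_xp))
    if size_x + size_xp == 0:
        return 1.0
    return 2.0 * matched / (size_x + size_xp)


@dataclass(frozen=True)
class VolumetricTraits:
    """Total volume and percentage calcite for one segmentation."""

    external_volume_um3: float
    internal_volume_um3: float
    total_volume_um3: float
    percentage_calcite: float | None  #: None when internal volume is zero

    @property
    def percentage_calcite_defined(self) -> bool:
        return self.percentage_calcite is not None


def volumetric_traits(
    labels: np.ndarray,
    voxel_size_um: float,
    calcite_convention: str = "literal",
) -> VolumetricTraits:
    """Measure volumes (µm³) and percentage calcite from a label grid.

    ``calcite_convention="literal"`` divides external by internal volume;
    ``"fraction_of_total"`` divides external by total foreground volume.
    With zero internal volume the percentage is flagged undefined (``None``),
    never infinity.
    """
    if voxel_size_um <= 0:
        raise SpecificationError(f"voxel_size_um must be > 0, got {voxel_size_um}")
    if calcite_convention not in ("literal", "fraction_of_total"):
        raise SpecificationError(
            f"unknown calcite_convention {calcite_convention!r}"
        )
    labels = np.asarray(labels)
    vox3 = float(voxel_size_um) ** 3
    n_ext = int(np.count_nonzero(labels == EXTERNAL))
    n_int = int(np.count_nonzero(labels == INTERNAL))
    ext = n_ext * vox3
    internal = n_int * vox3
    if calcite_convention == "literal":
        pct = (ext / internal) * 100.0 if n_int > 0 else None
    else:
        pct = (ext / (ext + internal)) * 100.0 if (n_ext + n_int) > 0 else None
    return VolumetricTraits(
        external_volume_um3=ext,
        internal_volume_um3=internal,
        total_volume_um3=ext + internal,
        percentage_calcite=pct,
    )
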