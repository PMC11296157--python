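"""Axis-order data augmentation.

Each specimen is materialised in six distinct 3D orientations named by the
order in which the original axes appear: ``xyz`` (identity), ``yzx``,
``zyx``, ``xzy``, ``yxz`` and ``zxy``.  An orientation name ``abc`` reads
"the new x axis is the original *a* axis, the new y axis the original *b*
axis, the new z axis the original *c* axis".  These are pure axis
permutations (array transposes): three of the five non-identity ones are
improper (mirror) transforms; ``proper=True`` adds a single axis flip to
each odd permutation to make it a proper rotation (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import SpecificationError
from .stackio import ORIENTATION_NAMES, VolumePair

_AXIS_LETTERS = "xyz"


def _name_to_perm(name: str) -> tuple[int, int, int]:
    # perm[i] = source semantic axis (0=x,1=y,2=z) of new semantic axis i
    return tuple(_AXIS_LETTERS.index(ch) for ch in name)  # type: ignore[return-value]


def _perm_to_name(perm: tuple[int, int, int]) -> str:
    return "".join(_AXIS_LETTERS[i] for i in perm)


@dataclass(frozen=True)
class Orientation:
    """One of the six axis orders, as a permutation of (x, y, z)."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in ORIENTATION_NAMES:
            raise SpecificationError(
                f"unknown orientation {self.name!r}; expected one of {ORIENTATION_NAMES}"
            )

    @property
    def axis_permutation(self) -> tuple[int, int, int]:
        """Source semantic axis of each new semantic axis, x-first."""
        return _name_to_perm(self.name)

    @property
    def array_axes(self) -> tuple[int, int, int]:
        """Axes argument for ``np.transpose`` on a (z, y, x)-indexed array."""
        perm = self.axis_permutation
        # array axis 0 is semantic z (= new axis 2), etc.; semantic axis s
        # lives at array axis 2 - s
        return tuple(2 - perm[2 - a] for a in range(3))  # type: ignore[return-value]

    @property
    def is_proper(self) -> bool:
        """True when the permutation is an even (rotation-only) permutation."""
        p = self.axis_permutation
        inversions = sum(
            p[i] > p[j] for i in range(3) for j in range(i + 1, 3)
        )
        return inversions % 2 == 0

    def compose(self, first: str) -> str:
        """Name of the orientation reached by applying ``self`` to a volume
        already in orientation ``first``."""
        q = _name_to_perm(first)
        p = self.axis_permutation
        return _perm_to_name(tuple(q[p[i]] for i in range(3)))

    def inverse(self) -> "Orientation":
        p = self.axis_permutation
        inv = [0, 0, 0]
        for i, s in enumerate(p):
            inv[s] = i
        return Orientation(_perm_to_name(tuple(inv)))


ORIENTATIONS = tuple(Orientation(name) for name in ORIENTATION_NAMES)


def reorient(pair: VolumePair, o: Orientation | str, proper: bool = False) -> VolumePair:
    """Permute the axes of a pair's grey and label grids identically.

    The voxel multiset — and hence every per-label count — is unchanged.
    With ``proper=True`` odd permutations additionally flip the new x axis so
    that every orientation is a proper rotation.
    """
    if isinstance(o, str):
        o = Orientation(o)
    axes = o.array_axes
    grey = np.ascontiguousarray(np.transpose(pair.grey, axes))
    labels = np.ascontiguousarray(np.transpose(pair.labels, axes))
    if proper and not o.is_proper:
        grey = grey[:, :, ::-1].copy()
        labels = labels[:, :, ::-1].copy()
    return replace(
        pair,
        grey=grey,
        labels=labels,
        orientation_tag=o.compose(pair.orientation_tag),
    )


def augment_set(pairs: list[VolumePair], proper: bool = False) -> list[VolumePair]:
    """Materialise all six orientations of every pair (originals included).

    Returns ``6 * len(pairs)`` pairs ordered originals-first, then by
    orientation name in the canonical order, stable in specimen order.
    Refuses input that is already augmented (non-``"xyz"`` tags) to prevent
    double augmentation.
    """
    for p in pairs:
        if p.orientation_tag != "xyz":
            raise SpecificationError(
                f"pair {p.specimen_id!r} has orientation {p.orientation_tag!r}; "
                "augment_set requires canonical 'xyz' input"
            )
    out = [p.copy() for p in pairs]
    for o in ORIENTATIONS[1:]:
        for p in pairs:
            out.append(reorient(p, o, proper=proper))
    return out


def count_foreground_slices(pair: VolumePair) -> int:
    """Number of constant-z (XY) slices containing any non-background voxel."""
    return int(np.count_nonzero(pair.labels.reshape(pair.labels.shape[0], -1).any(axis=1)))
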