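"""Paired greyscale / label stack I/O.

Volumes are indexed ``(z, y, x)``; page ``k`` of a multipage TIFF is the XY
slice at depth ``k``.  Greyscale stacks are written as 16-bit TIFF, label
stacks as 8-bit TIFF with the fixed label convention

====================  ====
class                 code
====================  ====
background            0
external (wall)       1
internal (cavity)     2
====================  ====

A plain-text sidecar (``<grey stem>.meta.txt``) records specimen identity,
voxel size and orientation so a pair can be reloaded without external
bookkeeping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import DimensionError, LabelError, SpecificationError

BACKGROUND = 0
EXTERNAL = 1
INTERNAL = 2
LABEL_CODES = (BACKGROUND, EXTERNAL, INTERNAL)
LABEL_NAMES = {BACKGROUND: "background", EXTERNAL: "external", INTERNAL: "internal"}

#: the six axis-order names; "xyz" is the identity orientation
ORIENTATION_NAMES = ("xyz", "yzx", "zyx", "xzy", "yxz", "zxy")


@dataclass
class VolumePair:
    """One specimen: greyscale volume, label volume and metadata.

    Attributes
    ----------
    specimen_id:
        Free-text identity of the specimen.
    grey:
        3D ``uint16`` intensity grid, indexed ``(z, y, x)``.
    labels:
        3D ``uint8`` categorical grid over ``{0, 1, 2}``, same shape as
        ``grey``.
    voxel_size_um:
        Isotropic voxel edge length in micrometres; strictly positive.
    orientation_tag:
        One of the six axis-order names; ``"xyz"`` for canonical data.
    """

    specimen_id: str
    grey: np.ndarray
    labels: np.ndarray
    voxel_size_um: float
    orientation_tag: str = "xyz"
    params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.grey = np.asarray(self.grey)
        self.labels = np.asarray(self.labels)
        validate_pair(self.grey, self.labels)
        if self.voxel_size_um <= 0:
            raise SpecificationError(
                f"voxel_size_um must be > 0, got {self.voxel_size_um}"
            )
        if self.orientation_tag not in ORIENTATION_NAMES:
            raise SpecificationError(
                f"unknown orientation_tag {self.orientation_tag!r}; "
                f"expected one of {ORIENTATION_NAMES}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grey.shape)

    def with_labels(self, labels: np.ndarray) -> "VolumePair":
        return replace(self, labels=np.asarray(labels, dtype=np.uint8))

    def copy(self) -> "VolumePair":
        return replace(self, grey=self.grey.copy(), labels=self.labels.copy())


def validate_pair(grey: np.ndarray, labels: np.ndarray) -> None:
    """Check the two grids against the type invariants.

    Raises :class:`DimensionError` on shape mismatch (naming both shapes) and
    :class:`LabelError` listing any codes outside the convention; codes are
    reported, never silently remapped.
    """
    if grey.ndim != 3 or labels.ndim != 3:
        raise DimensionError(
            f"expected 3D grids, got grey.ndim={grey.ndim}, labels.ndim={labels.ndim}"
        )
    if grey.shape != labels.shape:
        raise DimensionError(
            f"grey shape {tuple(grey.shape)} != label shape {tuple(labels.shape)}"
        )
    codes = np.unique(labels)
    bad = [int(c) for c in codes if int(c) not in LABEL_CODES]
    if bad:
        raise LabelError(f"unknown label codes {bad}; permitted codes are {LABEL_CODES}")


def _sidecar_path(grey_path: str | os.PathLike) -> str:
    base, _ = os.path.splitext(os.fspath(grey_path))
    return base + ".meta.txt"


def write_pair(
    pair: VolumePair, grey_path: str | os.PathLike, label_path: str | os.PathLike
) -> None:
    """Write a pair as 16-bit grey TIFF + 8-bit label TIFF + text sidecar.

    Page ``k`` of each file is the XY slice at depth ``k``.
    """
    grey = np.asarray(pair.grey, dtype=np.uint16)
    labels = np.asarray(pair.labels, dtype=np.uint8)
    tifffile.imwrite(os.fspath(grey_path), grey, photometric="minisblack")
    tifffile.imwrite(os.fspath(label_path), labels, photometric="minisblack")
    with open(_sidecar_path(grey_path), "w", encoding="utf-8") as fh:
        fh.write(f"specimen_id: {pair.specimen_id}\n")
        fh.write(f"voxel_size_um: {pair.voxel_size_um}\n")
        fh.write(f"orientation_tag: {pair.orientation_tag}\n")


def read_pair(
    grey_path: str | os.PathLike,
    label_path: str | os.PathLike,
    voxel_size_um: float | None = None,
    specimen_id: str | None = None,
) -> VolumePair:
    """Read a grey/label TIFF pair into a :class:`VolumePair`.

    ``voxel_size_um`` and ``specimen_id`` default to the values recorded in
    the sidecar file when present.  Grey data of other integer bit depths is
    accepted and widened/narrowed to ``uint16``; label data must already use
    the three-code convention.
    """
    grey = np.atleast_3d(tifffile.imread(os.fspath(grey_path)))
    labels = np.atleast_3d(tifffile.imread(os.fspath(label_path)))
    if grey.dtype != np.uint16:
        info = np.iinfo(grey.dtype) if np.issubdtype(grey.dtype, np.integer) else None
        if info is not None and info.max > np.iinfo(np.uint16).max:
            grey = (grey.astype(np.float64) * (65535.0 / info.max)).astype(np.uint16)
        else:
            grey = grey.astype(np.uint16)
    labels = labels.astype(np.uint8, casting="unsafe")

    meta: dict[str, str] = {}
    sidecar = _sidecar_path(grey_path)
    if os.path.exists(sidecar):
        with open(sidecar, encoding="utf-8") as fh:
            for line in fh:
                if ":" in line:
                    key, value = line.split(":", 1)
                    meta[key.strip()] = value.strip()
    if voxel_size_um is None:
        voxel_size_um = float(meta.get("voxel_size_um", "nan"))
        if not np.isfinite(voxel_size_um):
            raise SpecificationError(
                "voxel_size_um not given and no sidecar metadata found"
            )
    if specimen_id is None:
        specimen_id = meta.get(
            "specimen_id", os.path.splitext(os.path.basename(os.fspath(grey_path)))[0]
        )
    return VolumePair(
        specimen_id=specimen_id,
        grey=grey,
        labels=labels,
        voxel_size_um=float(voxel_size_um),
        orientation_tag=meta.get("orientation_tag", "xyz"),
    )
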