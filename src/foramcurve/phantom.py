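"""Synthetic chambered-shell phantom generator.

Produces populations of paired grey/label volumes with the statistical
structure the downstream analysis assumes: a bright calcite-like wall, an
internal cavity partially filled with sediment-like material whose intensity
is close to the wall's (the dial that makes the internal structure hard to
segment), imaging noise, and specimen-to-specimen variation in size and
shape.

Geometry: chambers are balls placed along a logarithmic spiral that rises
axially (a minimal trochospiral).  The cavity is the union of the balls
shrunk by the wall thickness; the wall (external class) is the union of the
full balls minus the cavity, so later chambers carve through earlier walls
and the outer wall stays continuous.  Sediment infill occupies the lowest-z
fraction of the cavity (sediment settles); infill changes only the grey
intensity — its label stays *internal*, mirroring how manual segmentation
assigns sediment-filled cavity to the internal class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, SpecificationError
from .stackio import BACKGROUND, EXTERNAL, INTERNAL, VolumePair

DEFAULT_INTENSITY_MEANS = {
    "background": 5000.0,
    "wall": 45000.0,
    "cavity": 12000.0,
    "infill": 42000.0,
}


@dataclass
class PhantomParams:
    """Parameters of a single synthetic specimen.

    ``chamber_radius_vox`` is the radius of the first (smallest) chamber;
    successive chamber radii grow by ``spiral_growth_rate``.  All linear
    parameters are in voxels.
    """

    n_chambers: int = 6
    chamber_radius_vox: float = 5.0
    spiral_growth_rate: float = 1.12
    trochospire_pitch: float = 1.0
    wall_thickness_vox: float = 2.0
    infill_fraction: float = 0.0
    intensity_means: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    noise_sd: float = 1500.0
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 1.75
    seed: int = 0
    #: angular step between successive chambers (radians)
    angle_step: float = 1.9
    #: chamber-centre distance from the coil axis, as a fraction of radius
    coil_tightness: float = 0.85
    #: allowed |wall - infill| contrast, relative to wall - cavity contrast
    infill_contrast_tol: float = 0.35
    #: "shrink" scales the geometry down to fit the volume; "error" raises
    fit_mode: str = "shrink"

    def validate(self) -> None:
        if self.n_chambers < 1:
            raise SpecificationError("n_chambers must be >= 1")
        if self.spiral_growth_rate <= 1.0 and self.n_chambers > 1:
            raise SpecificationError("spiral_growth_rate must be > 1")
        if self.wall_thickness_vox < 1:
            raise SpecificationError("wall_thickness_vox must be >= 1")
        if not 0.0 <= self.infill_fraction <= 1.0:
            raise SpecificationError("infill_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.voxel_size_um <= 0:
            raise SpecificationError("noise_sd >= 0 and voxel_size_um > 0 required")
        if self.trochospire_pitch < 0:
            raise SpecificationError("trochospire_pitch must be >= 0")
        m = self.intensity_means
        for key in ("background", "wall", "cavity", "infill"):
            if key not in m:
                raise SpecificationError(f"intensity_means missing {key!r}")
        if not m["wall"] > m["cavity"]:
            raise SpecificationError("intensity_means: wall must exceed cavity")
        if abs(m["wall"] - m["infill"]) > self.infill_contrast_tol * (
            m["wall"] - m["cavity"]
        ):
            raise SpecificationError(
                "intensity_means: infill must sit close to wall "
                f"(|wall-infill| <= {self.infill_contrast_tol} * (wall-cavity))"
            )
        if self.fit_mode not in ("shrink", "error"):
            raise SpecificationError("fit_mode must be 'shrink' or 'error'")


def _chamber_centres_radii(
    params: PhantomParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Chamber centres (z, y, x offsets from volume centre) and radii."""
    k = np.arange(params.n_chambers, dtype=np.float64)
    radii = params.chamber_radius_vox * params.spiral_growth_rate**k
    theta = k * params.angle_step
    rho = params.coil_tightness * radii
    centres = np.stack(
        [
            k * params.trochospire_pitch,  # z
            rho * np.sin(theta),  # y
            rho * np.cos(theta),  # x
        ],
        axis=1,
    )
    centres -= centres.mean(axis=0, keepdims=True)
    return centres, radii


def generate_phantom(params: PhantomParams, specimen_id: str = "phantom") -> VolumePair:
    """Render one specimen; deterministic given ``params.seed``.

    Raises :class:`GeometryError` when the chambers cannot fit inside
    ``volume_shape`` (``fit_mode="error"``) or cannot be shrunk to fit while
    keeping a wall at least one voxel thick (``fit_mode="shrink"``).
    """
    params.validate()
    centres, radii = _chamber_centres_radii(params)
    shape = np.asarray(params.volume_shape, dtype=np.float64)

    # margin of 1 voxel to keep the outer wall off the volume faces
    half_extent = np.abs(centres).max(axis=0) + radii.max()
    limit = shape / 2.0 - 1.0
    scale = float(np.min(limit / np.maximum(half_extent, 1e-9)))
    if scale < 1.0:
        if params.fit_mode == "error":
            raise GeometryError(
                f"chambers (half extent {half_extent}) do not fit inside "
                f"volume_shape {params.volume_shape}"
            )
        centres = centres * scale
        radii = radii * scale
        if radii.min() <= params.wall_thickness_vox + 1.0:
            raise GeometryError(
                "phantom cannot be shrunk to fit volume_shape while keeping "
                f"a {params.wall_thickness_vox}-voxel wall; enlarge the volume "
                "or reduce chamber_radius_vox/n_chambers"
            )

    zz, yy, xx = np.meshgrid(
        *(np.arange(n, dtype=np.float32) for n in params.volume_shape), indexing="ij"
    )
    centre_of_volume = (shape - 1.0) / 2.0
    solid = np.zeros(params.volume_shape, dtype=bool)
    cavity = np.zeros(params.volume_shape, dtype=bool)
    for (cz, cy, cx), r in zip(centres + centre_of_volume, radii):
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        solid |= d2 <= r**2
        r_in = r - params.wall_thickness_vox
        if r_in > 0:
            cavity |= d2 <= r_in**2
    labels = np.full(params.volume_shape, BACKGROUND, dtype=np.uint8)
    labels[solid] = EXTERNAL
    labels[cavity] = INTERNAL

    # sediment settles: infill occupies the lowest-z slab of the cavity
    infill = np.zeros(params.volume_shape, dtype=bool)
    if params.infill_fraction > 0 and cavity.any():
        z_of_cavity = zz[cavity]
        cut = np.quantile(z_of_cavity, params.infill_fraction)
        infill = cavity & (zz <= cut)

    m = params.intensity_means
    grey = np.full(params.volume_shape, m["background"], dtype=np.float64)
    grey[labels == EXTERNAL] = m["wall"]
    grey[labels == INTERNAL] = m["cavity"]
    grey[infill] = m["infill"]
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        grey = grey + rng.normal(0.0, params.noise_sd, size=grey.shape)
    grey = np.clip(np.rint(grey), 0, 65535).astype(np.uint16)

    return VolumePair(
        specimen_id=specimen_id,
        grey=grey,
        labels=labels,
        voxel_size_um=params.voxel_size_um,
        params={"phantom": params},
    )


@dataclass
class PopulationSpec:
    """A population of phantoms with per-specimen parameter variation.

    ``variation`` maps a scalar :class:`PhantomParams` field name to either a
    ``(low, high)`` uniform range or a ``{"mean": m, "sd": s}`` normal law;
    dotted keys like ``"intensity_means.infill"`` address entries of the
    intensity map; every other field is copied from ``base``.  Integer
    fields are rounded.
    """

    n_specimens: int
    split: tuple[int, int, int]  # (n_train, n_val, n_test)
    base: PhantomParams = field(default_factory=PhantomParams)
    variation: dict = field(default_factory=dict)
    seed: int = 0
    id_prefix: str = "syn"

    _INT_FIELDS = ("n_chambers",)

    def validate(self) -> None:
        if self.n_specimens < 1:
            raise SpecificationError("n_specimens must be >= 1")
        if len(self.split) != 3 or any(s < 0 for s in self.split):
            raise SpecificationError("split must be three non-negative integers")
        if sum(self.split) != self.n_specimens:
            raise SpecificationError(
                f"split {self.split} must sum to n_specimens={self.n_specimens}"
            )
        for name in self.variation:
            if name.startswith("intensity_means."):
                if name.split(".", 1)[1] not in self.base.intensity_means:
                    raise SpecificationError(f"unknown intensity class in {name!r}")
            elif not hasattr(self.base, name):
                raise SpecificationError(f"unknown PhantomParams field {name!r}")

    def draw_params(self, rng: np.random.Generator, seed: int) -> PhantomParams:
        updates: dict = {"seed": seed, "intensity_means": dict(self.base.intensity_means)}
        for name, law in self.variation.items():
            if isinstance(law, dict):
                value = rng.normal(law["mean"], law["sd"])
            else:
                low, high = law
                value = rng.uniform(low, high)
            if name.startswith("intensity_means."):
                updates["intensity_means"][name.split(".", 1)[1]] = float(value)
                continue
            if name in self._INT_FIELDS:
                value = max(1, int(round(value)))
            elif name == "infill_fraction":
                value = float(np.clip(value, 0.0, 1.0))
            updates[name] = value
        return replace(self.base, **updates)


def generate_population(
    spec: PopulationSpec,
) -> tuple[list[VolumePair], list[VolumePair], list[VolumePair]]:
    """Generate ``spec.n_specimens`` phantoms and split them train/val/test.

    Per-specimen parameters are drawn from ``spec.variation``; the whole
    population is reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    noise_seeds = rng.integers(0, 2**31 - 1, size=spec.n_specimens)
    pairs = []
    for i in range(spec.n_specimens):
        params = spec.draw_params(rng, seed=int(noise_seeds[i]))
        pairs.append(
            generate_phantom(params, specimen_id=f"{spec.id_prefix}{i:03d}")
        )
    n_train, n_val, n_test = spec.split
    return (
        pairs[:n_train],
        pairs[n_train : n_train + n_val],
        pairs[n_train + n_val :],
    )


def desk_population_spec(
    n_specimens: int = 16,
    split: tuple[int, int, int] = (8, 3, 5),
    infill: str = "none",
    seed: int = 0,
    volume_shape: tuple[int, int, int] = (24, 24, 24),
) -> PopulationSpec:
    """Standard desk-scale population: small trochospiral shells with
    size/shape variation.

    ``infill="none"`` gives cleanly separable class intensities;
    ``infill="heavy"`` fills 50–95% of each cavity with material whose
    intensity approaches the wall's (varying per specimen), which is what
    makes the internal structure hard to segment.
    """
    if infill not in ("none", "heavy"):
        raise SpecificationError("infill must be 'none' or 'heavy'")
    base = PhantomParams(
        n_chambers=4,
        chamber_radius_vox=5.0,
        spiral_growth_rate=1.15,
        trochospire_pitch=1.0,
        wall_thickness_vox=2.0,
        infill_fraction=0.0,
        noise_sd=1200.0,
        volume_shape=volume_shape,
    )
    variation = {
        "chamber_radius_vox": (4.0, 5.5),
        "n_chambers": (3, 5),
        "spiral_growth_rate": (1.05, 1.2),
    }
    if infill == "heavy":
        variation["infill_fraction"] = (0.5, 0.95)
        variation["intensity_means.infill"] = (34000.0, 40000.0)
    return PopulationSpec(
        n_specimens=n_specimens, split=split, base=base,
        variation=variation, seed=seed,
    )


def sphere_shell_params(
    r_out: float,
    wall_thickness: float,
    volume_shape: tuple[int, int, int] | None = None,
    **kwargs,
) -> PhantomParams:
    """Single-chamber (spherical shell) phantom, handy for analytic checks."""
    if volume_shape is None:
        n = 2 * (int(math.ceil(r_out)) + 2)
        volume_shape = (n, n, n)
    return PhantomParams(
        n_chambers=1,
        chamber_radius_vox=r_out,
        trochospire_pitch=0.0,
        wall_thickness_vox=wall_thickness,
        volume_shape=volume_shape,
        **kwargs,
    )
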