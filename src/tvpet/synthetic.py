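"""Synthetic phantoms, line-integral projection and Poisson counting noise.

The module provides everything needed to exercise the reconstruction chain
without external data: piecewise-constant ellipse phantoms (stylised brain
and thorax presets), a discrete line-integral forward projector for direct
and oblique sinograms, and a Poisson counting-noise model parameterised by
the expected total event count.

Composition rule: a pixel's activity is the *sum* of the activities of all
shapes covering its centre, so nested structures are built by stacking
ellipses.  All shape activities must be non-negative.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ImageGrid, ObliqueSinogramSet, ScannerGeometry, Sinogram2D

__all__ = [
    "EllipseSpec",
    "PhantomSpec",
    "brain_like_spec",
    "thorax_like_spec",
    "disc_spec",
    "make_phantom",
    "forward_project",
    "make_oblique_set",
    "apply_counting_noise",
    "default_geometry",
]

#: Sampling step along each LOR, as a fraction of the pixel size.
LINE_SAMPLING_STEP = 0.5


@dataclass(frozen=True)
class EllipseSpec:
    """One elliptical component of a phantom.

    ``center`` and ``semi_axes`` are in pixel units relative to the image
    centre; ``angle_deg`` rotates the ellipse counter-clockwise.
    """

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    angle_deg: float = 0.0
    activity: float = 1.0


@dataclass
class PhantomSpec:
    """Recipe for a piecewise-constant phantom.

    Parameters
    ----------
    grid_size
        Pixels per side of the square image.
    shapes
        Elliptical components, composed additively.
    roi_labels
        Map from ROI id (positive integer) to the indices of the shapes
        making up that region.
    background_shape
        Index of the shape whose *exclusive* coverage defines the
        background region used by contrast recovery (pixels covered by this
        shape and by no other).
    preset_name
        Optional tag recording which preset produced the spec.
    """

    grid_size: int
    shapes: List[EllipseSpec] = field(default_factory=list)
    roi_labels: Dict[int, List[int]] = field(default_factory=dict)
    background_shape: Optional[int] = None
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.grid_size <= 0:
            raise ValueError("grid_size must be positive")
        r_f = self.grid_size / 2.0
        for i, sh in enumerate(self.shapes):
            if sh.activity < 0:
                raise ValueError(f"shape {i}: activity must be non-negative")
            if min(sh.semi_axes) <= 0:
                raise ValueError(f"shape {i}: semi-axes must be positive")
            reach = float(np.hypot(*sh.center)) + max(sh.semi_axes)
            if reach > r_f:
                raise ValueError(
                    f"shape {i} extends to radius {reach:.2f}, outside the "
                    f"field-of-view circle of radius {r_f:.2f}"
                )
        for roi_id, idx in self.roi_labels.items():
            if roi_id <= 0:
                raise ValueError("ROI ids must be positive integers")
            for j in idx:
                if not 0 <= j < len(self.shapes):
                    raise ValueError(f"ROI {roi_id} references missing shape {j}")

    def to_dict(self) -> dict:
        return {
            "grid_size": self.grid_size,
            "shapes": [dataclasses.asdict(s) for s in self.shapes],
            "roi_labels": {str(k): list(v) for k, v in self.roi_labels.items()},
            "background_shape": self.background_shape,
            "preset_name": self.preset_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        shapes = [
            EllipseSpec(
                center=tuple(s["center"]),
                semi_axes=tuple(s["semi_axes"]),
                angle_deg=float(s.get("angle_deg", 0.0)),
                activity=float(s.get("activity", 1.0)),
            )
            for s in d.get("shapes", [])
        ]
        return cls(
            grid_size=int(d["grid_size"]),
            shapes=shapes,
            roi_labels={int(k): list(v) for k, v in d.get("roi_labels", {}).items()},
            background_shape=d.get("background_shape"),
            preset_name=d.get("preset_name"),
        )


def brain_like_spec(grid_size: int = 64) -> PhantomSpec:
    """Stylised brain phantom: white-matter base, two gray-matter lobes and
    two small hot lesions (ROI 1 and ROI 2).

    Activities follow a typical FDG gray:white uptake ratio of 4:1, with
    lesions at twice gray-matter uptake.  The geometry scales linearly with
    ``grid_size`` (default 64).
    """
    f = grid_size / 64.0
    shapes = [
        EllipseSpec((0.0, 0.0), (26.0 * f, 22.0 * f), 0.0, 0.25),     # white matter base
        EllipseSpec((0.0, 9.5 * f), (20.0 * f, 8.0 * f), 0.0, 0.75),  # gray lobe
        EllipseSpec((0.0, -9.5 * f), (20.0 * f, 8.0 * f), 0.0, 0.75), # gray lobe
        EllipseSpec((10.0 * f, 10.0 * f), (3.0 * f, 3.0 * f), 0.0, 1.0),   # lesion ROI1
        EllipseSpec((-12.0 * f, -7.0 * f), (2.5 * f, 2.5 * f), 0.0, 1.0),  # lesion ROI2
    ]
    return PhantomSpec(
        grid_size=grid_size,
        shapes=shapes,
        roi_labels={1: [3], 2: [4]},
        background_shape=0,
        preset_name="brain_like",
    )


def thorax_like_spec(grid_size: int = 128) -> PhantomSpec:
    """Stylised thorax phantom: body ellipse, two lung fields, a spine disc,
    a mediastinum block and five hot lesions (ROI 1-5).

    Additive composition cannot express activity *below* the body base, so
    the lungs are modelled as distinct (slightly raised) regions rather
    than cold ones; the phantom emulates the region layout, not the
    attenuation physics, of a thorax.
    """
    f = grid_size / 128.0
    shapes = [
        EllipseSpec((0.0, 0.0), (52.0 * f, 40.0 * f), 0.0, 0.30),      # body
        EllipseSpec((-24.0 * f, 4.0 * f), (18.0 * f, 13.0 * f), 10.0, 0.05),   # left lung
        EllipseSpec((24.0 * f, 4.0 * f), (18.0 * f, 13.0 * f), -10.0, 0.05),   # right lung
        EllipseSpec((0.0, -30.0 * f), (6.0 * f, 6.0 * f), 0.0, 0.40),  # spine
        EllipseSpec((0.0, 12.0 * f), (10.0 * f, 9.0 * f), 0.0, 0.50),  # mediastinum
        EllipseSpec((-24.0 * f, 8.0 * f), (3.5 * f, 3.5 * f), 0.0, 1.2),   # ROI1
        EllipseSpec((26.0 * f, 0.0), (3.0 * f, 3.0 * f), 0.0, 1.2),        # ROI2
        EllipseSpec((-10.0 * f, -18.0 * f), (2.5 * f, 2.5 * f), 0.0, 1.2), # ROI3
        EllipseSpec((12.0 * f, -20.0 * f), (2.5 * f, 2.5 * f), 0.0, 1.2),  # ROI4
        EllipseSpec((0.0, 28.0 * f), (2.0 * f, 2.0 * f), 0.0, 1.2),        # ROI5
    ]
    return PhantomSpec(
        grid_size=grid_size,
        shapes=shapes,
        roi_labels={1: [5], 2: [6], 3: [7], 4: [8], 5: [9]},
        background_shape=0,
        preset_name="thorax_like",
    )


def disc_spec(grid_size: int = 64, radius: Optional[float] = None,
              activity: float = 1.0) -> PhantomSpec:
    """Uniform centred disc; the workhorse analytic test phantom."""
    if radius is None:
        radius = 0.3 * grid_size
    return PhantomSpec(
        grid_size=grid_size,
        shapes=[EllipseSpec((0.0, 0.0), (radius, radius), 0.0, activity)],
        roi_labels={1: [0]},
        background_shape=0,
        preset_name="disc",
    )


_PRESETS = {
    "brain_like": brain_like_spec,
    "thorax_like": thorax_like_spec,
    "disc": disc_spec,
}


def preset_spec(name: str, **kwargs) -> PhantomSpec:
    """Look up a phantom preset by name."""
    try:
        return _PRESETS[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")


def _shape_mask(shape: EllipseSpec, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    th = np.deg2rad(shape.angle_deg)
    dx = xx - shape.center[0]
    dy = yy - shape.center[1]
    xr = dx * np.cos(th) + dy * np.sin(th)
    yr = -dx * np.sin(th) + dy * np.cos(th)
    a, b = shape.semi_axes
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec, pixel_size: float = 1.0) -> ImageGrid:
    """Rasterise a phantom spec onto an ``(N, N)`` grid.

    Each pixel receives the sum of activities of shapes covering its
    centre.  The ROI label map is filled from ``spec.roi_labels`` (later
    ROI ids overwrite earlier ones on overlap).
    """
    n = spec.grid_size
    c = (n - 1) / 2.0
    ix = np.arange(n) - c
    xx, yy = np.meshgrid(ix, ix, indexing="ij")
    values = np.zeros((n, n))
    masks = []
    for shape in spec.shapes:
        m = _shape_mask(shape, xx, yy)
        masks.append(m)
        values += shape.activity * m
    roi_map = np.zeros((n, n), dtype=np.int64)
    for roi_id in sorted(spec.roi_labels):
        region = np.zeros((n, n), dtype=bool)
        for j in spec.roi_labels[roi_id]:
            region |= masks[j]
        roi_map[region] = roi_id
    return ImageGrid(values, pixel_size=pixel_size, roi_map=roi_map)


def background_mask(spec: PhantomSpec, pixel_size: float = 1.0) -> np.ndarray:
    """Pixels covered by the background shape and by no other shape."""
    if spec.background_shape is None:
        raise ValueError("phantom spec declares no background shape")
    n = spec.grid_size
    c = (n - 1) / 2.0
    ix = np.arange(n) - c
    xx, yy = np.meshgrid(ix, ix, indexing="ij")
    bg = _shape_mask(spec.shapes[spec.background_shape], xx, yy)
    for j, shape in enumerate(spec.shapes):
        if j != spec.background_shape:
            bg &= ~_shape_mask(shape, xx, yy)
    return bg


def default_geometry(grid_size: int, n_s: Optional[int] = None,
                     n_phi: Optional[int] = None, n_rings: int = 4,
                     delta_values: Sequence[float] = (0.0,),
                     pixel_size: float = 1.0) -> ScannerGeometry:
    """A scanner whose field of view exactly covers an ``N x N`` image."""
    if n_s is None:
        n_s = grid_size
    if n_phi is None:
        n_phi = int(np.ceil(1.5 * grid_size))
    r_f = grid_size * pixel_size / 2.0
    return ScannerGeometry(
        r_f=r_f,
        L=grid_size * pixel_size / 2.0,
        n_rings=n_rings,
        n_s=n_s,
        n_phi=n_phi,
        delta_values=tuple(delta_values),
    )


def _line_samples(geometry: ScannerGeometry, pixel_size: float):
    """Sample offsets along each LOR and the quadrature weight."""
    step = LINE_SAMPLING_STEP * pixel_size
    n_l = int(np.ceil(2.0 * geometry.r_f / step)) + 1
    l = np.linspace(-geometry.r_f, geometry.r_f, n_l)
    return l, float(l[1] - l[0])


def forward_project(image: ImageGrid, geometry: ScannerGeometry) -> Sinogram2D:
    """Discrete line integrals of a 2D image along every LOR ``(s, phi)``.

    Each LOR is sampled at half-pixel spacing with bilinear interpolation;
    the bin value is the Riemann sum along the line.  The operation is
    linear in the image.
    """
    px = image.pixel_size
    c = image.center
    s = geometry.s_coords
    phi = geometry.phi_coords
    l, dl = _line_samples(geometry, px)
    cos, sin = np.cos(phi), np.sin(phi)
    # coordinates shaped (n_s, n_phi, n_l)
    x = s[:, None, None] * cos[None, :, None] - l[None, None, :] * sin[None, :, None]
    y = s[:, None, None] * sin[None, :, None] + l[None, None, :] * cos[None, :, None]
    vals = map_coordinates(
        image.values,
        [x / px + c, y / px + c],
        order=1,
        mode="constant",
        cval=0.0,
    )
    data = vals.sum(axis=2) * dl
    return Sinogram2D(data, s, phi, z=0.0)


def make_oblique_set(
    volume: Union[Sequence[ImageGrid], np.ndarray],
    geometry: ScannerGeometry,
    z_coords: Optional[np.ndarray] = None,
    pixel_size: float = 1.0,
) -> ObliqueSinogramSet:
    """Oblique line integrals ``p(s, phi, z, delta)`` of an image stack.

    The entry at ``(s, phi, z, delta)`` is the normalised oblique line
    integral: the integrand is sampled trilinearly along the tilted line
    ``(s cos(phi) - l sin(phi), s sin(phi) + l cos(phi), z + l * delta)``
    and the transaxial parameter ``l`` is the integration variable, which
    absorbs the conventional ``1 / (1 + delta^2)`` path-length
    normalisation.  Lines are truncated where they leave the volume's
    axial extent.
    """
    if isinstance(volume, np.ndarray):
        vol = np.asarray(volume, dtype=np.float64)
        if vol.ndim != 3:
            raise ValueError("volume array must be 3D (x, y, z)")
        px = pixel_size
    else:
        slices = list(volume)
        px = slices[0].pixel_size
        for sl in slices:
            if sl.values.shape != slices[0].values.shape or sl.pixel_size != px:
                raise ValueError("volume slices must share grid and pixel size")
        vol = np.stack([sl.values for sl in slices], axis=2)
    if z_coords is None:
        z_coords = geometry.z_coords
    z_coords = np.asarray(z_coords, dtype=np.float64)
    if vol.shape[2] != z_coords.size:
        raise ValueError("number of slices must match z grid")
    if vol.shape[2] > 1:
        dz = float(z_coords[1] - z_coords[0])
    else:
        dz = 1.0
    deltas = geometry.delta_values
    if 0.0 not in deltas:
        raise ValueError("delta list must contain 0")

    c = (vol.shape[0] - 1) / 2.0
    s = geometry.s_coords
    phi = geometry.phi_coords
    l, dl = _line_samples(geometry, px)
    cos, sin = np.cos(phi), np.sin(phi)
    x = s[:, None, None] * cos[None, :, None] - l[None, None, :] * sin[None, :, None]
    y = s[:, None, None] * sin[None, :, None] + l[None, None, :] * cos[None, :, None]
    xi = x / px + c
    yi = y / px + c

    z_span = z_coords[-1] - z_coords[0]
    data = np.empty((geometry.n_s, geometry.n_phi, z_coords.size, len(deltas)))
    for di, d in enumerate(deltas):
        if abs(d) * geometry.r_f > z_span / 2.0 + dz:
            warnings.warn(
                f"delta={d:g}: oblique LORs leave the axial extent for every "
                "slice; sinograms are truncated",
                stacklevel=2,
            )
        for zi, z in enumerate(z_coords):
            zline = (z + l * d - z_coords[0]) / dz
            zi3 = np.broadcast_to(zline[None, None, :], xi.shape)
            vals = map_coordinates(
                vol, [xi, yi, zi3], order=1, mode="constant", cval=0.0
            )
            data[:, :, zi, di] = vals.sum(axis=2) * dl
    return ObliqueSinogramSet(data, geometry, z_coords)


def apply_counting_noise(sino, total_counts: float, seed: int,
                         preserve_scale: bool = False):
    """Replace sinogram bins by Poisson draws at a given total count budget.

    Bins are scaled so their sum equals ``total_counts`` in expectation and
    replaced by independent Poisson draws.  With ``preserve_scale=True``
    the draws are scaled back to the input's intensity units (calibrated,
    "pre-corrected" data whose noise level is set by the count budget);
    otherwise raw counts are returned.

    All-zero input is returned unchanged.  The same seed reproduces the
    same output bit for bit.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    data = sino.data
    if np.any(data < 0):
        raise ValueError("sinogram must be non-negative before counting noise")
    tot = data.sum()
    if tot == 0:
        return dataclasses.replace(sino, data=data.copy())
    scale = total_counts / tot
    rng = np.random.default_rng(seed)
    counts = rng.poisson(data * scale).astype(np.float64)
    if preserve_scale:
        counts = counts / scale
    return dataclasses.replace(sino, data=counts)
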