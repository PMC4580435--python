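"""Shared containers: images, scanner geometry, direct and oblique sinograms.

Conventions used throughout the package
---------------------------------------
* Images are square ``(N, N)`` arrays; array axis 0 is the ``x`` axis and
  axis 1 the ``y`` axis.  Pixel ``(0, 0)`` sits at the array corner and the
  image centre is at index ``((N-1)/2, (N-1)/2)``.
* A line of response (LOR) is parameterised by its signed transaxial offset
  ``s`` (``s = 0`` passes through the image centre), azimuthal angle
  ``phi in [0, pi)``, axial midpoint ``z`` and axial tangent
  ``delta = tan(theta)``.
* Lengths (``s``, ``z``, pixel size, field-of-view radius) share one unit;
  the default unit is one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageGrid",
    "ScannerGeometry",
    "Sinogram2D",
    "ObliqueSinogramSet",
]


@dataclass
class ImageGrid:
    """A square activity image, optionally carrying an ROI label map.

    Parameters
    ----------
    values
        ``(N, N)`` activity per pixel (arbitrary activity units).
    pixel_size
        Side length of one pixel, in the package length unit.
    roi_map
        Optional ``(N, N)`` integer label map; 0 means "no ROI".
    """

    values: np.ndarray
    pixel_size: float = 1.0
    roi_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"image must be square 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.roi_map is not None:
            self.roi_map = np.asarray(self.roi_map, dtype=np.int64)
            if self.roi_map.shape != self.values.shape:
                raise ValueError("roi_map shape must match image shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def center(self) -> float:
        """Index of the image centre along either axis."""
        return (self.n - 1) / 2.0

    def mass(self) -> float:
        """Total activity, i.e. integral of the image over its support."""
        return float(self.values.sum()) * self.pixel_size**2


@dataclass(frozen=True)
class ScannerGeometry:
    """Cylindrical scanner description used by the projector and rebinner.

    Attributes
    ----------
    r_f
        Field-of-view (transaxial) radius.  Radial bins span ``[-r_f, r_f]``.
    L
        Axial length of the cylinder.
    n_rings
        Number of detector rings.  The canonical rebinned stack contains
        ``2 * n_rings - 1`` slices: ``n_rings`` direct planes and
        ``n_rings - 1`` cross planes between adjacent rings.
    n_s, n_phi
        Number of radial and angular bins of one sinogram.
    delta_values
        Axial tangents ``delta = tan(theta)`` at which oblique sinograms
        are recorded; must contain 0 (the direct plane).
    """

    r_f: float
    L: float
    n_rings: int
    n_s: int
    n_phi: int
    delta_values: tuple = (0.0,)

    def __post_init__(self) -> None:
        if self.n_s <= 0 or self.n_phi <= 0:
            raise ValueError("n_s and n_phi must be positive")
        if self.n_rings <= 0:
            raise ValueError("n_rings must be positive")
        if self.r_f <= 0 or self.L <= 0:
            raise ValueError("r_f and L must be positive")
        dv = tuple(float(d) for d in self.delta_values)
        if not np.all(np.isfinite(dv)):
            raise ValueError("delta values must be finite")
        object.__setattr__(self, "delta_values", dv)

    @property
    def ds(self) -> float:
        """Radial bin width."""
        return 2.0 * self.r_f / self.n_s

    @property
    def s_coords(self) -> np.ndarray:
        """Radial bin centres, symmetric about 0 and spanning [-r_f, r_f]."""
        return (np.arange(self.n_s) - (self.n_s - 1) / 2.0) * self.ds

    @property
    def phi_coords(self) -> np.ndarray:
        """Angular samples, uniform over [0, pi)."""
        return np.arange(self.n_phi) * (np.pi / self.n_phi)

    @property
    def dz(self) -> float:
        """Axial slice spacing (half the ring pitch)."""
        return self.L / self.n_rings / 2.0

    @property
    def n_slices(self) -> int:
        return 2 * self.n_rings - 1

    @property
    def z_coords(self) -> np.ndarray:
        """Axial positions of the direct + cross slices, centred on z = 0."""
        return (np.arange(self.n_slices) - (self.n_rings - 1)) * self.dz


@dataclass
class Sinogram2D:
    """One direct (in-plane) sinogram ``p(s, phi)`` for a slice at ``z``."""

    data: np.ndarray
    s_coords: np.ndarray
    phi_coords: np.ndarray
    z: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.s_coords = np.asarray(self.s_coords, dtype=np.float64)
        self.phi_coords = np.asarray(self.phi_coords, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2D (s, phi)")
        if self.data.shape != (self.s_coords.size, self.phi_coords.size):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with coordinate "
                f"lengths ({self.s_coords.size}, {self.phi_coords.size})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram values must be finite")
        if not np.allclose(self.s_coords, -self.s_coords[::-1]):
            raise ValueError("s_coords must be symmetric about 0")

    @property
    def n_s(self) -> int:
        return self.data.shape[0]

    @property
    def n_phi(self) -> int:
        return self.data.shape[1]

    @property
    def ds(self) -> float:
        return float(self.s_coords[1] - self.s_coords[0])

    def total(self) -> float:
        return float(self.data.sum())


@dataclass
class ObliqueSinogramSet:
    """The 4-parameter 3D data set ``p(s, phi, z, delta)``.

    ``data`` is indexed ``(s, phi, z, delta)``; the delta axis follows
    ``geometry.delta_values`` and must include the direct plane
    ``delta = 0``.
    """

    data: np.ndarray
    geometry: ScannerGeometry
    z_coords: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.z_coords is None:
            self.z_coords = self.geometry.z_coords
        self.z_coords = np.asarray(self.z_coords, dtype=np.float64)
        g = self.geometry
        expected = (g.n_s, g.n_phi, self.z_coords.size, len(g.delta_values))
        if self.data.shape != expected:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with geometry "
                f"(expected {expected})"
            )
        if 0.0 not in g.delta_values:
            raise ValueError("delta_values must contain the direct plane delta=0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("oblique sinogram values must be finite")

    @property
    def n_z(self) -> int:
        return self.z_coords.size

    @property
    def delta_index0(self) -> int:
        """Index of the direct (delta = 0) plane."""
        return self.geometry.delta_values.index(0.0)

    def direct_plane(self) -> np.ndarray:
        """The ``(s, phi, z)`` array of direct sinograms."""
        return self.data[:, :, :, self.delta_index0]

    def slice_sinogram(self, z_index: int, delta_index: int = None) -> Sinogram2D:
        di = self.delta_index0 if delta_index is None else delta_index
        g = self.geometry
        return Sinogram2D(
            self.data[:, :, z_index, di],
            g.s_coords,
            g.phi_coords,
            z=float(self.z_coords[z_index]),
        )

    def total(self) -> float:
        return float(self.data.sum())


def as_sinogram_stack(obset: ObliqueSinogramSet) -> list:
    """Direct-plane view of an oblique set as a list of :class:`Sinogram2D`."""
    return [obset.slice_sinogram(i) for i in range(obset.n_z)]
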