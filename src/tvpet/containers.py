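"""Self-describing file containers for sinograms and images.

A container is a JSON header file plus a sibling raw little-endian float64
payload (``<path>`` and ``<path>.raw``).  The header records the axes
order ``(s, phi, z, delta)`` (singleton axes allowed), the coordinate
vectors, units and a provenance log, so every artifact can reconstruct the
command that made it.  Images can additionally be exported as 32-bit TIFF.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional, Union

import numpy as np
import tifffile

from .core import ImageGrid, ObliqueSinogramSet, ScannerGeometry, Sinogram2D

__all__ = [
    "ContainerError",
    "write_sinogram",
    "read_sinogram",
    "write_image",
    "read_image",
]

_SINO_FORMAT = "tvpet-sinogram-v1"
_IMAGE_FORMAT = "tvpet-image-v1"


class ContainerError(ValueError):
    """Raised for malformed or inconsistent container files."""


def _payload_path(path: str) -> str:
    return path + ".raw"


def _write_payload(path: str, array: np.ndarray) -> None:
    array.astype("<f8").tofile(_payload_path(path))


def _read_payload(path: str, shape) -> np.ndarray:
    ppath = _payload_path(path)
    expected = int(np.prod(shape)) * 8
    actual = os.path.getsize(ppath)
    if actual != expected:
        raise ContainerError(
            f"payload {ppath}: expected {expected} bytes for shape "
            f"{tuple(shape)}, got {actual}"
        )
    return np.fromfile(ppath, dtype="<f8").reshape(shape)


def write_sinogram(
    sino: Union[Sinogram2D, ObliqueSinogramSet],
    path: str,
    provenance: Optional[List[dict]] = None,
) -> str:
    """Write a direct sinogram or an oblique set; returns the header path."""
    provenance = provenance or []
    if isinstance(sino, Sinogram2D):
        header = {
            "format": _SINO_FORMAT,
            "axes": ["s", "phi"],
            "shape": list(sino.data.shape),
            "s_coords": sino.s_coords.tolist(),
            "phi_coords": sino.phi_coords.tolist(),
            "z": sino.z,
            "units": {"s": "length", "phi": "rad"},
            "dtype": "<f8",
            "provenance": provenance,
        }
        payload = sino.data
    elif isinstance(sino, ObliqueSinogramSet):
        g = sino.geometry
        header = {
            "format": _SINO_FORMAT,
            "axes": ["s", "phi", "z", "delta"],
            "shape": list(sino.data.shape),
            "s_coords": g.s_coords.tolist(),
            "phi_coords": g.phi_coords.tolist(),
            "z_coords": sino.z_coords.tolist(),
            "delta_values": list(g.delta_values),
            "geometry": {
                "r_f": g.r_f,
                "L": g.L,
                "n_rings": g.n_rings,
                "n_s": g.n_s,
                "n_phi": g.n_phi,
            },
            "units": {"s": "length", "phi": "rad", "z": "length", "delta": "1"},
            "dtype": "<f8",
            "provenance": provenance,
        }
        payload = sino.data
    else:
        raise TypeError(f"cannot write object of type {type(sino).__name__}")
    with open(path, "w") as fh:
        json.dump(header, fh, indent=1)
    _write_payload(path, payload)
    return path


def read_sinogram(path: str) -> Union[Sinogram2D, ObliqueSinogramSet]:
    """Read a container written by :func:`write_sinogram`.

    Dispatches on the declared axes: a 2-axis header yields a
    :class:`Sinogram2D`, a 4-axis header an :class:`ObliqueSinogramSet`.
    """
    with open(path) as fh:
        try:
            header = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ContainerError(f"{path}: invalid JSON header: {exc}") from exc
    if header.get("format") != _SINO_FORMAT:
        raise ContainerError(
            f"{path}: unexpected format field {header.get('format')!r}"
        )
    for key in ("axes", "shape"):
        if key not in header:
            raise ContainerError(f"{path}: header missing field {key!r}")
    shape = header["shape"]
    data = _read_payload(path, shape)
    axes = header["axes"]
    if axes == ["s", "phi"]:
        return Sinogram2D(
            data,
            np.asarray(header["s_coords"]),
            np.asarray(header["phi_coords"]),
            z=float(header.get("z", 0.0)),
        )
    if axes == ["s", "phi", "z", "delta"]:
        gd = header["geometry"]
        geometry = ScannerGeometry(
            r_f=gd["r_f"],
            L=gd["L"],
            n_rings=gd["n_rings"],
            n_s=gd["n_s"],
            n_phi=gd["n_phi"],
            delta_values=tuple(header["delta_values"]),
        )
        return ObliqueSinogramSet(data, geometry,
                                  np.asarray(header["z_coords"]))
    raise ContainerError(f"{path}: unsupported axes order {axes}")


def write_image(
    image: ImageGrid,
    path: str,
    format: str = "raw+json",
    provenance: Optional[List[dict]] = None,
) -> str:
    """Write an image as ``raw+json`` (lossless float64) or ``tiff32``.

    With ``tiff32`` the ROI label map, when present, is written as a
    companion integer TIFF ``<path>.roi.tif``.
    """
    if image.n == 0:
        raise ContainerError("refusing to write a zero-size image")
    provenance = provenance or []
    if format == "tiff32":
        tifffile.imwrite(path, image.values.astype(np.float32))
        if image.roi_map is not None:
            tifffile.imwrite(path + ".roi.tif", image.roi_map.astype(np.int32))
        return path
    if format == "raw+json":
        header = {
            "format": _IMAGE_FORMAT,
            "shape": list(image.values.shape),
            "pixel_size": image.pixel_size,
            "dtype": "<f8",
            "has_roi_map": image.roi_map is not None,
            "provenance": provenance,
        }
        with open(path, "w") as fh:
            json.dump(header, fh, indent=1)
        _write_payload(path, image.values)
        if image.roi_map is not None:
            image.roi_map.astype("<i8").tofile(path + ".roi.raw")
        return path
    raise ContainerError(f"unsupported image format {format!r}")


def read_image(path: str) -> ImageGrid:
    """Read a ``raw+json`` image container."""
    with open(path) as fh:
        try:
            header = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ContainerError(f"{path}: invalid JSON header: {exc}") from exc
    if header.get("format") != _IMAGE_FORMAT:
        raise ContainerError(f"{path}: not an image container")
    values = _read_payload(path, header["shape"])
    roi_map = None
    if header.get("has_roi_map"):
        roi_map = np.fromfile(path + ".roi.raw", dtype="<i8").reshape(
            header["shape"]
        )
    return ImageGrid(values, pixel_size=float(header.get("pixel_size", 1.0)),
                     roi_map=roi_map)


def read_provenance(path: str) -> List[dict]:
    with open(path) as fh:
        return json.load(fh).get("provenance", [])
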