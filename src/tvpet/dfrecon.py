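"""Direct Fourier (DF) reconstruction and frequency-domain data preparation.

The classic three-step DF reconstructor for parallel projections:

1. per-angle 1D FFT of the radial profiles (central slice theorem),
2. interpolation of the resulting polar frequency samples onto a Cartesian
   frequency grid (``gridding``),
3. inverse 2D FFT.

The gridded :class:`FourierSamples` object is also the data term of the
TV-constrained solver: its ``values`` are stored in the *unitary*,
centre-origin convention, so that the forward model ``u -> mask * fft2c(u)``
is an operator of norm 1 and DF reconstruction is simply
``real(ifft2c(values))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, Sinogram2D

__all__ = [
    "PolarFourierSamples",
    "FourierSamples",
    "radial_fft",
    "grid_polar_to_cartesian",
    "prepare_fourier_data",
    "df_reconstruct",
    "fft2c",
    "ifft2c",
]


@dataclass
class PolarFourierSamples:
    """Per-angle 1D spectra of a sinogram: samples of the image's 2D
    transform on a polar grid.

    ``values[i, j]`` is the unitary 1D DFT of the (zero-padded) radial
    profile at angle ``phi_coords[j]``, evaluated at signed radial
    frequency ``omega_coords[i]`` (cycles per length unit, centred on 0).
    """

    values: np.ndarray
    omega_coords: np.ndarray
    phi_coords: np.ndarray

    @property
    def n_omega(self) -> int:
        return self.omega_coords.size

    @property
    def d_omega(self) -> float:
        return float(self.omega_coords[1] - self.omega_coords[0])

    @property
    def ds(self) -> float:
        """Radial sample spacing implied by the frequency grid."""
        return 1.0 / (self.n_omega * self.d_omega)


@dataclass
class FourierSamples:
    """Cartesian frequency-plane data ``f`` with a sampled/unsampled mask.

    ``values`` is an ``(N, N)`` complex array in fftshifted layout
    (frequency origin at the array centre), scaled so that a unitary
    centred 2D FFT of the image reproduces it on the sampled bins.
    ``mask`` flags bins that received at least one polar sample.
    """

    values: np.ndarray
    mask: np.ndarray
    grid_size: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.grid_size, self.grid_size):
            raise ValueError("values must be (grid_size, grid_size)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if np.any((self.values != 0) & ~self.mask):
            raise ValueError("mask must cover every nonzero bin")


def _phase_ramp(n: int, pixel_size: float) -> np.ndarray:
    """Per-axis phase that recentres the DFT on the image centre (N-1)/2."""
    freqs = np.fft.fftfreq(n, d=pixel_size)
    return np.exp(2j * np.pi * freqs * ((n - 1) / 2.0) * pixel_size)


def fft2c(u: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Unitary 2D FFT with spatial origin at the image centre and the
    frequency origin at the array centre (fftshifted output)."""
    n = u.shape[0]
    r = _phase_ramp(n, pixel_size)
    return np.fft.fftshift(np.fft.fft2(u, norm="ortho") * r[:, None] * r[None, :])


def ifft2c(F: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Inverse of :func:`fft2c` (unitary)."""
    n = F.shape[0]
    r = _phase_ramp(n, pixel_size)
    return np.fft.ifft2(np.fft.ifftshift(F) / (r[:, None] * r[None, :]), norm="ortho")


def radial_fft(sino: Sinogram2D, pad_factor: int = 4) -> PolarFourierSamples:
    """Unitary 1D FFT of each zero-padded radial profile.

    Zero padding (``pad_factor`` times the radial bin count) oversamples
    the radial frequency axis, which controls interpolation error in the
    subsequent gridding step.  The spectra carry the phase appropriate for
    radial samples centred on ``s = 0``, and the frequency axis is
    fftshift-centred on 0.
    """
    if sino.n_s < 2:
        raise ValueError("need at least two radial bins")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    n_pad = int(pad_factor) * sino.n_s
    ds = sino.ds
    padded = np.zeros((n_pad, sino.n_phi))
    padded[: sino.n_s] = sino.data
    spec = np.fft.fft(padded, axis=0, norm="ortho")
    nu = np.fft.fftfreq(n_pad, d=ds)
    # profiles start at s_coords[0], not 0: shift theorem
    spec *= np.exp(-2j * np.pi * nu * sino.s_coords[0])[:, None]
    return PolarFourierSamples(
        values=np.fft.fftshift(spec, axes=0),
        omega_coords=np.fft.fftshift(nu),
        phi_coords=sino.phi_coords.copy(),
    )


def _hermitian_symmetrize(values: np.ndarray, mask: np.ndarray):
    """Average each frequency bin with the conjugate of its mirror bin.

    Operates on fftshifted arrays; unsampled members of a pair contribute
    nothing, so a bin whose mirror is unsampled keeps its own value.
    """
    vu = np.fft.ifftshift(values)
    mu = np.fft.ifftshift(mask).astype(np.float64)
    n = vu.shape[0]
    idx = (-np.arange(n)) % n
    vm = np.conj(vu[np.ix_(idx, idx)])
    mm = mu[np.ix_(idx, idx)]
    cnt = mu + mm
    out = np.zeros_like(vu)
    nz = cnt > 0
    out[nz] = (vu * mu + vm * mm)[nz] / cnt[nz]
    return np.fft.fftshift(out), np.fft.fftshift(nz)


def grid_polar_to_cartesian(
    polar: PolarFourierSamples, grid_size: int, pixel_size: float = 1.0
) -> FourierSamples:
    """Interpolate polar frequency samples onto an ``N x N`` Cartesian grid.

    Each Cartesian bin inside the sampled polar disk receives the bilinear
    (distance-weighted, 4-nearest-sample) interpolation of the polar data
    in ``(radial frequency, angle)`` coordinates.  Bins beyond the maximum
    radial frequency are flagged unsampled.  The DC bin is the mean of the
    per-angle DC values, and Hermitian symmetry is enforced so a real image
    is recovered by the inverse transform.
    """
    n_phi = polar.phi_coords.size
    if n_phi < 2:
        raise ValueError("need at least two angles")
    omega = polar.omega_coords
    d_omega = polar.d_omega
    n_pad = polar.n_omega
    # convert unitary per-angle spectra to continuous-transform samples
    phys = polar.values * (np.sqrt(n_pad) * polar.ds)
    # extend the angular axis to phi = pi using P(nu, phi + pi) = P(-nu, phi);
    # on an fftshifted even-length axis, frequency negation is flip + roll
    mirror = phys[::-1, :1]
    if n_pad % 2 == 0:
        mirror = np.roll(mirror, 1, axis=0)
    ext = np.concatenate([phys, mirror], axis=1)
    d_phi = np.pi / n_phi

    fc = np.fft.fftshift(np.fft.fftfreq(grid_size, d=pixel_size))
    uu = fc[:, None]
    vv = fc[None, :]
    rr = np.hypot(uu, vv)
    th = np.arctan2(vv, uu)  # (-pi, pi]
    sign = np.where(th < 0, -1.0, 1.0)
    th = np.where(th < 0, th + np.pi, th)
    # arctan2 returns exactly pi on the negative-u axis: fold to (0, -r)
    at_pi = th >= np.pi
    th = np.where(at_pi, th - np.pi, th)
    sign = np.where(at_pi, -sign, sign)
    rs = sign * rr

    inside = (rs >= omega[0]) & (rs <= omega[-1])
    ri = (rs - omega[0]) / d_omega
    ti = th / d_phi
    i0 = np.clip(np.floor(ri).astype(int), 0, n_pad - 2)
    j0 = np.clip(np.floor(ti).astype(int), 0, n_phi - 1)
    fr = ri - i0
    ft = ti - j0
    interp = (
        ext[i0, j0] * (1 - fr) * (1 - ft)
        + ext[i0 + 1, j0] * fr * (1 - ft)
        + ext[i0, j0 + 1] * (1 - fr) * ft
        + ext[i0 + 1, j0 + 1] * fr * ft
    )
    values = np.where(inside, interp, 0.0 + 0.0j)
    # DC: all angles sample the origin; use their mean
    zero_row = np.argmin(np.abs(omega))
    if abs(omega[zero_row]) < 1e-12 * d_omega + 1e-300:
        dc = phys[zero_row].mean()
        ic = grid_size // 2
        if grid_size % 2 == 1:
            ic = (grid_size - 1) // 2
        if abs(fc[ic]) == 0.0:
            values[ic, ic] = dc
    values, mask = _hermitian_symmetrize(values, inside)
    # unitary centred-FFT data convention
    values = values / (grid_size * pixel_size**2)
    return FourierSamples(values=values, mask=mask, grid_size=grid_size,
                          pixel_size=pixel_size)


def prepare_fourier_data(
    sino: Sinogram2D, grid_size: int, pad_factor: int = 4,
    pixel_size: float = 1.0,
) -> FourierSamples:
    """Radial FFT followed by gridding: the frequency-domain data ``f``."""
    polar = radial_fft(sino, pad_factor=pad_factor)
    return grid_polar_to_cartesian(polar, grid_size, pixel_size=pixel_size)


def df_reconstruct(
    sino: Sinogram2D, grid_size: int, pad_factor: int = 4,
    pixel_size: float = 1.0,
) -> ImageGrid:
    """Three-step direct Fourier reconstruction of one sinogram.

    Unsampled frequency bins are treated as zero (the minimum-norm
    completion), and the real part of the inverse transform is returned.
    """
    fs = prepare_fourier_data(sino, grid_size, pad_factor=pad_factor,
                              pixel_size=pixel_size)
    u = ifft2c(fs.values, pixel_size=pixel_size).real
    return ImageGrid(u, pixel_size=pixel_size)
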