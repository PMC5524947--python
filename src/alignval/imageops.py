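"""Volume projection, CTF simulation, normalization and 2D alignment.

The validation method compares each experimental particle image against
projections of the map on a regular angular grid, using normalized cross
correlation (NCC) after an exhaustive in-plane rotation + shift search.
This module supplies those image-level operations.

Geometric conventions (consistent across the package)
------------------------------------------------------
* Arrays are indexed ``[y, x]`` (and volumes ``[z, y, x]``); the image/volume
  origin is the center pixel ``N // 2`` (0-based).
* A particle orientation ``(rot, tilt, psi, sx, sy)`` projects the volume
  along the viewing direction ``d(rot, tilt)`` of
  :func:`alignval.geometry.euler_to_direction`; ``psi`` is an anticlockwise
  in-plane rotation (degrees, about +z of the projection frame) and
  ``(sx, sy)`` translate the projected content by ``+s`` pixels.
* ``transform_image(img, psi, s)`` applies the same in-plane operator in 2D,
  so ``project(rot, tilt, psi, s) == transform_image(project(rot, tilt), psi, s)``
  up to interpolation.
* NCC is computed under a circular mask (default radius ``0.45 N``) after
  normalizing both images to zero mean / unit variance over the mask and
  zeroing outside it; by Cauchy-Schwarz the score is then exactly in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import fft as sfft

from .geometry import Orientation

__all__ = [
    "MapVolume",
    "ParticleImage",
    "CTFParams",
    "MatchSet",
    "Align2DResult",
    "DegenerateImageError",
    "electron_wavelength",
    "ctf_evaluate",
    "ctf_filter_2d",
    "apply_ctf",
    "project_volume",
    "project_directions",
    "transform_image",
    "circular_mask",
    "normalize_image",
    "align2d",
    "global_search",
    "prepare_references",
]

DEFAULT_MASK_FRACTION = 0.45  # NCC mask radius as fraction of box size


class DegenerateImageError(ValueError):
    """Raised when an operation receives an image with no contrast."""


@dataclass
class MapVolume:
    """Cubic 3D density map with its voxel size in Angstrom."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("box size must be even")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass
class ParticleImage:
    """Square 2D particle image with its pixel size in Angstrom."""

    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"image must be square, got shape {self.data.shape}")

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class CTFParams:
    """Weak-phase contrast transfer function parameters.

    Defocus is in Angstrom, positive = underfocus; ``defocus_angle`` (degrees)
    is the azimuth of the ``defocus_u`` axis; ``voltage`` in kV, ``cs``
    (spherical aberration) in mm, ``amplitude_contrast`` a fraction in [0, 1],
    ``phase_shift`` in degrees.
    """

    defocus_u: float = 10000.0
    defocus_v: float = 10000.0
    defocus_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.1
    phase_shift: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v**2)


def ctf_evaluate(ctf: CTFParams, freq: np.ndarray, azimuth: np.ndarray = 0.0) -> np.ndarray:
    """CTF value at spatial frequency ``freq`` (1/A) and ``azimuth`` (radians).

    ``-sqrt(1 - A^2) sin(gamma) - A cos(gamma)`` with
    ``gamma = pi lam dz(theta) f^2 - (pi/2) Cs lam^3 f^4 + phase_shift``;
    the zero-frequency limit is ``-A`` (negative white-on-black convention).
    """
    f = np.asarray(freq, dtype=float)
    lam = electron_wavelength(ctf.voltage)
    dz = 0.5 * (ctf.defocus_u + ctf.defocus_v) + 0.5 * (
        ctf.defocus_u - ctf.defocus_v
    ) * np.cos(2.0 * (np.asarray(azimuth) - np.deg2rad(ctf.defocus_angle)))
    cs_a = ctf.cs * 1e7  # mm -> Angstrom
    gamma = (
        np.pi * lam * dz * f**2
        - 0.5 * np.pi * cs_a * lam**3 * f**4
        + np.deg2rad(ctf.phase_shift)
    )
    a = ctf.amplitude_contrast
    return -np.sqrt(1.0 - a * a) * np.sin(gamma) - a * np.cos(gamma)


def ctf_filter_2d(n: int, pixel_size: float, ctf: CTFParams) -> np.ndarray:
    """CTF sampled on the ``rfft2`` frequency grid of an n x n image."""
    fy = np.fft.fftfreq(n, d=pixel_size)[:, None]
    fx = np.fft.rfftfreq(n, d=pixel_size)[None, :]
    f = np.hypot(fx, fy)
    azimuth = np.arctan2(fy, fx)
    return ctf_evaluate(ctf, f, azimuth)


def apply_ctf(img, ctf: CTFParams | None, pixel_size: float | None = None):
    """Multiply an image (or image stack, leading axes) by the CTF in Fourier space.

    ``ctf=None`` is the identity (pass-through).  Accepts a
    :class:`ParticleImage` (returns the same type) or a bare array with
    ``pixel_size`` given.
    """
    if isinstance(img, ParticleImage):
        out = apply_ctf(img.data, ctf, img.pixel_size)
        return ParticleImage(out, img.pixel_size)
    if ctf is None:
        return np.array(img, dtype=np.float64)
    if pixel_size is None:
        raise ValueError("pixel_size required for array input")
    arr = np.asarray(img, dtype=np.float64)
    n = arr.shape[-1]
    h = ctf_filter_2d(n, pixel_size, ctf)
    return sfft.irfft2(sfft.rfft2(arr, axes=(-2, -1)) * h, s=(n, n), axes=(-2, -1))


# ---------------------------------------------------------------------------
# projection


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _projection_to_volume_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Matrix mapping projection-frame (x, y, z) to volume-frame coordinates.

    Chosen so the ray (projection +z axis) points along
    ``euler_to_direction(rot, tilt)`` in the volume frame and ``psi`` is an
    anticlockwise in-plane rotation of the projected image.
    """
    return _rot_z(rot) @ _rot_y(tilt) @ _rot_z(-psi)


def project_volume(vol: MapVolume, o: Orientation) -> ParticleImage:
    """Line-integral projection of the volume at orientation ``o``.

    Real-space implementation: the volume is resampled (trilinear) on the
    rotated ray grid and summed along the ray; the integration step is one
    voxel, so pixel values carry units of density x Angstrom.  The projected
    content is translated by ``(shift_x, shift_y)`` pixels.  Linear in the
    volume by construction.
    """
    n = vol.box_size
    c = float(n // 2)
    at = _projection_to_volume_matrix(o.rot, o.tilt, o.psi)
    z = np.arange(n) - c
    y = np.arange(n) - c - o.shift_y
    x = np.arange(n) - c - o.shift_x
    zc, yc, xc = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([xc, yc, zc])  # projection-frame (x, y, z)
    volpts = np.einsum("ij,jabc->iabc", at, pts)  # volume-frame (x, y, z)
    coords = [volpts[2] + c, volpts[1] + c, volpts[0] + c]  # (z, y, x) index order
    samples = ndimage.map_coordinates(vol.data, coords, order=1, mode="constant", cval=0.0)
    proj = samples.sum(axis=0) * vol.voxel_size
    return ParticleImage(proj, vol.voxel_size)


def project_directions(vol: MapVolume, eulers: np.ndarray) -> np.ndarray:
    """Stack of projections at ``(rot, tilt)`` pairs (psi = 0, no shift), shape (G, N, N)."""
    eulers = np.atleast_2d(eulers)
    out = np.empty((len(eulers), vol.box_size, vol.box_size))
    for i, (r, t) in enumerate(eulers):
        out[i] = project_volume(vol, Orientation(rot=r, tilt=t)).data
    return out


# ---------------------------------------------------------------------------
# 2D transforms, masks, normalization


def _rot2(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s], [s, c]])  # acts on (x, y)


def transform_image(img: np.ndarray, psi: float, shift=(0.0, 0.0)) -> np.ndarray:
    """Rotate by ``psi`` degrees (anticlockwise) then translate by ``shift`` (sx, sy) px.

    ``out(x) = img(R(-psi) (x - s))`` about the center pixel, bilinear
    interpolation, zero fill.
    """
    img = np.asarray(img, dtype=np.float64)
    n = img.shape[-1]
    c = float(n // 2)
    r = _rot2(-psi)
    m_yx = np.array([[r[1, 1], r[1, 0]], [r[0, 1], r[0, 0]]])  # same map in (y, x) order
    center = np.array([c, c])
    s_yx = np.array([shift[1], shift[0]], dtype=float)
    offset = center - m_yx @ (center + s_yx)
    return ndimage.affine_transform(img, m_yx, offset=offset, order=1, mode="constant", cval=0.0)


def circular_mask(n: int, radius: float | None = None) -> np.ndarray:
    """Boolean disk of given radius (pixels) about the center pixel."""
    if radius is None:
        radius = DEFAULT_MASK_FRACTION * n
    c = float(n // 2)
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def normalize_image(
    img: np.ndarray, mask_radius: float | None = None, zero_outside: bool = False
) -> np.ndarray:
    """Affine-rescale to zero mean / unit variance over the circular mask.

    Raises :class:`DegenerateImageError` on a (masked-)constant image.  With
    ``zero_outside`` the returned image is also zeroed beyond the mask, the
    form used by the NCC search.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = circular_mask(img.shape[-1], mask_radius)
    vals = img[..., mask]
    mean = vals.mean(axis=-1)
    std = vals.std(axis=-1)
    if np.any(std < 1e-12):
        raise DegenerateImageError("constant image under the mask")
    out = (img - mean[..., None, None]) / std[..., None, None]
    if zero_outside:
        out = out * mask
    return out


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class Align2DResult:
    ncc: float
    psi: float
    shift: tuple[float, float]


@dataclass
class MatchSet:
    """Top-xi most similar map projections for one particle.

    ``weights`` are NCC values sorted non-increasing (ties by lower grid
    index); ``psis``/``shifts`` are the in-plane angle and shift that map each
    grid projection onto the particle.
    """

    particle_index: int
    directions: np.ndarray  # (xi, 3)
    weights: np.ndarray  # (xi,)
    grid_indices: np.ndarray  # (xi,)
    psis: np.ndarray = None  # (xi,)
    shifts: np.ndarray = None  # (xi, 2)

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.directions) != len(self.weights) or len(self.weights) < 1:
            raise ValueError("directions/weights length mismatch or empty")

    @property
    def xi(self) -> int:
        return len(self.weights)


def _window_dft_matrix(n: int, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real/imag parts of the inverse-rFFT evaluation matrix at given (tx, ty)
    pixel offsets: ``corr[t] = Re(spectrum_flat) @ e_re - Im(...) @ e_im``.

    Half-spectrum columns with a distinct conjugate partner carry weight 2.
    """
    ky = np.fft.fftfreq(n, d=1.0 / n)[:, None]  # integer frequencies
    kx = np.fft.rfftfreq(n, d=1.0 / n)[None, :]
    wgt = np.where((kx == 0) | (kx == n // 2), 1.0, 2.0)
    phase = (
        2.0
        * np.pi
        / n
        * (kx[..., None] * offsets[:, 0] + ky[..., None] * offsets[:, 1])
    )  # (n, n//2+1, W)
    e = (wgt[..., None] / (n * n)) * np.exp(1j * phase)
    e = e.reshape(-1, len(offsets))
    return np.ascontiguousarray(e.real), np.ascontiguousarray(e.imag)


def _shift_window(n: int, max_shift: int):
    """Wrapped index grids for correlation shifts with |t| <= max_shift."""
    t = np.arange(-int(max_shift), int(max_shift) + 1)
    ty, tx = np.meshgrid(t, t, indexing="ij")
    keep = (ty**2 + tx**2) <= max_shift**2
    ty, tx = ty[keep], tx[keep]
    return ty % n, tx % n, np.column_stack([tx, ty])  # index grids + (sx, sy) offsets


def align2d(
    exp: np.ndarray,
    ref: np.ndarray,
    rot_step: float = 5.0,
    max_shift: float | None = None,
    mask_radius: float | None = None,
) -> Align2DResult:
    """Exhaustive in-plane rotation + shift alignment of ``ref`` onto ``exp``.

    Searches rotations in steps of ``rot_step`` degrees with an FFT
    translational search per rotation (shift magnitude <= ``max_shift``,
    default box/8).  Returns the maximizing ``(ncc, psi, shift)`` such that
    ``transform_image(ref, psi, shift)`` best matches ``exp``.
    """
    exp = np.asarray(exp, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if exp.shape != ref.shape:
        raise ValueError("image dimensions differ")
    n = exp.shape[-1]
    if max_shift is None:
        max_shift = n // 8
    mask = circular_mask(n, mask_radius)
    npix = int(mask.sum())
    expn = normalize_image(exp, mask_radius, zero_outside=True)
    f_exp = sfft.rfft2(expn)
    iy, ix, offsets = _shift_window(n, int(round(max_shift)))
    best = (-np.inf, 0.0, (0.0, 0.0))
    for psi in np.arange(0.0, 360.0, rot_step):
        r = transform_image(ref, psi) if psi != 0.0 else ref
        rn = normalize_image(r, mask_radius, zero_outside=True)
        # C[t] = sum_x r(x) exp(x + t); peak at t means exp ~= r translated by t
        corr = sfft.irfft2(np.conj(sfft.rfft2(rn)) * f_exp, s=(n, n))
        vals = corr[iy, ix] / npix
        k = int(np.argmax(vals))
        if vals[k] > best[0]:
            best = (float(vals[k]), float(psi), (float(offsets[k, 0]), float(offsets[k, 1])))
    return Align2DResult(ncc=best[0], psi=best[1], shift=best[2])


def prepare_references(
    refs: np.ndarray, mask_radius: float | None = None
) -> tuple[np.ndarray, int]:
    """Masked-normalize a (G, N, N) projection stack and return conj rFFTs + mask pixel count."""
    n = refs.shape[-1]
    mask = circular_mask(n, mask_radius)
    npix = int(mask.sum())
    vals = refs[:, mask]
    mean = vals.mean(axis=1)
    std = vals.std(axis=1)
    std = np.where(std < 1e-12, 1.0, std)  # flat references contribute ncc ~ 0
    normed = (refs - mean[:, None, None]) / std[:, None, None] * mask
    return np.conj(sfft.rfft2(normed, axes=(-2, -1))), npix


def global_search(
    exp: np.ndarray,
    refs: np.ndarray,
    directions: np.ndarray,
    xi: int = 7,
    rot_step: float = 5.0,
    max_shift: float | None = None,
    mask_radius: float | None = None,
    particle_index: int = -1,
    prepared: tuple[np.ndarray, int] | None = None,
) -> MatchSet:
    """Align a particle against every grid projection; keep the top ``xi`` by NCC.

    ``refs`` is the (G, N, N) stack of map projections with viewing
    ``directions`` (G, 3).  The in-plane search rotates the particle (one FFT
    per rotation step) and correlates against all references at once, which is
    equivalent to rotating each reference.  Precomputed ``prepared``
    references (from :func:`prepare_references`) may be passed to amortize
    work across particles.
    """
    exp = np.asarray(exp, dtype=np.float64)
    g = len(directions)
    if xi > g:
        raise ValueError(f"xi={xi} exceeds grid size {g}")
    n = exp.shape[-1]
    if max_shift is None:
        max_shift = n // 8
    if prepared is None:
        prepared = prepare_references(np.asarray(refs, dtype=np.float64), mask_radius)
    f_refs_conj, npix = prepared
    iy, ix, offsets = _shift_window(n, int(round(max_shift)))

    psis = np.arange(0.0, 360.0, rot_step)
    rotated = np.empty((len(psis), n, n))
    rotated[0] = exp
    for i, phi in enumerate(psis[1:], start=1):
        rotated[i] = transform_image(exp, phi)
    rotated = normalize_image(rotated, mask_radius, zero_outside=True)
    f_rot = sfft.rfft2(rotated, axes=(-2, -1))

    best_val = np.full(g, -np.inf)
    best_rot = np.zeros(g, dtype=int)
    best_off = np.zeros(g, dtype=int)
    # evaluate the correlation only at the searched shift offsets: a direct
    # window DFT (two small matmuls) instead of full inverse FFTs
    e_re, e_im = _window_dft_matrix(n, offsets)
    nw = len(offsets)
    f_ref = np.conj(f_refs_conj).reshape(g, -1)
    for r in range(len(psis)):
        # C[t] = sum_x rotated_exp(x) ref(x + t)
        prod = np.conj(f_rot[r]).reshape(-1) * f_ref  # (G, F)
        vals = prod.real @ e_re - prod.imag @ e_im  # (G, W)
        k = np.argmax(vals, axis=1)
        v = vals[np.arange(g), k]
        upd = v > best_val
        best_val[upd] = v[upd]
        best_rot[upd] = r
        best_off[upd] = k[upd]
    best_val /= npix

    order = np.argsort(-best_val, kind="stable")[:xi]
    # peak at t means ref = rotate(exp, phi) translated by t, so ref maps onto
    # exp under psi = -phi, shift = -R(-phi) t
    out_psi = np.empty(xi)
    out_shift = np.empty((xi, 2))
    for j, gi in enumerate(order):
        phi = psis[best_rot[gi]]
        t = offsets[best_off[gi]].astype(float)  # (tx, ty)
        out_psi[j] = (-phi) % 360.0
        out_shift[j] = _rot2(-phi) @ (-t)
    return MatchSet(
        particle_index=particle_index,
        directions=np.asarray(directions, dtype=float)[order],
        weights=best_val[order],
        grid_indices=order,
        psis=out_psi,
        shifts=out_shift,
    )
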