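"""Noise power spectrum estimation from uniform phantom regions.

The NPS describes noise *texture*, complementing the voxel SD used as the
noise-magnitude surrogate: iterative/deep-learning reconstructions shift the
in-plane NPS peak toward lower spatial frequencies (coarser noise) and
flatten the z-direction spectrum, even when the SD alone would look similar.

Estimator conventions (the normalization is stated here because it varies
across the literature):

* in-plane: non-overlapping square patches from each slice of a uniform
  region; each patch is detrended by a fitted 2-D polynomial, DFT'd, and the
  squared magnitude is scaled by (dx*dy)/(Nx*Ny) giving units HU^2 mm^2.
  Patch spectra are averaged and radially binned (bin width = one DFT bin)
  into a 1-D profile against radial frequency in mm^-1.
* z-direction: non-overlapping axial segments of in-mask columns, detrended
  by a 1-D polynomial, scaled by dz/Nz, units HU^2 mm.

With these scalings the integral of the spectrum over the frequency domain
equals the detrended voxel variance (Parseval), which is the basis of the
variance-conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import VoxelVolume
from .segmentation import ROIMask

__all__ = ["NPSCurve", "PeakResult", "nps_inplane", "nps_z", "nps_peak",
           "radial_profile"]


@dataclass
class NPSCurve:
    """Radially binned (in-plane) or axial 1-D noise power spectrum."""

    axis: str  # "in_plane" | "z"
    frequencies: np.ndarray  # mm^-1, 0 .. Nyquist
    power: np.ndarray
    n_patches: int
    detrend_order: int
    variance: float  # detrended sample variance the spectrum integrates to
    power_2d: np.ndarray | None = field(default=None, repr=False)
    freq_2d: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        if (self.power < -1e-12).any():
            raise ValueError("power must be non-negative")

    def total_power(self) -> float:
        """Integral of the spectrum over its frequency domain.

        Equals the detrended voxel variance up to estimator noise (Parseval);
        computed from the full 2-D spectrum in-plane, and from the half
        spectrum with Hermitian symmetry for the z direction.
        """
        if self.axis == "in_plane":
            if self.power_2d is None:
                raise ValueError("2-D spectrum not retained")
            fx, fy = self.freq_2d
            dfx, dfy = fx[1] - fx[0], fy[1] - fy[0]
            return float(self.power_2d.sum() * dfx * dfy)
        df = float(self.frequencies[1] - self.frequencies[0])
        p = self.power
        # even segment length: bins 1..N/2-1 appear twice in the full DFT
        return float(df * (p[0] + 2.0 * p[1:-1].sum() + p[-1]))


class PeakResult(float):
    """Peak frequency (mm^-1); ``flat`` marks a spectrally flat curve."""

    flat: bool

    def __new__(cls, value: float, flat: bool):
        obj = super().__new__(cls, value)
        obj.flat = flat
        return obj


def radial_profile(power2d: np.ndarray, fx: np.ndarray,
                   fy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially bin a 2-D spectrum (bin width = one DFT bin, up to Nyquist)."""
    fr = np.hypot(fx[:, None], fy[None, :])
    dfreq = float(fx[1] - fx[0])
    nyq = float(np.abs(fx).max())
    nbins = int(np.floor(nyq / dfreq)) + 1
    which = np.minimum((fr / dfreq + 0.5).astype(int), nbins)
    counts = np.bincount(which.ravel(), minlength=nbins + 1)[:nbins]
    sums = np.bincount(which.ravel(), weights=power2d.ravel(),
                       minlength=nbins + 1)[:nbins]
    freqs = np.arange(nbins) * dfreq
    return freqs, np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _poly2d_detrend(patch: np.ndarray, order: int) -> np.ndarray:
    if order < 0:
        return patch
    ny, nx = patch.shape
    y, x = np.mgrid[0:ny, 0:nx]
    x = (x - x.mean()) / max(nx / 2.0, 1)
    y = (y - y.mean()) / max(ny / 2.0, 1)
    cols = [x.ravel() ** i * y.ravel() ** j
            for i in range(order + 1) for j in range(order + 1 - i)]
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    return patch - (A @ coef).reshape(patch.shape)


def _find_patches(mask2d: np.ndarray, edge: int) -> list[tuple[int, int]]:
    """Non-overlapping edge x edge squares fully inside a 2-D mask.

    The scan is anchored at the mask's bounding box so irregular regions
    (e.g. an elliptical lung field) are tiled where the mask actually is.
    """
    if not mask2d.any():
        return []
    idx = np.argwhere(mask2d)
    (imin, jmin), (imax, jmax) = idx.min(axis=0), idx.max(axis=0)
    out = []
    for i in range(imin, imax - edge + 2, edge):
        for j in range(jmin, jmax - edge + 2, edge):
            if mask2d[i:i + edge, j:j + edge].all():
                out.append((i, j))
    return out


def nps_inplane(
    vol: VoxelVolume,
    uniform_mask: ROIMask,
    patch_edge: int = 64,
    detrend_order: int = 2,
) -> NPSCurve:
    """Radially averaged in-plane NPS from a uniform region."""
    dx, dy = vol.spacing[0], vol.spacing[1]
    acc = None
    var_acc, n_patches = 0.0, 0
    for k in range(vol.shape[2]):
        m2 = uniform_mask.mask[:, :, k]
        if not m2.any():
            continue
        for (i, j) in _find_patches(m2, patch_edge):
            patch = vol.voxels[i:i + patch_edge, j:j + patch_edge, k]
            d = _poly2d_detrend(patch, detrend_order)
            spec = np.abs(np.fft.fft2(d)) ** 2 * (dx * dy) / (patch_edge ** 2)
            acc = spec if acc is None else acc + spec
            var_acc += float(d.var())
            n_patches += 1
    if n_patches < 4:
        raise ValueError(
            f"too few patches ({n_patches}); need >= 4 non-overlapping "
            f"{patch_edge}x{patch_edge} patches inside the mask"
        )
    nps2d = acc / n_patches
    fx = np.fft.fftfreq(patch_edge, d=dx)
    fy = np.fft.fftfreq(patch_edge, d=dy)
    freqs, profile = radial_profile(nps2d, fx, fy)
    return NPSCurve(axis="in_plane", frequencies=freqs, power=profile,
                    n_patches=n_patches, detrend_order=detrend_order,
                    variance=var_acc / n_patches,
                    power_2d=nps2d, freq_2d=(fx, fy))


def nps_z(
    vol: VoxelVolume,
    uniform_mask: ROIMask,
    detrend_order: int = 2,
    segment_length: int = 32,
) -> NPSCurve:
    """Z-direction NPS from axial columns of a uniform region."""
    dz = vol.spacing[2]
    run = uniform_mask.mask
    if run.shape[2] < segment_length:
        raise ValueError(
            f"mask spans {run.shape[2]} slices; need >= {segment_length}"
        )
    zidx = np.arange(segment_length, dtype=float)
    zc = (zidx - zidx.mean()) / (segment_length / 2.0)
    A = np.stack([zc ** p for p in range(detrend_order + 1)], axis=1)
    proj = A @ np.linalg.pinv(A)
    acc = np.zeros(segment_length)
    var_acc, n_segs = 0.0, 0
    full = run.all(axis=2)
    cols = np.argwhere(full) if full.any() else None
    if cols is None or len(cols) == 0:
        # fall back to longest common run of slices
        per_slice = run.any(axis=(0, 1))
        ks = np.where(per_slice)[0]
        raise ValueError("no columns fully inside the mask along z "
                         f"(mask slices: {len(ks)})")
    nz = run.shape[2]
    for (i, j) in cols:
        for z0 in range(0, nz - segment_length + 1, segment_length):
            seg = vol.voxels[i, j, z0:z0 + segment_length]
            d = seg - proj @ seg
            acc += np.abs(np.fft.fft(d)) ** 2 * dz / segment_length
            var_acc += float(d.var())
            n_segs += 1
    acc /= n_segs
    nhalf = segment_length // 2 + 1
    freqs = np.fft.rfftfreq(segment_length, d=dz)
    return NPSCurve(axis="z", frequencies=freqs, power=acc[:nhalf],
                    n_patches=n_segs, detrend_order=detrend_order,
                    variance=var_acc / n_segs)


def nps_peak(curve: NPSCurve, flatness_ratio: float = 1.25) -> PeakResult:
    """Frequency of maximum power with parabolic sub-bin refinement.

    A curve whose maximum does not exceed ``flatness_ratio`` times the
    median power (excluding the DC bin) is flagged flat and reported as 0.
    """
    p = curve.power
    f = curve.frequencies
    if len(p) < 3:
        raise ValueError("curve too short")
    body = p[1:]
    med = float(np.median(body))
    if med <= 0 or body.max() <= flatness_ratio * med:
        return PeakResult(0.0, flat=True)
    k = 1 + int(np.argmax(body))
    if 0 < k < len(p) - 1:
        y0, y1, y2 = p[k - 1], p[k], p[k + 1]
        denom = (y0 - 2 * y1 + y2)
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = f[1] - f[0]
    return PeakResult(float(f[k] + delta * df), flat=False)
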