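"""Fourier-domain scan simulation and network-I/O normalization.

The routine and fast protocols are modelled as centered k-space matrix
truncation (the standard low-resolution MRI surrogate) with optional
complex Gaussian k-space noise whose level grows with the acceleration
factor, followed by zero-fill reconstruction onto the protocol's
display grid.

Routine protocol: 320 x 256 acquisition, acceleration 2, reconstructed
on the 512 grid (0.43 mm pixels at 220 mm FOV).  Fast protocol:
192 x 128 acquisition, acceleration 3, reconstructed on the 256 grid
(0.86 mm pixels).  The frequency-encoding axis is mapped to image rows.

Network normalization follows the stored-intensity convention:
norm = stored / normalize_para * 2 - 1 with normalize_para 45,000 /
22,000 / 1,800 for T1 / T2 / PD, mapping stored values into [-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sp_fft

from .phantom import FOV_MM, QuantMap, STORED_MAX, RESCALE_SLOPE

__all__ = [
    "ScanProtocol", "NormalizationSpec", "NORMALIZE_PARA", "default_protocols",
    "scaled_protocol", "kspace_truncate", "add_acquisition_noise",
    "resample_kspace", "simulate_routine", "simulate_fast", "zero_fill_upsample",
    "normalize", "denormalize", "normalization_spec",
]

#: per-parameter normalization constants (stored-intensity units)
NORMALIZE_PARA = {"T1": 45000.0, "T2": 22000.0, "PD": 1800.0}

#: default fast-scan k-space noise level per parameter (stored units),
#: chosen so fast-map pixel SD in uniform WM lands near 3x the routine map's
DEFAULT_FAST_SIGMA = {"T1": 90.0, "T2": 8.5, "PD": 7.0}


@dataclass(frozen=True)
class ScanProtocol:
    name: str                     # "routine" | "fast"
    acq_matrix: tuple[int, int]   # (frequency, phase) encoded samples
    accel_factor: int
    recon_grid: int               # square display grid
    fov: float = FOV_MM           # mm
    noise_sigma: float = 0.0      # k-space noise, stored-intensity units

    def __post_init__(self):
        if self.acq_matrix[0] > self.recon_grid or self.acq_matrix[1] > self.recon_grid:
            raise ValueError("acquisition matrix cannot exceed the recon grid")
        if self.accel_factor < 1:
            raise ValueError("accel_factor must be >= 1")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.recon_grid


def default_protocols(parameter: str = "T1", noisy: bool = True
                      ) -> tuple[ScanProtocol, ScanProtocol]:
    """(routine, fast) protocols with the study's matrix/acceleration values."""
    fast_sigma = DEFAULT_FAST_SIGMA[parameter] if noisy else 0.0
    routine = ScanProtocol("routine", (320, 256), 2, 512, noise_sigma=0.0)
    fast = ScanProtocol("fast", (192, 128), 3, 256, noise_sigma=fast_sigma)
    return routine, fast


def scaled_protocol(protocol: ScanProtocol, factor: float) -> ScanProtocol:
    """Proportionally shrink a protocol for desk-scale grids (e.g. factor 1/4
    maps routine 320x256@512 to 80x64@128)."""
    return replace(protocol,
                   acq_matrix=(int(round(protocol.acq_matrix[0] * factor)),
                               int(round(protocol.acq_matrix[1] * factor))),
                   recon_grid=int(round(protocol.recon_grid * factor)))


def _centered_slice(n: int, keep: int) -> slice:
    lo = (n - keep) // 2
    return slice(lo, lo + keep)


def _crop_kspace(k: np.ndarray, keep: tuple[int, int]) -> np.ndarray:
    # For an even crop the raw band (-K/2 .. K/2-1) is asymmetric; the
    # unmatched -K/2 Nyquist line is zeroed so the kept band is conjugate
    # symmetric — the output stays exactly real and truncation is
    # idempotent.  A full-axis crop keeps the axis untouched.
    ks = sp_fft.fftshift(k)
    ks = ks[_centered_slice(k.shape[0], keep[0]),
            _centered_slice(k.shape[1], keep[1])].copy()
    if keep[0] % 2 == 0 and keep[0] < k.shape[0]:
        ks[0, :] = 0.0
    if keep[1] % 2 == 0 and keep[1] < k.shape[1]:
        ks[:, 0] = 0.0
    return sp_fft.ifftshift(ks)


def _pad_kspace(k: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    ks = sp_fft.fftshift(k)
    out = np.zeros(out_shape, dtype=complex)
    out[_centered_slice(out_shape[0], k.shape[0]),
        _centered_slice(out_shape[1], k.shape[1])] = ks
    return sp_fft.ifftshift(out)


def kspace_truncate(qmap: QuantMap, acq_matrix: tuple[int, int],
                    clip: bool = True) -> QuantMap:
    """Centered k-space crop to ``acq_matrix`` with zero-fill back to the
    input grid: forward FFT, rectangular crop, zero-pad, inverse FFT,
    real part.

    With ``clip=True`` (default) ringing-induced negatives are clipped
    to zero since quantitative values are physical; the clip slightly
    perturbs the spectrum, so exact idempotence of the truncation holds
    only on the unclipped (purely linear) path.
    """
    rows, cols = qmap.grid
    if acq_matrix[0] > rows or acq_matrix[1] > cols:
        raise ValueError("acq_matrix larger than the map grid")
    k = sp_fft.fft2(qmap.values, norm="forward")
    k = _pad_kspace(_crop_kspace(k, acq_matrix), (rows, cols))
    img = sp_fft.ifft2(k, norm="forward").real
    return qmap.with_values(np.clip(img, 0.0, None) if clip else img)


def resample_kspace(qmap: QuantMap, out_grid: int) -> QuantMap:
    """Change the display grid by centered k-space crop/zero-pad (zero-fill
    interpolation).  Intensity scale is preserved (DC stays the mean)."""
    k = sp_fft.fft2(qmap.values, norm="forward")
    n = qmap.grid[0]
    if out_grid < n:
        k = _crop_kspace(k, (out_grid, out_grid))
    elif out_grid > n:
        k = _pad_kspace(k, (out_grid, out_grid))
    img = sp_fft.ifft2(k, norm="forward").real
    fov = qmap.pixel_spacing * n
    return qmap.with_values(np.clip(img, 0.0, None), pixel_spacing=fov / out_grid)


def zero_fill_upsample(qmap: QuantMap, out_grid: int) -> QuantMap:
    """Zero-fill interpolation to a larger display grid."""
    if out_grid < qmap.grid[0]:
        raise ValueError("zero_fill_upsample only enlarges the grid")
    return resample_kspace(qmap, out_grid)


def add_acquisition_noise(qmap: QuantMap, protocol: ScanProtocol,
                          rng_seed: int) -> QuantMap:
    """Seeded complex Gaussian k-space noise (unitary FFT convention).

    The per-axis sigma is the protocol's base ``noise_sigma`` (stored
    units) amplified by sqrt(accel_factor x grid-area / acquired-area):
    fewer acquired samples at higher acceleration means noisier maps.
    Values are converted to physical units via the rescale slope.
    """
    if protocol.noise_sigma == 0:
        return qmap.with_values(qmap.values.copy())
    rng = np.random.default_rng(rng_seed)
    area_ratio = (qmap.grid[0] * qmap.grid[1]) / (
        protocol.acq_matrix[0] * protocol.acq_matrix[1])
    sigma_stored = protocol.noise_sigma * np.sqrt(protocol.accel_factor * area_ratio)
    sigma_phys = sigma_stored * qmap.rescale_slope
    k = sp_fft.fft2(qmap.values, norm="ortho")
    noise = rng.normal(0, sigma_phys, qmap.grid) + 1j * rng.normal(
        0, sigma_phys, qmap.grid)
    img = sp_fft.ifft2(k + noise, norm="ortho").real
    return qmap.with_values(np.clip(img, 0.0, None))


def simulate_routine(map_hr: QuantMap, protocol: ScanProtocol,
                     rng_seed: int = 0) -> QuantMap:
    """Routine scan of a ground-truth map: truncate to the routine
    acquisition matrix, add routine-level noise, return on the same
    (high-resolution) grid via zero-fill."""
    if map_hr.grid != (protocol.recon_grid, protocol.recon_grid):
        raise ValueError("input must be on the protocol's recon grid")
    out = kspace_truncate(map_hr, protocol.acq_matrix)
    return add_acquisition_noise(out, protocol, rng_seed)


def simulate_fast(map_hr: QuantMap, protocol: ScanProtocol,
                  rng_seed: int = 0) -> QuantMap:
    """Fast scan: truncate the ground-truth grid to the fast acquisition
    matrix, add acceleration-scaled noise, reconstruct on the fast
    display grid (half the input grid by default)."""
    out = kspace_truncate(map_hr, protocol.acq_matrix)
    out = add_acquisition_noise(out, protocol, rng_seed)
    return resample_kspace(out, protocol.recon_grid)


@dataclass(frozen=True)
class NormalizationSpec:
    parameter: str
    normalize_para: float

    def __post_init__(self):
        if self.normalize_para <= 0:
            raise ValueError("normalize_para must be positive")
        if self.normalize_para <= STORED_MAX[self.parameter]:
            raise ValueError("normalize_para must exceed the stored maximum")


def normalization_spec(parameter: str) -> NormalizationSpec:
    return NormalizationSpec(parameter, NORMALIZE_PARA[parameter])


def normalize(qmap: QuantMap, spec: NormalizationSpec) -> np.ndarray:
    """stored / normalize_para * 2 - 1, into [-1, 1)."""
    stored = qmap.values / qmap.rescale_slope
    return stored / spec.normalize_para * 2.0 - 1.0


def denormalize(image: np.ndarray, spec: NormalizationSpec,
                pixel_spacing: float,
                rescale_slope: float = RESCALE_SLOPE) -> QuantMap:
    """Inverse of :func:`normalize`; output clipped to the physical range."""
    stored = (np.asarray(image, dtype=float) + 1.0) / 2.0 * spec.normalize_para
    phys = stored * rescale_slope
    hi = STORED_MAX[spec.parameter] * rescale_slope
    return QuantMap(np.clip(phys, 0.0, hi), spec.parameter, pixel_spacing,
                    rescale_slope=rescale_slope)
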