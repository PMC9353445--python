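"""Apply a correction to the binarized target, yielding a continuous dose.

Two correction paths exist and are mutually exclusive per run: the full
frequency-space correction mask C(k, z) for scattering resins, or a pure
real-space amplitude correction exp(d/l) for absorptive non-scattering
resins.  Both use the rotating-vial depth convention d(r) = R - r.

The spatially varying inverse filter is realized with a bank of
``n_depth_bins`` global filters spanning depths [0, R]; each voxel takes
the value linearly interpolated between the two bracketing depth bins
according to its own effective depth.  Negative filter ringing is clipped,
the dose is confined to the target support, and the result is normalized
to a maximum of 1 (absolute dose scaling belongs to exposure time/power,
outside this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .characterize import AttenuationFit, CorrectionMask
from .phantoms import depth_map
from .volume import VialGeometry, VoxelVolume

__all__ = ["TargetDose", "correct_target_dose", "amplitude_correction", "normalize_dose"]


@dataclass
class TargetDose:
    """Continuous corrected target dose in [0, 1] on the same grid as the
    binary target, with a provenance record of how it was produced."""

    volume: VoxelVolume
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.volume.values
        if v.size and (v.min() < 0 or v.max() > 1 + 1e-12):
            raise ValueError("target dose values must lie in [0, 1]")


def normalize_dose(values: np.ndarray) -> np.ndarray:
    """Scale so the maximum is 1 (idempotent; zero volumes stay zero)."""
    m = float(values.max()) if values.size else 0.0
    return values / m if m > 0 else values


def _check_binary(target: VoxelVolume) -> None:
    if not target.is_binary():
        raise ValueError("target must be a binary {0,1} volume")


def correct_target_dose(
    target: VoxelVolume,
    mask: CorrectionMask,
    geometry: VialGeometry,
    n_depth_bins: int = 16,
) -> TargetDose:
    """Boost the target's spatial frequencies according to C(k, z) at each
    voxel's effective depth.

    Per horizontal slice, filtered versions ``F^-1[C(|k|, d_b) F[D]]`` are
    computed at ``n_depth_bins`` depths spanning [0, R] (the 1D mask k-axis
    is applied radially in the 2D slice frequency plane); each voxel
    interpolates between the two bracketing bins at its depth d(r) = R - r.
    """
    _check_binary(target)
    if n_depth_bins < 2:
        raise ValueError("n_depth_bins must be >= 2")
    R = geometry.radius
    if mask.z[-1] < R - 1e-9:
        raise ValueError(
            f"mask depth range ({mask.z[-1]} mm) shorter than vial radius {R} mm"
        )
    nx, ny, nz = target.shape
    pitch = target.pitch
    depths = np.linspace(0.0, R, n_depth_bins)

    kx = np.fft.fftfreq(nx, d=pitch)
    ky = np.fft.rfftfreq(ny, d=pitch)
    K = np.hypot(kx[:, None], ky[None, :])
    C_bins = mask.radial(K, depths)  # (n_bins, nx, n_ky)

    d = depth_map(geometry, target)  # (nx, ny), NaN outside vial
    d = np.clip(np.nan_to_num(d, nan=0.0), 0.0, R)
    # fractional bin coordinate of every (x, y) position
    b = d / (R / (n_depth_bins - 1))
    b0 = np.minimum(b.astype(int), n_depth_bins - 2)
    frac = b - b0

    values = target.values.astype(float)
    out = np.empty_like(values)
    ix = np.arange(nx)[:, None]
    iy = np.arange(ny)[None, :]
    for iz in range(nz):
        F = np.fft.rfft2(values[:, :, iz])
        filtered = np.fft.irfft2(C_bins * F[None], s=(nx, ny), axes=(1, 2))
        lo = filtered[b0, ix, iy]
        hi = filtered[b0 + 1, ix, iy]
        out[:, :, iz] = lo + frac * (hi - lo)

    out = np.clip(out, 0.0, None)
    out *= values > 0  # confine the dose to the target support
    out = normalize_dose(out)
    return TargetDose(
        target.copy(values=out),
        provenance={
            "correction": "frequency_mask",
            "n_depth_bins": n_depth_bins,
            "c_max": mask.c_max,
            "eps": mask.eps,
            "window": mask.window,
            "pattern_count": mask.pattern_count,
            "vial_inner_diameter_mm": geometry.inner_diameter,
        },
    )


def amplitude_correction(
    target: VoxelVolume,
    fit: AttenuationFit,
    geometry: VialGeometry,
) -> TargetDose:
    """Real-space correction for a purely absorptive resin: each voxel is
    scaled by exp(d(r)/l) with the fitted attenuation length l."""
    _check_binary(target)
    l = fit.length_mm
    if not l > 0:
        raise ValueError("attenuation length must be > 0")
    values = target.values.astype(float)
    if np.isinf(l):
        out = values.copy()
    else:
        d = depth_map(geometry, target)
        d = np.clip(np.nan_to_num(d, nan=0.0), 0.0, geometry.radius)
        out = values * np.exp(d / l)[:, :, None]
        out = normalize_dose(out)
    return TargetDose(
        target.copy(values=out),
        provenance={
            "correction": "amplitude",
            "attenuation_length_mm": l,
            "r_squared": fit.r_squared,
            "vial_inner_diameter_mm": geometry.inner_diameter,
        },
    )
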