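"""From side-view stacks to correction masks.

The characterization pipeline mirrors the optical measurement: a set of
structured patterns is projected through the resin, a side-view camera
records one image per pattern, and the per-depth 1D Fourier magnitude
spectra (along the structured transverse axis) are averaged over patterns.
Dividing the incident averaged spectrum at z = 0 by the spectrum at each
depth yields a correction mask C(k, z) >= 0 that says how much each spatial
frequency must be boosted at each depth to counteract scattering.  The
inverse is regularized with a noise floor and a hard cap (unbounded inverse
filtering amplifies measurement noise).

For absorptive, non-scattering resins the same apparatus supports a simpler
real-space correction: a log-linear fit of the mean transverse intensity
versus depth yields the attenuation length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import stats

from .scatter import SideViewStack

__all__ = [
    "SpectrumMap",
    "CorrectionMask",
    "AttenuationFit",
    "average_spectra",
    "build_correction_mask",
    "fit_attenuation_length",
]

_WINDOWS = ("hann", "none")


@dataclass
class SpectrumMap:
    """Mean magnitude spectrum S(k, z) over patterns.

    ``S`` has shape (n_k, n_z); ``k`` is the nonnegative half-spectrum in
    cycles/mm; ``z`` in mm with the z = 0 column present.
    """

    S: np.ndarray
    k: np.ndarray
    z: np.ndarray
    pattern_count: int
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.S.shape != (len(self.k), len(self.z)):
            raise ValueError("S shape must be (len(k), len(z))")
        if self.z[0] != 0:
            raise ValueError("z axis must start at 0 (incident spectrum)")


@dataclass
class CorrectionMask:
    """Multiplicative spatial-frequency boost C(k, z), C(k, 0) = 1."""

    C: np.ndarray
    k: np.ndarray
    z: np.ndarray
    c_max: float
    eps: float
    pattern_count: int = 0
    window: str = "hann"
    flagged_k: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def at_depths(self, depths: np.ndarray) -> np.ndarray:
        """Linearly interpolate the mask columns at the given depths (mm).

        Returns shape (n_k, len(depths)); depths must lie inside the mask
        z-range."""
        depths = np.asarray(depths, dtype=float)
        if depths.min() < self.z[0] - 1e-9 or depths.max() > self.z[-1] + 1e-9:
            raise ValueError(
                f"depths [{depths.min()}, {depths.max()}] mm outside mask "
                f"z-range [{self.z[0]}, {self.z[-1]}] mm"
            )
        out = np.empty((len(self.k), len(depths)))
        for i in range(len(self.k)):
            out[i] = np.interp(depths, self.z, self.C[i])
        return out

    def radial(self, k_query: np.ndarray, depths: np.ndarray) -> np.ndarray:
        """Evaluate the 1D k-axis mask on arbitrary |k| values per depth
        (isotropy assumption); clamps beyond the tabulated k-range.

        Returns shape (len(depths), *k_query.shape)."""
        cols = self.at_depths(depths)  # (n_k, n_d)
        kq = np.asarray(k_query, dtype=float).ravel()
        out = np.empty((cols.shape[1], kq.size))
        for j in range(cols.shape[1]):
            out[j] = np.interp(kq, self.k, cols[:, j])
        return out.reshape(cols.shape[1], *np.shape(k_query))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.C, dtype=np.float32))
        meta = {
            "k_axis_cycles_per_mm": [float(v) for v in self.k],
            "z_axis_mm": [float(v) for v in self.z],
            "pattern_count": self.pattern_count,
            "eps": self.eps,
            "C_max": self.c_max,
            "window": self.window,
            "flagged_k": [int(i) for i in self.flagged_k],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionMask":
        path = Path(path)
        C = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            C,
            np.asarray(meta["k_axis_cycles_per_mm"]),
            np.asarray(meta["z_axis_mm"]),
            float(meta["C_max"]),
            float(meta["eps"]),
            int(meta.get("pattern_count", 0)),
            meta.get("window", "hann"),
            np.asarray(meta.get("flagged_k", []), dtype=int),
        )


@dataclass
class AttenuationFit:
    """Log-linear attenuation fit: ln I(z) = intercept - z / length."""

    length_mm: float  # math.inf sentinel when no decay is detected
    intercept: float
    r_squared: float
    z_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValueError("fitted length must be > 0")


def average_spectra(stack: SideViewStack, window: str = "hann") -> SpectrumMap:
    """Per-depth 1D magnitude spectra along the structured transverse axis,
    averaged over patterns.

    A window ('hann' by default, 'none' to disable) is applied along the
    transverse axis before the transform to suppress edge leakage on
    measured stacks; the choice is recorded so measured and synthetic paths
    match bit-for-bit.  Magnitude (not power) spectra are averaged, and the
    DC term is kept so the mask can also encode net attenuation.
    """
    if window not in _WINDOWS:
        raise ValueError(f"window must be one of {_WINDOWS}")
    images = np.asarray(stack.images, dtype=float)
    if images.ndim != 3:
        raise ValueError("stack images must have shape (patterns, y, z)")
    n_y = images.shape[1]
    w = np.hanning(n_y) if window == "hann" else np.ones(n_y)
    spec = np.abs(np.fft.rfft(images * w[None, :, None], axis=1))
    S = spec.mean(axis=0)
    return SpectrumMap(S, stack.k, stack.z, images.shape[0], window)


def build_correction_mask(
    spectra: SpectrumMap, c_max: float = 10.0, eps: float = 1e-3
) -> CorrectionMask:
    """Invert the averaged spectra into a correction mask.

    C(k, z) = S(k, 0) / max(S(k, z), eps * max S), clipped to [0, c_max];
    the z = 0 column is identically 1.  Frequencies whose incident spectrum
    falls below the noise floor cannot be inverted: they are flagged and set
    to 1.
    """
    if not c_max > 0:
        raise ValueError("c_max must be > 0")
    floor = eps * float(spectra.S.max())
    incident = spectra.S[:, :1]
    C = incident / np.maximum(spectra.S, floor)
    flagged = np.flatnonzero(spectra.S[:, 0] <= floor)
    if len(flagged):
        C[flagged, :] = 1.0
    C = np.clip(C, 0.0, c_max)
    C[:, 0] = 1.0
    return CorrectionMask(
        C,
        spectra.k,
        spectra.z,
        c_max,
        eps,
        spectra.pattern_count,
        spectra.window,
        flagged,
    )


def fit_attenuation_length(
    profile,
    z=None,
    z_range: tuple[float, float] | None = None,
) -> AttenuationFit:
    """Least-squares line fit of ln(mean transverse intensity) versus depth.

    ``profile`` may be a :class:`SideViewStack` (its mean transverse
    intensity per depth is used) or a 1D intensity profile with matching
    depth grid ``z`` (mm).  Returns the attenuation length ``-1/slope``; a
    nonnegative slope yields the ``inf`` sentinel (no decay).
    """
    if isinstance(profile, SideViewStack):
        z = profile.z
        profile = profile.axial_profile()
    profile = np.asarray(profile, dtype=float)
    z = np.asarray(z, dtype=float)
    if profile.shape != z.shape:
        raise ValueError("profile and z must have the same shape")
    if z_range is not None:
        sel = (z >= z_range[0]) & (z <= z_range[1])
        profile, z = profile[sel], z[sel]
    if profile.size < 2:
        raise ValueError("need at least two samples to fit")
    if np.any(profile <= 0):
        raise ValueError("intensity must be strictly positive over the fit range")
    res = stats.linregress(z, np.log(profile))
    length = math.inf if res.slope >= 0 else -1.0 / res.slope
    return AttenuationFit(
        length, float(res.intercept), float(res.rvalue**2), (float(z[0]), float(z[-1]))
    )
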