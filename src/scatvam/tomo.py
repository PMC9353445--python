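"""Projection-pattern computation and print-dose simulation.

Tomographic VAM deposits a volumetric dose as the backprojection of a set
of nonnegative amplitude patterns projected from many angles into the
rotating vial.  Computing the patterns is the inverse problem: start from
the ramp-filtered Radon transform of the (corrected) target dose, clip
negatives (the projector cannot emit negative light), then refine with
projected-gradient iterations that minimize the squared mismatch between
the deposited dose and the target subject to the positivity constraint.

The projector is pixel-driven: each in-circle pixel splats into the two
nearest detector bins with linear weights, and back_project is the exact
sparse transpose, so the forward/adjoint pair passes a dot-product test to
machine precision.  Angles span [0, 2pi) (not [0, pi)) because attenuation
in a turbid medium breaks the parallel-beam symmetry.

simulate_print_dose replays a pattern set through the parametric scattering
medium: at each angle the pattern propagates along the optical axis, its
spatial-frequency content attenuated by T(k, z) with depth measured from a
flat entry plane tangent to the vial wall (so the vial center sits at depth
R), and the attenuated, blurred field is accumulated into the volume in the
frame rotated by that angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import sparse

from .scatter import ScatteringMedium, transfer_function
from .volume import VialGeometry, VoxelVolume

__all__ = [
    "PatternSet",
    "DoseVolume",
    "Projector",
    "forward_project",
    "back_project",
    "fbp_initialize",
    "optimize_patterns",
    "OptimizeResult",
    "quantize_patterns",
    "simulate_print_dose",
    "default_angles",
]


def default_angles(n_angles: int = 360) -> np.ndarray:
    """Evenly spaced projection angles over a full rotation [0, 2pi)."""
    if n_angles < 1:
        raise ValueError("need at least one angle")
    return np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)


@dataclass
class PatternSet:
    """Nonnegative projection patterns, one 2D image per angle.

    ``patterns`` has shape (n_angles, n_s, n_z): transverse-lateral
    (detector) axis by vertical (vial) axis, with pixel pitch in mm.
    8-bit sets hold integers 0..255 plus the dequantization scale.
    """

    angles: np.ndarray
    patterns: np.ndarray
    pixel_pitch: float
    bit_depth: str = "float"  # "float" or "uint8"
    scale: float = 1.0  # dequantized value = patterns * scale (uint8 sets)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) < 1:
            raise ValueError("angle count must be >= 1")
        if self.patterns.shape[0] != len(self.angles):
            raise ValueError("patterns/angles length mismatch")
        if self.patterns.size and self.patterns.min() < 0:
            raise ValueError("pattern values must be >= 0")
        if self.bit_depth not in ("float", "uint8"):
            raise ValueError("bit_depth must be 'float' or 'uint8'")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def as_float(self) -> np.ndarray:
        if self.bit_depth == "uint8":
            return self.patterns.astype(float) * self.scale
        return np.asarray(self.patterns, dtype=float)

    def save(self, directory: str | Path) -> None:
        """Export as an indexed TIFF stack directory plus a JSON manifest —
        the shape a DMD playback tool consumes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(self.n_angles - 1)))
        dtype = np.uint8 if self.bit_depth == "uint8" else np.float32
        for i in range(self.n_angles):
            tifffile.imwrite(
                directory / f"pattern_{i:0{width}d}.tif",
                self.patterns[i].astype(dtype),
            )
        manifest = {
            "angles_deg": [float(np.degrees(a)) for a in self.angles],
            "pixel_pitch_mm": self.pixel_pitch,
            "bit_depth": self.bit_depth,
            "scale": self.scale,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "PatternSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        files = sorted(directory.glob("pattern_*.tif"))
        patterns = np.stack([tifffile.imread(f) for f in files])
        return cls(
            np.radians(manifest["angles_deg"]),
            patterns,
            float(manifest["pixel_pitch_mm"]),
            manifest.get("bit_depth", "float"),
            float(manifest.get("scale", 1.0)),
        )


@dataclass
class DoseVolume:
    """Accumulated light exposure (arbitrary units) with provenance."""

    volume: VoxelVolume
    medium: ScatteringMedium | None = None
    provenance: dict = field(default_factory=dict)


class Projector:
    """Parallel-beam projector on an n-by-n slice grid.

    For angle theta the detector coordinate of pixel (x, y) (centered, in
    pixel units) is s = -x sin(theta) + y cos(theta); forward projection
    splats each pixel inside the reconstruction circle into its two nearest
    detector bins with linear weights (times the pitch, so sinogram values
    approximate line integrals in mm); back_project is the exact transpose.
    """

    def __init__(self, n: int, angles: np.ndarray, pitch: float = 1.0):
        self.n = int(n)
        self.angles = np.asarray(angles, dtype=float)
        self.pitch = float(pitch)
        c = (self.n - 1) / 2.0
        ii, jj = np.meshgrid(np.arange(self.n), np.arange(self.n), indexing="ij")
        x = (ii - c).ravel()
        y = (jj - c).ravel()
        self.in_circle = (x**2 + y**2 <= c**2 + 1e-9).reshape(self.n, self.n)
        flat_circle = self.in_circle.ravel()
        pix = np.arange(self.n * self.n)

        rows, cols, data = [], [], []
        for a, th in enumerate(self.angles):
            s = -x * np.sin(th) + y * np.cos(th) + c
            i0 = np.floor(s).astype(np.int64)
            w1 = s - i0
            for ib, wb in ((i0, 1.0 - w1), (i0 + 1, w1)):
                ok = flat_circle & (ib >= 0) & (ib < self.n) & (wb > 0)
                rows.append(a * self.n + ib[ok])
                cols.append(pix[ok])
                data.append(wb[ok] * self.pitch)
        A = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(self.angles) * self.n, self.n * self.n),
        )
        self.A = A.tocsr()
        self.AT = self.A.T.tocsr()

    def _check_circle(self, slices: np.ndarray) -> None:
        outside = slices[~self.in_circle]
        if outside.size and np.abs(outside).max() > 1e-12 * max(
            np.abs(slices).max(), 1e-300
        ):
            raise ValueError("slice has content outside the reconstruction circle")

    def forward(self, slices: np.ndarray, check_circle: bool = True) -> np.ndarray:
        """Line integrals: (n, n[, n_z]) -> sinogram (n_angles, n_s[, n_z])."""
        slices = np.asarray(slices, dtype=float)
        single = slices.ndim == 2
        if single:
            slices = slices[:, :, None]
        if slices.shape[:2] != (self.n, self.n):
            raise ValueError(f"expected ({self.n}, {self.n}, ...) slices")
        if check_circle:
            self._check_circle(slices)
        out = (self.A @ slices.reshape(self.n * self.n, -1)).reshape(
            len(self.angles), self.n, -1
        )
        return out[:, :, 0] if single else out

    def back(self, sino: np.ndarray) -> np.ndarray:
        """Adjoint: sinogram (n_angles, n_s[, n_z]) -> slices (n, n[, n_z])."""
        sino = np.asarray(sino, dtype=float)
        single = sino.ndim == 2
        if single:
            sino = sino[:, :, None]
        if sino.shape[:2] != (len(self.angles), self.n):
            raise ValueError(
                f"expected ({len(self.angles)}, {self.n}, ...) sinogram, "
                f"got {sino.shape}"
            )
        out = (self.AT @ sino.reshape(len(self.angles) * self.n, -1)).reshape(
            self.n, self.n, -1
        )
        return out[:, :, 0] if single else out


_projector_cache: dict[tuple, Projector] = {}


def _get_projector(n: int, angles: np.ndarray, pitch: float) -> Projector:
    key = (n, float(pitch), tuple(np.round(np.asarray(angles, float), 12)))
    if key not in _projector_cache:
        if len(_projector_cache) > 4:
            _projector_cache.clear()
        _projector_cache[key] = Projector(n, angles, pitch)
    return _projector_cache[key]


def forward_project(slice_, angles, pitch: float = 1.0) -> np.ndarray:
    """Radon transform of a slice: line integrals along each angle's
    parallel ray bundle, sampled at the pattern pixel pitch."""
    slice_ = np.asarray(slice_, dtype=float)
    return _get_projector(slice_.shape[0], angles, pitch).forward(slice_)


def back_project(sino, angles, pitch: float = 1.0) -> np.ndarray:
    """Adjoint of :func:`forward_project`, accumulated over angles."""
    sino = np.asarray(sino, dtype=float)
    return _get_projector(sino.shape[1], angles, pitch).back(sino)


def _ramp_filter(sino: np.ndarray, pitch: float) -> np.ndarray:
    """Ram-Lak filter along the detector axis (axis 1)."""
    n_s = sino.shape[1]
    m = 1 << int(np.ceil(np.log2(2 * n_s)))
    f = np.abs(np.fft.rfftfreq(m, d=pitch))
    F = np.fft.rfft(sino, n=m, axis=1)
    out = np.fft.irfft(F * f[None, :, None] if sino.ndim == 3 else F * f, n=m, axis=1)
    return out[:, :n_s]


def fbp_initialize(target, n_angles: int = 360, angles=None) -> PatternSet:
    """Filtered-backprojection pattern initialization.

    Per horizontal slice, the target is Radon-transformed and ramp
    filtered; negative pattern values are clipped to zero (positivity).
    ``target`` is a VoxelVolume or a TargetDose.
    """
    volume = getattr(target, "volume", target)
    if angles is None:
        if n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        angles = default_angles(n_angles)
    angles = np.asarray(angles, dtype=float)
    proj = _get_projector(volume.shape[0], angles, volume.pitch)
    sino = proj.forward(volume.values.astype(float))  # (n_angles, n_s, n_z)
    filtered = _ramp_filter(sino, volume.pitch)
    # scale so that back(patterns) approximates the target amplitude
    filtered *= np.pi / (len(angles) * volume.pitch)
    return PatternSet(angles, np.clip(filtered, 0.0, None), volume.pitch)


@dataclass
class OptimizeResult:
    patterns: PatternSet
    loss_history: np.ndarray
    converged: bool


def optimize_patterns(
    target,
    init: PatternSet,
    iterations: int = 50,
    step: float | None = None,
    tolerance: float = 1e-4,
) -> OptimizeResult:
    """Projected-gradient (Landweber) refinement under positivity.

    Minimizes ``sum((back_project(P) - target)^2)`` over nonnegative
    pattern sets P, starting from ``init``.  The default step is the
    inverse of a power-iteration estimate (fixed seed) of the spectral norm
    of the normal operator.  Stops at ``iterations`` or when the relative
    loss change drops below ``tolerance``; three consecutive loss increases
    raise (step too large).
    """
    volume = getattr(target, "volume", target)
    proj = _get_projector(volume.shape[0], init.angles, volume.pitch)
    D = volume.values.astype(float)
    P = init.as_float().copy()

    if step is None:
        rng = np.random.default_rng(1234)
        v = rng.standard_normal((proj.n, proj.n, 1))
        v /= np.linalg.norm(v)
        lam = 1.0
        for _ in range(12):
            w = proj.back(proj.forward(v, check_circle=False))
            lam = float(np.linalg.norm(w))
            v = w / lam
        step = 1.0 / (2.0 * lam)  # 1 / Lipschitz constant of the gradient

    losses = []
    n_increase = 0
    converged = False
    for it in range(iterations):
        residual = proj.back(P) - D
        loss = float(np.sum(residual**2))
        losses.append(loss)
        if it > 0:
            prev = losses[-2]
            if loss > prev:
                n_increase += 1
                if n_increase >= 3:
                    raise RuntimeError(
                        "optimization diverging (loss increased 3 consecutive "
                        "steps); use a smaller step"
                    )
            else:
                n_increase = 0
            if prev > 0 and abs(prev - loss) / prev < tolerance:
                converged = True
                break
        if loss == 0.0:
            converged = True
            break
        P = np.clip(P - step * 2.0 * proj.forward(residual, check_circle=False), 0.0, None)
    out = PatternSet(init.angles, P, init.pixel_pitch)
    return OptimizeResult(out, np.asarray(losses), converged)


def quantize_patterns(patterns: PatternSet) -> PatternSet:
    """Quantize a float pattern set for an 8-bit DMD: linear map of
    [0, global max] to integers 0..255 by rounding."""
    if patterns.bit_depth == "uint8":
        return patterns
    values = patterns.as_float()
    m = float(values.max()) if values.size else 0.0
    if m == 0.0:
        q = np.zeros_like(values, dtype=np.uint8)
        scale = 1.0
    else:
        q = np.round(values / m * 255.0).astype(np.uint8)
        scale = m / 255.0
    return PatternSet(patterns.angles, q, patterns.pixel_pitch, "uint8", scale)


def simulate_print_dose(
    patterns: PatternSet,
    medium: ScatteringMedium | None,
    geometry: VialGeometry,
) -> DoseVolume:
    """Accumulate the dose a pattern set deposits through the medium.

    For each angle the pattern propagates along the optical axis with its
    spectrum attenuated by T(k, depth); depth is measured from a flat entry
    plane tangent to the vial wall, so the rotation axis sits at depth R.
    The blurred field is accumulated into the volume in the frame rotated
    by that angle.  ``medium=None`` means a transparent medium, in which
    case the dose equals ``back_project`` of the patterns up to scale.
    """
    P = patterns.as_float()
    n_angles, n_s, n_z = P.shape
    n = n_s
    pitch = patterns.pixel_pitch
    R = geometry.radius
    if n * pitch < 2 * R - 1e-9:
        raise ValueError(
            f"patterns ({n * pitch:.3g} mm wide) do not cover the vial "
            f"cross-section ({2 * R:.3g} mm)"
        )
    c = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x = (ii - c).ravel()
    y = (jj - c).ravel()
    flat_circle = (x**2 + y**2 <= c**2 + 1e-9)
    q = np.flatnonzero(flat_circle)
    xq, yq = x[q], y[q]

    # transfer function on the propagation grid: depth of the t-th plane
    # (pixel units along the ray) from the tangent entry plane
    t_planes = (np.arange(n) - c) * pitch + R
    z_planes = np.maximum(t_planes, 0.0)
    if medium is None:
        T = None
    else:
        k = np.fft.rfftfreq(n, d=pitch)
        T = transfer_function(medium, k, z_planes)  # (n_t, n_k)

    dose = np.zeros((n * n, n_z))
    for a, th in enumerate(patterns.angles):
        if T is None:
            field = np.broadcast_to(P[a][None], (n, n_s, n_z))
        else:
            F = np.fft.rfft(P[a], axis=0)  # (n_k, n_z)
            field = np.fft.irfft(T[:, :, None] * F[None], n=n_s, axis=1)
            field = np.clip(field, 0.0, None)
        field = field.reshape(n * n_s, n_z)

        s = -xq * np.sin(th) + yq * np.cos(th) + c
        t = xq * np.cos(th) + yq * np.sin(th) + c
        i0 = np.floor(s).astype(np.int64)
        j0 = np.floor(t).astype(np.int64)
        fs = s - i0
        ft = t - j0
        for dj, wt in ((0, 1.0 - ft), (1, ft)):
            jb = np.clip(j0 + dj, 0, n - 1)
            for di, ws in ((0, 1.0 - fs), (1, fs)):
                ib = np.clip(i0 + di, 0, n_s - 1)
                w = wt * ws
                dose[q] += w[:, None] * field[jb * n_s + ib]

    vol = VoxelVolume(dose.reshape(n, n, n_z), pitch)
    return DoseVolume(
        vol,
        medium,
        provenance={
            "n_angles": n_angles,
            "vial_inner_diameter_mm": geometry.inner_diameter,
            "transparent": medium is None,
        },
    )
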