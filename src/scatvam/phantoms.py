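"""Test geometries for tomographic volumetric printing.

Generators for the benchmark phantoms (a gear with inner and outer cogs, a
vascular construct with a solid core and open channels), voxelization of STL
meshes, and the rotating-vial depth convention: a voxel at radius ``r`` from
the rotation axis has effective penetration depth ``d = R - r`` where ``R``
is the vial inner radius, maximal on the axis.

All phantoms are strictly binary ({0, 1} uint8), decided at voxel centers
with no antialiasing, and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VialGeometry, VoxelVolume

__all__ = [
    "GearSpec",
    "VesselPhantomSpec",
    "make_gear",
    "make_vascular_phantom",
    "depth_map",
    "voxelize_mesh",
    "cog_arc_width",
]


@dataclass
class GearSpec:
    """Gear with rectangular cogs protruding outward on the rim and inward
    on the bore.

    Cog angular extent is set so that the arc width at the mid-cog radius
    equals the requested width.  Radial protrusion depths default to the cog
    width (square-ish teeth).  Lengths in mm.
    """

    outer_radius: float = 5.5
    bore_radius: float = 2.0
    outer_cog_count: int = 16
    outer_cog_width: float = 0.75
    inner_cog_count: int = 12
    inner_cog_width: float = 0.46
    height: float = 2.0
    outer_cog_depth: float | None = None
    inner_cog_depth: float | None = None

    def __post_init__(self) -> None:
        if self.outer_cog_depth is None:
            self.outer_cog_depth = self.outer_cog_width
        if self.inner_cog_depth is None:
            self.inner_cog_depth = self.inner_cog_width
        if min(self.outer_cog_width, self.inner_cog_width) <= 0:
            raise ValueError("cog widths must be > 0")
        if not 0 < self.bore_radius < self.outer_radius:
            raise ValueError("need 0 < bore_radius < outer_radius")
        for count, width, r_mid in (
            (self.outer_cog_count, self.outer_cog_width, self.outer_mid_radius),
            (self.inner_cog_count, self.inner_cog_width, self.inner_mid_radius),
        ):
            if count > 0 and count * width >= 2 * np.pi * r_mid:
                raise ValueError(
                    f"{count} cogs of width {width} mm overlap at radius {r_mid} mm"
                )

    @property
    def outer_mid_radius(self) -> float:
        return self.outer_radius - 0.5 * self.outer_cog_depth  # type: ignore[operator]

    @property
    def inner_mid_radius(self) -> float:
        return self.bore_radius - 0.5 * self.inner_cog_depth  # type: ignore[operator]


@dataclass
class VesselPhantomSpec:
    """Solid cylindrical construct with vertical open channels on a circular
    orbit around a solid core, emulating vasculature.  Lengths in mm."""

    core_diameter: float = 4.0
    channel_count: int = 4
    channel_diameter: float = 1.0
    orbit_radius: float = 3.5
    outer_diameter: float = 11.0
    height: float = 4.0
    manifold: bool = False  # horizontal ring linking the channels mid-height

    def __post_init__(self) -> None:
        core_r = 0.5 * self.core_diameter
        ch_r = 0.5 * self.channel_diameter
        if self.channel_count > 0:
            if self.orbit_radius - ch_r <= core_r:
                raise ValueError("channels intersect the solid core")
            if self.orbit_radius + ch_r >= 0.5 * self.outer_diameter:
                raise ValueError("channels extend outside the construct")


def _grid(radius: float, height: float, pitch: float):
    """Square in-plane grid centered on the rotation axis."""
    n = int(np.ceil(2 * radius / pitch)) + 2
    nz = max(int(round(height / pitch)), 1)
    c = 0.5 * n * pitch  # axis position
    xy = (np.arange(n) + 0.5) * pitch - c
    x = xy[:, None]
    y = xy[None, :]
    return n, nz, x, y


def _in_cog(phi: np.ndarray, count: int, width: float, r_mid: float) -> np.ndarray:
    if count == 0:
        return np.zeros_like(phi, dtype=bool)
    half = 0.5 * width / r_mid  # half-angle so arc width at r_mid == width
    step = 2 * np.pi / count
    return np.abs((phi + 0.5 * step) % step - 0.5 * step) <= half


def make_gear(spec: GearSpec, pitch: float) -> VoxelVolume:
    """Voxelize a gear phantom.

    Raises if ``pitch`` is too coarse to resolve the narrowest cog
    (pitch must be at most min cog width / 4).
    """
    min_width = min(spec.outer_cog_width, spec.inner_cog_width)
    if pitch > min_width / 4:
        raise ValueError(
            f"pitch {pitch} mm too coarse for the narrowest cog "
            f"({min_width} mm); need pitch <= {min_width / 4:.4g} mm"
        )
    n, nz, x, y = _grid(spec.outer_radius, spec.height, pitch)
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)

    body = (r >= spec.bore_radius) & (r <= spec.outer_radius - spec.outer_cog_depth)
    outer = (
        (r > spec.outer_radius - spec.outer_cog_depth)
        & (r <= spec.outer_radius)
        & _in_cog(phi, spec.outer_cog_count, spec.outer_cog_width, spec.outer_mid_radius)
    )
    inner = (
        (r >= spec.bore_radius - spec.inner_cog_depth)
        & (r < spec.bore_radius)
        & _in_cog(phi, spec.inner_cog_count, spec.inner_cog_width, spec.inner_mid_radius)
    )
    slice2d = (body | outer | inner).astype(np.uint8)
    values = np.repeat(slice2d[:, :, None], nz, axis=2)
    return VoxelVolume(values, pitch)


def make_vascular_phantom(spec: VesselPhantomSpec, pitch: float) -> VoxelVolume:
    """Voxelize the vascular construct: solid bulk with void channel tubes
    open at the top and bottom faces."""
    if spec.channel_count > 0 and pitch > spec.channel_diameter / 4:
        raise ValueError(
            f"pitch {pitch} mm too coarse for {spec.channel_diameter} mm channels"
        )
    outer_r = 0.5 * spec.outer_diameter
    n, nz, x, y = _grid(outer_r, spec.height, pitch)
    r = np.hypot(x, y)
    solid = r <= outer_r

    ch_r = 0.5 * spec.channel_diameter
    void = np.zeros_like(solid)
    for i in range(spec.channel_count):
        ang = 2 * np.pi * i / spec.channel_count
        cx = spec.orbit_radius * np.cos(ang)
        cy = spec.orbit_radius * np.sin(ang)
        void |= np.hypot(x - cx, y - cy) <= ch_r

    values = np.repeat((solid & ~void).astype(np.uint8)[:, :, None], nz, axis=2)

    if spec.manifold and spec.channel_count > 0:
        z = (np.arange(nz) + 0.5) * pitch - 0.5 * spec.height
        ring = (r[:, :, None] - spec.orbit_radius) ** 2 + z[None, None, :] ** 2 <= ch_r**2
        values[ring & (values > 0)] = 0
    return VoxelVolume(values, pitch)


def depth_map(geometry: VialGeometry, volume: VoxelVolume) -> np.ndarray:
    """Per-voxel effective penetration depth ``d(r) = R - r`` in mm.

    Returns a 2D (x, y) map (the depth is invariant along the rotation
    axis); positions outside the vial cross-section are NaN.
    """
    r = geometry.radial_distance(volume)
    d = geometry.radius - r
    d[r > geometry.radius] = np.nan
    return d


def voxelize_mesh(mesh, pitch: float) -> VoxelVolume:
    """Voxelize a watertight triangle mesh to binary occupancy.

    Occupancy is decided by a point-in-solid test at voxel centers,
    implemented as ray-crossing parity along vertical columns.  ``mesh`` may
    be a path to an STL file (binary or ASCII) or a ``trimesh.Trimesh``.
    """
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.load(str(mesh), force="mesh")
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError("mesh is empty")
    if not mesh.is_watertight:
        raise ValueError(
            "mesh is not watertight (open boundary edges present); "
            "repair it before voxelization"
        )

    lo, hi = mesh.bounds
    n = np.maximum(np.ceil((hi - lo) / pitch).astype(int), 1)
    nx, ny, nz = int(n[0]), int(n[1]), int(n[2])
    # tiny in-plane jitter keeps column rays off shared triangle edges
    eps = 1e-6 * pitch
    xs = lo[0] + (np.arange(nx) + 0.5) * pitch + eps
    ys = lo[1] + (np.arange(ny) + 0.5) * pitch + 2 * eps
    zs = lo[2] + (np.arange(nz) + 0.5) * pitch

    # rasterize z-crossings of every triangle over the (x, y) columns it
    # covers (barycentric inside test, vertical rays)
    tri = mesh.triangles  # (n_f, 3, 3)
    cols: list[np.ndarray] = []
    z_hits: list[np.ndarray] = []
    for (p1, p2, p3) in tri:
        det = (p2[1] - p3[1]) * (p1[0] - p3[0]) + (p3[0] - p2[0]) * (p1[1] - p3[1])
        if abs(det) < 1e-14:
            continue  # triangle vertical in z: never crossed transversally
        x0 = min(p1[0], p2[0], p3[0])
        x1 = max(p1[0], p2[0], p3[0])
        y0 = min(p1[1], p2[1], p3[1])
        y1 = max(p1[1], p2[1], p3[1])
        ix = np.nonzero((xs >= x0) & (xs <= x1))[0]
        iy = np.nonzero((ys >= y0) & (ys <= y1))[0]
        if not len(ix) or not len(iy):
            continue
        px = xs[ix][:, None]
        py = ys[iy][None, :]
        a = ((p2[1] - p3[1]) * (px - p3[0]) + (p3[0] - p2[0]) * (py - p3[1])) / det
        b = ((p3[1] - p1[1]) * (px - p3[0]) + (p1[0] - p3[0]) * (py - p3[1])) / det
        c = 1.0 - a - b
        inside = (a >= 0) & (b >= 0) & (c >= 0)
        if not inside.any():
            continue
        z = a * p1[2] + b * p2[2] + c * p3[2]
        gi, gj = np.nonzero(inside)
        cols.append(ix[gi] * ny + iy[gj])
        z_hits.append(z[inside])

    values = np.zeros((nx, ny, nz), dtype=np.uint8)
    if cols:
        col = np.concatenate(cols)
        zh = np.concatenate(z_hits)
        order = np.lexsort((zh, col))
        col, zh = col[order], zh[order]
        for c0, start in zip(*np.unique(col, return_index=True)):
            stop = start + np.count_nonzero(col[start:] == c0)
            z_col = zh[start:stop]
            # merge duplicates from adjacent coplanar triangles
            z_col = z_col[np.concatenate(([True], np.diff(z_col) > 1e-9))]
            if len(z_col) % 2:
                continue  # tangential graze; leave the column empty
            fill = np.zeros(nz, dtype=bool)
            for z0, z1 in z_col.reshape(-1, 2):
                fill |= (zs >= z0) & (zs <= z1)
            values[c0 // ny, c0 % ny, :] = fill
    return VoxelVolume(values, pitch, origin=tuple(lo))


def cog_arc_width(
    volume: VoxelVolume,
    radius: float,
    axis_xy: tuple[float, float] | None = None,
    oversample: int = 8,
) -> float:
    """Mean arc width (mm) of solid runs along the circle of given radius.

    Samples the mid-height slice at nearest voxels around the circle and
    averages the arc length of contiguous occupied runs — used to read back
    the cog width of a voxelized gear.
    """
    if axis_xy is None:
        axis_xy = volume.center_xy()
    iz = volume.shape[2] // 2
    sl = volume.values[:, :, iz]
    # angular step giving an arc step of pitch / oversample
    dphi = volume.pitch / (oversample * radius)
    nphi = int(np.ceil(2 * np.pi / dphi))
    phi = np.arange(nphi) * (2 * np.pi / nphi)
    px = axis_xy[0] + radius * np.cos(phi)
    py = axis_xy[1] + radius * np.sin(phi)
    ix = np.clip(((px - volume.origin[0]) / volume.pitch - 0.5).round().astype(int), 0, sl.shape[0] - 1)
    iy = np.clip(((py - volume.origin[1]) / volume.pitch - 0.5).round().astype(int), 0, sl.shape[1] - 1)
    occ = sl[ix, iy] > 0
    if occ.all() or not occ.any():
        raise ValueError("circle does not cross any cog boundary")
    # rotate so the sequence starts at a 0, close it circularly, and read
    # off the contiguous occupied runs
    first_zero = int(np.argmin(occ))
    occ = np.roll(occ, -first_zero)
    closed = np.concatenate([occ, occ[:1]]).astype(np.int8)
    d = np.diff(closed)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    run_lengths = stops - starts
    arc_step = radius * 2 * np.pi / nphi
    return float(run_lengths.mean() * arc_step)
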