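"""Phantom generators, depth conventions, and mesh voxelization."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from scatvam import (
    GearSpec,
    VesselPhantomSpec,
    VialGeometry,
    cog_arc_width,
    depth_map,
    make_gear,
    make_vascular_phantom,
    voxelize_mesh,
)


class TestGear:
    def test_binary_and_deterministic(self, small_gear):
        assert small_gear.is_binary()
        again = make_gear(GearSpec(height=0.88), pitch=0.11)
        assert np.array_equal(small_gear.values, again.values)

    def test_coarse_pitch_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            make_gear(GearSpec(), pitch=0.2)  # > 0.46/4

    def test_rotational_symmetry(self):
        # equal cog counts give an exactly N-fold symmetric gear
        spec = GearSpec(outer_cog_count=12, inner_cog_count=12, height=0.2)
        vol = make_gear(spec, pitch=0.05)
        sl = vol.values[:, :, 0].astype(float)
        rot = ndimage.rotate(sl, 360 / 12, reshape=False, order=0)
        overlap = np.count_nonzero((sl > 0) & (rot > 0)) / np.count_nonzero(
            (sl > 0) | (rot > 0)
        )
        assert overlap > 0.97

    def test_halving_pitch_scales_voxel_count_by_8(self):
        spec = GearSpec(height=0.8)
        coarse = make_gear(spec, pitch=0.08)
        fine = make_gear(spec, pitch=0.04)
        ratio = np.count_nonzero(fine.values) / np.count_nonzero(coarse.values)
        assert ratio == pytest.approx(8.0, rel=0.02)

    def test_inner_cog_arc_width_matches_spec(self):
        """Voxelized inner cogs read back at their specified 460 um width."""
        spec = GearSpec(height=0.1)
        vol = make_gear(spec, pitch=0.02)
        width = cog_arc_width(vol, spec.inner_mid_radius)
        assert width == pytest.approx(0.46, abs=2 * vol.pitch)

    def test_cogs_protrude_both_ways(self, small_gear):
        spec = GearSpec()
        n = small_gear.shape[0]
        c = (n - 1) / 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r = np.hypot(ii - c, jj - c) * small_gear.pitch
        sl = small_gear.values[:, :, 0] > 0
        rim_band = (r > spec.outer_radius - spec.outer_cog_depth) & (
            r <= spec.outer_radius - 0.1
        )
        bore_band = (r >= spec.bore_radius - spec.inner_cog_depth + 0.1) & (
            r < spec.bore_radius
        )
        # cog bands are partially filled: some matter (cogs), some void (gaps)
        for band in (rim_band, bore_band):
            frac = sl[band].mean()
            assert 0.05 < frac < 0.95


class TestVascularPhantom:
    def test_core_diameter_in_voxels(self):
        """The 4-mm solid core spans 80 fully-solid voxels at 50 um pitch,
        and the millimetric channels cut 20-voxel voids."""
        spec = VesselPhantomSpec(height=0.2)
        vol = make_vascular_phantom(spec, pitch=0.05)
        n = vol.shape[0]
        c = (n - 1) / 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r = np.hypot(ii - c, jj - c) * vol.pitch
        core = r <= 0.5 * spec.core_diameter - vol.pitch
        assert (vol.values[:, :, 0][core] == 1).all()
        assert int(np.ceil(spec.core_diameter / vol.pitch)) == 80
        # a row through two opposite channel centers shows 1-mm voids
        row = vol.values[:, :, 0][int(round(c))]
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], row, [0])))))
        assert np.count_nonzero(np.abs(runs - 20) <= 1) == 2

    def test_four_open_channels(self):
        spec = VesselPhantomSpec(height=0.4)
        vol = make_vascular_phantom(spec, pitch=0.1)
        void = vol.values == 0
        labels, n = ndimage.label(void)
        exterior = labels[0, 0, 0]
        open_channels = 0
        for lab in range(1, n + 1):
            if lab == exterior:
                continue
            mask = labels == lab
            if mask[:, :, 0].any() and mask[:, :, -1].any():
                open_channels += 1
        assert open_channels == 4

    def test_zero_channels_gives_solid_cylinder(self):
        spec = VesselPhantomSpec(channel_count=0, height=1.0)
        vol = make_vascular_phantom(spec, pitch=0.05)
        expected = np.pi * (0.5 * spec.outer_diameter) ** 2 * spec.height
        measured = np.count_nonzero(vol.values) * vol.pitch**3
        assert measured == pytest.approx(expected, rel=0.02)

    def test_overlapping_channels_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            VesselPhantomSpec(core_diameter=6.0, orbit_radius=3.0)


class TestDepthMap:
    @pytest.mark.parametrize(
        "diameter, r, expected",
        [(16.0, 0.0, 8.0), (16.0, 8.0, 0.0), (13.0, 3.25, 3.25)],
    )
    def test_linear_radial_depth(self, diameter, r, expected, small_gear):
        geom = VialGeometry(diameter)
        d = depth_map(geom, small_gear)
        cx, cy = small_gear.center_xy()
        # pick the voxel closest to radius r along the +x direction
        x, y = small_gear.xy_centers()
        ix = np.argmin(np.abs(x - (cx + r)))
        iy = np.argmin(np.abs(y - cy))
        actual_r = np.hypot(x[ix] - cx, y[iy] - cy)
        assert d[ix, iy] == pytest.approx(diameter / 2 - actual_r, abs=1e-9)
        assert expected == pytest.approx(diameter / 2 - r)

    def test_masked_outside_and_bounded(self, small_gear):
        geom = VialGeometry(10.0)
        d = depth_map(geom, small_gear)
        inside = ~np.isnan(d)
        assert np.nanmax(d) <= geom.radius + 1e-9
        assert np.nanmin(d) >= 0.0
        r = geom.radial_distance(small_gear)
        assert np.isnan(d[r > geom.radius]).all()


class TestVoxelizeMesh:
    def test_unit_cube(self):
        mesh = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        vol = voxelize_mesh(mesh, pitch=0.1)
        assert vol.shape == (10, 10, 10)
        assert np.count_nonzero(vol.values) == 1000

    def test_sphere_volume_matches_mesh_volume(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        vol = voxelize_mesh(mesh, pitch=0.04)
        measured = np.count_nonzero(vol.values) * vol.pitch**3
        assert measured == pytest.approx(mesh.volume, rel=0.01)

    def test_non_watertight_rejected(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]]
        )
        with pytest.raises(ValueError, match="watertight"):
            voxelize_mesh(mesh, pitch=0.1)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            voxelize_mesh(trimesh.Trimesh(), pitch=0.1)
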