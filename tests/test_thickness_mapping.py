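import numpy as np
import pytest

import choroidmap as cm
from choroidmap.segmentation import SurfaceMap
from choroidmap.thickness_mapping import (
    FoveaNotFoundError,
    ThicknessMap,
    classify_sector,
    locate_fovea,
    ring_profile,
    sector_summary,
    thickness_normal,
)
from choroidmap.volume_io import SECTOR_ORDER

AX_UM = 10.0 / 1.38  # geometric µm per axial pixel at the default spacing


def surface(z, name="RPE_outer", valid=None):
    z = np.asarray(z, dtype=float)
    valid = np.ones_like(z, dtype=bool) if valid is None else valid
    return SurfaceMap(boundary_name=name, z=z, valid=valid)


def make_map(ct, dx=0.05, dy=0.05, laterality="OD", fovea=(0.0, 0.0)):
    return ThicknessMap(ct=np.asarray(ct, dtype=float), lateral_spacing_x_mm=dx,
                        lateral_spacing_y_mm=dy, laterality=laterality,
                        fovea_xy_mm=fovea)


def radial_grid(n=81, dx=0.125):
    half = (n - 1) / 2
    x = (np.arange(n) - half) * dx
    return np.meshgrid(x, x, indexing="ij")


class TestLocateFovea:
    def _ilm_with_pit(self, center_mm=(0.0, 0.0), n=(128, 64), d=(0.04, 0.08)):
        x = (np.arange(n[0]) - (n[0] - 1) / 2) * d[0]
        y = (np.arange(n[1]) - (n[1] - 1) / 2) * d[1]
        xx, yy = np.meshgrid(x, y, indexing="ij")
        rho2 = (xx - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
        depth_px = 80 + 18.0 * np.exp(-rho2 / (2 * 0.4**2))
        return surface(depth_px, "ILM"), d

    def test_centered_pit_found(self):
        ilm, d = self._ilm_with_pit()
        x, y = locate_fovea(ilm, d[0], d[1], AX_UM)
        assert abs(x) <= d[0] and abs(y) <= d[1]

    def test_offset_pit_found(self):
        ilm, d = self._ilm_with_pit(center_mm=(0.8, -0.4))
        x, y = locate_fovea(ilm, d[0], d[1], AX_UM)
        assert abs(x - 0.8) <= d[0]
        assert abs(y + 0.4) <= d[1]

    def test_flat_ilm_raises(self):
        flat = surface(np.full((64, 32), 80.0), "ILM")
        with pytest.raises(FoveaNotFoundError, match="pit"):
            locate_fovea(flat, 0.04, 0.08, AX_UM)


class TestThicknessNormal:
    def test_flat_parallel_planes(self):
        n = 40
        sep_px = 250.0 / AX_UM
        rpe = surface(np.full((n, n), 100.0))
        csi = surface(np.full((n, n), 100.0 + sep_px), "CSI")
        tmap = thickness_normal(rpe, csi, 0.05, 0.05, AX_UM, "OD")
        inner = tmap.ct[5:-5, 5:-5]
        np.testing.assert_allclose(inner, 250.0, atol=0.5)

    def test_tilted_parallel_planes_cosine_rule(self):
        """Planes tilted 30° from horizontal with vertical separation v
        have normal separation v·cos30°."""
        theta = np.deg2rad(30.0)
        dx_mm = 0.02
        n = 120
        slope_px_per_col = np.tan(theta) * dx_mm * 1000.0 / AX_UM
        base = 40.0 + slope_px_per_col * np.arange(n)
        v_um = 300.0
        rpe = surface(np.tile(base[:, None], (1, 30)))
        csi = surface(np.tile((base + v_um / AX_UM)[:, None], (1, 30)), "CSI")
        tmap = thickness_normal(rpe, csi, dx_mm, 1.0, AX_UM, "OD",
                                rpe_smooth_sigma_mm=0.0001)
        inner = tmap.ct[20:-20, 5:-5]
        expected = v_um * np.cos(theta)
        assert np.nanmax(np.abs(inner - expected)) < 1.0

    def test_curved_geometry_matches_dense_ray_oracle(self):
        """Normal thickness on a curved surface pair agrees with a dense
        (0.01-px step) ray march oracle."""
        n = 60
        dx = 0.05
        x = (np.arange(n) - n / 2) * dx
        xx, yy = np.meshgrid(x, x, indexing="ij")
        rpe_um = 700.0 - 8.0 * (xx**2 + yy**2)
        csi_um = rpe_um + 220.0 + 15.0 * xx
        rpe = surface(rpe_um / AX_UM)
        csi = surface(csi_um / AX_UM, "CSI")
        tmap = thickness_normal(rpe, csi, dx, dx, AX_UM, "OD",
                                rpe_smooth_sigma_mm=0.0001)

        # oracle at a handful of interior pixels
        from scipy.interpolate import RegularGridInterpolator
        xi = np.arange(n) * dx * 1000.0
        itp = RegularGridInterpolator((xi, xi), csi_um)
        gx, gy = np.gradient(rpe_um, dx * 1000.0, dx * 1000.0)
        for i, j in [(20, 20), (30, 30), (25, 35), (35, 22)]:
            norm = np.sqrt(gx[i, j] ** 2 + gy[i, j] ** 2 + 1)
            nvec = np.array([-gx[i, j], -gy[i, j], 1.0]) / norm
            t_grid = np.arange(0.0, 400.0, 0.01 * AX_UM)
            pts = np.column_stack([xi[i] + t_grid * nvec[0],
                                   xi[j] + t_grid * nvec[1]])
            f = rpe_um[i, j] + t_grid * nvec[2] - itp(pts)
            k = np.argmax(f >= 0)
            oracle = t_grid[k]
            assert tmap.ct[i, j] == pytest.approx(oracle, abs=1.0)

    def test_no_crossing_marks_invalid(self):
        rpe = surface(np.full((10, 10), 50.0))
        csi = surface(np.full((10, 10), 50.0 + 2000.0 / AX_UM), "CSI")
        tmap = thickness_normal(rpe, csi, 0.05, 0.05, AX_UM, "OD",
                                max_distance_um=1000.0)
        assert not tmap.valid.any()


class TestSectorSummary:
    def test_constant_map_all_sectors_equal(self):
        xx, yy = radial_grid()
        tmap = make_map(np.full_like(xx, 321.0), dx=0.125, dy=0.125)
        means = sector_summary(tmap).mean_um
        for s in SECTOR_ORDER:
            assert means[s] == pytest.approx(321.0, abs=1e-9)

    def test_radially_symmetric_map_equal_inner_sectors(self):
        xx, yy = radial_grid()
        r = np.hypot(xx, yy)
        tmap = make_map(200.0 + 30.0 * r, dx=0.125, dy=0.125)
        m = sector_summary(tmap).mean_um
        assert m["NIM"] == pytest.approx(m["TIM"], abs=1.0)
        assert m["SIM"] == pytest.approx(m["IIM"], abs=1.0)
        assert m["NIM"] == pytest.approx(m["SIM"], abs=1.0)

    def test_linear_gradient_matches_pixel_oracle(self):
        """Sector means equal an independent per-pixel classification."""
        xx, yy = radial_grid()
        ct = 150.0 + 20.0 * xx + 7.0 * yy
        tmap = make_map(ct, dx=0.125, dy=0.125)
        means = sector_summary(tmap).mean_um

        sums = {s: [] for s in SECTOR_ORDER}
        for i in range(xx.shape[0]):
            for j in range(xx.shape[1]):
                u, v = xx[i, j], yy[i, j]  # OD: x already temporal-positive
                r = np.hypot(u, v)
                if r < 0.5:
                    s = "Fovea"
                elif r < 5.0:
                    ring = "IM" if r < 2.5 else "OM"
                    if abs(u) >= abs(v):
                        s = ("T" if u >= 0 else "N") + ring
                    else:
                        s = ("S" if v >= 0 else "I") + ring
                else:
                    continue
                sums[s].append(ct[i, j])
        for s in SECTOR_ORDER:
            assert means[s] == pytest.approx(np.mean(sums[s]), abs=1e-9), s

    def test_partition_and_area_weighted_mean(self):
        """Every pixel inside the 10-mm disk is in exactly one sector and
        the whole-disk mean is the count-weighted mean of sector means."""
        xx, yy = radial_grid(n=101, dx=0.1)
        rng = np.random.default_rng(0)
        ct = 150.0 + 50.0 * rng.random(xx.shape)
        labels = classify_sector(xx, yy)
        r = np.hypot(xx, yy)
        assert np.all((labels != "") == (r < 5.0))
        tmap = make_map(ct, dx=0.1, dy=0.1)
        summ = sector_summary(tmap)
        counts = {s: int((labels == s).sum()) for s in SECTOR_ORDER}
        weighted = sum(summ.mean_um[s] * counts[s] for s in SECTOR_ORDER)
        total = sum(counts.values())
        disk_mean = ct[r < 5.0].mean()
        assert weighted / total == pytest.approx(disk_mean, rel=1e-9)

    def test_od_os_mirror_invariance(self):
        """Mirroring the horizontal axis and flipping laterality leaves
        every named sector (and the ring profile) unchanged."""
        xx, yy = radial_grid()
        rng = np.random.default_rng(3)
        ct = 150.0 + 80.0 * rng.random(xx.shape) + 20.0 * xx
        od = make_map(ct, dx=0.125, dy=0.125, laterality="OD")
        os_ = make_map(ct[::-1, :].copy(), dx=0.125, dy=0.125, laterality="OS")
        m_od = sector_summary(od).mean_um
        m_os = sector_summary(os_).mean_um
        for s in SECTOR_ORDER:
            assert m_od[s] == pytest.approx(m_os[s], abs=1e-9), s
        p_od = ring_profile(od)
        p_os = ring_profile(os_)
        np.testing.assert_allclose(p_od.mean_um, p_os.mean_um, atol=1e-9)

    def test_fovea_outside_grid_errors(self):
        tmap = make_map(np.full((20, 20), 100.0), fovea=(9.0, 0.0))
        with pytest.raises(ValueError, match="outside"):
            sector_summary(tmap)

    def test_sparse_sector_flagged_missing(self):
        xx, yy = radial_grid()
        ct = np.full_like(xx, 200.0)
        ct[xx > 0.6] = np.nan  # wipe most of the temporal side
        tmap = make_map(ct, dx=0.125, dy=0.125)
        summ = sector_summary(tmap)
        assert np.isnan(summ.mean_um["TOM"])
        assert summ.valid_fraction["TOM"] < 0.25


class TestRingProfile:
    def test_constant_map_all_bins_equal(self):
        xx, yy = radial_grid()
        tmap = make_map(np.full_like(xx, 250.0), dx=0.125, dy=0.125)
        prof = ring_profile(tmap)
        assert len(prof.offsets_mm) == 11
        np.testing.assert_allclose(prof.mean_um, 250.0, atol=1e-9)

    def test_empty_bin_flagged_missing(self):
        # 4-mm-wide grid: no pixels at 5 mm
        x = (np.arange(33) - 16) * 0.125
        xx, yy = np.meshgrid(x, x, indexing="ij")
        tmap = make_map(np.full_like(xx, 250.0), dx=0.125, dy=0.125)
        prof = ring_profile(tmap)
        assert np.isnan(prof.mean_um[0]) and prof.counts[0] == 0
        assert np.isnan(prof.mean_um[-1]) and prof.counts[-1] == 0
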