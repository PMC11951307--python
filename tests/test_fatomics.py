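"""Fat-omics geometry and features: partitions, probabilities, invariances."""

import numpy as np
import pytest

from ctcsfat.core import CTVolume, RegionMask
from ctcsfat.fatomics import (
    DEFAULT_N_RIBBONS,
    EmptyEATError,
    assign_slabs_ribbons,
    default_bin_edges,
    extract_features,
    fat_thickness,
    feature_names,
)
from ctcsfat.phantom import PhantomSpec, generate_phantom

SPACING = (3.0, 0.5, 0.5)


def box_masks(shape=(8, 20, 20), peri=((0, 8), (2, 18), (2, 18)), eat_border=2):
    """Rectangular pericardium with an EAT band of given voxel thickness."""
    peri_m = np.zeros(shape, bool)
    peri_m[peri[0][0]:peri[0][1], peri[1][0]:peri[1][1], peri[2][0]:peri[2][1]] = True
    inner = np.zeros(shape, bool)
    inner[
        peri[0][0]:peri[0][1],
        peri[1][0] + eat_border : peri[1][1] - eat_border,
        peri[2][0] + eat_border : peri[2][1] - eat_border,
    ] = True
    eat_m = peri_m & ~inner
    return RegionMask(eat_m, "eat"), RegionMask(peri_m, "pericardium")


class TestAssignSlabsRibbons:
    def test_slabs_partition_eat_into_equal_slice_bands(self):
        eat, peri = box_masks(shape=(8, 20, 20))
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        assert set(np.unique(geo.slab[eat.mask])) == {1, 2, 3, 4}
        for k in (1, 2, 3, 4):
            slices = np.unique(np.nonzero(geo.slab == k)[0])
            assert len(slices) == 2  # 8 occupied slices -> 2 per slab
        assert (geo.slab > 0).sum() == eat.count()

    def test_every_eat_voxel_gets_exactly_one_ribbon(self):
        eat, peri = box_masks()
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        assert np.array_equal(geo.ribbon > 0, eat.mask)
        assert geo.ribbon.max() <= DEFAULT_N_RIBBONS

    def test_outer_ribbon_of_spherical_shell_is_largest(self):
        # uniform spherical shell: band volume ~ r^2, so the outermost
        # distance band holds the most voxels and the innermost the fewest
        from ctcsfat.phantom import PhantomSpec, generate_phantom

        ph = generate_phantom(
            PhantomSpec(
                grid_shape=(48, 48, 48), voxel_spacing=(1.0, 1.0, 1.0),
                pericardium_semiaxes_mm=(20.0, 20.0, 20.0),
                shell_thickness_mm=5.0, seed=5,
            )
        )
        geo = assign_slabs_ribbons(ph.eat, ph.pericardium, ph.volume.spacing)
        counts = [(geo.ribbon == k).sum() for k in range(1, geo.n_ribbons + 1)]
        assert counts[0] == max(counts)
        assert counts[0] > counts[-1]

    def test_empty_eat_raises(self):
        _, peri = box_masks()
        empty = RegionMask(np.zeros(peri.shape, bool), "eat")
        with pytest.raises(EmptyEATError):
            assign_slabs_ribbons(empty, peri, SPACING)

    def test_eat_outside_pericardium_rejected(self):
        eat, peri = box_masks()
        leaky = eat.mask.copy()
        leaky[0, 0, 0] = True
        with pytest.raises(ValueError, match="contained"):
            assign_slabs_ribbons(RegionMask(leaky, "eat"), peri, SPACING)


class TestExtractFeatures:
    def _volume_for(self, eat, hu_value=-100.0):
        hu = np.full(eat.shape, 40.0)
        hu[eat.mask] = hu_value
        return CTVolume(hu=hu, spacing=SPACING)

    def test_point_mass_bin_probability_is_one(self):
        eat, peri = box_masks()
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        vol = self._volume_for(eat, hu_value=-80.0)  # in [-90, -70)
        vec = extract_features(vol, geo)
        for k in range(1, geo.n_ribbons + 1):
            if (geo.ribbon == k).any():
                assert vec[f"SR{k}_Pro_90_70"] == 1.0
                assert vec[f"SR{k}_Pro_170_150"] == 0.0

    def test_known_fraction_in_bin(self):
        eat, peri = box_masks()
        geo = assign_slabs_ribbons(eat, peri, SPACING, n_ribbons=1)
        hu = np.full(eat.shape, 40.0)
        idx = np.argwhere(eat.mask)
        hu[tuple(idx.T)] = -80.0
        quarter = idx[: len(idx) // 4]
        hu[tuple(quarter.T)] = -140.0  # in [-150, -130)
        vec = extract_features(CTVolume(hu=hu, spacing=SPACING), geo)
        assert vec["SR1_Pro_150_130"] == pytest.approx(len(quarter) / len(idx))

    def test_probabilities_sum_to_one_per_nonempty_partition(self, shell_phantom):
        geo = assign_slabs_ribbons(
            shell_phantom.eat, shell_phantom.pericardium, shell_phantom.volume.spacing
        )
        vec = extract_features(shell_phantom.volume, geo)
        edges = default_bin_edges()
        bins = [f"Pro_{abs(int(a))}_{abs(int(b))}" for a, b in zip(edges[:-1], edges[1:])]
        for k in range(1, geo.n_ribbons + 1):
            if (geo.ribbon == k).any():
                assert sum(vec[f"SR{k}_{b}"] for b in bins) == pytest.approx(1.0)
        for k in range(1, 5):
            if (geo.slab == k).any():
                assert sum(vec[f"SL{k}_{b}"] for b in bins) == pytest.approx(1.0)

    def test_volume_is_count_times_voxel_volume(self):
        eat, peri = box_masks()
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        vec = extract_features(self._volume_for(eat), geo)
        assert vec["volume_mm3"] == pytest.approx(eat.count() * 3.0 * 0.5 * 0.5)

    def test_symmetric_hu_distribution_has_zero_skewness(self):
        eat, peri = box_masks()
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        hu = np.full(eat.shape, 40.0)
        idx = np.argwhere(eat.mask)
        half = len(idx) // 2
        hu[tuple(idx[:half].T)] = -120.0
        hu[tuple(idx[half : 2 * half].T)] = -80.0
        hu[tuple(idx[2 * half :].T)] = -100.0
        vec = extract_features(CTVolume(hu=hu, spacing=SPACING), geo)
        assert vec["hu_skewness"] == pytest.approx(0.0, abs=0.05)

    def test_single_ribbon_spatial_equals_global_histogram(self, shell_phantom):
        geo = assign_slabs_ribbons(
            shell_phantom.eat, shell_phantom.pericardium,
            shell_phantom.volume.spacing, n_ribbons=1,
        )
        vec = extract_features(shell_phantom.volume, geo)
        edges = default_bin_edges()
        for a, b in zip(edges[:-1], edges[1:]):
            name = f"Pro_{abs(int(a))}_{abs(int(b))}"
            assert vec[f"SR1_{name}"] == pytest.approx(vec[name])

    def test_translation_invariance(self):
        eat, peri = box_masks(shape=(8, 24, 24))
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        rng = np.random.default_rng(8)
        hu = np.full(eat.shape, 40.0)
        hu[eat.mask] = rng.uniform(-180.0, -40.0, eat.count())
        vec = extract_features(CTVolume(hu=hu, spacing=SPACING), geo)

        shift = (0, 3, 2)
        hu_t = np.roll(hu, shift, axis=(0, 1, 2))
        eat_t = RegionMask(np.roll(eat.mask, shift, axis=(0, 1, 2)), "eat")
        peri_t = RegionMask(np.roll(peri.mask, shift, axis=(0, 1, 2)), "pericardium")
        geo_t = assign_slabs_ribbons(eat_t, peri_t, SPACING)
        vec_t = extract_features(CTVolume(hu=hu_t, spacing=SPACING), geo_t)
        for name, value in vec.values.items():
            assert vec_t[name] == pytest.approx(value, abs=1e-9), name

    def test_empty_ribbon_probabilities_are_zero_with_warning(self):
        # one-voxel EAT: inner ribbons of a 5-band partition are empty
        shape = (3, 10, 10)
        peri_m = np.zeros(shape, bool)
        peri_m[1, 2:8, 2:8] = True
        eat_m = np.zeros(shape, bool)
        eat_m[1, 2, 2] = True
        geo = assign_slabs_ribbons(RegionMask(eat_m, "eat"), RegionMask(peri_m, "p"), SPACING)
        hu = np.full(shape, -80.0)
        with pytest.warns(RuntimeWarning, match="empty partition"):
            vec = extract_features(CTVolume(hu=hu, spacing=SPACING), geo)
        assert vec["SL2_Pro_90_70"] == 0.0

    def test_schema_is_stable(self):
        names = feature_names()
        assert names == feature_names()
        assert len(names) == len(set(names))
        # three families present
        assert "volume_mm3" in names and "hu_skewness" in names
        assert "SR4_Pro_90_70" in names and "SL1_Pro_170_150" in names
        eat, peri = box_masks()
        geo = assign_slabs_ribbons(eat, peri, SPACING)
        vec = extract_features(self._volume_for(eat), geo)
        assert list(vec.values) == names


class TestFatThickness:
    def test_uniform_shell_thickness_recovered(self):
        # spherical EAT shell of 5 mm thickness at 0.5 mm in-plane spacing
        shape = (10, 64, 64)
        spacing = (3.0, 0.5, 0.5)
        zz, yy, xx = np.meshgrid(
            np.arange(shape[0]) * spacing[0],
            np.arange(shape[1]) * spacing[1],
            np.arange(shape[2]) * spacing[2],
            indexing="ij",
        )
        c = np.array(shape) * np.array(spacing) / 2
        r_inplane = np.sqrt((yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        mid = shape[0] // 2
        peri_m = (r_inplane <= 14.0) & (np.abs(zz - c[0]) < 1.5 * spacing[0])
        eat_m = peri_m & (r_inplane > 9.0)
        geo = assign_slabs_ribbons(RegionMask(eat_m, "eat"), RegionMask(peri_m, "p"), spacing)
        mean_t, max_t = fat_thickness(geo)
        assert mean_t == pytest.approx(5.0, abs=0.5)
        assert max_t == pytest.approx(5.0, abs=1.0)

    def test_single_voxel_thickness_is_in_plane_extent(self):
        shape = (3, 10, 10)
        m = np.zeros(shape, bool)
        m[1, 5, 5] = True
        geo = assign_slabs_ribbons(RegionMask(m, "eat"), RegionMask(m, "p"), SPACING)
        mean_t, max_t = fat_thickness(geo)
        assert mean_t == pytest.approx(0.5)
        assert max_t == pytest.approx(0.5)

    def test_doubling_spacing_doubles_thickness(self):
        eat, peri = box_masks()
        geo1 = assign_slabs_ribbons(eat, peri, SPACING)
        geo2 = assign_slabs_ribbons(eat, peri, (6.0, 1.0, 1.0))
        m1, x1 = fat_thickness(geo1)
        m2, x2 = fat_thickness(geo2)
        assert m2 == pytest.approx(2 * m1, rel=0.05)
        assert x2 == pytest.approx(2 * x1, rel=0.05)
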