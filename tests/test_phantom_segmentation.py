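import numpy as np
import pytest

from bonenet.core import FrameSchedule
from bonenet.kinetics import DEFAULT_INPUT_FUNCTION, KineticParams, apply_physical_decay, simulate_tissue_tac
from bonenet.phantom import PhantomSpec, Region, rasterize_phantom
from bonenet.segmentation import (
    HUWindow,
    extract_hu,
    extract_tacs,
    restrict_labels,
    threshold_mask,
)
from bonenet.synthetic import bin_to_frames

SHORT_SCHEDULE = FrameSchedule.from_counts([(4, 150), (2, 300)])  # 20 min, 6 frames


def three_region_phantom() -> PhantomSpec:
    """Regions straddling the bone HU window: 100 (soft), 400 (bone), 60000 (metal-like)."""
    kin = KineticParams(K1=0.3, k2=0.3, k3=0.05)
    return PhantomSpec(
        shape=(16, 16, 16),
        regions={
            "soft": Region(kind="box", lo=(1, 1, 1), hi=(4, 4, 4)),
            "bone": Region(kind="box", lo=(6, 6, 6), hi=(9, 9, 9)),
            "metal": Region(kind="sphere", center=(12.0, 12.0, 12.0), radius=2.0),
        },
        hu={"soft": 100.0, "bone": 400.0, "metal": 60000.0},
        kinetics={"soft": kin, "bone": kin, "metal": kin},
        background_hu=0.0,
    )


class TestThresholdMask:
    def test_all_zero_volume_gives_empty_mask(self):
        assert not threshold_mask(np.zeros((4, 4, 4)), HUWindow(332, 50000)).any()

    def test_boundary_value_is_retained(self):
        # closed interval: HU exactly 332 (and exactly 50000) is bone
        vol = np.full((3, 3, 3), 332.0)
        assert threshold_mask(vol, HUWindow(332, 50000)).all()
        vol[:] = 50000.0
        assert threshold_mask(vol, HUWindow(332, 50000)).all()

    def test_window_straddling_phantom_keeps_only_the_bone_region(self):
        spec = three_region_phantom()
        ct, _, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        mask = threshold_mask(ct, HUWindow(332, 50000))
        lab = np.asarray(labels.dataobj)
        assert set(np.unique(lab[mask])) == {2}  # only the 400-HU region survives
        assert mask.sum() == 27

    def test_windowing_is_idempotent(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 1000, size=(8, 8, 8))
        window = HUWindow(332, 50000)
        mask = threshold_mask(vol, window)
        masked = np.where(mask, vol, 0.0)
        np.testing.assert_array_equal(threshold_mask(masked, window), mask)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            HUWindow(500, 500)


class TestRestrictLabels:
    def test_identity_mask_keeps_raw_label_counts(self):
        spec = three_region_phantom()
        _, _, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        lab = np.asarray(labels.dataobj)
        vois = restrict_labels(lab, np.ones_like(lab, dtype=bool), {"soft": 1, "bone": 2, "metal": 3})
        counts = vois.voxel_counts
        assert counts["soft"] == 27 and counts["bone"] == 27
        assert counts["metal"] == int((lab == 3).sum())

    def test_all_false_mask_flags_every_bone_empty(self):
        lab = np.ones((4, 4, 4), dtype=int)
        with pytest.warns(UserWarning, match="no voxels"):
            vois = restrict_labels(lab, np.zeros_like(lab, dtype=bool), {"bone": 1})
        assert vois.empty_bones == ["bone"]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            restrict_labels(np.ones((4, 4, 4), int), np.ones((5, 5, 5), bool), {"bone": 1})

    def test_counts_partition_retained_voxels(self):
        spec = three_region_phantom()
        ct, _, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        mask = threshold_mask(ct, HUWindow(0.0, 1e6))
        vois = restrict_labels(labels, mask, {"soft": 1, "bone": 2, "metal": 3})
        lab = np.asarray(labels.dataobj)
        assert sum(vois.voxel_counts.values()) == int(((lab > 0) & mask).sum())


class TestExtraction:
    def test_uniform_region_tac_equals_simulated_curve(self):
        spec = three_region_phantom()
        ct, pet, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        mask = threshold_mask(ct, HUWindow(332, 50000))
        vois = restrict_labels(labels, mask, {"bone": 2})
        tac = extract_tacs(pet, SHORT_SCHEDULE, vois)

        t = np.arange(0.0, 20.2, 0.05)
        curve = simulate_tissue_tac(DEFAULT_INPUT_FUNCTION, spec.kinetics["bone"], t)
        curve = apply_physical_decay(curve, t, direction="decay")
        expected = bin_to_frames(curve, t, SHORT_SCHEDULE)
        np.testing.assert_allclose(tac.values.loc["bone"].to_numpy(), expected, atol=1e-9)

    def test_merged_regions_average_their_curves(self):
        # two disjoint equal-size regions with curves f and g merged into
        # one VOI read out as (f+g)/2
        kin_f = KineticParams(K1=0.4, k2=0.3, k3=0.08)
        kin_g = KineticParams(K1=0.1, k2=0.5, k3=0.02)
        spec = PhantomSpec(
            shape=(12, 12, 12),
            regions={
                "f": Region(kind="box", lo=(1, 1, 1), hi=(3, 3, 3)),
                "g": Region(kind="box", lo=(6, 6, 6), hi=(8, 8, 8)),
            },
            hu={"f": 400.0, "g": 400.0},
            kinetics={"f": kin_f, "g": kin_g},
        )
        _, pet, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        lab = np.asarray(labels.dataobj)
        merged = np.where(lab > 0, 1, 0)
        vois = restrict_labels(merged, np.ones_like(merged, bool), {"merged": 1})
        tac = extract_tacs(pet, SHORT_SCHEDULE, vois)

        separate = restrict_labels(lab, np.ones_like(lab, bool), {"f": 1, "g": 2})
        sep = extract_tacs(pet, SHORT_SCHEDULE, separate)
        expected = 0.5 * (sep.values.loc["f"] + sep.values.loc["g"])
        np.testing.assert_allclose(tac.values.loc["merged"], expected, atol=1e-12)

    def test_extraction_commutes_with_positive_scaling(self):
        spec = three_region_phantom()
        ct, pet, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        vois = restrict_labels(labels, threshold_mask(ct, HUWindow(0, 1e6)), {"bone": 2})
        base = extract_tacs(pet, SHORT_SCHEDULE, vois).values.to_numpy()
        scaled = extract_tacs(np.asarray(pet.dataobj) * 3.5, SHORT_SCHEDULE, vois).values.to_numpy()
        np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-12)

    def test_empty_voi_yields_missing_values_not_zeros(self):
        spec = three_region_phantom()
        ct, pet, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        mask = threshold_mask(ct, HUWindow(332, 50000))
        with pytest.warns(UserWarning):
            vois = restrict_labels(labels, mask, {"soft": 1, "bone": 2})
        with pytest.warns(UserWarning, match="empty"):
            tac = extract_tacs(pet, SHORT_SCHEDULE, vois)
        assert tac.values.loc["soft"].isna().all()
        assert tac.values.loc["bone"].notna().all()

    def test_phantom_hu_readout_is_exact(self):
        spec = three_region_phantom()
        ct, _, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        vois = restrict_labels(labels, np.ones(spec.shape, bool), {"soft": 1, "bone": 2, "metal": 3})
        hu = extract_hu(ct, vois)
        assert hu["soft"] == 100.0 and hu["bone"] == 400.0 and hu["metal"] == 60000.0

    def test_mixed_region_hu_is_the_mean(self):
        ct = np.full((4, 4, 4), 400.0)
        ct[:2] = 600.0
        vois = restrict_labels(np.ones_like(ct, int), np.ones_like(ct, bool), {"bone": 1})
        assert extract_hu(ct, vois)["bone"] == pytest.approx(500.0)


class TestPhantomValidation:
    def test_overlapping_regions_rejected(self):
        kin = KineticParams(K1=0.3, k2=0.3, k3=0.05)
        spec = PhantomSpec(
            shape=(8, 8, 8),
            regions={
                "a": Region(kind="box", lo=(1, 1, 1), hi=(4, 4, 4)),
                "b": Region(kind="box", lo=(3, 3, 3), hi=(6, 6, 6)),
            },
            hu={"a": 400.0, "b": 500.0},
            kinetics={"a": kin, "b": kin},
        )
        with pytest.raises(ValueError, match="overlap"):
            rasterize_phantom(spec, SHORT_SCHEDULE)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Region(kind="box", lo=(0, 0, 0), hi=(10, 10, 10)).mask((8, 8, 8))

    def test_shared_affine_across_outputs(self):
        spec = three_region_phantom()
        ct, pet, labels = rasterize_phantom(spec, SHORT_SCHEDULE)
        np.testing.assert_array_equal(ct.affine, pet.affine)
        np.testing.assert_array_equal(ct.affine, labels.affine)
        assert pet.shape == spec.shape + (len(SHORT_SCHEDULE),)
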