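import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from fetalbiom import (
    BiometryConfig,
    MissingStructureError,
    PhantomSpec,
    SegmentationVolume,
    generate_phantom,
    locate_atrial_slice,
    measure_ad,
    measure_all,
    measure_cbpd,
    measure_tcd,
)


def strip_label(volume, label):
    labels = volume.labels.copy()
    labels[labels == label] = 0
    return SegmentationVolume(labels, volume.spacing_mm, volume.schema)


class TestCBPD:
    def test_recovers_phantom_equatorial_width(self, small_phantom):
        vol, truth = small_phantom
        m = measure_cbpd(vol)
        assert m.value_mm == pytest.approx(truth.cbpd_mm, abs=2 * vol.spacing_mm[1])
        # the chosen slice is near-equatorial: its cerebrum area is close to max
        cer = (vol.labels == vol.schema.cerebrum).sum(axis=(1, 2))
        assert cer[m.slice_index] >= 0.9 * cer.max()

    def test_invariant_to_in_plane_rotation(self, small_spec, small_phantom):
        vol, truth = small_phantom
        rotated, _ = generate_phantom(replace(small_spec, in_plane_rotation_deg=20.0))
        m = measure_cbpd(rotated)
        assert m.value_mm == pytest.approx(truth.cbpd_mm, abs=2 * vol.spacing_mm[1])

    def test_missing_cerebrum_raises(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(MissingStructureError, match="cerebrum"):
            measure_cbpd(strip_label(vol, vol.schema.cerebrum))

    def test_full_fraction_never_smaller_than_half(self, small_phantom):
        vol, _ = small_phantom
        half = measure_cbpd(vol, BiometryConfig(cbpd_superior_fraction=0.5))
        full = measure_cbpd(vol, BiometryConfig(cbpd_superior_fraction=1.0))
        assert full.value_mm >= half.value_mm - 1e-9

    def test_monotone_under_mask_dilation(self, small_phantom):
        vol, _ = small_phantom
        prev = measure_cbpd(vol).value_mm
        labels = vol.labels.copy()
        for _ in range(2):
            grown = ndimage.binary_dilation(labels == vol.schema.cerebrum)
            labels = labels.copy()
            labels[grown & (labels == 0)] = vol.schema.cerebrum
            value = measure_cbpd(
                SegmentationVolume(labels, vol.spacing_mm, vol.schema)
            ).value_mm
            assert value >= prev - 1e-9
            prev = value


class TestTCD:
    def test_recovers_phantom_transverse_diameter(self, small_phantom):
        vol, truth = small_phantom
        m = measure_tcd(vol)
        assert m.value_mm == pytest.approx(truth.tcd_mm, abs=2 * vol.spacing_mm[1])

    def test_single_slice_cerebellum_is_measured_there(self, schema):
        labels = np.zeros((5, 40, 40), np.int16)
        rr, cc = np.mgrid[0:40, 0:40]
        labels[0, ((rr - 20) / 14.0) ** 2 + ((cc - 20) / 8.0) ** 2 <= 1] = schema.cerebrum
        labels[3, ((rr - 20) / 10.0) ** 2 + ((cc - 20) / 6.0) ** 2 <= 1] = schema.cerebellum
        vol = SegmentationVolume(labels, (3, 1, 1), schema)
        m = measure_tcd(vol)
        assert m.slice_index == 3
        assert m.value_mm == pytest.approx(13.0, abs=2.0)  # 2 × 6 mm + edges

    def test_missing_cerebellum_raises(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(MissingStructureError, match="cerebellum"):
            measure_tcd(strip_label(vol, vol.schema.cerebellum))


class TestAtrialSlice:
    def test_matches_analytic_truth(self, small_phantom):
        vol, truth = small_phantom
        assert locate_atrial_slice(vol) == truth.atrial_slice

    def test_area_tie_picks_smaller_index(self, schema):
        labels = np.zeros((6, 20, 20), np.int16)
        labels[2, 5:8, 5:8] = schema.left_ventricle
        labels[4, 5:8, 5:8] = schema.left_ventricle  # identical area
        labels[0, 0:15, 0:15] = schema.cerebrum
        vol = SegmentationVolume(labels, (3, 1, 1), schema)
        assert locate_atrial_slice(vol) == 2

    def test_without_ventricles_raises(self, small_phantom):
        vol, _ = small_phantom
        bare = strip_label(
            strip_label(vol, vol.schema.left_ventricle), vol.schema.right_ventricle
        )
        with pytest.raises(MissingStructureError):
            locate_atrial_slice(bare)

    def test_template_strategy_requires_template(self, small_phantom):
        vol, _ = small_phantom
        cfg = BiometryConfig(atrial_locator="template_correlation")
        with pytest.raises(ValueError, match="template"):
            locate_atrial_slice(vol, cfg)

    def test_template_of_atrial_slice_relocates_it(self, small_phantom):
        from fetalbiom import extract_slice, BinaryMask

        vol, truth = small_phantom
        lv, rv = vol.schema.left_ventricle, vol.schema.right_ventricle
        combined = (vol.labels[truth.atrial_slice] == lv) | (
            vol.labels[truth.atrial_slice] == rv
        )
        cfg = BiometryConfig(
            atrial_locator="template_correlation",
            template=BinaryMask(combined, vol.in_plane_spacing_mm),
        )
        assert locate_atrial_slice(vol, cfg) == truth.atrial_slice


class TestAD:
    def test_recovers_short_diameter_of_tilted_ventricle(self, small_phantom):
        vol, truth = small_phantom
        sp = vol.spacing_mm[1]
        assert measure_ad(vol, "left").value_mm == pytest.approx(truth.lad_mm, abs=2 * sp)
        assert measure_ad(vol, "right").value_mm == pytest.approx(truth.rad_mm, abs=2 * sp)

    def test_circular_ventricle_reads_diameter(self, schema):
        labels = np.zeros((3, 60, 60), np.int16)
        rr, cc = np.mgrid[0:60, 0:60]
        labels[1, (rr - 30) ** 2 + (cc - 30) ** 2 <= 8**2] = schema.left_ventricle
        labels[1, (rr - 30) ** 2 + (cc - 45) ** 2 <= 3**2] = schema.right_ventricle
        labels[0, 10:50, 10:50] = schema.cerebrum
        vol = SegmentationVolume(labels, (3, 1, 1), schema)
        m = measure_ad(vol, "left")
        assert m.value_mm == pytest.approx(16.0, abs=2.0)

    def test_side_absent_on_atrial_slice_raises(self, schema):
        labels = np.zeros((3, 20, 20), np.int16)
        labels[1, 5:10, 5:12] = schema.left_ventricle
        vol = SegmentationVolume(labels, (3, 1, 1), schema)
        with pytest.raises(MissingStructureError, match="right_ventricle"):
            measure_ad(vol, "right")

    def test_invalid_side_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            measure_ad(small_phantom[0], "up")


class TestMeasureAll:
    def test_complete_phantom_within_tolerance(self, small_phantom):
        vol, truth = small_phantom
        sp = vol.spacing_mm[1]
        values = measure_all(vol).values_mm()
        for name, true_value in truth.as_dict().items():
            assert values[name] == pytest.approx(
                true_value, abs=max(2 * sp, 0.015 * true_value)
            ), name

    def test_deterministic(self, small_phantom):
        vol, _ = small_phantom
        a, b = measure_all(vol), measure_all(vol)
        assert a.values_mm() == b.values_mm()
        for name in ("cbpd", "tcd", "lad", "rad"):
            np.testing.assert_array_equal(
                a.as_dict()[name].endpoints_mm, b.as_dict()[name].endpoints_mm
            )

    def test_reports_all_missing_structures_at_once(self, small_phantom):
        vol, _ = small_phantom
        bare = strip_label(
            strip_label(vol, vol.schema.left_ventricle), vol.schema.right_ventricle
        )
        with pytest.raises(MissingStructureError) as exc:
            measure_all(bare)
        assert set(exc.value.structures) == {"left_ventricle", "right_ventricle"}

    def test_values_scale_exactly_with_in_plane_spacing(self, small_phantom):
        vol, _ = small_phantom
        base = measure_all(vol).values_mm()
        s = 1.7
        scaled_vol = SegmentationVolume(
            vol.labels,
            (vol.spacing_mm[0], s * vol.spacing_mm[1], s * vol.spacing_mm[2]),
            vol.schema,
        )
        scaled = measure_all(scaled_vol).values_mm()
        for name in base:
            assert scaled[name] == pytest.approx(s * base[name], rel=1e-12)
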