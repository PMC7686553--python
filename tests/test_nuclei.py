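"""Projection, detection, dual-threshold classing and layer accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

from gliaquant.core import CortexLayout, ImageStack, default_mpfc_layout
from gliaquant.imgsim import SimParams, generate_cortex_stack
from gliaquant.nuclei import (
    DetectedNucleus,
    ThresholdPair,
    assign_layers,
    classify_activation,
    detect_nuclei,
    layer_counts,
    longitudinal_profile,
    project_stack,
)


class TestProjection:
    def test_single_slice_is_identity(self, rng):
        data = rng.random((1, 1, 8, 8))
        stack = ImageStack(data, (1.0, 0.5, 0.5))
        for mode in ("max", "sum"):
            flat = project_stack(stack, mode)
            assert np.array_equal(flat.data[0], data[0, 0])

    def test_constant_slices(self):
        data = np.stack([np.full((4, 4), 3.0), np.full((4, 4), 5.0)])[None]
        stack = ImageStack(data, (1.0, 0.5, 0.5))
        assert np.all(project_stack(stack, "max").data == 5.0)
        assert np.all(project_stack(stack, "sum").data == 8.0)

    def test_max_never_exceeds_sum_for_nonnegative(self, rng):
        data = rng.random((2, 5, 16, 16))
        stack = ImageStack(data, (1.0, 0.5, 0.5))
        assert np.all(
            project_stack(stack, "max").data <= project_stack(stack, "sum").data + 1e-12
        )

    def test_2d_input_rejected(self):
        stack = ImageStack(np.zeros((1, 4, 4)), (0.5, 0.5))
        with pytest.raises(ValueError, match="2D"):
            project_stack(stack)


class TestDetection:
    def _disc_image(self, area_um2=300.0, px=0.5, value=500.0):
        img = np.zeros((200, 200))
        r_px = np.sqrt(area_um2 / np.pi) / px
        rr, cc = disk((100, 100), r_px, shape=img.shape)
        img[rr, cc] = value
        return img, rr.size * px * px

    def test_single_disc_detected_with_rendered_area(self):
        img, rendered = self._disc_image()
        found = detect_nuclei(img, 0.5, min_area_um2=200.0)
        assert len(found) == 1
        assert found[0].area_um2 == pytest.approx(rendered, abs=2 * 0.25)
        assert found[0].mean_gray == pytest.approx(500.0)

    def test_area_floor_excludes(self):
        img, _ = self._disc_image()
        assert detect_nuclei(img, 0.5, min_area_um2=400.0) == []

    def test_flat_image_yields_empty_list(self):
        assert detect_nuclei(np.zeros((32, 32)), 0.5) == []

    def test_disjoint_nuclei_counted_exactly(self, small_layout):
        params = SimParams(seed=11, noise_sd=0.0,
                           nucleus_count={"negative": 0, "cfos_plus": 5,
                                          "cfos_plusplus": 5})
        stack, truth = generate_cortex_stack(params, small_layout, nz=1)
        found = detect_nuclei(stack.channel("cfos"), stack.pixel_size_um)
        assert len(found) == 10


class TestClassification:
    @pytest.mark.parametrize(
        "area,gray,expected",
        [
            (250.0, 450.0, "cfos_plusplus"),
            (250.0, 350.0, "cfos_plus"),
            (150.0, 450.0, "cfos_plus"),
            (200.0, 450.0, "cfos_plus"),  # boundary falls to cfos_plus
            (250.0, 400.0, "cfos_plus"),
        ],
    )
    def test_dual_threshold_cases(self, area, gray, expected):
        nuc = DetectedNucleus(centroid_um=(0, 0), area_um2=area, mean_gray=gray)
        out = classify_activation([nuc], ThresholdPair(200.0, 400.0))
        assert out[0].activation_class == expected

    @settings(max_examples=50, deadline=None)
    @given(
        min_area=st.floats(50, 500),
        min_int=st.floats(100, 1200),
        bump_a=st.floats(0, 200),
        bump_i=st.floats(0, 400),
    )
    def test_raising_thresholds_never_adds_strong_nuclei(
        self, min_area, min_int, bump_a, bump_i
    ):
        rng = np.random.default_rng(42)
        nuclei = [
            DetectedNucleus((0, 0), a, g)
            for a, g in zip(rng.uniform(20, 600, 40), rng.uniform(50, 1500, 40))
        ]

        def strong(pair):
            return sum(
                1
                for n in classify_activation(nuclei, pair)
                if n.activation_class == "cfos_plusplus"
            )

        low = strong(ThresholdPair(min_area, min_int))
        high = strong(ThresholdPair(min_area + bump_a, min_int + bump_i))
        assert high <= low


class TestLayers:
    def test_half_open_boundary(self):
        layout = CortexLayout(
            layer_widths=[("I", 130.0), ("II/III", 80.0)],
            field_size_um=(300.0, 100.0, 10.0),
        )
        at_boundary = DetectedNucleus((130.0, 10.0), 100.0, 100.0)
        at_zero = DetectedNucleus((0.0, 10.0), 100.0, 100.0)
        past_end = DetectedNucleus((250.0, 10.0), 100.0, 100.0)
        out = assign_layers([at_boundary, at_zero, past_end], layout)
        assert out[0].layer == "II/III"
        assert out[1].layer == "I"
        assert out[2].layer == "beyond_II/III"

    def test_per_layer_counts_match_ground_truth(self):
        layout = default_mpfc_layout(field_y_um=300.0)
        params = SimParams(seed=21, noise_sd=0.0)
        stack, truth = generate_cortex_stack(params, layout, nz=1)
        found = detect_nuclei(stack.channel("cfos"), stack.pixel_size_um)
        found = assign_layers(found, layout)
        table = layer_counts(found, layout)
        want = {}
        for t in truth.nuclei:
            if t.activation_class != "negative":
                want[t.layer] = want.get(t.layer, 0) + 1
        for _, row in table.iterrows():
            assert row["count"] == want.get(row["layer"], 0)
        assert table["count"].sum() == len(found)

    def test_empty_and_single_layer_tables(self):
        layout = CortexLayout(
            layer_widths=[("II/III", 80.0), ("V", 120.0)],
            field_size_um=(200.0, 100.0, 10.0),
        )
        assert (layer_counts([], layout)["count"] == 0).all()
        ten = [DetectedNucleus((100.0, 50.0), 50.0, 50.0) for _ in range(10)]
        table = layer_counts(assign_layers(ten, layout), layout)
        by_layer = dict(zip(table["layer"], table["count"]))
        assert by_layer == {"II/III": 0, "V": 10}
        density = table.loc[table["layer"] == "V", "density_per_mm2"].iloc[0]
        assert density == pytest.approx(10 / (120.0 * 100.0 / 1e6))


class TestLongitudinalProfile:
    def test_constant_image(self):
        prof = longitudinal_profile(np.full((10, 20), 7.0), 0.5)
        assert np.all(prof.mean_intensity == 7.0)
        assert np.all(np.diff(prof.distance_um) > 0)

    def test_bright_band_peak_located(self):
        img = np.zeros((20, 600))
        img[:, 400:440] = 100.0  # 200-220 um at 0.5 um/px
        prof = longitudinal_profile(img, 0.5)
        peak = prof.distance_um[np.argmax(prof.mean_intensity)]
        assert 200.0 <= peak <= 220.0

    def test_profile_is_linear_in_the_image(self, rng):
        a, b = rng.random((10, 30)), rng.random((10, 30))
        pa = longitudinal_profile(a, 1.0).mean_intensity
        pb = longitudinal_profile(b, 1.0).mean_intensity
        pab = longitudinal_profile(a + b, 1.0).mean_intensity
        assert np.allclose(pab, pa + pb)

    def test_layout_wider_than_image_rejected(self):
        layout = CortexLayout(
            layer_widths=[("V", 500.0)], field_size_um=(500.0, 100.0, 10.0)
        )
        with pytest.raises(ValueError, match="wider"):
            longitudinal_profile(np.zeros((10, 100)), 0.5, layout)

    def test_layer_grouped_means(self):
        layout = CortexLayout(
            layer_widths=[("I", 10.0), ("V", 10.0)],
            field_size_um=(20.0, 10.0, 10.0),
        )
        img = np.zeros((4, 20))
        img[:, 10:] = 6.0  # layer V half at 1 um pitch
        prof = longitudinal_profile(img, 1.0, layout)
        assert prof.layer_means["I"] == pytest.approx(0.0)
        assert prof.layer_means["V"] == pytest.approx(6.0)
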