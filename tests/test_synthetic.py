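import numpy as np
import pytest

from chewsim.imaging import channel_variance
from chewsim.synthetic import (
    ADULT_MIX,
    CHILD_MIX,
    MixSpec,
    PanelSpec,
    generate_bolus_image,
    generate_force_curve,
    generate_invitro_image_set,
    generate_invivo_image_set,
    generate_panel,
    generate_triangle_session,
    invitro_hardness_mean,
)
from chewsim.texture import extract_hardness
from chewsim.transposition import build_grid


class TestPanelGeneration:
    def test_zero_spread_panel_equals_generating_means(self):
        spec = PanelSpec(
            "child", size=4, replicate_cv=0.0,
            params={name: (mu, 0.0) for name, (mu, _) in
                    PanelSpec("child").params.items()},
        )
        records = generate_panel(spec, seed=0)
        assert all(r.mouth_volume == pytest.approx(38.24) for r in records)
        assert all(r.mastication_time == pytest.approx(6.92) for r in records)
        assert all(r.n_compressions == 9 for r in records)  # round(8.62)

    def test_bit_reproducible_under_seed(self):
        a = generate_panel(PanelSpec("adult", size=10), seed=42)
        b = generate_panel(PanelSpec("adult", size=10), seed=42)
        assert [r.mouth_volume for r in a] == [r.mouth_volume for r in b]
        assert [r.meta for r in a] == [r.meta for r in b]

    def test_all_parameters_positive_and_counts_floored(self):
        spec = PanelSpec("child", size=50,
                         params={"saliva_volume": (0.05, 0.2)})
        records = generate_panel(spec, seed=3)
        assert all(r.saliva_volume_measured > 0 for r in records)
        assert all(r.n_compressions >= 1 for r in records)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            PanelSpec("child", size=0)


class TestBolusImageGeneration:
    def test_unmixed_image_has_closed_form_two_phase_variance(self, small_mix):
        """At zero compressions and zero noise the red-channel variance is
        exactly f(1-f)(r1-r0)^2 for the realised colored fraction f."""
        img = generate_bolus_image(small_mix, 0, 0, seed=0)
        f = img.meta["colored_fraction"]
        r1 = small_mix.colored_rgb[0]
        r0 = small_mix.base_rgb[0]
        measured = channel_variance(img, "red").variance
        assert measured == pytest.approx(f * (1 - f) * (r1 - r0) ** 2,
                                         abs=1e-15)
        assert f == pytest.approx(small_mix.colored_fraction, abs=0.01)

    @pytest.mark.parametrize("rpm", [4, 15])
    def test_variance_nonincreasing_in_compressions(self, rpm):
        """Mean variance over 20 seeds decreases along the compression grid."""
        spec = MixSpec(shape=(96, 96))
        means = []
        for n in (1, 2, 6, 8, 10, 14, 18):
            vals = [
                channel_variance(
                    generate_bolus_image(spec, n, rpm, seed=s), "red"
                ).variance
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_higher_rotation_speed_mixes_more(self, small_mix):
        for n in (2, 8, 18):
            v4 = channel_variance(
                generate_bolus_image(small_mix, n, 4, seed=1), "red"
            ).variance
            v15 = channel_variance(
                generate_bolus_image(small_mix, n, 15, seed=1), "red"
            ).variance
            assert v15 < v4

    def test_vanishing_colored_fraction_approaches_noise_floor(self):
        spec = MixSpec(shape=(96, 96), colored_fraction=0.005, noise_sd=0.01)
        img = generate_bolus_image(spec, 0, 0, seed=0)
        v = channel_variance(img, "red").variance
        f = img.meta["colored_fraction"]
        phase = f * (1 - f) * (spec.colored_rgb[0] - spec.base_rgb[0]) ** 2
        # essentially the two-phase term plus the noise floor, far below the
        # default-fraction variance (~0.03)
        assert v == pytest.approx(phase + spec.noise_sd**2, rel=0.3)
        assert v < 1e-3

    def test_invalid_phase_color_rejected(self):
        with pytest.raises(ValueError):
            MixSpec(colored_rgb=(1.5, 0.0, 0.0))
        with pytest.raises(ValueError):
            MixSpec(colored_fraction=0.0)


class TestImageSets:
    def test_full_panel_yields_360_invivo_and_28_invitro_images(self):
        spec_small = MixSpec(shape=(48, 48))
        panel = (
            generate_panel(PanelSpec("child", size=30), seed=0)
            + generate_panel(PanelSpec("adult", size=30), seed=1)
        )
        images = generate_invivo_image_set(
            panel, spec_small, spec_small, seed=2, replicates=2
        )
        assert len(images) == 360  # 60 subjects x 3 stages x 2 replicates
        vitro = generate_invitro_image_set(
            build_grid(), spec_small, seed=3, replicates=2
        )
        assert len(vitro) == 28  # 14 settings x 2 replicates

    def test_single_subject_yields_six_images(self):
        panel = generate_panel(PanelSpec("child", size=1), seed=0)
        spec = MixSpec(shape=(48, 48))
        images = generate_invivo_image_set(panel, spec, spec, seed=0)
        assert len(images) == 6
        assert {img.origin.stage for img in images} == {33, 66, 99}

    def test_replicates_differ_only_by_noise(self):
        panel = generate_panel(PanelSpec("child", size=1), seed=0)
        spec = MixSpec(shape=(48, 48), noise_sd=0.01)
        images = generate_invivo_image_set(panel, spec, spec, seed=0,
                                           stages=(33,), replicates=2)
        a, b = images
        assert a.origin == b.origin
        diff = a.pixels - b.pixels
        assert np.abs(diff).max() < 0.1  # noise-scale differences only
        assert not np.array_equal(a.pixels, b.pixels)

    def test_child_boli_less_homogeneous_than_adult_at_every_stage(self):
        panel = (
            generate_panel(PanelSpec("child", size=8), seed=10)
            + generate_panel(PanelSpec("adult", size=8), seed=11)
        )
        images = generate_invivo_image_set(panel, seed=12, replicates=1)
        acc: dict = {}
        for img in images:
            key = (img.origin.group, img.origin.stage)
            acc.setdefault(key, []).append(
                channel_variance(img, "red").variance
            )
        for stage in (33, 66, 99):
            assert np.mean(acc[("child", stage)]) > np.mean(
                acc[("adult", stage)]
            )
        for group in ("child", "adult"):
            assert (np.mean(acc[(group, 33)]) > np.mean(acc[(group, 66)])
                    > np.mean(acc[(group, 99)]))


class TestForceCurveGeneration:
    def test_zero_noise_is_exactly_invertible(self):
        for h in (0.0, 0.66, 50.83, 112.24):
            curve = generate_force_curve(h, "back_extrusion", 0.0, seed=0)
            assert extract_hardness(curve) == h

    def test_mean_extraction_unbiased_over_seeds(self):
        """CLT bound: mean of 100 extractions within 0.15 N of the target."""
        extracted = [
            extract_hardness(
                generate_force_curve(50.83, "back_extrusion", 0.5, seed=s)
            )
            for s in range(100)
        ]
        assert abs(np.mean(extracted) - 50.83) < 0.15

    def test_penetration_and_back_extrusion_share_endpoint_contract(self):
        for mode in ("penetration", "back_extrusion"):
            curve = generate_force_curve(7.7, mode, 0.0, seed=0)
            assert extract_hardness(curve) == pytest.approx(7.7)

    def test_negative_hardness_rejected(self):
        with pytest.raises(ValueError):
            generate_force_curve(-1.0)

    def test_invitro_hardness_model_orderings(self):
        for rpm in (4, 15):
            h = [invitro_hardness_mean(n, rpm) for n in (1, 2, 6, 8, 10, 14, 18)]
            assert all(a > b for a, b in zip(h, h[1:]))
        for n in (1, 6, 18):
            assert invitro_hardness_mean(n, 15) < invitro_hardness_mean(n, 4)


class TestTriangleSessionGeneration:
    def test_perfect_discriminators_all_correct(self):
        assert generate_triangle_session(30, 1.0, seed=0) == 30

    def test_empty_panel(self):
        assert generate_triangle_session(0, 0.5, seed=0) == 0

    def test_pure_guessing_mean_near_one_third(self):
        counts = [generate_triangle_session(30, 0.0, seed=s)
                  for s in range(1000)]
        se = np.sqrt(30 * (1 / 3) * (2 / 3)) / np.sqrt(1000)
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            generate_triangle_session(10, 1.5)
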