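"""Generators: panel structure, saturating colour responses, renders, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinotaste.chemicals import CHEMICALS
from vinotaste.synthetic import (
    ChemProfile,
    default_dye_model,
    generate_panel,
    render_image_pair,
    simulate_color_response,
    simulate_spectrum,
    well_layout,
    WAVELENGTHS_NM,
)
from vinotaste.taste import score_panel


def zero_profile(**overrides) -> ChemProfile:
    conc = {c: 0.0 for c in CHEMICALS}
    conc.update(overrides)
    return ChemProfile("t", conc, "dry")


class TestGeneratePanel:
    def test_panel_size_and_base_mixture_split(self):
        panel = generate_panel(23, 22, seed=1)
        assert len(panel) == 45
        assert sum(p.sample_id.startswith("base") for p in panel) == 23
        assert sum(p.sample_id.startswith("mix") for p in panel) == 22

    def test_sweet_fraction_roughly_30pct(self):
        panel = generate_panel(23, 0, seed=4)
        assert sum(p.cluster == "sweet" for p in panel) == 7

    def test_seeded_determinism(self):
        a = generate_panel(2, 0, seed=7)
        b = generate_panel(2, 0, seed=7)
        for pa, pb in zip(a, b):
            assert pa.concentrations == pb.concentrations
            assert pa.cluster == pb.cluster

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_panel(1, 0, seed=0)
        with pytest.raises(ValueError):
            generate_panel(5, -1, seed=0)

    def test_mixture_convexity(self):
        panel = generate_panel(10, 15, seed=3)
        base = {p.sample_id: p for p in panel if p.sample_id.startswith("base")}
        mixes = [p for p in panel if p.sample_id.startswith("mix")]
        assert mixes
        lo = {c: min(p.concentrations[c] for p in base.values()) for c in CHEMICALS}
        hi = {c: max(p.concentrations[c] for p in base.values()) for c in CHEMICALS}
        for m in mixes:
            for c in CHEMICALS:
                assert lo[c] - 1e-9 <= m.concentrations[c] <= hi[c] + 1e-9

    def test_profiles_validate_invariants(self):
        with pytest.raises(ValueError):
            ChemProfile("bad", {c: -1.0 for c in CHEMICALS}, "dry")
        with pytest.raises(ValueError):
            ChemProfile("bad", {"sucrose": 1.0}, "dry")

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_determinism_property(self, seed):
        a = generate_panel(4, 2, seed)
        b = generate_panel(4, 2, seed)
        assert all(
            pa.concentrations == pb.concentrations for pa, pb in zip(a, b)
        )


class TestColorResponse:
    def test_zero_profile_gives_zero_matrix(self, dye_model):
        delta = simulate_color_response(zero_profile(), dye_model, noise_sd=0.0)
        assert np.allclose(delta, 0.0)

    def test_saturation_limit(self, dye_model):
        idx = CHEMICALS.index("fructose")
        prof = zero_profile(fructose=1e15)
        delta = simulate_color_response(prof, dye_model, noise_sd=0.0)
        assert np.allclose(delta, dye_model.sensitivity[:, :, idx], atol=1e-6)

    def test_half_saturation_gives_half_sensitivity(self, tiny_dye_model):
        # fructose at its half-saturation constant -> exactly half the
        # full-saturation colour change (Langmuir term = 1/2)
        prof = zero_profile(fructose=1000.0)
        delta = simulate_color_response(prof, tiny_dye_model, noise_sd=0.0)
        assert np.allclose(delta[0], [20.0, -10.0, 5.0])

    def test_unknown_chemical_named_in_error(self, dye_model):
        conc = {c: 0.0 for c in CHEMICALS}
        conc["caffeine"] = 5.0
        prof = ChemProfile.__new__(ChemProfile)
        prof.sample_id, prof.concentrations, prof.cluster = "x", conc, "dry"
        with pytest.raises(ValueError, match="caffeine"):
            simulate_color_response(prof, dye_model)

    def test_noise_is_seeded(self, dye_model, panel45):
        a = simulate_color_response(panel45[0], dye_model, noise_sd=2.0, seed=5)
        b = simulate_color_response(panel45[0], dye_model, noise_sd=2.0, seed=5)
        assert np.array_equal(a, b)


class TestRenderImagePair:
    def test_zero_deltas_noiseless_identical_rasters(self, dye_model):
        pair = render_image_pair(np.zeros((8, 3)), dye_model, pixel_noise_sd=0.0)
        assert np.array_equal(pair.before, pair.after)

    def test_noiseless_well_means_exact(self, dye_model, rng):
        deltas = rng.uniform(-20, 20, (8, 3))
        pair = render_image_pair(deltas, dye_model, pixel_noise_sd=0.0)
        yy, xx = np.mgrid[0 : pair.before.shape[0], 0 : pair.before.shape[1]]
        for i, (cy, cx) in enumerate(pair.centers):
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= pair.radius**2
            np.testing.assert_allclose(
                pair.after[mask].mean(axis=0) - pair.before[mask].mean(axis=0),
                deltas[i],
                atol=1e-10,
            )

    def test_noisy_well_mean_within_3_standard_errors(self, dye_model, rng):
        # radius 24 -> ~1800 px per well, sd 2 -> s.e. < 0.05 per channel
        layout = well_layout(radius=24.0, pitch=64.0, margin=40.0)
        deltas = rng.uniform(-10, 10, (8, 3))
        pair = render_image_pair(
            deltas, dye_model, pixel_noise_sd=2.0, seed=11, layout=layout
        )
        yy, xx = np.mgrid[0 : pair.before.shape[0], 0 : pair.before.shape[1]]
        for i, (cy, cx) in enumerate(pair.centers):
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= pair.radius**2
            diff = pair.after[mask].mean(axis=0) - pair.before[mask].mean(axis=0)
            assert np.all(np.abs(diff - deltas[i]) < 0.2)

    def test_out_of_range_delta_records_clip_warning(self, dye_model):
        deltas = np.zeros((8, 3))
        deltas[0, 0] = 500.0  # pushes well 0 red channel far beyond 255
        pair = render_image_pair(deltas, dye_model, pixel_noise_sd=0.0)
        assert pair.clip_warnings and "well 0" in pair.clip_warnings[0]
        assert np.array_equal(pair.truth_delta, deltas)  # truth is pre-clip


class TestSimulateSpectrum:
    def test_zero_concentration_is_baseline(self, tiny_dye_model):
        spec = simulate_spectrum("alizarin", "fructose", 0.0, tiny_dye_model)
        baseline = np.exp(-((WAVELENGTHS_NM - 550.0) ** 2) / (2 * 30.0**2))
        np.testing.assert_allclose(spec, baseline, atol=1e-12)

    def test_single_peak_max_at_center(self, tiny_dye_model):
        spec = simulate_spectrum("alizarin", "fructose", 500.0, tiny_dye_model)
        assert WAVELENGTHS_NM[np.argmax(spec)] == 550

    def test_monotone_in_concentration_for_positive_gain(self, tiny_dye_model):
        s1 = simulate_spectrum("alizarin", "fructose", 100.0, tiny_dye_model)
        s2 = simulate_spectrum("alizarin", "fructose", 5000.0, tiny_dye_model)
        assert np.all(s2 >= s1 - 1e-12)
        assert np.all(s1 >= 0) and np.all(s2 >= 0)

    def test_unknown_dye_errors(self, tiny_dye_model):
        with pytest.raises(ValueError, match="unknown dye"):
            simulate_spectrum("nosuchdye", "fructose", 1.0, tiny_dye_model)


class TestClusterStructure:
    def test_sweet_scores_strictly_above_dry_at_zero_noise(self, panel45):
        scores = score_panel(panel45)
        clusters = np.array([p.cluster for p in panel45])
        for col in ("sweetness", "sourness"):
            sweet = scores.loc[clusters == "sweet", col]
            dry = scores.loc[clusters == "dry", col]
            assert sweet.min() > dry.max()

    def test_mixture_scores_between_parent_scores(self):
        # linearity of the score formulas: a blend's score lies between
        # its parents' scores; verified through the panel's convex hull
        panel = generate_panel(23, 22, seed=2)
        scores = score_panel(panel)
        base_mask = scores["sample_id"].str.startswith("base")
        for col in ("sweetness", "sourness"):
            base_vals = scores.loc[base_mask, col]
            mix_vals = scores.loc[~base_mask, col]
            assert mix_vals.min() >= base_vals.min() - 1e-9
            assert mix_vals.max() <= base_vals.max() + 1e-9


def test_default_dye_model_rows_distinct(dye_model):
    flat = dye_model.sensitivity.reshape(8, -1)
    for i in range(8):
        for j in range(i + 1, 8):
            assert not np.allclose(flat[i], flat[j])


def test_dye_model_yaml_round_trip(tmp_path, dye_model):
    path = tmp_path / "model.yaml"
    dye_model.to_yaml(path)
    back = type(dye_model).from_yaml(path)
    assert np.allclose(back.sensitivity, dye_model.sensitivity)
    assert np.allclose(back.baseline_rgb, dye_model.baseline_rgb)
    assert back.dyes == dye_model.dyes
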