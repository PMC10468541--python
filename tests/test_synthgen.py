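"""Synthetic scene generator: determinism, geometry, degradation physics,
manifest round-trips, and the rater simulator's calibration."""

import numpy as np
import pytest
from scipy import ndimage

from dermaqx.annotations import RaterEvaluation, collapse_verdict
from dermaqx.metrics import confusion_counts, f1
from dermaqx.synthgen import (
    DEFAULT_DEGRADATION_MIX,
    DegradationSpec,
    InvalidSceneError,
    SceneSpec,
    apply_degradation,
    generate_base_image,
    generate_dataset,
    identity_profile,
    regenerate_from_manifest,
    simulate_raters,
    symmetric_profile,
    write_manifest,
)
from dermaqx.taxonomy import EXPLANATION_INDEX, EXPLANATIONS, QUALITY_CLASSES

LESION_SPEC = SceneSpec("lesion", (64, 64), lesion_center=(32.0, 30.0),
                        lesion_radii=(20.0, 12.0))


def laplacian_variance(pixels: np.ndarray) -> float:
    """Reference sharpness statistic: variance of the Laplacian response of
    the luminance channel, via an explicit convolution kernel."""
    gray = pixels.astype(np.float64).mean(axis=2)
    kernel = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)
    return float(ndimage.convolve(gray, kernel, mode="nearest").var())


class TestBaseImage:
    def test_deterministic_given_spec_and_seed(self):
        a, _ = generate_base_image(LESION_SPEC, seed=7)
        b, _ = generate_base_image(LESION_SPEC, seed=7)
        assert np.array_equal(a.pixels, b.pixels)
        c, _ = generate_base_image(LESION_SPEC, seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_healthy_skin_has_empty_mask(self):
        _, truth = generate_base_image(SceneSpec("healthy_skin"), seed=0)
        assert truth.lesion_mask.sum() == 0
        assert truth.quality_class == "healthy_skin"

    def test_lesion_mask_matches_analytic_ellipse_area(self):
        # semi-axes (20, 12) px -> pixel count within 5% of pi*20*12
        _, truth = generate_base_image(LESION_SPEC, seed=3)
        area = truth.lesion_mask.sum()
        assert area == pytest.approx(np.pi * 20 * 12, rel=0.05)

    def test_lesion_darker_than_surrounding_skin(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=5)
        inside = rec.pixels[truth.lesion_mask].mean()
        outside = rec.pixels[~truth.lesion_mask].mean()
        assert inside < outside - 20

    def test_no_skin_differs_from_skin_rendering(self):
        skin, _ = generate_base_image(SceneSpec("healthy_skin", texture_seed=4), seed=1)
        other, truth = generate_base_image(SceneSpec("no_skin", texture_seed=4), seed=1)
        assert truth.quality_class == "no_skin"
        # non-skin texture is cool-toned: blue channel dominates red
        assert other.pixels[:, :, 2].mean() > other.pixels[:, :, 0].mean()
        assert skin.pixels[:, :, 0].mean() > skin.pixels[:, :, 2].mean()

    def test_out_of_frame_lesion_rejected(self):
        bad = SceneSpec("lesion", (64, 64), lesion_center=(5.0, 32.0),
                        lesion_radii=(10.0, 10.0))
        with pytest.raises(InvalidSceneError, match="margin"):
            generate_base_image(bad, seed=0)

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidSceneError, match="32x32"):
            generate_base_image(SceneSpec("healthy_skin", (16, 16)), seed=0)

    def test_geometry_present_iff_lesion(self):
        with pytest.raises(InvalidSceneError):
            SceneSpec("healthy_skin", lesion_center=(32.0, 32.0),
                      lesion_radii=(5.0, 5.0))
        with pytest.raises(InvalidSceneError):
            SceneSpec("lesion")


class TestDegradations:
    @pytest.mark.parametrize("operator", EXPLANATIONS)
    def test_severity_zero_is_identity(self, operator):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        out, out_truth = apply_degradation(
            rec, truth, [DegradationSpec(operator, 0.0)], seed=0)
        assert np.array_equal(out.pixels, rec.pixels)
        assert not out_truth.explanations.any()
        assert out_truth.quality_class == "lesion"

    def test_low_resolution_factor_one_is_identity(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        spec = DegradationSpec("low_resolution", 0.9, {"factor": 1})
        out, _ = apply_degradation(rec, truth, [spec], seed=0)
        assert np.array_equal(out.pixels, rec.pixels)

    def test_blur_reduces_laplacian_variance(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        out, out_truth = apply_degradation(
            rec, truth, [DegradationSpec("blurry", 0.8)], seed=0)
        assert laplacian_variance(out.pixels) < laplacian_variance(rec.pixels)
        assert out_truth.quality_class == "poor_quality"
        assert out_truth.explanations[EXPLANATION_INDEX["blurry"]] == 1

    def test_unknown_operator_and_bad_severity_rejected(self):
        with pytest.raises(InvalidSceneError, match="unknown degradation"):
            DegradationSpec("sepia", 0.5)
        with pytest.raises(InvalidSceneError, match="severity"):
            DegradationSpec("blurry", 1.5)

    def test_empty_spec_list_rejected(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        with pytest.raises(InvalidSceneError, match="non-empty"):
            apply_degradation(rec, truth, [], seed=0)

    def test_below_threshold_severity_sets_no_bit(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        out, out_truth = apply_degradation(
            rec, truth, [DegradationSpec("blurry", 0.2)], seed=0)
        assert not out_truth.explanations.any()
        assert out_truth.quality_class == "lesion"
        # ... but the image itself is already slightly blurred
        assert laplacian_variance(out.pixels) < laplacian_variance(rec.pixels)

    def test_framing_moves_lesion_centroid_and_mask(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        spec = DegradationSpec("bad_framing", 0.9, {"angle": 0.0})
        out, out_truth = apply_degradation(rec, truth, [spec], seed=0)
        c0 = ndimage.center_of_mass(truth.lesion_mask)
        c1 = ndimage.center_of_mass(out_truth.lesion_mask)
        assert c1[1] > c0[1] + 10  # shifted along +x by 0.9*0.45*64 px
        # darker lesion pixels moved with the mask
        assert out.pixels[out_truth.lesion_mask].mean() < out.pixels.mean() - 15

    def test_too_far_away_shrinks_lesion_area(self):
        rec, truth = generate_base_image(LESION_SPEC, seed=2)
        out, out_truth = apply_degradation(
            rec, truth, [DegradationSpec("too_far_away", 1.0)], seed=0)
        assert 0 < out_truth.lesion_mask.sum() < truth.lesion_mask.sum() / 4

    @pytest.mark.parametrize("operator,statistic,direction", [
        ("blurry", laplacian_variance, -1),
        ("bad_light",
         lambda px: abs(px.astype(float).mean() - 128.0), +1),
        ("low_resolution", lambda px: np.nan, 0),  # handled via effective resolution
        ("too_far_away", lambda px: np.nan, 0),   # handled via mask area below
        ("bad_framing", lambda px: np.nan, 0),    # handled via centroid below
    ])
    def test_severity_monotonicity(self, operator, statistic, direction):
        rec, truth = generate_base_image(LESION_SPEC, seed=9)
        severities = [0.0, 0.25, 0.5, 0.75, 1.0]
        values = []
        for s in severities:
            params = {"angle": 0.0} if operator == "bad_framing" else (
                {"direction": 1.0} if operator == "bad_light" else {})
            out, out_truth = apply_degradation(
                rec, truth, [DegradationSpec(operator, s, dict(params))], seed=0)
            if operator == "too_far_away":
                values.append(-out_truth.lesion_mask.sum())
            elif operator == "low_resolution":
                # effective resolution: number of distinct pixel columns
                col_changes = np.any(np.diff(out.pixels.astype(int), axis=1) != 0,
                                     axis=(0, 2)).sum()
                values.append(-(col_changes + 1))
            elif operator == "bad_framing":
                c = ndimage.center_of_mass(out_truth.lesion_mask)
                values.append((c[0] - 32) ** 2 + (c[1] - 30) ** 2)
            else:
                values.append(direction * statistic(out.pixels))
        diffs = np.diff(values)
        assert np.all(diffs >= -1e-9), (operator, values)
        assert values[-1] > values[0], (operator, values)


class TestGenerateDataset:
    def test_counts_and_label_consistency(self, small_dataset):
        classes = [t.quality_class for _, t in small_dataset]
        for c in QUALITY_CLASSES:
            assert classes.count(c) == 10
        for _, t in small_dataset:
            if t.explanations.any():
                assert t.quality_class == "poor_quality"
            if t.quality_class == "poor_quality":
                assert t.explanations.any()

    def test_manifest_regeneration_is_byte_identical(self, small_dataset, tmp_path):
        path = tmp_path / "manifest.jsonl"
        write_manifest(small_dataset, path)
        regen = regenerate_from_manifest(path)
        assert len(regen) == len(small_dataset)
        for (a, ta), (b, tb) in zip(small_dataset, regen):
            assert a.image_id == b.image_id
            assert np.array_equal(a.pixels, b.pixels)
            assert ta.quality_class == tb.quality_class
            assert np.array_equal(ta.explanations, tb.explanations)

    def test_single_operator_mix_forces_that_bit(self):
        recs = generate_dataset({"poor_quality": 12}, {"blurry": 1.0}, seed=4)
        for _, t in recs:
            assert t.explanations[EXPLANATION_INDEX["blurry"]] == 1
            assert t.explanations.sum() == 1

    def test_two_operator_mix_frequencies_match_conditional_expectation(self):
        # Independent inclusion at p=0.5 each, conditioned on >= 1 operator
        # present, gives marginal inclusion p/(1 - (1-p)^2) = 2/3 per operator.
        n = 500
        recs = generate_dataset({"poor_quality": n},
                                {"blurry": 0.5, "bad_light": 0.5}, seed=6)
        expected = 0.5 / (1.0 - 0.25)
        sigma = np.sqrt(expected * (1 - expected) / n)
        for op in ("blurry", "bad_light"):
            freq = np.mean([t.explanations[EXPLANATION_INDEX[op]]
                            for _, t in recs])
            assert abs(freq - expected) < 3 * sigma, (op, freq)

    def test_zero_total_counts_rejected(self):
        with pytest.raises(InvalidSceneError, match="at least one image"):
            generate_dataset({"lesion": 0}, DEFAULT_DEGRADATION_MIX, seed=0)

    def test_same_seed_reproduces_dataset(self):
        a = generate_dataset({"lesion": 3, "poor_quality": 3}, seed=5)
        b = generate_dataset({"lesion": 3, "poor_quality": 3}, seed=5)
        for (ra, _), (rb, _) in zip(a, b):
            assert np.array_equal(ra.pixels, rb.pixels)


class TestSimulateRaters:
    def test_noiseless_panel_reproduces_ground_truth(self, small_dataset):
        profiles = [identity_profile(f"r{i}") for i in range(3)]
        evals = simulate_raters(small_dataset, profiles, 3, seed=0)
        truth_by_id = {rec.image_id: t for rec, t in small_dataset}
        assert len(evals) == 3 * len(small_dataset)
        for ev in evals:
            t = truth_by_id[ev.image_id]
            assert collapse_verdict(ev.verdict) == t.quality_class
            assert set(ev.explanations) == set(t.explanation_tags())

    def test_rater_count_preconditions(self, small_dataset):
        profiles = [identity_profile(f"r{i}") for i in range(5)]
        with pytest.raises(InvalidSceneError):
            simulate_raters(small_dataset, profiles, 12, seed=0)
        with pytest.raises(InvalidSceneError):
            simulate_raters(small_dataset, [], 1, seed=0)

    def test_pairwise_agreement_matches_confusion_closed_form(self):
        # With identical symmetric profiles the probability that two raters
        # agree on an image of true class c is sum_k M[c,k]^2; averaging over
        # the class prior gives the expected raw agreement.
        prof = symmetric_profile("p", accuracy=0.7)
        profiles = [symmetric_profile(f"r{i}", accuracy=0.7) for i in range(2)]
        counts = {c: 250 for c in QUALITY_CLASSES}
        recs = generate_dataset(counts, {"blurry": 1.0}, seed=8)
        evals = simulate_raters(recs, profiles, 2, seed=9)
        by_rater = {}
        for e in evals:
            by_rater.setdefault(e.rater_id, {})[e.image_id] = collapse_verdict(e.verdict)
        ids = list(by_rater["r0"])
        agree = np.mean([by_rater["r0"][i] == by_rater["r1"][i] for i in ids])
        m = prof.confusion
        expected = float(np.mean([np.sum(m[c] ** 2) for c in range(4)]))
        sigma = np.sqrt(expected * (1 - expected) / len(ids))
        assert abs(agree - expected) < 4 * sigma

    def test_empirical_pairwise_f1_matches_monte_carlo_oracle(self):
        """Per-class pairwise F1 of two identical noisy raters on n images
        agrees within ±0.03 with a direct Monte-Carlo oracle at 10x samples
        that draws verdict pairs straight from the confusion matrix."""
        acc = 0.75
        n, n_mc = 2000, 20000
        profiles = [symmetric_profile(f"r{i}", accuracy=acc) for i in range(2)]
        counts = {c: n // 4 for c in QUALITY_CLASSES}
        recs = generate_dataset(counts, {"blurry": 1.0}, seed=21)
        evals = simulate_raters(recs, profiles, 2, seed=22)
        by_rater = {}
        for e in evals:
            by_rater.setdefault(e.rater_id, {})[e.image_id] = collapse_verdict(e.verdict)
        ids = list(by_rater["r0"])
        a = [by_rater["r0"][i] for i in ids]
        b = [by_rater["r1"][i] for i in ids]

        # oracle: draw (emit_a, emit_b) independently given a uniform true class
        m = profiles[0].confusion
        rng = np.random.default_rng(99)
        true = rng.integers(0, 4, size=n_mc)
        cum = m.cumsum(axis=1)
        ea = (rng.random(n_mc)[:, None] < cum[true]).argmax(axis=1)
        eb = (rng.random(n_mc)[:, None] < cum[true]).argmax(axis=1)
        for ci, cls in enumerate(QUALITY_CLASSES):
            observed = f1(confusion_counts([x == cls for x in a],
                                           [x == cls for x in b], True))
            oracle = f1(confusion_counts((ea == ci).tolist(),
                                         (eb == ci).tolist(), True))
            assert abs(observed - oracle) < 0.03, (cls, observed, oracle)
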