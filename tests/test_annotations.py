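"""Verdict collapse, plurality/union fusion, class weights, and IO."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermaqx.annotations import (
    DuplicateEvaluationError,
    RaterEvaluation,
    VerdictParseError,
    build_reference_standard,
    collapse_verdict,
    compute_class_weights,
    fuse_explanations,
    fuse_quality,
    label_distribution_table,
    read_evaluations,
    write_evaluations,
)
from dermaqx.taxonomy import EXPLANATIONS, QUALITY_CLASSES, TIEBREAK_PRIORITY


def ev(rater, image, verdict, tags=()):
    return RaterEvaluation(rater, image, verdict, tuple(tags))


class TestCollapseVerdict:
    @pytest.mark.parametrize("verdict,expected", [
        ("L20.9", "lesion"),
        ("Z99", "lesion"),
        ("C43.9", "lesion"),
        ("B07", "lesion"),
        ("healthy_skin", "healthy_skin"),
        ("no_skin", "no_skin"),
        ("poor_quality", "poor_quality"),
    ])
    def test_collapse(self, verdict, expected):
        assert collapse_verdict(verdict) == expected

    @pytest.mark.parametrize("bad", ["banana", "l20.9", "L2", "20.9", ""])
    def test_unparseable_verdicts(self, bad):
        with pytest.raises(VerdictParseError):
            collapse_verdict(bad)

    def test_parse_error_names_offending_record(self):
        with pytest.raises(VerdictParseError, match="banana"):
            collapse_verdict("banana")


class TestFusion:
    def test_strict_majority(self):
        evals = [ev("a", "i", "L20.9"), ev("b", "i", "L30.9"),
                 ev("c", "i", "poor_quality", ["blurry"])]
        assert fuse_quality(evals).quality_class == "lesion"

    def test_tie_prefers_withholding(self):
        evals = [ev("a", "i", "poor_quality", ["blurry"]),
                 ev("b", "i", "healthy_skin")]
        assert fuse_quality(evals).quality_class == "poor_quality"

    def test_single_rater(self):
        fused = fuse_quality([ev("a", "i", "no_skin")])
        assert fused.quality_class == "no_skin"
        assert fused.n_raters == 1
        assert fused.vote_counts["no_skin"] == 1

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            fuse_quality([])

    def test_plurality_matches_brute_force_on_all_three_rater_panels(self):
        """All 4^3 = 64 vote configurations against an independent argmax
        with the stated tie-break priority."""
        tokens = {"lesion": "L20.9", "no_skin": "no_skin",
                  "healthy_skin": "healthy_skin", "poor_quality": "poor_quality"}
        for votes in itertools.product(QUALITY_CLASSES, repeat=3):
            evals = [ev(f"r{i}", "img", tokens[v]) for i, v in enumerate(votes)]
            fused = fuse_quality(evals)
            # oracle: count by hand, break ties by scanning the priority list
            counts = {c: votes.count(c) for c in QUALITY_CLASSES}
            best = max(counts.values())
            expected = [c for c in TIEBREAK_PRIORITY if counts[c] == best][0]
            assert fused.quality_class == expected, votes
            assert sum(fused.vote_counts.values()) == fused.n_raters == 3

    def test_explanation_union_matches_set_union_exhaustively(self):
        """All 2-rater combinations of explanation tag subsets (sizes 0-2)
        reproduce the set union."""
        subsets = [()] + [(e,) for e in EXPLANATIONS] + list(
            itertools.combinations(EXPLANATIONS, 2))
        for tags_a, tags_b in itertools.product(subsets, repeat=2):
            evals = [
                ev("a", "i", "poor_quality" if tags_a else "L20.9", tags_a),
                ev("b", "i", "poor_quality" if tags_b else "L20.9", tags_b),
            ]
            bits = fuse_explanations(evals)
            expected = set(tags_a) | set(tags_b)
            assert {e for e, b in zip(EXPLANATIONS, bits) if b} == expected

    def test_single_dissenting_rater_sets_bit(self):
        evals = [ev(f"r{i}", "i", "L20.9") for i in range(11)]
        evals.append(ev("r11", "i", "poor_quality", ["blurry"]))
        fused = fuse_quality(evals)
        assert fused.quality_class == "lesion"
        assert fused.explanations[EXPLANATIONS.index("blurry")] == 1

    def test_no_poor_votes_means_no_bits(self):
        assert not fuse_explanations([ev("a", "i", "L20.9"),
                                      ev("b", "i", "healthy_skin")]).any()

    @given(st.sampled_from(QUALITY_CLASSES), st.integers(1, 12))
    @settings(max_examples=30, deadline=None)
    def test_unanimous_panel_is_idempotent(self, cls, n):
        token = "L20.9" if cls == "lesion" else cls
        fused = fuse_quality([ev(f"r{i}", "i", token) for i in range(n)])
        assert fused.quality_class == cls

    @given(st.lists(st.sampled_from(EXPLANATIONS), max_size=5, unique=True),
           st.lists(st.sampled_from(EXPLANATIONS), max_size=5, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_adding_a_rater_never_clears_a_bit(self, tags_a, tags_b):
        base = [ev("a", "i", "poor_quality" if tags_a else "no_skin", tags_a)]
        more = base + [ev("b", "i", "poor_quality" if tags_b else "no_skin", tags_b)]
        assert np.all(fuse_explanations(more) >= fuse_explanations(base))


class TestClassWeights:
    def test_campaign_scale_counts(self):
        # counts of a 26,635-image four-class training split with clip 10
        w = compute_class_weights({"lesion": 17534, "no_skin": 461,
                                   "healthy_skin": 3903, "poor_quality": 4737},
                                  clip=10.0)
        assert w.rounded() == {"lesion": 1.0, "no_skin": 10.0,
                               "healthy_skin": 4.49, "poor_quality": 3.7}
        # full precision retained internally
        assert w.weights["healthy_skin"] == pytest.approx(17534 / 3903, rel=1e-12)

    def test_equal_counts_give_unit_weights(self):
        w = compute_class_weights({"a": 5, "b": 5}, clip=10.0)
        assert w.weights == {"a": 1.0, "b": 1.0}

    def test_clip_engages(self):
        w = compute_class_weights({"a": 1000, "b": 1}, clip=10.0)
        assert w.weights == {"a": 1.0, "b": 10.0}

    def test_modal_class_weight_is_one(self, rng):
        for _ in range(20):
            counts = {f"c{i}": int(rng.integers(1, 10000)) for i in range(4)}
            w = compute_class_weights(counts)
            modal = max(counts, key=counts.get)
            assert w.weights[modal] == 1.0
            assert all(1.0 <= v <= w.clip for v in w.weights.values())

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            compute_class_weights({"a": 10, "b": 0})


class TestReferenceStandard:
    def test_matches_brute_force_enumeration(self):
        evals = [
            ev("r1", "img1", "L20.9"), ev("r2", "img1", "L30.9"),
            ev("r1", "img2", "poor_quality", ["bad_light"]),
            ev("r2", "img2", "healthy_skin"),
            ev("r1", "img3", "no_skin"), ev("r2", "img3", "Z99"),
        ]
        rs = build_reference_standard(evals)
        by_img = rs.by_image()
        # manual enumeration: img1 unanimous lesion; img2 1-1 tie -> poor
        # (withholding priority); img3 1-1 tie -> no_skin over lesion
        assert by_img["img1"].quality_class == "lesion"
        assert by_img["img2"].quality_class == "poor_quality"
        assert by_img["img3"].quality_class == "no_skin"
        assert rs.class_counts == {"lesion": 1, "no_skin": 1,
                                   "healthy_skin": 0, "poor_quality": 1}
        assert rs.explanation_counts["bad_light"] == 1
        assert sum(rs.explanation_counts.values()) == 1

    def test_unanimous_counts(self):
        evals = [ev(f"r{i}", f"img{j}", "healthy_skin")
                 for i in range(3) for j in range(4)]
        rs = build_reference_standard(evals)
        assert rs.class_counts["healthy_skin"] == 4

    def test_duplicate_rater_image_pair_rejected(self):
        evals = [ev("r1", "img1", "L20.9"), ev("r1", "img1", "no_skin")]
        with pytest.raises(DuplicateEvaluationError):
            build_reference_standard(evals)

    def test_explanation_counts_follow_union_rule(self):
        evals = [
            ev("r1", "a", "poor_quality", ["blurry", "bad_light"]),
            ev("r2", "a", "poor_quality", ["blurry"]),
            ev("r1", "b", "poor_quality", ["too_far_away"]),
            ev("r2", "b", "L20.9"),
        ]
        rs = build_reference_standard(evals)
        assert rs.explanation_counts == {"bad_framing": 0, "bad_light": 1,
                                         "blurry": 1, "low_resolution": 0,
                                         "too_far_away": 1}


class TestDistributionTable:
    def test_totals_and_means(self):
        train = {"lesion": 17534, "no_skin": 461, "healthy_skin": 3903,
                 "poor_quality": 4737}
        test = {"lesion": 4803, "no_skin": 265, "healthy_skin": 2421,
                "poor_quality": 2385}
        df = label_distribution_table(train, test)
        assert df.loc["total", "train"] == 26635
        assert df.loc["total", "test"] == 9874
        assert df.loc["total", "all"] == 36509
        assert df.loc["mean", "train"] == pytest.approx(6658.75)
        assert df.loc["mean", "test"] == pytest.approx(2468.5)

    def test_mean_divides_by_the_number_of_classes(self):
        # five-row table: the mean must be the sum over 5, not over 4
        counts = {"bad_framing": 1947, "bad_light": 5144, "blurry": 5499,
                  "low_resolution": 3965, "too_far_away": 936}
        df = label_distribution_table(counts, counts, order=list(counts))
        assert df.loc["total", "train"] == 17491
        assert df.loc["mean", "train"] == pytest.approx(17491 / 5)


class TestIO:
    @pytest.mark.parametrize("ext", ["jsonl", "csv"])
    def test_roundtrip(self, tmp_path, ext):
        evals = [
            ev("r1", "img1", "L20.9"),
            ev("r2", "img1", "poor_quality", ["blurry", "bad_light"]),
            ev("r1", "img2", "no_skin"),
        ]
        path = tmp_path / f"evals.{ext}"
        write_evaluations(evals, path)
        back = read_evaluations(path)
        assert back == evals

    def test_explanations_require_poor_quality_verdict(self):
        with pytest.raises(VerdictParseError):
            ev("r1", "img1", "L20.9", ["blurry"])

    def test_unknown_tag_rejected(self):
        with pytest.raises(VerdictParseError, match="grainy"):
            ev("r1", "img1", "poor_quality", ["grainy"])
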