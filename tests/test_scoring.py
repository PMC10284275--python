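"""Comment tokenization, per-second weighted-sum scoring and normalization."""

import numpy as np
import pytest

from elevdec.scoring import (
    Comment,
    CommentStream,
    ScoreSeries,
    ScoringError,
    compare_with_selfreport,
    moving_average,
    read_comments_csv,
    read_selfreport_csv,
    score_seconds,
    tokenize_comment,
    write_comments_csv,
    write_scores_csv,
    zscore_across_videos,
)


class TestTokenize:
    def test_degree_word_scales_weight(self, tiny_dictionary):
        toks = tokenize_comment("very touching", tiny_dictionary)
        assert [(t.term, t.dict_score, t.weight) for t in toks] == [
            ("touching", 2, 1.5)
        ]

    def test_negator_flips_sign(self, tiny_dictionary):
        (tok,) = tokenize_comment("not touching", tiny_dictionary)
        assert tok.weight == -1.0 and tok.dict_score == 2

    def test_modifiers_compose_multiplicatively(self, tiny_dictionary):
        (tok,) = tokenize_comment("not very touching", tiny_dictionary)
        assert tok.weight == -1.5

    def test_no_lexicon_terms_yields_empty(self, tiny_dictionary):
        assert tokenize_comment("the weather is sunny", tiny_dictionary) == []

    def test_bare_entry_term_has_unit_weight(self, tiny_dictionary):
        for term in tiny_dictionary.entries:
            (tok,) = tokenize_comment(term, tiny_dictionary)
            assert tok.weight == 1.0 and tok.term == term

    def test_longest_match_wins(self, tiny_dictionary):
        # "a little" must match as one degree word, not fall apart
        (tok,) = tokenize_comment("a little touching", tiny_dictionary)
        assert tok.weight == 0.75

    def test_modifier_without_entry_contributes_nothing(self, tiny_dictionary):
        assert tokenize_comment("very sunny day", tiny_dictionary) == []

    def test_modifier_consumed_by_first_entry(self, tiny_dictionary):
        toks = tokenize_comment("very touching and nice", tiny_dictionary)
        assert [(t.term, t.weight) for t in toks] == [
            ("touching", 1.5), ("nice", 1.0)
        ]

    def test_matching_is_case_insensitive(self, tiny_dictionary):
        (tok,) = tokenize_comment("VERY Touching", tiny_dictionary)
        assert tok.weight == 1.5

    def test_external_tokenizer_hook(self, tiny_dictionary):
        toks = tokenize_comment("xxx", tiny_dictionary,
                                tokenizer=lambda s: ["not", "touching"])
        assert [(t.term, t.weight) for t in toks] == [("touching", -1.0)]


class TestScoreSeconds:
    def test_weighted_sum_over_comment_total(self, tiny_dictionary):
        # second 0 holds tokens (2, w=1) and (1, w=1.5); N=100 comments
        comments = [Comment(0.2, "touching"), Comment(0.7, "very nice")]
        comments += [Comment(5.0 + 0.009 * i, "zzz") for i in range(98)]
        stream = CommentStream("v", 10, comments)
        series = score_seconds(stream, tiny_dictionary)
        assert series.per_second[0] == pytest.approx((2 * 1 + 1 * 1.5) / 100)

    def test_second_without_comments_scores_zero(self, tiny_dictionary):
        stream = CommentStream("v", 5, [Comment(1.5, "touching")])
        series = score_seconds(stream, tiny_dictionary)
        assert series.per_second[1] != 0
        assert all(series.per_second[i] == 0 for i in (0, 2, 3, 4))

    def test_all_zero_score_comments_give_zero_series(self, tiny_dictionary):
        stream = CommentStream("v", 3, [Comment(0.1, "lol"), Comment(2.2, "first")])
        assert np.all(score_seconds(stream, tiny_dictionary).per_second == 0)

    def test_integer_timestamp_goes_to_later_window(self, tiny_dictionary):
        stream = CommentStream("v", 4, [Comment(2.0, "touching")])
        series = score_seconds(stream, tiny_dictionary)
        assert series.per_second[2] == pytest.approx(2.0)
        assert series.per_second[1] == 0

    def test_doubling_comments_leaves_scores_unchanged(self, tiny_dictionary):
        comments = [Comment(0.5, "very touching"), Comment(3.3, "not nice"),
                    Comment(3.9, "lol")]
        one = score_seconds(CommentStream("v", 5, comments), tiny_dictionary)
        two = score_seconds(CommentStream("v", 5, comments * 2), tiny_dictionary)
        np.testing.assert_allclose(two.per_second, one.per_second)

    def test_order_invariance_within_second(self, tiny_dictionary):
        comments = [Comment(1.1, "touching"), Comment(1.8, "not nice"),
                    Comment(1.4, "very inspiring")]
        fwd = score_seconds(CommentStream("v", 3, comments), tiny_dictionary)
        rev = score_seconds(CommentStream("v", 3, comments[::-1]), tiny_dictionary)
        np.testing.assert_allclose(fwd.per_second, rev.per_second)

    def test_stream_validation(self):
        with pytest.raises(ScoringError):
            CommentStream("v", 0, [])
        with pytest.raises(ScoringError):
            CommentStream("v", 5, [Comment(5.0, "late")])
        with pytest.raises(ScoringError):
            Comment(-1.0, "early")


class TestZScore:
    def test_zero_mean_unit_sd(self, tiny_dictionary):
        raw = ScoreSeries(np.array([0.0, 0.02, 0.04]), (("v", 0, 3),))
        z = zscore_across_videos([raw])
        assert z.per_second.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.per_second.std() == pytest.approx(1.0)
        assert z.normalized == "zscored"

    def test_matches_zscore_of_concatenation(self):
        a = ScoreSeries(np.array([0.1, 0.4]), (("a", 0, 2),))
        b = ScoreSeries(np.array([0.2, 0.9, 0.3]), (("b", 0, 3),))
        z = zscore_across_videos([a, b])
        cat = np.array([0.1, 0.4, 0.2, 0.9, 0.3])
        np.testing.assert_allclose(z.per_second, (cat - cat.mean()) / cat.std())
        assert z.video_boundaries == (("a", 0, 2), ("b", 2, 3))

    def test_constant_input_rejected(self):
        c = ScoreSeries(np.zeros(5), (("v", 0, 5),))
        with pytest.raises(ScoringError, match="variance"):
            zscore_across_videos([c])

    def test_inverse_affine_recovers_raw(self, rng):
        raw_vals = rng.normal(size=40) * 0.01 + 0.02
        raw = ScoreSeries(raw_vals, (("v", 0, 40),))
        z = zscore_across_videos([raw])
        back = z.per_second * raw_vals.std() + raw_vals.mean()
        np.testing.assert_allclose(back, raw_vals, atol=1e-14)


class TestCompareWithSelfreport:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=30)
        s = ScoreSeries(x, (("v", 0, 30),))
        assert compare_with_selfreport(s, x)[0] == pytest.approx(1.0)
        assert compare_with_selfreport(s, -x)[0] == pytest.approx(-1.0)

    def test_planted_coupling_detected(self, rng):
        latent = np.sin(np.linspace(0, 6 * np.pi, 200))
        danmaku = ScoreSeries(latent + 0.5 * rng.normal(size=200),
                              (("v", 0, 200),))
        selfreport = latent + 0.5 * rng.normal(size=200)
        r, p = compare_with_selfreport(danmaku, selfreport)
        assert r > 0.3 and p < 1e-3

    def test_errors(self):
        s = ScoreSeries(np.arange(5.0), (("v", 0, 5),))
        with pytest.raises(ScoringError):
            compare_with_selfreport(s, np.arange(4.0))
        with pytest.raises(ScoringError):
            compare_with_selfreport(s, np.ones(5))


def test_moving_average_is_per_video_and_noop_at_width_1():
    s = ScoreSeries(np.array([0.0, 1.0, 0.0, 1.0]),
                    (("a", 0, 2), ("b", 2, 2)))
    assert moving_average(s, 1) is s
    sm = moving_average(s, 3)
    # smoothing never mixes the two videos
    np.testing.assert_allclose(sm.per_second[:2], [1 / 3, 2 / 3])
    np.testing.assert_allclose(sm.per_second[2:], [1 / 3, 2 / 3])


def test_csv_round_trips(tmp_path, tiny_dictionary):
    stream = CommentStream("v1", 5, [Comment(0.5, "very touching"),
                                     Comment(3.25, "not nice")])
    p = tmp_path / "comments.csv"
    write_comments_csv(stream, p)
    back = read_comments_csv(p, "v1", 5)
    assert back.comments == stream.comments

    raw = score_seconds(stream, tiny_dictionary)
    z = zscore_across_videos([raw])
    sp = tmp_path / "scores.csv"
    write_scores_csv(raw, z, sp)
    import pandas as pd

    df = pd.read_csv(sp)
    assert list(df.columns) == ["video_id", "second", "raw_score", "z_score"]
    np.testing.assert_allclose(df["z_score"], z.per_second)

    srp = tmp_path / "sr.csv"
    pd.DataFrame({"second": range(5), "value": np.linspace(0, 1, 5)}).to_csv(
        srp, index=False)
    np.testing.assert_allclose(read_selfreport_csv(srp),
                               np.linspace(0, 1, 5))
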