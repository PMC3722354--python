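"""Behavioural reading measures: RT trimming, WLE, accuracy, n-grams, ladder."""

import numpy as np
import pandas as pd
import pytest

from lexidcm.behavior import (
    inclusion_threshold,
    ladder_transition,
    ngram_decompose,
    ngram_frequency_index,
    partial_correlation,
    reading_measures,
    score_accuracy,
    shared_letters,
    text_wpm,
    trim_and_mean_rt,
    validate_trials,
    word_length_effect,
)


class TestTrimAndMean:
    def test_symmetric_sample_untouched(self):
        mean, n_excl = trim_and_mean_rt([500, 510, 490, 505, 495])
        assert mean == pytest.approx(500.0)
        assert n_excl == 0

    def test_extreme_outlier_excluded(self):
        # mean 750, SD ~612; |2000 - 750| > 2 SD, survivors average 500
        mean, n_excl = trim_and_mean_rt([500, 510, 490, 505, 495, 2000])
        assert mean == pytest.approx(500.0)
        assert n_excl == 1

    def test_constant_rts(self):
        mean, n_excl = trim_and_mean_rt([640.0] * 5)
        assert mean == 640.0 and n_excl == 0

    def test_single_pass_only(self):
        # 3000 is excluded on the first pass; 100 would fall outside 2 SD of
        # the survivors but single-pass trimming keeps it
        rts = [100, 500, 510, 490, 505, 495, 3000]
        mean, n_excl = trim_and_mean_rt(rts)
        assert n_excl == 1
        assert mean == pytest.approx(np.mean([100, 500, 510, 490, 505, 495]))

    def test_too_few_rts_undefined(self):
        mean, _ = trim_and_mean_rt([500.0])
        assert np.isnan(mean)


class TestWordLengthEffect:
    def test_exact_linear_slope(self):
        assert word_length_effect({3: 500, 4: 550, 5: 600, 6: 650}) == pytest.approx(50.0)

    def test_constant_means_give_zero(self):
        assert word_length_effect({3: 700, 4: 700, 5: 700, 6: 700}) == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        y = {L: 500 + 40 * L + rng.normal(0, 25) for L in (3, 4, 5, 6)}
        x = np.array([3.0, 4, 5, 6])
        yv = np.array([y[L] for L in (3, 4, 5, 6)])
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.inv(X.T @ X) @ X.T @ yv
        assert word_length_effect(y) == pytest.approx(beta[1], abs=1e-10)

    def test_shift_invariance_and_scaling(self):
        base = {3: 510.0, 4: 580.0, 5: 620.0, 6: 700.0}
        shifted = {k: v + 123.4 for k, v in base.items()}
        scaled = {k: 2.0 * v for k, v in base.items()}
        assert word_length_effect(shifted) == pytest.approx(word_length_effect(base))
        assert word_length_effect(scaled) == pytest.approx(2 * word_length_effect(base))

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            word_length_effect({4: 500.0})


class TestAccuracy:
    def test_partial_credit_scheme(self):
        assert score_accuracy(["correct", "correct", "self_corrected", "error"]) == 62.5

    def test_all_correct(self):
        assert score_accuracy(["correct"] * 7) == 100.0

    def test_voicekey_failures_excluded_from_denominator(self):
        assert score_accuracy(["correct", "voicekey_fail"]) == 100.0

    def test_no_valid_trials(self):
        with pytest.raises(ValueError):
            score_accuracy(["voicekey_fail"])

    def test_permutation_invariant(self):
        trials = ["correct"] * 5 + ["error"] * 2 + ["self_corrected"] * 3
        rng = np.random.default_rng(1)
        shuffled = list(trials)
        rng.shuffle(shuffled)
        assert score_accuracy(shuffled) == score_accuracy(trials)


class TestSpeedAndThresholds:
    @pytest.mark.parametrize("n,dur,expected", [
        (90, 30.0, 180.0), (87, 60.0, 87.0), (94, 88.5, 63.7288135593),
    ])
    def test_words_per_minute(self, n, dur, expected):
        assert text_wpm(n, dur) == pytest.approx(expected)

    def test_nonpositive_duration(self):
        with pytest.raises(ValueError):
            text_wpm(90, 0.0)

    def test_inclusion_threshold_from_control_stats(self):
        # control three-letter word RT: mean 495.3 ms, SD 84.3 ms
        assert inclusion_threshold(495.3, 84.3) == pytest.approx(663.9)
        assert inclusion_threshold(0.0, 1.0) == pytest.approx(2.0)
        # WLE criterion from the printed control mean/SD (1.1, 9.4 ms/letter)
        assert inclusion_threshold(1.1, 9.4) == pytest.approx(19.9)


class TestNgrams:
    def test_house_decomposition(self):
        assert ngram_decompose("house", 2) == ["ho", "ou", "us", "se"]
        assert ngram_decompose("house", 3) == ["hou", "ous", "use"]

    def test_word_of_length_n(self):
        assert ngram_decompose("at", 2) == ["at"]

    def test_short_word_empty(self):
        assert ngram_decompose("at", 3) == []

    def test_hand_counted_index(self):
        # "cat": bigrams [ca, at]; reference counts ca twice, at never
        assert ngram_frequency_index("cat", ["cap", "can"], 2) == pytest.approx(1.0)

    def test_disjoint_reference_gives_zero(self):
        assert ngram_frequency_index("cat", ["dog", "pig"], 2) == 0.0

    def test_linear_in_reference_counts(self):
        ref = ["cap", "can", "atom"]
        once = ngram_frequency_index("cat", ref, 2)
        twice = ngram_frequency_index("cat", ref * 2, 2)
        assert twice == pytest.approx(2 * once)

    def test_within_list_self_exclusion(self):
        # a word does not count its own occurrence in its own list
        assert ngram_frequency_index("cat", ["cat", "cap"], 2, exclude_self=True) \
            == pytest.approx(0.5)

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(2)
        letters = "abcdef"
        for _ in range(5):
            words = [
                "".join(rng.choice(list(letters), size=rng.integers(3, 7)))
                for _ in range(30)
            ]
            target = words[0]
            for n in (2, 3):
                grams = [target[i:i + n] for i in range(len(target) - n + 1)]
                brute = sum(
                    1
                    for g in grams
                    for w in words
                    for i in range(len(w) - n + 1)
                    if w[i:i + n] == g
                ) / len(grams)
                assert ngram_frequency_index(target, words, n) == pytest.approx(brute)


class TestPartialCorrelation:
    def test_y_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=50)
        x = rng.normal(size=50)
        assert abs(partial_correlation(x, c, c)) < 1e-10

    def test_constant_covariate_reduces_to_pearson(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 40))
        r = partial_correlation(x, y, np.full(40, 3.0))
        assert r == pytest.approx(pearsonr(x, y)[0], abs=1e-12)

    def test_recovers_known_partial_correlation(self):
        rng = np.random.default_rng(5)
        n = 500
        c = rng.normal(size=n)
        rho = 0.5
        u = rng.normal(size=n)
        v = rho * u + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        x = 2.0 * c + u
        y = -1.0 * c + v
        assert partial_correlation(x, y, c) == pytest.approx(rho, abs=0.1)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=["x", "y", "c"])
        df["x"] += 0.5 * df["c"]
        df["y"] += 0.8 * df["c"] + 0.4 * df["x"]
        ours = partial_correlation(df["x"], df["y"], df["c"])
        theirs = float(pingouin.partial_corr(df, x="x", y="y", covar="c")["r"].iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestLadder:
    @pytest.mark.parametrize("level,correct,expected", [
        ("easy", True, "medium"),
        ("medium", True, "hard"),
        ("hard", True, "hard"),
        ("hard", False, "medium"),
        ("medium", False, "easy"),
        ("easy", False, "easy"),
    ])
    def test_transitions(self, level, correct, expected):
        new, pence = ladder_transition(level, correct)
        assert new == expected
        assert pence == int(correct)

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            ladder_transition("impossible", True)

    def test_shared_letters_multiset(self):
        assert shared_letters("food", "foot") == 3
        assert shared_letters("food", "hate") == 0
        assert shared_letters("food", "odd") == 2  # o and one d


class TestTrialTables:
    def make_table(self):
        rows = []
        rng = np.random.default_rng(7)
        for L, word in ((3, "cat"), (4, "door"), (5, "house"), (6, "window")):
            for _ in range(6):
                rows.append(
                    {
                        "word": word,
                        "length": L,
                        "list": "trained",
                        "timepoint": "t1",
                        "rt_ms": 500 + 50 * (L - 3) + rng.normal(0, 10),
                        "outcome": "correct",
                    }
                )
        return pd.DataFrame(rows)

    def test_measures_round_trip(self):
        m = reading_measures(self.make_table())
        assert len(m) == 1
        assert m["wle_ms_per_letter"].iloc[0] == pytest.approx(50.0, abs=10.0)
        assert m["accuracy_pct"].iloc[0] == 100.0

    def test_validation_catches_length_mismatch(self):
        df = self.make_table()
        df.loc[0, "length"] = 5
        with pytest.raises(ValueError, match="length"):
            validate_trials(df)

    def test_validation_catches_unknown_outcome(self):
        df = self.make_table()
        df.loc[0, "outcome"] = "mystery"
        with pytest.raises(ValueError, match="outcome"):
            validate_trials(df)
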