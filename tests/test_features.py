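import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coughkit.audio_core import AudioClip, TARGET_RATE
from coughkit.features import (
    FEATURE_NAMES,
    SelectionSpec,
    extract_features,
    select_by_variance,
    select_k_best,
)
from coughkit.segmentation import SoundEvent
from coughkit.synth_fixtures import gen_cough

SR = TARGET_RATE


def _event(x):
    return SoundEvent(clip=AudioClip(x, SR, label="cough"), start_s=0.0,
                      end_s=len(x) / SR, sound_type="cough")


class TestExtractFeatures:
    def test_vector_has_120_values_in_documented_order(self, rng):
        v = extract_features(gen_cough(rng, 0.4))
        assert v.shape == (120,)
        assert len(FEATURE_NAMES) == 120
        assert FEATURE_NAMES[0] == "mfcc_01" and FEATURE_NAMES[40] == "d_01"
        assert FEATURE_NAMES[80] == "dd_01" and FEATURE_NAMES[-1] == "dd_40"

    def test_silence_is_finite_with_zero_deltas(self):
        v = extract_features(_event(np.zeros(SR)))
        assert np.all(np.isfinite(v))
        np.testing.assert_allclose(v[40:], 0.0, atol=1e-9)

    def test_deterministic(self, rng):
        ev = gen_cough(rng, 0.35)
        assert np.array_equal(extract_features(ev), extract_features(ev))

    def test_stationary_signal_shift_invariance(self, rng):
        # identical stationary content shifted by one hop (~12 ms) inside
        # silence padding: the multiset of analysis frames is unchanged,
        # so the mean-pooled MFCC block must agree to high precision
        tone = 0.3 * np.sin(2 * np.pi * 500 * np.arange(SR) / SR)
        pad = np.zeros(SR // 2)
        shift = np.zeros(512)  # one analysis hop
        a = np.concatenate([pad, tone, pad])
        b = np.concatenate([pad, shift, tone, pad[: len(pad) - len(shift)]])
        va = extract_features(_event(a))[:40]
        vb = extract_features(_event(b))[:40]
        np.testing.assert_allclose(va, vb, rtol=1e-3, atol=1e-3)

    def test_too_short_event_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_event(np.zeros(100)))


def _brute_force_k_best(X, y, k):
    """Independent oracle: explicit one-way ANOVA F per column, full sort."""
    scores = []
    for j in range(X.shape[1]):
        g0, g1 = X[y == 0, j], X[y == 1, j]
        gm = X[:, j].mean()
        ssb = len(g0) * (g0.mean() - gm) ** 2 + len(g1) * (g1.mean() - gm) ** 2
        ssw = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
        dfb, dfw = 1, len(X) - 2
        scores.append((ssb / dfb) / (ssw / dfw) if ssw > 0 else -np.inf)
    order = np.argsort(-np.asarray(scores), kind="stable")
    return set(order[:k])


class TestSelectKBest:
    def test_k_equals_feature_count_is_identity(self, rng):
        X = rng.standard_normal((20, 12))
        y = np.r_[np.zeros(10), np.ones(10)]
        assert np.array_equal(select_k_best(X, y, 12), np.arange(12))

    def test_single_separating_feature_found(self, rng):
        X = rng.standard_normal((40, 20))
        y = np.r_[np.zeros(20), np.ones(20)]
        X[y == 1, 7] += 10.0
        assert np.array_equal(select_k_best(X, y, 1), [7])

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(5):
            X = rng.standard_normal((20, 120))
            y = rng.integers(0, 2, 20)
            if len(np.unique(y)) < 2:
                continue
            for k in (1, 10, 60, 120):
                assert set(select_k_best(X, y, k)) == _brute_force_k_best(X, y, k)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError):
            select_k_best(X, np.zeros(10), 2)  # single class
        with pytest.raises(ValueError):
            select_k_best(X, np.r_[np.zeros(5), np.ones(5)], 0)
        with pytest.raises(ValueError):
            select_k_best(X, np.r_[np.zeros(5), np.ones(5)], 6)


class TestSelectByVariance:
    def test_constant_column_always_smallest(self, rng):
        X = rng.standard_normal((15, 10))
        X[:, 3] = 2.5
        assert 3 in select_by_variance(X, 1, "smallest")

    def test_full_k_is_identity(self, rng):
        X = rng.standard_normal((10, 8))
        assert np.array_equal(select_by_variance(X, 8, "smallest"), np.arange(8))

    def test_known_variances_largest(self, rng):
        # one random profile scaled per column: sample variance of column j
        # is exactly var(profile) * (j+1)^2, so the ranking is deterministic
        profile = rng.standard_normal(30)[:, None]
        X = profile * np.arange(1, 121)
        got = set(select_by_variance(X, 10, "largest"))
        brute = set(np.argsort(-X.var(axis=0, ddof=1), kind="stable")[:10])
        assert got == brute
        assert got == set(range(110, 120))

    def test_matches_brute_force_both_modes(self, rng):
        X = rng.standard_normal((20, 120))
        for mode, sign in (("smallest", 1), ("largest", -1)):
            got = set(select_by_variance(X, 25, mode))
            brute = set(np.argsort(sign * X.var(axis=0, ddof=1), kind="stable")[:25])
            assert got == brute

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            select_by_variance(rng.standard_normal((1, 5)), 2, "smallest")
        with pytest.raises(ValueError):
            select_by_variance(rng.standard_normal((5, 5)), 2, "median")


class TestSelectionSpec:
    def test_variance_mode_requirement(self):
        with pytest.raises(ValueError):
            SelectionSpec("variance", 70)
        with pytest.raises(ValueError):
            SelectionSpec("k_best", 70, "smallest")
        SelectionSpec("variance", 70, "smallest")
        SelectionSpec("k_best", 120)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(1, 120), st.integers(0, 2**31 - 1))
def test_selection_returns_k_distinct_valid_indices(k, seed):
    r = np.random.default_rng(seed)
    X = r.standard_normal((12, 120))
    idx = select_by_variance(X, k, "smallest")
    assert len(idx) == k == len(set(idx.tolist()))
    assert idx.min() >= 0 and idx.max() < 120
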