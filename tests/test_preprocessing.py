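"""Preprocessing stages: SMOTE geometry, scaling, elevation, images, splits."""

import numpy as np
import pandas as pd
import pytest

from pdresnet.preprocessing import (ElevationSpec, EraseParams, Normalizer,
                                    SmoteParams, flatten_image, make_batches,
                                    polynomial_elevate, random_erase,
                                    resize_image, smote_balance,
                                    split_train_test, to_image)

# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def _toy_table(features, labels):
    df = pd.DataFrame(np.asarray(features, dtype=float))
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    df.insert(0, "subject_id", [f"S{i}" for i in range(len(df))])
    df["diagnosis"] = labels
    df["severity"] = "none"
    return df


def test_smote_balances_study_sizes(default_cohort):
    bal = smote_balance(default_cohort, SmoteParams(5, 0))
    counts = bal.diagnosis.value_counts()
    assert counts["PD"] == counts["HC"] == 296
    assert int(bal.synthetic.sum()) == 135
    # originals untouched, in original order
    orig = bal.loc[~bal.synthetic].drop(columns="synthetic")
    pd.testing.assert_frame_equal(orig, default_cohort)


def test_smote_balanced_input_unchanged():
    df = _toy_table(np.arange(12).reshape(6, 2), ["PD"] * 3 + ["HC"] * 3)
    out = smote_balance(df, SmoteParams(1, 0))
    assert len(out) == 6 and not out.synthetic.any()


def test_smote_synthetic_points_lie_between_neighbours():
    """With a 2-point minority and k=1 every synthetic sample must sit on
    the segment joining the two originals."""
    a, b = np.array([0.0, 0.0, 1.0]), np.array([2.0, 1.0, 3.0])
    feats = np.vstack([a, b] + [[10 + i, 10 - i, i] for i in range(8)])
    df = _toy_table(feats, ["HC", "HC"] + ["PD"] * 8)
    out = smote_balance(df, SmoteParams(1, 42))
    synth = out.loc[out.synthetic, [f"f{i}" for i in range(3)]].to_numpy()
    assert len(synth) == 6
    for s in synth:
        cross = np.cross(s - a, b - a)
        assert np.allclose(cross, 0.0, atol=1e-10)
        t = np.dot(s - a, b - a) / np.dot(b - a, b - a)
        assert -1e-12 <= t <= 1 + 1e-12


def test_smote_error_cases(default_cohort):
    single = default_cohort[default_cohort.diagnosis == "PD"]
    with pytest.raises(ValueError, match="two classes"):
        smote_balance(single, SmoteParams(5, 0))
    df = _toy_table(np.arange(20).reshape(10, 2), ["HC"] * 3 + ["PD"] * 7)
    with pytest.raises(ValueError, match="k"):
        smote_balance(df, SmoteParams(5, 0))


def test_smote_determinism():
    df = _toy_table(np.random.default_rng(0).normal(size=(30, 4)),
                    ["HC"] * 10 + ["PD"] * 20)
    out1 = smote_balance(df, SmoteParams(3, 9))
    out2 = smote_balance(df, SmoteParams(3, 9))
    pd.testing.assert_frame_equal(out1, out2)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def test_normalizer_examples():
    norm = Normalizer().fit(np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]]))
    out = norm.transform(np.array([[2.0, 5.0], [4.0, 5.0], [6.0, 5.0]]))
    assert np.allclose(out[:, 0], [0.0, 0.5, 1.0])
    assert np.allclose(out[:, 1], 0.0)          # constant column maps to 0
    # out-of-range test value clips into [0, 1]
    assert np.allclose(norm.transform(np.array([7.0, 5.0])), [1.0, 0.0])
    assert np.allclose(norm.transform(np.array([1.0, 5.0])), [0.0, 0.0])


def test_normalizer_unfitted_errors():
    with pytest.raises(RuntimeError, match="fit"):
        Normalizer().transform(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# Polynomial elevation + images
# ---------------------------------------------------------------------------


def _elevation_oracle(x, side, include_squares=True):
    """Independent double-loop enumeration of the degree-2 term order."""
    terms = list(x)
    if include_squares:
        terms += [v * v for v in x]
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            terms.append(x[i] * x[j])
    terms = terms[:side * side]
    terms += [0.0] * (side * side - len(terms))
    return np.array(terms)


def test_elevation_matches_enumeration_oracle(rng):
    for n, side in [(3, 3), (5, 4), (194, 117)]:
        x = rng.uniform(size=n)
        got = polynomial_elevate(x, ElevationSpec(target_side=side))
        assert got.shape == (side * side,)
        assert np.allclose(got, _elevation_oracle(x, side))


def test_elevation_toy_terms():
    out = polynomial_elevate(np.array([1.0, 2.0, 3.0]), ElevationSpec(target_side=3))
    # originals, squares, then cross terms (1*2, 1*3, 2*3)
    assert np.allclose(out, [1, 2, 3, 1, 4, 9, 2, 3, 6])


def test_elevation_default_length_is_117_squared():
    out = polynomial_elevate(np.ones(194))
    assert out.shape == (13_689,)


def test_elevation_zero_vector_and_padding():
    out = polynomial_elevate(np.zeros(194))
    assert not out.any()
    padded = polynomial_elevate(np.array([1.0, 2.0]), ElevationSpec(target_side=3))
    assert np.allclose(padded, [1, 2, 1, 4, 2, 0, 0, 0, 0])


def test_elevation_rejects_non_finite():
    with pytest.raises(ValueError, match="finite"):
        polynomial_elevate(np.array([1.0, np.nan, 2.0]))


def test_to_image_row_major_and_round_trip(rng):
    img = to_image(np.array([1.0, 2.0, 3.0, 4.0]), 2)
    assert np.allclose(img, [[1, 2], [3, 4]])
    v = rng.normal(size=49)
    assert np.allclose(flatten_image(to_image(v, 7)), v)
    with pytest.raises(ValueError, match="length"):
        to_image(np.arange(5.0), 2)


def _resize_oracle_1d(img, new_side):
    """Two-pass separable 1-D interpolation (np.interp per axis)."""
    side = img.shape[0]
    src = np.linspace(0, side - 1, new_side)
    rows = np.stack([np.interp(src, np.arange(side), img[r]) for r in range(side)])
    return np.stack([np.interp(src, np.arange(side), rows[:, c])
                     for c in range(new_side)], axis=1)


def test_resize_shapes_and_constant():
    img = np.full((117, 117), 3.25)
    out = resize_image(img, 112)
    assert out.shape == (112, 112)
    assert np.allclose(out, 3.25)


@pytest.mark.parametrize("side,new_side", [(3, 5), (7, 5), (117, 112)])
def test_resize_matches_separable_oracle(side, new_side, rng):
    img = rng.normal(size=(side, side))
    assert np.allclose(resize_image(img, new_side),
                       _resize_oracle_1d(img, new_side), atol=1e-9)


def test_resize_linear_ramp_is_exact():
    # bilinear interpolation reproduces a separable linear ramp exactly
    r = np.arange(3.0)
    img = r[:, None] + 2 * r[None, :]
    out = resize_image(img, 5)
    rr = np.linspace(0, 2, 5)
    assert np.allclose(out, rr[:, None] + 2 * rr[None, :])


def test_resize_errors():
    with pytest.raises(ValueError):
        resize_image(np.ones((1, 1)), 5)
    with pytest.raises(ValueError):
        resize_image(np.ones((4, 4)), 0)


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------


def test_split_sizes_nearest_integer():
    y = np.array([0, 1] * 296)
    split = split_train_test(592, 0.3, True, 0, labels=y)
    assert len(split.test_ids) == 178
    assert len(split.train_ids) == 414
    split10 = split_train_test(10, 0.3, True, 0, labels=np.array([0, 1] * 5))
    assert len(split10.test_ids) == 3


def test_split_stratification_and_coverage():
    y = np.array([1] * 296 + [0] * 296)
    split = split_train_test(592, 0.3, True, 7, labels=y)
    assert np.array_equal(np.sort(np.concatenate([split.train_ids, split.test_ids])),
                          np.arange(592))
    assert len(np.intersect1d(split.train_ids, split.test_ids)) == 0
    assert y[split.test_ids].sum() == 89          # 89 PD + 89 HC in test
    assert len(split.test_ids) - y[split.test_ids].sum() == 89


def test_split_determinism_and_errors():
    y = np.array([0, 1] * 10)
    a = split_train_test(20, 0.3, True, 3, labels=y)
    b = split_train_test(20, 0.3, True, 3, labels=y)
    assert np.array_equal(a.test_ids, b.test_ids)
    with pytest.raises(ValueError):
        split_train_test(20, 1.5, True, 0, labels=y)
    with pytest.raises(ValueError):
        split_train_test(20, 0.3, True, 0, labels=np.zeros(20))


# ---------------------------------------------------------------------------
# Random erasing
# ---------------------------------------------------------------------------


def test_random_erase_probability_zero_is_identity(rng):
    img = rng.uniform(size=(20, 20))
    out = random_erase(img, EraseParams(probability=0.0), rng)
    assert np.array_equal(out, img)


def test_random_erase_deterministic_under_seed():
    img = np.zeros((30, 30))
    params = EraseParams(probability=1.0)
    out1 = random_erase(img, params, np.random.default_rng(5))
    out2 = random_erase(img, params, np.random.default_rng(5))
    assert np.array_equal(out1, out2)


def test_random_erase_modifies_exactly_one_rectangle(rng):
    img = np.full((40, 40), -1.0)  # fill values in [0,1] cannot collide
    params = EraseParams(probability=1.0)
    for _ in range(20):
        out = random_erase(img, params, rng)
        changed = out != img
        rows = np.flatnonzero(changed.any(axis=1))
        cols = np.flatnonzero(changed.any(axis=0))
        h, w = len(rows), len(cols)
        assert changed.sum() == h * w
        assert changed[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].all()
        area_frac = (h * w) / img.size
        assert 0.+0.005 < area_frac < 0.40  # rounded bounds around (0.02, 0.33)


def test_random_erase_fill_rules(rng):
    img = np.full((20, 20), 0.7)
    out = random_erase(img, EraseParams(probability=1.0, fill_rule="zero"), rng)
    changed = out != img
    assert changed.any() and np.allclose(out[changed], 0.0)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


def test_batches_of_592_are_25x23_plus_17():
    batches = make_batches(np.arange(592), 23, shuffle=True, rng=0)
    sizes = [len(b) for b in batches]
    assert len(batches) == 26
    assert sizes[:-1] == [23] * 25 and sizes[-1] == 17
    assert np.array_equal(np.sort(np.concatenate(batches)), np.arange(592))


def test_batches_exact_and_errors():
    assert [len(b) for b in make_batches(np.arange(23), 23, shuffle=False)] == [23]
    with pytest.raises(ValueError):
        make_batches(np.array([]), 23)
    with pytest.raises(ValueError):
        make_batches(np.arange(5), 0)


def test_batches_shuffle_deterministic():
    a = make_batches(np.arange(100), 7, shuffle=True, rng=3)
    b = make_batches(np.arange(100), 7, shuffle=True, rng=3)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)
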