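"""Attention aggregation, region statistics and heatmap rendering."""

import numpy as np
import pandas as pd
import pytest

from histoage.attention import (AttentionResult, region_attention_summary,
                                region_comparison, render_heatmap,
                                tile_region_label)


def result(weights, coords=None):
    weights = np.asarray(weights, dtype=float)
    m = weights.shape[1]
    if coords is None:
        coords = np.stack([np.arange(m) * 256, np.zeros(m, dtype=int)], axis=1)
    return AttentionResult("s1", coords, weights)


def test_head_mean_is_arithmetic_mean_of_heads():
    res = result([[0.2, 0.8], [0.6, 0.4]])
    np.testing.assert_allclose(res.head_mean, [0.4, 0.6])


# ------------------------------------------------------------- tile labels
def test_tile_fully_inside_region_gets_its_label():
    ann = np.full((256, 512), 2, dtype=np.uint8)
    ann[:, 256:] = 3
    labels = tile_region_label(np.array([[0, 0], [256, 0]]), ann)
    np.testing.assert_array_equal(labels, [2, 3])


def test_majority_label_wins_60_40():
    ann = np.zeros((256, 256), dtype=np.uint8)
    ann[:, :154] = 1   # ~60%
    ann[:, 154:] = 2   # ~40%
    assert tile_region_label(np.array([[0, 0]]), ann)[0] == 1


def test_exact_tie_breaks_to_smaller_label_id():
    ann = np.zeros((256, 256), dtype=np.uint8)
    ann[:, :128] = 2
    ann[:, 128:] = 1
    # brute-force pixel count: both labels cover 256*128 pixels
    assert (ann == 1).sum() == (ann == 2).sum()
    assert tile_region_label(np.array([[0, 0]]), ann)[0] == 1


def test_mostly_unlabeled_tile_unassigned():
    ann = np.zeros((256, 256), dtype=np.uint8)
    ann[:64, :64] = 1  # ~6% labeled
    assert tile_region_label(np.array([[0, 0]]), ann)[0] == -1


def test_annotation_not_covering_slide_rejected():
    with pytest.raises(ValueError):
        tile_region_label(np.array([[256, 0]]), np.zeros((256, 256), dtype=np.uint8))


# --------------------------------------------------------- region medians
def test_uniform_weights_give_equal_region_medians():
    res = result([np.full(6, 1 / 6), np.full(6, 1 / 6)])
    labels = np.array([1, 1, 2, 2, 3, 3])
    df = region_attention_summary([res], [labels])
    assert df["median_attention"].nunique() == 1


def test_region_median_matches_hand_computation():
    res = result([[0.1, 0.2, 0.9, 0.0], [0.1, 0.2, 0.9, 0.0]])
    labels = np.array([5, 5, 5, 7])
    df = region_attention_summary([res], [labels])
    assert df.set_index("region").loc[5, "median_attention"] == pytest.approx(0.2)


def test_absent_region_is_missing_not_zero():
    res = result([[0.5, 0.5], [0.5, 0.5]])
    df = region_attention_summary([res], [np.array([1, 1])],
                                  legend={1: "gm", 2: "wm"})
    assert set(df["region"]) == {"gm"}


def test_region_medians_permutation_invariant():
    rng = np.random.default_rng(0)
    w = rng.dirichlet(np.ones(12))
    labels = rng.integers(1, 4, 12)
    base = region_attention_summary([result([w, w])], [labels])
    perm = rng.permutation(12)
    res_p = result([w[perm], w[perm]])
    permuted = region_attention_summary([res_p], [labels[perm]])
    merged = base.merge(permuted, on="region")
    np.testing.assert_allclose(merged["median_attention_x"],
                               merged["median_attention_y"])


# ------------------------------------------------------------- comparison
def test_identical_groups_anova_f_zero():
    df = pd.DataFrame({"region": list("aabb"), "median_attention": [1.0, 1, 1, 1]})
    out = region_comparison(df)
    assert out["anova_f"] == 0.0


def test_anova_f_closed_form():
    # between SS 54 on 2 df, within SS 6 on 6 df -> F = 27
    df = pd.DataFrame({
        "region": np.repeat(["a", "b", "c"], 3),
        "median_attention": [1.0, 2, 3, 4, 5, 6, 7, 8, 9],
    })
    out = region_comparison(df)
    assert out["anova_f"] == pytest.approx(27.0)


def test_singleton_region_dropped_with_record():
    df = pd.DataFrame({
        "region": ["a", "a", "b", "b", "c"],
        "median_attention": [1.0, 2, 4, 5, 9],
    })
    out = region_comparison(df)
    assert out["dropped"] == ["c"]


def test_tukey_pairs_symmetric():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({
        "region": np.repeat(["a", "b", "c"], 8),
        "median_attention": np.concatenate(
            [rng.normal(mu, 0.1, 8) for mu in (0.0, 0.5, 1.0)]),
    })
    tukey = region_comparison(df)["tukey"]
    pairs = set(map(tuple, tukey[["group1", "group2"]].to_numpy()))
    assert len(pairs) == 3  # each unordered pair appears once


# ---------------------------------------------------------------- heatmap
def test_uniform_attention_renders_uniform_mid_color():
    slide = np.full((256, 512, 3), 255, dtype=np.uint8)
    res = result([[0.5, 0.5], [0.5, 0.5]], coords=np.array([[0, 0], [256, 0]]))
    img = render_heatmap(res, slide)
    np.testing.assert_array_equal(img[:, :256], img[:, 256:])


def test_single_max_tile_is_reddest():
    slide = np.full((256, 768, 3), 255, dtype=np.uint8)
    res = result([[0.1, 0.8, 0.1], [0.1, 0.8, 0.1]],
                 coords=np.array([[0, 0], [256, 0], [512, 0]]))
    img = render_heatmap(res, slide)
    redness = [int(img[128, 128 + k * 256, 0]) - int(img[128, 128 + k * 256, 2])
               for k in range(3)]
    assert np.argmax(redness) == 1


def test_render_deterministic_bytes():
    rng = np.random.default_rng(2)
    slide = rng.integers(0, 255, (256, 512, 3)).astype(np.uint8)
    w = rng.dirichlet(np.ones(2))
    res = result([w, w], coords=np.array([[0, 0], [256, 0]]))
    assert render_heatmap(res, slide).tobytes() == render_heatmap(res, slide).tobytes()


def test_minmax_normalization_preserves_region_rank_order():
    rng = np.random.default_rng(3)
    w = rng.dirichlet(np.ones(9))
    labels = rng.integers(1, 4, 9)
    raw = region_attention_summary([result([w, w])], [labels])
    span = np.ptp(w)
    scaled = (w - w.min()) / span
    norm = region_attention_summary([result([scaled, scaled])], [labels])
    merged = raw.merge(norm, on="region")
    order_raw = merged["median_attention_x"].rank()
    order_norm = merged["median_attention_y"].rank()
    np.testing.assert_array_equal(order_raw, order_norm)


def test_out_of_bounds_coordinates_rejected():
    slide = np.full((256, 256, 3), 255, dtype=np.uint8)
    res = result([[1.0], [1.0]], coords=np.array([[256, 0]]))
    with pytest.raises(ValueError):
        render_heatmap(res, slide)
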