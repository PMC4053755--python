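"""Exponential binning, per-bin moments, bootstrap and sign statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epistat import binning_stats as bs
from epistat.epistasis_core import pair_stats_from_logs


def make_pairs(G01, G10, E):
    G01 = np.asarray(G01, float)
    G10 = np.asarray(G10, float)
    return pair_stats_from_logs(G01, G10, G01 + G10 + np.asarray(E, float))


@pytest.mark.parametrize(
    "G, n",
    [
        (-0.3, -1),        # inside [-0.5, -0.25)
        (-1.0, 0),         # left edge of the outermost bin is included
        (-0.5, -1),        # shared edge belongs to the inner bin
        (-0.004, -7),      # [-0.0078125, -0.00390625)
        (-0.00390625, bs.OUT_OF_RANGE),   # inner limit itself is out
        (-1.5, bs.OUT_OF_RANGE),
        (0.2, bs.OUT_OF_RANGE),
        (np.nan, bs.OUT_OF_RANGE),
        (-np.inf, bs.OUT_OF_RANGE),
    ],
)
def test_bin_index_edges_and_range(G, n):
    assert bs.bin_index(G) == n


def test_bin_index_mirrored_beneficial_side():
    assert bs.bin_index(0.3, side="beneficial") == -1
    assert bs.bin_index(1.0, side="beneficial") == 0
    assert bs.bin_index(-0.3, side="beneficial") == bs.OUT_OF_RANGE


def test_grid_validation_rejects_unsorted_exponents():
    with pytest.raises(ValueError):
        bs.BinGrid(exponents=(0, -1))


def test_bin_counts_plus_excluded_equals_input():
    rng = np.random.default_rng(0)
    G01 = -np.exp(rng.uniform(np.log(1e-4), np.log(2.0), 5000))
    G10 = -np.exp(rng.uniform(np.log(1e-4), np.log(2.0), 5000))
    pairs = make_pairs(G01, G10, np.zeros(5000))
    pairs.loc[:49, "lethal"] = True
    out = bs.compute_bin_stats(pairs, B=0)
    assert out["count"].sum() + out.attrs["n_out_of_range"] + out.attrs["n_lethal"] == 5000


def test_symmetric_pooling_merges_mirror_bins():
    pairs = make_pairs([-0.3, -0.08], [-0.08, -0.3], [0.1, -0.1])
    out = bs.compute_bin_stats(pairs, B=0)
    assert len(out) == 1
    assert out.iloc[0]["count"] == 2
    assert out.index[0] == (-3, -1)


def test_closed_form_variances_per_bin():
    a = 0.37
    pairs = make_pairs([-0.3] * 2, [-0.3] * 2, [a, -a])
    out = bs.compute_bin_stats(pairs, B=50, seed=0)
    row = out.iloc[0]
    assert row["mean_E"] == pytest.approx(0.0, abs=1e-12)
    assert row["var_E"] == pytest.approx(2 * a * a)  # unbiased variance of {a, -a}
    same = make_pairs([-0.3] * 5, [-0.3] * 5, [0.2] * 5)
    row = bs.compute_bin_stats(same, B=50, seed=0).iloc[0]
    assert row["var_E"] == 0 and row["ci25"] == 0 and row["ci75"] == 0


def test_var_estimate_and_order_invariance():
    rng = np.random.default_rng(7)
    v = 0.04
    E = rng.normal(0, np.sqrt(v), 10_000)
    pairs = make_pairs(np.full(E.size, -0.3), np.full(E.size, -0.3), E)
    out = bs.compute_bin_stats(pairs, B=0)
    assert out.iloc[0]["var_E"] == pytest.approx(v, rel=0.05)
    perm = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
    out2 = bs.compute_bin_stats(perm, B=0)
    assert out2.iloc[0]["var_E"] == pytest.approx(out.iloc[0]["var_E"], abs=1e-15)


def bootstrap_oracle(E, B, seed, n01, n10, chunk=200):
    """Independent re-implementation of the documented bootstrap contract."""
    rng = np.random.default_rng([seed, 913, n01 + 256, n10 + 256])
    variances = []
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, E.size, size=(b, E.size))
        for row in idx:
            x = E[row]
            m = x.mean()
            variances.append(((x - m) ** 2).sum() / (x.size - 1))
        done += b
    q25, q75 = np.percentile(variances, [25, 75])
    return q25, q75


def test_bootstrap_quantiles_match_independent_oracle():
    rng = np.random.default_rng(3)
    E = rng.normal(0, 0.2, 400)
    pairs = make_pairs(np.full(E.size, -0.3), np.full(E.size, -0.3), E)
    out = bs.compute_bin_stats(pairs, B=300, seed=11)
    q25, q75 = bootstrap_oracle(E, 300, 11, -1, -1)
    assert out.iloc[0]["ci25"] == pytest.approx(q25, abs=1e-12)
    assert out.iloc[0]["ci75"] == pytest.approx(q75, abs=1e-12)
    # and the run is reproducible bit for bit
    again = bs.compute_bin_stats(pairs, B=300, seed=11)
    pd.testing.assert_frame_equal(out, again)


@pytest.mark.parametrize(
    "G01, G10, kept, G",
    [
        (-0.50, -0.45, True, -0.475),
        (-0.50, -0.30, False, None),
        (-0.45, -0.50, True, -0.475),  # symmetric in the two arguments
    ],
)
def test_select_diagonal_rule(G01, G10, kept, G):
    pairs = make_pairs([G01], [G10], [0.0])
    out = bs.select_diagonal(pairs, tolerance=0.2)
    assert (len(out) == 1) == kept
    if kept:
        assert out.iloc[0]["G"] == pytest.approx(G)


def test_sign_probability_counts_and_degenerate_sem():
    pairs = make_pairs([-0.3] * 4, [-0.3] * 4, [0.9, -0.1, 0.0, -0.2])
    diag = bs.select_diagonal(pairs)
    out = bs.sign_epistasis_probability(diag, B=200, seed=0)
    assert out.iloc[0]["S"] == pytest.approx(0.25)
    none = make_pairs([-0.3] * 4, [-0.3] * 4, [-0.1] * 4)
    out0 = bs.sign_epistasis_probability(bs.select_diagonal(none), B=200, seed=0)
    assert out0.iloc[0]["S"] == 0 and out0.iloc[0]["sem"] == 0


def test_sign_probability_matches_gaussian_flip_oracle():
    """On the exact diagonal, sign epistasis <=> E > |G|, so S = 1 - Phi(|G|/sigma)."""
    rng = np.random.default_rng(5)
    sigma = 0.3
    for G in (-0.3, -0.09):
        E = rng.normal(0, sigma, 40_000)
        pairs = make_pairs(np.full(E.size, G), np.full(E.size, G), E)
        out = bs.sign_epistasis_probability(bs.select_diagonal(pairs), B=50, seed=0)
        expected = 1 - stats.norm.cdf(abs(G) / sigma)
        assert out["S"].iloc[0] == pytest.approx(expected, abs=0.01)


def test_sign_probability_flat_when_sigma_proportional_to_G():
    """If sigma(G,G) scales like |G| the flip probability is scale-free,
    while the square-root law makes it fall off with |G|."""
    rng = np.random.default_rng(9)
    Gs = np.repeat([-0.05, -0.1, -0.2, -0.4], 30_000)
    for law, check in (
        (lambda g: 0.8 * np.abs(g), "flat"),
        (lambda g: np.sqrt(0.2 * np.abs(g)), "decreasing"),
    ):
        E = rng.normal(0, law(Gs))
        pairs = make_pairs(Gs, Gs, E)
        out = bs.sign_epistasis_probability(
            bs.select_diagonal(pairs), B=100, seed=0
        ).sort_values("mean_G")  # most deleterious first
        S = out["S"].to_numpy()
        if check == "flat":
            assert np.ptp(S) < 0.02
        else:
            assert np.all(np.diff(S) > 0)  # S grows as |G| shrinks
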