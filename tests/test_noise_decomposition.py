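"""Mock-dataset construction and variance deconvolution."""

import numpy as np
import pandas as pd
import pytest

from epistat import binning_stats as bs
from epistat import epistasis_core as ec
from epistat import io_sga
from epistat import noise_decomposition as nd
from epistat import synthetic_data as sd

from conftest import make_dataset


def test_config_validation():
    with pytest.raises(ValueError, match="df > 2"):
        nd.MockConfig(df=2.0)
    with pytest.raises(ValueError):
        nd.MockConfig(n_mocks=0)
    nd.MockConfig(df=1.0, gaussian=True)  # gaussian shifts need no df


def test_zero_sd_mock_is_exactly_multiplicative():
    ds = make_dataset(
        [
            {"query_id": "A", "array_id": "B", "g01": 0.9, "g10": 0.8, "g11": 0.5,
             "sd01": 0.0, "sd10": 0.0, "sd11": 0.0},
            {"query_id": "A", "array_id": "C", "g01": 0.9, "g10": 0.6, "g11": 0.7,
             "sd01": 0.0, "sd10": 0.0, "sd11": 0.0},
        ]
    )
    mock = nd.build_mock_dataset(ds, nd.MockConfig(seed=0), 0)
    assert np.allclose(mock.frame["g11"], mock.frame["g01"] * mock.frame["g10"])
    E = ec.pair_stats(mock)["E"]
    assert np.allclose(E, 0.0)


def test_records_without_uncertainty_are_excluded_and_counted():
    ds = make_dataset(
        [
            {"query_id": "A", "array_id": "B"},
            {"query_id": "C", "array_id": "D", "sd11": np.nan},
        ]
    )
    mock = nd.build_mock_dataset(ds, nd.MockConfig(seed=0), 0)
    assert len(mock) == 1
    assert mock.filter_log["no_uncertainty"] == 1


def test_mock_seeding_contract():
    ds = make_dataset(
        [{"query_id": "A", "array_id": "B", "g01": 0.9, "g10": 0.8, "g11": 0.72}]
    )
    cfg = nd.MockConfig(seed=5)
    m0a = nd.build_mock_dataset(ds, cfg, 0).frame
    m0b = nd.build_mock_dataset(ds, cfg, 0).frame
    m1 = nd.build_mock_dataset(ds, cfg, 1).frame
    pd.testing.assert_frame_equal(m0a, m0b)
    assert not np.allclose(m0a["g11"], m1["g11"])


def test_mock_shift_sd_matches_reported_sd():
    """Monte-Carlo check of the scale contract: the t shift's standard
    deviation equals the record's reported uncertainty."""
    n = 100_000
    frame = pd.DataFrame(
        {
            "query_id": [f"q{i}" for i in range(n)],
            "array_id": [f"a{i}" for i in range(n)],
            "g01": 1.0, "g10": 1.0, "g11": 1.0,
            "sd01": 0.0, "sd10": 0.0, "sd11": 0.05, "n_reps": 4,
        }
    )
    ds = io_sga.Dataset(frame=frame)
    mock = nd.build_mock_dataset(ds, nd.MockConfig(df=5, seed=2), 0)
    shift = mock.frame["g11"].to_numpy() - 1.0
    assert shift.std() == pytest.approx(0.05, rel=0.03)
    assert abs(shift.mean()) < 3 * 0.05 / np.sqrt(n)


def test_single_shift_shared_across_pairs_of_a_gene():
    ds = make_dataset(
        [
            {"query_id": "A", "array_id": "B", "g01": 0.9, "sd01": 0.05},
            {"query_id": "A", "array_id": "C", "g01": 0.9, "sd01": 0.05},
        ]
    )
    mock = nd.build_mock_dataset(ds, nd.MockConfig(seed=1), 0)
    g = mock.frame["g01"].to_numpy()
    assert g[0] == g[1] != 0.9


def test_noise_variance_zero_for_zero_sd():
    rows = [
        {"query_id": f"q{i}", "array_id": f"a{i}", "g01": 0.7, "g10": 0.6,
         "g11": 0.42, "sd01": 0.0, "sd10": 0.0, "sd11": 0.0}
        for i in range(100)
    ]
    ds = make_dataset(rows)
    nv = nd.noise_variance_by_bin(ds, nd.MockConfig(n_mocks=3, seed=0))
    assert np.allclose(nv["var_noise"], 0.0)


def test_doubling_sd_quadruples_noise_variance():
    rng = np.random.default_rng(4)
    n = 4000
    g01 = rng.uniform(0.55, 0.9, n)
    g10 = rng.uniform(0.55, 0.9, n)
    rows = pd.DataFrame(
        {
            "query_id": [f"q{i}" for i in range(n)],
            "array_id": [f"a{i}" for i in range(n)],
            "g01": g01, "g10": g10, "g11": g01 * g10,
            "sd01": 0.01, "sd10": 0.01, "sd11": 0.01, "n_reps": 4,
        }
    )
    ds = io_sga.Dataset(frame=rows)
    ds2 = io_sga.Dataset(frame=rows.assign(sd01=0.02, sd10=0.02, sd11=0.02))
    cfg = nd.MockConfig(n_mocks=5, seed=3)
    v1 = nd.noise_variance_by_bin(ds, cfg)["var_noise"]
    v2 = nd.noise_variance_by_bin(ds2, cfg)["var_noise"]
    # edge bins hold a handful of boundary records; the median over bins
    # is robust to them
    ratio = (v2 / v1).dropna()
    assert 3.2 < ratio.median() < 4.8


def test_decompose_arithmetic_floor_and_alignment():
    idx = pd.MultiIndex.from_tuples([(-1, -1), (0, 0)], names=["n01", "n10"])
    obs = pd.DataFrame(
        {"count": [100, 100], "var_E": [0.010, 0.003],
         "ci25": [0.009, 0.0025], "ci75": [0.011, 0.0035],
         "low_confidence": [False, False]},
        index=idx,
    )
    noise = pd.DataFrame({"var_noise": [0.004, 0.004]}, index=idx)
    dec = nd.decompose_variance(obs, noise)
    assert dec.loc[(-1, -1), "var_bio"] == pytest.approx(0.006)
    assert dec.loc[(-1, -1), "ratio"] == pytest.approx(2.5)
    assert dec.loc[(0, 0), "var_bio"] == 0.0
    assert dec.loc[(0, 0), "ratio"] == pytest.approx(0.75)
    with pytest.raises(ValueError, match="not aligned"):
        nd.decompose_variance(obs, noise.iloc[:1])


def _decompose_synthetic(noise_cfg, seed=21):
    cfg = sd.SyntheticConfig(n_genes=800, n_pairs=60_000, seed=seed)
    ds, truth = sd.generate_dataset(cfg)
    ds = io_sga.deduplicate_pairs(io_sga.apply_filters(ds))
    pairs = ec.pair_stats(ds)
    bins = bs.compute_bin_stats(pairs, B=300, seed=seed)
    nv = nd.noise_variance_by_bin(ds, noise_cfg)
    return nd.decompose_variance(bins, nv.reindex(bins.index))


def test_recovered_biological_variance_tracks_generator_truth():
    """End-to-end: var_bio per strongly deleterious bin approximates the
    generator's harmonic surface c*2|ab|/(a+b)."""
    dec = _decompose_synthetic(nd.MockConfig(n_mocks=5, seed=21), seed=21)
    checked = 0
    for (i, j), row in dec.iterrows():
        if i < -3 or row["count"] < 30:
            continue
        G01, G10 = -1.5 * 2.0 ** (i - 1), -1.5 * 2.0 ** (j - 1)
        expect = 0.079 * 2 * abs(G01 * G10) / (abs(G01) + abs(G10))
        assert row["var_bio"] == pytest.approx(expect, rel=0.6)
        checked += 1
    assert checked >= 3


def test_distribution_robustness_gaussian_vs_t():
    """Because variances add, swapping t shifts for gaussian shifts of the
    same sd changes the recovered biological variance only marginally."""
    dec_t = _decompose_synthetic(nd.MockConfig(n_mocks=5, seed=8), seed=8)
    dec_g = _decompose_synthetic(nd.MockConfig(n_mocks=5, seed=8, gaussian=True), seed=8)
    big = dec_t["var_bio"] > 0.005
    rel = ((dec_t["var_bio"] - dec_g["var_bio"]).abs() / dec_t["var_bio"])[big]
    assert (rel < 0.25).mean() >= 0.9
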