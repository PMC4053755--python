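"""Noise-only mock datasets and variance deconvolution.

Measurement error in growth rates masquerades as epistasis: even under an
exactly multiplicative world, noisy g01, g10, g11 produce a spread of
apparent E values.  To quantify that contribution we build mock datasets
in which biology is exactly multiplicative — singles keep their reported
growth rates, every double is set to g01*g10 — and then shift every growth
rate by an independent Student's-t draw whose standard deviation equals
the record's reported uncertainty.  Heavy-tailed t shifts emulate the
occasional gross measurement error; because variances add for independent
errors, the per-bin variance of E in the mocks estimates the
noise-generated part of the observed variance regardless of the exact
shift distribution, and

    var_bio = max(var_obs - var_noise, 0)

is the biologically generated part.  The characteristic interaction
strength is sqrt(var_bio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import binning_stats, epistasis_core, io_sga

__all__ = [
    "MockConfig",
    "build_mock_dataset",
    "noise_variance_by_bin",
    "decompose_variance",
]


@dataclass(frozen=True)
class MockConfig:
    """Configuration of the noise-only mock ensemble.

    ``df`` is the Student's-t degrees of freedom of the shifts (must be
    > 2 so the variance-matching scale exists); ``scale_mode`` chooses
    whether the reported sd sets the shift's standard deviation
    (``"sd"``, default — required for variance additivity) or its raw
    scale parameter (``"scale"``).  ``gaussian`` swaps t shifts for
    normal ones of equal sd (robustness checks).
    """

    n_mocks: int = 9
    df: float = 5.0
    scale_mode: str = "sd"
    gaussian: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mocks < 1:
            raise ValueError("n_mocks must be >= 1")
        if not self.gaussian and self.df <= 2:
            raise ValueError(
                "Student's-t shifts need df > 2 for a finite variance"
            )
        if self.scale_mode not in ("sd", "scale"):
            raise ValueError(f"unknown scale_mode: {self.scale_mode!r}")


def _shift(rng: np.random.Generator, sd: np.ndarray, cfg: MockConfig) -> np.ndarray:
    """Random shifts with standard deviation equal to ``sd`` elementwise."""
    if cfg.gaussian:
        return rng.normal(0.0, 1.0, size=sd.shape) * sd
    t = rng.standard_t(cfg.df, size=sd.shape)
    if cfg.scale_mode == "sd":
        # standard_t has variance df/(df-2); rescale so the shift sd == sd
        t = t / np.sqrt(cfg.df / (cfg.df - 2.0))
    return t * sd


def build_mock_dataset(ds: io_sga.Dataset, cfg: MockConfig, mock_index: int) -> io_sga.Dataset:
    """One no-epistasis mock: multiplicative doubles plus reported-sd noise.

    Records lacking any of the three uncertainties are excluded up front
    (logged under ``no_uncertainty``).  Each gene's single-mutant growth
    rate receives one shift shared across every pair that references it,
    mirroring how a single measured fitness enters many pairs; each
    double receives its own shift.  Randomness is fully determined by
    ``(cfg.seed, mock_index)``; different indices give independent mocks.
    """
    f = ds.frame
    has_sd = (
        np.isfinite(f["sd01"].to_numpy(float))
        & np.isfinite(f["sd10"].to_numpy(float))
        & np.isfinite(f["sd11"].to_numpy(float))
    )
    f = f.loc[has_sd].reset_index(drop=True)
    rng = np.random.default_rng([int(cfg.seed), 929, int(mock_index)])

    # one noisy value per gene-side; first occurrence defines (g, sd)
    q = f[["query_id", "g01", "sd01"]].drop_duplicates("query_id").set_index("query_id")
    a = f[["array_id", "g10", "sd10"]].drop_duplicates("array_id").set_index("array_id")
    q_noisy = q["g01"].to_numpy(float) + _shift(rng, q["sd01"].to_numpy(float), cfg)
    a_noisy = a["g10"].to_numpy(float) + _shift(rng, a["sd10"].to_numpy(float), cfg)
    g01 = pd.Series(q_noisy, index=q.index).reindex(f["query_id"]).to_numpy()
    g10 = pd.Series(a_noisy, index=a.index).reindex(f["array_id"]).to_numpy()

    null11 = f["g01"].to_numpy(float) * f["g10"].to_numpy(float)
    g11 = null11 + _shift(rng, f["sd11"].to_numpy(float), cfg)

    mock = f.assign(g01=g01, g10=g10, g11=g11)
    out = io_sga.Dataset(
        frame=mock,
        provenance=f"mock[{mock_index}] of {ds.provenance}",
        filter_log={"no_uncertainty": int((~has_sd).sum())},
    )
    # shifted values <= 0 are removed exactly as in the real analysis
    return io_sga.apply_filters(out)


def noise_variance_by_bin(
    ds: io_sga.Dataset,
    cfg: MockConfig,
    grid: binning_stats.BinGrid = binning_stats.DEFAULT_GRID,
) -> pd.DataFrame:
    """Across-mock mean of per-bin var(E) under the no-epistasis null.

    Runs the full epistasis + binning pipeline on each of ``cfg.n_mocks``
    mocks.  Returns one row per bin seen in any mock: ``var_noise`` (mean
    over mocks), ``sd_mocks`` (spread over mocks, diagnostic) and
    ``n_mocks`` (how many mocks populated the bin).
    """
    per_mock = []
    for i in range(cfg.n_mocks):
        mock = build_mock_dataset(ds, cfg, i)
        stats = binning_stats.compute_bin_stats(
            epistasis_core.pair_stats(mock), grid, B=0
        )
        per_mock.append(stats["var_E"].rename(i))
    wide = pd.concat(per_mock, axis=1)
    out = pd.DataFrame(
        {
            "var_noise": wide.mean(axis=1),
            "sd_mocks": wide.std(axis=1, ddof=1) if cfg.n_mocks > 1 else np.nan,
            "n_mocks": wide.notna().sum(axis=1),
        }
    )
    return out.sort_index()


def decompose_variance(obs: pd.DataFrame, noise: pd.DataFrame, z_null: float = 1.645) -> pd.DataFrame:
    """Split observed per-bin variance into noise and biological parts.

    ``obs`` is a bin-stats table (``compute_bin_stats``), ``noise`` comes
    from :func:`noise_variance_by_bin` on the same grid.  Any bin present
    in one table but not the other raises a ValueError naming the bins.

    Output columns: var_obs, var_noise, var_bio = max(var_obs -
    var_noise, 0), sigma_bio = sqrt(var_bio), ratio = var_obs/var_noise,
    and ``null_consistent`` — whether the excess over noise is within
    ``z_null`` standard errors of zero.  The standard error combines the
    bootstrap sd of var_obs (estimated from the 25-75% quantile spread as
    IQR/1.349) with the standard error of the noise estimate itself
    (``sd_mocks / sqrt(n_mocks)`` when the noise table carries the mock
    spread); the default z = 1.645 is a one-sided 5% false-positive
    level per bin.
    """
    missing_in_noise = obs.index.difference(noise.index)
    missing_in_obs = noise.index.difference(obs.index)
    if len(missing_in_noise) or len(missing_in_obs):
        raise ValueError(
            "bin grids are not aligned; "
            f"missing in noise table: {list(missing_in_noise)}; "
            f"missing in observed table: {list(missing_in_obs)}"
        )
    var_obs = obs["var_E"].astype(float)
    var_noise = noise["var_noise"].reindex(obs.index).astype(float)
    var_bio = (var_obs - var_noise).clip(lower=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = var_obs / var_noise
    sigma_boot = (obs["ci75"] - obs["ci25"]) / 1.349
    se2 = sigma_boot.astype(float) ** 2
    if "sd_mocks" in noise.columns and "n_mocks" in noise.columns:
        sem_noise = (
            noise["sd_mocks"].reindex(obs.index).astype(float)
            / np.sqrt(noise["n_mocks"].reindex(obs.index).astype(float))
        )
        se2 = se2 + sem_noise.fillna(0.0) ** 2
    null_consistent = (var_obs - var_noise) <= z_null * np.sqrt(se2)
    out = pd.DataFrame(
        {
            "count": obs["count"],
            "var_obs": var_obs,
            "var_noise": var_noise,
            "var_bio": var_bio,
            "sigma_bio": np.sqrt(var_bio),
            "ratio": ratio,
            "null_consistent": null_consistent,
            "low_confidence": obs["low_confidence"],
        }
    )
    for k in ("n_lethal", "n_out_of_range", "n_pairs"):
        if k in obs.attrs:
            out.attrs[k] = obs.attrs[k]
    return out
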