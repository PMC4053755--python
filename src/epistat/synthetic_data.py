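"""Synthetic SGA-like double-mutant datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes so
that every downstream stage can be tested without external downloads:

* single-mutant relative fitnesses drawn from a mixture — most genes
  near-neutral, a log-uniform deleterious tail, a small beneficial
  fraction, and a small lethal fraction;
* for each sampled gene pair a latent epistasis value E with zero (or
  configured) mean and variance given by a tunable scaling surface
  evaluated at the true single-mutant log effects, drawn from a Gaussian
  core plus a negative-exponential tail (the heavy left tail of strong
  negative interactions seen in real interaction data);
* the double-mutant growth rate g11 = g01 * g10 * 2^E (multiplicative
  null times the epistasis factor), with a configurable fraction of
  synthetic-lethal doubles;
* replicate-level measurement noise: every growth rate is measured
  ``n_reps`` times with Student's-t errors; the recorded value is the
  replicate mean and the recorded uncertainty the standard error of that
  mean (so downstream noise deconvolution faces realistic, itself-noisy
  uncertainty estimates).

All randomness flows from ``SyntheticConfig.seed``; identical configs
reproduce identical datasets (and files) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io_sga
from .scaling_fit import surface_basis

__all__ = ["EffectMix", "NoiseModel", "SyntheticConfig", "GroundTruth",
           "generate_dataset", "generate_null_dataset", "write_raw_table"]


@dataclass(frozen=True)
class EffectMix:
    """Mixture over single-mutant fitness classes (weights are normalized).

    Neutral genes have log growth uniform in +/- ``neutral_halfwidth``;
    deleterious genes have |G| log-uniform over [del_min, del_max];
    beneficial genes have G uniform in (0, beneficial_max]; lethal genes
    have growth rate exactly 0.
    """

    w_neutral: float = 0.79
    w_deleterious: float = 0.19
    w_beneficial: float = 0.01
    w_lethal: float = 0.01
    neutral_halfwidth: float = 0.01
    del_min: float = 0.004
    del_max: float = 1.0
    beneficial_max: float = 0.03

    def weights(self) -> np.ndarray:
        w = np.array([self.w_neutral, self.w_deleterious,
                      self.w_beneficial, self.w_lethal], float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mixture weights must be non-negative, not all zero")
        return w / w.sum()


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement noise, t-distributed.

    Growth rates are colony-size ratios, so measurement error is
    multiplicative: each replicate has sd ``rel * true value`` plus an
    optional absolute floor ``abs``.  ``n_reps`` replicates are averaged
    into the reported value.
    """

    rel: float = 0.05
    abs: float = 0.0
    n_reps: int = 4
    df: float = 5.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("replicate count must be >= 1")
        if (self.rel > 0 or self.abs > 0) and self.df <= 2:
            raise ValueError("t noise needs df > 2")

    def replicate_sd(self, true_g: np.ndarray) -> np.ndarray:
        return self.rel * np.asarray(true_g, float) + self.abs


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic dataset."""

    n_genes: int = 1500
    n_pairs: int = 200_000
    effect_dist: EffectMix = field(default_factory=EffectMix)
    c_true: float = 0.079
    surface_model: str = "harmonic"
    tail_weight: float = 0.05
    mean_E: float = 0.0
    lethal_pair_fraction: float = 0.01
    beneficial_epistasis: bool = False
    #: double-mutant measurements: ~4 replicate colonies each
    noise: NoiseModel = field(default_factory=NoiseModel)
    #: single-mutant fitnesses are pinned down by genome-wide control
    #: crosses, so their effective replication is far higher
    noise_single: NoiseModel = field(
        default_factory=lambda: NoiseModel(rel=0.05, n_reps=64)
    )
    e_clip: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_true < 0:
            raise ValueError("c_true must be >= 0")
        if not 0 <= self.tail_weight <= 1:
            raise ValueError("tail_weight must be in [0, 1]")
        if not 0 <= self.lethal_pair_fraction <= 1:
            raise ValueError("lethal_pair_fraction must be in [0, 1]")
        if self.surface_model not in ("harmonic", "sqrt_product"):
            raise ValueError("surface_model must be harmonic or sqrt_product")


@dataclass
class GroundTruth:
    """Latent state of a generated dataset (for oracle comparisons)."""

    config: SyntheticConfig
    gene_g: pd.Series          # true single-mutant relative growth per gene
    true_E: np.ndarray         # latent epistasis per emitted pair
    true_g11: np.ndarray       # latent double-mutant growth per pair
    n_clipped: int = 0


def _draw_single_effects(n: int, mix: EffectMix, rng: np.random.Generator) -> np.ndarray:
    """True single-mutant relative growth rates for n genes."""
    cls = rng.choice(4, size=n, p=mix.weights())
    G = np.zeros(n)
    m = cls == 0
    G[m] = rng.uniform(-mix.neutral_halfwidth, mix.neutral_halfwidth, m.sum())
    m = cls == 1
    G[m] = -np.exp(rng.uniform(np.log(mix.del_min), np.log(mix.del_max), m.sum()))
    m = cls == 2
    G[m] = rng.uniform(0.0, mix.beneficial_max, m.sum())
    g = np.exp2(G)
    g[cls == 3] = 0.0
    return g


def _standardized_mixture(n: int, tail_weight: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance draws: Gaussian core + negative-exponential tail.

    The tail component is -(Exp(1)) (mean -1, var 1); the mixture is
    standardized in closed form, so the samples have exactly unit
    variance in expectation and negative skewness for tail_weight > 0.
    """
    w = tail_weight
    tail = rng.random(n) < w
    x = rng.normal(0.0, 1.0, n)
    x[tail] = -rng.exponential(1.0, tail.sum())
    mean = -w
    var = (1.0 + w) - w * w   # E[x^2] = (1-w) + 2w, minus mean^2
    return (x - mean) / np.sqrt(var)


def _measure(true_g: np.ndarray, noise: NoiseModel, rng: np.random.Generator):
    """Replicate measurements: (reported value, reported sd, n_reps).

    Reported value = replicate mean; reported sd = sample sd of the
    replicates / sqrt(n_reps), i.e. the standard error of the estimate —
    the quantity a mock-noise shift must match for variances to add.
    Truly lethal genotypes (growth 0) report 0 with zero uncertainty:
    absent colonies are unambiguous.
    """
    n = true_g.size
    if noise.rel == 0 and noise.abs == 0:
        return true_g.copy(), np.zeros(n), np.full(n, noise.n_reps)
    rep_sd = noise.replicate_sd(true_g)
    scale = rep_sd[:, None] / np.sqrt(noise.df / (noise.df - 2.0))
    reps = true_g[:, None] + scale * rng.standard_t(noise.df, size=(n, noise.n_reps))
    alive = true_g > 0
    value = np.where(alive, reps.mean(axis=1), 0.0)
    if noise.n_reps > 1:
        sd = np.where(alive, reps.std(axis=1, ddof=1) / np.sqrt(noise.n_reps), 0.0)
    else:
        sd = np.where(alive, rep_sd, 0.0)
    return value, sd, np.full(n, noise.n_reps)


def generate_dataset(cfg: SyntheticConfig) -> tuple[io_sga.Dataset, GroundTruth]:
    """Generate a raw-table-style dataset plus its latent ground truth.

    Pairs are sampled without replacement from all unordered gene pairs.
    Latent E has variance equal to the configured surface at the true
    (G01, G10); pairs involving a beneficial single get E = 0 unless
    ``beneficial_epistasis`` is enabled; pairs involving a lethal single,
    and the configured fraction of synthetic-lethal pairs, get g11 = 0.
    |E| draws beyond ``e_clip`` are clipped and counted in
    ``GroundTruth.n_clipped``.
    """
    rng = np.random.default_rng([int(cfg.seed), 947])
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    gene_g = _draw_single_effects(cfg.n_genes, cfg.effect_dist, rng)

    n_all = cfg.n_genes * (cfg.n_genes - 1) // 2
    if cfg.n_pairs > n_all:
        raise ValueError(f"n_pairs={cfg.n_pairs} exceeds available pairs ({n_all})")
    flat = rng.choice(n_all, size=cfg.n_pairs, replace=False)
    # unrank the upper-triangle index (i < j)
    i = (cfg.n_genes - 2 - np.floor(
        np.sqrt(-8.0 * flat + 4.0 * cfg.n_genes * (cfg.n_genes - 1) - 7) / 2.0 - 0.5
    )).astype(np.int64)
    j = (flat + i + 1 - i * (2 * cfg.n_genes - i - 1) // 2).astype(np.int64)

    g01 = gene_g[i]
    g10 = gene_g[j]
    with np.errstate(divide="ignore"):
        G01 = np.where(g01 > 0, np.log2(np.where(g01 > 0, g01, 1.0)), -np.inf)
        G10 = np.where(g10 > 0, np.log2(np.where(g10 > 0, g10, 1.0)), -np.inf)

    viable = (g01 > 0) & (g10 > 0)
    var = np.zeros(cfg.n_pairs)
    var[viable] = cfg.c_true * surface_basis(G01[viable], G10[viable], cfg.surface_model)
    if not cfg.beneficial_epistasis:
        var[(G01 > 0) & (G10 > 0)] = 0.0
    E = cfg.mean_E + np.sqrt(var) * _standardized_mixture(cfg.n_pairs, cfg.tail_weight, rng)
    clip = np.abs(E) > cfg.e_clip
    E = np.clip(E, -cfg.e_clip, cfg.e_clip)
    E[~viable] = 0.0

    g11 = np.where(viable, g01 * g10 * np.exp2(E), 0.0)
    lethal_pair = viable & (rng.random(cfg.n_pairs) < cfg.lethal_pair_fraction)
    g11[lethal_pair] = 0.0

    # a gene's single-mutant fitness is measured once and shared by all
    # of its pairs, as in a real array; each double is measured per pair
    v_g, sd_g, _ = _measure(gene_g, cfg.noise_single, rng)
    v01, sd01 = v_g[i], sd_g[i]
    v10, sd10 = v_g[j], sd_g[j]
    v11, sd11, nr = _measure(g11, cfg.noise, rng)

    frame = pd.DataFrame(
        {
            "query_id": gene_ids[i],
            "array_id": gene_ids[j],
            "g01": v01,
            "g10": v10,
            "g11": v11,
            "sd01": sd01,
            "sd10": sd10,
            "sd11": sd11,
            "n_reps": nr,
        }
    )
    ds = io_sga.Dataset(frame=frame, provenance=f"synthetic(seed={cfg.seed})")
    truth = GroundTruth(config=cfg, gene_g=pd.Series(gene_g, index=gene_ids),
                        true_E=E, true_g11=g11, n_clipped=int(clip.sum()))
    return ds, truth


def generate_null_dataset(cfg: SyntheticConfig) -> io_sga.Dataset:
    """A no-epistasis dataset (c_true = 0, no tail) with noise kept on.

    The oracle input for false-positive control of the noise
    decomposition: all latent E are exactly zero.
    """
    null_cfg = replace(cfg, c_true=0.0, tail_weight=0.0, mean_E=0.0)
    ds, truth = generate_dataset(null_cfg)
    assert not truth.true_E.any()
    return ds


def write_raw_table(ds: io_sga.Dataset, path, dialect: io_sga.Dialect = io_sga.NATIVE_DIALECT) -> None:
    """Write the dataset as a TSV readable by ``io_sga.read_raw_table``."""
    io_sga.write_table(ds, path, dialect)
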