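"""Exponential binning of mutation pairs and per-bin epistasis moments.

Pairs are binned by the log growth effects of their two single mutants on a
grid of exponentially growing intervals: bin n covers [-2^n, -2^(n-1)),
left-closed, right-open, for integer n from -7 to 0 by default.  The grid
therefore spans log growth -1 to -2^-8 = -0.0039, i.e. relative growth-rate
effects from 0.5 to 0.997; exponential widths keep per-bin occupancy
roughly constant because mild effects vastly outnumber severe ones.

Per 2-D bin we report the count, mean and unbiased variance of the
geometric epistasis E, with 25-75% bootstrap quantiles of the variance,
plus the fraction of sign-epistatic pairs.  Bins (i, j) and (j, i) are
pooled by default since the variance is a symmetric function of the two
single-mutant effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scaling_fit import surface_basis

__all__ = [
    "OUT_OF_RANGE",
    "BinGrid",
    "bin_index",
    "compute_bin_stats",
    "select_diagonal",
    "diagonal_variance",
    "sign_epistasis_probability",
]

#: integer marker for log growth outside the grid (also NaN / lethal inputs)
OUT_OF_RANGE = -128

_SIGN_SET = frozenset({"single_sign", "reciprocal_sign"})


@dataclass(frozen=True)
class BinGrid:
    """Exponential bin grid over deleterious log growth effects.

    ``exponents`` lists the admissible n; bin n is [-2^n, -2^(n-1)).
    ``symmetric`` pools 2-D bin (i, j) with (j, i).  With ``side
    ='beneficial'`` in :func:`bin_index` the grid is mirrored to
    (2^(n-1), 2^n] for positive effects.
    """

    exponents: tuple = tuple(range(-7, 1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        exps = tuple(int(n) for n in self.exponents)
        if list(exps) != sorted(set(exps)):
            raise ValueError("exponents must be strictly increasing integers")
        object.__setattr__(self, "exponents", exps)

    @property
    def n_min(self) -> int:
        return self.exponents[0]

    @property
    def n_max(self) -> int:
        return self.exponents[-1]

    def edges(self, n: int) -> tuple[float, float]:
        """Left (inclusive) and right (exclusive) edge of bin n."""
        return (-(2.0 ** n), -(2.0 ** (n - 1)))

    def center(self, n: int) -> float:
        """Geometric-mean center of bin n (a negative log growth)."""
        return -np.sqrt(2.0 ** n * 2.0 ** (n - 1))


DEFAULT_GRID = BinGrid()


def bin_index(G, grid: BinGrid = DEFAULT_GRID, side: str = "deleterious"):
    """Map log growth values to bin exponents, or :data:`OUT_OF_RANGE`.

    Deleterious side: G in [-2^n, -2^(n-1)) -> n, i.e. n = ceil(log2(-G)),
    with the left (more negative) edge included.  The mirrored beneficial
    side bins positive G into (2^(n-1), 2^n].  Non-finite values and
    anything outside the grid map to :data:`OUT_OF_RANGE`.
    """
    G = np.asarray(G, dtype=float)
    scalar = G.ndim == 0
    G = np.atleast_1d(G)
    if side == "deleterious":
        x = -G
    elif side == "beneficial":
        x = G.copy()
    else:
        raise ValueError(f"unknown side: {side!r}")
    out = np.full(G.shape, OUT_OF_RANGE, dtype=np.int64)
    ok = np.isfinite(x) & (x > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.ceil(np.log2(np.where(ok, x, 1.0))).astype(np.int64)
    if side == "deleterious":
        # left edge -2^n belongs to bin n; exact powers already satisfy this
        inside = ok & (n >= grid.n_min) & (n <= grid.n_max) & (x > 2.0 ** (grid.n_min - 1))
    else:
        inside = ok & (n >= grid.n_min) & (n <= grid.n_max)
    out[inside] = n[inside]
    return int(out[0]) if scalar else out


def _bin_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-bin generator; offsets keep entries non-negative."""
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def _bootstrap_variances(E: np.ndarray, B: int, rng: np.random.Generator,
                         chunk: int = 200) -> np.ndarray:
    """B bootstrap replicates of the unbiased variance of E (chunked)."""
    n = E.size
    out = np.empty(B)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        out[done:done + b] = E[idx].var(axis=1, ddof=1)
        done += b
    return out


def compute_bin_stats(
    pairs: pd.DataFrame,
    grid: BinGrid = DEFAULT_GRID,
    B: int = 1000,
    seed: int = 0,
    min_count: int = 50,
) -> pd.DataFrame:
    """Per-bin moments of E over the 2-D (G01, G10) grid.

    Input is a PairStats table (``epistasis_core.pair_stats``).  Lethal and
    out-of-range pairs are excluded (their counts are attached as frame
    attrs ``n_lethal`` / ``n_out_of_range`` so that bin counts + both
    always equal the number of input pairs).  For each populated bin with
    at least two pairs: count, mean_E, unbiased var_E, the 25th/75th
    percentiles of the variance over ``B`` bootstrap resamples, the
    fraction of sign-epistatic pairs with its bootstrap SEM, and the mean
    G01/G10 of the contributing pairs.  ``B = 0`` skips the bootstrap.

    Bootstrap draws for bin (n01, n10) come from
    ``default_rng([seed, 913, n01 + 256, n10 + 256])`` in the order
    variance-resamples then sign-resamples, each as ``integers(0, n,
    size=(B, n))`` consumed in chunks of 200 rows; this contract is fixed
    so results are reproducible bit-for-bit and externally checkable.
    """
    usable = ~pairs["lethal"].to_numpy(bool)
    n01 = bin_index(pairs["G01"].to_numpy(float), grid)
    n10 = bin_index(pairs["G10"].to_numpy(float), grid)
    inside = usable & (n01 != OUT_OF_RANGE) & (n10 != OUT_OF_RANGE)
    swap = (n01 > n10) if grid.symmetric else np.zeros_like(n01, dtype=bool)
    lo = np.where(swap, n10, n01)
    hi = np.where(swap, n01, n10)
    Ga = pairs["G01"].to_numpy(float)
    Gb = pairs["G10"].to_numpy(float)
    sub = pd.DataFrame(
        {
            "n01": lo[inside],
            "n10": hi[inside],
            "E": pairs["E"].to_numpy(float)[inside],
            "sign": pairs["sign_class"].isin(_SIGN_SET).to_numpy()[inside],
            # pooled bins are unordered; sort the G pair to match (lo, hi)
            "G01": np.where(swap, Gb, Ga)[inside],
            "G10": np.where(swap, Ga, Gb)[inside],
            # per-pair surface bases, averaged per bin so that scaling
            # fits regress on the exact within-bin mean rather than the
            # basis at the mean G (the bases are concave, so the latter
            # is biased upward over wide bins)
            "basis_harmonic": surface_basis(Ga, Gb, "harmonic")[inside],
            "basis_sqrt_product": surface_basis(Ga, Gb, "sqrt_product")[inside],
        }
    )
    rows = []
    for (b01, b10), g in sub.groupby(["n01", "n10"], sort=True):
        E = g["E"].to_numpy()
        sign = g["sign"].to_numpy()
        row = {
            "n01": int(b01),
            "n10": int(b10),
            "count": E.size,
            "mean_G01": g["G01"].mean(),
            "mean_G10": g["G10"].mean(),
            "basis_harmonic": g["basis_harmonic"].mean(),
            "basis_sqrt_product": g["basis_sqrt_product"].mean(),
            "mean_E": E.mean(),
            "var_E": E.var(ddof=1) if E.size > 1 else np.nan,
            "sign_fraction": sign.mean(),
            "low_confidence": E.size < min_count,
        }
        if B > 0 and E.size > 1:
            rng = _bin_rng(seed, 913, b01 + 256, b10 + 256)
            vb = _bootstrap_variances(E, B, rng)
            row["ci25"], row["ci75"] = np.percentile(vb, [25, 75])
            idx = rng.integers(0, sign.size, size=(B, sign.size))
            row["sem_sign"] = sign[idx].mean(axis=1).std(ddof=1)
        else:
            row["ci25"] = row["ci75"] = row["sem_sign"] = np.nan
        rows.append(row)
    cols = [
        "n01", "n10", "count", "mean_G01", "mean_G10",
        "basis_harmonic", "basis_sqrt_product", "mean_E", "var_E",
        "ci25", "ci75", "sign_fraction", "sem_sign", "low_confidence",
    ]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.set_index(["n01", "n10"])
    else:
        out.index = pd.MultiIndex.from_arrays([[], []], names=["n01", "n10"])
    out.attrs["n_lethal"] = int((~usable).sum())
    out.attrs["n_out_of_range"] = int((usable & ~inside).sum())
    out.attrs["n_pairs"] = int(len(pairs))
    return out


def select_diagonal(pairs: pd.DataFrame, tolerance: float = 0.2) -> pd.DataFrame:
    """Pairs whose two single-mutant effects agree within a fraction.

    Keeps rows with |G01 - G10| <= tolerance * max(|G01|, |G10|) (both
    finite) and assigns G = (G01 + G10) / 2.  Symmetric in the two
    arguments.  The returned table keeps E and sign_class for downstream
    1-D analyses.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    G01 = pairs["G01"].to_numpy(float)
    G10 = pairs["G10"].to_numpy(float)
    finite = np.isfinite(G01) & np.isfinite(G10) & ~pairs["lethal"].to_numpy(bool)
    close = np.abs(G01 - G10) <= tolerance * np.maximum(np.abs(G01), np.abs(G10))
    keep = finite & close
    out = pairs.loc[keep, ["E", "sign_class", "lethal"]].copy()
    out.insert(0, "G", (G01[keep] + G10[keep]) / 2.0)
    return out.reset_index(drop=True)


def _resolve_1d_bins(G: np.ndarray, grid, bins_per_octave: int = 1):
    """1-D bin codes for diagonal analyses.

    ``grid`` may be a BinGrid (optionally refined into ``bins_per_octave``
    equal log-width sub-bins per octave) or an explicit array of edges
    (ascending, applied to -|G| via right-open convention).
    Returns (codes, out-of-range mask); codes index arbitrary but stable.
    """
    if isinstance(grid, BinGrid):
        x = -np.asarray(G, float)
        ok = np.isfinite(x) & (x > 2.0 ** (grid.n_min - 1)) & (x <= 2.0 ** grid.n_max)
        with np.errstate(divide="ignore", invalid="ignore"):
            pos = np.log2(np.where(ok, x, 1.0)) - (grid.n_min - 1)
        codes = np.ceil(pos * bins_per_octave).astype(int) - 1
        codes[~ok] = -1
        return codes, ~ok
    edges = np.asarray(grid, float)
    codes = np.searchsorted(edges, np.asarray(G, float), side="right") - 1
    bad = (codes < 0) | (codes >= edges.size - 1) | ~np.isfinite(G)
    codes[bad] = -1
    return codes, bad


def diagonal_variance(
    diagonal: pd.DataFrame,
    grid=DEFAULT_GRID,
    bins_per_octave: int = 2,
    B: int = 1000,
    seed: int = 0,
    min_count: int = 50,
) -> pd.DataFrame:
    """var(E | G, G) over 1-D bins of the diagonal slice.

    Returns one row per populated bin: mean_G, count, mean_E, var_E and
    bootstrap 25-75% quantiles of the variance.  Bootstrap for 1-D bin k
    uses ``default_rng([seed, 917, k])`` with the same draw contract as
    :func:`compute_bin_stats`.
    """
    codes, bad = _resolve_1d_bins(diagonal["G"].to_numpy(float), grid, bins_per_octave)
    E = diagonal["E"].to_numpy(float)
    G = diagonal["G"].to_numpy(float)
    rows = []
    for k in np.unique(codes[~bad]):
        m = codes == k
        if m.sum() < 2:
            continue
        Eb = E[m]
        row = {
            "bin": int(k),
            "mean_G": G[m].mean(),
            "count": int(m.sum()),
            "mean_E": Eb.mean(),
            "var_E": Eb.var(ddof=1),
            "low_confidence": m.sum() < min_count,
        }
        if B > 0:
            rng = _bin_rng(seed, 917, k)
            vb = _bootstrap_variances(Eb, B, rng)
            row["ci25"], row["ci75"] = np.percentile(vb, [25, 75])
        else:
            row["ci25"] = row["ci75"] = np.nan
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["bin", "mean_G", "count", "mean_E", "var_E", "ci25", "ci75",
                 "low_confidence"],
    ).set_index("bin")


def sign_epistasis_probability(
    diagonal: pd.DataFrame,
    grid=DEFAULT_GRID,
    bins_per_octave: int = 1,
    B: int = 1000,
    seed: int = 0,
    reciprocal_only: bool = False,
) -> pd.DataFrame:
    """S(G, G): per-bin probability of sign epistasis with bootstrap SEM.

    By default counts single_sign and reciprocal_sign pairs together; set
    ``reciprocal_only`` to count fitness valleys only (which variant the
    headline statistic should use is a genuine modelling choice, so both
    are exposed).  SEM is the standard deviation of the bin fraction over
    ``B`` bootstrap resamples (``default_rng([seed, 919, k])``).
    """
    if reciprocal_only:
        flag = (diagonal["sign_class"] == "reciprocal_sign").to_numpy()
    else:
        flag = diagonal["sign_class"].isin(_SIGN_SET).to_numpy()
    codes, bad = _resolve_1d_bins(diagonal["G"].to_numpy(float), grid, bins_per_octave)
    G = diagonal["G"].to_numpy(float)
    rows = []
    for k in np.unique(codes[~bad]):
        m = codes == k
        f = flag[m]
        row = {
            "bin": int(k),
            "mean_G": G[m].mean(),
            "count": int(m.sum()),
            "S": f.mean(),
        }
        if B > 0 and f.size > 1:
            rng = _bin_rng(seed, 919, k)
            idx = rng.integers(0, f.size, size=(B, f.size))
            row["sem"] = f[idx].mean(axis=1).std(ddof=1)
        else:
            row["sem"] = 0.0 if f.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["bin", "mean_G", "count", "S", "sem"]).set_index("bin")
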