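"""One-parameter scaling laws for the variance of epistasis.

The central empirical law: binned over the single-mutant log growth
effects, the variance of geometric epistasis is well described by the
symmetric harmonic-mean surface

    var(G01, G10) = 2c |G01 * G10| / (|G01| + |G10|),

which reduces to var(G, G) = c|G| on the diagonal — so the characteristic
interaction strength sigma = sqrt(var) grows only like sqrt(|G|): doubling
both mutational effects strengthens typical epistasis by sqrt(2), not 2.
A slightly less accurate alternative is var = c*sqrt(|G01*G10|), which
shares the diagonal behaviour; a per-slice Michaelis-Menten form
var(G10 | G01) = v|G10|/(K + |G10|) is also provided for slice diagnostics.
Fisher's geometric model, by contrast, cannot produce var(G, G) growing
slower than G^2 (see :mod:`epistat.fisher_model`), which is what the
diagonal log-log scaling exponent diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ScalingFit",
    "surface_basis",
    "fit_surface",
    "predict_sigma",
    "predict_interval",
    "scaling_exponent",
]

MODELS = ("harmonic", "sqrt_product", "michaelis_menten_slice")


def surface_basis(G01, G10, model: str = "harmonic"):
    """The variance surface at c = 1 (so var = c * basis).

    harmonic: 2|G01*G10|/(|G01|+|G10|); sqrt_product: sqrt(|G01*G10|).
    Both vanish when either effect vanishes and are symmetric.
    """
    a = np.abs(np.asarray(G01, float))
    b = np.abs(np.asarray(G10, float))
    if model == "harmonic":
        s = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    elif model == "sqrt_product":
        out = np.sqrt(a * b)
    else:
        raise ValueError(f"no closed-form basis for model {model!r}")
    return out if np.ndim(out) else float(out)


@dataclass
class ScalingFit:
    """A fitted variance surface.

    ``c`` is the single coefficient of the harmonic or sqrt_product
    surface (log2-scale variance per unit |G| on the diagonal); for the
    Michaelis-Menten slice model, per-slice (v, K) live in ``slices``.
    """

    model: str
    c: Optional[float] = None
    slices: Optional[pd.DataFrame] = None
    residuals: Optional[pd.Series] = None
    weighting: str = "count"
    degenerate: bool = False

    def predict_var(self, G01, G10):
        if self.model in ("harmonic", "sqrt_product"):
            return self.c * surface_basis(G01, G10, self.model)
        raise ValueError("slice model has no global surface")


def fit_surface(
    bins: pd.DataFrame,
    model: str = "harmonic",
    weighting: str = "count",
    var_col: str = "var_bio",
    include_low_confidence: bool = False,
    min_effect: Optional[float] = None,
    scale: str = "log",
) -> ScalingFit:
    """Weighted least-squares fit of a variance surface to binned data.

    ``bins`` needs columns mean_G01, mean_G10, ``var_col`` and (for the
    default weighting) count; rows flagged ``low_confidence`` are dropped
    unless requested, as are beneficial-effect rows (positive mean G) —
    interactions between beneficial mutations are treated separately.
    ``min_effect`` drops bins that reach below the measurement
    resolution: when the table is indexed by bin exponents the test is on
    the bin's inner (closest-to-zero) edge 2^(n-1), otherwise on the mean
    effect.  Such bins are dominated by near-neutral genes scattered in
    by single-mutant measurement error — the near-neutral class
    outnumbers each deleterious octave many-fold, so even small scatter
    fills small-effect bins with pairs whose true effects (hence true
    epistasis variance) are far below the bin label, biasing the fitted
    coefficient downward.  Callers that know the single-mutant
    uncertainties should set it to the width of the near-neutral band
    plus a few times the typical log-growth error (the pipeline does).
    The one-parameter surfaces are linear in c, so the weighted
    least-squares fit is closed form.  Because the sampling error of a
    variance estimate is proportional to the variance itself, the fit is
    performed on the log scale by default (``scale='log'``): the model
    log var = log c + log f has homoscedastic per-bin errors of variance
    ~ (kappa - 1)/n, so bin-count weights are inverse-variance optimal
    and c is the count-weighted geometric mean of var/f.  ``scale=
    'linear'`` gives the plain weighted least squares c = sum(w f v) /
    sum(w f^2), which is dominated by the few largest-effect bins.  When
    the bin table carries a ``basis_<model>`` column (the within-bin
    mean of the per-pair basis, provided by ``compute_bin_stats``) it is
    used as f; otherwise f is evaluated at the bin-mean (G01, G10),
    which is slightly biased upward over wide bins.  The
    Michaelis-Menten slice model fits (v, K) per fixed-G01 slice by
    bounded least squares instead.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if var_col not in bins.columns:
        raise KeyError(f"bin table lacks required column {var_col!r}")
    tab = bins
    if not include_low_confidence and "low_confidence" in tab.columns:
        tab = tab.loc[~tab["low_confidence"].astype(bool)]
    tab = tab.loc[(tab["mean_G01"] < 0) & (tab["mean_G10"] < 0)]
    if min_effect is not None:
        if isinstance(tab.index, pd.MultiIndex) and tab.index.names == ["n01", "n10"]:
            inner01 = 2.0 ** (tab.index.get_level_values("n01").to_numpy(float) - 1)
            inner10 = 2.0 ** (tab.index.get_level_values("n10").to_numpy(float) - 1)
            tab = tab.loc[(inner01 >= min_effect) & (inner10 >= min_effect)]
        else:
            tab = tab.loc[
                (tab["mean_G01"].abs() >= min_effect)
                & (tab["mean_G10"].abs() >= min_effect)
            ]
    tab = tab.loc[np.isfinite(tab[var_col].astype(float))]
    if len(tab) < 2:
        raise ValueError("need at least 2 usable deleterious bins to fit")
    v = tab[var_col].to_numpy(float)
    if weighting == "count":
        w = tab["count"].to_numpy(float)
    elif weighting == "uniform":
        w = np.ones(len(tab))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    if model == "michaelis_menten_slice":
        rows = []
        for n01, g in tab.groupby(level="n01"):
            if len(g) < 3:
                continue
            x = np.abs(g["mean_G10"].to_numpy(float))
            y = g[var_col].to_numpy(float)
            try:
                (vmax, K), _ = optimize.curve_fit(
                    lambda x, vmax, K: vmax * x / (K + x),
                    x, y, p0=[max(y.max(), 1e-6), np.median(x)],
                    bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
                )
            except RuntimeError:
                continue
            rows.append({"n01": n01, "v": vmax, "K": K,
                         "mean_G01": g["mean_G01"].mean(), "n_bins": len(g)})
        return ScalingFit(
            model=model, slices=pd.DataFrame(rows).set_index("n01"),
            weighting=weighting,
        )

    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    basis_col = f"basis_{model}"
    if basis_col in tab.columns:
        f = tab[basis_col].to_numpy(float)
    else:
        f = surface_basis(tab["mean_G01"], tab["mean_G10"], model)
    degenerate = False
    if scale == "log":
        pos = (v > 0) & (f > 0)
        if not np.any(pos):
            c, degenerate = 0.0, True
        else:
            wl = w[pos] / w[pos].sum()
            c = float(np.exp(np.sum(wl * (np.log(v[pos]) - np.log(f[pos])))))
    else:
        denom = float(np.sum(w * f * f))
        if denom == 0 or not np.any(v > 0):
            c, degenerate = 0.0, True
        else:
            c = max(float(np.sum(w * f * v) / denom), 0.0)
    residuals = pd.Series(c * f - v, index=tab.index, name="residual")
    return ScalingFit(model=model, c=c, residuals=residuals,
                      weighting=weighting, degenerate=degenerate)


def predict_sigma(G01, G10, fit: ScalingFit):
    """Characteristic epistasis strength sigma = sqrt(var) under a fit.

    On the diagonal both default surfaces give sigma(G, G) = sqrt(c|G|).
    """
    return np.sqrt(fit.predict_var(G01, G10))


def predict_interval(G01, G10, sigma):
    """+/- one-sigma interval for the double mutant's relative growth rate.

    The null prediction is G11 = G01 + G10; the interval is
    [2^(G11 - sigma), 2^(G11 + sigma)].  sigma = 0 collapses the interval
    onto the multiplicative null 2^G11 = g01*g10.
    """
    sigma = np.asarray(sigma, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    G11 = np.asarray(G01, float) + np.asarray(G10, float)
    lo, hi = np.exp2(G11 - sigma), np.exp2(G11 + sigma)
    if np.ndim(lo):
        return lo, hi
    return float(lo), float(hi)


def scaling_exponent(
    diagonal: pd.DataFrame,
    var_col: str = "var_E",
    B: int = 2000,
    seed: int = 0,
    ci: float = 95.0,
) -> dict:
    """Log-log slope of var(G, G) versus |G| with a bootstrap CI over bins.

    ``diagonal`` needs columns mean_G, ``var_col`` and count (weights).
    Slope ~ 1 diagnoses the harmonic/sqrt_product family (var
    proportional to |G|); slope >= 2 diagnoses Fisher-like geometric
    scaling.  The CI (``default_rng([seed, 937])``) propagates each
    bin's own variance uncertainty when the table carries bootstrap
    quantile columns ci25/ci75 (parametric resampling of log var — much
    better behaved than bin resampling when only a handful of bins
    exist); otherwise it resamples bins with replacement.  At least 3
    bins with positive variance are required.
    """
    tab = diagonal.loc[
        np.isfinite(diagonal[var_col].astype(float)) & (diagonal[var_col] > 0)
    ]
    if "low_confidence" in tab.columns:
        keep = tab.loc[~tab["low_confidence"].astype(bool)]
        if len(keep) >= 3:
            tab = keep
    if len(tab) < 3:
        raise ValueError("need at least 3 diagonal bins with positive variance")
    x = np.log(np.abs(tab["mean_G"].to_numpy(float)))
    y = np.log(tab[var_col].to_numpy(float))
    w = tab["count"].to_numpy(float)

    def _wls(x, y, w):
        W = w / w.sum()
        xm, ym = np.sum(W * x), np.sum(W * y)
        return np.sum(W * (x - xm) * (y - ym)) / np.sum(W * (x - xm) ** 2)

    slope = _wls(x, y, w)
    rng = np.random.default_rng([int(seed), 937])
    reps = []
    have_ci = {"ci25", "ci75"}.issubset(tab.columns) and bool(
        np.all(np.isfinite(tab[["ci25", "ci75"]].to_numpy(float)))
    )
    if have_ci:
        v = tab[var_col].to_numpy(float)
        sd_v = (tab["ci75"] - tab["ci25"]).to_numpy(float) / 1.349
        sd_log = sd_v / v
        for _ in range(B):
            y_star = y + rng.normal(0.0, sd_log)
            reps.append(_wls(x, y_star, w))
        method = "parametric"
    else:
        for _ in range(B):
            idx = rng.integers(0, len(x), size=len(x))
            if np.unique(x[idx]).size < 2:
                continue
            reps.append(_wls(x[idx], y[idx], w[idx]))
        method = "bins"
    lo, hi = np.percentile(reps, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return {"exponent": float(slope), "ci_low": float(lo), "ci_high": float(hi),
            "n_bins": int(len(tab)), "B": int(len(reps)), "ci_method": method}
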