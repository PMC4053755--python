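"""Per-pair epistasis transforms on double-mutant growth rates.

Definitions, with all growth rates relative to wild type (g00 = 1) and
"log growth" G = log2(g):

* geometric epistasis  E = G11 - G01 - G10, the log2 fold deviation of the
  double mutant from the multiplicative null g11 = g01*g10.  E = +1 means
  the double mutant grows twice as fast as predicted, E = -1 half as fast.
  |E| does not depend on which genotype corner is labelled wild type.
* traditional epistasis  e = g11 - g01*g10, the growth-rate difference from
  the same null.  e is bounded below by -g01*g10 (attained at g11 = 0), so
  it compresses interactions between strongly deleterious mutations: a
  synthetic lethal between two very sick singles has e ~ 0.

Synthetic lethal doubles (g11 = 0) have E = -inf; the sentinel is carried
explicitly and every moment computation downstream excludes it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_sga import Dataset

__all__ = [
    "LETHAL",
    "log_growth",
    "geometric_epistasis",
    "traditional_epistasis",
    "traditional_lower_bound",
    "classify_sign_epistasis",
    "pair_stats",
    "pair_stats_from_logs",
]

#: sentinel log growth / epistasis for lethal (zero-growth) genotypes
LETHAL = -np.inf

#: sign-epistasis classes, in increasing order of landscape ruggedness
SIGN_CLASSES = ("none", "single_sign", "reciprocal_sign")


def log_growth(g, g00: float = 1.0):
    """log2 of the relative growth rate; g <= 0 maps to the lethal sentinel.

    Scalar or array.  The -inf sentinel is deliberate and flagged by being
    non-finite; it must never be averaged (downstream code masks it).
    """
    g = np.asarray(g, dtype=float)
    if g00 <= 0:
        raise ValueError("reference growth rate g00 must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(g > 0, np.log2(np.where(g > 0, g, 1.0) / g00), LETHAL)
    return out if out.ndim else float(out)


def geometric_epistasis(G01, G10, G11):
    """E = G11 - (G01 + G10): deviation from the additive null on log growth."""
    return np.asarray(G11, float) - (np.asarray(G01, float) + np.asarray(G10, float))


def traditional_epistasis(g01, g10, g11):
    """e = g11 - g01*g10 (g00 = 1).  Finite even for lethal doubles."""
    return np.asarray(g11, float) - np.asarray(g01, float) * np.asarray(g10, float)


def traditional_lower_bound(g01, g10):
    """Minimum achievable e for given singles: -g01*g10, attained at g11 = 0."""
    return -(np.asarray(g01, float) * np.asarray(g10, float))


def classify_sign_epistasis(G01, G10, G11):
    """Classify each pair as none / single_sign / reciprocal_sign.

    Mutation A's effect in B's background is G11 - G10 (solo effect G01),
    and symmetrically for B.  A mutation "flips" when its conditional
    effect has strictly opposite sign to its solo effect; exact zeros
    (either effect) never flip.  One flip -> single_sign, two ->
    reciprocal_sign.  For two deleterious singles, reciprocal_sign is
    equivalent to G11 > max(G01, G10): the double mutant is fitter than
    both singles, a fitness valley.

    Returns an object array of class labels (scalar for scalar input).
    """
    G01 = np.asarray(G01, float)
    G10 = np.asarray(G10, float)
    G11 = np.asarray(G11, float)
    cond_a = G11 - G10  # effect of the query mutation in the array background
    cond_b = G11 - G01
    flip_a = (np.sign(cond_a) * np.sign(G01)) < 0
    flip_b = (np.sign(cond_b) * np.sign(G10)) < 0
    n_flips = np.asarray(flip_a, dtype=int) + np.asarray(flip_b, dtype=int)
    out = np.asarray(SIGN_CLASSES, dtype=object)[n_flips]
    return out if isinstance(out, np.ndarray) else str(out)


def pair_stats_from_logs(G01, G10, G11, query_id=None, array_id=None) -> pd.DataFrame:
    """Assemble a PairStats table directly from log growth rates."""
    G01 = np.asarray(G01, float)
    G10 = np.asarray(G10, float)
    G11 = np.asarray(G11, float)
    lethal = ~np.isfinite(G11)
    E = np.where(lethal, LETHAL, geometric_epistasis(G01, G10, np.where(lethal, 0.0, G11)))
    g01, g10 = np.exp2(G01), np.exp2(G10)
    g11 = np.where(lethal, 0.0, np.exp2(np.where(lethal, 0.0, G11)))
    out = pd.DataFrame(
        {
            "G01": G01,
            "G10": G10,
            "G11": G11,
            "E": E,
            "e": traditional_epistasis(g01, g10, g11),
            "sign_class": classify_sign_epistasis(G01, G10, np.where(lethal, LETHAL, G11)),
            "lethal": lethal,
        }
    )
    if query_id is not None:
        out.insert(0, "query_id", np.asarray(query_id))
        out.insert(1, "array_id", np.asarray(array_id))
    return out


def pair_stats(ds: Dataset) -> pd.DataFrame:
    """Per-pair derived quantities for every record of a filtered dataset.

    Columns: query_id, array_id, G01, G10, G11, E, e, sign_class, lethal.
    ``lethal`` marks pairs in which any genotype has non-positive growth;
    such pairs carry -inf sentinels in the corresponding G (and E) columns
    and must be excluded from moment computations (binning does so).
    """
    f = ds.frame
    g01 = f["g01"].to_numpy(float)
    g10 = f["g10"].to_numpy(float)
    g11 = f["g11"].to_numpy(float)
    G01 = np.atleast_1d(log_growth(g01))
    G10 = np.atleast_1d(log_growth(g10))
    G11 = np.atleast_1d(log_growth(g11))
    lethal = ~(np.isfinite(G01) & np.isfinite(G10) & np.isfinite(G11))
    E = np.where(lethal, LETHAL, G11 - G01 - G10)
    return pd.DataFrame(
        {
            "query_id": f["query_id"].to_numpy(),
            "array_id": f["array_id"].to_numpy(),
            "G01": G01,
            "G10": G10,
            "G11": G11,
            "E": E,
            "e": traditional_epistasis(g01, g10, g11),
            "sign_class": classify_sign_epistasis(G01, G10, G11),
            "lethal": lethal,
        }
    )
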