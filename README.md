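# epistat

Statistics of pairwise genetic interactions on genome-scale double-mutant
fitness data.

High-throughput screens such as the yeast Synthetic Genetic Array (SGA)
measure the relative growth rates of millions of double knockout mutants.
`epistat` quantifies how strongly gene pairs interact, how the *typical*
interaction strength scales with the growth-rate effects of the mutations
being combined, how much of the apparent interaction signal is produced by
measurement noise, and how the resulting fitness-landscape ruggedness
compares with Fisher's geometric model.  It is aimed at people analyzing
SGA-style fitness tables and at modellers who need realistic, tunable
synthetic interaction data with known ground truth.

## The statistic and the scaling law

With growth rates relative to wild type (g00 = 1) and "log growth"
G = log2(g), the multiplicative null model predicts g11 = g01·g10 for a
double mutant, i.e. G11 = G01 + G10.  Epistasis is measured geometrically:

    E = G11 − G01 − G10,

the log2 fold deviation of the double mutant from the null; |E| does not
depend on which genotype is called wild type.  The traditional difference
measure e = g11 − g01·g10 is bounded below by −g01·g10, so it compresses
interactions between very deleterious mutations (a synthetic lethal between
two very sick singles has e ≈ 0); `epistat` computes both and exposes the
bias explicitly.

Binning pairs by (G01, G10) on exponentially growing intervals and taking
per-bin variances of E (with measurement noise removed via no-epistasis
mock datasets) yields the one-parameter harmonic scaling surface

    var(E | G01, G10) = 2c·|G01·G10| / (|G01| + |G10|),   c ≈ 0.079,

which reduces to var(G, G) = c·|G| on the diagonal: the characteristic
interaction strength σ = √var grows only like √|G|.  Doubling both
mutational effects strengthens typical epistasis by √2, not 2 — far weaker
than Fisher's geometric model, which cannot scale slower than var ∝ G².
A consequence is that sign epistasis (a mutation beneficial in the other
mutant's background) becomes *more* likely among small-effect mutations.

## Worked example

```python
import numpy as np
from epistat import ScalingFit, log_growth, predict_interval, predict_sigma

# closed-form prediction: two knockouts, each reducing growth by 5%
fit = ScalingFit(model="harmonic", c=0.079)
G = log_growth(0.95)
sigma = round(float(predict_sigma(G, G, fit)), 3)
lo, hi = predict_interval(G, G, sigma)
print(f"G01 = G10 = {G:.3f}   null G11 = {2*G:.3f}")
print(f"sigma(G, G)  = {sigma:.3f}")
print(f"1-sigma interval for g11: [{lo:.2f}, {hi:.2f}]")

# full synthetic pipeline: recover the scaling coefficient
from epistat.cli_report import PipelineConfig, run_pipeline
cfg = PipelineConfig.from_dict({"simulate": {"n_pairs": 200_000}, "seed": 1})
bundle = run_pipeline(cfg)
e = bundle["exponent"]
print(f"recovered c  = {bundle['fit'].c:.4f}   (generated with c_true = 0.079)")
print(f"diagonal log-log exponent = {e['exponent']:.2f} "
      f"(95% CI [{e['ci_low']:.2f}, {e['ci_high']:.2f}])")
```

Output:

```
G01 = G10 = -0.074   null G11 = -0.148
sigma(G, G)  = 0.076
1-sigma interval for g11: [0.86, 0.95]
recovered c  = 0.0767   (generated with c_true = 0.079)
diagonal log-log exponent = 0.97 (95% CI [0.59, 1.36])
```

Two 5% knockouts are predicted to interact with characteristic strength
σ = 0.076 log2-fold, so the double mutant's growth rate plausibly ranges
from 0.86 to 0.95 — it is not unlikely that epistasis cancels one
mutation's entire effect.  The pipeline run simulates 200,000 SGA-like
pairs with known ground truth (harmonic surface, heavy-tailed E, t-
distributed replicate noise), subtracts the noise contribution estimated
from nine mock datasets, and recovers the generative coefficient within a
few percent; the diagonal scaling exponent is consistent with the linear
law (exponent 1) and excludes the Fisher-model bound (exponent 2).

## Command line

```
epistat simulate --n-pairs 200000 --seed 1 --out sim.tsv.gz
epistat analyze  --input sim.tsv.gz --outdir out/ --seed 1
epistat fit      --bins out/bins.tsv --var-col var_E
epistat fgm      --n-pairs 100000 --seed 1 --out fgm.tsv
epistat report   --config pipeline.yaml
```

`analyze` writes tidy TSV tables (per-bin statistics, noise decomposition,
diagonal slice, sign-epistasis probability, interaction rankings) plus a
JSON fit report and a run log with the seed and filter counts.  Real
SGA-style raw tables are read with a configurable column dialect
(`--dialect costanzo2010` for the published raw layout).

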