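# dielpath

Statistical analysis of diel (24-hour) transcript dynamics measured under
fluctuating field conditions.

Plants growing outdoors integrate timing information from their circadian
clock with temperature and light cues. A canonical readout of this
integration is the signaling cascade from a morning-peaked clock transcript
(e.g. *CCA1*) through a nuclear sigma factor (*SIG5*) to the blue-light
responsive promoter of the chloroplast gene *psbD*. Interpreting replicated
RT-qPCR or RNA-seq time courses from such field campaigns raises three
recurring questions, and this package implements one tool for each:

1. **When do two conditions differ?** A Bayesian *smooth trend model* (STM):
   each condition's latent log2 abundance follows a second-order random walk
   `mu[t] = 2 mu[t-1] - mu[t-2] + N(0, s2)`, alternative conditions add a
   difference component `delta[t]` with the same dynamics, and a timepoint is
   called significant when the pointwise 95% credible interval of `delta`
   excludes zero. Fitted by a Gibbs sampler alternating exact
   forward-filter backward-sampling (FFBS) state draws with conjugate
   inverse-gamma variance updates.
2. **Which external drivers explain a transcript's dynamics?** A *local
   level model with exogenous variables* (LLMX): a first-order random-walk
   diel trend shared across condition-series plus linear effects of z-scored
   ambient temperature, irradiance, and the upstream transcript,
   `alpha[s,t] = mu[t] + b_T z(T) + b_L z(L) + b_U z(U)`. Supports
   counterfactuals (clamp one driver at its grand mean) and cross-year
   prediction with stored standardization constants.
3. **Is the coupling causal?** *Convergent cross-mapping* (CCM): the
   attractor reconstructed from a putative effect is used to predict the
   putative cause by simplex projection; skill (Pearson rho) that exceeds a
   1,000-member *diel-surrogate* band (surrogates keep the mean time-of-day
   profile, randomize residual order) and grows with library size indicates
   causality. A time-to-prediction offset `tp` probes transduction delays.

A JTK_CYCLE-style rhythmicity module (Jonckheere–Terpstra/Kendall statistics
against cosine references with an exact convolution null), Benjamini–
Hochberg q-values, diel fold changes, and a temperature-correlation screen
round out the pipeline, and a seeded synthetic-data module generates
environments, the three-gene cascade, coupled logistic maps, and null series
so every stage is testable without field data.

## Worked example

```python
import numpy as np
from dielpath import (
    SmoothTrendModel, LocalLevelExogModel, ccm_test,
    two_season_scenario, aggregate_env,
)
from dielpath.llmx import upstream_regressor

scen = two_season_scenario(seed=1, n_hours=24.0)     # cool + warm campaigns
envs = scen.pop("_env")

# 1. season contrast for the mid (sigma-factor-like) gene
stm = SmoothTrendModel(seed=1, n_chains=2, n_warmup=500, n_iter=750)
stm.fit([scen["cool"]["SIG"], scen["warm"]["SIG"]])
print(round(stm.fit_correlation(), 3))
print(stm.difference_significance(force=True)[:1])

# 2. driver attribution
resp = [scen[c]["SIG"] for c in ("cool", "warm")]
exog = {
    "temperature": np.array([aggregate_env(envs[c], s.grid)["temperature"]
                             for c, s in zip(("cool", "warm"), resp)]),
    "irradiance": np.array([aggregate_env(envs[c], s.grid)["irradiance"]
                            for c, s in zip(("cool", "warm"), resp)]),
    "upstream": np.array([upstream_regressor(scen[c]["CLOCK"])
                          for c in ("cool", "warm")]),
}
llmx = LocalLevelExogModel(seed=1, n_chains=2, n_warmup=500, n_iter=750)
llmx.fit(resp, exog)
print(llmx.coefficient_summary()[["variable", "median", "significant"]])
```

prints (numbers from this exact script):

```
1.0
[{'component': 'delta', 'start': 0, 'end': 3, 'sign': -1}]
      variable    median  significant
0  temperature -0.438614         True
1   irradiance  0.508823         True
2     upstream  0.713753         True
```

The STM trend tracks the observed replicate means almost perfectly (r =
1.00) and flags a significantly lower warm-minus-cool difference over the
first four timepoints; the LLMX attributes the mid gene's dynamics to a
negative temperature effect and positive irradiance and upstream-clock
effects — the same sign pattern the simulation encodes (the upstream
median is attenuated below its generating value because the regressor is a
noisy replicate mean and shares its diel shape with the trend).

A command-line interface mirrors the library
(`dielpath simulate|rhythm|stm|llmx|ccm|run`); `dielpath run --config
cfg.yaml` executes the whole pipeline and writes per-stage CSV/JSON plus a
provenance record with every seed.

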