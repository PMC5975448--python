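# survscreen

Permutation-calibrated **joint covariate screening** for censored survival
data.

Given an expression table (samples × features) with right-censored survival
outcomes, `survscreen` hunts for *k*-tuples of features that are **jointly**
prognostic — including combinations whose members are individually
unremarkable. Selection runs in two steps:

1. **Association screen.** Every *k*-tuple is fitted jointly in a Cox
   proportional-hazards model by maximum partial likelihood (Breslow ties),

   L(β) = ∏ᵢ exp(x₍ᵢ₎β) / Σ_{j ∈ R(t₍ᵢ₎)} exp(x₍ⱼ₎β),

   giving per-component Wald statistics z_j = β̂_j / se(β̂_j). Each z_j is
   referred not to the normal approximation but to a permutation null z⁰
   obtained by re-pairing the (time, event) outcomes with the fixed
   expression rows and refitting; p_j = (1 + #{|z⁰| ≥ |z_j|}) / (B + 1). A
   tuple survives when **every** component is significant.
2. **Stratification screen.** Each surviving tuple's risk score
   s = x′β̂ splits the cohort at a cutoff (median by default) into high- and
   low-risk groups. The two-group log-rank statistic
   Q = (Σᵢ (d₁ᵢ − ê₁ᵢ))² / Σᵢ v̂₁ᵢ, with ê₁ᵢ = n₁ᵢdᵢ/nᵢ and hypergeometric
   variance v̂₁ᵢ = n₁ᵢn₀ᵢdᵢ(nᵢ−dᵢ)/(nᵢ²(nᵢ−1)), is calibrated by the same
   outcome-permutation null. Kaplan–Meier curves and Harrell's C-index are
   reported as diagnostics.

A synthetic-cohort generator (40 independent features, one strong and one
weak planted effect, lognormal survival times, exact 10% censoring) and a
repeated-simulation study harness that counts false-positive and
false-negative selections are included as first-class, tested components.

## Worked example

```python
import pandas as pd
from survscreen import JointCovariateDetector, SimulationSpec, simulate_dataset

ds = simulate_dataset(SimulationSpec(n=150, seed=10))   # 150 x 40 cohort
X = pd.DataFrame(ds.expression, columns=list(ds.feature_ids))
det = JointCovariateDetector(k=1, alpha1=0.02, alpha2=0.02,
                             n_permutations=199, random_state=2)
det.fit(X, (ds.time, ds.event))
print(det.results_frame().to_string(index=False))
```

prints (one row per tuple that survived step 1):

```
     features   cutoff  logrank_Q  perm_p  c_index  selected failure
alternative-1 0.003014  12.323194   0.005 0.660305      True
```

The strongly prognostic planted feature `alternative-1` survives step 1;
its median-split risk groups separate with log-rank Q ≈ 12.3, whose
permutation p = 1/200 sits at the add-one floor (B = 199), and the risk
score orders survival times with C ≈ 0.66. `det.support_` /
`det.transform(X)` then select those feature columns, and the estimator
composes with scikit-learn pipelines.

The same pipeline is scriptable from a shell:

```bash
survscreen simulate --n 500 --seed 1 --outdir run/
survscreen step1 --input run/simulated.tsv --k 2 --alpha1 0.001 \
    --permutations 1000 --outdir run/
survscreen step2 --input run/simulated.tsv --step1-results run/step1_k2.tsv \
    --alpha2 0.001 --outdir run/
survscreen study --replicates 20 --n 500 --outdir run/   # FP/FN accounting
```

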