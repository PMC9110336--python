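# mmbm — multilevel multinomial behavioural models of child time allocation

`mmbm` is a research-grade implementation of the statistical pipeline used in
cross-cultural studies of how hunter-gatherer and mixed-subsistence forager
children spend their time. Behavioural observations of children are coded
into five activity categories — childcare, food production, domestic work,
play, and other — and modelled with a baseline-category multinomial logistic
regression whose intercepts vary by child and by society with full 4×4
covariance across categories:

    log(π_kij / π_5ij) = β_k + ν_individual_ki + ν_society_kj + Σ_m β_km x_im

    (ν_1i,…,ν_4i) ~ Normal(0, Ω_I),   (ν_1j,…,ν_4j) ~ Normal(0, Ω_S),
    Ω = diag(σ) · R · diag(σ)

Five nested candidate models probe individual characteristics (age, gender),
environment (NPP, annual mean temperature, annual precipitation), ecological
risk (dangerous mammal density, water quality/quantity), and the gendered
division of food production labour. Models are estimated by an in-package
No-U-Turn sampler with non-centered (Cholesky) random effects, checked with
split R-hat and divergence counts, compared by WAIC with Akaike-style
weights, and interpreted through posterior predicted activity probabilities
with 89% credible intervals.

The package is aimed at human behavioural ecologists and cross-cultural
researchers who want this model class without a Stan toolchain, and it is
fully exercisable without any field data: a synthetic-data module generates
datasets from the same generative process with known parameters (emulating
the structure of the published 12-society, 690-child sample), so the whole
pipeline is validated by parameter recovery.

## Worked example

Simulate a small six-society study from known parameters, fit the
intercept-only and individual-level models, compare them, and predict
activity probabilities for girls and boys in middle childhood:

```python
import warnings
from mmbm import (scaled_design, generate, build_dataset, fit, McmcConfig,
                  compare, summarize_fixed_effects, prediction_table, ModelSpec)
from mmbm.observations import expand_observations

truth = scaled_design(n_societies=6, children_per_society=12, obs_per_child=40)
data = generate(truth, seed=1)
records = expand_observations(data.observations, data.code_map)

fits = {}
for m in (1, 2):
    spec = ModelSpec.for_model(m)
    ds = build_dataset(records, data.children, data.societies, spec)
    fits[f"model_{m}"] = fit(spec, ds, McmcConfig(chains=2, iterations=800, seed=1))

print(compare(fits))
```

```
  model        waic     p_waic        se  weight
model_2 5721.068212 142.988430 89.725925 0.99835
model_1 5733.878297 155.439315 89.798679 0.00165
```

The model with age and gender effects wins essentially all of the weight —
as it should, since the data were generated with strong age and gender
differences. Its play coefficients (posterior mean, SD, equal-tailed 95%
interval, and whether the interval excludes zero):

```python
s = summarize_fixed_effects(fits["model_2"])
print(s[s.category == "play"])
```

```
category               term      mean       sd  ci95_low  ci95_high  excludes_zero
    play          intercept -1.066790 0.402066 -1.806085  -0.230311           True
    play                boy  0.992478 0.359396  0.315343   1.691370           True
    play             middle -0.424479 0.338758 -1.092906   0.215179          False
    play         adolescent -2.332475 0.495283 -3.350419  -1.391155           True
    play prop_non_foraged_z -0.049118 0.346600 -0.888610   0.600275          False
```

The generating values (boy +0.67, adolescent −2.18, …) sit inside these
intervals. Predicted probabilities for a typical child in a typical society
(random effects at zero), with 89% credible intervals:

```python
profiles = {"girl_middle": {"boy": 0, "middle": 1, "adolescent": 0,
                            "prop_non_foraged_z": 0.0},
            "boy_middle":  {"boy": 1, "middle": 1, "adolescent": 0,
                            "prop_non_foraged_z": 0.0}}
print(prediction_table(fits["model_2"], ModelSpec.for_model(2), profiles))
```

```
    profile        category     mean    low89   high89
girl_middle       childcare 0.027524 0.014581 0.042356
girl_middle food_production 0.073753 0.029502 0.149039
girl_middle   domestic_work 0.116434 0.073331 0.166039
girl_middle            play 0.150092 0.082706 0.233102
girl_middle           other 0.632198 0.558798 0.697313
 boy_middle       childcare 0.007934 0.003063 0.014231
 boy_middle food_production 0.098147 0.039926 0.191464
 boy_middle   domestic_work 0.051321 0.029106 0.080610
 boy_middle            play 0.206295 0.118438 0.317824
 boy_middle           other 0.636303 0.536133 0.713439
```

Boys play more and do less childcare and domestic work — the gender
contrasts the generating parameters encode.

A command-line interface mirrors the library: `mmbm simulate`, `mmbm fit`,
`mmbm compare`, `mmbm summarize`, `mmbm predict`, and `mmbm run --config
run.yaml` for the full ingest → covariates → fit → compare → summarize
pipeline with subset refits (e.g. excluding one society, or excluding
adolescents).

See `docs/methods.md` for the model, priors, sampler design, covariate
constructions, and the limits of what synthetic-data validation shows.

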