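# trapcatch

Catch modelling for Malaise-trap campaigns: per-species negative-binomial
regression of insect catches on season, rainfall, dead wood and forest
type, with subfamily-level significance testing by summed likelihood
ratios against a resampled null, pairwise habitat contrasts, catch
prediction, and a synthetic campaign generator that makes the whole
pipeline testable without field data.

## The problem

A Malaise trap is a passive tent-like interceptor for flying insects;
between service visits (~two weeks) its catch accumulates into one
*sample*. A year-long campaign over a successional gradient — primary
rainforest, swampy primary forest, selectively logged ("disturbed")
forest, clearcut former plantation, farmland — yields hundreds of samples
of parasitoid wasps (Rhyssinae), whose larvae develop in wood-boring
insect hosts inside decaying trunks. The questions are ecological: when
do these wasps fly, does rain suppress catches, does decaying wood
attract them, and how do catches fall along the successional gradient?

## The model

For each species, the expected catch in one sample is

    E[catch] = days · exp(a₁ + a₂·date + a₃·rain + a₄·deadwood + a_foresttype)

where `days` is the sampling effort (a log offset), `date` counts days
from a campaign reference to the midpoint of the service interval,
`rain` is mean daily rainfall (mm·d⁻¹) over the interval, `deadwood` is
a trap-level score Σ dbh²/distance over *clearly decaying* trees in two
trap-centred transects (dbh in m), and forest type is dummy-coded with
primary forest as the reference. Errors are NB2: Var = μ + μ²/θ, with θ
profiled per species. Forest levels that catch nothing at all (farmland,
in practice) are complete-separation cases; their coefficients are
reported clamped at −15 and flagged.

Term significance is species-wise and subfamily-level: likelihood ratios
between the full model and the model without the term, summed over
species, compared with a null distribution of resampled campaigns
(parametric bootstrap from the null fits by default; site-blocked PIT
residual schemes available), with p = (1 + exceedances)/(B + 1) and no
multiplicity adjustment. Forest types are also contrasted pairwise by
merging two levels in the null model.

## Worked example

```python
from trapcatch import (filter_samples, assemble_design, fit_species,
                       term_test, predict_catch)
from trapcatch.synthetic_data import make_default_scenario, generate_dataset

dataset = generate_dataset(make_default_scenario(seed=1))
design = assemble_design(filter_samples(dataset))
fit = fit_species(design, "Epirhyssa_overlaeti")
print({k: round(v, 3) for k, v in fit.coefficients.items()})
r = term_test(design, "deadwood", B=199, seed=7)
print(round(r.sum_lr, 1), r.overall_p)
print(round(predict_catch(fit, 120.0, 2.5, 0.27, "primary", 14.0), 3))
```

prints (seed 1):

```
{'intercept': -5.628, 'date': 0.004, 'rain': -0.017, 'deadwood': 4.08,
 'swamp': -0.277, 'disturbed': -1.3, 'clearcut': -2.032, 'farm': -15.0}
182.4 0.005
0.233
```

The fitted coefficients recover the generating ones (dead wood 4.08 vs
4.42 generated; `farm` at −15 is the flagged separation artefact of a
habitat with zero catches). The dead-wood term's summed likelihood ratio
of 182.4 is far beyond anything in the 199-resample null, so its p-value
sits at the floor 1/200. The last line is the expected 14-day catch of
this species at a trap with the highest observed dead-wood score, in
primary forest, mid-campaign, in moderate rain: about 0.23 wasps —
exp(4.08 × 0.27) ≈ 3 times the catch of an identical trap with no
decaying wood.

The same pipeline is scriptable from a shell:

```sh
trapcatch simulate --seed 1 --out data/
trapcatch covariates --in data/ --out work/
trapcatch fit --in work/ --out work/
trapcatch test --in work/ --out work/ -B 999 --seed 1
trapcatch report --in work/ --out report/
```

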