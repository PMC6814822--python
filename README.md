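# ssdevol

Phylogenetic comparative analysis of **sexual size dimorphism (SSD)**
evolution, built around the carnivoran question: do social system (a proxy
for sexual selection) and diet (a proxy for intersexual niche divergence)
shape the evolution of male-biased size dimorphism?

The package implements the full analysis chain as reusable, tested library
code, exercisable end-to-end on synthetic data:

- **Dimorphism index and regime coding.** SSD is quantified by the size
  dimorphism index, `SDI = ±(S_L/S_S − 1)·100`, positive when males are the
  larger sex. Species are coded into four social systems and five dietary
  regimes, collapsed to six combined regimes
  ({solitary, group} × {carnivory, omnivory, other}) for multi-optima
  modelling.
- **Rensch's rule.** Phylogenetic reduced major axis (RMA) regression of
  ln male mass on ln female mass with Pagel's λ estimated simultaneously by
  maximum likelihood; the slope is tested against 1 on the log scale with
  Clarke's effective degrees of freedom (slope > 1 ⇒ positive Rensch trend).
- **Stochastic character mapping.** Mk (ER/SYM/ARD) rate estimation by
  Felsenstein pruning, and full regime histories drawn conditionally on tip
  states (joint node-state sampling + uniformization bridges per branch).
- **Multi-optima Ornstein–Uhlenbeck model selection.** BM1, OU1, and OUM
  models (regime-specific optima Θ, shared α and σ²) fitted by ML on each
  mapped tree; small-sample AICc weights averaged across map replicates;
  phylogenetic half-life `ln 2 / α`; parametric-bootstrap confidence
  intervals; Brownian ancestral states of SDI.
- **Reversible-jump MCMC shift detection.** Multi-peak OU sampler over the
  number, placement, and magnitude of SDI optimum shifts (Poisson(15) prior
  on shift count, at most one shift per branch), with Gelman–Rubin and
  effective-sample-size diagnostics and per-branch posterior shift
  probabilities.
- **Synthetic data.** Yule trees, Gillespie regime histories, and exact
  multivariate-normal trait draws reproduce the statistical shape of the
  study data, so every stage is testable without downloads.

## Worked example

```python
import ssdevol as sv

# a study-shaped synthetic dataset: 166 species, 60-Myr tree, 6 regimes
tree, history, table, _ = sv.generate_dataset(sv.paper_like_recipe(), seed=1)

# Rensch's rule: phylogenetic RMA of ln male on ln female mass
print(sv.PhyloRMA.from_table(tree, table).fit().summary())

# five-model OU comparison across stochastic regime maps
sdi = table.sdi_vector(order=tree.tip_labels)
maps = {}
for char, col in (("social", "social_system"), ("diet", "diet"),
                  ("social_diet", "combined_regime")):
    states = table.states(col, order=tree.tip_labels)
    mk = sv.fit_mk(tree, states)
    maps[f"OUM_{char}"] = sv.sample_simmaps(tree, mk.model, states, 20, seed=2)
comp = sv.compare_models(maps, sdi, tree=tree)
print(comp.summary())
print(f"phylogenetic half-life: {comp.fits[comp.best_model].half_life:.2f} Myr")
```

prints

```
Phylogenetic RMA regression — clade: all (n = 166)
  slope       0.9999 ± 0.0164   (H0: slope = 1)
  intercept   0.2633
  lambda      0.9976
  R^2         0.9559
  T = 0.006,  df = 112.97,  P = 0.9952
  Rensch's rule: none

Model comparison over 20 stochastic maps
          model  mean_AICc   dAICc  mean_AICcW
            BM1  1305.2918 84.6662      0.0000
            OU1  1297.5462 76.9205      0.0000
     OUM_social  1249.2697 28.6441      0.0014
       OUM_diet  1272.2119 51.5863      0.0000
OUM_social_diet  1220.6257  0.0000      0.9986
best model: OUM_social_diet (mean AICcW = 0.999)

phylogenetic half-life: 5.10 Myr
```

The slope near 1 (P = 0.995) means this dataset shows no Rensch trend —
male and female masses scale isometrically. The model comparison decisively
favours the combined social × diet OU model (mean AICc weight 0.999): SDI is
pulled toward regime-specific optima, and the short half-life (~5 Myr
against a 60-Myr tree) indicates fast adaptation, exactly the structure the
generator placed in the data (solitary-carnivorous optimum at 50%, other
regimes between 6% and 33%, half-life 3.16 Myr).

A command-line shell wraps the same library calls:

```sh
ssdevol simulate --seed 1 --out results/
ssdevol rma results/simulated_tree.nwk results/simulated_traits.csv
ssdevol all --seed 1 --out results/   # full pipeline + manifest
```

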