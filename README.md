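# trophicniche

Tools for quantifying the trophic niches of sympatric consumers from
three complementary data streams: **fecal contents** (what was eaten in
the last hour), **blood stable isotopes** (what was assimilated over the
preceding weeks), and **weighted bipartite consumer–resource networks**
built from both.  The package grew out of a study of three coexisting
*Turdus* thrushes feeding on five arthropod guilds and C3 / C4-CAM
fruits, but every stage is generic over consumers and resource
categories.

It is aimed at field ornithologists and trophic ecologists who have a
long-format fecal-item table, consumer δ¹³C/δ¹⁵N values, and per-source
isotope summaries, and want the full chain of standard analyses with one
reproducible seed.

## What it computes

**Diet composition** (per species and food item *i*): frequency of
occurrence FO%, numeric and volumetric shares N%, V%, their prey-specific
forms PN%, PV% (averaged only over samples containing the item), and the
prey-specific index of relative importance

    PSIRI% = (PN% + PV%) · FO% / 2 / 100 ,      Σᵢ PSIRI% = 100.

Species are classified into predominant/secondary diet guilds (e.g.
FR_IN, frugivorous secondarily insectivorous) from pooled volume shares
(>35% predominant, 10–35% secondary).

**Niche breadth and overlap** on diet-proportion vectors *p*: Levins'
B = 1/Σpᵢ², standardised B̂_A = (B−1)/(n−1) ∈ [0,1], and Pianka's
overlap O = Σpᵢⱼpᵢₖ / √(Σpᵢⱼ²·Σpᵢₖ²) ∈ [0,1].

**Bayesian stable-isotope mixing model** (SIAR model class): consumer
value x for element *j* follows

    x_ij ~ Normal( Σₖ pₖ(μ_jk + λ_jk),  Σₖ pₖ²(ω_jk² + τ_jk²) + σ_j² )

with a flat Dirichlet prior on the diet proportions *p*, trophic
discrimination factors λ ± τ (default whole-blood passerine values
2.2 ± 0.1 ‰ for δ¹³C, 2.6 ± 0.2 ‰ for δ¹⁵N), and a half-Normal(0, 5 ‰)
prior on the residual scales σ_j.  The posterior is sampled by adaptive
Metropolis on additive-log-ratio coordinates, with split-R̂ diagnostics,
and summarised as equal-tailed 95% credible intervals per source.

**Isotopic niches**: small-sample-corrected standard ellipse areas
SEAc = π√det(Σ̂)·(n−1)/(n−2) in δ-space, bootstrap standardisation to a
common n, and pairwise ellipse-overlap percentages.

**Bipartite networks**: one matrix weighted by PSIRI% (diet) and one by
mixing-model 95%-CI midpoints (isotope); weighted nestedness WNODF,
standardised Kullback–Leibler specialization d′ ∈ [0,1] with exact
marginal-constrained bounds, and a vaznull null model (preserving
connectance and total interaction quanta) for significance testing.

## Worked example

Rebuild the isotope network of the three-thrush study from the printed
credible-interval table bundled with the package:

```python
from trophicniche import AnalysisConfig, nestedness_test, wnodf
from trophicniche.datasets import thrush_isotope_network
from trophicniche.network import specialization_table

net = thrush_isotope_network()       # 3 consumers x 7 source groups
print(wnodf(net))
print(specialization_table(net).round(3))
res = nestedness_test(net, AnalysisConfig(n_null=1000, rng_seed=1))
print(f"observed={res.observed_wnodf:.2f} "
      f"null_ci=({res.null_ci[0]:.2f}, {res.null_ci[1]:.2f}) "
      f"significant={res.significant}")
```

prints

```
31.25
        consumer     d  d_min  d_max  d_prime
T_amaurochalinus 0.025    0.0  1.076    0.023
    T_albicollis 0.116    0.0  1.070    0.108
   T_rufiventris 0.154   -0.0  1.110    0.139
observed=31.25 null_ci=(13.19, 31.25) significant=False
```

The network is weakly nested (WNODF 31.25 of 100), sitting exactly on
the upper bound of its null distribution — the marginal pattern the
original study reported — and all three thrushes are generalists
(d′ ≪ 1), with the predator-leaning *T. rufiventris* the most
specialised.

A complete synthetic study with known ground truth runs end to end in a
couple of minutes:

```python
from trophicniche import AnalysisConfig, ScenarioConfig, run_study, simulate_study

study = simulate_study(ScenarioConfig(rng_seed=1))   # 3 species, 7 sources
cfg = AnalysisConfig(rng_seed=1, n_null=200)
res = run_study(study.feces, study.blood, study.sources, cfg)
print(res.guilds)
print(res.niche_overlap.round(2))
```

```
   species predominant secondary  code
consumer_A          FR        IN FR_IN
consumer_B          FR      None    FR
consumer_C          FR      None    FR
 species_1  species_2  overlap_area  overlap_pct
consumer_A consumer_B          1.17        25.42
consumer_A consumer_C          0.96        16.23
consumer_B consumer_C          0.16         2.44
```

The two consumers simulated with similar fruit-leaning diets overlap
most in δ-space; the divergent predator-leaning consumer barely overlaps
either — and `res.ci` shows its true diet (60% predators, 29% C3
fruits) recovered inside every 95% credible interval.

The same stages are available from a shell:

```bash
trophicniche simulate --seed 1 --out-dir study/
trophicniche run-all study/feces.csv study/isotopes.csv study/sources.csv \
    --seed 1 --out-dir results/
```

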