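# seedpassage

Joint Bayesian modelling of seed excretion and germination after ingestion
by wild ungulates (endozoochory).

## The problem

Many herbaceous plants disperse by being eaten: an herbivore swallows the
seeds with the foliage, carries them for hours to days, and defecates some
of them — sometimes still able to germinate — kilometres away.  Predicting
where such seeds end up requires knowing (i) how long seeds stay in the
vector's gut (the retention time), and (ii) how many survive the passage.
Both are estimated here from feeding experiments: captive roe deer
(*Capreolus capreolus*), red deer (*Cervus elaphus*) and wild boar
(*Sus scrofa*) each ingest a known mixture of seeds of six plants
(*Calluna vulgaris*, *Juncus effusus*, *Plantago media*, *Prunella
vulgaris*, *Rubus fruticosus*, *Trifolium pratense*), and every fresh
feces is collected for 54 h — every 3 h up to 24 h, every 6 h thereafter.
From each feces two weighed subsamples are taken: one dissected under a
stereomicroscope to count seeds, one grown out to count seedlings.

The package is written for ecologists and biostatisticians who want to fit
this model to their own feeding-experiment data, or to study its behaviour
(identifiability, power, convergence) on simulated experiments.  Because
the counts are doubly subsampled and imperfectly detected, a naive
per-interval tally badly underestimates excretion; the model below handles
the whole observation chain explicitly.

## The model

For animal $i$ (species $s(i)$), plant $j$ and collection time $t$
(interval length $\Delta_t$), with $N^{tot}_{ij}$ ingested seeds:

**Excretion** — initial gut load and per-interval release

$$Nt_{ij,0} \sim \mathrm{Poisson}(N^{tot}_{ij}), \qquad
  Nf_{ij,t} \sim \mathrm{Binomial}(Nt_{ij,t-1},\; pexeff_{ij,t}), \qquad
  Nt_{ij,t} = Nt_{ij,t-1} - Nf_{ij,t}$$

$$pexeff_{ij,t} = defec_{i,t} \cdot pex_{ij,t} \cdot \Delta_t, \qquad
  defec_{i,t} \sim \mathrm{Bernoulli}\!\big(1 - e^{-\delta_{s(i)}\Delta_t}\big)$$

$$\operatorname{logit} pex_{ij,t} = a_{sj} + b_{sj} t + c_{sj} t^2 + \varepsilon^e_{ijt},
  \qquad c_{sj} \le 0$$

The concavity constraint gives the excretion curve an interior maximum;
the collection-grid time of that maximum is the retention-time estimate
(MRT).

**Dissection** — a subsample of relative weight $WD_{i,t}$ is dissected and
seeds are detected with probability $\lambda$:

$$Nfd_{ij,t} \sim \mathrm{Binomial}(Nf_{ij,t}, WD_{i,t}), \qquad
  Y_{ij,t} \sim \mathrm{Binomial}(Nfd_{ij,t}, \lambda_{ij,t}), \qquad
  \operatorname{logit}\lambda = \operatorname{logit} pviz_{sj} + \varepsilon^d$$

**Germination** — the non-dissected remainder feeds the germination sample
(relative weight $WG_{i,t}$):

$$G_{ij,t} \sim \mathrm{Binomial}(Nf_{ij,t} - Nfd_{ij,t},\; pg_{ij,t}), \qquad
  \operatorname{logit} pg = \operatorname{logit}(WG \cdot pgerm) + \varepsilon^g,
  \qquad \operatorname{logit} pgerm_{ij,t} = \gamma_{0,sj} + \gamma_{1,sj} t$$

Because the initial load is Poisson and every later step is a binomial
thinning, the latent counts collapse exactly (Poisson splitting):

$$Y_{ij,t} \sim \mathrm{Poisson}\!\big(N^{tot} q_t \, WD \, \lambda\big), \quad
  G_{ij,t} \sim \mathrm{Poisson}\!\big(N^{tot} q_t (1-WD)\, pg\big), \quad
  q_t = pexeff_t \prod_{u<t} (1 - pexeff_u)$$

This marginal form is the default fitting target (it also serves as an
analytic oracle against the complete-data density), with the detection
probability additionally integrated out in closed form during sampling.
Posterior sampling is blockwise adaptive random-walk Metropolis with
Gelman–Rubin convergence checks (threshold 1.2) and posterior predictive
checks on replicated counts.

## Worked example

No feeding-experiment dataset is distributed with the package, so the
example simulates one at the built-in parameter presets and refits it:

```python
import seedpassage as sp

model = sp.SeedExcretionModel.from_simulation(seed=1)   # 3 species x 6 replicates
res = model.fit(sp.desk_settings(seed=2))               # ~45 s on one core
print(res.summary())
```

Output (abridged):

```
Joint seed excretion / germination model
========================================================
chains: 3   retained draws/chain: 2000   backend: marginal

Defecation probability per 3-h interval (median [95% CrI]):
  red_deer     0.78 [0.67; 0.87]
  roe_deer     0.68 [0.57; 0.78]
  wild_boar    0.39 [0.29; 0.49]

Retention time (grid argmax, h) and max excretion probability:
  roe_deer   x Juncus_effusus     MRT   18 h [18; 21]  max pex 0.0023 [0.0013; 0.0156]
  wild_boar  x Rubus_fruticosus   MRT   42 h [42; 42]  max pex 0.0930 [0.0813; 0.1035]
  wild_boar  x Trifolium_pratense MRT   48 h [48; 48]  max pex 0.0186 [0.0144; 0.0333]
  ...

Max germination probability over the window (median [95% CrI]):
  red_deer   x Juncus_effusus     0.560 [0.104; 0.862]
  red_deer   x Prunella_vulgaris  0.000 [0.000; 0.935]  [degenerate: no seedlings]
  ...
```

Reading it: the two ruminants defecate in most 3-h intervals while the
wild boar does not; seeds leave the ruminants around 18–36 h but the boar
around 36–48 h (pairs whose median argmax sits on the first or last
collection time are flagged — the curve is still rising or falling there,
so the retention time is censored by the 54-h horizon); and germination
after passage is rare, with pairs that produced no seedlings flagged as
degenerate rather than reported as spuriously precise zeros.
`res.convergence()` printed `max Rhat = 1.003` for this fit, within the
1.2 acceptance threshold.

The same pipeline is available from the shell:

```bash
seedpassage simulate --seed 1 --out sim/
seedpassage fit --trials sim/trials.csv --feces sim/feces.csv --seed 2 --out fit/
seedpassage diagnose --fit-dir fit/
seedpassage summarize --trials sim/trials.csv --feces sim/feces.csv --fit-dir fit/ --out tables/
seedpassage report --trials sim/trials.csv --feces sim/feces.csv --fit-dir fit/ --out report/
```

## File formats

`trials.csv`: `animal_id, species, replicate, plant, ntot` — one row per
animal x plant with the ingested seed total.
`feces.csv`: `animal_id, time_h, defec, w_g, wd_g, wg_g, plant, y_count,
g_count` — one row per animal x collection time x plant; weights (whole
feces, dissected sample, germination sample, grams) repeat across the
plant rows of a time; `defec = 0` rows carry zeros.  Times are hours since
the last ingestion.  Fits persist as `draws.csv`
(`chain, iter, parameter, value`), `convergence.csv` (parameter, Rhat,
effective sample size) and `summary_table2.csv` (per species x plant max
excretion probability and retention time with 95% CrIs and the boundary
flag).  Seed-trait tables use
`plant, length_mm, width_mm, height_mm, mass_mg, shape_variance,
longevity_index, mix_count_roe, mix_count_other`.

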