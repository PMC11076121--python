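# colonytrack

Movement, home-range and social-network analysis for ultra-wideband (UWB)
tracking of chicks in a ground-nesting gull colony.

Semi-precocial gull chicks roam around their nest from about a week of age,
and how far they roam — and whom they bump into — depends on how densely
their neighbours breed. `colonytrack` implements the full analysis chain for
a cross-fostering + UWB-tracking experiment on this question, for movement
ecologists and behavioural biologists working with high-resolution tag data
in fenced, plot-structured colonies:

* **cleaning** — boundary-buffer, artifact-line and speed filters for raw
  fixes, plus resampling to a regular grid;
* **movement metrics** — movement activity (mean 5-min step length) and its
  across-day repeatability `R = s_a^2 / (s_a^2 + s_e^2)` from a REML
  random-intercept model with parametric-bootstrap CI;
* **home range** — 95% kernel utilization distribution with reference
  bandwidth `h_ref = sqrt((var_x + var_y)/2) n^(-1/6)`;
* **social network** — proximity associations (< 0.6 m at the same 30 s
  rounded timestamp) on the raw fixes; degree and association strength per
  chick, siblings counted separately;
* **covariates** — pre-/post-natal mean distance to the three nearest
  nests (NN3) and fence proximity;
* **inference** — Gaussian and Poisson mixed models of the four responses,
  likelihood-ratio / Wald term tests, the interaction-dropping rule, and a
  node-label permutation null constrained within plots;
* **synthetic data** — a generator emulating the colony layout,
  Ornstein-Uhlenbeck chick movement with planted density effects and
  sibling cohesion, and the tags' gap structure and noise, so the whole
  pipeline is testable end to end.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a study-sized colony, run the pipeline and inspect the headline
numbers:

```python
from colonytrack import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    outdir="out", scenario="paperlike", seed=7, n_boot=200, n_perm=1000,
))

rep = report["repeatability"]
print(f"repeatability R = {rep['R']:.2f} (95% CI {rep['ci_low']:.2f}-{rep['ci_high']:.2f})")
sib = report["sibling_correlation"]
print(f"sibling correlation of movement r = {sib['movement_r']:.2f}")
for row in report["models"]["movement"]["terms"]:
    print(f"movement ~ {row['term']:>14}: coef {row['coef']:+.3f}  p = {row['p']:.4f}")
```

prints (seed 7):

```
repeatability R = 0.79 (95% CI 0.70-0.85)
sibling correlation of movement r = 0.99
movement ~            sex: coef +0.008  p = 0.5722
movement ~           size: coef +0.001  p = 0.7811
movement ~        nn3_pre: coef +0.024  p = 0.0096
movement ~       nn3_post: coef +0.134  p = 0.0000
movement ~          fence: coef -0.092  p = 0.0303
movement ~ nn3_pre_x_post: coef +0.014  p = 0.0115
```

Movement activity is highly repeatable across the three tracking days and
strongly correlated between siblings. The post-natal neighbour distance is
the dominant predictor: chicks reared with closer neighbours move less
(+0.134 on the sqrt-metre scale per metre of NN3). The same run fits the
home-range, degree and strength models and attaches within-plot permutation
p-values to the network models (`report["models"]["strength"]["permutation"]`).

The same stages are available as shell commands:

```sh
colonytrack simulate --scenario paperlike --seed 7 --outdir sim/
colonytrack clean --fixes sim/fixes_observed.csv --colony sim/colony.json --out clean.csv
colonytrack metrics --clean clean.csv --out metrics.csv --repeatability
colonytrack network --fixes sim/fixes_observed.csv --chicks sim/chicks.csv --out net.csv
```

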