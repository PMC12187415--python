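# fishsde

Quantitative analysis of collective intermittent exploration in small
groups of fish, from tracked 2-D trajectories to a data-driven stochastic
model of the interindividual distance.

Zebrafish in a circular arena alternate between swimming close to their
conspecifics and short bouts of far-distance exploration, and the balance
between the two shifts with the available visual information. This
package implements the full quantitative pipeline for studying that
behaviour:

- **visual cues** — per-frame *opacity* (the fraction of a fish's visible
  angular field, 2π − γ with a blind angle γ ≈ 21°, occluded by
  conspecific bodies modelled as 3 cm discs) and *optic flow* (the
  integral of the absolute angular speed of those occlusions across the
  visible field), computed analytically from angular-interval geometry
  and validated against a brute-force ray-casting oracle;
- **exploration episodes** — maximal runs where the interindividual
  distance x(t) (pairwise distance for dyads, mean pairwise distance for
  triads) exceeds 3 body lengths (9 cm) for more than 3 s after prior
  close proximity, summarised by duration T and amplitude A per trial;
- **SDE identification** — the distance process is modelled as
  dx = F(x) dt + G(x) dW. Drift and squared diffusion are estimated
  pointwise from forward increments (Kramers–Moyal conditional moments),
  averaged in 0.1 cm state bins, and their functional forms selected by
  stepwise sparse regression: a polynomial library fit by LASSO
  (coordinate descent with soft-thresholding), iterative pruning of small
  coefficients, and K-fold cross-validated error as the stopping and
  selection rule. The result is a cubic drift
  F(x) = a₀ + a₁x + a₂x² + a₃x³ and a parabolic diffusion
  G(x) = b₀ + b₁x + b₂x²;
- **bistable potential** — the cubic drift derives from a tilted
  double-well landscape V(x) = −αx − β(x − xl)²(x − xh)², with the
  close-proximity well at xl, the exploration well at xh, barrier set by
  β and bias by α; closed-form conversions between (α, β, xl, xh) and
  the cubic, trapezoidal reconstruction of V from binned drift, and a
  bistability report (wells, barrier, tilt direction);
- **in-silico experiments** — Euler–Maruyama integration of identified
  models, a four-condition design (dyads/triads × bright/dark) with a
  fixed number of trials per condition, interquartile-range outlier
  exclusion, and a two-way ANOVA (Type II, with η² effect sizes) on the
  per-trial episode statistics;
- **synthetic data** — seeded generators for distance paths from built-in
  bright/dark regimes, 2-D group trajectories embedded in the arena that
  reproduce a given distance series, and visual-geometry fixtures with
  ray-cast ground truth. Everything the pipeline consumes can be
  generated from a seed; no downloads are required.

## Worked example

Generate five synthetic "dark" dyad trials (10 min at 30 Hz each),
detect exploration episodes, and identify the distance SDE:

```python
import numpy as np
from fishsde import (SynthSpec, SSRConfig, generate_trials,
                     interindividual_distance, detect_episodes,
                     bistability_report)
from fishsde.inference import identify_sde

spec = SynthSpec(illumination="dark", group_size=2, seed=0)
trials = generate_trials(spec, n_trials=5)
series = [interindividual_distance(t) for t in trials]

eps = [detect_episodes(s) for s in series]
n_eps = sum(len(e) for e in eps)
mean_T = np.mean([ep.duration for e in eps for ep in e])
mean_A = np.mean([ep.amplitude for e in eps for ep in e])
print(f"episodes: {n_eps}, mean duration {mean_T:.1f} s, mean amplitude {mean_A:.1f} cm")

model, binned, drift_res, diff_res = identify_sde(series, SSRConfig(seed=0))
print("drift coefficients:", np.round(model.drift.coefficients, 4))
print("diffusion (b0, b1, b2):", np.round(model.diffusion.coefficients, 4))
rep = bistability_report(model)
print(f"wells at {rep['wells'][0]:.2f} and {rep['wells'][1]:.2f} cm, "
      f"barrier at {rep['barrier_x']:.2f} cm, tilt: {rep['tilt_direction']}")
```

Output:

```
episodes: 11, mean duration 73.3 s, mean amplitude 13.5 cm
drift coefficients: [ 5.428  -1.9591  0.1999 -0.0061  0.      0.    ]
diffusion (b0, b1, b2): [ 0.9496  0.1111 -0.0056]
wells at 4.71 and 16.84 cm, barrier at 11.23 cm, tilt: toward_close
```

The generating "dark" regime has wells at 5 and 17 cm and diffusion
(0.80, 0.12, −0.006): from 90 000 samples the pipeline selects a cubic
drift whose wells land within ~0.3 cm of the truth, a downward-curved
parabola for the noise amplitude, and a landscape tilted toward
close-proximity swimming — long (~73 s), far (~13.5 cm) episodes are
exactly what that shallow, weakly tilted landscape produces.

## Command line

Each pipeline stage is a subcommand writing plain CSV/JSON, so any stage
can be inspected or replaced:

```bash
fishsde synth --seed 0 --illumination dark --n-trials 5 --out traj.csv
fishsde metrics traj.csv --out cues.csv
fishsde episodes traj.csv --out episodes.csv --stats-out stats.csv
fishsde infer traj.csv --out model.json --binned-out binned.csv
fishsde potential model.json --out report.json --curve-out potential.csv
fishsde simulate model.json --seed 1 --n-trials 10 --out paths.csv
fishsde insilico --seed 0 --out insilico.csv --anova-out anova.json
```

A YAML config (`--config`) can override arena geometry, visual-field,
episode, inference and simulation defaults; rerunning a stage with the
same inputs and seed reproduces its outputs byte for byte.

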