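# p2an — prior-conditioned attention network for ECG inverse imaging

Electrocardiographic imaging (ECGI) estimates cardiac **transmembrane
potentials** (TMP) from **body-surface potentials** (BSP) by inverting the
linear forward model

    Ω = H U,        U ∈ ℝ^{M×L} (TMP, mV),  Ω ∈ ℝ^{N×L} (BSP, mV),

where `H` is the transfer matrix between M cardiac surface nodes and N
torso electrodes. The inversion is severely ill-posed. This package
implements a reconstruction network — the **prior-to-attention network
(P2AN)** — that stabilizes the inversion with a priori physiological
knowledge: the healthy *standard TMP* `u` of the same geometry enters both
through cross-attention (its embedding supplies keys and values in every
decoder block) and through the objective

    L_total = ‖H û − Ω‖² + λ‖û − u‖²,   λ = 0.01,

so training needs no measured TMP at all. Around the model the package
provides everything needed to study it end to end on synthetic geometry:

* an equivalent-double-layer forward model built from analytic triangle
  solid angles on a spherical heart (128 nodes) inside a 64-electrode
  torso shell (`p2an.geometry`);
* an action-potential simulator with two lesion families — myocardial
  ischemia (regional 25–80% amplitude reduction) and ventricular
  hypertrophy (regional 25–50 ms depolarization delay) — plus calibrated
  Gaussian measurement noise at 30/25/20/15 dB SNR (`p2an.simulate`);
* classical and learned baselines: Tikhonov, (unrolled) ISTA and a
  per-time-sample FFNN (`p2an.baselines`);
* metrics and statistics: relative error (RE), per-node Pearson
  correlation (CC), lesion-centroid localization error (LE, mm), paired
  t-tests and Cohen's d (`p2an.metrics`);
* a config-driven pipeline and CLI gluing simulation → training →
  evaluation (`p2an.pipeline`, `p2an` console command).

Intended users: researchers in computational cardiac electrophysiology who
want a fully reproducible, CPU-sized testbed for prior-conditioned ECGI
reconstruction methods.

## Worked example

```python
import numpy as np
from p2an.pipeline import (build_environment, simulate_task, train_solver,
                           evaluate_solver, study_config)

cfg = study_config(seed=1)           # 128 nodes, 64 electrodes, 20 eval cases
env = build_environment(cfg)         # mesh, electrodes, H, standard TMP
eval_cases, train_cases = simulate_task(cfg, env, "MI")
model = train_solver(cfg, env, train_cases, "p2an")   # ~minutes on one CPU
metrics = evaluate_solver(model, eval_cases, env, cfg)
clean = metrics[np.isinf(metrics.snr_db)]
print(clean[["RE", "CC", "LE_mm"]].mean())
```

prints (seed 1; your hardware will differ only in runtime)

```
RE        0.025
CC        1.000
LE_mm    13.729
```

meaning: averaged over the 20 held-out ischemia cases, the reconstructed
TMP deviates from the simulated ground truth by ~2.5% per node in
relative L2 norm, tracks the per-node waveforms with correlation > 0.999,
and the centroid of the detected lesion area lands within ~14 mm of the
true lesion centroid (the mesh's mean node spacing is ~16 mm).

The same study from the shell:

```sh
p2an simulate --config cfg.yaml
p2an train    --config cfg.yaml --solver p2an
p2an evaluate --config cfg.yaml
p2an report   --config cfg.yaml
```

`report` renders the per-task "mean (SD)" tables (rows RE / CC / LE (mm),
columns P2AN / ISTA / FFNN) for clean and each noise level.

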