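# sstembatch

Quantitative planning and quality control for **batch-processed serial-section
transmission electron microscopy (ssTEM)**.

Reconstructing neural tissue in 3-D from serial ultrathin sections fails
catastrophically when two *consecutive* sections are lost: a single missing
section can be interpolated across, a missing pair cannot. At the scale of a
cubic millimetre (~25,000 sections of 40 nm), even a 1% per-section loss rate
makes a traditionally processed run — one section per TEM grid — very unlikely
to finish intact. Batch processing distributes consecutive sections across the
`m` substrates of a batch (each substrate holding `c` sections), so a
consecutive pair can only be lost when a batch loses two or more whole
substrates. This package implements the closed-form models that quantify this
trade, a Monte-Carlo simulator that validates and bounds them, and the
image/placement quality-control metrics used to show that batched collection
does not degrade the data.

## The models

With per-section loss rate `p`, the probability of losing a specified
consecutive pair is `p²`, and the traditional-process experiment yield over
the `n − 1` pair slots is

    Y_trad = (1 − p²)^(n−1)            # ≈ 8% at n = 25000, p = 0.01

For batches of `m` substrates × `c` sections with per-substrate loss rate
`p′`, a batch fails when it loses ≥ 2 substrates,

    P = 1 − [(1 − p′)^m + m p′ (1 − p′)^(m−1)]

and the experiment yield over `k = ⌈n / (c m)⌉` batches is

    Y_batch = (1 − P)^k                # ≈ 91% at m = 4, c = 40, p′ = 0.01

Collection time and consumable cost are linear in `n`:

    T_trad  = (t_img + t_pickup,man + t_load) · n
    T_batch = (t_load / (c m) + t_img + t_pickup,robot) · n
    C_trad  = n · c_grid               C_batch = (n / s) · w

where `s` is sections per microfabricated wafer and `w` the wafer cost.

Alongside the models sit the validation metrics: edge-spread-function (ESF)
roll-off slope and Michelson contrast over annotated synaptic vesicles,
section-centroid detection and placement accuracy / aperture containment,
cycle-time statistics, and Fisher's exact comparison of 2×2 yield tables.
Seeded synthetic generators produce every input with ground truth for
recovery testing.

## Worked example

```python
from sstembatch import (BatchLayout, ExperimentPlan, LossRates, SimulationConfig,
                        batched_experiment_yield, simulate_batched,
                        traditional_experiment_yield)

plan, rates, layout = ExperimentPlan(25000), LossRates(0.01, 0.01), BatchLayout(4, 40)
print(round(traditional_experiment_yield(plan, rates), 3))     # 0.082
print(round(batched_experiment_yield(plan, layout, rates), 4)) # 0.9112
mc = simulate_batched(plan, layout, rates, SimulationConfig(trials=10000, seed=1))
print(round(mc.yield_estimate, 4), round(mc.mc_stderr, 4))     # 0.9078 0.0029
```

The batched layout lifts the success probability from 8.2% to 91.1% — an
order of magnitude — and the strict-mode Monte-Carlo estimate agrees with the
closed form to within sampling error. The `examples/` directory holds one
narrative script per capability:

* `plan_experiment.py` — yield / time / cost at the published operating point
  and a grid search for the best batch layout;
* `simulate_collection.py` — Monte-Carlo vs closed form, plus the exact
  no-two-adjacent-losses recurrence;
* `image_quality_demo.py` — ESF slope and Michelson contrast recovered from a
  synthetic vesicle image;
* `placement_demo.py` — placement statistics, centroid re-detection from a
  rendered substrate photo, cycle times, and the Fisher yield comparison.

A thin CLI mirrors the library (`sstembatch plan yield --n 25000`,
`sstembatch simulate …`, `sstembatch qc esf …`, `sstembatch placement …`,
`sstembatch synth …`); results land as JSON/CSV in `--outdir` with a run
manifest, and one `--seed` flag controls all randomness.

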