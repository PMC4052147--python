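# ppdecode

Sequential Monte Carlo decoding of arm kinematics from multielectrode
spike trains observed as point processes, with tuning models that include
recent **ensemble spiking history**.

Motor brain–machine interfaces reconstruct continuous movement (cursor or
limb position, velocity, acceleration) from the spiking of motor-cortical
neurons. Treating each spike train as a point process in fine 10-ms bins
keeps the spike-timing information that coarse rate binning discards: with
conditional intensity λ(t), the probability of the binary count dN in one
bin is `exp(dN·log(λΔ) − λΔ)`. Classical decoders model λ as a function of
the kinematics x_t alone ("mov" model); neurons, however, are also driven
by their own and their neighbours' recent spiking. `ppdecode` implements
the log-linear tuning model

    λ(x_t, H_t) = exp(α0 + Σᵢ αᵢ x_tⁱ + Σⱼ βⱼ H_tʲ)

("full" model), where H_tʲ counts neuron j's spikes in the window
[t − l, t), and a particle filter that propagates kinematic hypotheses
through a linear transition model `x_k = A[x_{k−1}; H_{k−1}] + w`, weights
them by the joint point-process likelihood of the observed spike vector,
and applies systematic resampling every bin, with cumulative weights
computed by a work-efficient balanced-tree prefix scan. Goodness of fit
is assessed with ROC/AUC spike prediction and time-rescaling KS analysis.

The package is written for computational neuroscientists and BMI
researchers who want a tested, reproducible reference implementation of
this decoding loop, together with a synthetic coupled-ensemble generator
that closes the encode → decode → evaluate cycle without animal
recordings.

## Worked example

Simulate a coupled 15-neuron, 240-s session, fit both model kinds on the
first 120 s, decode the rest and compare:

```python
import numpy as np
import ppdecode as pp

cfg = pp.SimulationConfig(n_neurons=15, duration=240.0, seed=3)
rng = np.random.default_rng(cfg.seed)
kin = pp.simulate_kinematics(cfg, rng)
truth = pp.draw_true_tuning(cfg, rng)
spikes = pp.simulate_ensemble(kin, truth, rng=rng)
print(f"mean rate {spikes.mean_rates().mean():.2f} Hz")

res = pp.run_session(
    spikes, kin, train_bins=12_000, kinds=("mov", "full"),
    n_particles=300, decode_seed=11, n_decode_runs=3,
)
for kind in ("mov", "full"):
    print(f"{kind:4s} position RMSE {res[kind]['pos_rmse']:.3f}")
```

prints

```
mean rate 4.30 Hz
mov  position RMSE 0.812
full position RMSE 0.689
```

RMSE is in normalized (z-scored) kinematic units, so 1.0 is the score of
the constant train-mean predictor: both decoders track the position well,
and the full model — whose observation model knows the realized ensemble
history — tracks it better. The same comparison across eight seeded
sessions, with a left-tail paired t-test on the session RMSEs, is run by

```bash
ppdecode compare --sessions 8 --neurons 15 --seconds 240 \
    --train-seconds 120 --particles 300 --seed 300 --out report.json
```

The CLI also exposes `simulate`, `fit`, `gof`, `decode` and
`scan-history` (the held-out-AUC sweep that selects the history window
l; on data generated with l = 100 ms it recovers 100 ms). All commands
write TSV/JSON and log their seeds.

As an estimator, `pp.SMCDecoder(kind="full", n_particles=1000,
random_state=0)` follows the scikit-learn conventions
(`fit(spikes, kinematics)`, `predict`, `get_params`/`set_params`).

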