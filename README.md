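# dnmark

Early-warning signals for critical transitions in noisy multivariate time
series, built around two ideas:

1. **Distribution embedding ("making big noise smaller").** A state series
   x(t) perturbed by strong noise is transformed, through sliding windows,
   into the series of its first and second moments — n means u_i and
   n(n+1)/2 covariances v_ij, i.e. N = n(n+3)/2 *distribution variables*.
   Window averaging suppresses the fluctuations, so the embedded series is
   far less noisy than the raw one, and the classical critical-slowing-down
   (CSD) indicators — rising variance and rising lag-1 autocorrelation —
   become informative again even when strong noise has destroyed them in
   the raw data. Under strong noise the transition is a *distribution*
   transition: it happens near the bifurcation of the moment system, which
   precedes the bifurcation of the deterministic skeleton.

2. **The dynamical network marker (DNM).** Approaching a transition, a
   dominant group of variables emerges whose members fluctuate strongly
   (SD_d up), correlate tightly with each other (PCC_in up) and decouple
   from the rest (PCC_out down). The composite score

       I = SD_d · PCC_in / (PCC_out + ε)

   (ε a small constant guarding against zero division) rises sharply
   before the transition and provides the warning signal.

The package is aimed at anyone hunting regime shifts in noisy systems —
gene-regulatory and physiological state transitions, lake eutrophication,
financial stress — and ships the stochastic-simulation and moment-equation
machinery needed to validate the method end to end: an Euler–Maruyama SDE
integrator with quasi-static parameter sweeps, the fold normal form
dx/dt = p + 3x − x³ + σξ and an 18-node regulatory network as model
systems, exact moment ODEs for linear SDEs (du/dt = Au + b,
dV/dt = AV + VAᵀ + D), the one-dimensional Gaussian closure
(du/dt = f(u) + ½f″(u)v, dv/dt = 2f′(u)v + σ²), and an equilibrium
continuation that locates the fold of the moment system.

## Worked example

Sweep the fold model quasi-statically from p = −6 to 6 under big noise
(σ = 1.0), keep only the data before the state jump, and compare the raw
and embedded views:

```python
import numpy as np
from dnmark import (SlidingWindowSpec, TimeSeriesMatrix, dominant_group_track,
                    sliding_window_moments, snr, windowed_indicators)
from dnmark.experiments import SIGMA_BIG, detect_jump, fold_sweep

traj = fold_sweep(SIGMA_BIG, seed=0)
j = detect_jump(traj)                       # first committed crossing of x = 1
print(f"jump at t={traj.times[j]:.2f} (p={traj.parameter_track[j]:.1f})")

ts = TimeSeriesMatrix(times=traj.times[:j], values=traj.states[:j])
spec = SlidingWindowSpec(length=10, step=1)
moments = sliding_window_moments(ts, spec)   # columns u_1, v_1_1

raw = windowed_indicators(ts, spec)
emb = windowed_indicators(moments, spec)
print(raw.trend_tau.loc["x1", ["sd", "ar1"]].to_numpy())
print(emb.trend_tau.loc["v_1_1", ["sd", "ar1"]].to_numpy())
print(snr(ts, moments, spec)["ratio"])

dnm = dominant_group_track(moments, spec)
print(f"DNM warning at t={dnm.warning_time:.1f}, peak at t={dnm.peak_time:.1f}")
```

Output (seed 0):

```
jump at t=69.91 (p=0.9)
[0.194 0.105]
[0.288 0.043]
1.8095580752683966
DNM warning at t=26.9, peak at t=61.9
```

Reading: the noise pushed the state jump to p = 0.9, well before the
deterministic fold at p = 2. The Kendall trends of SD and lag-1
autocorrelation are positive for both representations here, but over many
replicates the raw trends become unreliable while the embedded ones stay
positive (the test suite measures exactly that contrast over 50 seeded
sweeps). The embedding raises the aggregate signal-to-noise ratio by
about 1.8×, and the DNM score on the embedded (u, v) series exceeds its
baseline excursion threshold at t ≈ 27 — far ahead of the jump at
t ≈ 70 — and peaks just before it.

The same pipeline is available from the shell:

```sh
dnmark simulate --model fold --sigma 1.0 --seed 0 --out traj.csv
dnmark embed --input traj.csv --out moments.csv
dnmark dnm --input moments.csv --out dnm.json
dnmark report --input traj.csv --outdir report/
```

`dnmark simulate --model network ...` sweeps the packaged 18-node
regulatory network, whose second-order embedding has 189 moment
variables.

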