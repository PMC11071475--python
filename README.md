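# petkinetics

Single-molecule binding kinetics for enzymes that act on insoluble
substrates, built around TIRF microscopy of quantum-dot-labeled PETase
binding to surface-immobilized PET film.

## The problem

PET-degrading enzymes only erode the *surface* of their insoluble
substrate, so bulk Michaelis–Menten assays cannot cleanly separate the
binding rate k_on, the unbinding rate k_off and the turnover rate k_cat.
Single-molecule imaging sidesteps this: each landing of a labeled enzyme
on the substrate film is observed directly, so the landing frequency and
the residence (dwell) time distribution become the primary observables.

Two identities carry the kinetic content. A bound enzyme leaves the
surface either by unbinding or by completing catalysis (followed by rapid
product release), so the fast-phase dwell time constant measures an
*apparent* off-rate

```
k_off_app = k_off + k_cat = 1 / tau_fast
```

which immediately bounds the turnover rate (k_cat ≤ k_off_app), and each
binding encounter ends productively with probability

```
p_catalysis = k_cat / (k_cat + k_off)
```

Dwell-time distributions are biexponential in practice: a fast phase
(specific, catalytically relevant binding) plus a slow phase from
nonspecifically stuck labels whose apparent durations are set by
photobleaching/blinking of the quantum dot, not by chemistry. The package
therefore includes the two control analyses that justify this reading:
population photobleaching fits of immobilized emitters, and the
laser-power dependence of the slow component.

## What the package does

* `simulate` — ground-truth generator: Poisson landings at a normalized
  rate (events·μm⁻²·s⁻¹·M⁻¹), two-population exponential dwell mixture,
  optional bleach-truncation clock, rendered TIFF movies (Gaussian PSF on
  noisy background), population bleach traces.
* `kymograph` — reslice a movie into y-bands (spacing matched to the PSF)
  and project into a single position–time image.
* `detect` — threshold + 8-connected streak grouping, gap bridging,
  censoring flags, landing-rate normalization per area/time/concentration.
* `survival` — empirical 1−CDF, mono/biexponential least-squares fits
  with covariance or bootstrap standard errors, an independent
  maximum-likelihood mixture fit, and an F-test model comparison.
* `photobleach` — mean-intensity traces, exponential-decay fits, and the
  laser-power monotonicity report.
* `kinetics` — apparent off-rate, k_cat upper bound, catalysis
  probability, corrected landing rates (overall × fast-phase amplitude),
  Welch t-tests between conditions.
* `pipeline` / `cli` — end-to-end orchestration (`petkinetics run`),
  cohort simulation (`petkinetics simulate`), and per-stage subcommands
  (`kymo`, `detect`, `fit`, `bleach`, `summarize`).

## Worked example

```python
import numpy as np
from petkinetics import (
    SimulationConfig, simulate_dwell_times, empirical_survival,
    fit_biexponential, report_off_rate, catalysis_probability,
    simulate_landing_events, landing_rate, aggregate_landing_rates,
)

# 2000 dwell times from a wild-type-like mixture, 5 frames/s acquisition
dwells = simulate_dwell_times(2000, tau_fast=2.7, tau_slow=38.6,
                              fast_fraction=0.7, frame_interval=0.2, seed=1)
curve = empirical_survival(dwells, min_observable=0.2)
fit = fit_biexponential(curve, se_method="bootstrap", n_boot=100)
print(f"tau_fast = {fit.tau_fast:.2f} +/- {fit.se_tau_fast:.2f} s")
print(f"tau_slow = {fit.tau_slow:.1f} +/- {fit.se_tau_slow:.1f} s")
print(f"amp_fast = {fit.amp_fast:.2f}")
print(f"k_off_app = {report_off_rate(fit.tau_fast):.2f} 1/s")

# a 9-movie cohort at the wild-type landing rate, re-normalized
config = SimulationConfig(seed=1)   # 1070 /um^2/s/M, 80x80 um, 600 s, 8 nM
rng = np.random.default_rng(1)
rates = [
    landing_rate(len(simulate_landing_events(config, seed=rng)),
                 config.fov_area, config.movie_duration, config.concentration)
    for _ in range(9)
]
est = aggregate_landing_rates(rates)
print(f"landing rate = {est.mean:.0f} +/- {est.sem:.0f} /um^2/s/M (N={est.n_movies})")

# encounter outcome for a supplied split of k_off_app = 0.37 1/s
d = catalysis_probability(k_off=0.20, k_cat=0.17)
print(f"p_catalysis = {d.p_catalysis:.3f}")
```

Output:

```
tau_fast = 2.75 +/- 0.09 s
tau_slow = 39.8 +/- 2.3 s
amp_fast = 0.73
k_off_app = 0.36 1/s
landing rate = 1161 +/- 62 /um^2/s/M (N=9)
p_catalysis = 0.459
```

The fitted constants recover the generator's ground truth (2.7 s, 38.6 s,
amplitude 0.7) within their bootstrap standard errors; the cohort mean
landing rate scatters around the input 1070 μm⁻²·s⁻¹·M⁻¹ with the
expected Poisson counting error; and with the apparent off-rate split as
0.20 + 0.17 s⁻¹, 46% of binding encounters end in catalysis.

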