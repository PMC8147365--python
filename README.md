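# fallwatch

Software re-creation of a hybridized video/ultrasonic fall-detection
platform: a webcam tracks the face centroid of one subject (transverse
motion, pixels) while a three-element ultrasonic array measures the
chest range (longitudinal motion, cm). Fused into 3D movement
trajectories, these signals feed a probabilistic three-state model of
human motion — **normal**, **transition**, **falling** — built with
discrete data density functional theory (DDFT). The package is for
researchers who want to study or extend that modeling chain without the
hardware: a sensor simulator stands in for the platform, and every
downstream stage (fusion, clustering, fall map, alarm logic,
cross-validated evaluation) is an importable, tested library module with
a thin CLI on top.

## The model

Data points in the 2D map space (longitudinal range *z*, overall
centroid speed) are treated as particles. A Gaussian mixture supplies
the data density ρ(r), from which two energy density functionals are
built:

    t[ρ](r) = 2π² ρ(r)                      (kinetic — cluster significance)
    u[ρ](r) = ½ Σᵢ ρ(rᵢ′) / ‖r − rᵢ′‖ ,  r ≠ rᵢ′   (potential — data similarity)

with the adaptive scaling factor γ = ½⟨u⟩/⟨t⟩ making them commensurable.
The Hamiltonian and Lagrangian densities

    H[ρ] = γ² t[ρ] + γ u[ρ]        L[ρ] = γ² t[ρ] − γ u[ρ]

carry the cluster structure: the mean Hamiltonian as a function of the
candidate component count K flattens at the true cluster number (the
turning point of the Hamiltonian curve), and the zero level set of L —
where kinetic and potential densities balance — traces the cluster
boundaries. On fall data the selected number is two (normal motion and
falling); the region beyond 1.5 Mahalanobis standard deviations of both
cluster ellipses is the transition zone, and any sample entering it
raises the alarm. Point-level evaluation collapses the states to a
binary task (positive = transition/fall) and reports accuracy,
sensitivity and precision under event-level 10-fold cross-validation.

## Worked example

```bash
fallwatch simulate --seed 0 --out data/            # 140 synthetic fall events
fallwatch fit      --data data/sensors.csv --seed 0 --out models/
fallwatch evaluate --data data/sensors.csv --seed 0 --k 10 --out report.json
```

The `fit` step prints the selected cluster number and scaling factor:

```
K*=2 gamma=84.3345 -> models in models
```

meaning the Hamiltonian curve stabilized at two clusters — the normal
and falling motions — with γ ≈ 84.3 balancing the kinetic and potential
terms on the training density. The `evaluate` step prints the pooled
cross-validated metrics:

```
accuracy=0.88 sensitivity=1.0 precision=0.85
```

Read: 88 % of the 4,200 windowed points are classified into the correct
binary class, virtually every true transition/fall sample is caught
(sensitivity 1.0), and 85 % of alarm-class predictions are genuine
(the shortfall is normal-motion samples straying outside the 1.5-SD
normal ellipse, the designed false-alarm trade-off of the region rule).
`report.json` additionally records per-fold detail, the confusion
counts, and the mean alarm lead time (seconds from first alarm to the
true fall onset; about 1.3 s on the default synthetic conditions, of
the same order as the ~0.7 s the physical platform reports).

As a library:

```python
from fallwatch import sensor_sim, fusion, evaluate

frames, truths = sensor_sim.simulate_dataset(sensor_sim.SimConfig(seed=0))
events = fusion.dataset_trajectories(frames)       # 140 windowed events
report = evaluate.kfold_cv(events, k=10, seed=0)
print(report.pooled.rounded())                     # {'accuracy': 0.88, ...}
```

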