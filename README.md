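# jawfl

Analysis pipeline for **in vivo / in situ muscle force–length (FL)
studies of jaw muscles**, built around the kind of experiment in which a
jaw-closing muscle (e.g. the rat superficial masseter) is instrumented
with EMG electrodes, sonomicrometry crystals and a tendon-buckle force
transducer, recorded during natural biting on foods of different hardness,
and then characterised in situ with twitch and submaximal tetanic
ergometry.  The package is for muscle physiologists and biomechanists who
want that whole workflow — raw-voltage conditioning, FL-curve fitting,
per-bite feature extraction, operating-range mapping and the statistics —
as tested, reusable code rather than a chain of one-off scripts.

Because raw animal recordings from such studies are rarely shareable,
`jawfl` ships a first-class **synthetic-data generator**: it simulates
muscles with known ground truth (FL curves, calibration constants,
activation–hardness coupling) and emits the same multichannel trials the
real experiment produces.  Every stage of the analysis is validated by
recovering those known parameters.

## The science in brief

Active muscle stress σ depends on fascicle strain ε = (L − L_O)/L_O: it
rises on the ascending limb, peaks (σ_O = F_O/PCSA) on the plateau around
the optimal length L_O, and falls on the descending limb.  Two quantities
organise the analysis:

* **Activation-dependent plateau shift.**  The twitch FL curve peaks at a
  longer length than the submaximal tetanic curve from the same muscle;
  the shift is reported as 100·(L_O_twitch − L_O_tet)/L_O_tet, of order
  10 % for skeletal muscle.
* **In vivo operating points.**  Each bite contributes a point
  (ε at peak force, peak stress F_MAX/PCSA) that is superimposed on the
  in situ tetanic curve and classified onto the ascending limb, plateau
  (≥ 95 % of F_O on the fitted curve) or descending limb.

Per power stroke, seven response variables are extracted: integrated
rectified EMG (mV·s), fascicle lengths at power-stroke onset (L_MAX), EMG
onset (L_ACT) and peak force (L_MIN), the power-stroke shortening strain,
the force rise, and the peak force F_MAX.  Two-factor linear models
(individual × food hardness) with partial η² effect sizes and an
EMG–force least-squares regression with 95 % confidence/prediction limits
complete the statistics.  Details and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from jawfl import (FOODS, GeneratorConfig, MusclePrep, SonoConfig,
                   build_fl_curve, compute_plateau_shift,
                   fit_buckle_calibration, make_muscle_truth,
                   map_operating_points, process_bite_trial,
                   simulate_bite_trial, simulate_calibration_pair,
                   simulate_ergometry_session, summarize_operating_ranges)

truth = make_muscle_truth(GeneratorConfig(), seed=1)     # ground-truth muscle
prep = MusclePrep(pcsa_cm2=truth.pcsa)

curves = {}
for protocol in ("tetanic", "twitch"):                    # in situ ergometry
    trials = simulate_ergometry_session(truth, protocol=protocol, seed=1)
    curves[protocol] = build_fl_curve(trials, prep, protocol)
shift = compute_plateau_shift(curves["twitch"].L_O, curves["tetanic"].L_O)

ct = simulate_calibration_pair(truth, 5, seed=1)          # buckle calibration
model = fit_buckle_calibration(
    [(t.channel("buckle_voltage"), t.channel("force")) for t in ct],
    [t.truth["rise_window"] for t in ct])

sono = SonoConfig(gain=truth.sono_gain, epoxy_offset=truth.epoxy_offset,
                  segment_factor=truth.segment_factor)
feats = [process_bite_trial(simulate_bite_trial(truth, food, seed=100*j + i),
                            model, sono, curves["tetanic"].L_O)
         for j, food in enumerate(FOODS.values()) for i in range(5)]
points = map_operating_points(feats, curves["tetanic"])
```

Output:

```
tetanic: L_O = 7.86 mm, F_O = 6.86 N, stress_O = 11.1 N/cm^2
twitch : L_O = 8.85 mm, F_O = 0.48 N
plateau shift = 12.6 % of tetanic L_O   (truth: 12.3 %)
buckle calibration: slope = 0.0223 V/N, pooled r^2 = 0.916
        food_E  n  strain_median  stress_median  n_plateau  n_descending
group
almond   19.40  5          0.165          6.496          0             5
cheese    0.45  5          0.003          2.373          5             0
chow     50.44  5          0.188          5.999          0             5
raisin   0.22   5         -0.008          2.325          5             0
```

The twitch optimum sits 12.6 % to the right of the tetanic optimum
(truth 12.3 % for this muscle): analysing this muscle with twitches alone
would misplace its plateau by that much.  Bites on soft foods (raisin,
cheese) land on the FL plateau at low stress; bites on hard foods
(almond, chow) land on the descending limb at high stress — the
qualitative signature the mapping stage is designed to expose.

A thin CLI wraps the same functions
(`jawfl simulate|calibrate|flcurve|bites|map|stats --help`).

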