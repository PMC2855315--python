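# hedonose

Predicting the pleasantness of odors from electronic-nose (eNose)
measurements.

Human odor perception is organized primarily along a hedonic axis — how
pleasant or unpleasant a smell is — and a substantial part of that axis is
written into the physical chemistry of the odorant itself. That makes it
learnable by a machine: an array of non-specific chemical sensors (here a
16-sensor array of 8 metal-oxide and 8 quartz-microbalance sensors) produces
a response pattern per odorant, and a small regression model can be tuned to
the median pleasantness that human raters assign on a 0–30 visual-analogue
scale (VAS). `hedonose` implements that pipeline end to end, for researchers
in machine olfaction and chemosensory psychophysics:

1. **Feature extraction** — each of the 16 sensor signals contributes four
   kinetic parameters (baseline-corrected peak height, latency to peak, and
   the half-max crossing times on the rise and decay flanks); the pairwise
   peak ratios within each 8-sensor module (2 × C(8,2) = 56) are appended,
   for a canonical 120-feature signature per measurement. The feature
   matrix is normalized by columns (z-score, removing sensor-type bias) and
   then rows (unit norm, removing per-measurement vapor-concentration gain).
2. **Quality control** — repeated measurements of an odorant must cluster
   together; a sample assigned to another odorant's held-out nearest
   centroid is an instrument failure and is removed.
3. **Hedonic model** — an ensemble of 20 small feedforward networks
   (120 inputs → 5 tanh hidden units → linear output), each trained by
   full-batch gradient descent for 20 epochs from an independent random
   initialization. The prediction is the ensemble average of the centered
   target *median VAS − 15*, so a positive prediction classifies an odorant
   as pleasant and a negative one as unpleasant.
4. **Evaluation battery** — leave-group-out cross-validation (holding out
   whole odorants, never single repetitions), classification accuracy under
   widening mid-scale exclusion bands, a permutation null obtained by
   scrambling the odorant–pleasantness assignment and retraining, a power
   curve over training-set sizes, and human-agreement statistics
   (subject-pairwise, subject-to-median, test–retest, and the
   machine-to-human percent ratio).
5. **Synthetic data** — a seeded generator emulating both the sensor
   physics (rise/decay kinetics, shared concentration gain, per-sensor
   instability, occasional pattern-destroying failures) and the raters
   (subject noise, two sessions, cohort-specific scale usage), so the whole
   pipeline is exercisable and testable with no instrument.

## Worked example

```python
import hedonose as hn

study = hn.generate_benchmark(seed=0)          # 76 odorants x 5 repetitions
features, qc = hn.prepare_features(study.measurements)
targets = hn.median_pleasantness(study.ratings)

res = hn.PleasantnessModel(features, targets).fit(seed=0)
print(res.summary())

cv = hn.leave_group_out(features, targets, group_size=25, n_repeats=20, seed=0)
print(f"leave-25-out: median r = {cv.median_r:.2f}, "
      f"p<0.05 in {cv.fraction_significant:.0%} of repeats")
```

prints

```
Odor pleasantness ensemble network
============================================
Training samples:           351
Training odorants:          76
Ensemble members:           20
Hidden units / epochs:      5 / 20
Learning rate / init:       1.0 / 0.2
Seed:                       0
Training Pearson r:         0.861 (p = 2.1e-23)
============================================
Targets are median VAS - 15; positive predictions classify as pleasant.
leave-25-out: median r = 0.83, p<0.05 in 100% of repeats
```

The QC step kept 351 of the 380 simulated measurements (cluster accuracy
0.924). Training r is the in-sample correlation between the fitted
per-odorant predictions and the median ratings; the leave-25-out line is the
honest generalization estimate: the median correlation between predicted and
observed median pleasantness over 20 random 25-odorant hold-outs, with the
fraction of repeats reaching two-tailed p < 0.05. Widening the mid-scale
exclusion band raises categorical accuracy — on this run, from 0.72 with no
band to 1.00 when odorants rated between 10 and 20 are excluded — because
sign errors concentrate near the hedonic midpoint.

The same pipeline is scriptable from the shell:

```sh
hedonose simulate --odorants 76 --reps 5 --subjects 15 --seed 0 --out study/
hedonose extract  --measurements study/measurements --out features.csv
hedonose qc       --features features.csv --out mask.csv --report qc.json
hedonose train    --features features.csv --ratings study/ratings.csv \
                  --mask mask.csv --out model.json --seed 0
hedonose predict  --model model.json --features features.csv --out preds.csv
hedonose evaluate --features features.csv --ratings study/ratings.csv \
                  --mode cv --seed 0 --out cv.json
```

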