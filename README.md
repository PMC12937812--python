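# nfsim

Simulated closed-loop fMRI neurofeedback studies, end to end.

Real-time fMRI neurofeedback (rt-fMRI-NF) trains participants to
self-modulate brain activity: a classifier decodes each incoming BOLD
volume and drives a visual display (here, a flashing cross) that the
participant tries to control through motor imagery. Studies of this
design — e.g. motor-imagery training in movement disorders, with paced
finger tapping before and after the intervention — rest on a chain of
computations: online volume preprocessing, linear SVM decoding,
latency-aware display logic, TR-wise outcome scoring, inter-tap-interval
behavioral metrics, event-related GLMs of "successful imagery", and
group-level covariate maps. Human BOLD data from such trials are rarely
shareable, so none of this chain is easy to test.

`nfsim` re-creates the whole chain on synthetic data with known ground
truth. It generates seeded six-run sessions (tapping, tapping, imagery,
imagery, tapping, tapping at TR = 2 s) with planted motor-network
activation, drift, motion-coupled nuisance and Gaussian noise, then runs
them through the same analysis path a real study uses. Every stage is
testable for recovery (does the decoder find the planted network? do
covariate clusters land on the coupled region?) and calibration (are
voxelwise false-positive rates nominal?).

## The computations at the core

- **Decoder.** A linear SVM `f(x) = w·x + b` over analysis-mask voxels
  (brain mask minus a visual-cortex exclusion mask, resampled with a
  20% voxel-occupancy rule), trained on tapping-vs-rest TRs of runs 1–2
  with labels shifted ~4 s for hemodynamic delay. Feedback is driven by
  the signed distance to the hyperplane.
- **Online contract.** Each incoming volume is residualized against
  intercept, linear trend and six motion series estimated *only on the
  volumes acquired earlier in the same run* (with the known block
  regressor protecting the fit from absorbing task signal), then
  smoothed — no future data ever touches a decode.
- **Feedback state machine.** The display at TR *t* reflects the decode
  of volume *t − 2* (the 4 s transport latency); the two leading
  practice blocks show the ideal pattern and kick-start the nuisance
  history. Each displayed TR is scored TP/FP/TN/FN against its block
  condition; ITAP accuracy = TP/(TP+FN), noITAP accuracy = TN/(TN+FP),
  overall = (TP+TN)/all scored.
- **Tapping metrics.** Instantaneous rate 1/Δt per tap pair; run score
  is the RMSE of rate deviations from the instructed pace (1 or 4 Hz);
  missed taps per gap are max(0, round(Δt·rate) − 1) over ideal taps;
  the improvement score is ΔRMSE = RMSE(run 2) − RMSE(run 5).
- **GLM.** Canonical double-gamma HRF; first-level OLS with
  successful-imagery (true-ITAP) and other-imagery stick regressors;
  group one-sample t maps; ΔRMSE covariate t maps controlling for a
  clinical severity score; p < 0.001 voxel threshold with cluster-extent
  k under face connectivity; ROI means and Spearman correlations.
- **Group statistics.** One-sample t (raw or summary-statistic input),
  balanced repeated-measures ANOVA with Mauchly sphericity checks and
  conditional Greenhouse–Geisser correction, signed-rank Wilcoxon with
  tie/continuity-corrected Z, Spearman's rho.

## Worked example

```python
from nfsim.synthetic import generate_session
from nfsim.classifier import (offline_preprocess, train_classifier,
                              evaluate_held_out,
                              task_regressor_from_schedule)
from nfsim.feedback import run_feedback, score_trace

session = generate_session(subject_id=0, seed=42)
pre = [offline_preprocess(session.runs[r][0],
                          session.truth.motion_params[r],
                          task_regressor=task_regressor_from_schedule(
                              session.runs[r][1]))
       for r in (1, 2)]
model = train_classifier(pre, [session.runs[r][1] for r in (1, 2)],
                         session.masks)

trace = run_feedback(model, session.runs[3][0], session.runs[3][1],
                     session.truth.motion_params[3])
counts, acc = score_trace(trace)
print(f"imagery run 3: TP={counts.tp} FP={counts.fp} "
      f"TN={counts.tn} FN={counts.fn}")
print(f"ITAP accuracy {acc.itap_acc:.1%}, noITAP accuracy "
      f"{acc.noitap_acc:.1%}, overall {acc.overall_acc:.1%}")

held = evaluate_held_out(model, [session.runs[r][0] for r in (5, 6)],
                         [session.runs[r][1] for r in (5, 6)],
                         [session.truth.motion_params[r] for r in (5, 6)])
print(f"held-out runs 5-6: tap {held['tap_accuracy']:.1%}, "
      f"rest {held['rest_accuracy']:.1%}, "
      f"overall {held['overall_accuracy']:.1%}")
```

prints

```
imagery run 3: TP=24 FP=7 TN=39 FN=21
ITAP accuracy 53.3%, noITAP accuracy 84.8%, overall 69.2%
held-out runs 5-6: tap 85.6%, rest 94.3%, overall 89.9%
```

The decoder generalizes near 90% to the held-out tapping runs (its
positive control), while imagery accuracy sits modestly above chance —
the weaker planted imagery amplitude emulates how much harder covert
imagery is to decode than overt movement.

A full 16-subject study — cohort generation, per-subject training,
neurofeedback replay, behavioral scoring, first-level and group GLMs,
and the behavioral test battery — runs from the command line:

```bash
nfsim run-all --seed 1 --out study_out/
```

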