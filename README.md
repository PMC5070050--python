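# dyadkin

Motion-feature extraction and validation statistics for dual-sensor
parent–infant interaction recordings ("interaction imaging").

Clinicians and developmental researchers rate the quality of early
mother–infant interaction with global instruments such as the CIB
(Coding Interactive Behavior, 43 codes averaged into composites rated
1–5). `dyadkin` targets the complementary, fully automatic route: two
RGB-D sensors each track one partner's 3D skeleton during a short
tabletop play session, and the package turns the two streams into a
fixed vector of interpretable motion features, then asks whether those
features carry the clinically rated signal.

The pipeline is:

1. **Co-registration** — a rigid transform `p ↦ R p + t` between the two
   sensor frames is fitted by SVD least squares (Kabsch/Umeyama) to
   corresponding calibration points, and the clock offset by normalised
   cross-correlation of two hand-clap audio envelopes, refined to
   sub-sample precision.
2. **Feature extraction** — from the aligned recording, per partner the
   quantity of movement `qom[i] = Σ_j ‖p_j[i] − p_j[i−1]‖ / Δt` and the
   motion-activity ratio (time-smoothed `qom > θ` state); dyadically the
   inter-head distance and each partner's contribution to its change,
   the fraction of time face-to-face or oriented to the task, and three
   couplings of the two activity states: the directional synchrony
   ratio (movement onsets answered within a 3 s window), the overlap
   ratio (both moving) and the pause ratio (both still) — 17 features
   per session.
3. **Validation** — Spearman correlation of each feature with each of 8
   CIB composites under Holm step-down correction, nonparametric group
   tests (exact rank-sum, Fisher), and linear-kernel SVM classification
   of high-risk vs low-risk dyads under seeded stratified k-fold
   cross-validation.

No clinical recordings ship with the package; a synthetic dyad
generator (`dyadkin.simulate`) produces sessions with known ground
truth — two-state Markov activity, onset response coupling, gaze bouts,
tracker dropout and jitter, and CIB-like composites monotonically
linked to the generator's true parameters — so every stage is testable
end to end. See `docs/methods.md` for the model details.

## Worked example

```python
import pandas as pd
import dyadkin as dk

# a 10+10 cohort: control vs at-risk generator presets, 4 min at 30 Hz
sessions, cib, labels = dk.simulate_cohort(10, seed=42)

rows = []
for (sid, rec, truth), lab in zip(sessions, labels):
    fs = dk.extract_feature_vector(
        rec, session_id=sid, group="risk" if lab else "control"
    )
    rows.append({"session_id": sid, "group": fs.group, **fs.values})
feats = pd.DataFrame(rows)

res = dk.classify_dyads(feats, labels, k=10, seed=1)
print("training:", res.training_accuracy, "cv:", res.total_accuracy)

rep = dk.correlate_features_with_cib(feats, cib.reset_index())
cell = ("pause_ratio", "dyadic_reciprocity")
print(f"rho={rep.rho.loc[cell]:.3f}  p_holm={rep.p_holm.loc[cell]:.2e}")
```

prints

```
training: 1.0 cv: 1.0
rho=0.910  p_holm=4.32e-07
```

The two generator presets differ in maternal activity, maternal
movement responsiveness and mutual gaze, so the linear classifier
separates the groups perfectly both on the training data and under
10-fold stratified cross-validation, and the planted positive link
between joint pausing and rated dyadic reciprocity survives Holm
correction with a large positive rank correlation.

The same workflow is available from the shell:

```sh
dyadkin simulate --out data --n-per-group 10 --seed 42 --split-sensors
dyadkin extract data/control01 --out runs/control01 --group control
dyadkin validate --features features.csv --cib data/cib.csv --out validation --k 10
dyadkin report --correlations validation/correlations.csv
```

With `--split-sensors` each session is written as two raw sensor
captures (misaligned frames and clocks) plus calibration-point and
clap-envelope fixtures, and `extract` re-estimates the registration
before computing features.

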