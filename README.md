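# gaitspeed

Estimation of instantaneous bipedal motion speed (walking **and** running,
km/h) from raw windows of leg-worn IMU sensors — 3-axis accelerometer +
3-axis gyroscope at the thigh, shin and/or foot — without hand-designed gait
features.  The intended users are researchers in wearable-sensor
biomechanics and inertial navigation (pedestrian dead reckoning) who need a
speed estimate that keeps working where classical features such as
zero-velocity updates degrade, e.g. during running or with cheap saturating
sensors.

## Method

The core model is a **semi-supervised variational autoencoder with a
weighted-sine decoder**.  A convolutional encoder maps a 2 s raw window
`X ∈ ℝ^{C×1024}` (512 Hz) to a Gaussian posterior `q(z|X) = N(μ(X), diag σ(X)²)`;
a draw `z = μ + σ∘ε` feeds both a dense speed-prediction head `h(z)` and a
decoder that reconstructs the window as a sum of H weighted sine waves,

    X̂[c, τ] = Σ_k (W₁z)[c,k] · sin((W₂z)_k · τ + (W₃z)_k),

exploiting the quasi-periodicity of gait.  Training minimizes, per window
and at one shared latent draw,

    α‖y − h(z)‖² + ‖X − X̂‖² + β·KL(q(z|X) ‖ N(0, I)),

so the unsupervised reconstruction regularizes the supervised regression —
valuable on small multi-subject cohorts.  Evaluation is leave-one-subject-out
(LOSO): each subject serves once as a fully unseen test set, and the metric
is the mean over subjects of the per-subject mean absolute error in km/h.

The surrounding pipeline — 20-column recording I/O with fixed count→unit
multipliers (0.0024 → m/s², 0.061 → deg/s, saturation at ±80 m/s² / ±2000
deg/s), resampling of irregular ~400 Hz streams to 512 Hz, center-labeled
windowing, rotation + relative-noise augmentation of training folds,
patience-20 early stopping, uniform random hyper-parameter search, and a
sensor-placement study — is included, together with a synthetic gait-signal
generator so everything is testable without real recordings.  See
`docs/methods.md` for the model details and design decisions.

## Worked example

```python
import numpy as np
from gaitspeed import SVAERegressor, SensorSelection, convert_units
from gaitspeed.preprocess import resample_uniform, make_windows, WindowSet
from gaitspeed.synthetic import synthesize_cohort
from gaitspeed.train_eval import split_train_val

# three synthetic subjects, 2 min each, foot sensor only (6 channels)
recs = [convert_units(r) for r in synthesize_cohort(3, 120.0, seed=2)]
sel = SensorSelection(("foot",))
windows = {r.subject_id: make_windows(resample_uniform(r, sel=sel), stride=512)
           for r in recs}

# train on S01+S02, hold out S03 entirely
pool = WindowSet.concatenate([windows["S01"], windows["S02"]])
train, val = split_train_val(pool, rng=np.random.default_rng(0))
model = SVAERegressor(decoder="sine", latent_len=64, n_sine=10,
                      normalize_tau=True, beta=1e-4, batch_size=32,
                      max_epochs=15, seed=0)
model.fit(train.X, train.y, X_val=val.X, y_val=val.y)

test = windows["S03"]
pred = model.predict(test.X)
mae = np.mean(np.abs(pred - test.y))
baseline = np.mean(np.abs(test.y - pool.y.mean()))
print(f"unseen-subject MAE {mae:.2f} km/h (constant-mean baseline {baseline:.2f})")
```

Output:

```
unseen-subject MAE 3.46 km/h (constant-mean baseline 5.38)
```

The model, trained on two subjects, estimates the third, fully unseen
subject's speed with ~3.5 km/h mean error over a 1–24 km/h speed range —
well below the ~5.4 km/h error of always predicting the training mean.
Two training subjects are a deliberately tiny example; the 6-subject
leave-one-subject-out experiment in `scripts/acceptance.py` roughly halves
this error, and larger cohorts with longer training shrink it further.

The same experiments are scriptable from the shell:

```bash
gaitspeed simulate  --out data/ --n-subjects 6 --duration 300 --seed 1
gaitspeed loocv     --data-dir data/ --out results/ --placements foot --epochs 15
gaitspeed placement --data-dir data/ --out results_placement/ --epochs 15
```

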