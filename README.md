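# vibroscreen

Screening for depression and anxiety from head–neck micro-vibrations,
side by side with the Zung self-rating scales.

Affective state modulates involuntary micro-movements of the head and
neck (the vestibulo-emotional reflex): 0.1–10 Hz oscillations with
amplitudes of ~10–1000 μm, invisible to the eye but measurable from
video. `vibroscreen` implements the full analysis stack for evaluating
such an AI screen against self-report scales and a clinical gold
standard, for biostatisticians and methods researchers working on
objective psychiatric screening:

* **Vibration imaging** — per-pixel amplitude maps
  `A(x,y) = (1/N) Σᵢ |U_{x,y,i} − Ū_{x,y}|` and dominant-frequency maps
  `F(x,y) = argmax_{f∈B} |STFT{s_{x,y}(t)}(f)|` over B = 0.1–10 Hz,
  with regional mean/variance/entropy and spectral features.
* **CNN–BiLSTM dual-risk scorer** — a residual CNN encodes 8-frame time
  slices into vectors z_t; a bidirectional LSTM aggregates them into a
  state h; parallel heads output `p_dep = σ(W_dp h + b_dep)`,
  `p_anx = σ(W_ax h + b_anx)` plus continuous severities. Implemented
  in NumPy with verified analytic gradients; trains at desk scale on
  one CPU.
* **Calibration and tiers** — temperature scaling `σ(logit(p)/T)`,
  Youden-index (J = sens + spec − 1) cutpoints, three risk tiers
  (asymptomatic/mild, moderate, severe), Brier score and reliability
  curves.
* **Zung SDS/SAS scoring** — reverse-keyed items, standard score =
  round(raw × 1.25), Chinese-norm severity bands (SDS 53/63/72+, SAS
  50/60/70).
* **Dual-axis gold standard** — keyword-quantified 1–5 clinical
  severities per axis; severity ≥ 3 is high-risk.
* **Diagnostics** — sensitivity/specificity/precision/F1, rank-based
  AUC, macro-F1, percentile bootstrap CIs (B = 1000), decision-curve
  net benefit, and logical-OR combined screens with relative-gain
  reporting.
* **Synthetic data** — seeded generators for micro-vibration videos and
  screening cohorts (98 subjects; 73 depression-positive, 52
  anxiety-positive by default), plus the six reconstructed reference
  confusion matrices.

Everything is exposed both as sklearn-style estimators
(`CNNBiLSTMClassifier`, `TemperatureScaler`, `TierStratifier`,
`ScaleScorer`, `VibrationFeatureExtractor`) that compose with sklearn
pipelines, and as a `vibroscreen` command-line tool
(`simulate · extract · train · score · calibrate · evaluate · report`).

## Worked example

Evaluate the six reconstructed reference screening matrices (98
outpatients; depression and anxiety axes; AI screen, Zung scale, and
their logical-OR combination):

```sh
vibroscreen report --fixtures --seed 1 --out report/
```

prints

```
## Depression screening

| Instrument | F1 | Precision | Recall | Specificity | Gain |
|---|---|---|---|---|---|
| scale | 0.824 | 0.813 | 0.836 | 0.440 |  |
| ai | 0.838 | 0.745 | 0.959 | 0.040 |  |
| combined | 0.847 | 0.742 | 0.986 | 0.000 | F1 ↑ 2.8%, Recall ↑ 18.0% |

- AI-unique detections: 15.1% of gold positives

## Anxiety screening

| Instrument | F1 | Precision | Recall | Specificity | Gain |
|---|---|---|---|---|---|
| scale | 0.471 | 0.480 | 0.462 | 0.435 |  |
| ai | 0.455 | 0.469 | 0.442 | 0.435 |  |
| combined | 0.590 | 0.514 | 0.692 | 0.261 | F1 ↑ 25.4%, Recall ↑ 50.0% |

- AI-unique detections: 23.1% of gold positives
```

Reading the depression rows: the AI screen catches 95.9% of the 73
clinically high-risk subjects (the scale: 83.6%) at the cost of a 4.0%
specificity; OR-combining the two raises recall to 98.6% (1 missed case
in 73) — an 18% relative recall gain — because 11 of the 73 gold
positives (15.1%) are caught *only* by the AI screen. On the anxiety
axis the two instruments perform similarly alone but see different
patients, so the combination lifts recall from 46.2% to 69.2% (+50%
relative) and F1 from 0.471 to 0.590 (+25.4%).

The same machinery runs on synthetic cohorts end to end:

```python
from vibroscreen.pipeline import RunConfig, run_pipeline, render_report

bundle = run_pipeline(RunConfig(seed=11))   # 98 subjects, 73/52 positives
print(render_report(bundle))                # scale vs AI vs OR-combined,
                                            # temperature, tier cutpoints
```

And the video path:

```python
from vibroscreen import CNNBiLSTMClassifier, roc_auc
from vibroscreen.synthetic import generate_labeled_videos

cubes, table = generate_labeled_videos(200, effect_size=2.0, seed=42)
y = table.label.to_numpy()
est = CNNBiLSTMClassifier(epochs=18, random_state=0).fit(cubes[:150], y[:150])
print(roc_auc(est.predict_scores(cubes[150:])["p_dep"], y[150:]))  # 0.93
```

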