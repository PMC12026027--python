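# mi-adapt

Motor-imagery brain–computer interfaces (MI-BCIs) decode imagined
movements (left hand, right hand, foot, tongue) from EEG, but how well
they work varies enormously between people — a sizeable fraction of
healthy users never exceeds 70% decoding accuracy.  `mi-adapt` is a
tested, reusable pipeline for quantifying a subject's **MI-BCI
adaptability** and relating it to properties of their **functional brain
networks**, aimed at BCI researchers who want a reproducible way to
screen candidate users or to study the network correlates of imagery
skill.

Because human EEG of this kind is rarely shareable, the package includes
a first-class synthetic-data module that emulates the whole acquisition —
a balanced 4-class imagery paradigm, band-limited oscillations over pink
noise, event-related desynchronization (ERD), and ground-truth
phase-lagged coupling between chosen channel pairs — so every stage of
the analysis can be validated against a known answer.

## What it computes

**Adaptability.** For each subject, each of the six task pairs
(LH–RH, LH–F, LH–T, RH–F, RH–T, F–T) is classified with a linear SVM
under stratified 10-fold cross-validation, and the adaptability score is
the mean of the six accuracies.  Four feature routes are implemented,
with fixed dimensionalities on a 35+35-epoch pair:

| method  | features per epoch | content |
|---------|--------------------|---------|
| PSD     | 21 | band-mean multitaper power, 8–30 Hz, 21 sensorimotor channels |
| WPD+DWT | 36 | 12 wavelet sub-bands × (mean, SD, mean power) |
| RF      | 12 | 6 bands × Riemannian distances δ(C, Ḡ₁), δ(C, Ḡ₂) to class-mean covariances |
| FBCSP   | 24 | 6 bands × 4 CSP log-variance features |

All trainable steps (CSP filters, Riemannian class means,
standardization) are fitted inside training folds only; the extractors
are scikit-learn transformers, so they drop into ordinary `Pipeline` /
`cross_val_score` machinery.

**Functional networks.** Connectivity is the weighted phase lag index
between channels x and y,

    WPLI_xy = | ⟨ im S_xy ⟩ |  /  ⟨ | im S_xy | ⟩ ,

with the cross-spectrum S_xy observed at every time sample of the
band-limited analytic signals, pooled over epochs (α 8–12, β1 13–20,
β2 20–30 Hz; 0/0 ≡ 0).  The 60×60 matrix is binarized by keeping the top
10% of connections (177 edges of 1770 pairs), and the binary graph is
summarized per node by degree k, clustering coefficient C, nodal path
length, local efficiency E and betweenness centrality BC, then averaged
over 15 key electrodes per hemisphere (KL/KR, CL/CR, …) together with
left-minus-right differences (KD, CD, …).

**Screening.** Each network property is correlated with each method's
adaptability across subjects (Pearson), and flagged significant when
p < 0.05 **and** |r| > 0.273 (the two-sided 5% critical correlation with
df = 50).

## Worked example

One synthetic subject, 30 key electrodes, 12 trials per task, with
moderate ERD and tongue-conditional β2 coupling in the right hemisphere:

```python
from miadapt import (BANDS, Coupling, Erd, KEY_30, SynthSpec,
                     compute_adaptability, generate_paradigm,
                     hemisphere_summary, node_metrics, run_preprocess,
                     simulate_recording, threshold_top_fraction,
                     wpli_matrix)

schedule = generate_paradigm(sets=1, trials_per_set=48, imagery_s=3.0,
                             rest_s=1.5, seed=11)
spec = SynthSpec(
    montage=KEY_30, fs=250.0, snr=0.15,
    erd=(Erd("left_hand", ("C4", "C6", "CP4"), attenuation=0.3),
         Erd("right_hand", ("C3", "C5", "CP3"), attenuation=0.3),
         Erd("foot", ("C1", "C2", "CP1", "CP2"), attenuation=0.3),
         Erd("tongue", ("FC3", "FC4", "F3", "F4"), attenuation=0.3)),
    coupling=tuple(Coupling(a, b, band=(20.0, 30.0), strength=0.8, task="tongue")
                   for a, b in [("C2", "C4"), ("C4", "C6"), ("CP2", "CP4")]),
    seed=11,
)
rec = simulate_recording(schedule, spec)
epochs = run_preprocess(rec, keep=spec.montage, target_fs=250.0,
                        window=(0.25, 2.5), per_task_keep=12)

score = compute_adaptability(epochs, method="psd", folds=10, seed=11)
for (a, b), acc in score.pairwise.items():
    print(f"{a:>10} vs {b:<10} accuracy = {acc:.3f}")
print(f"adaptability (mean of 6 pairs) = {score.mean:.3f}")

cm = wpli_matrix(epochs, BANDS["beta2"], task="tongue")
net = threshold_top_fraction(cm, fraction=0.10)
summary = hemisphere_summary(node_metrics(net), net)
print(f"tongue beta2 network: {net.n_edges} edges retained")
print(f"mean right-hemisphere degree KR = {summary.KR:.2f}, "
      f"left KL = {summary.KL:.2f}, difference KD = {summary.KD:.2f}")
```

prints

```
 left_hand vs right_hand accuracy = 0.917
 left_hand vs foot       accuracy = 1.000
 left_hand vs tongue     accuracy = 0.917
right_hand vs foot       accuracy = 1.000
right_hand vs tongue     accuracy = 0.967
      foot vs tongue     accuracy = 1.000
adaptability (mean of 6 pairs) = 0.967
tongue beta2 network: 44 edges retained
mean right-hemisphere degree KR = 3.33, left KL = 2.53, difference KD = -0.80
```

A high-skill subject: every imagery pair classifies above 0.9, and the
right hemisphere (which carries the simulated tongue-task coupling) has
a visibly higher mean degree than the left in the thresholded β2
network.

## Command line

Each pipeline stage is also exposed as a subcommand over a single YAML
config: `mi-adapt simulate | preprocess | features | adaptability |
connectivity | metrics | screen | run-all`, e.g.

```bash
mi-adapt run-all --config study.yaml --out study_out
```

`run-all` simulates a cohort whose per-subject "skill" scales both ERD
depth and right-hemisphere coupling, runs every stage, and writes
adaptability tables, network-property tables, the screening grid and a
hashed run manifest; re-running the same config is bit-identical.

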