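# emgait

Gait-phase classification and gait-event prediction from surface EMG.

`emgait` is for movement scientists and biomedical engineers who want to
estimate *when* the foot is on the ground — and the timing of heel-strike
(HS) and toe-off (TO) — from muscle activity alone, without foot-switches,
pressure mats or IMUs. It implements the full chain from raw multi-channel
sEMG to scored gait events, plus a synthetic gait/EMG simulator so every
stage can be exercised end-to-end without access to recorded data.

## The method

Ten sEMG channels (tibialis anterior, gastrocnemius lateralis, medial
hamstrings, vastus lateralis, rectus femoris — both legs) sampled at 2 kHz
are band-passed (20–450 Hz FIR), rectified, smoothed (zero-phase 2nd-order
Butterworth, 5 Hz) and min–max normalized per subject into envelopes
*e_m(t) ∈ [0, 1]*. Non-overlapping 20-sample windows from the ten channels
are interleaved into 200-sample vectors **x** and labeled by the binary
foot–floor-contact signal (0 = stance, 1 = swing); windows containing a
transition are masked. A multi-layer perceptron (200–512–256–128–1, ReLU,
sigmoid output, label 1 iff σ(z) > 0.5) is trained with SGD (lr 0.01) on
binary cross-entropy, early-stopped on the accuracy of a chronological
validation tail (patience 10, best weights restored).

Arranged chronologically, the predicted labels reconstruct the contact
signal; phases shorter than 175 ms are rejected as spikes, HS/TO are read
off the 1→0 / 0→1 transitions, and predictions are matched to ground truth
within a tolerance T (600 ms default, 50 ms strict):

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2·precision·recall / (precision + recall),
    MAE = mean |t_g − t_p|  over matched pairs.

Two protocols are built in: **intra-subject** (10-fold cross-validation
over contiguous time slots of one subject's walk) and **inter-subject**
(leave-one-subject-out over a cohort), with a Shapiro–Wilk-gated
t test / Kruskal–Wallis comparison between them.

## Worked example

```python
from emgait import (
    GaitSimParams, MLPConfig, StudyConfig, generate_subject,
)
from emgait.protocols import run_intra_subject

rec = generate_subject(GaitSimParams(duration_s=300.0, seed=1), "S1")
cfg = StudyConfig(seed=1, mlp=MLPConfig(max_epochs=30, patience=10))
report = run_intra_subject(rec, cfg)

for metric in ("test_accuracy", "hs_mae_ms", "to_mae_ms"):
    mean, sd = report.summary[metric]
    print(f"{metric}: {mean:.3f} ± {sd:.3f}")
```

Output (a few minutes on one CPU):

```
test_accuracy: 0.987 ± 0.002
hs_mae_ms: 4.748 ± 0.875
to_mae_ms: 17.062 ± 2.535
```

Read: averaged over the 10 folds, 98.7 % of unseen 10-ms windows of this
synthetic subject are classified into the correct phase, predicted
heel-strikes land within ~5 ms of ground truth on average and toe-offs
within ~17 ms — toe-off is the harder event, as the plantar-flexor
activity that precedes it fades gradually. Synthetic walks are strictly
phase-locked and noise-stationary, so these figures are an upper bound on
what identical machinery achieves on real recordings.

The same workflow runs from the shell:

```bash
emgait simulate --subjects 5 --duration-s 180 --heterogeneity 0.5 \
    --seed 7 --out data/
emgait run-intra --data data/S1.csv --events data/S1_events.csv \
    --seed 7 --out intra_S1.json
emgait run-inter --data data/ --seed 7 --out inter.json
emgait compare --a intra_S1.json --b inter.json --metric hs_mae_ms
```

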